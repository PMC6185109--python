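"""Genome coordinate frame: chromosomes, bin grids and optional mappability.

Everything downstream (copy tracks, binned profiles, region calls) lives on
the bin grid defined here. Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeSpec"]


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with a shared bin width.

    Parameters
    ----------
    chroms:
        Ordered ``(name, length)`` pairs; lengths in bases, > 0.
    bin_width:
        Width of the analysis bins in bases (default 1000). The last bin of
        each chromosome may be shorter than ``bin_width``.
    mappability:
        Optional per-bin fraction of uniquely mappable positions in [0, 1],
        one array per chromosome covering every bin. ``None`` means fully
        mappable.
    """

    chroms: tuple[tuple[str, int], ...]
    bin_width: int = 1000
    mappability: dict[str, np.ndarray] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValueError("GenomeSpec needs at least one chromosome")
        object.__setattr__(self, "chroms", tuple((str(n), int(l)) for n, l in self.chroms))
        names = [n for n, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        if self.mappability is not None:
            for name in names:
                if name not in self.mappability:
                    raise ValueError(f"mappability missing chromosome {name!r}")
                m = np.asarray(self.mappability[name], dtype=float)
                if m.shape != (self.n_bins(name),):
                    raise ValueError(
                        f"mappability for {name!r} has {m.shape[0]} bins, "
                        f"expected {self.n_bins(name)}"
                    )
                if np.any(m < 0) or np.any(m > 1):
                    raise ValueError(f"mappability for {name!r} outside [0, 1]")
                self.mappability[name] = m

    # -- grid helpers -----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for n, l in self.chroms:
            if n == chrom:
                return l
        raise KeyError(chrom)

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_width)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(n) for n in self.names)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_width

    def bin_ends(self, chrom: str) -> np.ndarray:
        ends = self.bin_starts(chrom) + self.bin_width
        return np.minimum(ends, self.length(chrom))

    def bin_centers(self, chrom: str) -> np.ndarray:
        return (self.bin_starts(chrom) + self.bin_ends(chrom)) / 2.0

    def mappability_of(self, chrom: str) -> np.ndarray:
        if self.mappability is None:
            return np.ones(self.n_bins(chrom))
        return self.mappability[chrom]

    def with_bin_width(self, bin_width: int) -> "GenomeSpec":
        """Same chromosomes on a different bin grid (mappability dropped)."""
        return GenomeSpec(chroms=self.chroms, bin_width=bin_width)
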