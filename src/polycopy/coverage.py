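"""Read-depth profiles: binning, RPM normalization, log2 ratios, smoothing.

The observable the whole pipeline works on is a per-bin read count track,
normalized to reads per million (RPM), compared against a uniform-copy
control sample as a smoothed log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "BinnedProfile",
    "RatioProfile",
    "bin_reads",
    "normalize_rpm",
    "log2_ratio",
    "smooth",
    "window_depth",
]

RPM_SCALE = 1e6


@dataclass
class BinnedProfile:
    """Per-bin integer read counts, optionally RPM-normalized.

    ``counts[chrom]`` covers every bin of ``genome``'s grid; ``rpm`` is
    ``None`` until :func:`normalize_rpm` is applied and then sums to 1e6
    across the genome.
    """

    genome: GenomeSpec
    counts: dict[str, np.ndarray]
    rpm: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for name in self.genome.names:
            if name not in self.counts:
                raise ValueError(f"counts missing chromosome {name!r}")
            c = np.asarray(self.counts[name])
            if c.shape != (self.genome.n_bins(name),):
                raise ValueError(
                    f"counts for {name!r}: {c.shape[0]} bins, expected "
                    f"{self.genome.n_bins(name)}"
                )
            if np.any(c < 0):
                raise ValueError(f"negative counts on {name!r}")
            self.counts[name] = c

    @property
    def total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    @property
    def normalized(self) -> bool:
        return self.rpm is not None

    def to_bedgraph(self, which: str = "counts") -> pd.DataFrame:
        values = self.counts if which == "counts" else self.rpm
        if values is None:
            raise ValueError("profile is not RPM-normalized")
        frames = []
        for name in self.genome.names:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "start": self.genome.bin_starts(name),
                        "end": self.genome.bin_ends(name),
                        "value": values[name],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class RatioProfile:
    """Per-bin log2(sample/control); NaN marks bins missing in both inputs."""

    genome: GenomeSpec
    values: dict[str, np.ndarray]
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        for name in self.genome.names:
            if name not in self.values:
                raise ValueError(f"values missing chromosome {name!r}")
            v = np.asarray(self.values[name], dtype=float)
            if v.shape != (self.genome.n_bins(name),):
                raise ValueError(f"values for {name!r} do not tile the bin grid")
            self.values[name] = v

    def to_bedgraph(self) -> pd.DataFrame:
        frames = []
        for name in self.genome.names:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "start": self.genome.bin_starts(name),
                        "end": self.genome.bin_ends(name),
                        "value": self.values[name],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def bin_reads(
    reads: pd.DataFrame, genome: GenomeSpec, bin_width: int | None = None
) -> BinnedProfile:
    """Count reads per bin, assigning each read by its start coordinate.

    ``reads`` is a BED3-like frame with ``chrom``/``start`` (``end`` ignored
    for assignment). Reads on chromosomes absent from ``genome`` raise.
    """
    if bin_width is not None and bin_width != genome.bin_width:
        genome = genome.with_bin_width(bin_width)
    known = set(genome.names)
    bad = sorted(set(reads["chrom"].unique()) - known)
    if bad:
        raise ValueError(f"reads on unknown chromosomes: {', '.join(map(str, bad))}")
    counts: dict[str, np.ndarray] = {}
    grouped = dict(iter(reads.groupby("chrom", observed=True)))
    for name in genome.names:
        n = genome.n_bins(name)
        if name in grouped:
            starts = grouped[name]["start"].to_numpy(dtype=np.int64)
            if starts.size and (starts.min() < 0 or starts.max() >= genome.length(name)):
                raise ValueError(f"read start outside chromosome {name!r}")
            counts[name] = np.bincount(starts // genome.bin_width, minlength=n)[:n]
        else:
            counts[name] = np.zeros(n, dtype=np.int64)
    return BinnedProfile(genome=genome, counts=counts)


def profile_from_counts(genome: GenomeSpec, counts: dict[str, np.ndarray]) -> BinnedProfile:
    return BinnedProfile(genome=genome, counts={k: np.asarray(v) for k, v in counts.items()})


def normalize_rpm(profile: BinnedProfile) -> BinnedProfile:
    """Scale counts so they sum to one million across the genome."""
    total = profile.total
    if total <= 0:
        raise ValueError("cannot RPM-normalize a profile with zero total reads")
    rpm = {name: c * (RPM_SCALE / total) for name, c in profile.counts.items()}
    return BinnedProfile(genome=profile.genome, counts=profile.counts, rpm=rpm)


def log2_ratio(
    sample: BinnedProfile, control: BinnedProfile, pseudocount: float = 0.5
) -> RatioProfile:
    """Per-bin log2((rpm_sample + pc) / (rpm_control + pc)).

    Bins where both raw counts are zero are flagged missing (NaN) rather
    than carrying a pseudocount artifact. Requires both profiles normalized
    on the same bin grid.
    """
    if sample.genome.names != control.genome.names or (
        sample.genome.bin_width != control.genome.bin_width
    ):
        raise ValueError("sample and control are on different bin grids")
    if not sample.normalized or not control.normalized:
        raise ValueError("log2_ratio requires RPM-normalized profiles")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values: dict[str, np.ndarray] = {}
    for name in sample.genome.names:
        s = sample.rpm[name]
        c = control.rpm[name]
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.log2((s + pseudocount) / (c + pseudocount))
        missing = (sample.counts[name] == 0) & (control.counts[name] == 0)
        v = np.where(missing, np.nan, v)
        values[name] = v
    return RatioProfile(genome=sample.genome, values=values, smoothing_window=1)


def center_background(profile: RatioProfile) -> RatioProfile:
    """Shift a log2 ratio track so the copy-neutral background sits at zero.

    Total-read scaling makes ratios sum-preserving, not background-
    preserving: depleted or amplified regions shift every other bin's ratio
    away from zero by the sample's copy-mass imbalance. The background mode
    is located with the shorth (midpoint of the shortest interval holding
    half the bins) — unlike the plain median it is robust to the one-sided
    contamination that depleted domains add to the left tail — and
    subtracted, restoring log2 = 0 for the fully replicated baseline.
    """
    v = np.sort(
        np.concatenate([profile.values[n] for n in profile.genome.names])
    )
    v = v[np.isfinite(v)]
    if v.size == 0:
        return profile
    k = max(1, v.size // 2)
    widths = v[k:] - v[: v.size - k]
    i = int(np.argmin(widths)) if widths.size else 0
    shift = float((v[i] + v[min(i + k, v.size - 1)]) / 2.0)
    return RatioProfile(
        genome=profile.genome,
        values={n: vals - shift for n, vals in profile.values.items()},
        smoothing_window=profile.smoothing_window,
    )


def median_log2_ratio(profile: BinnedProfile, pseudocount: float = 0.5) -> RatioProfile:
    """Per-bin log2 depth relative to the genome-wide median RPM.

    The self-comparison track used to find depleted bins within a single
    sample (e.g. control-sample artifacts from mappability dips). Zero-count
    bins stay defined — strongly negative via the pseudocount — because a
    coverage hole is exactly what this track must expose.
    """
    if not profile.normalized:
        raise ValueError("median_log2_ratio requires an RPM-normalized profile")
    all_rpm = np.concatenate([profile.rpm[n] for n in profile.genome.names])
    baseline = float(np.median(all_rpm[all_rpm > 0]))
    values = {
        name: np.log2((profile.rpm[name] + pseudocount) / (baseline + pseudocount))
        for name in profile.genome.names
    }
    return RatioProfile(genome=profile.genome, values=values, smoothing_window=1)


def smooth(profile: RatioProfile, window_bins: int = 9) -> RatioProfile:
    """Centered moving average ignoring missing bins.

    Edges use the available asymmetric window; bins missing on input stay
    missing on output. ``window_bins`` must be odd (1 = identity).
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError(f"smoothing window must be a positive odd integer, got {window_bins}")
    if window_bins == 1:
        return replace(profile, values=dict(profile.values), smoothing_window=1)
    kernel = np.ones(window_bins)
    out: dict[str, np.ndarray] = {}
    for name, v in profile.values.items():
        valid = np.isfinite(v)
        num = np.convolve(np.where(valid, v, 0.0), kernel, mode="same")
        den = np.convolve(valid.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[~valid] = np.nan  # missingness propagates
        out[name] = sm
    return RatioProfile(genome=profile.genome, values=out, smoothing_window=window_bins)


def window_depth(
    reads: pd.DataFrame, genome: GenomeSpec, window: int = 10_000
) -> BinnedProfile:
    """Read counts in fixed windows (default 10 kb); used for pericentric arms."""
    return bin_reads(reads, genome, bin_width=window)
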