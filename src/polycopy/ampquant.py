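"""Amplicon gradient quantification.

Developmental gene amplification fires one origin repeatedly; the resulting
copy-number gradient encodes two separable quantities: the peak height at
the origin (how often it fired) and the distance between the half-maximum
points on each arm (how far replication forks travelled). This module
measures both on a smoothed log2 copy-number ratio profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import RatioProfile

__all__ = [
    "AmpliconQuant",
    "find_peak",
    "half_max_coords",
    "gradient_width",
    "quantify_amplicon",
    "quantify_windows",
    "compare_genotypes",
]


@dataclass
class AmpliconQuant:
    """Peak and half-maximum geometry of one amplicon gradient.

    ``width = right - left`` in bases; ``scale`` records whether the halving
    was done on the log2 track itself or on linearized copy number.
    ``left_at_edge``/``right_at_edge`` flag arms whose profile never crossed
    half-maximum inside the analysis window.
    """

    amplicon: str
    chrom: str
    peak_coord: float
    peak_value: float
    left: float
    right: float
    scale: str = "log2"
    left_at_edge: bool = False
    right_at_edge: bool = False

    @property
    def width(self) -> float:
        return self.right - self.left

    def __post_init__(self) -> None:
        if not (self.left <= self.peak_coord <= self.right):
            raise ValueError("half-max coordinates must bracket the peak")


# ---------------------------------------------------------------------------
# array-level core


def _window_arrays(profile: RatioProfile, chrom: str, start: int, end: int):
    if chrom not in profile.values:
        raise KeyError(chrom)
    centers = profile.genome.bin_centers(chrom)
    mask = (centers >= start) & (centers < end)
    return centers[mask], profile.values[chrom][mask]


def peak_from_arrays(pos: np.ndarray, val: np.ndarray) -> tuple[float, float]:
    """Coordinate/value of the maximum; ties broken toward the window
    midpoint, then leftmost."""
    finite = np.isfinite(val)
    if not finite.any():
        raise ValueError("window contains no defined bins")
    vmax = np.max(val[finite])
    cand = np.flatnonzero(finite & (val == vmax))
    mid = (pos[0] + pos[-1]) / 2.0
    dist = np.abs(pos[cand] - mid)
    # stable lexsort: distance to midpoint first, then position (leftmost)
    best = cand[np.lexsort((pos[cand], dist))[0]]
    return float(pos[best]), float(vmax)


def _to_scale(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log2":
        return values
    if scale == "linear":
        return np.power(2.0, values)
    raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")


def halfmax_from_arrays(
    pos: np.ndarray,
    val: np.ndarray,
    peak_coord: float,
    peak_value: float,
    scale: str = "log2",
) -> tuple[float, float, bool, bool]:
    """First half-maximum crossing on each arm, linearly interpolated.

    Scanning outward from the peak, the crossing is placed between the last
    bin at or above half-maximum and the first bin below it; if an arm never
    drops below half-maximum inside the window the window edge is returned
    and flagged.
    """
    y = _to_scale(val, scale)
    y_peak = _to_scale(np.array([peak_value]), scale)[0]
    if y_peak <= 0:
        raise ValueError(f"peak value must be positive on the {scale} scale, got {y_peak}")
    target = y_peak / 2.0
    pk = int(np.argmin(np.abs(pos - peak_coord)))

    def scan(indices: np.ndarray, edge: float) -> tuple[float, bool]:
        prev_i = pk
        for i in indices:
            if not np.isfinite(y[i]):
                continue
            if y[i] <= target:
                y0, y1 = y[prev_i], y[i]
                if y1 == y0:
                    return float(pos[i]), False
                frac = (y0 - target) / (y0 - y1)
                return float(pos[prev_i] + frac * (pos[i] - pos[prev_i])), False
            prev_i = i
        return float(edge), True

    left, left_edge = scan(np.arange(pk - 1, -1, -1), pos[0])
    right, right_edge = scan(np.arange(pk + 1, len(pos)), pos[-1])
    return left, right, left_edge, right_edge


# ---------------------------------------------------------------------------
# profile-level interface


def find_peak(
    profile: RatioProfile, chrom: str, start: int, end: int
) -> tuple[float, float]:
    """Bin-center coordinate and value of the maximum smoothed signal in a window."""
    pos, val = _window_arrays(profile, chrom, start, end)
    if pos.size == 0:
        raise ValueError("window contains no bins")
    return peak_from_arrays(pos, val)


def half_max_coords(
    profile: RatioProfile,
    chrom: str,
    start: int,
    end: int,
    peak: tuple[float, float],
    scale: str = "log2",
) -> tuple[float, float, bool, bool]:
    pos, val = _window_arrays(profile, chrom, start, end)
    return halfmax_from_arrays(pos, val, peak[0], peak[1], scale=scale)


def gradient_width(q: AmpliconQuant) -> float:
    """Distance between the two half-maximum coordinates, in bases."""
    return q.width


def quantify_amplicon(
    profile: RatioProfile,
    chrom: str,
    start: int,
    end: int,
    name: str = "amplicon",
    scale: str = "log2",
) -> AmpliconQuant:
    """Peak + half-max geometry for one amplicon window."""
    pos, val = _window_arrays(profile, chrom, start, end)
    if pos.size == 0:
        raise ValueError(f"window {chrom}:{start}-{end} contains no bins")
    pc, pv = peak_from_arrays(pos, val)
    left, right, le, re = halfmax_from_arrays(pos, val, pc, pv, scale=scale)
    return AmpliconQuant(
        amplicon=name,
        chrom=chrom,
        peak_coord=pc,
        peak_value=pv,
        left=left,
        right=right,
        scale=scale,
        left_at_edge=le,
        right_at_edge=re,
    )


def quantify_windows(
    profile: RatioProfile, windows: pd.DataFrame, scale: str = "log2"
) -> list[AmpliconQuant]:
    """Quantify every window of a BED-like frame (chrom/start/end[/name])."""
    out = []
    for i, row in windows.reset_index(drop=True).iterrows():
        name = str(row["name"]) if "name" in row and pd.notna(row.get("name")) else f"amp{i}"
        out.append(
            quantify_amplicon(
                profile, row["chrom"], int(row["start"]), int(row["end"]), name=name, scale=scale
            )
        )
    return out


def quants_to_frame(quants: list[AmpliconQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "amplicon": [q.amplicon for q in quants],
            "chrom": [q.chrom for q in quants],
            "peak_coord": [q.peak_coord for q in quants],
            "peak_value": [q.peak_value for q in quants],
            "half_max_left": [q.left for q in quants],
            "half_max_right": [q.right for q in quants],
            "width": [q.width for q in quants],
            "scale": [q.scale for q in quants],
            "left_at_edge": [q.left_at_edge for q in quants],
            "right_at_edge": [q.right_at_edge for q in quants],
        }
    )


def compare_genotypes(
    quants_by_genotype: dict[str, list[AmpliconQuant]],
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-amplicon width ratio and peak difference versus a reference genotype.

    Replicates (repeated entries for one amplicon within a genotype) are
    averaged; with >= 2 replicates per genotype a Welch two-sample t-test on
    widths is reported per amplicon.
    """
    if not quants_by_genotype:
        raise ValueError("no genotypes supplied")
    genotypes = list(quants_by_genotype)
    if reference is None:
        reference = genotypes[0]
    if reference not in quants_by_genotype:
        raise KeyError(reference)

    def by_amp(quants: list[AmpliconQuant]) -> dict[str, list[AmpliconQuant]]:
        d: dict[str, list[AmpliconQuant]] = {}
        for q in quants:
            d.setdefault(q.amplicon, []).append(q)
        return d

    ref = by_amp(quants_by_genotype[reference])
    rows = []
    for gt in genotypes:
        cur = by_amp(quants_by_genotype[gt])
        for amp in ref:
            if amp not in cur:
                continue
            w_ref = np.array([q.width for q in ref[amp]], dtype=float)
            p_ref = np.array([q.peak_value for q in ref[amp]], dtype=float)
            w = np.array([q.width for q in cur[amp]], dtype=float)
            p = np.array([q.peak_value for q in cur[amp]], dtype=float)
            row = {
                "amplicon": amp,
                "genotype": gt,
                "reference": reference,
                "n_replicates": len(w),
                "width": w.mean(),
                "width_ratio": w.mean() / w_ref.mean(),
                "peak_value": p.mean(),
                "peak_diff_log2": p.mean() - p_ref.mean(),
            }
            if gt != reference and len(w) >= 2 and len(w_ref) >= 2:
                res = stats.ttest_ind(w, w_ref, equal_var=False)
                row["width_welch_p"] = float(res.pvalue)
            else:
                row["width_welch_p"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
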