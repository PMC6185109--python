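"""Small tabular statistics: ddPCR copy-number ratios, cell-count
fractions with replicate SEM, and iPOND MS1 protein roll-up.

These are the bench-adjacent summaries of the study design: droplet-digital
PCR concentrations ratioed against a fully replicated control locus,
EdU-positive cell fractions reported as percentages, and MS1 peak areas
summed per protein and normalized to histone H3.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ddpcr_ratio",
    "count_fraction",
    "replicate_fraction",
    "ipond_enrichment",
]


def _sem(values: np.ndarray) -> float:
    """Standard error of the mean, sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def ddpcr_ratio(table: pd.DataFrame, control: str | None = None) -> pd.DataFrame:
    """Per-target mean copy-number ratio to a fully replicated control.

    ``table`` columns: ``target``, ``replicate``, ``concentration`` and
    either an ``is_control`` boolean column or a ``control`` target name.
    Each replicate's target concentration is divided by that replicate's
    control concentration; mean and SEM are taken over replicates.
    """
    df = table.copy()
    if control is not None:
        df["is_control"] = df["target"] == control
    if "is_control" not in df.columns:
        raise ValueError("ddpcr_ratio needs an is_control column or a control target name")
    if (df["concentration"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    ctrl = df[df["is_control"]].set_index("replicate")["concentration"]
    if ctrl.index.has_duplicates:
        ctrl = df[df["is_control"]].groupby("replicate")["concentration"].mean()
    rows = []
    for target, grp in df[~df["is_control"]].groupby("target", sort=False):
        ratios = []
        for _, row in grp.iterrows():
            rep = row["replicate"]
            if rep not in ctrl.index:
                raise ValueError(f"no control measurement for replicate {rep!r}")
            c = ctrl.loc[rep]
            if c <= 0:
                raise ValueError(f"control concentration is zero in replicate {rep!r}")
            ratios.append(row["concentration"] / c)
        ratios = np.asarray(ratios, dtype=float)
        rows.append((target, ratios.mean(), _sem(ratios), ratios.size))
    return pd.DataFrame(rows, columns=["target", "mean_ratio", "sem", "n_replicates"])


def count_fraction(k: int, n: int, decimals: int = 1) -> float:
    """Percentage 100*k/n, half-up rounded to ``decimals`` places.

    Matches printed percentages of the form "k of n cells; x.y%".
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= k <= n):
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    pct = Decimal(100 * k) / Decimal(n)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def replicate_fraction(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-group mean percentage across biological replicates, with SEM.

    ``table`` columns: ``group``, ``replicate``, ``k``, ``n``. Each
    replicate contributes its own percentage; the group summary is the
    unweighted mean and SEM over replicates (SEM is NaN for one replicate).
    """
    rows = []
    for group, grp in table.groupby("group", sort=False):
        pcts = np.array(
            [count_fraction(int(r["k"]), int(r["n"]), decimals=6) for _, r in grp.iterrows()]
        )
        mean = float(
            Decimal(repr(float(pcts.mean()))).quantize(
                Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
            )
        )
        rows.append((group, mean, _sem(pcts), pcts.size))
    return pd.DataFrame(rows, columns=["group", "mean_percent", "sem", "n_replicates"])


def _protein_intensity(table: pd.DataFrame) -> pd.Series:
    """Sum MS1 peak areas over peptides and charge states per protein."""
    if (table["area"] < 0).any():
        raise ValueError("MS1 areas must be >= 0")
    return table.groupby("protein", sort=False)["area"].sum()


def ipond_enrichment(
    pulse: pd.DataFrame, chase: pd.DataFrame, normalizer: str = "H3"
) -> pd.DataFrame:
    """Histone-normalized protein intensities and pulse/chase enrichment.

    Input tables have columns ``protein``, ``peptide``, ``charge``, ``area``
    (one row per peptide x charge state). Protein intensity is the sum of
    its peptide/charge areas; each sample is normalized to the summed area
    of ``normalizer`` (histone H3); enrichment is normalized pulse over
    normalized chase, NaN-flagged where the chase intensity is zero.
    """
    ip = _protein_intensity(pulse)
    ic = _protein_intensity(chase)
    for name, inten in (("pulse", ip), ("chase", ic)):
        if normalizer not in inten.index or inten[normalizer] <= 0:
            raise ValueError(f"normalizer {normalizer!r} absent or zero in {name} sample")
    proteins = ip.index.union(ic.index, sort=False)
    norm_p = ip.reindex(proteins, fill_value=0.0) / ip[normalizer]
    norm_c = ic.reindex(proteins, fill_value=0.0) / ic[normalizer]
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(norm_c > 0, norm_p / norm_c, np.nan)
    return pd.DataFrame(
        {
            "protein": proteins,
            "pulse_normalized": norm_p.to_numpy(),
            "chase_normalized": norm_c.to_numpy(),
            "enrichment": enrich,
        }
    )
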