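"""End-to-end workflows and run configuration.

Two workflows tie the stages together, mirroring the study design:

* ``run_ur_pipeline`` — polytene tissue vs uniform-copy control: bin, RPM
  normalize, log2 ratio, smooth, call underreplicated regions with the
  control-overlap and minimum-length filters, then compare scaled region
  depths (UR vs fully replicated complement) with a Welch t-test.
* ``run_amp_pipeline`` — follicle-cell amplicons: per genotype, a smoothed
  log2 profile is quantified over supplied amplicon windows (peak +
  half-max width) and genotypes are compared against a reference.

Every parameter is echoed into a machine-readable manifest next to the
outputs, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .ampquant import compare_genotypes, quantify_windows, quants_to_frame
from .coverage import (
    BinnedProfile,
    RatioProfile,
    bin_reads,
    log2_ratio,
    center_background,
    median_log2_ratio,
    normalize_rpm,
    smooth,
)
from .genome import GenomeSpec
from .urcall import (
    URRegion,
    candidate_depletion_mask,
    region_read_depth,
    regions_to_frame,
    scale_samples,
    segment_depleted,
    welch_t,
)

__all__ = ["RunConfig", "run_ur_pipeline", "run_amp_pipeline", "complement_intervals"]


@dataclass
class RunConfig:
    """Run parameters; every field lands verbatim in the run manifest."""

    genome: str = ""
    sample: str = ""
    control: str = ""
    samples: dict[str, str] = field(default_factory=dict)  # genotype -> path (amp workflow)
    windows: str = ""  # amplicon windows BED (amp workflow)
    pericentric: str = ""  # pericentric annotation BED, optional
    bin_width: int = 1000
    pseudocount: float = 0.5
    smooth_window: int = 9
    theta: float = -0.5
    control_theta: float | None = None  # default: 2 * theta
    max_gap: int = 2
    min_length: int = 10_000
    halving_scale: str = "log2"
    read_length: int = 75
    seed: int = 0
    out_prefix: str = "polycopy_run"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Plain key=value config file; CLI overrides win."""
        fields = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
        cfg = cls()
        for key, value in {**fields, **overrides}.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                value = str(value).lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(value)
            elif isinstance(current, float):
                value = float(value)
            setattr(cfg, key, value)
        return cfg

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_profile(path: str | Path, genome: GenomeSpec) -> BinnedProfile:
    """Reads (BED3) or per-bin counts (bedGraph), detected by extension."""
    path = Path(path)
    if path.suffix.lower() in (".bedgraph", ".bg"):
        df = pio.read_bedgraph(path)
        counts = {
            name: np.zeros(genome.n_bins(name), dtype=np.int64) for name in genome.names
        }
        for chrom, grp in df.groupby("chrom", observed=True):
            if chrom not in counts:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            idx = grp["start"].to_numpy() // genome.bin_width
            counts[chrom][idx] = grp["value"].to_numpy().astype(np.int64)
        return BinnedProfile(genome=genome, counts=counts)
    return bin_reads(pio.read_bed(path), genome)


def complement_intervals(
    genome: GenomeSpec, *region_sets, min_length: int = 1
) -> list[tuple[str, int, int]]:
    """Genome minus the union of the given region sets, per chromosome."""
    out = []
    for name in genome.names:
        ivs = []
        for regions in region_sets:
            for r in regions:
                if isinstance(r, URRegion):
                    chrom, start, end = r.chrom, r.start, r.end
                else:
                    chrom, start, end = str(r[0]), int(r[1]), int(r[2])
                if chrom == name:
                    ivs.append((max(0, start), min(end, genome.length(name))))
        ivs.sort()
        cursor = 0
        for start, end in ivs:
            if start > cursor and start - cursor >= min_length:
                out.append((name, cursor, start))
            cursor = max(cursor, end)
        length = genome.length(name)
        if length > cursor and length - cursor >= min_length:
            out.append((name, cursor, length))
    return out


@dataclass
class URPipelineResult:
    regions: list
    audit: list
    control_calls: list
    ur_depths: pd.DataFrame
    fr_depths: pd.DataFrame
    welch: tuple[float, float, float] | None
    ratio_profile: object
    scale_factors: dict[str, float]


def run_ur_pipeline(
    config: RunConfig,
    genome: GenomeSpec | None = None,
    sample: BinnedProfile | None = None,
    control: BinnedProfile | None = None,
    pericentric=None,
    write: bool = True,
) -> URPipelineResult:
    """Underreplication profiling workflow (see module docstring).

    Inputs may be given as in-memory objects (simulated data) or read from
    the paths in ``config``.
    """
    if genome is None:
        genome = pio.read_chrom_sizes(config.genome, bin_width=config.bin_width)
    if sample is None:
        sample = _load_profile(config.sample, genome)
    if control is None:
        control = _load_profile(config.control, genome)
    if pericentric is None:
        pericentric = []
        if config.pericentric:
            bed = pio.read_bed(config.pericentric)
            pericentric = list(zip(bed["chrom"], bed["start"], bed["end"]))

    sample_n = normalize_rpm(sample)
    control_n = normalize_rpm(control)

    # stage: control self-calls — the control's own depth vs its genome-wide
    # median, given the same smoothing treatment as the sample comparison
    control_self_raw = median_log2_ratio(control_n, pseudocount=config.pseudocount)
    control_self = smooth(control_self_raw, config.smooth_window)
    # control artifacts of interest (mappability/assembly holes) are deep;
    # a stricter control threshold keeps borderline noise calls from
    # vetoing sample territory
    control_calls = segment_depleted(
        control_self,
        theta=config.control_theta if config.control_theta is not None else 2 * config.theta,
        max_gap=config.max_gap,
        min_length=config.min_length,
        raw_profile=control_self_raw if config.smooth_window > 1 else None,
    )

    # two-pass background centering: a robust-mode shift first, then a
    # median over bins outside candidate depleted neighbourhoods, so the
    # copy-neutral baseline is not dragged by the depleted mass itself
    raw_ratio = center_background(
        log2_ratio(sample_n, control_n, pseudocount=config.pseudocount)
    )
    candidates = candidate_depletion_mask(raw_ratio)
    residual = np.concatenate(
        [raw_ratio.values[n][~candidates[n]] for n in genome.names]
    )
    if residual.size and np.isfinite(residual).any():
        shift = float(np.nanmedian(residual))
        raw_ratio = RatioProfile(
            genome=genome,
            values={n: v - shift for n, v in raw_ratio.values.items()},
            smoothing_window=raw_ratio.smoothing_window,
        )
    ratio = smooth(raw_ratio, config.smooth_window)
    regions, audit = segment_depleted(
        ratio,
        control_calls=control_calls,
        theta=config.theta,
        max_gap=config.max_gap,
        min_length=config.min_length,
        pericentric=pericentric,
        raw_profile=raw_ratio if config.smooth_window > 1 else None,
        return_audit=True,
    )

    # depth statistics: UR calls vs the fully replicated complement
    euchromatic = [r for r in regions if r.label == "euchromatic"]
    fr_regions = complement_intervals(
        genome, regions, pericentric, control_calls, min_length=config.min_length
    )
    ur_depths = region_read_depth(sample, euchromatic, config.read_length)
    fr_depths = region_read_depth(sample, fr_regions, config.read_length)
    depth_frames = [df for df in (ur_depths, fr_depths) if not df.empty]
    all_depths = (
        pd.concat(depth_frames, ignore_index=True) if depth_frames else ur_depths
    )
    scaled, factors = scale_samples({"sample": all_depths}, {"sample": sample.total})
    welch = None
    if len(ur_depths) >= 2 and len(fr_depths) >= 2:
        try:
            welch = welch_t(ur_depths["depth"], fr_depths["depth"])
        except ValueError:
            welch = None

    if write:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pio.write_bedgraph(ratio.to_bedgraph(), f"{prefix}.log2.bedgraph")
        frame = regions_to_frame(audit)
        pio.write_tsv(frame, f"{prefix}.regions_audit.tsv")
        kept = regions_to_frame(regions)
        bed6 = kept.assign(
            name=[f"UR_{i}" for i in range(len(kept))],
            score=0,
            strand=".",
        )[["chrom", "start", "end", "name", "score", "strand"]]
        pio.write_bed(bed6, f"{prefix}.ur_regions.bed")
        pio.write_tsv(
            pd.concat(
                [ur_depths.assign(group="underreplicated"), fr_depths.assign(group="fully_replicated")],
                ignore_index=True,
            ),
            f"{prefix}.region_depths.tsv",
        )
        if welch is not None:
            pio.write_tsv(
                pd.DataFrame([welch], columns=["t", "df", "p"]), f"{prefix}.welch.tsv"
            )
        config.write_manifest(f"{prefix}.manifest.json")

    return URPipelineResult(
        regions=regions,
        audit=audit,
        control_calls=control_calls,
        ur_depths=ur_depths,
        fr_depths=fr_depths,
        welch=welch,
        ratio_profile=ratio,
        scale_factors=factors,
    )


@dataclass
class AmpPipelineResult:
    quants: dict[str, list]
    tables: dict[str, pd.DataFrame]
    comparison: pd.DataFrame


def run_amp_pipeline(
    config: RunConfig,
    genome: GenomeSpec | None = None,
    samples: dict[str, BinnedProfile] | None = None,
    control: BinnedProfile | None = None,
    windows: pd.DataFrame | None = None,
    reference: str | None = None,
    write: bool = True,
) -> AmpPipelineResult:
    """Amplicon quantification workflow (see module docstring)."""
    if genome is None:
        genome = pio.read_chrom_sizes(config.genome, bin_width=config.bin_width)
    if control is None:
        control = _load_profile(config.control, genome)
    if samples is None:
        if not config.samples:
            raise ValueError("amp workflow needs at least one genotype sample")
        samples = {name: _load_profile(path, genome) for name, path in config.samples.items()}
    if windows is None:
        windows = pio.read_bed(config.windows)

    control_n = normalize_rpm(control)
    quants = {}
    tables = {}
    for name, profile in samples.items():
        ratio = smooth(
            center_background(
                log2_ratio(normalize_rpm(profile), control_n, pseudocount=config.pseudocount)
            ),
            config.smooth_window,
        )
        qs = quantify_windows(ratio, windows, scale=config.halving_scale)
        quants[name] = qs
        tables[name] = quants_to_frame(qs)
    comparison = compare_genotypes(quants, reference=reference)

    if write:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            pio.write_tsv(table, f"{prefix}.{name}.halfmax.tsv")
        pio.write_tsv(comparison, f"{prefix}.genotype_comparison.tsv")
        config.write_manifest(f"{prefix}.manifest.json")
    return AmpPipelineResult(quants=quants, tables=tables, comparison=comparison)
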