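"""Synthetic polyploid genomes: endocycle underreplication, onion-skin
amplification, and read sampling.

Two generative models produce ground-truth copy-number tracks:

* **Endocycle underreplication** — a polytene tissue doubles its genome E
  times. Inside a fork-stalling domain each genome copy replicates only a
  prefix from the left edge and a suffix from the right edge per cycle
  (fork travel ~ Gamma), so the interior falls behind the 2^E baseline and
  the final relative copy number forms a flat-bottomed trough with sloped
  shoulders.

* **Onion-skin amplification** — one replication origin re-fires without
  intervening mitosis. Each round every copy covering the origin fires with
  probability ``p_fire`` and buds a child bubble spanning ``[c-L, c+R]``
  clipped to its template, producing nested bubbles whose coverage forms a
  gradient that peaks at the origin and decays with fork-travel distance.

Reads are then drawn per bin (negative binomial around depth x copy x
mappability) to emulate shallow Illumina copy-number sequencing; a paired
uniform-copy control plays the role of early-embryo DNA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import BinnedProfile
from .genome import GenomeSpec

__all__ = [
    "ForkDistance",
    "URDomainSpec",
    "AmpliconSpec",
    "ReadSimParams",
    "CopyNumberTrack",
    "SimTruth",
    "simulate_endocycles",
    "simulate_amplification",
    "expected_amplicon_profile",
    "sample_reads",
    "make_control",
    "make_copy_track",
    "ur_benchmark_implants",
    "mc_mean_log2_amplicon_profile",
]

COPY_CAP = 2 ** 20  # explicit-simulation guard
STOCHASTIC_E_LIMIT = 12  # 'auto' mode switches to expected above this


@dataclass(frozen=True)
class ForkDistance:
    """Per-firing fork travel distance.

    ``gamma`` draws Gamma(shape, scale=mean/shape); ``fixed`` always travels
    ``distance`` bases (``inf`` = unbounded, clipped only by the template).
    """

    kind: str = "gamma"
    mean: float = 30_000.0
    shape: float = 3.0
    distance: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "fixed"):
            raise ValueError(f"unknown fork-distance family {self.kind!r}")
        if self.kind == "gamma" and (self.mean <= 0 or self.shape <= 0):
            raise ValueError("gamma fork distance needs mean > 0 and shape > 0")
        if self.kind == "fixed" and self.distance < 0:
            raise ValueError("fixed fork distance must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "gamma":
            return rng.gamma(self.shape, self.mean / self.shape, size=n)
        return np.full(n, self.distance, dtype=float)

    def survival(self, d: np.ndarray) -> np.ndarray:
        """P(travel >= d)."""
        d = np.asarray(d, dtype=float)
        if self.kind == "gamma":
            return sps.gamma.sf(d, a=self.shape, scale=self.mean / self.shape)
        return (d <= self.distance).astype(float)


@dataclass(frozen=True)
class URDomainSpec:
    """A fork-stalling (underreplicating) domain.

    Per endocycle each copy replicates a Gamma(fork_mean, fork_shape) prefix
    from the left edge and an independent suffix from the right edge;
    ``stall_hard`` forbids forks from crossing the domain midpoint.
    """

    chrom: str
    start: int
    end: int
    endocycles: int = 10
    fork_mean: float = 20_000.0
    fork_shape: float = 2.0
    stall_hard: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"domain start {self.start} >= end {self.end}")
        if self.endocycles < 0:
            raise ValueError("endocycles must be >= 0")
        if self.fork_mean <= 0 or self.fork_shape <= 0:
            raise ValueError("fork_mean and fork_shape must be > 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AmpliconSpec:
    """An onion-skin amplification locus."""

    chrom: str
    origin: int
    rounds: int = 6
    p_fire: float = 1.0
    dist_left: ForkDistance = field(default_factory=ForkDistance)
    dist_right: ForkDistance = field(default_factory=ForkDistance)
    window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fire <= 1.0):
            raise ValueError("p_fire must lie in [0, 1]")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        ws, we = self.window
        if not (ws <= self.origin < we):
            raise ValueError(
                f"origin {self.origin} outside analysis window [{ws}, {we})"
            )


@dataclass(frozen=True)
class ReadSimParams:
    """Sequencing emulation: depth per copy-1 bin, read length, NB dispersion."""

    mean_depth: float = 30.0
    read_length: int = 75
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class CopyNumberTrack:
    """Per-bin relative copy number; 1 = fully replicated baseline."""

    genome: GenomeSpec
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name in self.genome.names:
            if name not in self.values:
                raise ValueError(f"copy track missing chromosome {name!r}")
            v = np.asarray(self.values[name], dtype=float)
            if v.shape != (self.genome.n_bins(name),):
                raise ValueError(f"copy track for {name!r} does not tile the bin grid")
            if np.any(v < 0):
                raise ValueError(f"negative copy number on {name!r}")
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


@dataclass
class SimTruth:
    """Everything needed to regenerate and evaluate a simulation run."""

    kind: str
    seed: int
    mode: str
    params: dict
    domains: list[dict] = field(default_factory=list)
    amplicon: dict | None = None

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _uniform_track(genome: GenomeSpec) -> dict[str, np.ndarray]:
    return {name: np.ones(genome.n_bins(name)) for name in genome.names}


def _check_nonoverlap(domains: list[URDomainSpec]) -> None:
    by_chrom: dict[str, list[URDomainSpec]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds, ds[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping domains on {chrom}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )


def _edge_survivals(dom: URDomainSpec, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle P(left fork reaches x), P(right fork reaches x)."""
    dist = ForkDistance(kind="gamma", mean=dom.fork_mean, shape=dom.fork_shape)
    d_left = centers - dom.start
    d_right = dom.end - centers
    s_left = dist.survival(d_left)
    s_right = dist.survival(d_right)
    if dom.stall_hard:
        half = dom.length / 2.0
        s_left = np.where(d_left < half, s_left, 0.0)
        s_right = np.where(d_right < half, s_right, 0.0)
    return s_left, s_right


def _expected_domain_ratio(dom: URDomainSpec, centers: np.ndarray) -> np.ndarray:
    """Exact expected relative copy number at each position.

    Coverage of a position is inherited side-wise: a copy whose material
    reaches x only from the left edge can pass coverage to its child only
    through the left fork. Tracking the expected number of copies covering
    x from both sides (a), left only (b) and right only (c) gives linear
    per-cycle recurrences:

        a' = a (1 + sl sr)
        b' = b (1 + sl) + a sl (1 - sr)
        c' = c (1 + sr) + a (1 - sl) sr

    starting from one fully covering copy (a=1); the relative copy number
    is (a + b + c) / 2^E.
    """
    sl, sr = _edge_survivals(dom, centers)
    a = np.ones_like(sl)
    b = np.zeros_like(sl)
    c = np.zeros_like(sl)
    for _ in range(dom.endocycles):
        a, b, c = (
            a * (1.0 + sl * sr),
            b * (1.0 + sl) + a * sl * (1.0 - sr),
            c * (1.0 + sr) + a * (1.0 - sl) * sr,
        )
    return (a + b + c) / 2.0 ** dom.endocycles


def _count_coverage_left_right(
    l_ext: np.ndarray, r_ext: np.ndarray, d_left: np.ndarray, d_right: np.ndarray
) -> np.ndarray:
    """#copies covering each position given per-copy edge extents."""
    counts = np.zeros(d_left.shape[0], dtype=np.int64)
    copy_block = 65_536
    bin_block = 256
    for c0 in range(0, l_ext.shape[0], copy_block):
        lc = l_ext[c0 : c0 + copy_block, None]
        rc = r_ext[c0 : c0 + copy_block, None]
        for b0 in range(0, d_left.shape[0], bin_block):
            dl = d_left[None, b0 : b0 + bin_block]
            dr = d_right[None, b0 : b0 + bin_block]
            counts[b0 : b0 + bin_block] += ((lc > dl) | (rc >= dr)).sum(axis=0)
    return counts


def simulate_endocycles(
    genome: GenomeSpec,
    domains: list[URDomainSpec],
    mode: str = "expected",
    seed: int = 0,
    copy_cap: int = COPY_CAP,
) -> tuple[CopyNumberTrack, SimTruth]:
    """Relative copy-number track after E endocycles with fork-limited domains.

    ``expected`` mode returns the exact analytic expectation (side-wise
    coverage recurrences, see ``_expected_domain_ratio``); ``stochastic``
    mode simulates every genome copy explicitly (copy count 2^E, capped);
    ``auto`` picks stochastic up to E = 12 and expected above.
    """
    if mode not in ("expected", "stochastic", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_nonoverlap(domains)
    for d in domains:
        if d.chrom not in genome.names:
            raise ValueError(f"domain on unknown chromosome {d.chrom!r}")
        if d.end > genome.length(d.chrom):
            raise ValueError(f"domain [{d.start}, {d.end}) exceeds {d.chrom} bounds")
    if mode == "auto":
        mode = "expected" if any(d.endocycles > STOCHASTIC_E_LIMIT for d in domains) else "stochastic"

    rng = np.random.default_rng(seed)
    values = _uniform_track(genome)
    truth_domains = []
    for dom in domains:
        centers = genome.bin_centers(dom.chrom)
        inside = (centers >= dom.start) & (centers < dom.end)
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            continue
        expected_ratio = _expected_domain_ratio(dom, centers[idx])
        if mode == "expected":
            ratio = expected_ratio
        else:
            n_final = 2 ** dom.endocycles
            if n_final > copy_cap:
                raise ValueError(
                    f"stochastic simulation of E={dom.endocycles} needs {n_final} "
                    f"copies (> cap {copy_cap}); use expected mode"
                )
            ratio = _stochastic_domain_ratio(dom, centers[idx], rng)
        values[dom.chrom][idx] = ratio
        truth_domains.append(
            {
                "chrom": dom.chrom,
                "start": dom.start,
                "end": dom.end,
                "endocycles": dom.endocycles,
                "fork_mean": dom.fork_mean,
                "fork_shape": dom.fork_shape,
                "stall_hard": dom.stall_hard,
                "expected_interior_ratio": float(expected_ratio.min()),
                "expected_mean_ratio": float(expected_ratio.mean()),
            }
        )
    truth = SimTruth(
        kind="endocycle",
        seed=seed,
        mode=mode,
        params={"bin_width": genome.bin_width},
        domains=truth_domains,
    )
    return CopyNumberTrack(genome=genome, values=values), truth


def _stochastic_domain_ratio(
    dom: URDomainSpec, centers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Explicit per-copy simulation of one domain; returns count / 2^E per bin."""
    dist = ForkDistance(kind="gamma", mean=dom.fork_mean, shape=dom.fork_shape)
    half = dom.length / 2.0
    # extents = how far each copy's replicated material reaches from each edge
    l_ext = np.array([float(dom.length)])
    r_ext = np.array([float(dom.length)])
    for _ in range(dom.endocycles):
        n = l_ext.shape[0]
        new_l = dist.sample(rng, n)
        new_r = dist.sample(rng, n)
        if dom.stall_hard:
            new_l = np.minimum(new_l, half)
            new_r = np.minimum(new_r, half)
        # child bubbles are clipped to their template's extent
        l_ext = np.concatenate([l_ext, np.minimum(new_l, l_ext)])
        r_ext = np.concatenate([r_ext, np.minimum(new_r, r_ext)])
    d_left = centers - dom.start
    d_right = dom.end - centers
    counts = _count_coverage_left_right(l_ext, r_ext, d_left, d_right)
    return counts / float(l_ext.shape[0])


def simulate_amplification(
    genome: GenomeSpec,
    amp: AmpliconSpec,
    mode: str = "stochastic",
    seed: int = 0,
    copy_cap: int = COPY_CAP,
) -> tuple[CopyNumberTrack, SimTruth]:
    """Onion-skin branching process at one origin.

    One copy initially spans the window. Each round every copy covering the
    origin fires with probability ``p_fire``; a firing copy buds a child
    spanning ``[c - L, c + R]`` intersected with its own span. The track is
    the number of copies covering each bin, relative to background 1.
    """
    if amp.chrom not in genome.names:
        raise ValueError(f"amplicon on unknown chromosome {amp.chrom!r}")
    ws, we = amp.window
    if ws < 0 or we > genome.length(amp.chrom):
        raise ValueError("amplicon window outside chromosome bounds")
    if mode not in ("expected", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    values = _uniform_track(genome)
    centers = genome.bin_centers(amp.chrom)
    inside = (centers >= ws) & (centers < we)
    idx = np.flatnonzero(inside)
    c = float(amp.origin)
    firing_counts: list[int] = []

    if mode == "expected":
        profile = expected_amplicon_profile(amp, centers[idx])
        values[amp.chrom][idx] = profile
        firing_counts = [int(round((1 + amp.p_fire) ** t * amp.p_fire)) for t in range(amp.rounds)]
    else:
        # reaches of each copy's span on either side of the origin
        l_reach = np.array([c - ws])
        r_reach = np.array([we - c])
        for _ in range(amp.rounds):
            n = l_reach.shape[0]
            fired = rng.random(n) < amp.p_fire
            nf = int(fired.sum())
            firing_counts.append(nf)
            if nf == 0:
                continue
            if n + nf > copy_cap:
                raise ValueError(
                    f"amplification exceeds copy cap {copy_cap}; "
                    "reduce rounds or use expected mode"
                )
            new_l = amp.dist_left.sample(rng, nf)
            new_r = amp.dist_right.sample(rng, nf)
            l_reach = np.concatenate([l_reach, np.minimum(new_l, l_reach[fired])])
            r_reach = np.concatenate([r_reach, np.minimum(new_r, r_reach[fired])])
        x = centers[idx]
        # a copy spans [c - l_reach, c + r_reach): x < c covered iff
        # l_reach >= c - x; x >= c covered iff r_reach > x - c
        counts = np.zeros(x.shape[0], dtype=np.int64)
        left_mask = x < c
        dl = c - x[left_mask]
        dr = x[~left_mask] - c
        sl = np.sort(l_reach)
        sr = np.sort(r_reach)
        counts[left_mask] = l_reach.shape[0] - np.searchsorted(sl, dl, side="left")
        counts[~left_mask] = r_reach.shape[0] - np.searchsorted(sr, dr, side="right")
        values[amp.chrom][idx] = counts.astype(float)

    pos = centers[idx]
    prof = values[amp.chrom][idx]
    truth = SimTruth(
        kind="amplicon",
        seed=seed,
        mode=mode,
        params={
            "origin": amp.origin,
            "rounds": amp.rounds,
            "p_fire": amp.p_fire,
            "window": list(amp.window),
            "dist_left": asdict(amp.dist_left),
            "dist_right": asdict(amp.dist_right),
            "bin_width": genome.bin_width,
        },
        amplicon={
            "origin": amp.origin,
            "firing_counts": firing_counts,
            "peak_copy": float(prof.max()) if prof.size else 1.0,
            "expected_halfmax_width": expected_halfmax_width(amp, pos),
        },
    )
    return CopyNumberTrack(genome=genome, values=values), truth


def expected_amplicon_profile(amp: AmpliconSpec, positions: np.ndarray) -> np.ndarray:
    """Analytic expected copy number: (1 + p_fire * S(d))^rounds per arm.

    Each copy covering a position x produces, per round, a child also
    covering x with probability p_fire * P(fork travel >= |x - c|) — the
    template clipping drops out because a parent covering x always has
    reach beyond x. The expected coverage therefore multiplies by the same
    factor every round.
    """
    x = np.asarray(positions, dtype=float)
    d_left = np.maximum(amp.origin - x, 0.0)
    d_right = np.maximum(x - amp.origin, 0.0)
    s = np.where(
        x < amp.origin, amp.dist_left.survival(d_left), amp.dist_right.survival(d_right)
    )
    return (1.0 + amp.p_fire * s) ** amp.rounds


def expected_halfmax_width(amp: AmpliconSpec, positions: np.ndarray) -> float | None:
    """Half-max width of the expected profile (log2 halving), via ampquant."""
    if positions.size < 3:
        return None
    from .ampquant import halfmax_from_arrays, peak_from_arrays

    prof = np.log2(expected_amplicon_profile(amp, positions))
    if prof.max() <= 0:
        return None
    pc, pv = peak_from_arrays(positions, prof)
    left, right, _, _ = halfmax_from_arrays(positions, prof, pc, pv, scale="log2")
    return float(right - left)


def mc_mean_log2_amplicon_profile(
    amp: AmpliconSpec,
    positions: np.ndarray,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Mean log2 copy number over many reruns of the branching process.

    The reference profile for half-maximum width measurements: because a
    measured profile is the log2 of a single realization, the comparable
    expectation averages the log2-transformed replicate profiles (averaging
    copy numbers first and taking log2 after overstates the shoulders where
    the branching process has high variance).
    """
    x = np.asarray(positions, dtype=float)
    c = float(amp.origin)
    ws, we = amp.window
    rng = np.random.default_rng(seed)
    total = np.zeros(x.size)
    d_left = c - x
    d_right = x - c
    for _ in range(n_replicates):
        l_reach = np.array([c - ws])
        r_reach = np.array([we - c])
        for _ in range(amp.rounds):
            n = l_reach.size
            fired = rng.random(n) < amp.p_fire
            nf = int(fired.sum())
            if nf == 0:
                continue
            l_reach = np.concatenate(
                [l_reach, np.minimum(amp.dist_left.sample(rng, nf), l_reach[fired])]
            )
            r_reach = np.concatenate(
                [r_reach, np.minimum(amp.dist_right.sample(rng, nf), r_reach[fired])]
            )
        sl = np.sort(l_reach)
        sr = np.sort(r_reach)
        counts = np.where(
            x < c,
            l_reach.size - np.searchsorted(sl, d_left, side="left"),
            r_reach.size - np.searchsorted(sr, d_right, side="right"),
        )
        total += np.log2(np.maximum(counts, 1))
    return total / n_replicates


def ur_benchmark_implants(
    genome: GenomeSpec,
    n_domains: int = 20,
    length_range: tuple[int, int] = (15_000, 200_000),
    copy_range: tuple[float, float] = (0.3, 0.7),
    n_small: int = 3,
    small_length_range: tuple[int, int] = (5_000, 8_000),
    small_copy: float = 0.3,
    spacing: int = 300_000,
    seed: int = 0,
) -> list[tuple[str, int, int, float]]:
    """Draw non-overlapping flat implants for caller-validation runs.

    ``n_domains`` callable-size domains plus ``n_small`` sub-minimum-length
    implants (length-filter probes), separated by at least ``spacing`` so
    calls cannot bridge neighbours. Domain lengths and copies are uniform
    over their ranges; the probes are deep (``small_copy``) and clearly
    sub-threshold in length — they test the length filter, while depth
    marginality is already exercised by the main domains.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.names
    lengths = np.concatenate(
        [
            rng.integers(length_range[0], length_range[1] + 1, size=n_domains),
            rng.integers(small_length_range[0], small_length_range[1] + 1, size=n_small),
        ]
    )
    copies = np.concatenate(
        [
            rng.uniform(copy_range[0], copy_range[1], size=n_domains),
            np.full(n_small, small_copy),
        ]
    )
    placed: list[tuple[str, int, int, float]] = []
    for length, copy in zip(lengths, copies):
        for _ in range(10_000):
            chrom = chroms[rng.integers(len(chroms))]
            max_start = genome.length(chrom) - int(length) - spacing
            if max_start <= spacing:
                continue
            start = int(rng.integers(spacing, max_start))
            end = start + int(length)
            if all(
                c != chrom or start - spacing >= e or end + spacing <= s
                for c, s, e, _ in placed
            ):
                placed.append((chrom, start, end, float(copy)))
                break
        else:
            raise ValueError("could not place implants; genome too small for spacing")
    return sorted(placed)


def make_copy_track(
    genome: GenomeSpec, implants: list[tuple[str, int, int, float]]
) -> tuple[CopyNumberTrack, SimTruth]:
    """Flat copy-number implants (chrom, start, end, copy) on a unit baseline.

    Ground-truth generator for caller-validation runs where exact interior
    copy values are prescribed rather than produced by the endocycle model.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, copy in implants:
        if chrom not in genome.names:
            raise ValueError(f"implant on unknown chromosome {chrom!r}")
        if start >= end:
            raise ValueError(f"implant start {start} >= end {end}")
        if copy < 0:
            raise ValueError("implant copy number must be >= 0")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs)
        for a, b in zip(ivs, ivs[1:]):
            if b[0] < a[1]:
                raise ValueError(f"overlapping implants on {chrom}: {a} and {b}")
    values = _uniform_track(genome)
    for chrom, start, end, copy in implants:
        centers = genome.bin_centers(chrom)
        values[chrom][(centers >= start) & (centers < end)] = copy
    truth = SimTruth(
        kind="implant",
        seed=0,
        mode="expected",
        params={"bin_width": genome.bin_width},
        domains=[
            {"chrom": c, "start": s, "end": e, "copy": v} for c, s, e, v in implants
        ],
    )
    return CopyNumberTrack(genome=genome, values=values), truth


def sample_reads(
    track: CopyNumberTrack,
    params: ReadSimParams,
    return_reads: bool = True,
) -> tuple[pd.DataFrame | None, BinnedProfile]:
    """Draw per-bin read counts and (optionally) read positions.

    Counts per bin are NB(mean = mean_depth * copy * mappability,
    dispersion); dispersion 0 means Poisson. Read starts are uniform within
    their bin; identical parameters and seed give byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    genome = track.genome
    counts: dict[str, np.ndarray] = {}
    frames = []
    for name in genome.names:
        mu = params.mean_depth * track.values[name] * genome.mappability_of(name)
        if params.dispersion == 0:
            c = rng.poisson(mu)
        else:
            n_param = 1.0 / params.dispersion
            p_param = n_param / (n_param + mu)
            c = rng.negative_binomial(n_param, p_param)
        counts[name] = c.astype(np.int64)
        if return_reads:
            total = int(c.sum())
            bin_starts = np.repeat(genome.bin_starts(name), c)
            bin_lens = np.repeat(genome.bin_ends(name) - genome.bin_starts(name), c)
            offsets = np.floor(rng.random(total) * bin_lens).astype(np.int64)
            starts = np.sort(bin_starts + offsets, kind="stable")
            ends = np.minimum(starts + params.read_length, genome.length(name))
            frames.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    profile = BinnedProfile(genome=genome, counts=counts)
    if not return_reads:
        return None, profile
    reads = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    return reads, profile


def make_control(
    genome: GenomeSpec, params: ReadSimParams, return_reads: bool = True
) -> tuple[pd.DataFrame | None, BinnedProfile]:
    """Uniform-copy control sample (the early-embryo analogue)."""
    track = CopyNumberTrack(genome=genome, values=_uniform_track(genome))
    return sample_reads(track, params, return_reads=return_reads)
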