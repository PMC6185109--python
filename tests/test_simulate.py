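"""Generative-model tests: endocycle underreplication, onion-skin
amplification, and read sampling, each checked against independent
brute-force oracles or closed-form limits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polycopy import (
    AmpliconSpec,
    CopyNumberTrack,
    ForkDistance,
    GenomeSpec,
    ReadSimParams,
    URDomainSpec,
    expected_amplicon_profile,
    make_control,
    make_copy_track,
    mc_mean_log2_amplicon_profile,
    sample_reads,
    simulate_amplification,
    simulate_endocycles,
    ur_benchmark_implants,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def brute_force_endocycle_profile(dom, centers, n_populations, seed):
    """Per-copy loop simulation of the edge-fork endocycle model."""
    rng = np.random.default_rng(seed)
    scale = dom.fork_mean / dom.fork_shape
    half = dom.length / 2.0
    means = []
    for _ in range(n_populations):
        copies = [(float(dom.length), float(dom.length))]
        for _ in range(dom.endocycles):
            children = []
            for left, right in copies:
                l_new = rng.gamma(dom.fork_shape, scale)
                r_new = rng.gamma(dom.fork_shape, scale)
                if dom.stall_hard:
                    l_new = min(l_new, half)
                    r_new = min(r_new, half)
                children.append((min(l_new, left), min(r_new, right)))
            copies.extend(children)
        counts = np.zeros(centers.size)
        for left, right in copies:
            covered = (centers - dom.start < left) | (dom.end - centers <= right)
            counts += covered
        means.append(counts / len(copies))
    return np.asarray(means)


def brute_force_amplicon_profiles(amp, centers, n_replicates, seed):
    """Per-copy loop simulation of the onion-skin branching process."""
    rng = np.random.default_rng(seed)
    c = amp.origin
    ws, we = amp.window
    out = []
    for _ in range(n_replicates):
        copies = [(float(ws), float(we))]
        for _ in range(amp.rounds):
            children = []
            for a, b in copies:
                if rng.random() < amp.p_fire:
                    left = amp.dist_left.sample(rng, 1)[0]
                    right = amp.dist_right.sample(rng, 1)[0]
                    children.append((max(c - left, a), min(c + right, b)))
            copies.extend(children)
        counts = np.zeros(centers.size)
        for a, b in copies:
            counts += (centers >= a) & (centers < b)
        out.append(counts)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# endocycle model


class TestEndocycles:
    def test_unbounded_forks_give_full_replication(self, small_genome):
        dom = URDomainSpec("chr2L", 1_000_000, 1_200_000, endocycles=8, fork_mean=1e12)
        track, _ = simulate_endocycles(small_genome, [dom], mode="expected")
        assert np.allclose(track.values["chr2L"], 1.0)

    def test_vanishing_forks_give_two_power_minus_e_interior(self, small_genome):
        dom = URDomainSpec("chr2L", 1_000_000, 1_200_000, endocycles=6, fork_mean=1e-6)
        track, truth = simulate_endocycles(small_genome, [dom], mode="expected")
        interior = track.values["chr2L"][1050:1150]
        assert np.allclose(interior, 2.0 ** -6)
        assert truth.domains[0]["expected_interior_ratio"] == pytest.approx(2.0 ** -6)

    def test_copy_is_one_outside_domains(self, small_genome):
        dom = URDomainSpec("chr2L", 1_000_000, 1_200_000, endocycles=10)
        for mode in ("expected", "stochastic"):
            track, _ = simulate_endocycles(small_genome, [dom], mode=mode, seed=3)
            v = track.values["chr2L"]
            assert np.all(v[:999] == 1.0) and np.all(v[1201:] == 1.0)
            assert np.all(v >= 0)

    def test_stochastic_matches_expected_within_3_se(self, small_genome):
        dom = URDomainSpec(
            "chr2L", 1_000_000, 1_200_000, endocycles=6, fork_mean=20_000, fork_shape=2
        )
        expected, _ = simulate_endocycles(small_genome, [dom], mode="expected")
        reps = []
        for seed in range(150):  # 150 x 64 = 9600 copy lineages
            t, _ = simulate_endocycles(small_genome, [dom], mode="stochastic", seed=seed)
            reps.append(t.values["chr2L"][1000:1200])
        reps = np.asarray(reps)
        se = np.maximum(reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0]), 1e-12)
        z = np.abs(reps.mean(axis=0) - expected.values["chr2L"][1000:1200]) / se
        # 3-SE agreement bin-wise; near-deterministic interior bins have
        # collapsing empirical SEs, so allow the expected multiplicity of
        # chance exceedances across 200 bins
        assert (z <= 3).mean() >= 0.97 and z.max() <= 6

    def test_expected_mode_matches_brute_force_oracle(self, small_genome):
        dom = URDomainSpec(
            "chr2L", 1_000_000, 1_200_000, endocycles=10, fork_mean=20_000, fork_shape=2
        )
        centers = small_genome.bin_centers("chr2L")[1000:1200:5]
        oracle = brute_force_endocycle_profile(dom, centers, n_populations=400, seed=9)
        se = np.maximum(oracle.std(axis=0, ddof=1) / np.sqrt(oracle.shape[0]), 1e-12)
        expected, _ = simulate_endocycles(small_genome, [dom], mode="expected")
        model = expected.values["chr2L"][1000:1200:5]
        diff = np.abs(oracle.mean(axis=0) - model)
        # 3 SE, floored at 1e-4 absolute copy ratio: deep-interior bins are
        # covered by exactly one lineage in every finite sample, so their
        # empirical SE collapses while the expectation differs by ~1e-5
        tol = np.maximum(3 * se, 1e-4)
        assert (diff <= tol).mean() >= 0.95 and np.all(diff <= 2 * tol)

    def test_stall_hard_floors_midpoint(self, small_genome):
        dom = URDomainSpec(
            "chr2L", 1_000_000, 1_400_000, endocycles=4, fork_mean=1e12, stall_hard=True
        )
        track, _ = simulate_endocycles(small_genome, [dom], mode="expected")
        # with unbounded draws clipped at the midpoint, every position is
        # still reached by one fork or the other => ratio 1 everywhere
        assert track.values["chr2L"][1100:1300].max() <= 1.0
        mid = track.values["chr2L"][1200]
        assert mid < 1.0  # the exact midpoint is reachable from neither side

    def test_overlapping_domains_error_names_pair(self, small_genome):
        doms = [
            URDomainSpec("chr2L", 1_000_000, 1_200_000),
            URDomainSpec("chr2L", 1_100_000, 1_300_000),
        ]
        with pytest.raises(ValueError, match="1000000.*1200000.*1100000"):
            simulate_endocycles(small_genome, doms)

    def test_copy_cap_advises_expected_mode(self, small_genome):
        dom = URDomainSpec("chr2L", 1_000_000, 1_200_000, endocycles=25)
        with pytest.raises(ValueError, match="expected mode"):
            simulate_endocycles(small_genome, [dom], mode="stochastic")

    def test_auto_mode_switches_on_large_e(self, small_genome):
        dom = URDomainSpec("chr2L", 1_000_000, 1_100_000, endocycles=14)
        _, truth = simulate_endocycles(small_genome, [dom], mode="auto")
        assert truth.mode == "expected"
        dom2 = URDomainSpec("chr2L", 1_000_000, 1_100_000, endocycles=6)
        _, truth2 = simulate_endocycles(small_genome, [dom2], mode="auto")
        assert truth2.mode == "stochastic"


# ---------------------------------------------------------------------------
# onion-skin amplification


def _amp(genome, **kw):
    defaults = dict(
        chrom="chr2L",
        origin=2_500_000,
        rounds=6,
        p_fire=1.0,
        window=(2_200_000, 2_800_000),
    )
    defaults.update(kw)
    return AmpliconSpec(**defaults)


class TestAmplification:
    def test_origin_law_exact_every_replicate(self, small_genome):
        unbounded = ForkDistance(kind="fixed", distance=np.inf)
        amp = _amp(small_genome, dist_left=unbounded, dist_right=unbounded)
        for seed in range(10):
            track, truth = simulate_amplification(small_genome, amp, seed=seed)
            assert track.values["chr2L"][2500] == 2 ** 6
            assert truth.amplicon["peak_copy"] == 2 ** 6

    def test_deterministic_forks_make_rectangle(self, small_genome):
        d = ForkDistance(kind="fixed", distance=50_000)
        amp = _amp(small_genome, rounds=5, dist_left=d, dist_right=d)
        track, _ = simulate_amplification(small_genome, amp, seed=1)
        v = track.values["chr2L"]
        inside = v[2451:2549]  # strictly inside [c-50k, c+50k)
        assert np.all(inside == 2 ** 5)
        assert np.all(v[2300:2449] == 1.0) and np.all(v[2551:2700] == 1.0)

    def test_no_firing_leaves_uniform_track(self, small_genome):
        amp = _amp(small_genome, p_fire=0.0)
        track, truth = simulate_amplification(small_genome, amp, seed=2)
        assert np.all(track.values["chr2L"] == 1.0)
        assert truth.amplicon["firing_counts"] == [0] * 6

    def test_firing_counts_double_with_certain_firing(self, small_genome):
        amp = _amp(small_genome)
        _, truth = simulate_amplification(small_genome, amp, seed=3)
        assert truth.amplicon["firing_counts"] == [1, 2, 4, 8, 16, 32]

    def test_stochastic_mean_matches_brute_force_oracle(self, small_genome):
        amp = _amp(small_genome, rounds=4, p_fire=0.8)
        centers = small_genome.bin_centers("chr2L")[2300:2700:8]
        oracle = brute_force_amplicon_profiles(amp, centers, n_replicates=400, seed=11)
        se = oracle.std(axis=0, ddof=1) / np.sqrt(oracle.shape[0])
        reps = []
        for seed in range(400):
            t, _ = simulate_amplification(small_genome, amp, seed=10_000 + seed)
            reps.append(t.values["chr2L"][2300:2700:8])
        reps = np.asarray(reps)
        se_m = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        tol = 3 * np.sqrt(se ** 2 + se_m ** 2)
        assert np.all(np.abs(oracle.mean(axis=0) - reps.mean(axis=0)) <= np.maximum(tol, 1e-9))

    def test_expected_profile_monotone_in_distance_from_origin(self, small_genome):
        amp = _amp(small_genome)
        x = np.linspace(2_200_000, 2_799_000, 400)
        prof = expected_amplicon_profile(amp, x)
        left = prof[x < amp.origin]
        right = prof[x >= amp.origin]
        assert np.all(np.diff(left) >= -1e-12)  # rises toward the origin
        assert np.all(np.diff(right) <= 1e-12)

    def test_mc_mean_log2_profile_matches_brute_force(self, small_genome):
        amp = _amp(small_genome, rounds=4)
        centers = small_genome.bin_centers("chr2L")[2350:2650:10]
        oracle = brute_force_amplicon_profiles(amp, centers, n_replicates=300, seed=21)
        oracle_log = np.log2(np.maximum(oracle, 1)).mean(axis=0)
        mc = mc_mean_log2_amplicon_profile(amp, centers, n_replicates=300, seed=22)
        se = np.log2(np.maximum(oracle, 1)).std(axis=0, ddof=1) / np.sqrt(300)
        assert np.all(np.abs(mc - oracle_log) <= 3 * np.maximum(se, 1e-9) * np.sqrt(2))

    def test_origin_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            AmpliconSpec(chrom="chr2L", origin=100, window=(200, 300))

    def test_window_outside_chromosome_rejected(self, small_genome):
        amp = _amp(small_genome, window=(2_200_000, 6_000_000), origin=2_500_000)
        with pytest.raises(ValueError, match="bounds"):
            simulate_amplification(small_genome, amp)


# ---------------------------------------------------------------------------
# read sampling


class TestSampleReads:
    def test_poisson_mean_within_one_percent(self):
        genome = GenomeSpec(chroms=(("chrX", 12_000_000),), bin_width=1000)
        track = CopyNumberTrack(genome=genome, values={"chrX": np.ones(12_000)})
        params = ReadSimParams(mean_depth=100, dispersion=0.0, seed=5)
        _, profile = sample_reads(track, params, return_reads=False)
        mean = profile.counts["chrX"].mean()
        assert abs(mean - 100) / 100 < 0.01

    def test_half_copy_domain_halves_depth(self, small_genome):
        track, _ = make_copy_track(small_genome, [("chr2L", 1_000_000, 2_000_000, 0.5)])
        params = ReadSimParams(mean_depth=60, dispersion=0.0, seed=6)
        _, profile = sample_reads(track, params, return_reads=False)
        c = profile.counts["chr2L"]
        t_domain = int(c[1000:2000].sum())
        t_background = int(c[2000:3000].sum())
        # rate ratio 0.5 : 1 => domain counts | total ~ Binomial(n, 1/3)
        res = stats.binomtest(t_domain, t_domain + t_background, p=1.0 / 3.0)
        assert res.pvalue > 0.001

    def test_same_seed_gives_byte_identical_bed(self, small_genome):
        track, _ = make_copy_track(small_genome, [("chr2L", 1_000_000, 1_050_000, 0.4)])
        params = ReadSimParams(mean_depth=5, seed=7)
        a, _ = sample_reads(track, params)
        b, _ = sample_reads(track, params)
        assert a.to_csv(sep="\t", header=False, index=False) == b.to_csv(
            sep="\t", header=False, index=False
        )

    def test_mappability_scales_depth(self):
        genome = GenomeSpec(
            chroms=(("chr4", 2_000_000),),
            bin_width=1000,
            mappability={"chr4": np.concatenate([np.zeros(500), np.ones(1500)])},
        )
        track = CopyNumberTrack(genome=genome, values={"chr4": np.ones(2000)})
        _, profile = sample_reads(track, ReadSimParams(mean_depth=50, seed=8), return_reads=False)
        assert profile.counts["chr4"][:500].sum() == 0
        assert profile.counts["chr4"][500:].mean() > 40

    def test_control_is_uniform_track_sampling(self, small_genome):
        reads, profile = make_control(small_genome, ReadSimParams(mean_depth=20, seed=9))
        assert profile.total == len(reads)
        assert set(reads["chrom"]) == {"chr2L"}
        assert (reads["end"] - reads["start"]).max() <= 75


class TestImplants:
    def test_overlapping_implants_rejected(self, small_genome):
        with pytest.raises(ValueError, match="overlap"):
            make_copy_track(
                small_genome,
                [("chr2L", 1_000_000, 1_200_000, 0.5), ("chr2L", 1_100_000, 1_300_000, 0.5)],
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_benchmark_implants_respect_spacing_and_ranges(self, seed):
        genome = GenomeSpec(chroms=(("chr2L", 25_000_000),), bin_width=1000)
        implants = ur_benchmark_implants(genome, seed=seed)
        assert len(implants) == 23
        big = [i for i in implants if i[2] - i[1] >= 15_000]
        small = [i for i in implants if i[2] - i[1] < 10_000]
        assert len(big) == 20 and len(small) == 3
        for c, s, e, copy in big:
            assert 15_000 <= e - s <= 200_000 and 0.3 <= copy <= 0.7
        for c, s, e, copy in small:
            assert 5_000 <= e - s <= 8_000 and copy == 0.3
        ordered = sorted(implants, key=lambda x: x[1])
        for a, b in zip(ordered, ordered[1:]):
            assert b[1] - a[2] >= 300_000
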