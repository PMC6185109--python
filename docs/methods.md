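# Methods

## Generative models

### Endocycle underreplication

A polytene tissue is modelled as one genome that doubles E times without
mitosis. Outside fork-stalling domains every position replicates each
cycle. Inside a domain `[s, e)`, each genome copy replicates only a prefix
of length `L ~ Gamma(fork_mean, fork_shape)` from the left edge and an
independent suffix `R` from the right edge per cycle; a child's replicated
extent is clipped to its template's (nested replication cannot exceed the
material it copies), and with `stall_hard` fork travel is additionally
capped at the domain midpoint. The reported track is the final number of
copies covering each bin divided by `2^E`, so 1 means fully replicated.

The expected track is computed exactly. Coverage of a position is inherited
side-wise — a copy whose material reaches `x` only from the left edge can
pass coverage on only through its left fork — so with per-cycle fork-arrival
probabilities `sl = P(L ≥ d_left)` and `sr = P(R ≥ d_right)`, the expected
numbers of copies covering `x` from both sides (`a`), left only (`b`) and
right only (`c`) follow

```
a' = a (1 + sl·sr)
b' = b (1 + sl) + a·sl·(1 − sr)
c' = c (1 + sr) + a·(1 − sl)·sr
```

from `a = 1`, and the relative copy number is `(a + b + c) / 2^E`. The
superficially plausible closed form `((1 + sl + sr − sl·sr)/2)^E` is *not*
the expectation of this process (it overstates the shoulders by ignoring
side-wise inheritance); the unit tests pin the recurrences against a naive
per-copy loop simulation. Stochastic mode simulates all `2^E` copies
explicitly (capped at `2^20`; `auto` switches to expected mode above
E = 12), and agrees with the expectation within Monte-Carlo error.

Limits: unbounded forks give ratio 1 everywhere; vanishing fork travel
gives `2^−E` in the interior. Defaults: E = 10 (a common polytene ploidy
order; a free parameter, not a claim), fork_mean 20 kb, gamma shape 2.

### Onion-skin amplification

One origin `c` inside an analysis window starts with a single spanning
copy. Each round, every copy covering `c` fires with probability `p_fire`
and buds a child spanning `[c − L, c + R]` intersected with its template
(`L, R` drawn from per-arm fork-travel distributions; `gamma(mean, shape)`
or deterministic). Copy number at `x` is the number of copies covering `x`,
relative to background 1. Because a copy covering `x` always has reach
beyond `x`, clipping drops out of the expectation and

```
E[N(x)] = (1 + p_fire · S(|x − c|))^F
```

with `S` the fork-travel survival function; at the origin with certain
firing the count is exactly `2^F` in every realization, which the tests
assert replicate by replicate.

For width comparisons the reference profile is the mean of the
*log2-transformed* replicate profiles (`mc_mean_log2_amplicon_profile`,
10,000 replicates by default): a measured profile is the log2 of a single
realization, and averaging copy numbers before taking logs overstates the
shoulders where the branching process has high variance (a Jensen gap of
10–20% in width).

### Read sampling

Per-bin counts are negative binomial with mean
`mean_depth × copy × mappability` and dispersion 0.05 (variance
`μ + 0.05 μ²`; dispersion 0 gives Poisson). Read starts are uniform within
their bin; read length 75 b. All randomness flows through one seeded
generator per call, and identical seeds give byte-identical BED output.
Defaults: 30× for underreplication runs, 100× for amplicon runs.

The generator emulates shallow copy-number sequencing depth structure only.
It does not model GC or fragment-length bias, PCR duplicates, chimeric or
multi-mapping reads, sequence content, or mappability estimated from
sequence (the mask is supplied, not computed). Passing tests therefore
demonstrate correctness of the pipeline's statistics under calibrated
overdispersed shot noise, not robustness to every real-library artifact.

## Coverage tracks

Reads are counted by start coordinate into fixed bins (1 kb default; 10 kb
windows for pericentric arms via `window_depth`). RPM normalization scales
counts to one million per sample. The comparison track is
`log2((rpm_s + ε)/(rpm_c + ε))` with pseudocount ε = 0.5 RPM — enough to
avoid infinities at shallow depth, negligible for covered bins — and bins
with zero raw counts in *both* samples are flagged missing (NaN) and stay
missing through smoothing. Smoothing is a centered moving average over an
odd number of bins (default 9) that ignores missing neighbours and uses
the available asymmetric window at chromosome edges.

**Background centering.** Total-read scaling is sum-preserving, not
background-preserving: depleted or amplified mass shifts every other bin's
ratio away from zero (≈ +0.06 log2 when ~4% of the genome's reads are
missing). The copy-neutral level is therefore located and subtracted: first
with the shorth (midpoint of the shortest interval holding half the bins —
robust to the one-sided contamination depleted domains add), then refined
as the median over bins outside the multi-scale candidate mask, since with
per-bin noise σ ≈ 0.6 and ~9% depleted mass even a robust global estimator
under-corrects by ~0.015 log2 — material when calls are made near the
depletion threshold. This assumes most of the genome is copy-neutral.

## Underreplicated-region calling

Two modes share one filter contract: a surviving region must not overlap
any control-sample call (≥ 1 bp) and must be *longer than* `min_length`
(10 kb; the strict inequality follows the defining wording "greater than
10 kb"). Rejected candidates are kept, flagged, in an audit table.

* **Threshold-merge** (no raw profile supplied): bins at or below θ
  (default −0.5 log2 ≈ 0.71× copy) merge into regions when separated by at
  most `max_gap` bins (default 2). Transparent and exactly reproducible,
  but per-bin thresholding has no power for domains whose depletion sits
  near θ — at 30× the per-bin noise is ~0.6 log2 while a copy-0.70 domain
  sits 0.014 below θ.

* **Scan mode** (the pipeline default): detection and classification are
  separated. Candidate neighbourhoods come from a multi-scale scan
  statistic on the raw track — a bin is a candidate when some centered
  window (1 to 129 bins, roughly dyadic) around it is significantly below
  background, `z < −τ` with `τ = sqrt(2 ln(7n))` (the classical
  genome-wide threshold, counting all scan scales), σ estimated robustly
  from successive differences, and each scale's hit mask dilated by its
  window so a firing window implicates its whole extent. Candidate runs
  are merged (`max_gap`), then split and trimmed by a two-level likelihood
  model: region depth μ against background 0 classifies a bin as regional
  when its value is below μ/2, so the maximum-subarray of `μ/2 − value`
  (Kadane) is the maximum-likelihood single-region placement; μ and the
  span are refined by alternation (EM), the span visited with the highest
  likelihood gain `n·μ̂²` wins (with an explicit deep-core-only comparison,
  so a shallow flank riding on a deep trough cannot absorb it), flanks are
  scanned recursively, each reported span must be genome-wide significant
  on its own, and the final extent runs between threshold-crossing bins.
  A span is then called underreplicated when its mean is at or below
  `θ + σ/√max(n, 100)` — θ is the depletion *definition*, detection power
  comes from pooling, and the one-standard-error slack (capped so short
  spans cannot exploit it) keeps domains whose true depth sits exactly at
  the threshold from being lost to estimation noise.

The control-sample call set is produced by the same machinery on the
control's own depth relative to its genome-wide median
(`median_log2_ratio`), at a stricter threshold (2θ by default): the
control filter exists to remove systematic artifacts — mappability and
assembly holes, which are deep — and a borderline noise call in the
control would otherwise veto sample territory.

Boundary accuracy is ± about one bin for deep domains. Domains whose true
depth lies within ~0.02 log2 of θ are called with the ~50–90% probability
that their realized mean clears the threshold — an information limit, not
an implementation one. Chance depressions adjacent to a deep sub-10 kb
trough occasionally form a genuinely > 10 kb depleted span, which is then
reported at its larger extent; the trough alone is never reported below
the length filter.

Region depth is `n_reads × read_length / region_length`; samples are
compared after scaling by total reads (reference_total / sample_total);
group contrasts use Welch's two-sample t-test (scipy, Welch–Satterthwaite
degrees of freedom). "Fully replicated" regions are the genome minus UR
calls, supplied pericentric annotation and control calls.

## Amplicon quantification

The peak is the bin-center coordinate of the maximum smoothed log2 value in
the window; ties break toward the window midpoint, then leftmost
(deterministic and documented). Each arm's half-maximum is the first
crossing of half the peak value scanning outward, linearly interpolated
between bin centers; evaluating the piecewise-linear profile at the
returned coordinate reproduces the target within 1e-6. If an arm never
crosses inside the window, the window edge is returned and flagged rather
than raising — shallow gradients can legitimately reach the edge. Halving
defaults to the log2 scale; a linear-scale option is provided because
halving log2 values is not halving copy number (on the log2 track it means
crossing `peak − 1` instead of `peak/2`), and the scale used is recorded in
every output. With gamma fork travel the log2-scale width is independent of
F, which is what makes peak (origin firing) and width (fork travel)
separable readouts. Genotype comparisons report width ratios and log2 peak
differences against a reference genotype, with a Welch test across
replicates when at least two are available per genotype.

## Tabular statistics

ddPCR: per-replicate target/control concentration ratio; mean and SEM
(sample SD, n−1, over biological replicates). Cell-count fractions:
`100·k/n` rounded half-up to one decimal, matching printed percentages;
per-group replicate summaries average per-replicate percentages
unweighted. iPOND: protein intensity is the sum of MS1 areas over peptides
and charge states, normalized per sample to the histone H3 sum; enrichment
is normalized pulse over normalized chase, NaN-flagged at zero chase. All
three are invariant under per-sample global rescaling by construction.

## Reference study conditions (benchmarks)

The validation workflows in `polycopy.benchmarks` regenerate everything
from a seed:

- amplicon runs: one 40 Mb chromosome (so RPM mass shifts from the
  amplified window stay small), origin at 20 Mb, ±280 kb window, 100×,
  F = 6, gamma shape 3; fork-travel ladder at means 15–75 kb with 20 seeds
  per setting against a 10,000-replicate Monte-Carlo reference width;
- separability: fork-travel mean 30 vs 60 kb at F = 6, and F = 5 vs 6 at
  mean 30 kb, 10 seeds per condition;
- underreplication benchmark: one 25 Mb chromosome at 30×, 20 flat
  implanted domains (15–200 kb, copy 0.3–0.7, ≥ 300 kb apart) plus three
  deep 5–8 kb length-filter probes (copy 0.3; at 1 kb bins a 9 kb probe is
  within one bin of the 10 kb cutoff, inside boundary-estimation error),
  and 100 re-sequenced replicates for the Welch separation rate.

Flat implants are used for caller validation because they prescribe exact
interior copy values; real (and simulated endocycle) domains have sloped
shoulders, which move called boundaries slightly inward relative to the
domain's outermost extent.

## Known limitations

- Segmentation assumes two levels (background plus locally constant
  depletion) and approximately Gaussian bin noise after the log2
  transform; gradual depletion slopes are called at their threshold
  crossings, not decomposed.
- The background-centering step assumes a copy-neutral majority of bins.
- No GC/mappability correction is computed; supplied masks only.
- The amplicon expectation treats per-copy firing and fork travel as
  independent across rounds; developmental timing (stage-dependent firing)
  is not modelled.
- `compare_region_sets` uses any-overlap (≥ 1 bp) detection by default;
  the overlap rule is a parameter because published call-set comparisons
  rarely state one.
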