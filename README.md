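# polycopy

Copy-number analysis for polyploid genomes that replicate without dividing.

In *Drosophila* polytene tissues (larval salivary glands), repeated
endocycles leave specific domains underreplicated: replication forks enter
each domain from its edges and stall, so the interior falls further behind
the 2^E genome-wide ploidy with every cycle and read-depth sequencing shows
flat-bottomed troughs with sloped shoulders. In ovarian follicle cells the
opposite happens at six loci (DAFCs): one origin re-fires repeatedly,
producing nested "onion-skin" replication bubbles whose coverage forms a
copy-number gradient — peak height records how often the origin fired,
while the distance between the half-maximum points on each arm records how
far forks travelled. Both phenomena are regulated by the SUUR–Rif1/PP1 axis
acting on fork progression.

`polycopy` implements this analysis end to end for people who want to test
such pipelines without the original sequencing data:

- **simulate** — generative models for both phenomena plus negative-binomial
  read sampling and a uniform-copy (early-embryo analogue) control;
- **coverage** — binned counts (1 kb default), RPM normalization,
  `log2(sample/control)` tracks with background centering and smoothing;
- **urcall** — underreplicated-region calling with the field's filter
  contract (no overlap with control-sample calls; length strictly > 10 kb),
  region read depth (`n_reads × read_length / region_length`), total-read
  scaling between samples, and Welch two-sample t-tests;
- **ampquant** — amplicon peak coordinate/height and interpolated
  half-maximum width per arm, with per-genotype comparisons;
- **tabstats** — ddPCR copy-number ratios with replicate SEM, cell-count
  percentages, and iPOND MS1 protein roll-up normalized to histone H3.

## Core quantities

For a domain entered by forks travelling `L, R ~ Gamma(mean, shape)` per
endocycle, the expected relative copy number at position `x` follows exact
side-wise coverage recurrences (see `docs/methods.md`); in the limits it is
1 (unbounded forks) and `2^-E` (stalled forks). For an amplicon with origin
`c`, firing probability `p` and fork-travel survival `S(d)`, the expected
copy number after `F` rounds is

```
E[N(x)] = (1 + p · S(|x − c|))^F,      N(c) = 2^F when p = 1.
```

The gradient width is `right − left` where each side is the first
half-maximum crossing of the smoothed log2 profile, linearly interpolated
(halving on the log2 or on the linear copy scale — both implemented).

## Worked example

Simulate a salivary-gland analogue with two fork-stalling domains after ten
endocycles, sequence it at 30× against an embryo-like control, and call
underreplicated regions:

```python
from polycopy import (
    GenomeSpec, URDomainSpec, ReadSimParams, RunConfig,
    simulate_endocycles, sample_reads, make_control, run_ur_pipeline,
)
from polycopy.urcall import regions_to_frame

genome = GenomeSpec(chroms=(("chr2L", 10_000_000),), bin_width=1000)
domains = [
    URDomainSpec("chr2L", 2_000_000, 2_300_000, endocycles=10, fork_mean=20_000, fork_shape=2),
    URDomainSpec("chr2L", 6_500_000, 6_620_000, endocycles=10, fork_mean=15_000, fork_shape=2),
]
track, truth = simulate_endocycles(genome, domains, mode="expected")
_, gland = sample_reads(track, ReadSimParams(mean_depth=30, seed=1), return_reads=False)
_, embryo = make_control(genome, ReadSimParams(mean_depth=30, seed=2), return_reads=False)

result = run_ur_pipeline(RunConfig(), genome=genome, sample=gland, control=embryo, write=False)
print(regions_to_frame(result.regions)[["chrom", "start", "end", "length", "mean_ratio"]])
t, df, p = result.welch
print(f"Welch t = {t:.2f}, df = {df:.1f}, p = {p:.2e}")
```

prints

```
   chrom    start      end  length  mean_ratio
0  chr2L  2014000  2285000  271000   -7.350977
1  chr2L  6512000  6608000   96000   -7.375520
Welch t = -233.40, df = 2.0, p = 1.77e-05
```

Both implanted domains are recovered; the called boundaries sit where the
sloped shoulders cross the depletion threshold, so they are slightly inside
the implanted edges. `mean_ratio` is the mean smoothed log2 depletion
(close to −10 in the interior, where copy number is ~2⁻¹⁰ of ploidy), and
the Welch test contrasts scaled read depth in underreplicated versus fully
replicated regions.

The same stages are available from the shell:

```
polycopy simulate-endocycle --genome genome.chrom.sizes --spec domains.json \
    --seed 3 --out-prefix sim
polycopy call-ur --genome genome.chrom.sizes --sample sim.counts.bedgraph \
    --control ctrl.counts.bedgraph --out-prefix calls
polycopy amp-quant --genome genome.chrom.sizes --control ctrl.counts.bedgraph \
    --sample wt=wt.counts.bedgraph --sample mut=mut.counts.bedgraph \
    --windows dafc_windows.bed --out-prefix quant
polycopy stats fractions --in counts.tsv --out percentages.tsv
```

All inputs and outputs are plain text: chrom.sizes, BED3/BED6, bedGraph,
TSV, and a JSON manifest echoing every parameter of a run.

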