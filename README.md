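# ampbench

Benchmarking toolkit for the two experimental error-correction strategies
used in amplicon-based deep sequencing: **read-pairing consensus** (keep a
mate pair only when the forward read exactly equals the reverse complement
of the reverse read) and **tag-clustering consensus** (Primer-ID/UMI style:
group reads by a 16-nt random tag, discard groups smaller than three, keep a
group only when every member read is identical). It is aimed at researchers
deciding which correction scheme to use for rare-variant detection — viral
quasispecies, tumor mutation monitoring, deep mutational scanning — where
the trade-off between residual error rate and coverage loss determines the
per-nucleotide sequencing cost.

## What it does

The package simulates clonal tagged amplicon libraries with known ground
truth and pushes them through four analysis schemes:

1. **Scheme 1** — raw reads, no correction;
2. **Scheme 2** — read-pairing consensus (ideal retention 1/2);
3. **Scheme 3** — tag-clustering consensus (ideal retention 1/c at c reads
   per tag, unanimity rule, minimum group size 3);
4. **Scheme 4** — read-pairing followed by tag-clustering (ideal 1/2c).

Surviving sequences are locally aligned to the 88-bp reference amplicon
(scores +1 match, −1 mismatch, −1 gap open, −0.5 gap extend; a length-g gap
costs `open + (g−1)·extend`) and every discrepancy is classified as a
transition (A↔G, C↔T), transversion (A↔C, A↔T, G↔C, G↔T), insertion or
deletion. Per-position error rates `count/coverage`, retention accounting
and fold costs `1/retention`, tag cluster-size distributions, Wilcoxon
signed-rank scheme comparisons, Shapiro–Wilk normality checks and
replicate/strand Pearson correlations are reported per
(scheme, strand, replicate) stratum.

The simulator emulates the benchmarked experimental design: a single 88-bp clonal
template; 8 random tag nucleotides plus a 3-bp replicate barcode in each
primer (a combined 16-nt tag per molecule, ~4×10⁹ tag space); about five
sequenced copies per tagged molecule; strand-asymmetric substitution rates
(reverse ≈ 3× forward); rare planted true variants; and Phred qualities
correlated with the injected errors. Every injected error is logged in a
truth table, so each scheme's behaviour can be validated exactly.

## Worked example

```python
from ampbench import (CopiesModel, SimConfig, simulate_library,
                      apply_scheme, build_profile, fold_cost)
from ampbench.library_io import tag_pairs

config = SimConfig(n_molecules=1000, copies=CopiesModel.fixed(5),
                   sub_rate_fwd=0.0, sub_rate_rev=0.0,
                   ins_rate=0.0, del_rate=0.0, seed=1)
lib = simulate_library(config)
pairs = tag_pairs(lib.pairs, config.layout)
for scheme in (2, 3, 4):
    r = apply_scheme(pairs, scheme, strand="forward")
    print(scheme, len(r.records), r.raw_reads,
          f"{r.retention:.2f}", f"{fold_cost(r.retention):.1f}")
```

prints

```
2 5000 10000 0.50 2.0
3 1000 5000 0.20 5.0
4 1000 10000 0.10 10.0
```

i.e. on an error-free library with exactly five read pairs per tagged
molecule, read-pairing keeps 50 % of raw reads (2-fold coverage cost),
tag-clustering keeps 20 % of its stream (5-fold), and the combined scheme
keeps 10 % (10-fold). With realistic error rates the realized retentions
drop below these ideals and the residual error rates separate the schemes:
tag-clustering suppresses substitutions hardest, read-pairing suppresses
indels hardest, and the combination does best on both (see the test suite's
Monte-Carlo checks).

The same pipeline is scriptable from the shell:

```bash
ampbench simulate --n-molecules 1000 --seed 1 --out-prefix lib/sim
ampbench correct lib/sim_R1.fastq lib/sim_R2.fastq --scheme 3 --out cons.fasta
ampbench profile cons.fasta --out profile.tsv
ampbench report --profiles profile.tsv --profiles other.tsv --out report.json
```

## Layout

- `ampbench.synthetic_data` — library simulator and ground-truth tables
- `ampbench.library_io` — paired FASTQ I/O, demultiplexing, tag extraction
- `ampbench.consensus_schemes` — the four correction schemes + quality filter
- `ampbench.error_profiling` — local alignment, error typing, rate profiles
- `ampbench.benchmark_stats` — retention/fold-cost, cluster sizes, statistics
- `ampbench.cli` — `ampbench simulate|correct|profile|report`

See `docs/methods.md` for the model, parameter defaults, and numerical
conventions.
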