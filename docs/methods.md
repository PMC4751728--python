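# Methods

## The benchmark design

A clonal (single-template) amplicon library is the cleanest substrate for
measuring sequencing error: every discrepancy from the reference that is not
a planted variant is, by construction, an error introduced by PCR or
sequencing. The pipeline models the tagged-amplicon design in which each
template molecule receives a unique random tag before amplification —
8 random nucleotides embedded in each of the two primers, so the molecule is
keyed by a combined 16-nt tag (4¹⁶ ≈ 4×10⁹ possible tags) — plus a 3-bp
replicate barcode present on both mates. Reads sharing a tag are
resamplings of one original molecule; mate pairs are two strand-opposite
observations of one sequencing cluster. The four analysis schemes exploit
these redundancies:

| scheme | redundancy used | ideal retention at c copies/tag |
|---|---|---|
| 1 raw | none | 1 |
| 2 read-pairing | mate concordance (exact reverse-complement match) | 1/2 |
| 3 tag-clustering | tag groups, unanimity, min size 3 | 1/c |
| 4 combined | scheme 2 then scheme 3 on paired consensuses | 1/(2c) |

Consensus here is strict unanimity, not majority vote: a tag group (or mate
pair) survives only if all of its sequences are identical. Retention is
counted per stream: schemes 2 and 4 against all raw reads (both mates),
schemes 1 and 3 against the reads of the selected strand, with the tag key
always the combined 16-nt tag (which requires mate association before
per-strand grouping). The reciprocal of retention is the fold increase in
per-nucleotide sequencing cost.

## The simulator

`synthetic_data.SimConfig` fixes the generative model; defaults are the
reference conditions the package is benchmarked under:

- **template**: the 88-bp protein G antibody-interacting domain fragment
  (54.5 % GC), the built-in `PROTEIN_G_AMPLICON`;
- **copies per tagged molecule**: zero-truncated Poisson, λ = 5
  (truncated mean ≈ 5.03), matching the expectation of ~5 sequenced copies
  per molecule (~30×10⁶ reads over ~6×10⁶ molecules); `fixed(c)` is
  available for exact-retention identities;
- **substitution rates**: 1×10⁻³ per nt forward, 3×10⁻³ reverse — the
  platform's 0.1–1 % per-nt range with the ~3× reverse-read excess;
  substitutions choose uniformly among the three alternative bases, so
  uniform errors split 1:2 between transitions and transversions;
- **indels**: single-base events, insertion 5×10⁻⁵ and deletion 1×10⁻⁴ per
  nt (an order of magnitude below substitutions, as observed on this
  platform);
- **hotspots**: optional per-position, per-strand substitution-rate
  overrides, for sequence-specific error patterns;
- **planted variants**: alternative template sequences drawn per molecule
  by frequency; these model true low-frequency mutations *and* PCR-phase
  errors (both are shared by all copies of a molecule and therefore
  uncorrectable by consensus);
- **qualities**: correct bases Phred 37; erroneous (substituted/inserted)
  bases uniform on Phred 2–30, making the Phred < 30 quality filter
  meaningfully correlated with error.

Reads are emitted at fixed length (12-bp prefix + 88-bp target region): a
deletion pulls one random downstream base into the read and an insertion
pushes the last template base off the end, as on a fixed-cycle sequencer.
The 12-bp prefix is 4 random nt + barcode + 4 random nt + 1 random filler
base; the filler reflects that the trimmed prefix is one base longer than
the designed 11-nt primer head, and it is never part of the tag key.
Prefix bases receive substitution errors at the strand's base rate (no
indels), which is what fragments tag clusters and produces the spurious
singleton tags seen in real data (`tag_error_probability`, 1−(1−p)^L, gives
the per-read chance of a corrupted tag: 1.6 % at p = 10⁻³, 14.9 % at 10⁻²).
A back-of-envelope range of 1.9–10 % sometimes quoted for p between 0.1 %
and 1 % is inconsistent with the closed form; the closed form is used and
the discrepancy simply noted.

Every injected error is logged (`region:pos:type:from:to`, positions
1-based in the unmutated read region, read orientation), and the truth
table is sufficient to replay each read from its molecule's true sequence —
the property the generator's tests enforce.

**What the simulator does not model**: flow-cell spatial effects,
phasing/pre-phasing optics, adapter read-through, PCR chimeras, quality
degradation along the read, or cycle-correlated errors. Passing tests
therefore demonstrate the schemes' behaviour under independent per-base
errors with strand asymmetry; systematic, tag-correlated errors (which real
tag-clustering cannot correct) enter only through planted variants.

### Cluster-size calibration

The copies-per-tag distribution of the real libraries is not knowable from
post-hoc summaries alone: the expectation was ~5 copies per
molecule while the realized non-singleton tag-cluster means were 3.5 and
4.1 (replicates 1/2), reflecting unequal amplification and tag-region
errors. The package keeps λ = 5 as the default (the stated design
expectation). For checks that target the realized cluster-size
distribution, a zero-truncated Poisson with λ = 3.5 reproduces non-singleton
means inside the observed [3.5, 4.1] band once tag-region errors fragment
clusters; that calibrated setting is used only where the realized
distribution is the quantity of interest.

## Alignment and error typing

Survivors are locally aligned to the reference with scores +1 match,
−1 mismatch, gap open −1, gap extend −0.5, where a length-g gap costs
`open + (g−1)·extend` (first gap column charged the opening penalty only).
N scores as a mismatch against every base. The implementation wraps
Biopython's `PairwiseAligner`; the test suite checks score equivalence
against an independent Smith–Waterman/Gotoh dynamic program on all short
sequence pairs.

Numerical conventions, chosen where the procedure is otherwise
underdetermined:

- **Tie-breaking** among co-optimal alignments: fewest gap columns, then
  widest reference span, then leftmost gap placement (bounded enumeration
  of co-optimal alignments). The span rule exists because a substitution
  near the read end often ties with a clipped alignment; preferring the
  wider span keeps the error observable and the choice deterministic.
- **Terminal blind spots**: under local alignment a mismatch in the
  outermost ~2 reference positions is clipped rather than aligned (the
  clipped segment scores at least as high, and Smith–Waterman resets at
  zero), so positions 1–2 and 87–88 systematically under-report
  substitutions. Pooled rate-recovery checks therefore use interior
  positions 3–86 (`ErrorProfile.overall_rate(..., start, end)`).
- **Adjacent substitution pairs**: two neighbouring substitutions that form
  a transposition score better as a one-base insertion plus deletion
  (−1 −1 with an extra match vs −2), so at the ~1 % error rate a small,
  predictable fraction of substitution pairs is typed as indels. Event
  *counts* are conserved; recovery checks at that rate compare the total
  event rate.
- **Error types**: mismatches are transitions (A↔G, C↔T) or transversions
  (the remaining pairs); a query N counts as a transversion by default
  (`n_policy="separate"` types it `n_call`); each gap column is one
  single-base event; an insertion is assigned to the reference position
  immediately 5′ of the inserted base, position 0 reserved for insertions
  before base 1. Coordinates are 1-based along the 88-nt reference.
- **Coverage** at a position counts records whose alignment spans it, not
  raw records; records scoring below half the maximal match score are
  counted unalignable and excluded. Reverse-strand records are
  reverse-complemented before alignment (error classes are invariant under
  complementation), so all profiles share forward reference coordinates.

## Statistics

Scheme comparisons use the two-sided Wilcoxon signed-rank test on paired
per-position rates, zero-differences dropped; the pairing unit is
position × type within the caller's selected types (single type =
within-type test, several = pooled). The degenerate all-zero case is
reported as p = 1 with zero pairs. The test is checked against exact
enumeration of the 2ⁿ sign assignments at small n. Normality uses
Shapiro–Wilk (constant vectors reported as degenerate), correlations use
Pearson r per error type with an optional least-squares fit, and no
multiple-testing correction is applied anywhere (raw p-values, stated in
the report footer).

## Problem sizes

The package's own validation runs at desk scale, chosen to make Monte-Carlo
standard errors small relative to the effects being checked: ideal-retention
identities on 1,000-molecule error-free libraries (exact, not statistical);
rate recovery on 10⁵ reads (50,000 molecules × 1 pair); the read-pairing
survival/residual oracle on 10⁵ pairs (3σ bands from binomial counts);
unanimity bounds at 4,000–6,000 molecules with fixed group sizes 3 and 5;
planted-variant fidelity and scheme orderings on 5,000–6,000 molecules at
~5 copies each. All random draws flow from one seeded generator per
library; identical seed and configuration give byte-identical FASTQ output.

## Known limitations

- The unanimity error bound e·(e/3)^(k−1) is so small at realistic e that
  the Monte-Carlo check can only confirm zero observed consensus errors;
  it is an upper-bound check, not a rate estimate.
- Realized retention of scheme 3 at c < 3 copies is 0 (minimum group size),
  while the closed-form ideal is 1/c; `ideal_retention` documents the
  divergence rather than hiding it.
- The per-position pairing unit cannot reproduce the magnitude of the
  p-values reported for the full-scale dataset (88 positions bound the
  attainable significance); both the within-type and pooled pairing units
  are provided, and no attempt is made to reverse-engineer the published
  sample unit.
- Whether the real analysis counted the trimmed 12-bp prefix as an 11-nt
  designed head plus one template base or a 12-nt designed head is not
  stated; both the trim length and the tag positions are configurable
  (`TagLayout`), with the 12-bp trim as default.
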