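"""Local alignment against the reference and per-position error profiling.

Discrepancies between an (error-corrected) read and the reference amplicon
are classified into four types — transition (A<->G, C<->T), transversion
(A<->C, A<->T, G<->C, G<->T), insertion and deletion — and accumulated into
per-position count/coverage profiles, one per (scheme, strand, replicate)
stratum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .consensus_schemes import ConsensusRecord
from .library_io import revcomp

ERROR_TYPES = ("transition", "transversion", "insertion", "deletion")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: Co-optimal alignments inspected for deterministic tie-breaking.
_MAX_TIEBREAK_ALIGNMENTS = 32


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring: +1 match, -1 mismatch, -1 gap open, -0.5 gap extend.

    A length-g gap costs ``gap_open + (g-1)*gap_extend``: the first gap
    column is charged the opening penalty only.  N scores as a mismatch
    against every base (including N).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -1.0
    gap_extend: float = -0.5
    mode: str = "local"

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > self.gap_extend or self.gap_extend > 0:
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise local alignment in gapped-string form (1-based ref coords)."""

    aligned_ref: str
    aligned_query: str
    score: float
    ref_start: int  # 1-based, inclusive
    ref_end: int  # 1-based, inclusive

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class ErrorEvent:
    """One classified discrepancy at a 1-based reference position.

    Insertions are assigned to the reference position immediately 5' of the
    inserted base; position 0 marks an insertion before the first base.
    """

    position: int
    type: str
    ref_base: str
    obs_base: str


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            matrix[a, b] = params.match if (a == b and a != "N") else params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = params.mode
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _gap_key(aln) -> tuple:
    """Tie-break key: fewest gap columns, then widest reference span, then
    leftmost gap placement.

    The span preference keeps co-optimal terminal mismatches aligned rather
    than clipped, so near-end substitutions stay observable."""
    aligned_ref, aligned_query = str(aln[0]), str(aln[1])
    gap_cols = tuple(
        i for i, (a, b) in enumerate(zip(aligned_ref, aligned_query)) if a == "-" or b == "-"
    )
    span = int(aln.coordinates[0][-1]) - int(aln.coordinates[0][0])
    return (len(gap_cols), -span, gap_cols)


def align_local(
    query: str, reference: str, params: ScoringParams | None = None
) -> AlignmentResult:
    """Maximal-scoring local alignment of query against reference.

    Among co-optimal alignments the one with the fewest gap columns, then
    the leftmost gap placement, is chosen (bounded enumeration), so the
    result is deterministic.
    """
    params = params or ScoringParams()
    if not query or not reference:
        raise ValueError("query and reference must be nonempty")
    if query == reference:  # exact-match fast path (the common case)
        return AlignmentResult(
            aligned_ref=reference,
            aligned_query=query,
            score=params.match * len(reference),
            ref_start=1,
            ref_end=len(reference),
        )
    aligner = _make_aligner(params)
    alignments = aligner.align(reference, query)
    if alignments.score <= 0:
        # no positive-scoring segment: empty local alignment
        return AlignmentResult(
            aligned_ref="", aligned_query="", score=0.0, ref_start=1, ref_end=0
        )
    best = None
    best_key = None
    for aln in itertools.islice(alignments, _MAX_TIEBREAK_ALIGNMENTS):
        key = _gap_key(aln)
        if best_key is None or key < best_key:
            best, best_key = aln, key
    assert best is not None
    return AlignmentResult(
        aligned_ref=str(best[0]),
        aligned_query=str(best[1]),
        score=float(best.score),
        ref_start=int(best.coordinates[0][0]) + 1,
        ref_end=int(best.coordinates[0][-1]),
    )


def classify_errors(aln: AlignmentResult, n_policy: str = "transversion") -> list[ErrorEvent]:
    """Classify every non-matching alignment column into an ErrorEvent.

    A run of g consecutive gap columns yields g single-base events.  Query N
    against a reference base counts as a transversion by default
    (``n_policy="separate"`` types it ``n_call`` instead).
    """
    if n_policy not in ("transversion", "separate"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    events: list[ErrorEvent] = []
    ref_pos = aln.ref_start - 1  # last reference position seen (0 = before first)
    for ref_base, obs_base in zip(aln.aligned_ref, aln.aligned_query):
        if ref_base == "-":
            events.append(ErrorEvent(ref_pos, "insertion", "-", obs_base))
            continue
        ref_pos += 1
        if obs_base == "-":
            events.append(ErrorEvent(ref_pos, "deletion", ref_base, "-"))
        elif obs_base != ref_base:
            if obs_base == "N":
                etype = "transversion" if n_policy == "transversion" else "n_call"
            elif (ref_base, obs_base) in _TRANSITIONS:
                etype = "transition"
            else:
                etype = "transversion"
            events.append(ErrorEvent(ref_pos, etype, ref_base, obs_base))
    return events


@dataclass
class ErrorProfile:
    """Per-position x per-type error counts with a coverage denominator.

    Row index runs 0..L along the reference (position 0 collects insertions
    before the first base; its coverage counts alignments starting at
    position 1).  Adding two profiles adds counts and coverages.
    """

    ref_length: int
    types: tuple[str, ...] = ERROR_TYPES
    scheme: str = ""
    strand: str = ""
    replicate: str = ""
    counts: np.ndarray = field(default=None)  # (L+1, n_types)
    coverage: np.ndarray = field(default=None)  # (L+1,)
    n_records: int = 0
    n_unalignable: int = 0

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((self.ref_length + 1, len(self.types)), dtype=np.int64)
        if self.coverage is None:
            self.coverage = np.zeros(self.ref_length + 1, dtype=np.int64)

    def add_alignment(self, aln: AlignmentResult, events: Iterable[ErrorEvent]) -> None:
        if aln.ref_end >= aln.ref_start:
            self.coverage[aln.ref_start : aln.ref_end + 1] += 1
            if aln.ref_start == 1:
                self.coverage[0] += 1
        type_index = {t: j for j, t in enumerate(self.types)}
        for ev in events:
            self.counts[ev.position, type_index[ev.type]] += 1
        self.n_records += 1

    def rates(self) -> np.ndarray:
        """Count / coverage per position and type; NaN where coverage is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.counts / self.coverage[:, None]
        out[self.coverage == 0] = np.nan
        return out

    def rate_vector(self, etype: str, positions: slice | None = None) -> np.ndarray:
        """Per-position rates for one type over reference positions 1..L."""
        j = self.types.index(etype)
        rates = self.rates()[1:, j]
        return rates if positions is None else rates[positions]

    def summary(self) -> pd.DataFrame:
        """Median and mean rate per error type across covered positions."""
        rows = []
        for etype in self.types:
            vec = self.rate_vector(etype)
            vec = vec[~np.isnan(vec)]
            rows.append(
                {
                    "type": etype,
                    "median_rate": float(np.median(vec)) if vec.size else np.nan,
                    "mean_rate": float(np.mean(vec)) if vec.size else np.nan,
                    "total_errors": int(self.counts[1:, self.types.index(etype)].sum()),
                }
            )
        return pd.DataFrame(rows)

    def overall_rate(
        self,
        types: Sequence[str] | None = None,
        start: int = 1,
        end: int | None = None,
    ) -> float:
        """Pooled errors / pooled coverage over reference positions start..end.

        Local alignment clips a mismatch at the very first or last reference
        position (the clipped alignment always scores higher), so terminal
        positions under-report substitutions; pass ``start=2, end=L-1`` for
        an unbiased interior estimate.
        """
        end = end if end is not None else self.ref_length
        idx = [self.types.index(t) for t in (types or self.types)]
        total_cov = int(self.coverage[start : end + 1].sum())
        if total_cov == 0:
            return float("nan")
        return float(self.counts[start : end + 1, idx].sum() / total_cov)

    def __add__(self, other: "ErrorProfile") -> "ErrorProfile":
        if self.ref_length != other.ref_length or self.types != other.types:
            raise ValueError("profiles must share reference length and type set")
        merged = ErrorProfile(
            ref_length=self.ref_length,
            types=self.types,
            scheme=self.scheme if self.scheme == other.scheme else f"{self.scheme}+{other.scheme}",
            strand=self.strand if self.strand == other.strand else "both",
            replicate=self.replicate
            if self.replicate == other.replicate
            else f"{self.replicate}+{other.replicate}",
        )
        merged.counts = self.counts + other.counts
        merged.coverage = self.coverage + other.coverage
        merged.n_records = self.n_records + other.n_records
        merged.n_unalignable = self.n_unalignable + other.n_unalignable
        return merged

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: scheme, strand, replicate, position, type, count, coverage, rate."""
        rates = self.rates()
        rows = []
        for pos in range(self.ref_length + 1):
            for j, etype in enumerate(self.types):
                rows.append(
                    {
                        "scheme": self.scheme,
                        "strand": self.strand,
                        "replicate": self.replicate,
                        "position": pos,
                        "type": etype,
                        "count": int(self.counts[pos, j]),
                        "coverage": int(self.coverage[pos]),
                        "rate": rates[pos, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_profile(
    records: Iterable[ConsensusRecord | str],
    reference: str,
    params: ScoringParams | None = None,
    *,
    min_score: float | None = None,
    scheme: str = "",
    strand: str = "",
    replicate: str = "",
    n_policy: str = "transversion",
) -> ErrorProfile:
    """Align every record to the reference and accumulate an error profile.

    Records whose strand is "reverse" are reverse-complemented before
    alignment so all positions are in forward reference coordinates (error
    classes are invariant under complementation).  Records scoring below
    ``min_score`` (default: half the maximal match score) are counted as
    unalignable and excluded from coverage.
    """
    params = params or ScoringParams()
    if min_score is None:
        min_score = 0.5 * params.match * len(reference)
    types = ERROR_TYPES if n_policy == "transversion" else ERROR_TYPES + ("n_call",)
    profile = ErrorProfile(
        ref_length=len(reference), types=types, scheme=scheme, strand=strand, replicate=replicate
    )
    for rec in records:
        if isinstance(rec, ConsensusRecord):
            seq = revcomp(rec.sequence) if rec.strand == "reverse" else rec.sequence
        else:
            seq = rec
        aln = align_local(seq, reference, params)
        if aln.score < min_score:
            profile.n_unalignable += 1
            continue
        profile.add_alignment(aln, classify_errors(aln, n_policy=n_policy))
    return profile


def tag_error_probability(p: float, tag_length: int = 16) -> float:
    """Chance of at least one sequencing error within an L-nt tag: 1-(1-p)^L.

    Tag errors inflate the singleton count in the cluster-size distribution,
    since a misread tag looks like a novel molecule.
    """
    if not 0 <= p <= 1:
        raise ValueError("per-nt error rate must lie in [0, 1]")
    if tag_length < 1:
        raise ValueError("tag_length must be >= 1")
    return 1.0 - (1.0 - p) ** tag_length
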