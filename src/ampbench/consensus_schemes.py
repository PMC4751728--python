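"""The four error-correction schemes and the Phred quality filter.

Scheme 1 passes raw reads through untouched.  Scheme 2 (read-pairing
consensus) keeps a mate pair only when the forward payload exactly equals
the reverse complement of the reverse payload.  Scheme 3 (tag-clustering
consensus) groups reads by the combined 16-nt tag, discards groups smaller
than three, and keeps a group only if every member read is identical —
strict unanimity, no majority vote.  Scheme 4 runs Scheme 2 first and then
tag-clusters the surviving paired consensuses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .library_io import ReadPair, TaggedRecord, revcomp


@dataclass(frozen=True)
class ConsensusRecord:
    """A surviving (consensus) sequence with its provenance."""

    sequence: str
    scheme: int
    strand: str  # "forward" | "reverse" | "paired"
    support: int  # raw reads backing this record
    tag_key: str = ""

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class ReadGroup:
    """Reads sharing one combined tag key."""

    tag_key: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def unanimous(self) -> bool:
        return len(set(self.members)) == 1


@dataclass
class SchemeResult:
    """Consensus records plus the retention bookkeeping for one scheme run."""

    scheme: int
    strand: str
    records: list[ConsensusRecord]
    raw_reads: int  # raw reads consumed by this stream
    discards: Counter = field(default_factory=Counter)

    @property
    def retained_reads(self) -> int:
        return sum(r.support for r in self.records)

    @property
    def retention(self) -> float:
        """Consensus records as a fraction of raw reads consumed."""
        return len(self.records) / self.raw_reads if self.raw_reads else 0.0


def quality_filter(record: TaggedRecord, threshold: int = 30) -> bool:
    """True iff every payload base has Phred >= threshold.

    The filter looks only at the target region; low-quality bases in the
    trimmed prefix do not count against the read.
    """
    return all(q >= threshold for q in record.payload_quals)


def filter_pairs_by_quality(
    pairs: list[ReadPair], threshold: int = 30
) -> tuple[list[ReadPair], int]:
    """Keep pairs where BOTH mates pass; returns (kept, n_discarded)."""
    kept = [
        p
        for p in pairs
        if quality_filter(p.fwd, threshold) and quality_filter(p.rev, threshold)
    ]
    return kept, len(pairs) - len(kept)


def scheme1_raw(records: list[TaggedRecord], strand: str = "forward") -> SchemeResult:
    """No correction: one consensus record per raw read, support 1."""
    out = [
        ConsensusRecord(sequence=r.payload, scheme=1, strand=strand, support=1)
        for r in records
    ]
    return SchemeResult(scheme=1, strand=strand, records=out, raw_reads=len(records))


def scheme2_read_pairing(pairs: list[ReadPair]) -> SchemeResult:
    """Read-pairing consensus: exact reverse-complement concordance.

    A retained pair emits one record carrying the forward payload (the mates
    are identical by construction), support 2.  Raw read accounting counts
    both mates, so the ideal error-free retention is 50 %.
    """
    records: list[ConsensusRecord] = []
    discards: Counter = Counter()
    for pair in pairs:
        if len(pair.fwd.payload) != len(pair.rev.payload):
            discards["length_mismatch"] += 1
        elif pair.fwd.payload == revcomp(pair.rev.payload):
            records.append(
                ConsensusRecord(
                    sequence=pair.fwd.payload,
                    scheme=2,
                    strand="paired",
                    support=2,
                    tag_key=pair.combined_tag,
                )
            )
        else:
            discards["mate_mismatch"] += 1
    return SchemeResult(
        scheme=2,
        strand="paired",
        records=records,
        raw_reads=2 * len(pairs),
        discards=discards,
    )


def group_by_tag(keyed_payloads: list[tuple[str, str]]) -> list[ReadGroup]:
    """Bucket (tag_key, payload) items by exact tag key, sorted by key."""
    buckets: dict[str, list[str]] = {}
    for key, payload in keyed_payloads:
        buckets.setdefault(key, []).append(payload)
    return [ReadGroup(key, members) for key, members in sorted(buckets.items())]


def _cluster_consensus(
    groups: list[ReadGroup],
    scheme: int,
    strand: str,
    raw_reads: int,
    min_group_size: int,
    support_per_member: int = 1,
) -> SchemeResult:
    """Unanimity consensus over tag groups (shared by schemes 3 and 4)."""
    records: list[ConsensusRecord] = []
    discards: Counter = Counter()
    for group in groups:  # groups arrive in lexicographic tag order
        if group.size < min_group_size:
            discards["group_too_small"] += group.size
        elif group.unanimous:
            records.append(
                ConsensusRecord(
                    sequence=group.members[0],
                    scheme=scheme,
                    strand=strand,
                    support=group.size * support_per_member,
                    tag_key=group.tag_key,
                )
            )
        else:
            discards["group_not_unanimous"] += group.size
    return SchemeResult(
        scheme=scheme, strand=strand, records=records, raw_reads=raw_reads, discards=discards
    )


def scheme3_tag_clustering(
    pairs: list[ReadPair], strand: str = "forward", min_group_size: int = 3
) -> SchemeResult:
    """Tag-clustering consensus on one read stream.

    The tag key is the combined 16-nt tag (forward-mate tag + reverse-mate
    tag), which requires mate association, but grouping and unanimity run
    independently per stream: the forward stream clusters forward payloads,
    the reverse stream clusters reverse payloads.  Retention is counted
    against the raw reads of that stream.
    """
    if strand not in ("forward", "reverse"):
        raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    keyed = [
        (p.combined_tag, p.fwd.payload if strand == "forward" else p.rev.payload)
        for p in pairs
    ]
    groups = group_by_tag(keyed)
    return _cluster_consensus(
        groups, scheme=3, strand=strand, raw_reads=len(pairs), min_group_size=min_group_size
    )


def scheme4_combined(pairs: list[ReadPair], min_group_size: int = 3) -> SchemeResult:
    """Combined consensus: read-pairing first, then tag-clustering.

    Grouping runs on the paired consensus sequences (not per strand); raw
    read accounting counts both mates, so the ideal error-free retention at
    five pairs per tag is 10 %.
    """
    paired = scheme2_read_pairing(pairs)
    keyed = [(rec.tag_key, rec.sequence) for rec in paired.records]
    groups = group_by_tag(keyed)
    result = _cluster_consensus(
        groups,
        scheme=4,
        strand="paired",
        raw_reads=2 * len(pairs),
        min_group_size=min_group_size,
        support_per_member=2,
    )
    result.discards.update(paired.discards)
    return result


def ideal_retention(copies_per_tag: int) -> dict[str, float]:
    """Closed-form error-free retention fractions at exactly c copies per tag.

    Scheme 2 keeps one record per pair (50 % of raw reads); scheme 3 keeps
    one record per c same-stream reads; scheme 4 keeps one record per 2c raw
    reads.  Note that at c < 3 the min-group-size rule makes the *realized*
    scheme 3/4 retention zero even though the closed form is 1/c.
    """
    if copies_per_tag < 1:
        raise ValueError("copies_per_tag must be >= 1")
    return {
        "scheme2": 0.5,
        "scheme3": 1.0 / copies_per_tag,
        "scheme4": 0.5 / copies_per_tag,
    }


def apply_scheme(
    pairs: list[ReadPair],
    scheme: int,
    strand: str = "forward",
    min_group_size: int = 3,
    quality_threshold: int | None = None,
) -> SchemeResult:
    """Run one correction scheme end to end, with an optional quality pre-filter.

    For the single-stream schemes (1 and 3) ``strand`` selects which mate's
    payloads are processed and the quality filter looks only at that mate;
    schemes 2 and 4 consume both mates and require both to pass.
    """
    n_qc_discarded = 0
    if quality_threshold is not None:
        if scheme in (1, 3):
            kept = [
                p
                for p in pairs
                if quality_filter(p.fwd if strand == "forward" else p.rev, quality_threshold)
            ]
            n_qc_discarded = len(pairs) - len(kept)
            pairs = kept
        else:
            pairs, n_qc_discarded = filter_pairs_by_quality(pairs, quality_threshold)
    if scheme == 1:
        records = [p.fwd if strand == "forward" else p.rev for p in pairs]
        result = scheme1_raw(records, strand=strand)
    elif scheme == 2:
        result = scheme2_read_pairing(pairs)
    elif scheme == 3:
        result = scheme3_tag_clustering(pairs, strand=strand, min_group_size=min_group_size)
    elif scheme == 4:
        result = scheme4_combined(pairs, min_group_size=min_group_size)
    else:
        raise ValueError(f"scheme must be 1..4, got {scheme}")
    if n_qc_discarded:
        per_pair = 2 if scheme in (2, 4) else 1
        result.discards["quality_filtered"] = n_qc_discarded * per_pair
        result.raw_reads += n_qc_discarded * per_pair
    return result
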