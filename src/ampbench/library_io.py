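"""Paired FASTQ I/O, barcode demultiplexing and tag/payload extraction.

Each raw read carries a 12-bp prefix in front of the 88-bp target region:
four random tag nucleotides, a 3-bp replicate barcode, four more random tag
nucleotides, and one trailing base that is trimmed but not part of the tag
key.  The two mates of a pair each contribute 8 random nucleotides, so a
molecule is identified by a combined 16-nt tag.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Raised when a FASTQ stream is malformed or mates are inconsistent."""


@dataclass(frozen=True)
class FastqRecord:
    """One raw FASTQ record (Phred+33 quality string)."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqFormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )


@dataclass(frozen=True)
class TagLayout:
    """Structure of the read prefix ahead of the target payload.

    The default mirrors a prefix of 4 random nt + 3-bp barcode + 4 random nt,
    trimmed as a 12-bp block: the 12th base is consumed but ignored for the
    tag key.  Both the trim length and the tag positions are configurable.
    """

    n_prefix: int = 4
    barcode_len: int = 3
    n_suffix: int = 4
    trim_len: int = 12
    payload_len: int = 88

    def __post_init__(self) -> None:
        if self.n_prefix + self.barcode_len + self.n_suffix > self.trim_len:
            raise ValueError(
                "n_prefix + barcode_len + n_suffix exceeds trim_len "
                f"({self.n_prefix}+{self.barcode_len}+{self.n_suffix} > {self.trim_len})"
            )
        for name in ("n_prefix", "barcode_len", "n_suffix", "trim_len", "payload_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def tag_len(self) -> int:
        """Random tag nucleotides contributed by one mate."""
        return self.n_prefix + self.n_suffix

    @property
    def min_read_len(self) -> int:
        return self.trim_len + self.payload_len


@dataclass(frozen=True)
class TaggedRecord:
    """A demultiplexed read split into barcode, tag and payload."""

    read_id: str
    mate: str  # "forward" | "reverse"
    barcode: str
    tag: str
    payload: str
    payload_quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.payload) != len(self.payload_quals):
            raise ValueError("payload and payload_quals must have equal length")


@dataclass(frozen=True)
class ReadPair:
    """A mate pair; the combined tag (fwd tag + rev tag) keys the molecule."""

    fwd: TaggedRecord
    rev: TaggedRecord

    @property
    def combined_tag(self) -> str:
        return self.fwd.tag + self.rev.tag


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[FastqRecord]:
    """Stream records from a (optionally gzipped) 4-line FASTQ file."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield FastqRecord(title.split()[0], seq.upper(), qual)


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")


def _core_id(read_id: str) -> str:
    """Read id with a trailing /1 or /2 mate suffix removed."""
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


def read_paired_fastq(path_fwd, path_rev) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Stream mate pairs from two FASTQ files in matched file order.

    Mates are matched strictly by position; ids (modulo /1, /2 suffixes) are
    checked and any mismatch or length difference aborts with the offending
    record number and file.
    """
    fwd_iter, rev_iter = read_fastq(path_fwd), read_fastq(path_rev)
    n = 0
    while True:
        fwd = next(fwd_iter, None)
        rev = next(rev_iter, None)
        n += 1
        if fwd is None and rev is None:
            return
        if fwd is None:
            raise FastqFormatError(
                f"{path_fwd} has fewer records than {path_rev} (ended before record {n})"
            )
        if rev is None:
            raise FastqFormatError(
                f"{path_rev} has fewer records than {path_fwd} (ended before record {n})"
            )
        if _core_id(fwd.id) != _core_id(rev.id):
            raise FastqFormatError(
                f"mate id mismatch at record {n}: {fwd.id!r} vs {rev.id!r}"
            )
        yield fwd, rev


def phred_from_string(quality: str) -> tuple[int, ...]:
    """Decode a Phred+33 quality string to integer scores."""
    return tuple(ord(c) - 33 for c in quality)


def phred_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def extract_tag_payload(
    record: FastqRecord, layout: TagLayout, mate: str
) -> TaggedRecord | None:
    """Split a raw read into tag, barcode and payload; None if too short.

    The extraction is a pure slice: prefix + payload re-concatenated equals
    the first ``trim_len + payload_len`` bases of the read.  Payloads
    containing N are retained.
    """
    if len(record.sequence) < layout.min_read_len:
        return None
    seq = record.sequence
    tag = seq[: layout.n_prefix] + seq[
        layout.n_prefix + layout.barcode_len : layout.n_prefix + layout.barcode_len + layout.n_suffix
    ]
    barcode = seq[layout.n_prefix : layout.n_prefix + layout.barcode_len]
    payload = seq[layout.trim_len : layout.trim_len + layout.payload_len]
    quals = phred_from_string(
        record.quality[layout.trim_len : layout.trim_len + layout.payload_len]
    )
    return TaggedRecord(
        read_id=_core_id(record.id),
        mate=mate,
        barcode=barcode,
        tag=tag,
        payload=payload,
        payload_quals=quals,
    )


def demultiplex(pair: ReadPair, barcode_map: dict[str, str]) -> str | None:
    """Replicate label when BOTH mates carry the same mapped barcode, else None.

    Barcode matching is exact: 3 bp is too short for mismatch tolerance.
    """
    label_f = barcode_map.get(pair.fwd.barcode)
    label_r = barcode_map.get(pair.rev.barcode)
    if label_f is not None and label_f == label_r:
        return label_f
    return None


@dataclass
class PairingStats:
    """Conservation accounting: pairs_in == retained + sum(discards)."""

    pairs_in: int = 0
    retained: int = 0
    discards: Counter = field(default_factory=Counter)

    def check_conservation(self) -> bool:
        return self.pairs_in == self.retained + sum(self.discards.values())


def load_read_pairs(
    path_fwd,
    path_rev,
    layout: TagLayout | None = None,
    barcode_map: dict[str, str] | None = None,
) -> tuple[dict[str, list[ReadPair]], PairingStats]:
    """Full intake: parse, extract, and (optionally) demultiplex mate pairs.

    Returns pairs bucketed by replicate label ("*" when no barcode_map is
    given) plus discard accounting (too-short reads, barcode mismatches).
    """
    layout = layout or TagLayout()
    stats = PairingStats()
    buckets: dict[str, list[ReadPair]] = {}
    for raw_fwd, raw_rev in read_paired_fastq(path_fwd, path_rev):
        stats.pairs_in += 1
        fwd = extract_tag_payload(raw_fwd, layout, "forward")
        rev = extract_tag_payload(raw_rev, layout, "reverse")
        if fwd is None or rev is None:
            stats.discards["read_too_short"] += 1
            continue
        pair = ReadPair(fwd, rev)
        if barcode_map is None:
            label = "*"
        else:
            label = demultiplex(pair, barcode_map)
            if label is None:
                stats.discards["barcode_mismatch"] += 1
                continue
        stats.retained += 1
        buckets.setdefault(label, []).append(pair)
    return buckets, stats


def tag_pairs(
    raw_pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    layout: TagLayout | None = None,
) -> list[ReadPair]:
    """Tag/payload-extract in-memory mate pairs (no FASTQ round trip).

    Pairs with a too-short mate are dropped silently; use load_read_pairs
    for full discard accounting on files.
    """
    layout = layout or TagLayout()
    out = []
    for raw_fwd, raw_rev in raw_pairs:
        fwd = extract_tag_payload(raw_fwd, layout, "forward")
        rev = extract_tag_payload(raw_rev, layout, "reverse")
        if fwd is not None and rev is not None:
            out.append(ReadPair(fwd, rev))
    return out


def write_discard_counts(stats: PairingStats, path) -> None:
    """Emit discard-reason counts as a two-column TSV."""
    with open(path, "w") as handle:
        handle.write("reason\tcount\n")
        handle.write(f"pairs_in\t{stats.pairs_in}\n")
        handle.write(f"retained\t{stats.retained}\n")
        for reason, count in sorted(stats.discards.items()):
            handle.write(f"{reason}\t{count}\n")
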