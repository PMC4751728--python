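"""Simulate clonal tagged amplicon libraries with known ground truth.

The generator emulates the benchmarked experimental design: a single 88-bp clonal
template (the protein G antibody-interacting domain fragment), a 16-nt random
tag per molecule (8 nt embedded in each primer), a 3-bp replicate barcode on
both mates, roughly five sequenced copies per tagged molecule, and
strand-asymmetric sequencing error rates (reverse reads ~3x the forward
rate).  Every injected error is logged in a truth table so that each
downstream correction scheme can be validated against known ground truth.

Reads are emitted at fixed length (prefix + payload): an injected deletion
pulls one downstream non-template base into the read and an insertion pushes
the last template base off the end, as on a real fixed-cycle sequencer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .library_io import FastqRecord, TagLayout, phred_to_string, revcomp, write_fastq

#: The 88-bp clonal amplicon: a fragment of the protein G
#: antibody-interacting domain, including both primer annealing regions.
PROTEIN_G_AMPLICON = (
    "AGTACGCTAACGACAACGGTGTCGACGGTGAATGGACCTACGACGACGCTACCAAAACCTTCACGGTTACC"
    "GAATCCGGAGGATCCGA"
)

#: Replicate barcodes carried by both primers of each technical replicate.
REPLICATE_BARCODES = {"ACA": "replicate1", "GTG": "replicate2"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class CopiesModel:
    """Distribution of sequenced copies (read pairs) per tagged molecule.

    ``fixed(c)`` yields exactly c copies; ``poisson(lam)`` is Poisson
    truncated at >= 1 (a molecule that was never sequenced is unobservable).
    With lam = 5 the truncated mean is ~5.03, matching the expectation of
    about five sequenced copies per tagged molecule.
    """

    kind: str
    value: float

    @classmethod
    def fixed(cls, c: int) -> "CopiesModel":
        return cls("fixed", c)

    @classmethod
    def poisson(cls, lam: float) -> "CopiesModel":
        return cls("poisson", lam)

    def validate(self) -> None:
        if self.kind not in ("fixed", "poisson"):
            raise SimConfigError(f"copies.kind: unknown model {self.kind!r}")
        if self.kind == "fixed" and (self.value < 1 or self.value != int(self.value)):
            raise SimConfigError("copies.value: fixed copy count must be a positive integer")
        if self.kind == "poisson" and self.value <= 0:
            raise SimConfigError("copies.value: poisson rate must be positive")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return int(self.value)
        # zero-truncated Poisson by rejection; cheap at lam ~ 5
        while True:
            k = int(rng.poisson(self.value))
            if k >= 1:
                return k


@dataclass(frozen=True)
class QualityModel:
    """Phred scores by error status.

    Correct bases get a single high score; erroneous (substituted or
    inserted) bases draw uniformly from a low range, so quality filtering is
    meaningfully correlated with the injected errors.
    """

    correct_phred: int = 37
    error_phred_min: int = 2
    error_phred_max: int = 30

    def validate(self) -> None:
        if not (0 <= self.error_phred_min <= self.error_phred_max <= 41):
            raise SimConfigError("quality: error Phred range must satisfy 0 <= min <= max <= 41")
        if not (0 <= self.correct_phred <= 41):
            raise SimConfigError("quality.correct_phred: out of Phred range")


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification of one synthetic library (one replicate)."""

    n_molecules: int
    template: str = PROTEIN_G_AMPLICON
    copies: CopiesModel = field(default_factory=lambda: CopiesModel.poisson(5.0))
    sub_rate_fwd: float | Sequence[float] = 1e-3
    sub_rate_rev: float | Sequence[float] = 3e-3
    ins_rate: float = 5e-5
    del_rate: float = 1e-4
    hotspots: tuple[tuple[int, str, float], ...] = ()
    planted_variants: tuple[tuple[str, float], ...] = ()
    quality: QualityModel = field(default_factory=QualityModel)
    tag_len_per_primer: int = 8
    barcode: str = "ACA"
    layout: TagLayout = field(default_factory=TagLayout)
    seed: int = 0

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise SimConfigError("n_molecules: must be a positive integer")
        if not self.template or set(self.template) - set("ACGT"):
            raise SimConfigError("template: must be a nonempty A/C/G/T string")
        self.copies.validate()
        self.quality.validate()
        for name in ("sub_rate_fwd", "sub_rate_rev"):
            rates = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if rates.ndim != 1 or np.any(rates < 0) or np.any(rates > 1):
                raise SimConfigError(f"{name}: rates must lie in [0, 1]")
            if rates.size not in (1, len(self.template)):
                raise SimConfigError(
                    f"{name}: per-position vector must have length {len(self.template)}"
                )
        for name in ("ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise SimConfigError(f"{name}: rate must lie in [0, 1]")
        for pos, strand, rate in self.hotspots:
            if not 1 <= pos <= len(self.template):
                raise SimConfigError(f"hotspots: position {pos} outside 1..{len(self.template)}")
            if strand not in ("forward", "reverse"):
                raise SimConfigError(f"hotspots: unknown strand {strand!r}")
            if not 0 <= rate <= 1:
                raise SimConfigError("hotspots: rate must lie in [0, 1]")
        total_freq = 0.0
        for seq, freq in self.planted_variants:
            if not seq or set(seq) - set("ACGT"):
                raise SimConfigError("planted_variants: sequences must be A/C/G/T")
            if not 0 < freq < 1:
                raise SimConfigError("planted_variants: frequencies must lie in (0, 1)")
            total_freq += freq
        if total_freq >= 1:
            raise SimConfigError("planted_variants: frequencies must sum to < 1")
        if self.tag_len_per_primer != self.layout.tag_len:
            raise SimConfigError(
                "tag_len_per_primer: must equal layout.n_prefix + layout.n_suffix "
                f"({self.layout.tag_len})"
            )
        if len(self.barcode) != self.layout.barcode_len or set(self.barcode) - set("ACGT"):
            raise SimConfigError(
                f"barcode: must be an A/C/G/T string of length {self.layout.barcode_len}"
            )
        if self.layout.payload_len != len(self.template):
            raise SimConfigError(
                "layout.payload_len: must equal the template length "
                f"({len(self.template)})"
            )


@dataclass(frozen=True)
class Molecule:
    """One tagged template molecule: the unit the tag-clustering scheme recovers."""

    molecule_id: str
    tag_fwd: str
    tag_rev: str
    true_sequence: str
    variant_label: str  # "template" or "variant<k>"

    @property
    def combined_tag(self) -> str:
        return self.tag_fwd + self.tag_rev


@dataclass
class TruthTable:
    """Ground truth: molecule -> tag map plus every injected read error.

    ``molecules`` has one row per tagged molecule; ``reads`` one row per
    emitted read (mate pairs give two rows sharing ``read_id``).  Injected
    errors are encoded ``region:pos:type:from:to`` joined by ``;`` where
    ``pos`` is 1-based in the unmutated read region (payload positions are in
    read orientation).
    """

    molecules: pd.DataFrame
    reads: pd.DataFrame

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.molecules.to_csv(directory / "truth_molecules.tsv", sep="\t", index=False)
        self.reads.to_csv(directory / "truth_reads.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory) -> "TruthTable":
        directory = Path(directory)
        molecules = pd.read_csv(directory / "truth_molecules.tsv", sep="\t")
        reads = pd.read_csv(
            directory / "truth_reads.tsv", sep="\t", keep_default_na=False
        )
        return cls(molecules, reads)


@dataclass
class SimulatedLibrary:
    """Output bundle: raw mate pairs plus the generating truth."""

    pairs: list[tuple[FastqRecord, FastqRecord]]
    truth: TruthTable
    config: SimConfig


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def generate_molecules(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[Molecule]:
    """Draw tagged molecules: independent uniform tags, variants by frequency.

    Tag collisions are allowed (the tag space is 4^16 ~ 4e9 for the default
    layout, so collisions are rare but possible) and simply recorded.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tag_len = config.tag_len_per_primer
    # variant assignment by cumulative frequency
    freqs = np.array([f for _, f in config.planted_variants], dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(freqs)]) if freqs.size else np.array([0.0])
    draws = rng.random(config.n_molecules)
    molecules = []
    for i in range(config.n_molecules):
        tag_fwd = _random_dna(rng, tag_len)
        tag_rev = _random_dna(rng, tag_len)
        idx = int(np.searchsorted(edges, draws[i], side="right")) - 1
        if config.planted_variants and idx < len(config.planted_variants):
            seq = config.planted_variants[idx][0]
            label = f"variant{idx + 1}"
        else:
            seq, label = config.template, "template"
        molecules.append(Molecule(f"M{i:07d}", tag_fwd, tag_rev, seq, label))
    return molecules


def _strand_sub_rates(config: SimConfig, strand: str, length: int) -> np.ndarray:
    """Per-position substitution rates in READ orientation for one strand."""
    base = config.sub_rate_fwd if strand == "forward" else config.sub_rate_rev
    rates = np.full(length, float(np.mean(base)), dtype=float)
    arr = np.atleast_1d(np.asarray(base, dtype=float))
    if arr.size == length:
        rates[:] = arr if strand == "forward" else arr[::-1]
    for pos, hs_strand, rate in config.hotspots:
        if hs_strand != strand:
            continue
        # hotspot positions are 1-based in reference coordinates
        idx = pos - 1 if strand == "forward" else length - pos
        rates[idx] = rate
    return rates


def _mutate(
    true_seq: str,
    sub_rates: np.ndarray,
    ins_rate: float,
    del_rate: float,
    quality: QualityModel,
    rng: np.random.Generator,
) -> tuple[str, list[int], list[str]]:
    """Inject per-nt substitution/indel errors into one read region.

    Returns (mutated sequence, per-base Phred list, error log entries with
    1-based positions in the *true* sequence).  Indels are single-base
    events; an insertion is placed after the position it is logged at.
    """
    n = len(true_seq)
    sub_mask = rng.random(n) < sub_rates if np.any(sub_rates > 0) else None
    ins_mask = rng.random(n) < ins_rate if ins_rate > 0 else None
    del_mask = rng.random(n) < del_rate if del_rate > 0 else None
    if sub_mask is None and ins_mask is None and del_mask is None:
        return true_seq, [quality.correct_phred] * n, []

    out: list[str] = []
    quals: list[int] = []
    errors: list[str] = []

    def err_qual() -> int:
        return int(rng.integers(quality.error_phred_min, quality.error_phred_max + 1))

    for i, base in enumerate(true_seq):
        if del_mask is not None and del_mask[i]:
            errors.append(f"{i + 1}:del:{base}:-")
        elif sub_mask is not None and sub_mask[i]:
            alternatives = _BASE_STR.replace(base, "")
            new = alternatives[int(rng.integers(0, 3))]
            out.append(new)
            quals.append(err_qual())
            errors.append(f"{i + 1}:sub:{base}:{new}")
        else:
            out.append(base)
            quals.append(quality.correct_phred)
        if ins_mask is not None and ins_mask[i]:
            ins_base = _BASE_STR[int(rng.integers(0, 4))]
            out.append(ins_base)
            quals.append(err_qual())
            errors.append(f"{i + 1}:ins:-:{ins_base}")
    return "".join(out), quals, errors


def _build_read(
    molecule: Molecule,
    strand: str,
    config: SimConfig,
    sub_rates: np.ndarray,
    rng: np.random.Generator,
) -> tuple[str, str, list[str]]:
    """Assemble one fixed-length raw read: 12-bp prefix + 88-bp region."""
    layout = config.layout
    tag = molecule.tag_fwd if strand == "forward" else molecule.tag_rev
    filler_len = layout.trim_len - layout.tag_len - layout.barcode_len
    filler = _random_dna(rng, filler_len) if filler_len else ""
    prefix_true = tag[: layout.n_prefix] + config.barcode + tag[layout.n_prefix :] + filler
    prefix_rate = float(
        np.mean(config.sub_rate_fwd if strand == "forward" else config.sub_rate_rev)
    )
    prefix, prefix_quals, prefix_errors = _mutate(
        prefix_true, np.full(len(prefix_true), prefix_rate), 0.0, 0.0, config.quality, rng
    )
    payload_true = (
        molecule.true_sequence if strand == "forward" else revcomp(molecule.true_sequence)
    )
    payload, payload_quals, payload_errors = _mutate(
        payload_true, sub_rates, config.ins_rate, config.del_rate, config.quality, rng
    )
    # fixed read length: deletions pull in downstream non-template bases,
    # insertions push template bases off the read end
    target = layout.payload_len
    if len(payload) < target:
        pad = _random_dna(rng, target - len(payload))
        payload += pad
        payload_quals += [config.quality.correct_phred] * len(pad)
    elif len(payload) > target:
        payload = payload[:target]
        payload_quals = payload_quals[:target]
    seq = prefix + payload
    qual = phred_to_string(prefix_quals + payload_quals)
    errors = [f"prefix:{e}" for e in prefix_errors] + [f"payload:{e}" for e in payload_errors]
    return seq, qual, errors


def simulate_reads(
    molecules: list[Molecule],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[FastqRecord, FastqRecord]], TruthTable]:
    """Sample sequenced copies of each molecule and emit raw mate pairs.

    Each copy yields a forward read (tag/barcode prefix + target region) and
    a reverse read (its own prefix + reverse-complemented target region),
    with independent per-strand errors and matching /1 and /2 ids.
    """
    if not molecules:
        raise ValueError("molecules must be nonempty")
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    length = config.layout.payload_len
    rates_fwd = _strand_sub_rates(config, "forward", length)
    rates_rev = _strand_sub_rates(config, "reverse", length)

    pairs: list[tuple[FastqRecord, FastqRecord]] = []
    read_rows: list[dict] = []
    for mol in molecules:
        n_copies = config.copies.sample(rng)
        for copy in range(n_copies):
            read_id = f"{mol.molecule_id}_C{copy + 1}"
            seq_f, qual_f, err_f = _build_read(mol, "forward", config, rates_fwd, rng)
            seq_r, qual_r, err_r = _build_read(mol, "reverse", config, rates_rev, rng)
            pairs.append(
                (
                    FastqRecord(f"{read_id}/1", seq_f, qual_f),
                    FastqRecord(f"{read_id}/2", seq_r, qual_r),
                )
            )
            for mate, errs in (("forward", err_f), ("reverse", err_r)):
                read_rows.append(
                    {
                        "read_id": read_id,
                        "molecule_id": mol.molecule_id,
                        "mate": mate,
                        "n_errors": len(errs),
                        "errors": ";".join(errs),
                    }
                )
    mol_rows = [
        {
            "molecule_id": m.molecule_id,
            "tag": m.combined_tag,
            "variant_label": m.variant_label,
            "true_sequence": m.true_sequence,
        }
        for m in molecules
    ]
    truth = TruthTable(pd.DataFrame(mol_rows), pd.DataFrame(read_rows))
    return pairs, truth


def simulate_library(
    config: SimConfig,
    out_fwd=None,
    out_rev=None,
    truth_dir=None,
) -> SimulatedLibrary:
    """Generate a full library; optionally write FASTQ mates and truth TSVs.

    Identical seed and config give byte-identical output files.
    """
    rng = np.random.default_rng(config.seed)
    molecules = generate_molecules(config, rng)
    pairs, truth = simulate_reads(molecules, config, rng)
    if out_fwd is not None:
        write_fastq((p[0] for p in pairs), out_fwd)
    if out_rev is not None:
        write_fastq((p[1] for p in pairs), out_rev)
    if truth_dir is not None:
        truth.write(truth_dir)
    return SimulatedLibrary(pairs, truth, config)


def load_sim_config(path, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a YAML key/value file; ``seed`` overrides."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    kwargs: dict = {}
    if "copies" in raw:
        spec = raw.pop("copies")
        (kind, value), = spec.items()
        kwargs["copies"] = CopiesModel(kind, float(value))
    if "quality" in raw:
        kwargs["quality"] = QualityModel(**raw.pop("quality"))
    if "layout" in raw:
        kwargs["layout"] = TagLayout(**raw.pop("layout"))
    if "hotspots" in raw:
        kwargs["hotspots"] = tuple(
            (int(p), str(s), float(r)) for p, s, r in raw.pop("hotspots")
        )
    if "planted_variants" in raw:
        kwargs["planted_variants"] = tuple(
            (str(s), float(f)) for s, f in raw.pop("planted_variants")
        )
    kwargs.update(raw)
    config = SimConfig(**kwargs)
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    return config
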