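"""Sequence input/output, the standard genetic code and codon extraction.

All internal computation uses the RNA alphabet (``U`` rather than ``T``);
DNA input is canonicalized on construction.  The standard genetic code is
taken from Biopython's NCBI table 1 and reorganized into synonymous-codon
families, the unit on which every codon-usage statistic operates.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_rna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RNA_BASES",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CODON_TO_AA",
    "SYNONYMOUS_FAMILIES",
    "DEGENERACY",
    "DEGENERACY_CLASSES",
    "SYNONYMOUS_CODONS_59",
    "AA_THREE_LETTER",
    "CodingSequence",
    "ReferenceUsageTable",
    "read_fasta",
    "write_fasta",
    "extract_codons",
    "parse_usage_table",
]

RNA_BASES = "UCAG"

_TABLE = unambiguous_rna_by_id[1]  # the standard genetic code

#: codon -> one-letter amino acid, with stops mapped to "*" (64 entries).
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*"))

#: amino acid -> tuple of synonymous codons, multi-codon families only
#: (Met and Trp, the two single-codon amino acids, are excluded).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_codon], [])
    SYNONYMOUS_FAMILIES[CODON_TO_AA[_codon]].append(_codon)
SYNONYMOUS_FAMILIES = {
    aa: tuple(sorted(codons))
    for aa, codons in SYNONYMOUS_FAMILIES.items()
    if len(codons) > 1
}

#: amino acid -> number of synonymous codons (2, 3, 4 or 6).
DEGENERACY: dict[str, int] = {aa: len(c) for aa, c in SYNONYMOUS_FAMILIES.items()}

#: degeneracy class -> amino acids: 9 two-fold, Ile alone three-fold,
#: 5 four-fold, and Leu/Ser/Arg six-fold — 59 synonymous codons in total.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _n in sorted(DEGENERACY.items()):
    DEGENERACY_CLASSES.setdefault(_n, [])
    DEGENERACY_CLASSES[_n].append(_aa)
DEGENERACY_CLASSES = {n: tuple(aas) for n, aas in DEGENERACY_CLASSES.items()}

#: the 59 synonymous codons in conventional report order: families ordered
#: Phe..Gly as codon tables print them, codons within a family by position
#: in the codon table (U, C, A, G at the wobble base).
SYNONYMOUS_CODONS_59: tuple[str, ...] = (
    "UUU", "UUC",
    "UUA", "UUG", "CUU", "CUC", "CUA", "CUG",
    "AUU", "AUC", "AUA",
    "GUU", "GUC", "GUA", "GUG",
    "UCU", "UCC", "UCA", "UCG", "AGU", "AGC",
    "CCU", "CCC", "CCA", "CCG",
    "ACU", "ACC", "ACA", "ACG",
    "GCU", "GCC", "GCA", "GCG",
    "UAU", "UAC",
    "CAU", "CAC",
    "CAA", "CAG",
    "AAU", "AAC",
    "AAA", "AAG",
    "GAU", "GAC",
    "GAA", "GAG",
    "UGU", "UGC",
    "CGU", "CGC", "CGA", "CGG", "AGA", "AGG",
    "GGU", "GGC", "GGA", "GGG",
)

AA_THREE_LETTER: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_VALID_CHARS = frozenset("ACGUN")


def canonicalize(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U."""
    return seq.upper().replace("T", "U")


@dataclass
class CodingSequence:
    """One coding sequence (CDS), stored in the RNA alphabet.

    Parameters
    ----------
    id : str
        Accession-like label.
    seq : str
        Nucleotide string over {A, C, G, T/U, N}; canonicalized to RNA.
    meta : dict, optional
        Free-form annotation (origin, isolation year, ...).
    """

    id: str
    seq: str
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = canonicalize(self.seq)
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )
        if len(self.seq) < 3:
            raise ValueError(f"sequence {self.id!r} is shorter than one codon")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceUsageTable:
    """A 64-codon usage table for a reference organism or gene set.

    ``counts`` may hold raw codon counts or per-thousand frequencies; every
    downstream use (reference RSCU, CAI weights) is scale-invariant.
    """

    source: str
    counts: dict[str, float]

    def __post_init__(self) -> None:
        counts = {canonicalize(c): float(v) for c, v in self.counts.items()}
        unknown = set(counts) - set(CODON_TO_AA)
        if unknown:
            raise ValueError(f"unknown codons in usage table: {sorted(unknown)}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("usage counts must be non-negative")
        missing = set(CODON_TO_AA) - set(counts)
        if missing:
            warnings.warn(
                f"usage table {self.source!r}: {len(missing)} codons absent, "
                "defaulting to count 0"
            )
            for c in missing:
                counts[c] = 0.0
        self.counts = counts


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a (multi-record) FASTA file into :class:`CodingSequence` records.

    The header token before the first whitespace becomes the id; sequences
    are uppercased and T is mapped to U.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, expected '>' header at line {lineno}"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(CodingSequence(id=rec.id, seq=str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences to FASTA (RNA alphabet as stored)."""
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def extract_codons(
    cds: CodingSequence | str,
    *,
    truncate: bool = False,
    allow_internal_stop: bool = False,
) -> list[str]:
    """Split a CDS into frame-0 codons, applying the eligibility rules.

    A trailing stop codon is removed; codons containing N are dropped with
    a warning.  A length not divisible by 3 is an error unless ``truncate``
    trims the incomplete tail; an internal stop codon is an error unless
    ``allow_internal_stop`` keeps it (it is then excluded from the output,
    since no usage statistic is defined for stop codons).
    """
    seq = cds.seq if isinstance(cds, CodingSequence) else canonicalize(cds)
    label = cds.id if isinstance(cds, CodingSequence) else "<sequence>"
    if len(seq) % 3 != 0:
        if truncate:
            seq = seq[: len(seq) - len(seq) % 3]
        else:
            raise ValueError(
                f"{label}: length {len(seq)} not divisible by 3 "
                "(pass truncate=True to trim)"
            )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    out: list[str] = []
    dropped = 0
    for pos, codon in enumerate(codons, start=1):
        if "N" in codon:
            dropped += 1
            continue
        if codon in STOP_CODONS:
            if allow_internal_stop:
                dropped += 1
                continue
            raise ValueError(f"{label}: internal stop codon {codon} at codon {pos}")
        out.append(codon)
    if dropped:
        warnings.warn(f"{label}: dropped {dropped} ambiguous/stop codon(s)")
    return out


_KAZUSA_FIELD = re.compile(r"([ACGTUacgtu]{3})\s+([\d.]+)\s*\(\s*(\d+)\s*\)")


def parse_usage_table(path: str | Path, source: str | None = None) -> ReferenceUsageTable:
    """Parse a codon-usage table file.

    Two dialects are accepted: the Kazusa codon-usage-database text format
    (``UUU 17.6 (714298)`` triplets, any layout) and a simple two-column
    ``codon,count`` (or whitespace-separated) format.  Missing codons
    default to count 0 with a warning; duplicate codons are an error.
    """
    path = Path(path)
    text = path.read_text()
    source = source or path.stem
    counts: dict[str, float] = {}

    def add(token: str, value: float) -> None:
        codon = canonicalize(token)
        if codon not in CODON_TO_AA:
            raise ValueError(f"{path}: unknown codon token {token!r}")
        if codon in counts:
            raise ValueError(f"{path}: duplicate codon {codon}")
        counts[codon] = value

    matches = _KAZUSA_FIELD.findall(text)
    if matches:
        for token, _freq, count in matches:
            add(token, float(count))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in re.split(r"[,\s]+", line) if p]
            if len(parts) < 2:
                raise ValueError(f"{path}: cannot parse line {lineno}: {line!r}")
            add(parts[0], float(parts[1]))
    if not counts:
        raise ValueError(f"{path}: no codon entries found")
    return ReferenceUsageTable(source=source, counts=counts)
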