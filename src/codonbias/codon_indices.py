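"""Codon-usage indices: RSCU, effective number of codons and CAI.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by its expected count under uniform usage within its synonymous
family.  ENc (effective number of codons, Wright 1990) summarizes overall
bias on a 20–61 scale from per-family codon homozygosities averaged within
degeneracy classes.  CAI (codon adaptation index, Sharp & Li 1987) is the
geometric mean of per-codon relative adaptiveness w against a reference
usage table.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_io import (
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    SENSE_CODONS,
    SYNONYMOUS_CODONS_59,
    SYNONYMOUS_FAMILIES,
    CodingSequence,
    ReferenceUsageTable,
    extract_codons,
)

__all__ = [
    "CodonCountTable",
    "RscuVector",
    "EncValue",
    "CaiValue",
    "PreferredCodonReport",
    "rscu",
    "enc",
    "expected_enc",
    "cai",
    "preferred_codons",
]


@dataclass
class CodonCountTable:
    """64-codon count vector for one sequence or a pooled set."""

    counts: dict[str, float]
    label: str = "counts"

    def __post_init__(self) -> None:
        full = {c: 0.0 for c in CODON_TO_AA}
        for codon, v in self.counts.items():
            if codon not in full:
                raise ValueError(f"unknown codon {codon!r}")
            if v < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] = float(v)
        self.counts = full

    @classmethod
    def from_codons(cls, codons: Iterable[str], label: str = "counts") -> "CodonCountTable":
        return cls(counts=dict(Counter(codons)), label=label)

    @classmethod
    def from_sequence(cls, cds: CodingSequence, **kwargs) -> "CodonCountTable":
        return cls.from_codons(extract_codons(cds, **kwargs), label=cds.id)

    @classmethod
    def from_sequences(
        cls, seqs: Iterable[CodingSequence], label: str = "pool", **kwargs
    ) -> "CodonCountTable":
        pooled: Counter = Counter()
        for s in seqs:
            pooled.update(extract_codons(s, **kwargs))
        return cls(counts=dict(pooled), label=label)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in self.counts}
        return CodonCountTable(counts=merged, label=f"{self.label}+{other.label}")

    def family_total(self, aa: str) -> float:
        return sum(self.counts[c] for c in SYNONYMOUS_FAMILIES[aa])

    @property
    def total(self) -> float:
        return sum(self.counts.values())


@dataclass
class RscuVector:
    """RSCU values for the 59 synonymous codons.

    Codons of families unobserved in the source counts carry NaN (missing),
    not 0: an RSCU of 0 means "family seen, codon never used".
    """

    values: dict[str, float]
    source: str = "rscu"
    family_totals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(SYNONYMOUS_CODONS_59) - set(self.values)
        if missing:
            raise ValueError(f"RSCU vector missing codons: {sorted(missing)}")

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]

    def as_array(self, codons: Sequence[str] = SYNONYMOUS_CODONS_59) -> np.ndarray:
        return np.array([self.values[c] for c in codons], dtype=float)


def rscu(counts: CodonCountTable, source: str | None = None) -> RscuVector:
    """RSCU_ij = X_ij / ((1/n_i) Σ_j X_ij) within each synonymous family."""
    values: dict[str, float] = {}
    totals: dict[str, float] = {}
    any_observed = False
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        tot = counts.family_total(aa)
        totals[aa] = tot
        if tot == 0:
            for c in codons:
                values[c] = math.nan
            continue
        any_observed = True
        expected = tot / len(codons)
        for c in codons:
            values[c] = counts.counts[c] / expected
    if not any_observed:
        raise ValueError("all-zero counts: RSCU undefined")
    return RscuVector(
        values=values, source=source or counts.label, family_totals=totals
    )


@dataclass
class EncValue:
    """Effective number of codons with its per-class mean homozygosities."""

    value: float
    class_means: dict[int, float]
    family_f: dict[str, float]
    family_n: dict[str, float]


def enc(counts: CodonCountTable) -> EncValue:
    """Wright's effective number of codons.

    Per family with total n ≥ 2, the codon homozygosity is
    F̂ = (n Σ p̂² − 1) / (n − 1); class means average F̂ over families with
    F̂ > 0.  ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6; an absent three-fold
    class mean (Ile unobserved) is replaced by (F̄2 + F̄4)/2, and the result
    is capped at 61.
    """
    family_f: dict[str, float] = {}
    family_n: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        n = counts.family_total(aa)
        family_n[aa] = n
        if n < 2:
            continue
        p2 = sum((counts.counts[c] / n) ** 2 for c in codons)
        f_hat = (n * p2 - 1.0) / (n - 1.0)
        if f_hat > 0:
            family_f[aa] = f_hat

    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = [family_f[aa] for aa in aas if aa in family_f]
        if fs:
            class_means[k] = float(np.mean(fs))
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    missing = [k for k in DEGENERACY_CLASSES if k not in class_means]
    if missing:
        raise ValueError(
            f"ENc not computable: no usable family in degeneracy class(es) {missing}"
        )
    value = (
        2.0
        + 9.0 / class_means[2]
        + 1.0 / class_means[3]
        + 5.0 / class_means[4]
        + 3.0 / class_means[6]
    )
    return EncValue(
        value=min(value, 61.0),
        class_means=class_means,
        family_f=family_f,
        family_n=family_n,
    )


def expected_enc(s: float) -> float:
    """Null-model ENc at synonymous GC3 fraction ``s``:
    2 + s + 29 / (s² + (1 − s)²)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass
class CaiValue:
    """Codon adaptation index with its relative-adaptiveness table."""

    value: float
    w: dict[str, float]
    reference: str


def _reference_weights(
    ref: ReferenceUsageTable | RscuVector, pseudocount: float
) -> dict[str, float]:
    """w_ij = RSCU_ij(ref) / max_j RSCU_ij(ref) for the 59 synonymous codons."""
    if isinstance(ref, RscuVector):
        ref_rscu = dict(ref.values)
    else:
        adjusted = {
            c: (v if v > 0 else pseudocount) for c, v in ref.counts.items()
        }
        ref_rscu = {}
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            tot = sum(adjusted[c] for c in codons)
            for c in codons:
                ref_rscu[c] = adjusted[c] * len(codons) / tot
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        fam = {c: ref_rscu[c] for c in codons}
        if any(math.isnan(v) for v in fam.values()):
            raise ValueError(f"reference RSCU missing for family {aa}")
        top = max(fam.values())
        if top <= 0:
            raise ValueError(f"reference family {aa} has no usage")
        for c, v in fam.items():
            w[c] = v / top
    return w


def cai(
    counts: CodonCountTable,
    ref: ReferenceUsageTable | RscuVector,
    *,
    include_single_codon: bool = False,
    pseudocount: float = 0.5,
) -> CaiValue:
    """Codon adaptation index of ``counts`` against a reference.

    Zero reference counts are replaced by ``pseudocount`` before the
    reference RSCU is formed (Sharp & Li convention).  By default the
    geometric mean runs over the 59 synonymous codons only; set
    ``include_single_codon`` for the dialect that also counts Met and Trp
    (their w ≡ 1 dilutes the index toward 1).
    """
    w = _reference_weights(ref, pseudocount)
    if include_single_codon:
        for aa in ("M", "W"):
            for codon, mapped in CODON_TO_AA.items():
                if mapped == aa:
                    w[codon] = 1.0
    log_sum = 0.0
    n = 0.0
    for codon, weight in w.items():
        k = counts.counts[codon]
        if k == 0:
            continue
        if weight <= 0:
            # a codon absent from the reference but present in the query:
            # pseudocount makes this unreachable for count-based references
            raise ValueError(f"zero reference weight for used codon {codon}")
        log_sum += k * math.log(weight)
        n += k
    if n == 0:
        raise ValueError("no scoreable codons in query")
    ref_label = ref.source if hasattr(ref, "source") else "reference"
    return CaiValue(value=math.exp(log_sum / n), w=w, reference=ref_label)


@dataclass
class PreferredCodonReport:
    """Per-family preferred codon (max RSCU) and the wobble-base tally."""

    winners: dict[str, str]
    ties: set[str]
    end_ac: int
    end_ug: int


def preferred_codons(vector: RscuVector) -> PreferredCodonReport:
    """The preferred codon of each of the 18 degenerate families.

    Ties are broken lexicographically and flagged.  Families missing from
    the vector are skipped with a warning and a partial result returned.
    """
    winners: dict[str, str] = {}
    ties: set[str] = set()
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        fam = {c: vector.values[c] for c in codons}
        if any(math.isnan(v) for v in fam.values()):
            warnings.warn(f"family {aa} missing from RSCU vector; skipped")
            continue
        top = max(fam.values())
        best = sorted(c for c, v in fam.items() if v == top)
        winners[aa] = best[0]
        if len(best) > 1:
            ties.add(aa)
    end_ac = sum(1 for c in winners.values() if c[2] in "AC")
    end_ug = sum(1 for c in winners.values() if c[2] in "UG")
    return PreferredCodonReport(winners=winners, ties=ties, end_ac=end_ac, end_ug=end_ug)
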