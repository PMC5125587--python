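"""Virus–host codon-usage comparison: RSCU bins, similarity index D(A,B), tAI.

A codon is *over-represented* at RSCU ≥ 1.6 and *under-represented* at
RSCU ≤ 0.6; virus and host "select a codon similarly" when both fall in the
same bin.  The boundary values themselves are assigned to the extreme bins
so that tables printed at 3 decimals classify stably.  D(A,B) = (1 − R)/2
with R the cosine between two 59-codon RSCU vectors: 0 for identical usage
patterns, 1 for diametrically opposed ones.  tAI scores codon–tRNA-pool
co-adaptation from tRNA gene copy numbers with the dos Reis wobble rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_indices import CodonCountTable, RscuVector
from .seq_io import (
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS_CODONS_59,
    canonicalize,
)

__all__ = [
    "RSCU_OVER",
    "RSCU_UNDER",
    "DEFAULT_WOBBLE_PENALTIES",
    "SimilarityReport",
    "TrnaPool",
    "TaiValue",
    "classify_rscu",
    "count_similar",
    "similarity_index",
    "compare_rscu",
    "tai",
]

RSCU_OVER = 1.6
RSCU_UNDER = 0.6


def classify_rscu(value: float) -> str:
    """Bin an RSCU value: ``under`` (≤ 0.6), ``over`` (≥ 1.6) or ``average``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "missing"
    if value < 0:
        raise ValueError(f"RSCU cannot be negative: {value}")
    if value <= RSCU_UNDER:
        return "under"
    if value >= RSCU_OVER:
        return "over"
    return "average"


def _values(vec: RscuVector | Mapping[str, float]) -> dict[str, float]:
    if isinstance(vec, RscuVector):
        return dict(vec.values)
    vals = dict(vec)
    missing = set(SYNONYMOUS_CODONS_59) - set(vals)
    if missing:
        raise ValueError(f"RSCU vector missing codons: {sorted(missing)}")
    return vals


@dataclass
class SimilarityReport:
    """Codon-by-codon bin comparison plus the aggregate similarity metrics."""

    table: pd.DataFrame  # codon, virus value/class, host value/class, match
    similar_count: int
    r: float
    d: float


def count_similar(
    virus: RscuVector | Mapping[str, float], host: RscuVector | Mapping[str, float]
) -> int:
    """Number of the 59 synonymous codons sharing an RSCU bin."""
    v, h = _values(virus), _values(host)
    return sum(
        1
        for c in SYNONYMOUS_CODONS_59
        if classify_rscu(v[c]) == classify_rscu(h[c]) != "missing"
    )


def similarity_index(
    virus: RscuVector | Mapping[str, float], host: RscuVector | Mapping[str, float]
) -> tuple[float, float]:
    """(R, D): cosine between paired RSCU vectors and D = (1 − R)/2.

    Codons missing (NaN) in either vector are dropped pairwise.
    """
    v, h = _values(virus), _values(host)
    pairs = [
        (v[c], h[c])
        for c in SYNONYMOUS_CODONS_59
        if not (math.isnan(v[c]) or math.isnan(h[c]))
    ]
    if not pairs:
        raise ValueError("no codons shared between the two vectors")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm RSCU vector")
    r = float(a.dot(b) / (na * nb))
    return r, (1.0 - r) / 2.0


def compare_rscu(
    virus: RscuVector | Mapping[str, float], host: RscuVector | Mapping[str, float]
) -> SimilarityReport:
    """Full virus-vs-host report: per-codon bins, similar count, R and D."""
    v, h = _values(virus), _values(host)
    rows = []
    for c in SYNONYMOUS_CODONS_59:
        cv, ch = classify_rscu(v[c]), classify_rscu(h[c])
        rows.append(
            {
                "codon": c,
                "aa": CODON_TO_AA[c],
                "virus_rscu": v[c],
                "host_rscu": h[c],
                "virus_class": cv,
                "host_class": ch,
                "match": cv == ch != "missing",
            }
        )
    table = pd.DataFrame(rows)
    r, d = similarity_index(virus, host)
    return SimilarityReport(
        table=table, similar_count=int(table["match"].sum()), r=r, d=d
    )


# ---------------------------------------------------------------------------
# tRNA adaptation index

#: wobble selective penalties s (dos Reis et al. 2004 defaults): the cost of
#: decoding through each non-Watson–Crick pairing between codon third base
#: and anticodon first (wobble) base.  Keys name codon-base:anticodon-base;
#: "I" is inosine, encoded as A in tRNA genes.
DEFAULT_WOBBLE_PENALTIES: dict[str, float] = {
    "U:G": 0.41,   # codon U read by G-starting anticodon
    "C:I": 0.28,   # codon C read by inosine (A-encoded) anticodon
    "A:I": 0.9999, # codon A read by inosine anticodon
    "G:U": 0.68,   # codon G read by U-starting anticodon
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _reverse_complement(codon: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(codon))


#: codon third base -> [(anticodon wobble base, penalty key or None)]
_WOBBLE_READERS = {
    "U": [("A", None), ("G", "U:G")],
    "C": [("G", None), ("A", "C:I")],
    "A": [("U", None), ("A", "A:I")],
    "G": [("C", None), ("U", "G:U")],
}


@dataclass
class TrnaPool:
    """tRNA gene copy numbers keyed by anticodon (RNA alphabet, 5'→3')."""

    copies: dict[str, float]
    source: str = "trna_pool"

    def __post_init__(self) -> None:
        clean = {}
        for anticodon, n in self.copies.items():
            ac = canonicalize(anticodon)
            if len(ac) != 3 or set(ac) - set("ACGU"):
                raise ValueError(f"invalid anticodon {anticodon!r}")
            if n < 0:
                raise ValueError(f"negative copy number for {anticodon}")
            clean[ac] = float(n)
        if not clean:
            raise ValueError("empty tRNA pool")
        self.copies = clean

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "TrnaPool":
        """Read a tab- or whitespace-delimited anticodon→copy-number table."""
        path = Path(path)
        copies: dict[str, float] = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            copies[parts[0]] = float(parts[1])
        return cls(copies=copies, source=source or path.stem)


@dataclass
class TaiValue:
    """tRNA adaptation index with its per-codon relative adaptiveness."""

    value: float
    w: dict[str, float]
    pool: str


def absolute_adaptiveness(
    pool: TrnaPool, penalties: Mapping[str, float] | None = None
) -> dict[str, float]:
    """W_i = Σ over admissible anticodons (1 − s) · tGCN for each sense codon."""
    s = dict(DEFAULT_WOBBLE_PENALTIES)
    if penalties:
        s.update(penalties)
    W: dict[str, float] = {}
    for codon in SENSE_CODONS:
        stem = _reverse_complement(codon)[1:]  # anticodon positions 35–36
        total = 0.0
        for wobble_base, key in _WOBBLE_READERS[codon[2]]:
            anticodon = wobble_base + stem
            penalty = 0.0 if key is None else s[key]
            total += (1.0 - penalty) * pool.copies.get(anticodon, 0.0)
        W[codon] = total
    return W


def tai(
    counts: CodonCountTable,
    pool: TrnaPool,
    penalties: Mapping[str, float] | None = None,
) -> TaiValue:
    """tRNA adaptation index of a codon count table against a tRNA pool.

    Relative adaptiveness w_i = W_i / max(W); codons with w = 0 (no decoding
    tRNA) take the geometric mean of the non-zero w.  tAI is the geometric
    mean of w over all sense codons of the sequence.
    """
    W = absolute_adaptiveness(pool, penalties)
    w_max = max(W.values())
    if w_max <= 0:
        raise ValueError("tRNA pool decodes no codon (all W zero)")
    w = {c: v / w_max for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm_nonzero = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    w = {c: (v if v > 0 else gm_nonzero) for c, v in w.items()}
    log_sum, n = 0.0, 0.0
    for codon in SENSE_CODONS:
        k = counts.counts[codon]
        if k:
            log_sum += k * math.log(w[codon])
            n += k
    if n == 0:
        raise ValueError("no sense codons in query")
    return TaiValue(value=math.exp(log_sum / n), w=w, pool=pool.source)
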