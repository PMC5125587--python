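"""Nucleotide and dinucleotide composition metrics of coding sequences.

Positional G+C metrics follow the CodonW conventions that dominate the
codon-usage literature: ``GC3`` is computed over the third positions of all
codons, whereas ``GC3s`` and the per-base ``X3s`` frequencies are restricted
to synonymous codons (Met, Trp and stop codons excluded).  The per-base
``X3s`` denominators additionally count only codons whose amino-acid family
can place that base at the wobble position — which is why the four X3s
columns of a usage report do not sum to 100%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import (
    CODON_TO_AA,
    RNA_BASES,
    SYNONYMOUS_FAMILIES,
    CodingSequence,
    canonicalize,
)

__all__ = [
    "CompositionSummary",
    "DinucleotideProfile",
    "OVER_REPRESENTED",
    "UNDER_REPRESENTED",
    "composition_summary",
    "dinucleotide_profile",
    "pool_composition",
    "pool_statistics",
]

#: dinucleotide odds-ratio thresholds: ρ above/below these marks a
#: dinucleotide as over-/under-represented relative to random association.
OVER_REPRESENTED = 1.23
UNDER_REPRESENTED = 0.78

#: per family, the set of bases that can occupy the synonymous third
#: position (e.g. {U, C} for Phe, all four for Ala).
_FAMILY_THIRD_BASES: dict[str, frozenset[str]] = {
    aa: frozenset(c[2] for c in codons)
    for aa, codons in SYNONYMOUS_FAMILIES.items()
}


@dataclass
class CompositionSummary:
    """Composition of one CDS; every field is a percentage.

    ``gc3s`` and the ``x3s`` fields are NaN when the sequence contains no
    synonymous codons (e.g. Met/Trp only).
    """

    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    u3s: float
    c3s: float
    g3s: float
    a: float
    u: float
    c: float
    g: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def composition_summary(codons: Sequence[str]) -> CompositionSummary:
    """Compute all composition percentages from a frame-0 codon list."""
    if not codons:
        raise ValueError("empty codon list")
    pos_counts = [
        {b: 0 for b in RNA_BASES},
        {b: 0 for b in RNA_BASES},
        {b: 0 for b in RNA_BASES},
    ]
    syn_third = {b: 0 for b in RNA_BASES}
    syn_possible = {b: 0 for b in RNA_BASES}
    n_syn = 0
    for codon in codons:
        for i, base in enumerate(codon):
            pos_counts[i][base] += 1
        aa = CODON_TO_AA.get(codon)
        if aa in _FAMILY_THIRD_BASES:
            n_syn += 1
            syn_third[codon[2]] += 1
            for b in _FAMILY_THIRD_BASES[aa]:
                syn_possible[b] += 1

    n = len(codons)
    total = 3 * n
    mono = {b: sum(pos_counts[i][b] for i in range(3)) for b in RNA_BASES}
    gc = 100.0 * (mono["G"] + mono["C"]) / total
    gc1, gc2, gc3 = (
        100.0 * (pos_counts[i]["G"] + pos_counts[i]["C"]) / n for i in range(3)
    )
    if n_syn:
        gc3s = 100.0 * (syn_third["G"] + syn_third["C"]) / n_syn
        x3s = {
            b: (100.0 * syn_third[b] / syn_possible[b]
                if syn_possible[b] else math.nan)
            for b in RNA_BASES
        }
    else:
        gc3s = math.nan
        x3s = {b: math.nan for b in RNA_BASES}
    return CompositionSummary(
        gc=gc,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=(gc1 + gc2) / 2.0,
        gc3s=gc3s,
        a3s=x3s["A"],
        u3s=x3s["U"],
        c3s=x3s["C"],
        g3s=x3s["G"],
        a=100.0 * mono["A"] / total,
        u=100.0 * mono["U"] / total,
        c=100.0 * mono["C"] / total,
        g=100.0 * mono["G"] / total,
    )


@dataclass
class DinucleotideProfile:
    """Dinucleotide relative-abundance (odds-ratio) profile of a sequence.

    ``rho[XY] = f_XY / (f_X * f_Y)`` with frequencies taken over the linear
    sequence (overlapping windows, no circular wraparound).
    """

    rho: dict[str, float]
    f_x: dict[str, float]
    f_xy: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.flags:
            self.flags = {d: classify_rho(r) for d, r in self.rho.items()}


def classify_rho(rho: float) -> str:
    if math.isnan(rho):
        return "undefined"
    if rho > OVER_REPRESENTED:
        return "over"
    if rho < UNDER_REPRESENTED:
        return "under"
    return "normal"


def dinucleotide_profile(cds: CodingSequence | str) -> DinucleotideProfile:
    """Odds ratios for the 16 dinucleotides of a CDS.

    Windows containing N are skipped in both the mono- and dinucleotide
    tallies, so an N interrupts rather than contributes a pair.
    """
    seq = cds.seq if isinstance(cds, CodingSequence) else canonicalize(cds)
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nucleotides")
    mono = {b: 0 for b in RNA_BASES}
    for base in seq:
        if base in mono:
            mono[base] += 1
    n_mono = sum(mono.values())
    di = {x + y: 0 for x in RNA_BASES for y in RNA_BASES}
    n_di = 0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair in di:
            di[pair] += 1
            n_di += 1
    if n_mono == 0 or n_di == 0:
        raise ValueError("no unambiguous positions to profile")
    f_x = {b: c / n_mono for b, c in mono.items()}
    f_xy = {d: c / n_di for d, c in di.items()}
    rho = {}
    for d, f in f_xy.items():
        denom = f_x[d[0]] * f_x[d[1]]
        rho[d] = f / denom if denom > 0 else math.nan
    return DinucleotideProfile(rho=rho, f_x=f_x, f_xy=f_xy)


def pool_statistics(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n−1), min and max of each numeric column.

    For a single row the SD is reported as 0 and ``attrs['degenerate_n']``
    is set, so callers can distinguish a true zero spread from n = 1.
    """
    if frame.empty:
        raise ValueError("empty table")
    num = frame.select_dtypes(include="number")
    out = pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "min": num.min(),
            "max": num.max(),
        }
    )
    if len(num) == 1:
        out["sd"] = 0.0
        out.attrs["degenerate_n"] = True
    return out


def pool_composition(summaries: Iterable[CompositionSummary]) -> pd.DataFrame:
    """Per-field mean/SD/min/max over a pool of composition summaries."""
    rows = [s.as_dict() for s in summaries]
    if not rows:
        raise ValueError("empty summary list")
    return pool_statistics(pd.DataFrame(rows))
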