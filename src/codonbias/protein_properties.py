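"""Hydrophobicity (GRAVY) and aromaticity of the encoded protein.

GRAVY is the mean Kyte–Doolittle hydropathy over all residues; aromaticity
is the fraction of Phe/Tyr/Trp residues.  Both co-vary with codon usage in
viral genomes because amino-acid choice constrains the codons available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seq_io import CODON_TO_AA

__all__ = ["KYTE_DOOLITTLE", "ProteinProfile", "translate", "protein_profile"]

#: Kyte & Doolittle (1982) hydropathy scale (the CodonW default).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_AROMATIC = frozenset("FYW")


@dataclass
class ProteinProfile:
    gravy: float
    aromo: float


def translate(codons: Sequence[str]) -> str:
    """Translate a frame-0 codon list under the standard genetic code."""
    residues = []
    for pos, codon in enumerate(codons, start=1):
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"unknown codon {codon!r} at position {pos}")
        if aa == "*":
            raise ValueError(f"stop codon {codon} at position {pos}")
        residues.append(aa)
    return "".join(residues)


def protein_profile(residues: str) -> ProteinProfile:
    """GRAVY and aromaticity of a protein given as one-letter residues."""
    if not residues:
        raise ValueError("empty residue string")
    unknown = set(residues) - set(KYTE_DOOLITTLE)
    if unknown:
        raise ValueError(f"unknown residue letters: {sorted(unknown)}")
    gravy = sum(KYTE_DOOLITTLE[r] for r in residues) / len(residues)
    aromo = sum(1 for r in residues if r in _AROMATIC) / len(residues)
    return ProteinProfile(gravy=gravy, aromo=aromo)
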