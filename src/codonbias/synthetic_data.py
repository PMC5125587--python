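"""Synthetic coding sequences with controlled codon-usage structure,
plus the packaged reference tables.

The generator draws residues i.i.d. from an amino-acid composition and then
picks a codon for each residue from a per-family distribution.  Four family
modes cover the regimes a codon-usage study contrasts:

``uniform``
    no bias: every synonymous codon equally likely (ENc → 61).
``single_codon``
    maximal bias: one codon per family (ENc = 20).
``target_rscu``
    codon probabilities proportional to a supplied RSCU vector, so the
    generated pool recovers that vector in expectation.
``gc3_biased``
    within each family the G/C-ending codons share probability θ and the
    A/U-ending codons share 1 − θ, so the pooled synonymous GC3 fraction
    equals θ in expectation regardless of amino-acid composition.

A mixing weight λ interpolates between the mode distribution (mutation-like
background) and a point mass on each family's preferred codon
(translational selection); λ = 1 collapses usage onto the preferred set.
Separately, :func:`mutation_driven_pool` generates codons as i.i.d. bases
under a strain-specific GC level, the regime in which GC12 tracks GC3 (the
neutrality limit).

The packaged tables are transcriptions of the study's printed per-strain
index table (46 ZIKV polyprotein CDSs) and 59-codon RSCU table (ZIKV,
H. sapiens, A. aegypti, A. albopictus); their checksums are verified on
load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_indices import RscuVector
from .seq_io import (
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMOUS_CODONS_59,
    SYNONYMOUS_FAMILIES,
    CodingSequence,
)

__all__ = [
    "AVERAGE_PROTEIN_COMPOSITION",
    "GeneratorSpec",
    "StrainMetricsTable",
    "generate",
    "mutation_driven_pool",
    "load_table1_fixture",
    "load_table2_fixture",
]

#: average amino-acid composition of proteins (UniProtKB/Swiss-Prot release
#: statistics, rounded); the default residue distribution of the generator.
AVERAGE_PROTEIN_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

_SINGLE_CODON_AA = {"M": "AUG", "W": "UGG"}

_FIXTURE_SHA256 = {
    "strain_metrics.csv": "7af86825f772aced72bc3ab28b94cf2d96ee9ce23ca22760c8c8ebc05f9d7d35",
    "host_rscu.csv": "62e8b0e4b3205b109d8b9e20ba35802789401c2f8ec5619f8469f52ebd9f450f",
}

#: the metric columns of the per-strain index table, in report order.
METRIC_COLUMNS = (
    "cai", "enc", "gc3s", "gc", "u3s", "c3s", "a3s", "g3s",
    "gravy", "aromo", "gc12", "gc3",
)


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic-CDS generator.

    The defaults emulate a pool the size and shape of the ZIKV study set:
    46 strains of 3423 codons (a flavivirus polyprotein) with a mild G/C
    bias at synonymous third positions (θ = 0.515, the observed GC3s
    regime) and no selection component.
    """

    seed: int
    n_sequences: int = 46
    length_codons: int = 3423
    aa_freqs: Mapping[str, float] | None = None
    mode: str = "gc3_biased"
    theta: float = 0.515
    target_rscu: Mapping[str, float] | None = None
    selection_weight: float = 0.0  # λ: 0 = mode distribution, 1 = preferred only
    preferred: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"uniform", "single_codon", "target_rscu", "gc3_biased"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.selection_weight <= 1.0:
            raise ValueError("selection_weight must be in [0, 1]")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.mode == "target_rscu" and self.target_rscu is None:
            raise ValueError("mode 'target_rscu' needs a target_rscu vector")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


def _normalized_aa_freqs(spec: GeneratorSpec) -> tuple[list[str], np.ndarray]:
    freqs = dict(spec.aa_freqs) if spec.aa_freqs else dict(AVERAGE_PROTEIN_COMPOSITION)
    unknown = set(freqs) - (set(SYNONYMOUS_FAMILIES) | set(_SINGLE_CODON_AA))
    if unknown:
        raise ValueError(f"unknown amino acids in composition: {sorted(unknown)}")
    aas = sorted(freqs)
    p = np.array([freqs[a] for a in aas], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("invalid amino-acid probability vector")
    return aas, p / p.sum()


def _mode_distribution(spec: GeneratorSpec, aa: str, codons: tuple[str, ...]) -> np.ndarray:
    if spec.mode == "uniform":
        return np.full(len(codons), 1.0 / len(codons))
    if spec.mode == "single_codon":
        p = np.zeros(len(codons))
        p[0] = 1.0
        return p
    if spec.mode == "target_rscu":
        vals = np.array([float(spec.target_rscu[c]) for c in codons])
        if (vals < 0).any() or vals.sum() <= 0:
            raise ValueError(f"invalid target RSCU for family {aa}")
        return vals / vals.sum()
    # gc3_biased: G/C-ending codons share theta, A/U-ending share 1 - theta
    gc = np.array([c[2] in "GC" for c in codons])
    p = np.empty(len(codons))
    p[gc] = spec.theta / gc.sum()
    p[~gc] = (1.0 - spec.theta) / (~gc).sum()
    return p


def _codon_distributions(spec: GeneratorSpec) -> dict[str, tuple[list[str], np.ndarray]]:
    preferred = dict(spec.preferred) if spec.preferred else None
    if preferred is None and spec.selection_weight > 0:
        # default preferred set: the packaged ZIKV RSCU winners
        from .codon_indices import preferred_codons

        preferred = preferred_codons(load_table2_fixture()["zikv"]).winners
    lam = spec.selection_weight
    dists: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa, codons in sorted(SYNONYMOUS_FAMILIES.items()):
        p = _mode_distribution(spec, aa, codons)
        if lam > 0:
            sel = np.array([1.0 if c == preferred[aa] else 0.0 for c in codons])
            p = (1.0 - lam) * p + lam * sel
        dists[aa] = (list(codons), p)
    for aa, codon in _SINGLE_CODON_AA.items():
        dists[aa] = ([codon], np.array([1.0]))
    return dists


def generate(spec: GeneratorSpec) -> list[CodingSequence]:
    """Draw ``spec.n_sequences`` synthetic CDSs; byte-identical per seed."""
    rng = np.random.default_rng(spec.seed)
    aas, aa_p = _normalized_aa_freqs(spec)
    dists = _codon_distributions(spec)
    out: list[CodingSequence] = []
    for i in range(spec.n_sequences):
        residues = rng.choice(aas, size=spec.length_codons, p=aa_p)
        codons = np.empty(spec.length_codons, dtype=object)
        for aa in sorted(set(residues)):
            idx = np.flatnonzero(residues == aa)
            fam, p = dists[aa]
            codons[idx] = rng.choice(fam, size=len(idx), p=p)
        out.append(
            CodingSequence(
                id=f"syn{i + 1:03d}",
                seq="".join(codons),
                meta={"origin": "synthetic", "mode": spec.mode},
            )
        )
    return out


def mutation_driven_pool(
    n_sequences: int,
    length_codons: int,
    seed: int,
    gc_range: tuple[float, float] = (0.40, 0.60),
) -> list[CodingSequence]:
    """Strain pool in the mutation-only (neutral) regime.

    Each strain gets its own GC level drawn uniformly from ``gc_range`` and
    its codons are i.i.d. bases at that level (stop codons resampled), so
    GC12 and GC3 both track the strain's GC level and correlate strongly
    across the pool — the neutrality-plot limit.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    out: list[CodingSequence] = []
    for i in range(n_sequences):
        g = rng.uniform(*gc_range)
        p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        draw = rng.choice(bases, size=(length_codons, 3), p=p)
        codons = np.array(["".join(row) for row in draw], dtype=object)
        while True:
            stops = np.flatnonzero(np.isin(codons, list(STOP_CODONS)))
            if len(stops) == 0:
                break
            redraw = rng.choice(bases, size=(len(stops), 3), p=p)
            codons[stops] = ["".join(row) for row in redraw]
        out.append(
            CodingSequence(
                id=f"mut{i + 1:03d}",
                seq="".join(codons),
                meta={"origin": "synthetic", "mode": "mutation_driven", "gc": f"{g:.4f}"},
            )
        )
    return out


# ---------------------------------------------------------------------------
# packaged fixtures


@dataclass
class StrainMetricsTable:
    """Rectangular per-strain index table (one row per CDS/strain)."""

    frame: pd.DataFrame
    provenance: str = "computed"

    def __post_init__(self) -> None:
        missing = set(METRIC_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"strain metrics table missing columns: {sorted(missing)}")


def _fixture_path(name: str) -> Path:
    path = files("codonbias.data").joinpath(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(
            f"packaged fixture {name} is corrupted (sha256 {digest[:12]}…)"
        )
    return path


def load_table1_fixture() -> StrainMetricsTable:
    """The packaged per-strain index table for the 46 ZIKV polyprotein CDSs."""
    frame = pd.read_csv(_fixture_path("strain_metrics.csv"))
    return StrainMetricsTable(frame=frame, provenance="fixture")


def load_table2_fixture() -> dict[str, RscuVector]:
    """Packaged 59-codon RSCU vectors: ZIKV pool and its three hosts."""
    frame = pd.read_csv(_fixture_path("host_rscu.csv"))
    vectors: dict[str, RscuVector] = {}
    for column in ("zikv", "homo_sapiens", "aedes_aegypti", "aedes_albopictus"):
        values = dict(zip(frame["codon"], frame[column].astype(float)))
        vectors[column] = RscuVector(values=values, source=column)
    return vectors
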