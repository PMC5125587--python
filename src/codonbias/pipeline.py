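"""End-to-end codon-usage analysis pipeline.

Runs every stage of the analysis on a strain pool — per-strain indices,
pooled RSCU, dinucleotide odds ratios, host comparison, correspondence
analysis, PR2/neutrality coordinates and the correlation tables — and
writes one CSV per artifact plus a JSON run log recording versions, seed
and all decision flags.  Values are carried at full precision internally
and rounded only at report time (CAI 3 dp, ENc 2 dp, percentages 2 dp,
D(A,B) 4 dp).
"""

from __future__ import annotations

import json
import math
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codon_indices import (
    CodonCountTable,
    RscuVector,
    cai,
    enc,
    preferred_codons,
    rscu,
)
from .composition import composition_summary, dinucleotide_profile, pool_statistics
from .host_adaptation import TrnaPool, compare_rscu, similarity_index, tai
from .multivariate import correspondence_analysis, neutrality, pr2_point, spearman
from .protein_properties import protein_profile, translate
from .seq_io import (
    AA_THREE_LETTER,
    CODON_TO_AA,
    SYNONYMOUS_CODONS_59,
    CodingSequence,
    parse_usage_table,
    read_fasta,
)
from .synthetic_data import GeneratorSpec, generate, load_table2_fixture

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_ROUND = {
    "cai": 3, "enc": 2, "gc3s": 2, "gc": 2, "u3s": 2, "c3s": 2, "a3s": 2,
    "g3s": 2, "gravy": 3, "aromo": 3, "gc12": 2, "gc3": 2, "tai": 3,
}


@dataclass
class PipelineConfig:
    """One input source (FASTA paths or a generator spec) plus flags."""

    outdir: str | Path
    fasta: Sequence[str | Path] | None = None
    generator: GeneratorSpec | None = None
    host_usage_tables: Mapping[str, str | Path] | None = None  # Kazusa files
    trna_pool: str | Path | None = None
    cai_reference: str = "homo_sapiens"
    truncate: bool = False
    allow_internal_stop: bool = False
    cai_include_single_codon: bool = False
    plots: bool = False

    def __post_init__(self) -> None:
        if (self.fasta is None) == (self.generator is None):
            raise ValueError("exactly one of fasta or generator must be given")


@dataclass
class PipelineResult:
    strain_metrics: pd.DataFrame
    pooled_rscu: pd.DataFrame
    dinucleotides: pd.DataFrame
    host_comparison: pd.DataFrame
    preferred: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    ca_rows: pd.DataFrame | None
    ca_inertia: np.ndarray | None
    pr2: pd.DataFrame
    neutrality_stats: dict[str, float]
    outputs: dict[str, Path] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _load_sequences(config: PipelineConfig) -> list[CodingSequence]:
    if config.generator is not None:
        return generate(config.generator)
    seqs: list[CodingSequence] = []
    for path in config.fasta:
        seqs.extend(read_fasta(path))
    return seqs


def _host_vectors(config: PipelineConfig) -> dict[str, RscuVector]:
    if config.host_usage_tables:
        vectors = {}
        for name, path in config.host_usage_tables.items():
            table = parse_usage_table(path, source=name)
            counts = CodonCountTable(counts=table.counts, label=name)
            vectors[name] = rscu(counts, source=name)
        return vectors
    fixture = load_table2_fixture()
    return {k: v for k, v in fixture.items() if k != "zikv"}


def _round_frame(frame: pd.DataFrame, default: int = 4) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(_ROUND.get(col, default))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = _load_sequences(config)
    hosts = _host_vectors(config)
    if config.cai_reference not in hosts:
        raise ValueError(
            f"CAI reference {config.cai_reference!r} not among hosts {sorted(hosts)}"
        )
    pool = TrnaPool.from_tsv(config.trna_pool) if config.trna_pool else None

    extract_flags = dict(
        truncate=config.truncate, allow_internal_stop=config.allow_internal_stop
    )
    skipped: list[str] = []
    rows: list[dict] = []
    per_strain_rscu: dict[str, dict[str, float]] = {}
    per_strain_codons: dict[str, list[str]] = {}
    dinuc_rows: list[dict] = []
    from .seq_io import extract_codons

    for s in seqs:
        try:
            codons = extract_codons(s, **extract_flags)
            counts = CodonCountTable.from_codons(codons, label=s.id)
            comp = composition_summary(codons)
            vec = rscu(counts)
            enc_v = enc(counts)
            cai_v = cai(
                counts,
                hosts[config.cai_reference],
                include_single_codon=config.cai_include_single_codon,
            )
            prof = protein_profile(translate(codons))
            row = {
                "accession": s.id,
                "cai": cai_v.value,
                "enc": enc_v.value,
                **comp.as_dict(),
            }
            row["gravy"], row["aromo"] = prof.gravy, prof.aromo
            if pool is not None:
                row["tai"] = tai(counts, pool).value
            rows.append(row)
            per_strain_rscu[s.id] = vec.values
            per_strain_codons[s.id] = codons
            dinuc_rows.append({"accession": s.id, **dinucleotide_profile(s).rho})
        except ValueError as err:
            warnings.warn(f"skipping {s.id}: {err}")
            skipped.append(s.id)
    if not rows:
        raise RuntimeError("all input sequences failed validation")

    metrics = pd.DataFrame(rows)

    # pooled RSCU (sum of counts over strains) alongside the host vectors
    pooled_counts = CodonCountTable.from_codons(
        [c for codons in per_strain_codons.values() for c in codons], label="pool"
    )
    pooled_vec = rscu(pooled_counts, source="pool")
    pooled = pd.DataFrame(
        {
            "aa": [AA_THREE_LETTER[CODON_TO_AA[c]] for c in SYNONYMOUS_CODONS_59],
            "codon": SYNONYMOUS_CODONS_59,
            "virus": [pooled_vec.values[c] for c in SYNONYMOUS_CODONS_59],
        }
    )
    for name, vec in hosts.items():
        pooled[name] = [vec.values[c] for c in SYNONYMOUS_CODONS_59]

    pref = preferred_codons(pooled_vec)
    preferred_frame = pd.DataFrame(
        {
            "aa": [AA_THREE_LETTER[a] for a in sorted(pref.winners)],
            "codon": [pref.winners[a] for a in sorted(pref.winners)],
            "tie": [a in pref.ties for a in sorted(pref.winners)],
        }
    )

    # dinucleotide odds ratios: mean ± SD across strains
    dinuc_frame = pd.DataFrame(dinuc_rows).set_index("accession")
    dinuc_stats = pool_statistics(dinuc_frame).reset_index(names="dinucleotide")

    # host comparison: pooled similar-codon counts and D, per-strain D spread
    host_rows = []
    for name, vec in hosts.items():
        report = compare_rscu(pooled_vec, vec)
        per_d = [
            similarity_index(per_strain_rscu[acc], vec.values)[1]
            for acc in per_strain_rscu
        ]
        host_rows.append(
            {
                "host": name,
                "similar_codons": report.similar_count,
                "r_pooled": report.r,
                "d_pooled": report.d,
                "d_mean": float(np.mean(per_d)),
                "d_sd": float(np.std(per_d, ddof=1)) if len(per_d) > 1 else 0.0,
            }
        )
    host_frame = pd.DataFrame(host_rows)

    # correspondence analysis on the strains x 59 RSCU matrix
    rscu_matrix = pd.DataFrame.from_dict(per_strain_rscu, orient="index")
    rscu_matrix = rscu_matrix[list(SYNONYMOUS_CODONS_59)]
    ca_rows = ca_inertia = None
    axes_frame = None
    if len(rscu_matrix) >= 2:
        ca_result = correspondence_analysis(rscu_matrix)
        ca_rows = ca_result.row_coords
        ca_inertia = ca_result.inertia_fractions
        axes_frame = ca_rows.iloc[:, : min(2, ca_rows.shape[1])]
    else:
        warnings.warn("correspondence analysis skipped: fewer than 2 strains")

    # PR2 and neutrality coordinates
    pr2_frame = pd.DataFrame(
        [
            {
                "accession": acc,
                "gc_bias": pr2_point(codons).gc_bias,
                "au_bias": pr2_point(codons).au_bias,
            }
            for acc, codons in per_strain_codons.items()
        ]
    )
    if len(metrics) >= 3:
        neut = neutrality(metrics["gc12"], metrics["gc3"])
        neut_stats = {
            "rho": neut.rho, "p": neut.p,
            "slope": neut.slope, "intercept": neut.intercept, "n": neut.n,
        }
    else:
        neut_stats = {"rho": math.nan, "p": math.nan, "slope": math.nan,
                      "intercept": math.nan, "n": len(metrics)}

    correlations = _correlation_tables(metrics, axes_frame)

    result = PipelineResult(
        strain_metrics=metrics,
        pooled_rscu=pooled,
        dinucleotides=dinuc_stats,
        host_comparison=host_frame,
        preferred=preferred_frame,
        correlations=correlations,
        ca_rows=ca_rows,
        ca_inertia=ca_inertia,
        pr2=pr2_frame,
        neutrality_stats=neut_stats,
        skipped=skipped,
    )
    _write_outputs(result, config, outdir)
    if config.plots:
        _write_plots(result, outdir)
    return result


def _correlation_tables(
    metrics: pd.DataFrame, axes: pd.DataFrame | None
) -> dict[str, pd.DataFrame]:
    """Spearman r (and p) grids mirroring the study's correlation tables."""
    out: dict[str, pd.DataFrame] = {}

    def grid(row_cols: Sequence[str], col_cols: Sequence[str], frame: pd.DataFrame):
        r = pd.DataFrame(index=row_cols, columns=col_cols, dtype=float)
        p = pd.DataFrame(index=row_cols, columns=col_cols, dtype=float)
        for a in row_cols:
            for b in col_cols:
                res = spearman(frame[a], frame[b])
                r.loc[a, b], p.loc[a, b] = res.rho, res.p
        return r, p

    if len(metrics) >= 3:
        r, p = grid(
            ["a", "u", "c", "g", "gc"],
            ["a3s", "u3s", "c3s", "g3s", "gc3s"],
            metrics,
        )
        out["composition_r"], out["composition_p"] = r, p
        if axes is not None and len(axes.columns) >= 1:
            joined = metrics.set_index("accession").join(axes)
            idx_cols = ["gc3s", "gc", "enc", "a", "u", "c", "g",
                        "a3s", "u3s", "c3s", "g3s"]
            r, p = grid(list(axes.columns), idx_cols, joined)
            out["axes_r"], out["axes_p"] = r, p
            r, p = grid(["aromo", "gravy"],
                        list(axes.columns) + ["gc3s", "gc", "enc"], joined)
            out["protein_r"], out["protein_p"] = r, p
    return out


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    def save(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = outdir / name
        _round_frame(frame).to_csv(path, index=kwargs.pop("index", False), **kwargs)
        result.outputs[name] = path

    save("strain_metrics.csv", result.strain_metrics)
    save("rscu_pooled.csv", result.pooled_rscu.round(3))
    save("dinucleotides.csv", result.dinucleotides)
    save("host_comparison.csv", result.host_comparison)
    save("preferred_codons.csv", result.preferred)
    save("pr2.csv", result.pr2)
    for name, frame in result.correlations.items():
        save(f"correlation_{name}.csv", frame.round(3), index=True)
    if result.ca_rows is not None:
        save("ca_row_coordinates.csv", result.ca_rows.round(6), index=True)
        pd.DataFrame(
            {
                "axis": [f"axis{i+1}" for i in range(len(result.ca_inertia))],
                "inertia_fraction": np.round(result.ca_inertia, 6),
            }
        ).to_csv(outdir / "ca_inertia.csv", index=False)
        result.outputs["ca_inertia.csv"] = outdir / "ca_inertia.csv"
    neut = {k: (round(v, 4) if isinstance(v, float) else v)
            for k, v in result.neutrality_stats.items()}
    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_sequences": int(len(result.strain_metrics)),
        "skipped": result.skipped,
        "neutrality": neut,
        "flags": {
            "truncate": config.truncate,
            "allow_internal_stop": config.allow_internal_stop,
            "cai_reference": config.cai_reference,
            "cai_include_single_codon": config.cai_include_single_codon,
            "rscu_bin_boundaries": "under <= 0.6, over >= 1.6 (boundary in extreme class)",
            "d_formula": "D = (1 - R) / 2",
        },
        "generator_seed": config.generator.seed if config.generator else None,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    result.outputs["run_log.json"] = outdir / "run_log.json"


def _write_plots(result: PipelineResult, outdir: Path) -> None:
    """Basic diagnostic plots: ENc–GC3s, CAI–ENc, neutrality, PR2, CA map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .codon_indices import expected_enc

    m = result.strain_metrics
    fig, ax = plt.subplots()
    s_grid = np.linspace(0.0, 1.0, 201)
    ax.plot(s_grid * 100, [expected_enc(s) for s in s_grid], "k-", lw=1,
            label="expected (null)")
    ax.scatter(m["gc3s"], m["enc"], s=12)
    ax.set_xlabel("GC3s (%)"); ax.set_ylabel("ENc"); ax.legend()
    fig.savefig(outdir / "enc_gc3s.png", dpi=150); plt.close(fig)

    fig, ax = plt.subplots()
    ax.scatter(m["cai"], m["enc"], s=12)
    ax.set_xlabel("CAI"); ax.set_ylabel("ENc")
    fig.savefig(outdir / "cai_enc.png", dpi=150); plt.close(fig)

    fig, ax = plt.subplots()
    ax.scatter(m["gc3"], m["gc12"], s=12)
    ax.set_xlabel("GC3 (%)"); ax.set_ylabel("GC12 (%)")
    fig.savefig(outdir / "neutrality.png", dpi=150); plt.close(fig)

    fig, ax = plt.subplots()
    ax.scatter(result.pr2["gc_bias"], result.pr2["au_bias"], s=12)
    ax.axhline(0.5, color="grey", lw=0.5); ax.axvline(0.5, color="grey", lw=0.5)
    ax.set_xlabel("G3/(G3+C3)"); ax.set_ylabel("A3/(A3+U3)")
    fig.savefig(outdir / "pr2.png", dpi=150); plt.close(fig)

    if result.ca_rows is not None and result.ca_rows.shape[1] >= 2:
        fig, ax = plt.subplots()
        ax.scatter(result.ca_rows.iloc[:, 0], result.ca_rows.iloc[:, 1], s=12)
        ax.set_xlabel("Axis 1"); ax.set_ylabel("Axis 2")
        fig.savefig(outdir / "ca.png", dpi=150); plt.close(fig)
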