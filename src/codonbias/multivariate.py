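"""Multivariate and correlation analyses of codon usage.

Correspondence analysis (CA) decomposes the strains × 59-codon RSCU matrix
into orthogonal axes ordered by the share of total chi-square inertia they
explain; the leading axes summarize the dominant trends in codon usage
across strains.  The PR2 plot places each strain at
(G3/(G3+C3), A3/(A3+U3)) over the four-codon families, where (0.5, 0.5) is
the parity-rule-2 expectation A = U and G = C.  The neutrality plot relates
GC12 to GC3 across strains: a slope near 1 indicates mutation pressure
acting equally on all codon positions, a flat cloud indicates selective
constraint on positions 1–2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import CODON_TO_AA

__all__ = [
    "CaResult",
    "Pr2Point",
    "SpearmanResult",
    "NeutralityResult",
    "PR2_QUARTET_PREFIXES",
    "correspondence_analysis",
    "pr2_point",
    "spearman",
    "neutrality",
]


@dataclass
class CaResult:
    """Correspondence-analysis decomposition of a strains × codons matrix."""

    row_coords: pd.DataFrame      # principal coordinates, one row per strain
    col_coords: pd.DataFrame      # principal coordinates, one row per codon
    inertia_fractions: np.ndarray
    total_inertia: float
    singular_values: np.ndarray


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int | None = None) -> CaResult:
    """Correspondence analysis of a non-negative strains × codons table.

    The matrix is treated as a contingency-style table: with relative
    matrix P = X/ΣX and row/column masses r, c, the standardized residuals
    S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2} are decomposed by SVD and
    principal coordinates are D^{-1/2} U Σ (rows) and D^{-1/2} V Σ
    (columns).  Columns that are entirely missing (NaN) or zero are dropped
    before the decomposition.  Axis signs are arbitrary; each axis is
    flipped so the first row's coordinate on it is non-negative.
    """
    if matrix.shape[0] < 2:
        raise ValueError("correspondence analysis needs at least 2 rows")
    X = matrix.dropna(axis=1, how="any")
    X = X.loc[:, (X != 0).any(axis=0)]
    values = X.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("matrix entries must be non-negative")
    if (values.sum(axis=1) == 0).any():
        raise ValueError("matrix contains an all-zero row")

    grand = values.sum()
    P = values / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(X.shape[0] - 1, X.shape[1] - 1)
    sv = sv[:max_axes]
    U = U[:, :max_axes]
    Vt = Vt[:max_axes]
    total_inertia = float((sv**2).sum())
    if total_inertia <= 1e-12:
        warnings.warn("matrix has (near-)identical row profiles: zero inertia")
        fractions = np.full(max_axes, np.nan)
    else:
        fractions = sv**2 / total_inertia

    rows = (U * sv) / np.sqrt(r)[:, None]
    cols = (Vt.T * sv) / np.sqrt(c)[:, None]
    # sign convention: first row non-negative on every axis
    for k in range(rows.shape[1]):
        if rows[0, k] < 0:
            rows[:, k] *= -1
            cols[:, k] *= -1

    if n_axes is not None:
        rows, cols = rows[:, :n_axes], cols[:, :n_axes]
        sv, fractions = sv[:n_axes], fractions[:n_axes]
    axes = [f"axis{k + 1}" for k in range(rows.shape[1])]
    return CaResult(
        row_coords=pd.DataFrame(rows, index=X.index, columns=axes),
        col_coords=pd.DataFrame(cols, index=X.columns, columns=axes),
        inertia_fractions=fractions,
        total_inertia=total_inertia,
        singular_values=sv,
    )


#: first-two-base prefixes of the eight four-codon quartets entering the
#: PR2 plot (Ala, Arg, Gly, Leu, Pro, Ser, Thr, Val); for the six-fold
#: families only the four-codon block counts, so AGR/AGY stay out.
PR2_QUARTET_PREFIXES = frozenset({"GC", "CG", "GG", "CU", "CC", "UC", "AC", "GU"})


@dataclass
class Pr2Point:
    """PR2 coordinates of one strain; NaN marks an undefined ratio."""

    au_bias: float  # A3 / (A3 + U3), the ordinate
    gc_bias: float  # G3 / (G3 + C3), the abscissa
    third_base_counts: dict[str, int]


def pr2_point(codons: Sequence[str]) -> Pr2Point:
    """Third-position parity biases over the four-codon quartets."""
    counts = {b: 0 for b in "ACGU"}
    for codon in codons:
        if codon[:2] in PR2_QUARTET_PREFIXES:
            counts[codon[2]] += 1
    if sum(counts.values()) == 0:
        raise ValueError("no codons from four-codon families")
    au_den = counts["A"] + counts["U"]
    gc_den = counts["G"] + counts["C"]
    au = counts["A"] / au_den if au_den else math.nan
    gc = counts["G"] / gc_den if gc_den else math.nan
    return Pr2Point(au_bias=au, gc_bias=gc, third_base_counts=counts)


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    defined: bool = True


def spearman(
    x: Sequence[float], y: Sequence[float], *, method: str = "t"
) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation.

    ``method='t'`` gives the usual two-sided p from the t approximation
    with n − 2 degrees of freedom; ``method='exact'`` enumerates all rank
    pairings (only for n ≤ 8).  A constant input leaves rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=math.nan, p=math.nan, n=n, defined=False)
    if method == "t":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(x, y)
        return SpearmanResult(rho=float(rho), p=float(p), n=n)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only for n <= 8")
        observed, _ = stats.spearmanr(x, y)
        count = 0
        total = 0
        for perm in permutations(y):
            rho_p, _ = stats.spearmanr(x, perm)
            if abs(rho_p) >= abs(observed) - 1e-12:
                count += 1
            total += 1
        return SpearmanResult(rho=float(observed), p=count / total, n=n)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class NeutralityResult:
    """Neutrality-plot statistics: rank correlation plus the OLS line."""

    rho: float
    p: float
    slope: float
    intercept: float
    n: int
    defined: bool = True


def neutrality(gc12: Sequence[float], gc3: Sequence[float]) -> NeutralityResult:
    """Spearman correlation and OLS regression of GC12 on GC3 across strains."""
    sp = spearman(gc12, gc3)
    if not sp.defined:
        return NeutralityResult(
            rho=math.nan, p=math.nan, slope=math.nan, intercept=math.nan,
            n=sp.n, defined=False,
        )
    fit = stats.linregress(np.asarray(gc3, float), np.asarray(gc12, float))
    return NeutralityResult(
        rho=sp.rho, p=sp.p, slope=float(fit.slope),
        intercept=float(fit.intercept), n=sp.n,
    )
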