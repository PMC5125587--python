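import math

import numpy as np
import pandas as pd
import pytest

from codonbias.multivariate import (
    correspondence_analysis,
    neutrality,
    pr2_point,
    spearman,
)

# ---------------------------------------------------------------------------
# brute-force CA oracle: total inertia and inter-row chi-square distances
# computed directly from the contingency-table definitions.


def chi_square_inertia(X):
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    return ((P - E) ** 2 / E).sum()


def chi_square_row_distances(X):
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    profiles = P / r[:, None]
    n = len(r)
    D = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            D[i, k] = np.sqrt((((profiles[i] - profiles[k]) ** 2) / c).sum())
    return D


TOY = pd.DataFrame(
    [[10, 2, 5, 3], [1, 12, 3, 4], [4, 3, 9, 8]],
    index=["r1", "r2", "r3"],
    columns=["c1", "c2", "c3", "c4"],
)


class TestCorrespondenceAnalysis:
    def test_toy_matrix_matches_chi_square_oracle(self):
        res = correspondence_analysis(TOY)
        X = TOY.to_numpy(float)
        assert res.total_inertia == pytest.approx(chi_square_inertia(X))
        assert res.inertia_fractions.sum() == pytest.approx(1.0)
        # Euclidean distances between full row principal coordinates equal
        # the chi-square distances between row profiles
        coords = res.row_coords.to_numpy()
        expected = chi_square_row_distances(X)
        for i in range(3):
            for k in range(3):
                got = np.linalg.norm(coords[i] - coords[k])
                assert got == pytest.approx(expected[i, k])

    def test_random_matrix_against_oracle(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.integers(1, 50, size=(5, 10)).astype(float))
        res = correspondence_analysis(X)
        assert res.total_inertia == pytest.approx(
            chi_square_inertia(X.to_numpy())
        )
        assert res.inertia_fractions.sum() == pytest.approx(1.0)

    def test_reconstruction_from_decomposition(self):
        res = correspondence_analysis(TOY)
        X = TOY.to_numpy(float)
        P = X / X.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        # standardized residuals rebuilt from principal coordinates
        F = res.row_coords.to_numpy()
        G = res.col_coords.to_numpy()
        S = np.zeros_like(P)
        for k, sv in enumerate(res.singular_values):
            if sv > 0:
                S += np.outer(np.sqrt(r) * F[:, k], np.sqrt(c) * G[:, k]) / sv
        rebuilt = np.outer(r, c) + np.sqrt(np.outer(r, c)) * S
        assert rebuilt == pytest.approx(P)

    def test_two_rows_single_axis_full_inertia(self):
        res = correspondence_analysis(TOY.iloc[:2])
        assert res.row_coords.shape[1] == 1
        assert res.inertia_fractions[0] == pytest.approx(1.0)

    def test_identical_rows_zero_inertia_warns_not_fails(self):
        X = pd.DataFrame([[1, 2, 3], [2, 4, 6]], dtype=float)
        with pytest.warns(UserWarning, match="zero inertia"):
            res = correspondence_analysis(X)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.inertia_fractions).all()

    def test_row_permutation_leaves_geometry_unchanged(self):
        res1 = correspondence_analysis(TOY)
        perm = TOY.iloc[[2, 0, 1]]
        res2 = correspondence_analysis(perm)
        c1 = res1.row_coords.loc[["r1", "r2", "r3"]].to_numpy()
        c2 = res2.row_coords.loc[["r1", "r2", "r3"]].to_numpy()
        # axis signs are arbitrary: compare pairwise distance matrices
        d1 = np.linalg.norm(c1[:, None] - c1[None], axis=2)
        d2 = np.linalg.norm(c2[:, None] - c2[None], axis=2)
        assert d1 == pytest.approx(d2)

    def test_sign_convention_first_row_non_negative(self):
        res = correspondence_analysis(TOY)
        assert (res.row_coords.iloc[0] >= 0).all()

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(TOY.iloc[:1])


class TestPr2Point:
    def test_balanced_third_bases_hit_the_center(self):
        p = pr2_point(["GCA", "GCU", "GCG", "GCC"])
        assert p.au_bias == pytest.approx(0.5)
        assert p.gc_bias == pytest.approx(0.5)

    def test_all_a_third_bases(self):
        p = pr2_point(["GCA", "CCA", "GUA"])
        assert p.au_bias == pytest.approx(1.0)
        assert math.isnan(p.gc_bias)

    def test_agr_block_of_six_fold_families_excluded(self):
        # AGA/AGG (Arg) and AGU/AGC (Ser) are outside the four-codon
        # quartets, so a sequence of only those has no PR2 signal
        with pytest.raises(ValueError):
            pr2_point(["AGA", "AGG", "AGU", "AGC"])

    def test_codon_shuffle_invariance(self):
        rng = np.random.default_rng(3)
        codons = ["GCA", "GCU", "CUG", "CCC", "ACA", "GUG", "AAA", "AUG"] * 5
        shuffled = list(codons)
        rng.shuffle(shuffled)
        a, b = pr2_point(codons), pr2_point(shuffled)
        assert a.au_bias == b.au_bias and a.gc_bias == b.gc_bias

    def test_biased_generator_lands_in_expected_quadrant(self):
        from codonbias.seq_io import extract_codons
        from codonbias.synthetic_data import GeneratorSpec, generate

        # A- and C-rich third positions: target RSCU putting most weight on
        # A/C-ending codons of every four-fold quartet
        from codonbias.seq_io import SYNONYMOUS_FAMILIES

        target = {}
        for codons in SYNONYMOUS_FAMILIES.values():
            for c in codons:
                target[c] = 3.0 if c[2] in "AC" else 0.5
        seqs = generate(
            GeneratorSpec(seed=77, n_sequences=1, length_codons=4000,
                          mode="target_rscu", target_rscu=target)
        )
        p = pr2_point(extract_codons(seqs[0]))
        assert p.au_bias > 0.5      # A used more than U
        assert p.gc_bias < 0.5      # C used more than G


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman([1, 2, 3], [2, 4, 9]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_fixture_cai_enc_correlation(self, table1):
        res = spearman(table1["cai"], table1["enc"])
        assert res.rho == pytest.approx(-0.749, abs=0.001)
        assert res.p < 0.01

    def test_constant_vector_flagged_undefined(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert not res.defined and math.isnan(res.rho)

    def test_invariant_under_monotone_transform(self):
        x = [0.3, 1.2, 5.0, 2.2, 4.1]
        y = [9, 2, 7, 4, 1]
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, np.log(np.array(y))).rho == pytest.approx(base)

    def test_exact_permutation_p_small_n(self):
        res = spearman([1, 2, 3, 4], [1, 3, 4, 9], method="exact")
        assert res.rho == pytest.approx(1.0)
        # only the identity and the reversal reach |rho| = 1 among 4! pairings
        assert res.p == pytest.approx(2 / 24)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


class TestNeutrality:
    def test_fixture_gc12_gc3(self, table1):
        res = neutrality(table1["gc12"], table1["gc3"])
        assert res.rho == pytest.approx(0.25, abs=0.05)
        assert res.p > 0.05

    def test_full_neutrality_limit(self):
        gc = [40.0, 45.0, 50.0, 55.0]
        res = neutrality(gc, gc)
        assert res.rho == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_gc12_flagged(self):
        res = neutrality([50.0, 50.0, 50.0], [40.0, 45.0, 52.0])
        assert not res.defined and math.isnan(res.slope)
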