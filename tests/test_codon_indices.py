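import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonbias.codon_indices import (
    CodonCountTable,
    cai,
    enc,
    expected_enc,
    preferred_codons,
    rscu,
)
from codonbias.seq_io import (
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    ReferenceUsageTable,
)

# ---------------------------------------------------------------------------
# independent oracle for Wright's effective number of codons: regroups the
# codons with Biopython translation and applies the published formula
# symbol by symbol, sharing no code with the implementation under test.


def wright_enc_oracle(count_dict):
    from Bio.Seq import Seq

    by_aa = {}
    for codon, n in count_dict.items():
        aa = str(Seq(codon.replace("U", "T")).translate())
        if aa == "*":
            continue
        by_aa.setdefault(aa, {})[codon] = n
    degeneracy = {}
    for codon in SENSE_CODONS:
        aa = str(Seq(codon.replace("U", "T")).translate())
        degeneracy[aa] = degeneracy.get(aa, 0) + 1
    f_by_class = {2: [], 3: [], 4: [], 6: []}
    for aa, k in degeneracy.items():
        if k == 1:
            continue
        counts = [by_aa.get(aa, {}).get(c, 0)
                  for c in SENSE_CODONS
                  if str(Seq(c.replace("U", "T")).translate()) == aa]
        n = sum(counts)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in counts) - 1) / (n - 1)
        if f > 0:
            f_by_class[k].append(f)
    fbar = {k: sum(v) / len(v) for k, v in f_by_class.items() if v}
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    value = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(value, 61.0)


def _counts_from_seed(seed, low=0, high=60):
    rng = np.random.default_rng(seed)
    return {c: int(rng.integers(low, high)) for c in SENSE_CODONS}


class TestRscu:
    def test_ala_family_by_hand(self):
        counts = CodonCountTable.from_codons(
            ["GCU", "GCU", "GCC", "GCA"]
        )
        vec = rscu(counts)
        assert vec["GCU"] == pytest.approx(2.0)
        assert vec["GCC"] == pytest.approx(1.0)
        assert vec["GCA"] == pytest.approx(1.0)
        assert vec["GCG"] == pytest.approx(0.0)

    def test_uniform_usage_gives_all_ones(self):
        counts = CodonCountTable(counts={c: 7 for c in SENSE_CODONS})
        vec = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in vec.values.values())

    def test_absent_family_is_missing_not_zero(self):
        counts = CodonCountTable.from_codons(["GCU", "GCC"])
        vec = rscu(counts)
        assert math.isnan(vec["UUU"])
        assert vec["GCG"] == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            rscu(CodonCountTable(counts={}))

    def test_family_sums_equal_degeneracy_and_counts_round_trip(self):
        counts = CodonCountTable(counts=_counts_from_seed(5, low=1))
        vec = rscu(counts)
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            assert sum(vec[c] for c in codons) == pytest.approx(len(codons))
            # reconstruction: count = RSCU * family_total / degeneracy
            for c in codons:
                rebuilt = vec[c] * vec.family_totals[aa] / len(codons)
                assert rebuilt == pytest.approx(counts.counts[c])


class TestEnc:
    def test_single_codon_per_family_is_maximal_bias(self):
        counts = {codons[0]: 100 for codons in SYNONYMOUS_FAMILIES.values()}
        value = enc(CodonCountTable(counts=counts)).value
        assert value == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self):
        counts = CodonCountTable(counts={c: 10_000 for c in SENSE_CODONS})
        assert enc(counts).value == pytest.approx(61.0, abs=0.05)

    @pytest.mark.parametrize("seed", [1, 7, 99])
    def test_matches_independent_wright_oracle(self, seed):
        raw = _counts_from_seed(seed)
        raw["UUU"], raw["UUC"] = 3, 1
        assert enc(CodonCountTable(counts=raw)).value == pytest.approx(
            wright_enc_oracle(raw)
        )

    def test_invariant_to_sequence_order_and_scaling_direction(self):
        base = _counts_from_seed(3, low=1, high=12)
        values = [
            enc(CodonCountTable(counts={c: k * v for c, v in base.items()})).value
            for k in (1, 2, 4, 8)
        ]
        diffs = np.diff(values)
        assert (np.sign(diffs) == np.sign(diffs[0])).all()
        assert (np.abs(np.diff(np.abs(diffs))) >= 0).all()
        assert np.all(np.abs(diffs[1:]) <= np.abs(diffs[:-1]) + 1e-12)

    def test_missing_class_is_an_error(self):
        counts = CodonCountTable.from_codons(["GCU", "GCC", "GCA"])  # Ala only
        with pytest.raises(ValueError, match="class"):
            enc(counts)


class TestExpectedEnc:
    @pytest.mark.parametrize(
        "s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
    )
    def test_direct_substitution(self, s, expected):
        assert expected_enc(s) == pytest.approx(expected)

    def test_symmetric_about_half_after_removing_linear_term(self):
        for s in np.linspace(0, 1, 21):
            assert expected_enc(s) - s == pytest.approx(
                expected_enc(1 - s) - (1 - s)
            )

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


def _reference_preferring(preferred_bias=9, other=1):
    counts = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        for i, c in enumerate(codons):
            counts[c] = preferred_bias if i == 0 else other
    return ReferenceUsageTable(source="toy", counts=counts)


class TestCai:
    def test_reference_preferred_only_query_scores_one(self):
        ref = _reference_preferring()
        query = CodonCountTable(
            counts={codons[0]: 5 for codons in SYNONYMOUS_FAMILIES.values()}
        )
        assert cai(query, ref).value == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        # Phe reference 1:4 makes w(UUU) = 0.25; one of each query codon
        # gives CAI = sqrt(0.25 * 1.0) = 0.5
        counts = {c: 0 for c in SENSE_CODONS}
        counts["UUU"], counts["UUC"] = 1, 4
        ref = ReferenceUsageTable(source="phe", counts=counts)
        query = CodonCountTable(counts={"UUU": 1, "UUC": 1})
        assert cai(query, ref).value == pytest.approx(0.5)

    def test_reference_scale_invariance(self):
        ref1 = _reference_preferring(9, 2)
        ref10 = ReferenceUsageTable(
            source="x10", counts={c: 10 * v for c, v in ref1.counts.items()}
        )
        query = CodonCountTable(counts=_counts_from_seed(11, low=1))
        assert cai(query, ref1).value == pytest.approx(cai(query, ref10).value)

    def test_single_codon_dialect_pulls_toward_one(self):
        ref = _reference_preferring(9, 1)
        query = CodonCountTable(counts={**_counts_from_seed(4, low=1), "AUG": 50})
        excl = cai(query, ref).value
        incl = cai(query, ref, include_single_codon=True).value
        assert excl < incl <= 1.0

    def test_zero_reference_counts_get_pseudocount(self):
        counts = {c: 0 for c in SENSE_CODONS}
        counts["GCU"] = 10  # rest of Ala family is zero in the reference
        ref = ReferenceUsageTable(source="sparse", counts=counts)
        query = CodonCountTable(counts={"GCC": 3})
        value = cai(query, ref).value
        assert 0 < value < 1


class TestPreferredCodons:
    def test_table2_virus_column_winners(self, table2):
        report = preferred_codons(table2["zikv"])
        assert len(report.winners) == 18
        assert report.end_ac == 13
        assert report.end_ug == 5
        assert report.winners["R"] == "AGA"
        assert not report.ties

    def test_uniform_rscu_all_ties(self):
        counts = CodonCountTable(counts={c: 3 for c in SENSE_CODONS})
        report = preferred_codons(rscu(counts))
        assert len(report.ties) == 18

    def test_missing_family_partial_result_with_warning(self):
        counts = CodonCountTable.from_codons(["GCU", "GCC", "UUU", "UUC"])
        with pytest.warns(UserWarning, match="missing"):
            report = preferred_codons(rscu(counts))
        assert set(report.winners) == {"A", "F"}


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rscu_family_sums_property(seed):
    counts = CodonCountTable(counts=_counts_from_seed(seed, low=1, high=40))
    vec = rscu(counts)
    for codons in SYNONYMOUS_FAMILIES.values():
        assert sum(vec[c] for c in codons) == pytest.approx(len(codons))
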