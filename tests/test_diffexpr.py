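"""Differential-expression unit and oracle tests.

The exact-test oracle enumerates the conditional binomial split of the
total with exact rational arithmetic (fractions), independent of the
log-space implementation it checks.
"""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import glucoshift as gs
from glucoshift.diffexpr import classify

from conftest import make_matrix


def binomial_split_oracle(a: int, b: int, n_a: int, n_b: int) -> float:
    """Two-sided conditional binomial p-value via exact enumeration."""
    t = a + b
    p = Fraction(n_a, n_a + n_b)
    q = 1 - p

    def pmf(x):
        from math import comb

        return comb(t, x) * p**x * q ** (t - x)

    obs = pmf(a)
    return float(sum(pmf(x) for x in range(t + 1) if pmf(x) <= obs))


class TestComputeTpm:
    def test_equal_genes_split_evenly(self):
        m = make_matrix([[10], [10]], ["LL"], lengths=[1000, 1000])
        tpm = gs.compute_tpm(m)
        np.testing.assert_allclose(tpm.iloc[:, 0], [500000, 500000])

    def test_zero_count_gives_zero_tpm(self):
        m = make_matrix([[0], [10]], ["LL"])
        assert gs.compute_tpm(m).iloc[0, 0] == 0

    def test_length_normalization(self):
        # counts (10, 20), lengths (100, 400): rates (0.1, 0.05)
        m = make_matrix([[10], [20]], ["LL"], lengths=[100, 400])
        tpm = gs.compute_tpm(m)
        np.testing.assert_allclose(tpm.iloc[:, 0], [666666.6667, 333333.3333], rtol=1e-9)

    def test_columns_sum_to_one_million(self, small_matrix):
        tpm = gs.compute_tpm(small_matrix)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_error_names_sample(self):
        m = make_matrix([[0, 5], [0, 5]], ["LL", "LL"])
        with pytest.raises(gs.ValidationError, match="LL_1"):
            gs.compute_tpm(m)


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_phi(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(100, size=(2000, 6))
        m = make_matrix(counts, ["LL"] * 3 + ["HH"] * 3)
        assert gs.estimate_dispersion(m, ("LL", "HH")) <= 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(12)
        phi = 0.1
        r = 1 / phi
        mu = 200.0
        counts = rng.negative_binomial(r, r / (r + mu), size=(2000, 6))
        m = make_matrix(counts, ["LL"] * 3 + ["HH"] * 3)
        assert 0.05 <= gs.estimate_dispersion(m, ("LL", "HH")) <= 0.2

    def test_constant_counts_give_zero(self):
        m = make_matrix(np.full((10, 6), 100), ["LL"] * 3 + ["HH"] * 3)
        assert gs.estimate_dispersion(m, ("LL", "HH")) == 0.0

    def test_single_replicate_raises(self):
        m = make_matrix([[5, 5]], ["LL", "HH"])
        with pytest.raises(gs.ValidationError, match="supply phi"):
            gs.estimate_dispersion(m, ("LL", "HH"))


class TestNbExactTest:
    def test_identical_groups_give_p_one(self):
        assert gs.nb_exact_test([50, 50], [50, 50], 0.1) == 1.0

    def test_zero_vs_ten_matches_binomial_closed_form(self):
        # 0 of 10 at p=1/2, two-sided: 2/1024
        p = gs.nb_exact_test([0, 0], [5, 5], 0.0)
        assert p == pytest.approx(2 * (1 / 1024), abs=1e-15)

    def test_agrees_with_enumeration_oracle_at_phi_zero(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_a = int(rng.integers(1, 4))
            n_b = int(rng.integers(1, 4))
            a = int(rng.integers(0, 31))
            b = int(rng.integers(0, 31))
            if a + b == 0:
                continue
            counts_a = [a] + [0] * (n_a - 1)
            counts_b = [b] + [0] * (n_b - 1)
            got = gs.nb_exact_test(counts_a, counts_b, 0.0)
            want = binomial_split_oracle(a, b, n_a, n_b)
            assert got == pytest.approx(want, rel=1e-12), (a, b, n_a, n_b)

    def test_negative_phi_and_empty_group_rejected(self):
        with pytest.raises(gs.ValidationError):
            gs.nb_exact_test([1], [1], -0.1)
        with pytest.raises(gs.ValidationError):
            gs.nb_exact_test([], [1], 0.0)

    def test_larger_dispersion_weakens_evidence(self):
        p0 = gs.nb_exact_test([10, 10, 10], [40, 40, 40], 0.0)
        p1 = gs.nb_exact_test([10, 10, 10], [40, 40, 40], 0.2)
        assert p1 > p0


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(gs.bh_fdr([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        # q_(3)=0.03, q_(2)=min(0.03, 0.02*3/2)=0.03, q_(1)=min(...,0.01*3)=0.03
        np.testing.assert_allclose(gs.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(gs.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(gs.ValidationError):
            gs.bh_fdr([0.5, 1.2])

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.uniform(size=50))
        q = gs.bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()
        assert (q >= p - 1e-15).all()


class TestCallDegs:
    def test_self_comparison_rejected(self, small_matrix, config):
        with pytest.raises(gs.ValidationError):
            gs.call_degs(small_matrix, ("LL", "LL"), config)

    def test_identical_condition_counts_unchanged(self, config):
        block = np.tile([[100], [50]], (1, 6))
        m = make_matrix(block, ["LL"] * 3 + ["HH"] * 3)
        recs = gs.call_degs(m, ("LL", "HH"), config, phi=0.1)
        assert all(r.reg_class == "unchanged" for r in recs)

    def test_swapping_comparison_negates_lfc_keeps_p(self, config):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.poisson(80, (50, 6)), ["LL"] * 3 + ["HH"] * 3)
        fwd = gs.call_degs(m, ("LL", "HH"), config, phi=0.05)
        rev = gs.call_degs(m, ("HH", "LL"), config, phi=0.05)
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc, abs=1e-9)
            assert f.p_value == pytest.approx(r.p_value, rel=1e-9)

    def test_record_invariants(self, config):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.poisson(60, (100, 6)), ["LL"] * 3 + ["L2H"] * 3)
        for r in gs.call_degs(m, ("LL", "L2H"), config):
            assert r.q_value >= r.p_value - 1e-12
            if r.reg_class.startswith("significant"):
                assert abs(r.log2fc) > config.log2_deg_fold
                assert r.q_value < config.deg_fdr
            elif r.reg_class.startswith("moderate"):
                assert abs(r.log2fc) > config.log2_moderate_fold

    def test_classify_boundaries(self, config):
        assert classify(2.5, 1e-6, 1e-6, config) == "significant_up"
        assert classify(-2.5, 1e-6, 1e-6, config) == "significant_down"
        assert classify(0.3, 0.5, 0.5, config) == "moderate_up"  # 2^0.3=1.23 > 1.2
        assert classify(0.1, 0.5, 0.5, config) == "unchanged"


class TestSummativeCall:
    @staticmethod
    def _annotation(groups):
        rows = []
        for gid, grp in groups.items():
            rows.append((gid, "", [], [], grp))
        df = pd.DataFrame(
            rows, columns=["gene_id", "product", "ec_numbers", "pathway_ids", "isoform_group"]
        ).set_index("gene_id")
        return gs.GeneAnnotationTable(df)

    def test_singleton_group_matches_gene_lfc(self, config):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.poisson(100, (5, 6)), ["LL"] * 3 + ["HH"] * 3)
        ann = self._annotation({"g1": "grp1"})
        recs = gs.summative_call(m, ann, "isoform_group", ("LL", "HH"), config, phi=0.05)
        assert len(recs) == 1
        deg = {r.gene_id: r for r in gs.call_degs(m, ("LL", "HH"), config, phi=0.05)}
        assert recs[0].log2fc == pytest.approx(deg["g1"].log2fc, abs=1e-9)

    def test_discordant_isoform_group_like_pgk(self, config):
        # 4 low-abundance isoforms up 4x, one 10x-more-abundant isoform down 8x:
        # the summative level drops while the significant isoforms mostly rise.
        counts = np.array(
            [[50] * 3 + [200] * 3] * 4  # four isoforms, 4x up
            + [[5000] * 3 + [625] * 3]  # dominant isoform, 8x down
            + [[20000] * 6]  # stable background gene outside the group
        )
        m = make_matrix(counts, ["LL"] * 3 + ["HH"] * 3)
        ann = self._annotation({f"g{i}": "pgk" for i in range(1, 6)})
        rec = gs.summative_call(m, ann, "isoform_group", ("LL", "HH"), config, phi=0.0)[0]
        assert rec.n_isoforms == 5
        assert rec.log2fc < 0
        assert rec.n_significant_isoforms >= 4
        assert rec.discordant is True

    def test_unchanged_group_not_discordant(self, config):
        m = make_matrix(np.full((3, 6), 200), ["LL"] * 3 + ["HH"] * 3)
        ann = self._annotation({f"g{i}": "grp" for i in range(1, 4)})
        rec = gs.summative_call(m, ann, "isoform_group", ("LL", "HH"), config, phi=0.1)[0]
        assert rec.reg_class == "unchanged"
        assert rec.discordant is False

    def test_empty_group_key_rejected(self, small_matrix, config):
        ann = self._annotation({})
        with pytest.raises((gs.ValidationError, KeyError)):
            gs.summative_call(small_matrix, ann, "isoform_group", ("LL", "HH"), config)
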