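import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sisterh3 import (
    average_fc,
    compute_fc,
    replicate_filter,
    screen_responsive,
    student_t_two_sample,
)
from sisterh3.exceptions import ConfigError, DesignError, InputError
from sisterh3.foldchange import (
    REPLICATE_DISAGREEMENT,
    ZERO_RPKM,
    FoldChangeTable,
    pooled_t_pvalues,
)
from sisterh3.io import DOUBLE, WT

from conftest import fc_table_from_arrays, make_design, make_matrix
from _oracle import t_p as oracle_t_p


def two_strain_matrix(gene_t0, gene_t1, ref_t0=100.0, ref_t1=100.0):
    """One gene + reference, WT and DOUBLE strains, two replicates with
    identical values (noise-free)."""
    design = make_design(roles=(WT, DOUBLE))
    values = {}
    for s in design.table["sample_id"]:
        t0 = s.split("_")[-2] == "T0"
        values[s] = [ref_t0 if t0 else ref_t1, gene_t0 if t0 else gene_t1]
    return make_matrix(values, ["ACT1", "G1"]), design


class TestComputeFC:
    def test_exact_power_of_two_ratio(self):
        m, d = two_strain_matrix(gene_t0=50.0, gene_t1=200.0)
        fc = compute_fc(m, d)
        assert fc.replicate_fcs("G1", WT).tolist() == [2.0, 2.0]

    def test_gene_tracking_reference_has_zero_fc(self):
        m, d = two_strain_matrix(gene_t0=100.0, gene_t1=100.0)
        fc = compute_fc(m, d)
        assert fc.replicate_fcs("G1", WT).tolist() == [0.0, 0.0]

    def test_reference_gene_fc_is_exactly_zero(self, small_experiment):
        matrix, design, _ = small_experiment
        fc = compute_fc(matrix, design)
        assert (fc.fc.loc["ACT1"] == 0.0).all()

    def test_library_scaling_absorbed_by_reference(self):
        m, d = two_strain_matrix(gene_t0=50.0, gene_t1=200.0)
        scaled = m.values.copy()
        t1_cols = [s for s in scaled.columns if "_T1_" in s]
        scaled[t1_cols] *= 10.0
        from sisterh3.io import ExpressionMatrix

        fc = compute_fc(ExpressionMatrix(scaled), d)
        assert fc.replicate_fcs("G1", WT).tolist() == [2.0, 2.0]

    def test_zero_rpkm_gene_excluded(self):
        m, d = two_strain_matrix(gene_t0=0.0, gene_t1=200.0)
        fc = compute_fc(m, d)
        assert fc.exclusions == {"G1": ZERO_RPKM}
        assert "G1" not in fc.kept_genes

    def test_pseudocount_mode_keeps_zero_gene(self):
        m, d = two_strain_matrix(gene_t0=0.0, gene_t1=200.0)
        fc = compute_fc(m, d, pseudocount=0.5)
        assert fc.exclusions == {}
        expected = math.log2(200.5 / 0.5)
        assert fc.replicate_fcs("G1", WT)[0] == pytest.approx(expected)

    def test_zero_reference_is_fatal(self):
        m, d = two_strain_matrix(gene_t0=50.0, gene_t1=200.0, ref_t0=0.0)
        with pytest.raises(InputError, match="ACT1"):
            compute_fc(m, d)

    def test_sample_missing_from_matrix_is_design_error(self):
        m, d = two_strain_matrix(50.0, 200.0)
        trimmed = m.values.drop(columns=["WT_T1_r2"])
        from sisterh3.io import ExpressionMatrix

        with pytest.raises(DesignError, match="WT_T1_r2"):
            compute_fc(ExpressionMatrix(trimmed), d)


class TestReplicateFilter:
    def _table(self, rep_fcs):
        return fc_table_from_arrays(
            ["G1"], {WT: np.array([rep_fcs]), DOUBLE: np.array([[0.0, 0.0]])}
        )

    def test_close_replicates_retained(self):
        out = replicate_filter(self._table([2.0, 2.1]), threshold=1.0)
        assert out.exclusions == {}

    def test_disagreeing_replicates_excluded(self):
        out = replicate_filter(self._table([2.0, -0.5]), threshold=1.0)
        assert out.exclusions == {"G1": REPLICATE_DISAGREEMENT}

    def test_infinite_threshold_keeps_everything(self):
        out = replicate_filter(self._table([5.0, -5.0]), threshold=math.inf)
        assert out.exclusions == {}

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            replicate_filter(self._table([0.0, 0.0]), method="bogus")


class TestAverageFC:
    @pytest.mark.parametrize(
        "reps, expected", [([1.0, 3.0], 2.0), ([0.7, 0.7], 0.7), ([-1.5, 0.5], -0.5)]
    )
    def test_fca_is_replicate_mean(self, reps, expected):
        t = fc_table_from_arrays(
            ["G1"], {WT: np.array([reps]), DOUBLE: np.array([[0.0, 0.0]])}
        )
        assert t.fca.loc["G1", WT] == expected

    def test_commutes_with_replicate_relabeling(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(4, 2))
        t1 = fc_table_from_arrays(["a", "b", "c", "d"], {WT: arr})
        t2 = fc_table_from_arrays(["a", "b", "c", "d"], {WT: arr[:, ::-1]})
        assert np.array_equal(t1.fca.to_numpy(), t2.fca.to_numpy())

    def test_excluded_genes_carry_no_fca(self):
        t = fc_table_from_arrays(
            ["G1", "G2"],
            {WT: np.array([[2.0, -2.0], [1.0, 1.0]]), DOUBLE: np.zeros((2, 2))},
        )
        filtered = average_fc(replicate_filter(t, threshold=1.0))
        assert "G1" not in filtered.fca.index and "G2" in filtered.fca.index


class TestStudentT:
    def test_matches_closed_form_df2_tail(self):
        # t = 2*sqrt(2), P = 1 - t/sqrt(2 + t^2) = 0.10557...
        p = student_t_two_sample([1, 2], [3, 4])
        assert p == pytest.approx(1.0 - 2 * math.sqrt(2) / math.sqrt(10), abs=1e-12)

    def test_identical_groups_give_p_one(self):
        assert student_t_two_sample([1, 2], [1, 2]) == 1.0

    def test_zero_variance_different_means_gives_p_zero(self):
        assert student_t_two_sample([0, 0], [1, 1]) == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            student_t_two_sample([1], [1, 2])

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=5),
        st.lists(st.floats(-50, 50), min_size=2, max_size=5),
    )
    def test_agrees_with_independent_transcription(self, a, b):
        assert student_t_two_sample(a, b) == pytest.approx(
            oracle_t_p(a, b), abs=1e-12
        )

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        vec = pooled_t_pvalues(A, B)
        scal = [student_t_two_sample(a, b) for a, b in zip(A, B)]
        assert vec == pytest.approx(scal, abs=1e-14)


class TestScreenResponsive:
    def _table(self, wt, dbl):
        return fc_table_from_arrays(
            ["G1"], {WT: np.array([wt]), DOUBLE: np.array([dbl])}
        )

    def test_clearly_shifted_gene_included(self):
        t = self._table([2.0, 2.1], [0.0, 0.1])
        resp = screen_responsive(t, alpha=0.05)
        # oracle: pooled t, df=2, closed-form tail
        assert resp.pvalues["G1"] == pytest.approx(
            oracle_t_p([2.0, 2.1], [0.0, 0.1]), abs=1e-12
        )
        assert "G1" in resp

    def test_overlapping_gene_not_included(self):
        t = self._table([1.0, 1.1], [1.05, 0.95])
        resp = screen_responsive(t, alpha=0.05)
        assert resp.pvalues["G1"] > 0.5 and "G1" not in resp

    def test_excluded_gene_never_enters(self):
        t = fc_table_from_arrays(
            ["G1"], {WT: np.array([[3.0, 3.0]]), DOUBLE: np.array([[0.0, 0.0]])}
        )
        t.exclusions["G1"] = ZERO_RPKM
        assert len(screen_responsive(t, alpha=0.05)) == 0

    def test_missing_role_is_design_error(self):
        t = fc_table_from_arrays(["G1"], {WT: np.array([[1.0, 1.0]])})
        with pytest.raises(DesignError):
            screen_responsive(t)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        t = fc_table_from_arrays(
            [f"G{i}" for i in range(40)],
            {WT: rng.normal(0, 1, (40, 2)), DOUBLE: rng.normal(0.5, 1, (40, 2))},
        )
        sets = [screen_responsive(t, alpha=a).genes for a in (0.0, 0.01, 0.2, 1.0)]
        assert sets[0] == frozenset()
        for lo, hi in zip(sets, sets[1:]):
            assert lo <= hi
        assert sets[-1] == frozenset(t.kept_genes)
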