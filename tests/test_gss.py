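import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from sisterh3 import (
    build_mid_set,
    classify_clusters,
    gss,
    mid_statistic,
    screen_responsive,
)
from sisterh3.exceptions import ClassificationWarning, DegenerateEndpointsError
from sisterh3.foldchange import ResponsiveSet
from sisterh3.gss import UNASSIGNED
from sisterh3.io import ASYM_A, ASYM_B, DOUBLE, WT

import pandas as pd

from conftest import fc_table_from_arrays, random_fc_arrays
from _oracle import classify as oracle_classify

finite_fc = st.floats(-20, 20)


def _responsive(genes, alpha=0.05):
    return ResponsiveSet(
        frozenset(genes), pd.Series(0.0, index=list(genes)), alpha
    )


class TestMidStatistic:
    @pytest.mark.parametrize(
        "asym, wt, dbl, expected",
        [
            (1.0, 2.0, 0.0, 1.0),   # strictly between
            (3.0, 2.0, 0.0, 2.0),   # outside: (1 + 3) / 2
            (2.0, 2.0, 0.0, 1.0),   # boundary: equals an endpoint
            (0.0, 2.0, 0.0, 1.0),   # other endpoint
            (-1.0, 2.0, 0.0, 2.0),  # outside on the DOUBLE side
        ],
    )
    def test_examples(self, asym, wt, dbl, expected):
        assert mid_statistic(asym, wt, dbl) == expected

    def test_degenerate_endpoints_raise(self):
        with pytest.raises(DegenerateEndpointsError):
            mid_statistic(1.0, 2.0, 2.0)

    @given(finite_fc, finite_fc, finite_fc)
    def test_at_least_one_and_one_iff_between(self, asym, wt, dbl):
        span = abs(wt - dbl)
        assume(span > 1e-6 * max(1.0, abs(wt), abs(dbl)))
        # keep the point away from the interval boundary, where the
        # betweenness predicate itself is float-ambiguous
        outside = max(min(wt, dbl) - asym, asym - max(wt, dbl))
        assume(outside <= 0 or outside > 1e-6 * span)
        m = mid_statistic(asym, wt, dbl)
        assert m >= 1.0 - 1e-12
        between = min(wt, dbl) <= asym <= max(wt, dbl)
        assert (m <= 1.0 + 1e-9) == between


class TestGSS:
    @pytest.mark.parametrize(
        "asym, wt, dbl, expected",
        [
            (1.0, 2.0, 0.0, 0.0),                  # exact midpoint
            (1.5, 2.0, 0.0, math.log2(3.0)),       # skew toward WT
            (0.5, 2.0, 0.0, -math.log2(3.0)),      # mirrored skew
            (2.0, 2.0, 0.0, math.inf),             # equals WT endpoint
            (0.0, 2.0, 0.0, -math.inf),            # equals DOUBLE endpoint
        ],
    )
    def test_examples(self, asym, wt, dbl, expected):
        assert gss(asym, wt, dbl) == pytest.approx(expected, abs=1e-12)

    def test_all_equal_is_degenerate(self):
        with pytest.raises(DegenerateEndpointsError):
            gss(1.0, 1.0, 1.0)

    @given(finite_fc, finite_fc, st.floats(0.01, 0.99))
    def test_antisymmetric_about_midpoint(self, wt, dbl, frac):
        assume(abs(wt - dbl) > 1e-3)
        asym = wt + frac * (dbl - wt)
        mid = (wt + dbl) / 2.0
        reflected = 2.0 * mid - asym
        assert gss(reflected, wt, dbl) == pytest.approx(
            -gss(asym, wt, dbl), abs=1e-9
        )

    def test_strictly_increasing_toward_wt(self):
        wt, dbl = 2.0, -1.0
        fracs = np.linspace(0.05, 0.95, 19)  # 0 = at WT .. 1 = at DOUBLE
        values = [gss(wt + f * (dbl - wt), wt, dbl) for f in fracs]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestMidSet:
    def _table(self, asym_a, asym_b):
        return fc_table_from_arrays(
            ["G1"],
            {
                WT: [[2.0, 2.0]],
                ASYM_A: [[asym_a, asym_a]],
                ASYM_B: [[asym_b, asym_b]],
                DOUBLE: [[0.0, 0.0]],
            },
        )

    def test_both_strains_between(self):
        t = self._table(1.2, 0.7)
        assert build_mid_set(t, _responsive({"G1"})) == {"G1"}

    def test_one_strain_outside_fails(self):
        t = self._table(1.2, 2.7)
        assert build_mid_set(t, _responsive({"G1"})) == frozenset()

    def test_non_responsive_gene_gated_out(self):
        t = self._table(1.2, 0.7)
        assert build_mid_set(t, _responsive(set())) == frozenset()

    def test_degenerate_endpoints_skipped_with_warning(self):
        t = fc_table_from_arrays(
            ["G1"],
            {r: [[1.0, 1.0]] for r in (WT, ASYM_A, ASYM_B, DOUBLE)},
        )
        with pytest.warns(ClassificationWarning):
            out = build_mid_set(t, _responsive({"G1"}))
        assert out == frozenset()


def run_pipeline_on(table, alpha=0.05):
    resp = screen_responsive(table, alpha=alpha)
    mid = build_mid_set(table, resp)
    return resp, mid, classify_clusters(table, mid, alpha=alpha)


class TestClassifyClusters:
    def five_gene_fixture(self):
        # one clear midpoint gene, one WT-like, one DOUBLE-like, one
        # noisy midpoint, one borderline near an endpoint
        reps = {
            WT: [[2.0, 2.1]] * 5,
            DOUBLE: [[-1.0, -0.9]] * 5,
            ASYM_A: [
                [0.5, 0.55],
                [2.0, 2.05],
                [-0.9, -0.95],
                [1.5, -0.5],
                [0.9, 0.95],
            ],
            ASYM_B: [
                [0.5, 0.45],
                [2.1, 2.0],
                [-0.85, -0.95],
                [0.5, 1.4],
                [0.5, 1.4],
            ],
        }
        genes = ["mid", "wt_like", "dbl_like", "noisy", "borderline"]
        return fc_table_from_arrays(genes, reps)

    def test_five_gene_fixture_matches_oracle(self):
        table = self.five_gene_fixture()
        resp, mid, cl = run_pipeline_on(table)
        fcs = {
            g: {r: table.replicate_fcs(g, r).tolist() for r in table.strain_roles}
            for g in table.genes
        }
        o_resp, o_mid, o_clusters = oracle_classify(fcs)
        assert resp.genes == frozenset(o_resp)
        assert mid == frozenset(o_mid)
        assert dict(cl.table["cluster"]) == o_clusters
        assert cl.table.loc["mid", "cluster"] == "II"
        assert cl.table.loc["wt_like", "cluster"] == "III"
        assert cl.table.loc["dbl_like", "cluster"] == "I"

    def test_noise_free_planted_modes_fully_recovered(self, noise_free_experiment):
        from sisterh3 import average_fc, compute_fc, replicate_filter, truth_cluster

        matrix, design, truth = noise_free_experiment
        table = average_fc(replicate_filter(compute_fc(matrix, design)))
        _, _, cl = run_pipeline_on(table)
        expected = truth_cluster(truth)
        for gene, assigned in cl.table["cluster"].items():
            assert assigned == expected[gene]
        # and no gene of a planted mode is lost from MID at sigma = 0
        planted = {g for g, c in expected.items() if c != "NONE"}
        assert planted == set(cl.table.index)

    def test_all_strains_identical_yields_empty_classification(self):
        t = fc_table_from_arrays(
            ["G1", "G2"],
            {r: [[0.3, 0.3], [1.0, 1.0]] for r in (WT, ASYM_A, ASYM_B, DOUBLE)},
        )
        resp = screen_responsive(t)
        assert len(resp) == 0
        with pytest.warns(ClassificationWarning):
            cl = classify_clusters(t, build_mid_set(t, resp))
        assert cl.table.empty and cl.gss_max is None

    def test_empty_cluster_ii_leaves_bounds_undefined(self):
        # redundant-only fixture: asym replicates exactly track WT
        t = fc_table_from_arrays(
            ["G1"],
            {
                WT: [[2.0, 2.1]],
                ASYM_A: [[2.0, 2.1]],
                ASYM_B: [[2.0, 2.1]],
                DOUBLE: [[0.0, 0.1]],
            },
        )
        resp, mid, _ = None, build_mid_set(t, _responsive({"G1"})), None
        with pytest.warns(ClassificationWarning, match="bounds"):
            cl = classify_clusters(t, mid)
        assert cl.gss_max is None and cl.gss_min is None
        assert (cl.table["cluster"] == UNASSIGNED).all()

    def test_invariant_under_asym_label_swap(self):
        rng = np.random.default_rng(8)
        arrays = random_fc_arrays(rng, 60)
        genes = [f"G{i}" for i in range(60)]
        t1 = fc_table_from_arrays(genes, arrays)
        swapped = dict(arrays)
        swapped[ASYM_A], swapped[ASYM_B] = arrays[ASYM_B], arrays[ASYM_A]
        t2 = fc_table_from_arrays(genes, swapped)
        _, _, c1 = run_pipeline_on(t1)
        _, _, c2 = run_pipeline_on(t2)
        assert dict(c1.table["cluster"]) == dict(c2.table["cluster"])
        assert c1.gss_max == c2.gss_max and c1.gss_min == c2.gss_min

    def test_clusters_disjoint_and_nested_in_mid(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(80)]
        t = fc_table_from_arrays(genes, random_fc_arrays(rng, 80))
        resp, mid, cl = run_pipeline_on(t)
        sets = [cl.cluster(c) for c in ("I", "II", "III")]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                assert not (a & b)
            assert a <= mid
        assert mid <= resp.genes

    def test_cluster_ii_members_have_finite_gss_within_bounds(self):
        rng = np.random.default_rng(10)
        genes = [f"G{i}" for i in range(120)]
        t = fc_table_from_arrays(genes, random_fc_arrays(rng, 120))
        _, _, cl = run_pipeline_on(t)
        ii = cl.table[cl.table["cluster"] == "II"]
        if len(ii):
            assert np.isfinite(ii[["gss_a", "gss_b"]]).all().all()
            assert (ii[["gss_a", "gss_b"]] <= cl.gss_max).all().all()
            assert (ii[["gss_a", "gss_b"]] >= cl.gss_min).all().all()
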