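"""Univariate screening: rank tests, FDR, time trends, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from _oracles import mw_enumeration_oracle

from neodx import (bh_adjust, compare_groups, mann_whitney,
                   pca_on_significant, significant_in_any, spearman_time)


class TestMannWhitney:
    def test_fully_shifted_samples(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_branch_matches_enumeration(self, rng):
        checked = 0
        while checked < 15:
            n, m = rng.integers(2, 7, size=2)
            x = rng.normal(size=n).round(3)
            y = rng.normal(size=m).round(3)
            if len(np.unique(np.concatenate([x, y]))) < n + m:
                continue  # exact branch requires no ties
            U, p = mann_whitney(x, y)
            Uo, po = mw_enumeration_oracle(x, y)
            assert U == pytest.approx(Uo)
            assert p == pytest.approx(po, abs=1e-12)
            checked += 1


class TestBhAdjust:
    @pytest.mark.parametrize("pvals, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.3], [0.3]),
    ])
    def test_hand_computed_step_up(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_matches_brute_force_oracle(self, rng):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            q = np.empty(m)
            for i in range(m):
                cands = [min(1.0, m * p[j] / (np.sum(p <= p[j])))
                         for j in range(m) if p[j] >= p[i]]
                q[i] = min(cands)
            return q

        for _ in range(50):
            p = rng.random(rng.integers(1, 9))
            np.testing.assert_allclose(bh_adjust(p), oracle(p),
                                       atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = rng.random(57)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        # monotone in rank of p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestBhProperties:
    """Derandomised property tests for the step-up adjustment."""

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_q_bounds_and_monotonicity(self, pvals):
        p = np.asarray(pvals)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1 + 1e-12)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = bh_adjust(pvals)
        q_perm = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestCompareGroups:
    def test_planted_glycine_flagged_up(self, panel, default_noise,
                                        glycine_only_template):
        from neodx.cohort import generate_cohort
        tab = generate_cohort(glycine_only_template, default_noise, 4)
        res = compare_groups(tab, "control", "case")
        row = res.table[res.table["analyte"] == "Gly"].iloc[0]
        assert row["significant"]
        assert row["direction"] == "up"

    def test_missing_group_errors(self, hie_table):
        with pytest.raises(ValueError, match="not present"):
            compare_groups(hie_table, "control", "nope")

    def test_monotone_transform_invariance(self, hie_table):
        res = compare_groups(hie_table, "control", "hie_6h")
        warped = hie_table.data.transform(lambda c: np.log1p(c) ** 2)
        from neodx.io import SampleTable
        tab2 = SampleTable(hie_table.panel, warped, hie_table.meta)
        res2 = compare_groups(tab2, "control", "hie_6h")
        np.testing.assert_allclose(res.table["p"], res2.table["p"])
        assert (res.table["significant"] ==
                res2.table["significant"]).all()


class TestSpearmanTime:
    def test_perfect_monotone(self, panel):
        """Strictly increasing concentration over distinct sampling
        times gives rho exactly 1."""
        import pandas as pd
        from neodx.io import SampleTable
        rng = np.random.default_rng(1)
        n = 8
        data = pd.DataFrame(
            rng.random((n, 57)) + 0.5, columns=panel.codes,
            index=[f"s{i}" for i in range(n)])
        data["Gly"] = np.arange(n) * 1.7 + 2.0
        meta = pd.DataFrame({"group": "g", "time_h": np.arange(n, dtype=float),
                             "treatment": "none"}, index=data.index)
        tab = SampleTable(panel, data, meta)
        assert spearman_time(tab).rho("Gly") == pytest.approx(1.0)

    def test_rank_formula_hand_value(self):
        rho = stats.spearmanr([3, 1, 2], [0, 3, 6]).statistic
        assert rho == pytest.approx(-0.5)

    def test_planted_time_trends(self, hie_table):
        ta = spearman_time(hie_table)
        g = ta.table[ta.table["analyte"] == "Gly"].iloc[0]
        m = ta.table[ta.table["analyte"] == "Met"].iloc[0]
        assert g["rho"] > 0 and g["p"] < 0.05
        assert m["rho"] < 0 and m["p"] < 0.05

    def test_single_time_point_errors(self, scenarios):
        tab = scenarios["validation_pool"].generate(0)
        with pytest.raises(ValueError, match="time"):
            spearman_time(tab)


class TestPca:
    def test_rank_one_data(self, panel):
        from neodx.io import SampleTable
        import pandas as pd
        rng = np.random.default_rng(0)
        line = rng.random(12)
        codes = panel.codes
        X = np.outer(line, np.linspace(1, 3, 57))
        data = pd.DataFrame(X, columns=codes,
                            index=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame({"group": "g", "time_h": 0.0,
                             "treatment": "none"}, index=data.index)
        tab = SampleTable(panel, data, meta)
        res = pca_on_significant(tab, codes[:3])
        assert res.explained_variance_ratio[0] == pytest.approx(1.0,
                                                                abs=1e-9)

    def test_loadings_orthonormal(self, hie_table):
        res = pca_on_significant(hie_table, hie_table.panel.codes[:10])
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]),
                                   atol=1e-9)

    def test_explained_variance_non_increasing(self, hie_table):
        res = pca_on_significant(hie_table, hie_table.panel.codes)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1 + 1e-9

    def test_zero_variance_dropped_with_warning(self, hie_table):
        import pandas as pd
        from neodx.io import SampleTable
        data = hie_table.data.copy()
        data["Gly"] = 1.0
        tab = SampleTable(hie_table.panel, data, hie_table.meta)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_on_significant(tab, ["Gly", "Met", "Ala"])
        assert res.dropped == ["Gly"]
        assert "Gly" not in res.analytes

    def test_groups_separate_in_pc_space(self, hie_table):
        """Control and 6 h samples should split along PC1–2."""
        from sklearn.metrics import silhouette_score
        res3 = compare_groups(hie_table, "control", "hie_3h")
        res6 = compare_groups(hie_table, "control", "hie_6h")
        sel = significant_in_any([res3, res6])
        pca = pca_on_significant(hie_table, sel)
        mask = hie_table.groups.isin(["control", "hie_6h"]).to_numpy()
        sil = silhouette_score(pca.scores[mask][:, :2],
                               hie_table.groups[mask])
        assert sil > 0.2
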