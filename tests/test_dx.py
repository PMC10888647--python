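"""Stepwise logistic diagnostic-model builder and split validation."""

import math

import numpy as np
import pytest

from neodx import (DxBuilder, expand_features, logistic_irls,
                   split_validation)
from neodx.cohort import generate_cohort
from neodx.logit import (ExpandedFeatures, backward_p_elimination,
                         stepwise_aic, vip_prefilter)


@pytest.fixture()
def gly_table(glycine_only_template, default_noise):
    return generate_cohort(glycine_only_template, default_noise, 3)


class TestExpandFeatures:
    def test_full_panel_feature_count(self, hie_table):
        feats = expand_features(hie_table)
        assert len(feats) == 57 + 57 + 57 * 56 // 2 == 1710

    def test_two_analyte_expansion(self, panel, hie_table):
        from neodx.io import SampleTable
        codes = ["Gly", "Met"]
        sub = SampleTable(panel.subset(codes), hie_table.data[codes],
                         hie_table.meta)
        feats = expand_features(sub)
        assert feats.names == ["Gly", "Met", "Gly^2", "Met^2", "Gly*Met"]

    def test_square_equals_elementwise_square(self, hie_table):
        feats = expand_features(hie_table)
        np.testing.assert_array_equal(
            feats.column("Gly^2"), hie_table.data["Gly"].to_numpy() ** 2)
        np.testing.assert_array_equal(
            feats.column("Gly*Ala"),
            hie_table.data["Gly"].to_numpy()
            * hie_table.data["Ala"].to_numpy())


class TestLogisticIrls:
    def test_matches_contingency_table_log_odds(self):
        """Binary predictor, non-separable: MLE equals the closed-form
        log-odds of the 2x2 table."""
        x = np.array([0.0] * 10 + [1.0] * 10).reshape(-1, 1)
        y = np.array([1] * 3 + [0] * 7 + [1] * 7 + [0] * 3, float)
        fit = logistic_irls(x, y)
        assert fit.ridge == 0.0
        assert fit.converged and not fit.separation
        assert fit.coef[0] == pytest.approx(math.log(3 / 7), abs=1e-6)
        assert fit.coef[1] == pytest.approx(math.log(49 / 9), abs=1e-6)

    def test_separation_flagged(self):
        x = np.linspace(-1, 1, 12).reshape(-1, 1)
        y = (x.ravel() > 0).astype(float)
        fit = logistic_irls(x, y)
        assert fit.separation

    def test_intercept_only(self):
        y = np.array([0.0, 0, 1, 1, 1])
        fit = logistic_irls(np.empty((5, 0)), y)
        assert fit.coef[0] == pytest.approx(math.log(3 / 2), abs=1e-6)


class TestVipPrefilter:
    def test_planted_signal_survives(self, gly_table):
        y = gly_table.binary_labels("control", "case")
        feats, _, _ = expand_features(
            gly_table.select_groups("control", "case")).standardized()
        surv = vip_prefilter(feats, y, n_ortho=2)
        assert "Gly" in surv.names
        assert "Gly^2" in surv.names

    def test_noise_survivor_fraction_bounded(self, rng):
        """mean(VIP^2)=1 pigeonholes the VIP>1 fraction well below 1."""
        M = rng.normal(size=(23, 300))
        y = np.array([0.0] * 11 + [1.0] * 12)
        feats = ExpandedFeatures([], [f"f{i}" for i in range(300)], M,
                                 [f"s{i}" for i in range(23)])
        surv = vip_prefilter(feats, y, n_ortho=2)
        assert len(surv.names) / 300 < 0.6

    def test_empty_survivor_set_errors(self, gly_table):
        y = gly_table.binary_labels("control", "case")
        feats = expand_features(gly_table)
        with pytest.raises(ValueError, match="VIP filter"):
            vip_prefilter(feats, y, threshold=1e6)


class TestStepwiseAic:
    def test_aic_strictly_decreases_along_path(self, gly_table):
        y = gly_table.binary_labels("control", "case")
        feats, _, _ = expand_features(gly_table).standardized()
        surv = vip_prefilter(feats, y)
        fit, path = stepwise_aic(surv, y)
        aics = [s["aic"] for s in path]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_recovers_planted_squared_term(self, panel, default_noise,
                                           rng):
        """y drawn from a logistic model in glycine^2: the first
        selected feature is glycine-derived (g or g^2, which are nearly
        collinear on positive data)."""
        from neodx.cohort import EffectTemplate, GroupSpec
        sub = panel.subset(["Gly", "Ala", "Met", "C2", "C4"])
        tmpl = EffectTemplate("flat", (GroupSpec("a", 20),
                                       GroupSpec("b", 20)))
        hits = n_runs = 0
        for seed in range(20):
            tab = generate_cohort(tmpl, default_noise, seed, panel=sub)
            feats, _, _ = expand_features(tab).standardized()
            g2 = feats.column("Gly^2")
            y = (rng.random(40)
                 < 1 / (1 + np.exp(-(0.5 + 3.0 * g2)))).astype(float)
            if np.bincount(y.astype(int), minlength=2).min() < 3:
                continue
            _, path = stepwise_aic(feats, y)
            n_runs += 1
            hits += len(path) > 1 and "Gly" in path[1]["added"]
        assert n_runs >= 15
        assert hits / n_runs >= 0.9

    def test_null_builder_selects_at_most_one_median(self, scenarios):
        """Full builder (prefilter + AIC + elimination) on null cohorts:
        the Wald-based elimination keeps the final model small."""
        builder = DxBuilder()
        counts = []
        for seed in range(20):
            tab = scenarios["null"].generate(seed)
            sub = tab.select_groups("g1", "g3")
            y = tab.binary_labels("g1", "g3")
            try:
                m = builder.build(expand_features(sub), y)
                counts.append(len(m.features))
            except ValueError:
                counts.append(0)
        assert np.median(counts) <= 1


class TestBackwardElimination:
    def _fit(self, feats, y):
        fit, _ = stepwise_aic(feats, y)
        return fit

    def test_fixed_point_when_all_significant(self, gly_table):
        y = gly_table.binary_labels("control", "case")
        feats, _, _ = expand_features(gly_table).standardized()
        surv = vip_prefilter(feats, y)
        fit = self._fit(surv, y)
        final, dropped = backward_p_elimination(fit, surv, y)
        if (fit.wald_p[1:] < 0.05).all():
            assert final.features == fit.features
            assert dropped == []
        assert (final.wald_p[1:] < 0.05).all() or not final.features
        assert len(dropped) <= len(fit.features)

    def test_junk_dropped_strong_kept(self, rng):
        n = 60
        strong = rng.normal(size=n)
        junk = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2.5 * strong))).astype(float)
        feats = ExpandedFeatures([], ["strong", "junk"],
                                 np.column_stack([strong, junk]),
                                 [f"s{i}" for i in range(n)])
        fit = logistic_irls(feats.matrix, y, ["strong", "junk"])
        final, dropped = backward_p_elimination(fit, feats, y)
        assert "strong" in final.features
        assert "junk" in dropped


class TestLooCvBuilder:
    def test_whole_builder_runs_inside_fold(self, gly_table):
        """The fold prediction for a sample equals rebuilding on the
        remaining samples only — held-out data cannot leak in."""
        from neodx.logit import loo_cv_logit
        y = gly_table.binary_labels("control", "case")
        feats = expand_features(gly_table)
        model = loo_cv_logit(feats, y)
        i = 0
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        train = ExpandedFeatures(
            feats.base_codes, feats.names, feats.matrix[mask],
            [s for j, s in enumerate(feats.sample_ids) if mask[j]])
        fold_model = DxBuilder().build(train, y[mask])
        expect = fold_model.predict_proba(
            ExpandedFeatures(feats.base_codes, feats.names,
                             feats.matrix[i:i + 1],
                             [feats.sample_ids[i]]))[0]
        assert model.cv_proba[i] == pytest.approx(expect, abs=1e-12)

    def test_metrics_populated_and_sane(self, gly_table):
        from neodx.logit import loo_cv_logit
        y = gly_table.binary_labels("control", "case")
        model = loo_cv_logit(expand_features(gly_table), y)
        assert 0 <= model.roc_curve.auc <= 1
        assert 0 <= model.sensitivity <= 1
        assert 0 <= model.specificity <= 1
        assert any("Gly" in f for f in model.features)


class TestSplitValidation:
    def test_deterministic_per_seed(self, scenarios):
        tab = scenarios["validation_pool"].generate(2)
        a = split_validation(tab, "control", "hie_6h", n_repeats=4,
                             seed=9)
        b = split_validation(tab, "control", "hie_6h", n_repeats=4,
                             seed=9)
        assert a.per_repeat.equals(b.per_repeat)

    def test_strong_effect_high_performance(self, scenarios):
        tab = scenarios["validation_pool"].generate(2)
        rep = split_validation(tab, "control", "hie_6h", n_repeats=15,
                               seed=1)
        for model in ("opls", "logistic"):
            assert rep.mean(model, "sensitivity") > 0.8
            assert rep.mean(model, "specificity") > 0.6

    def test_metrics_in_unit_interval(self, scenarios):
        tab = scenarios["validation_pool"].generate(2)
        rep = split_validation(tab, "control", "hie_6h", n_repeats=4,
                               seed=3)
        vals = rep.per_repeat[["sensitivity", "specificity"]].to_numpy()
        vals = vals[np.isfinite(vals)]
        assert ((vals >= 0) & (vals <= 1)).all()
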