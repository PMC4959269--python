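"""Bimodality classification and population statistics."""

import numpy as np
import pytest

from adiposwitch import (InputDomainError, classify_bimodality,
                         fraction_differentiated, graded_pakt_fat_relation,
                         preswitch_predictor_ranking)


def lognormal_mixture(rng, n, frac_high, mu_lo=0.0, mu_hi=1.0, sd=0.1):
    """log10-normal mixture with known labels; mu on the log10 scale."""
    labels = rng.random(n) < frac_high
    logs = np.where(labels, rng.normal(mu_hi, sd, n), rng.normal(mu_lo, sd, n))
    return 10.0 ** logs, labels


class TestClassifyBimodality:
    def test_identical_values_unimodal(self):
        res = classify_bimodality(np.full(100, 3.7))
        assert not res.is_bimodal

    def test_known_balanced_mixture(self):
        rng = np.random.default_rng(0)
        vals, _ = lognormal_mixture(rng, 2000, 0.5)
        res = classify_bimodality(vals)
        assert res.is_bimodal
        assert res.frac_high == pytest.approx(0.5, abs=0.03)
        assert 10 ** res.mean_low_log10 < res.threshold < 10 ** res.mean_high_log10

    def test_single_lognormal_unimodal(self):
        rng = np.random.default_rng(1)
        sigma = np.sqrt(np.log(1 + 0.3 ** 2))
        vals = np.exp(rng.normal(0, sigma, 2000))
        assert not classify_bimodality(vals).is_bimodal

    def test_minor_mode_below_floor_ignored(self):
        rng = np.random.default_rng(2)
        vals, _ = lognormal_mixture(rng, 2000, 0.98)
        assert not classify_bimodality(vals).is_bimodal

    def test_too_few_or_nonpositive_rejected(self):
        with pytest.raises(InputDomainError):
            classify_bimodality(np.ones(20))
        with pytest.raises(InputDomainError):
            classify_bimodality(np.concatenate([np.zeros(5), np.ones(60)]))

    @pytest.mark.parametrize("frac_high", [0.2, 0.5, 0.8])
    def test_classifier_accuracy_on_separated_mixtures(self, frac_high):
        """>= 95% label accuracy at 4-sd mode separation."""
        rng = np.random.default_rng(42)
        vals, labels = lognormal_mixture(rng, 2000, frac_high,
                                         mu_lo=0.0, mu_hi=0.8, sd=0.2)
        res = classify_bimodality(vals)
        assert res.is_bimodal
        pred = vals > res.threshold
        assert (pred == labels).mean() >= 0.95


class TestFractionDifferentiated:
    def _table(self, vals, time=96.0):
        import pandas as pd
        return pd.DataFrame({"cell_id": np.arange(len(vals)), "time_h": time,
                             "pparg": vals, "failed": False})

    def test_all_below_threshold(self):
        t = self._table(np.full(100, 0.5))
        res = fraction_differentiated(t, "pparg", 96.0, threshold_rule=1.0)
        assert res["fraction"] == 0.0

    def test_known_mixture_fraction(self):
        rng = np.random.default_rng(3)
        vals, _ = lognormal_mixture(rng, 2000, 0.30)
        res = fraction_differentiated(self._table(vals), "pparg", 96.0)
        assert res["fraction"] == pytest.approx(0.30, abs=0.03)
        assert res["ci_low"] < 0.30 < res["ci_high"]

    def test_unimodal_without_fallback_errors(self):
        rng = np.random.default_rng(4)
        vals = np.exp(rng.normal(0, 0.25, 500))
        with pytest.raises(InputDomainError):
            fraction_differentiated(self._table(vals), "pparg", 96.0)

    def test_unimodal_with_fallback_uses_fixed_threshold(self):
        rng = np.random.default_rng(4)
        vals = np.exp(rng.normal(0, 0.25, 500))
        res = fraction_differentiated(self._table(vals), "pparg", 96.0,
                                      fixed_threshold=50.0)
        assert res["fraction"] == 0.0 and res["threshold"] == 50.0


class TestPredictorRanking:
    def _table(self, rng, n=400):
        import pandas as pd
        labels = rng.random(n) < 0.5
        final_p = np.where(labels, 10.0, 1.0) * np.exp(rng.normal(0, 0.05, n))
        rows = []
        for t, noise in ((40.0, 1.0), (96.0, 0.0)):
            rows.append(pd.DataFrame({
                "cell_id": np.arange(n), "time_h": t,
                "pparg": np.where(labels, 2.0, 1.0) * np.exp(rng.normal(0, 0.02, n))
                if t == 40.0 else final_p,
                "cebpb": np.exp(rng.normal(0, 0.3, n)),
                "cebpa": np.exp(rng.normal(0, 0.3, n)),
                "failed": False}))
        return pd.concat(rows, ignore_index=True), labels

    def test_perfect_predictor_scores_one(self):
        rng = np.random.default_rng(5)
        table, _ = self._table(rng)
        res = preswitch_predictor_ranking(table, 40.0, 96.0)
        assert res["auc"]["pparg"] > 0.99
        assert res["ranking"][0] == "pparg"

    def test_shuffled_labels_score_half(self):
        rng = np.random.default_rng(6)
        table, _ = self._table(rng)
        final = table.time_h == 96.0
        vals = table.loc[final, "pparg"].to_numpy()
        table.loc[final, "pparg"] = rng.permutation(vals)
        res = preswitch_predictor_ranking(table, 40.0, 96.0,
                                          threshold=3.0)
        # predictors carry no information about permuted labels
        for f in ("cebpb", "cebpa"):
            assert res["auc"][f] == pytest.approx(0.5, abs=0.06)

    def test_preswitch_pparg_most_predictive_in_calibrated_model(self, dim_ensemble_96h):
        res = preswitch_predictor_ranking(dim_ensemble_96h, 48.0, 96.0)
        assert res["ranking"][0] == "pparg"
        assert res["auc"]["pparg"] > max(res["auc"]["cebpb"], res["auc"]["cebpa"])


class TestGradedFatRelation:
    def test_fat_tracks_pakt_more_than_pparg(self, ref):
        from adiposwitch import NoiseSpec, run_population, standard_dim_protocol
        noise = NoiseSpec(pakt_cv=0.3)  # insulin-pathway variability enabled
        # 120 h leaves commitment complete, so fat differences reflect the
        # graded insulin pathway rather than commitment-timing transients
        df = run_population(400, standard_dim_protocol(48.0, 120.0), ref, noise,
                            sample_times=[120.0], seed=21)
        res = graded_pakt_fat_relation(df, 120.0)
        assert res["corr_fat_pakt"] > res["corr_fat_pparg"]
        assert res["graded"]

    def test_non_bimodal_rejected(self, ref):
        import pandas as pd
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"cell_id": np.arange(300), "time_h": 96.0,
                           "pparg": np.exp(rng.normal(0, 0.2, 300)),
                           "pakt": 1.0, "fat": 1.0, "failed": False})
        with pytest.raises(InputDomainError):
            graded_pakt_fat_relation(df, 96.0)
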