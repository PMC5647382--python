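"""SVM models, EM imputation, threshold calibration, QC cascade."""

import numpy as np
import pandas as pd
import pytest

import msmimic as mm
from msmimic.classifier import _logit2

from conftest import holdout_beta


def _signature_matrix(pipeline, ids=None):
    cohort = pipeline["cohort"]
    beta = cohort.beta if ids is None else cohort.beta.subset_samples(ids)
    return beta.fill_median().subset_loci(pipeline["sig_model"].loci).to_numpy()


class TestTrainModels:
    def test_resubstitution_accuracy_is_perfect(self, pipeline):
        cohort, labels = pipeline["cohort"], pipeline["labels"]
        y = labels.loc[pipeline["train_ids"]].to_numpy()
        for model in (pipeline["full_model"], pipeline["sig_model"]):
            X = (
                cohort.beta.subset_samples(pipeline["train_ids"])
                .fill_median()
                .subset_loci(model.loci)
                .to_numpy()
            )
            calls = np.asarray(model.classes)[model.predict_proba(X).argmax(axis=1)]
            assert (calls == y).mean() == 1.0

    def test_probabilities_sum_to_one(self, pipeline):
        X = _signature_matrix(pipeline)
        P = pipeline["sig_model"].predict_proba(X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_full_and_signature_models_concordant_on_holdout(self, pipeline):
        beta = holdout_beta(pipeline).fill_median()
        full, sig = pipeline["full_model"], pipeline["sig_model"]
        calls_full = np.asarray(full.classes)[
            full.predict_proba(beta.subset_loci(full.loci).to_numpy()).argmax(axis=1)
        ]
        calls_sig = np.asarray(sig.classes)[
            sig.predict_proba(beta.subset_loci(sig.loci).to_numpy()).argmax(axis=1)
        ]
        assert (calls_full == calls_sig).mean() >= 0.95

    def test_missing_class_rejected(self, pipeline):
        cohort = pipeline["cohort"]
        with pytest.raises(ValueError):
            mm.train_models(
                cohort.beta,
                pd.Series("WNT", index=cohort.beta.sample_ids),
                pipeline["signature"],
            )

    def test_absent_signature_locus_rejected(self, pipeline):
        bogus = mm.SignatureDefinition.from_ids(["not_a_locus"] * 1 + [f"cg{i:07d}" for i in range(16)])
        with pytest.raises(ValueError, match="absent"):
            mm.train_models(
                pipeline["cohort"].beta, pipeline["labels"], bogus
            )

    def test_json_round_trip_preserves_predictions(self, pipeline, tmp_path):
        model = pipeline["sig_model"]
        X = _signature_matrix(pipeline)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = mm.ClassifierModel.from_json(path)
        np.testing.assert_allclose(model.predict_proba(X), back.predict_proba(X))
        assert back.max_missing_loci == mm.DEFAULT_MAX_MISSING
        assert back.probability_threshold == mm.DEFAULT_PROBABILITY_THRESHOLD


class TestImputation:
    def test_no_missing_is_identity(self, pipeline):
        x = _signature_matrix(pipeline)[0]
        np.testing.assert_array_equal(mm.impute_missing_em(x, pipeline["sig_model"]), x)

    def test_matches_gaussian_conditional_mean(self, pipeline, rng):
        """EM fixed point equals the Schur-complement conditional mean."""
        model = pipeline["sig_model"]
        mu, S = model.feature_means, model.covariance
        L = np.linalg.cholesky(S)
        for _ in range(5):
            z = mu + L @ rng.standard_normal(len(mu))
            beta_vec = 1.0 / (1.0 + np.exp2(-z))
            masked = beta_vec.copy()
            idx = rng.choice(len(mu), size=3, replace=False)
            masked[idx] = np.nan
            imputed = mm.impute_missing_em(masked, model)
            oi = np.flatnonzero(~np.isnan(masked))
            zo = _logit2(beta_vec[oi])
            cond = mu[idx] + S[np.ix_(idx, oi)] @ np.linalg.solve(
                S[np.ix_(oi, oi)], zo - mu[oi]
            )
            z_imp = np.log2(imputed[idx] / (1.0 - imputed[idx]))
            np.testing.assert_allclose(z_imp, cond, atol=1e-6)

    def test_observed_entries_untouched_and_imputed_in_range(self, pipeline, rng):
        x = _signature_matrix(pipeline)[3].copy()
        idx = rng.choice(len(x), size=5, replace=False)
        x[idx] = np.nan
        out = mm.impute_missing_em(x, pipeline["sig_model"])
        obs = ~np.isnan(x)
        np.testing.assert_array_equal(out[obs], x[obs])
        assert ((out[idx] >= 0.0) & (out[idx] <= 1.0)).all()

    def test_seven_missing_is_rejected_before_imputation(self, pipeline):
        x = _signature_matrix(pipeline)[0].copy()
        x[:7] = np.nan
        with pytest.raises(mm.LocusQCError):
            mm.impute_missing_em(x, pipeline["sig_model"])

    def test_class_conditional_flag(self, pipeline):
        x = _signature_matrix(pipeline)[0].copy()
        x[:2] = np.nan
        pooled = mm.impute_missing_em(x, pipeline["sig_model"])
        cc = mm.impute_missing_em(x, pipeline["sig_model"], class_label="WNT")
        assert pooled.shape == cc.shape
        with pytest.raises(ValueError):
            mm.impute_missing_em(x, pipeline["sig_model"], class_label="nope")


class TestThresholdCalibration:
    def test_missing_threshold_smoke_contract(self, pipeline):
        beta = holdout_beta(pipeline)
        thr = mm.calibrate_missing_threshold(
            pipeline["sig_model"], beta, n_boot=34, seed=0
        )
        assert isinstance(thr, int) and 0 <= thr <= 16

    def test_non_redundant_signature_collapses_at_one_mask(self, rng):
        """A single informative locus with no redundant partners: masking
        even one locus is unsafe, so the calibrated threshold is 0."""
        n_per = 30
        labels = pd.Series(
            ["a"] * n_per + ["b"] * n_per, index=[f"s{i}" for i in range(2 * n_per)]
        )
        cols = {"cg_info": np.concatenate([
            rng.uniform(0.85, 0.95, n_per), rng.uniform(0.05, 0.15, n_per)
        ])}
        # the remaining loci are label-independent noise, so nothing can
        # reconstruct cg_info once it is masked
        for j in range(7):
            cols[f"cg_noise{j}"] = rng.uniform(0.3, 0.7, size=len(labels))
        beta = mm.BetaMatrix(pd.DataFrame(cols, index=labels.index))
        signature = mm.SignatureDefinition.from_ids(list(cols))
        _, model = mm.train_models(beta, labels, signature, seed=0, n_top=8)
        thr = mm.calibrate_missing_threshold(model, beta, n_boot=800, seed=1)
        assert thr == 0

    def test_agreement_curve_monotone_after_smoothing(self, pipeline):
        # the threshold is computed from a running-minimum curve, so a larger
        # tolerance can never yield a smaller threshold
        beta = holdout_beta(pipeline)
        t_strict = mm.calibrate_missing_threshold(
            pipeline["sig_model"], beta, n_boot=170, tolerance=0.999, seed=3
        )
        t_loose = mm.calibrate_missing_threshold(
            pipeline["sig_model"], beta, n_boot=170, tolerance=0.5, seed=3
        )
        assert t_loose >= t_strict

    def test_probability_threshold_perfect_predictions(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        thr = mm.calibrate_probability_threshold(P, ["a", "b", "a"], classes=["a", "b"])
        assert thr == 0.0

    def test_probability_threshold_errors_below_point_seven(self):
        """Errors only at max-prob < 0.70: grid search lands on 0.70."""
        rows, truth = [], []
        for p in [0.95, 0.9, 0.85, 0.8, 0.75, 0.71, 0.70]:
            rows.append([p, 1 - p]); truth.append("a")
        for p in [0.69, 0.66, 0.62]:
            rows.append([p, 1 - p]); truth.append("b")  # wrong calls
        thr = mm.calibrate_probability_threshold(np.array(rows), truth, classes=["a", "b"])
        assert thr == pytest.approx(0.70)

    def test_probability_threshold_unattainable_rejected(self):
        P = np.array([[0.6, 0.4]])
        with pytest.raises(ValueError):
            mm.calibrate_probability_threshold(P, ["b"], classes=["a", "b"])

    def test_shipped_default_threshold(self, pipeline):
        assert pipeline["sig_model"].probability_threshold == 0.69
        assert pipeline["sig_model"].max_missing_loci == 6


class TestClassifySample:
    def test_clean_sample_passes_with_correct_call(self, pipeline):
        ids = pipeline["holdout_ids"]
        X = _signature_matrix(pipeline, ids)
        labels = pipeline["labels"].loc[ids]
        res = mm.classify_sample(X[0], pipeline["sig_model"], sample_id=ids[0])
        assert res.qc_code == "PASS"
        assert res.call == labels.iloc[0]
        assert res.probability >= 0.69

    def test_ambiguous_sample_is_nonclassifiable(self, pipeline):
        """A 50/50 mixture of two subgroup profiles falls below 0.69."""
        model = pipeline["sig_model"]
        cohort, labels = pipeline["cohort"], pipeline["labels"]
        means = {}
        for g in ("Grp3", "Grp4"):
            rows = labels.index[labels == g]
            means[g] = (
                cohort.beta.subset_samples(list(rows))
                .fill_median()
                .subset_loci(model.loci)
                .to_numpy()
                .mean(axis=0)
            )
        blend = 0.5 * means["Grp3"] + 0.5 * means["Grp4"]
        res = mm.classify_sample(blend, model)
        assert res.call == "NC"
        assert res.qc_code == "BELOW_THRESHOLD"
        assert max(res.probabilities.values()) < 0.69

    def test_too_many_missing_fails_locus_qc(self, pipeline):
        x = _signature_matrix(pipeline)[0].copy()
        x[:7] = np.nan
        res = mm.classify_sample(x, pipeline["sig_model"])
        assert (res.call, res.qc_code) == ("FAIL", "LOCUS_QC_FAIL")
        assert res.probabilities is None

    def test_six_missing_still_classified(self, pipeline):
        x = _signature_matrix(pipeline)[0].copy()
        x[:6] = np.nan
        res = mm.classify_sample(x, pipeline["sig_model"])
        assert res.call != "FAIL"
        assert res.n_missing_loci == 6

    def test_conversion_failure_dominates_everything(self, pipeline):
        model = pipeline["sig_model"]
        sig = mm.SignatureDefinition.from_ids(model.loci)
        x = _signature_matrix(pipeline)[0]
        record = mm.simulate_assay_records(
            x, sig, noise_sd=0.0, conversion_fail=True, seed=0, sample_id="cf"
        )
        res = mm.classify_sample(record, model)
        assert (res.call, res.qc_code) == ("FAIL", "BISULFITE_FAIL")

    def test_classification_is_deterministic(self, pipeline, rng):
        x = _signature_matrix(pipeline)[5].copy()
        x[rng.choice(len(x), 4, replace=False)] = np.nan
        a = mm.classify_sample(x, pipeline["sig_model"])
        b = mm.classify_sample(x, pipeline["sig_model"])
        assert a == b

    def test_replicate_assay_calls_concordant(self, pipeline):
        """Two noisy assay replicates of a sample give the same call."""
        model = pipeline["sig_model"]
        sig = mm.SignatureDefinition.from_ids(model.loci)
        ids = pipeline["holdout_ids"]
        X = _signature_matrix(pipeline, ids)
        agree = 0
        n_pairs = 200
        for i in range(n_pairs):
            row = X[i % len(ids)]
            r1 = mm.simulate_assay_records(row, sig, noise_sd=0.02, seed=2 * i)
            r2 = mm.simulate_assay_records(row, sig, noise_sd=0.02, seed=2 * i + 1)
            agree += (
                mm.classify_sample(r1, model).call == mm.classify_sample(r2, model).call
            )
        assert agree / n_pairs >= 0.95

    def test_classify_cohort_table_shape(self, pipeline):
        beta = holdout_beta(pipeline)
        calls = mm.classify_cohort(beta, pipeline["sig_model"])
        assert list(calls.columns) == ["sample_id", "call", "probability", "n_missing", "qc_code"]
        assert len(calls) == beta.n_samples
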