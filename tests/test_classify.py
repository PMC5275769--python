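import itertools

import numpy as np
import pandas as pd
import pytest

import oscc_mirna as om
from oscc_mirna.classify import model_from_json, model_to_json
from oscc_mirna.errors import PipelineError


def _labels(columns):
    return pd.Series(
        ["tumor" if c.startswith("T") else "normal" for c in columns], index=columns
    )


def _frame(X, prefix_split):
    n_feat, n_samp = np.asarray(X).shape
    cols = [f"T{i}" if i < prefix_split else f"N{i}" for i in range(n_samp)]
    return pd.DataFrame(np.asarray(X, dtype=float),
                        index=[f"m{i}" for i in range(n_feat)], columns=cols)


class TestSelectFeatures:
    def test_alpha_one_selects_everything(self, tiny_norm):
        features, weights = om.select_features(tiny_norm, alpha=1.0)
        assert set(features) == set(tiny_norm.mirna_ids)
        assert len(weights) == len(features)

    def test_strong_features_recovered(self, tiny_norm):
        features, _ = om.select_features(tiny_norm, alpha=0.001)
        assert {"m00", "m01", "m02", "m03", "m04"} <= set(features)

    def test_fallback_to_single_best_feature(self, tiny_norm):
        features, weights = om.select_features(tiny_norm, alpha=1e-30)
        assert len(features) == 1
        assert len(weights) == 1


class TestTrainPredict:
    def test_ccp_single_feature_predicts_nearer_class_mean(self):
        # one feature: tumor values ≈ 10, normal ≈ 2
        values = _frame([[10.0, 10.5, 9.5, 2.0, 2.5, 1.5]], prefix_split=3)
        model = om.train(values, _labels(values.columns), "CCP", alpha=0.5)
        test = pd.DataFrame({"near_t": [9.0], "near_n": [3.0]}, index=model.features)
        out = om.predict(model, test)
        assert out.loc["near_t", "predicted"] == "tumor"
        assert out.loc["near_n", "predicted"] == "normal"

    def test_ccp_score_matches_direct_weighted_sum(self, tiny_norm):
        """Compound covariate equals an independent direct Σ t_i x_is."""
        sub = om.NormalizedMatrix(
            values=tiny_norm.values.iloc[:5, :8], platform="ct",
            labels={s: tiny_norm.labels[s] for s in tiny_norm.values.columns[:8]},
        )
        model = om.train(sub, algorithm="CCP", alpha=1.0)
        out = om.predict(model, sub)
        X = sub.values.loc[model.features]
        c = model.weights @ X.to_numpy()
        mu_t = c[[s.startswith("T") for s in X.columns]].mean()
        mu_n = c[[s.startswith("N") for s in X.columns]].mean()
        sign = 1.0 if mu_t >= mu_n else -1.0
        expected = sign * (c - 0.5 * (mu_t + mu_n))
        assert np.allclose(out["score"].to_numpy(), expected)
        assert list(out["predicted"]) == [
            "tumor" if e > 0 else "normal" for e in expected
        ]

    def test_dlda_equals_nc_when_variances_equal(self):
        """With per-feature variances all equal, DLDA ranks by the same
        distances as the nearest-centroid rule."""
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, size=(6, 10))
        X[:, :5] += 1.0
        values = _frame(X, prefix_split=5)
        labels = _labels(values.columns)
        m_dlda = om.train(values, labels, "DLDA", alpha=1.0)
        m_dlda.class_stats["var"] = np.ones_like(m_dlda.class_stats["var"])
        m_nc = om.train(values, labels, "NC", alpha=1.0)
        p1 = om.predict(m_dlda, values)["predicted"]
        p2 = om.predict(m_nc, values)["predicted"]
        assert (p1 == p2).all()

    def test_bccp_posterior_half_at_symmetric_point(self):
        values = _frame([[4.0, 6.0, 2.0, 0.0]], prefix_split=2)
        model = om.train(values, _labels(values.columns), "BCCP", alpha=1.0)
        mu_t, mu_n = model.class_stats["mu"]
        w = float(model.weights[0])
        midpoint_x = (mu_t + mu_n) / (2 * w)
        test = pd.DataFrame({"mid": [midpoint_x]}, index=model.features)
        out = om.predict(model, test)
        # posterior 0.5 → score 0 → tie broken toward normal
        assert out.loc["mid", "score"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["mid", "predicted"] == "normal"

    def test_knn3_majority_vote(self):
        values = _frame([[0.0, 0.1, 0.2, 1.0, 1.1, 1.2]], prefix_split=3)
        model = om.train(values, _labels(values.columns), "3NN", alpha=1.0)
        test = pd.DataFrame({"a": [0.15], "b": [1.05]}, index=model.features)
        out = om.predict(model, test)
        assert out.loc["a", "predicted"] == "tumor"
        assert out.loc["b", "predicted"] == "normal"

    def test_svm_separates_train_data(self, tiny_norm):
        model = om.train(tiny_norm, algorithm="SVM", alpha=0.01)
        out = om.predict(model, tiny_norm)
        assert (out["predicted"] == _labels(tiny_norm.values.columns)).mean() == 1.0

    def test_unknown_algorithm_rejected(self, tiny_norm):
        with pytest.raises(PipelineError, match="PAM"):
            om.train(tiny_norm, algorithm="PAM")

    def test_model_json_round_trip(self, tiny_norm):
        for algo in om.ALGORITHMS:
            model = om.train(tiny_norm, algorithm=algo, alpha=0.05)
            back = model_from_json(model_to_json(model))
            out1 = om.predict(model, tiny_norm)
            out2 = om.predict(back, tiny_norm)
            assert np.allclose(out1["score"], out2["score"]), algo


class TestLoocv:
    def test_perfect_separation_all_algorithms(self, counts_cohort):
        result = counts_cohort[2]
        for algo in ("CCP", "BCCP", "DLDA"):
            cv = om.loocv(result.normalized, algorithm=algo)
            assert cv.accuracy == 1.0, algo

    def test_minimum_cohort_runs(self, tiny_norm):
        sub = om.NormalizedMatrix(
            values=tiny_norm.values.iloc[:, [0, 1, 6, 7]], platform="ct",
            labels=tiny_norm.labels,
        )
        cv = om.loocv(sub, algorithm="CCP", alpha_grid=(0.05, 0.5))
        assert len(cv.predictions) == 4

    def test_single_class_rejected(self, tiny_norm):
        labels = pd.Series("tumor", index=tiny_norm.sample_ids)
        with pytest.raises(PipelineError):
            om.loocv(tiny_norm, labels=labels)

    def test_no_leakage_from_held_out_sample(self, tiny_norm):
        """Corrupting the held-out sample's values never changes the
        features or alpha chosen in its own fold."""
        cv = om.loocv(tiny_norm, algorithm="CCP", alpha_grid=(0.01, 0.05))
        victim = tiny_norm.sample_ids[3]
        corrupted = tiny_norm.values.copy()
        corrupted[victim] += 500.0
        cv2 = om.loocv(
            om.NormalizedMatrix(values=corrupted, platform="ct",
                                labels=tiny_norm.labels),
            algorithm="CCP", alpha_grid=(0.01, 0.05),
        )
        fold1 = next(d for d in cv.fold_details if d["sample"] == victim)
        fold2 = next(d for d in cv2.fold_details if d["sample"] == victim)
        assert fold1["features"] == fold2["features"]
        assert fold1["alpha"] == fold2["alpha"]

    def test_accuracy_degrades_as_fold_shrinks(self):
        """Mean LOOCV accuracy is non-increasing in planted effect size."""
        from oscc_mirna.pipeline import preprocess

        means = []
        for fold in (4.0, 1.5, 1.0):
            accs = []
            for seed in (61, 62, 63):
                cfg = om.SimulationConfig(
                    n_tumor=8, n_normal=8, n_mirna=200, n_de=10,
                    fold_changes=(fold,), zero_inflation=0.1, seed=seed,
                )
                matrix, _ = om.simulate_counts(cfg)
                res = preprocess(matrix)
                accs.append(om.loocv(res.normalized, algorithm="CCP",
                                     alpha_grid=(0.001, 0.01)).accuracy)
            means.append(np.mean(accs))
        assert means[0] >= means[1] - 0.1
        assert means[0] >= means[2] - 0.1
        assert means[0] >= 0.9


class TestRoc:
    def test_perfect_ranking_auc_one(self):
        roc, auc = om.roc_curve([0.9, 0.8, 0.2, 0.1], ["tumor", "tumor", "normal", "normal"])
        assert auc == 1.0
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)

    def test_constant_scores_auc_half(self):
        _, auc = om.roc_curve([0.5] * 6, ["tumor"] * 3 + ["normal"] * 3)
        assert auc == 0.5

    def test_auc_equals_concordant_pair_count(self):
        """Trapezoid AUC equals the Mann–Whitney concordance fraction."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            scores = np.round(rng.normal(size=12), 1)  # rounding forces ties
            labels = np.array(["tumor"] * 6 + ["normal"] * 6)
            _, auc = om.roc_curve(scores, labels)
            t_scores, n_scores = scores[:6], scores[6:]
            conc = sum(
                1.0 if t > n else (0.5 if t == n else 0.0)
                for t, n in itertools.product(t_scores, n_scores)
            )
            assert auc == pytest.approx(conc / 36.0)

    def test_monotone_roc_coordinates(self, counts_cohort):
        cv = om.loocv(counts_cohort[2].normalized, algorithm="BCCP")
        assert (np.diff(cv.roc[:, 0]) >= 0).all()
        assert (np.diff(cv.roc[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(PipelineError):
            om.roc_curve([0.1, 0.2], ["tumor", "tumor"])


class TestExternalValidation:
    def test_independent_cohort_classified_perfectly(self):
        """At overwhelming planted effect size an independent cohort from the
        same population is classified with full accuracy."""
        from oscc_mirna.pipeline import preprocess

        cfg = om.SimulationConfig(
            n_tumor=10, n_normal=10, n_mirna=400, n_de=15,
            fold_changes=(8.0,), zero_inflation=0.1, seed=13,
        )
        train_matrix, _ = om.simulate_counts(cfg)
        model = om.train(preprocess(train_matrix).normalized,
                         algorithm="CCP", alpha=0.001)
        val_matrix, _ = om.simulate_counts(cfg, cohort_seed=78)
        cv = om.external_validate(model, preprocess(val_matrix).normalized)
        assert cv.accuracy == 1.0

    def test_resubstitution_at_least_as_good_as_loocv(self, counts_cohort):
        result = counts_cohort[2]
        model = om.train(result.normalized, algorithm="DLDA", alpha=0.001)
        resub = om.external_validate(model, result.normalized)
        cv = om.loocv(result.normalized, algorithm="DLDA", alpha_grid=(0.001,))
        assert resub.accuracy >= cv.accuracy

    def test_flipped_labels_mirror_accuracy(self, counts_cohort):
        result = counts_cohort[2]
        model = om.train(result.normalized, algorithm="CCP", alpha=0.001)
        straight = om.external_validate(model, result.normalized)
        flipped_labels = pd.Series(
            ["normal" if result.normalized.labels[s] == "tumor" else "tumor"
             for s in result.normalized.sample_ids],
            index=result.normalized.sample_ids,
        )
        flipped = om.external_validate(model, result.normalized, labels=flipped_labels)
        assert flipped.accuracy == pytest.approx(1.0 - straight.accuracy)

    def test_missing_feature_named(self, counts_cohort):
        result = counts_cohort[2]
        model = om.train(result.normalized, algorithm="CCP", alpha=0.001)
        reduced = result.normalized.values.drop(index=model.features[0])
        with pytest.raises(PipelineError, match=model.features[0]):
            om.predict(model, reduced)
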