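"""QDA fitting, discriminant classification and the misclassification report."""

import numpy as np
import pytest
from scipy import stats

from plaquemap.errors import InputError
from plaquemap.qda import (
    Prediction,
    QDAModel,
    classify,
    discriminant_scores,
    fit_qda,
    misclassification_report,
)
from plaquemap.roi import PREDICTORS, ROIFeatureVector


def feature_from_array(x, roi_id="r", plaque="p1", label="lipid"):
    vals = dict(zip(PREDICTORS, x))
    return ROIFeatureVector(
        roi_id=roi_id, plaque_id=plaque, tissue_label=label,
        mean_t1=vals["mean_t1"], mean_t2s=vals["mean_t2s"],
        sd_t1=vals["sd_t1"], sd_t2s=vals["sd_t2s"],
        max_t1=vals["max_t1"], min_t1=vals["min_t1"],
        n_pixels=int(vals["n_pixels"]),
    )


def random_features(rng, n, label, plaque="p1", t1_center=1000.0, t2s_center=12.0,
                    spread=1.0):
    out = []
    for i in range(n):
        m1 = t1_center + rng.normal(0, 50 * spread)
        m2 = abs(t2s_center + rng.normal(0, 2 * spread))
        # independent upper/lower excursions keep (mean, max, min) full rank
        up = abs(rng.normal(40, 10))
        down = abs(rng.normal(40, 10))
        out.append(
            ROIFeatureVector(
                roi_id=f"{plaque}:{label}:{i}", plaque_id=plaque, tissue_label=label,
                mean_t1=m1, mean_t2s=m2,
                sd_t1=abs(rng.normal(20, 5)), sd_t2s=abs(rng.normal(1.5, 0.5)),
                max_t1=m1 + up, min_t1=m1 - down,
                n_pixels=int(rng.integers(4, 10)),
            )
        )
    return out


class TestFitQDA:
    def test_means_and_covariances_match_bruteforce(self, rng):
        feats = random_features(rng, 30, "lipid") + random_features(
            rng, 25, "fibrous", t1_center=800.0
        )
        (model,), na = fit_qda(feats, scope="pooled", shrinkage=0.0)
        assert na == []
        for label in ("lipid", "fibrous"):
            x = np.stack([f.as_array() for f in feats if f.tissue_label == label])
            np.testing.assert_allclose(model.means[label], x.mean(axis=0), rtol=1e-12)
            np.testing.assert_allclose(
                model.covariances[label], np.cov(x, rowvar=False, ddof=1),
                rtol=1e-8, atol=1e-10,
            )
            assert model.priors[label] == pytest.approx(x.shape[0] / len(feats))

    def test_translation_equivariance(self, rng):
        feats_a = random_features(rng, 20, "lipid")
        shift = 123.0
        feats_b = [
            ROIFeatureVector(
                roi_id=f.roi_id + "s", plaque_id=f.plaque_id, tissue_label="fibrous",
                mean_t1=f.mean_t1 + shift, mean_t2s=f.mean_t2s,
                sd_t1=f.sd_t1, sd_t2s=f.sd_t2s,
                max_t1=f.max_t1 + shift, min_t1=f.min_t1 + shift,
                n_pixels=f.n_pixels,
            )
            for f in feats_a
        ]
        (model,), _ = fit_qda(feats_a + feats_b, scope="pooled", shrinkage=0.0)
        diff = model.means["fibrous"] - model.means["lipid"]
        expected = np.zeros(7)
        for i, p in enumerate(PREDICTORS):
            if p in ("mean_t1", "max_t1", "min_t1"):
                expected[i] = shift
        np.testing.assert_allclose(diff, expected, atol=1e-9)
        np.testing.assert_allclose(
            model.covariances["fibrous"], model.covariances["lipid"], atol=1e-8
        )

    def test_single_class_plaque_not_applicable(self, rng):
        feats = random_features(rng, 10, "fibrous", plaque="pf")
        feats += random_features(rng, 10, "fibrous", plaque="pm")
        feats += random_features(rng, 10, "lipid", plaque="pm", t1_center=600)
        models, na = fit_qda(feats, scope="per_plaque", shrinkage=0.1)
        assert [m.training_scope for m in models] == ["pm"]
        assert len(na) == 1 and na[0][0] == "pf"
        assert "not applicable" in na[0][1]

    def test_uniform_priors(self, rng):
        feats = random_features(rng, 30, "lipid") + random_features(rng, 10, "fibrous")
        (model,), _ = fit_qda(feats, scope="pooled", priors="uniform")
        assert model.priors["lipid"] == model.priors["fibrous"] == 0.5

    def test_shrinkage_one_never_singular(self, rng):
        # n_pixels constant within a class: raw covariance is singular and so
        # is its diagonal; the model must still come out positive definite
        feats = []
        for i in range(6):
            f = random_features(rng, 1, "lipid")[0]
            feats.append(feature_from_array(
                np.concatenate([f.as_array()[:6], [5]]), roi_id=f"l{i}", label="lipid"))
        for i in range(6):
            f = random_features(rng, 1, "fibrous", t1_center=700)[0]
            feats.append(feature_from_array(
                np.concatenate([f.as_array()[:6], [5]]), roi_id=f"f{i}", label="fibrous"))
        (model,), _ = fit_qda(feats, scope="pooled", shrinkage=1.0)
        for c in model.classes:
            assert np.linalg.eigvalsh(model.covariances[c]).min() > 0

    def test_empty_input_raises(self):
        with pytest.raises(InputError):
            fit_qda([])


#: the discriminant drops the class-independent -(p/2) ln(2 pi) term
LOG_NORM_CONST = 3.5 * np.log(2 * np.pi)


def simple_model(mu_shift=2.0, priors=(0.5, 0.5)):
    """Two 7-dim classes separated along mean_t1 only, identity covariances."""
    mu_a = np.array([0.0, 0, 0, 0, 10, -10, 5])
    mu_b = mu_a.copy()
    mu_b[0] = mu_shift
    return QDAModel(
        classes=("A", "B"),
        means={"A": mu_a, "B": mu_b},
        covariances={"A": np.eye(7), "B": np.eye(7)},
        priors={"A": priors[0], "B": priors[1]},
        shrinkage=0.0,
    )


class TestClassify:
    def test_1d_boundary_case(self):
        # class means 0 and 2 along one predictor, equal unit variances and
        # priors: the boundary sits at 1, so 0.9 goes to the first class.
        # Oracle: brute-force Gaussian log-density evaluation.
        model = simple_model()
        x = np.array([[0.9, 0, 0, 0, 10, -10, 5]])
        scores = discriminant_scores(model, x)
        for c in ("A", "B"):
            oracle = (
                stats.multivariate_normal.logpdf(
                    x[0], mean=model.means[c], cov=model.covariances[c]
                )
                + np.log(model.priors[c])
                + LOG_NORM_CONST
            )
            assert scores[c][0] == pytest.approx(oracle, rel=1e-9)
        assert scores["A"][0] > scores["B"][0]

    def test_point_at_class_mean_classified_there(self):
        model = simple_model()
        x = model.means["B"][None, :]
        scores = discriminant_scores(model, x)
        assert scores["B"][0] > scores["A"][0]

    def test_oracle_equivalence_many_rois(self, rng):
        # exhaustive independent evaluation: per-class multivariate-normal
        # log density + log prior, for every ROI
        feats = (
            random_features(rng, 60, "lipid", t1_center=1000)
            + random_features(rng, 50, "fibrous", t1_center=830)
            + random_features(rng, 45, "inflammation", t1_center=1300)
            + random_features(rng, 40, "hemorrhage", t1_center=1400)
        )
        (model,), _ = fit_qda(feats, scope="pooled", shrinkage=0.1)
        preds = classify(model, feats)
        x = np.stack([f.as_array() for f in feats])
        for i, p in enumerate(preds):
            oracle_scores = {
                c: stats.multivariate_normal.logpdf(
                    x[i], mean=model.means[c], cov=model.covariances[c]
                )
                + np.log(model.priors[c])
                + LOG_NORM_CONST
                for c in model.classes
            }
            best = max(model.classes, key=lambda c: oracle_scores[c])
            assert p.predicted_label == best
            for c in model.classes:
                assert p.discriminant_scores[c] == pytest.approx(
                    oracle_scores[c], rel=1e-8, abs=1e-8
                )

    def test_well_separated_classes_zero_misclassification(self, rng):
        feats = random_features(rng, 30, "lipid", t1_center=1000.0, spread=0.2)
        feats += random_features(rng, 30, "fibrous", t1_center=10000.0, spread=0.2)
        (model,), _ = fit_qda(feats, scope="pooled", shrinkage=0.1)
        preds = classify(model, feats)
        assert sum(p.misclassified for p in preds) == 0

    def test_affine_rescaling_invariance(self, rng):
        # full-covariance QDA with lambda = 0 is equivariant under an affine
        # map applied identically to every feature
        feats = random_features(rng, 40, "lipid") + random_features(
            rng, 40, "fibrous", t1_center=700
        )
        (model,), _ = fit_qda(feats, scope="pooled", shrinkage=0.0)
        base = [p.predicted_label for p in classify(model, feats)]

        scale, offset = 3.5, 11.0
        scaled = []
        for f in feats:
            x = f.as_array() * scale + offset
            scaled.append(
                feature_from_array(
                    np.concatenate([x[:6], [f.n_pixels]]), roi_id=f.roi_id,
                    plaque=f.plaque_id, label=f.tissue_label,
                )
            )
        # n_pixels kept integral; rescale only the six continuous predictors
        (model2,), _ = fit_qda(scaled, scope="pooled", shrinkage=0.0)
        rescaled = [p.predicted_label for p in classify(model2, scaled)]
        assert rescaled == base

    def test_dimension_mismatch_raises(self):
        model = simple_model()
        with pytest.raises(InputError):
            discriminant_scores(model, np.ones((1, 3)))

    def test_tie_broken_by_class_order(self):
        model = simple_model()
        x = np.array([[1.0, 0, 0, 0, 10, -10, 5]])  # exactly on the boundary
        scores = discriminant_scores(model, x)
        assert scores["A"][0] == pytest.approx(scores["B"][0], abs=1e-12)
        f = feature_from_array(x[0], roi_id="tie")
        (p,) = classify(model, [f])
        assert p.predicted_label == "A"


def make_pred(roi_id, plaque, true, pred):
    return Prediction(roi_id, plaque, true, pred, {})


class TestMisclassificationReport:
    def test_simple_rate(self):
        preds = [make_pred(f"r{i}", "p1", "lipid", "lipid") for i in range(7)]
        preds.append(make_pred("r7", "p1", "lipid", "fibrous"))
        rep = misclassification_report(preds)
        assert rep.per_plaque["p1"] == (8, 1, pytest.approx(12.5))

    def test_all_correct_degenerate_ci(self):
        preds = [make_pred(f"r{i}", f"p{i % 3}", "lipid", "lipid") for i in range(9)]
        rep = misclassification_report(preds)
        assert rep.mean_rate == 0.0
        assert rep.ci_low == rep.ci_high == 0.0

    def test_t_interval_oracle(self):
        # plaque rates {10, 15, 20}%: closed-form t(2) interval
        preds = []
        for pid, (n, k) in {"a": (10, 1), "b": (20, 3), "c": (10, 2)}.items():
            for i in range(n):
                preds.append(
                    make_pred(f"{pid}{i}", pid, "lipid", "lipid" if i >= k else "fibrous")
                )
        rep = misclassification_report(preds, ci_level=0.95)
        rates = np.array([10.0, 15.0, 20.0])
        assert rep.mean_rate == pytest.approx(15.0)
        se = rates.std(ddof=1) / np.sqrt(3)
        tq = stats.t.ppf(0.975, 2)
        assert rep.ci_low == pytest.approx(15.0 - tq * se)
        assert rep.ci_high == pytest.approx(15.0 + tq * se)
        assert rep.ci_low <= rep.mean_rate <= rep.ci_high

    def test_zero_eligible_plaques_empty_report(self):
        rep = misclassification_report([], excluded_plaques=[("p1", "one class")])
        assert rep.per_plaque == {}
        assert np.isnan(rep.mean_rate)
        assert rep.excluded_plaques == [("p1", "one class")]

    def test_mean_is_unweighted_across_plaques(self):
        preds = [make_pred(f"a{i}", "big", "l", "l") for i in range(99)]
        preds.append(make_pred("a99", "big", "l", "f"))  # 1%
        preds += [make_pred("b0", "small", "l", "f"), make_pred("b1", "small", "l", "f"),
                  make_pred("b2", "small", "l", "l"), make_pred("b3", "small", "l", "l")]  # 50%
        rep = misclassification_report(preds)
        assert rep.mean_rate == pytest.approx((1.0 + 50.0) / 2)


class TestModelSerialization:
    def test_json_roundtrip(self, rng, tmp_path):
        feats = random_features(rng, 15, "lipid") + random_features(
            rng, 15, "fibrous", t1_center=700
        )
        (model,), _ = fit_qda(feats, scope="pooled", shrinkage=0.2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = QDAModel.from_json(path)
        assert back.classes == model.classes
        assert back.priors == pytest.approx(model.priors)
        for c in model.classes:
            np.testing.assert_allclose(back.means[c], model.means[c])
            np.testing.assert_allclose(back.covariances[c], model.covariances[c])
        assert [p.predicted_label for p in classify(back, feats)] == [
            p.predicted_label for p in classify(model, feats)
        ]
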