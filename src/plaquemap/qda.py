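"""Quadratic discriminant analysis on ROI feature vectors.

Each tissue class is modeled as a multivariate Gaussian over the seven ROI
predictors; classification maximizes the log-discriminant

    delta_k(x) = -1/2 ln|S_k| - 1/2 (x - m_k)' S_k^{-1} (x - m_k) + ln p_k.

Class covariances are shrunk toward their diagonal, (1-l)*S + l*diag(S),
to keep them invertible at small per-class ROI counts; if the shrunk matrix
is still not positive definite a minimal diagonal ridge is escalated until
it is. Evaluation is resubstitution: the fitted models score the same
labeled ROIs, and a labeled ROI assigned to another class counts as
misclassified. Rates are reported per plaque with a Student-t confidence
interval across eligible plaques.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from plaquemap.errors import ConfigurationError, InputError
from plaquemap.roi import PREDICTORS, ROIFeatureVector

logger = logging.getLogger(__name__)

POOLED = "pooled"


@dataclass
class QDAModel:
    """Fitted per-class Gaussians: mean vectors, shrunk covariances, priors."""

    classes: tuple[str, ...]
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    priors: dict[str, float]
    shrinkage: float
    training_scope: str = POOLED

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ConfigurationError("QDA needs >= 2 classes")
        if not np.isclose(sum(self.priors.values()), 1.0):
            raise ConfigurationError("priors must sum to 1")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ConfigurationError("shrinkage must lie in [0, 1]")
        for cls in self.classes:
            cov = self.covariances[cls]
            if not np.allclose(cov, cov.T):
                raise ConfigurationError(f"covariance of {cls!r} is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ConfigurationError(f"covariance of {cls!r} is not positive definite")

    @property
    def n_features(self) -> int:
        return self.means[self.classes[0]].shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "means": {c: self.means[c].tolist() for c in self.classes},
            "covariances": {c: self.covariances[c].tolist() for c in self.classes},
            "priors": {c: self.priors[c] for c in self.classes},
            "shrinkage": self.shrinkage,
            "training_scope": self.training_scope,
            "predictors": list(PREDICTORS),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "QDAModel":
        p = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(p["classes"]),
            means={c: np.asarray(m, dtype=float) for c, m in p["means"].items()},
            covariances={
                c: np.asarray(m, dtype=float) for c, m in p["covariances"].items()
            },
            priors={c: float(v) for c, v in p["priors"].items()},
            shrinkage=float(p["shrinkage"]),
            training_scope=p["training_scope"],
        )


@dataclass(frozen=True)
class Prediction:
    roi_id: str
    plaque_id: str
    true_label: str
    predicted_label: str
    discriminant_scores: dict[str, float]

    @property
    def misclassified(self) -> bool:
        return self.predicted_label != self.true_label


@dataclass
class MisclassificationReport:
    """Per-plaque misclassification rates (%) with a cross-plaque t-interval."""

    per_plaque: dict[str, tuple[int, int, float]]  # plaque -> (n, n_mis, rate %)
    mean_rate: float
    ci_low: float
    ci_high: float
    ci_level: float
    ci_method: str
    excluded_plaques: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_plaque": {
                p: {"n_roi": n, "n_misclassified": m, "rate_percent": r}
                for p, (n, m, r) in self.per_plaque.items()
            },
            "mean_rate_percent": self.mean_rate,
            "ci_low_percent": self.ci_low,
            "ci_high_percent": self.ci_high,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "excluded_plaques": [list(e) for e in self.excluded_plaques],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _shrink(cov: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * cov + lam * np.diag(np.diag(cov))


def _ensure_pd(cov: np.ndarray) -> np.ndarray:
    """Escalate a tiny diagonal ridge until Cholesky succeeds."""
    scale = max(float(np.trace(cov)) / cov.shape[0], 1.0)
    ridge = 0.0
    for _ in range(40):
        try:
            np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
            break
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-12 * scale)
    if ridge > 0:
        cov = cov + ridge * np.eye(cov.shape[0])
    return cov


def fit_qda(
    features: Sequence[ROIFeatureVector],
    scope: Literal["per_plaque", "pooled"] = "per_plaque",
    shrinkage: float = 0.1,
    priors: Literal["empirical", "uniform"] = "empirical",
) -> tuple[list[QDAModel], list[tuple[str, str]]]:
    """Fit one QDA model per plaque (or one pooled model).

    Within each scope, classes with fewer than 2 ROIs are dropped; scopes
    retaining fewer than 2 classes are skipped and returned in the
    not-applicable list as (scope_id, reason) — mirroring specimens made of
    predominantly one tissue where QDA cannot be applied.
    """
    if not features:
        raise InputError("fit_qda requires a non-empty feature list")
    if scope not in ("per_plaque", POOLED):
        raise ConfigurationError(f"unknown scope {scope!r}")
    if not 0.0 <= shrinkage <= 1.0:
        raise ConfigurationError("shrinkage must lie in [0, 1]")

    if scope == POOLED:
        groups = {POOLED: list(features)}
    else:
        groups: dict[str, list[ROIFeatureVector]] = {}
        for f in features:
            groups.setdefault(f.plaque_id, []).append(f)

    models: list[QDAModel] = []
    not_applicable: list[tuple[str, str]] = []
    for gid, feats in groups.items():
        by_class: dict[str, list[ROIFeatureVector]] = {}
        for f in feats:
            by_class.setdefault(f.tissue_label, []).append(f)
        usable = {c: fs for c, fs in by_class.items() if len(fs) >= 2}
        if len(usable) < 2:
            reason = (
                f"QDA not applicable: {len(usable)} class(es) with >= 2 ROIs "
                f"(labels present: {sorted(by_class)})"
            )
            logger.info("scope %s: %s", gid, reason)
            not_applicable.append((gid, reason))
            continue
        classes = tuple(usable)
        n_total = sum(len(fs) for fs in usable.values())
        means, covs, pri = {}, {}, {}
        for c, fs in usable.items():
            x = np.stack([f.as_array() for f in fs])
            means[c] = x.mean(axis=0)
            covs[c] = _ensure_pd(_shrink(np.cov(x, rowvar=False, ddof=1), shrinkage))
            pri[c] = len(fs) / n_total if priors == "empirical" else 1.0 / len(usable)
        models.append(
            QDAModel(
                classes=classes,
                means=means,
                covariances=covs,
                priors=pri,
                shrinkage=shrinkage,
                training_scope=gid,
            )
        )
    return models, not_applicable


def discriminant_scores(model: QDAModel, x: np.ndarray) -> dict[str, np.ndarray]:
    """Log-discriminant delta_k for each class, vectorized over rows of x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise InputError(
            f"feature dimension {x.shape[1]} != model dimension {model.n_features}"
        )
    out = {}
    for c in model.classes:
        cov = model.covariances[c]
        chol = np.linalg.cholesky(cov)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        d = x - model.means[c]
        z = np.linalg.solve(chol, d.T)
        maha = (z**2).sum(axis=0)
        out[c] = -0.5 * logdet - 0.5 * maha + np.log(model.priors[c])
    return out


def classify(
    model: QDAModel, features: Sequence[ROIFeatureVector]
) -> list[Prediction]:
    """Assign each ROI to the class maximizing its log-discriminant.

    Ties break toward the earlier class in ``model.classes``.
    """
    if not features:
        return []
    x = np.stack([f.as_array() for f in features])
    scores = discriminant_scores(model, x)
    score_mat = np.stack([scores[c] for c in model.classes])  # (k, n)
    winner = np.argmax(score_mat, axis=0)  # first max -> declared class order
    preds = []
    for i, f in enumerate(features):
        preds.append(
            Prediction(
                roi_id=f.roi_id,
                plaque_id=f.plaque_id,
                true_label=f.tissue_label,
                predicted_label=model.classes[int(winner[i])],
                discriminant_scores={c: float(scores[c][i]) for c in model.classes},
            )
        )
    return preds


def misclassification_report(
    predictions: Sequence[Prediction],
    ci_level: float = 0.95,
    excluded_plaques: Sequence[tuple[str, str]] = (),
) -> MisclassificationReport:
    """Per-plaque misclassification rates plus a cross-plaque mean and CI.

    The CI is a Student-t interval on the per-plaque rates, clipped to
    [0, 100]; with a single eligible plaque or zero variance it degenerates
    to [mean, mean]. With zero eligible plaques an empty report is returned
    with a warning.
    """
    by_plaque: dict[str, list[Prediction]] = {}
    for p in predictions:
        by_plaque.setdefault(p.plaque_id, []).append(p)
    per_plaque = {}
    for pid, preds in by_plaque.items():
        n = len(preds)
        n_mis = sum(p.misclassified for p in preds)
        per_plaque[pid] = (n, n_mis, 100.0 * n_mis / n)
    rates = np.array([r for _, _, r in per_plaque.values()])
    if rates.size == 0:
        logger.warning("misclassification report: zero eligible plaques")
        return MisclassificationReport(
            per_plaque={},
            mean_rate=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            ci_level=ci_level,
            ci_method="student-t on per-plaque rates",
            excluded_plaques=list(excluded_plaques),
        )
    mean = float(rates.mean())
    if rates.size > 1 and rates.std(ddof=1) > 0:
        se = float(rates.std(ddof=1)) / np.sqrt(rates.size)
        tq = float(stats.t.ppf(0.5 + ci_level / 2.0, rates.size - 1))
        lo, hi = max(0.0, mean - tq * se), min(100.0, mean + tq * se)
    else:
        lo = hi = mean
    return MisclassificationReport(
        per_plaque=per_plaque,
        mean_rate=mean,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        ci_method="student-t on per-plaque rates",
        excluded_plaques=list(excluded_plaques),
    )
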