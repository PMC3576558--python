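"""Mahalanobis-distance discriminant classification of swallow features.

Each class c in {safe, unsafe} is summarized by its sample mean mu_c and a
regularized covariance

    Sigma_c(gamma) = (1 - gamma) * Sigma_c + gamma * (tr Sigma_c / d) * I,

and a test vector x is assigned to the class with the smaller squared
Mahalanobis distance d_c(x) = (x - mu_c)^T Sigma_c^{-1} (x - mu_c).
Per-class covariances (a quadratic boundary) are the default; a pooled
covariance (linear boundary) is available by configuration.  Exact distance
ties go to "unsafe": a screening tool should err toward flagging risk.

Evaluation is leave-one-out: each case is classified by a model trained on
all remaining cases.  Iteration order is deterministic and immaterial to
the results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger("swallowscreen")

SAFE = "safe"
UNSAFE = "unsafe"
LABELS = (SAFE, UNSAFE)


@dataclass(frozen=True)
class ClassifierConfig:
    """covariance: 'per_class' (quadratic boundary) or 'pooled' (linear).
    shrinkage: weight gamma in [0, 1] toward the scaled identity; shrinkage
    is mandatory (gamma > 0) whenever a class has fewer than 2x dimension
    members, since raw covariances are then near-singular."""

    covariance: str = "per_class"
    shrinkage: float = 0.1

    def __post_init__(self) -> None:
        if self.covariance not in ("per_class", "pooled"):
            raise ValueError(f"unknown covariance mode {self.covariance!r}")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")


def regularize(cov: np.ndarray, gamma: float) -> np.ndarray:
    """Shrink a covariance toward (tr(cov)/d) * I by weight gamma."""
    d = cov.shape[0]
    scale = np.trace(cov) / d
    if scale <= 0:
        scale = 1.0
    return (1.0 - gamma) * cov + gamma * scale * np.eye(d)


def mahalanobis_sq(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Squared Mahalanobis distance (x-mu)^T cov^{-1} (x-mu); zero iff x == mu."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.shape != mu.shape or cov.shape != (len(x), len(x)):
        raise ValueError("dimension mismatch between x, mu and covariance")
    diff = x - mu
    try:
        cho = linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"covariance not positive definite: {exc}") from exc
    return float(diff @ linalg.cho_solve(cho, diff))


@dataclass
class DiscriminantModel:
    """Fitted per-class means and regularized covariance estimates."""

    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    shrinkage: float
    feature_names: list[str] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return len(self.means[SAFE])

    def distances(self, x: np.ndarray) -> dict[str, float]:
        return {c: mahalanobis_sq(x, self.means[c], self.covariances[c]) for c in LABELS}

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "shrinkage": self.shrinkage,
            "feature_names": self.feature_names,
            "means": {c: self.means[c].tolist() for c in LABELS},
            "covariances": {c: self.covariances[c].tolist() for c in LABELS},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            means={c: np.asarray(doc["means"][c]) for c in LABELS},
            covariances={c: np.asarray(doc["covariances"][c]) for c in LABELS},
            shrinkage=float(doc["shrinkage"]),
            feature_names=list(doc["feature_names"]),
        )


@dataclass(frozen=True)
class DeviceResult:
    """The classifier's call for one subswallow, with both class distances."""

    key: tuple
    label: str
    d_safe: float
    d_unsafe: float
    untestable: bool = False


def fit_discriminant(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    feature_names: list[str] | None = None,
) -> DiscriminantModel:
    """Fit class means and (regularized) covariances from labeled vectors."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    d = X.shape[1]
    means: dict[str, np.ndarray] = {}
    raw_covs: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for c in LABELS:
        members = X[y == c]
        if len(members) < 2:
            raise ValueError(f"class {c!r} has {len(members)} member(s); need >= 2")
        means[c] = members.mean(axis=0)
        raw_covs[c] = np.cov(members, rowvar=False, ddof=1)
        counts[c] = len(members)

    gamma = config.shrinkage
    if min(counts.values()) < 2 * d and gamma == 0.0:
        raise ValueError(
            f"shrinkage required: smallest class has {min(counts.values())} "
            f"members for dimension {d} (< 2x dimension)"
        )

    if config.covariance == "pooled":
        n_s, n_u = counts[SAFE], counts[UNSAFE]
        pooled = ((n_s - 1) * raw_covs[SAFE] + (n_u - 1) * raw_covs[UNSAFE]) / (
            n_s + n_u - 2
        )
        raw_covs = {c: pooled for c in LABELS}

    covs = {c: regularize(raw_covs[c], gamma) for c in LABELS}
    for c in LABELS:  # model invariant: SPD after regularization
        linalg.cho_factor(covs[c])
    return DiscriminantModel(
        means=means,
        covariances=covs,
        shrinkage=gamma,
        feature_names=list(feature_names or []),
    )


def classify(model: DiscriminantModel, x: np.ndarray, key: tuple = ()) -> DeviceResult:
    """Assign the class of minimal Mahalanobis distance; ties -> unsafe."""
    dist = model.distances(x)
    label = SAFE if dist[SAFE] < dist[UNSAFE] else UNSAFE
    return DeviceResult(key=key, label=label, d_safe=dist[SAFE], d_unsafe=dist[UNSAFE])


def loo_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    keys: list[tuple] | None = None,
    feature_names: list[str] | None = None,
) -> list[DeviceResult]:
    """Leave-one-out evaluation: one DeviceResult per case.

    Each case is classified by a model fit on every other case.  A fold
    whose training set would lose a class entirely is flagged untestable
    (logged) rather than dropped.  Results are independent of case order.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(X)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 cases")
    for c in LABELS:
        if not (y == c).any():
            raise ValueError(f"class {c!r} absent from evaluation set")
    if keys is None:
        keys = [(i,) for i in range(n)]

    results: list[DeviceResult] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            model = fit_discriminant(X[mask], y[mask], config, feature_names)
        except ValueError as exc:
            logger.warning("LOO fold %s untestable: %s", keys[i], exc)
            results.append(
                DeviceResult(
                    key=keys[i], label=UNSAFE, d_safe=np.nan, d_unsafe=np.nan,
                    untestable=True,
                )
            )
            mask[i] = True
            continue
        results.append(classify(model, X[i], keys[i]))
        mask[i] = True
    return results


def results_to_frame(results: list[DeviceResult]) -> pd.DataFrame:
    """Tabulate device results (key columns, label, both distances)."""
    rows = []
    for r in results:
        row = dict(
            zip(["participant_id", "task_id", "bolus_id", "subswallow_index"], r.key)
        )
        row.update(
            device_label=r.label,
            d_safe=r.d_safe,
            d_unsafe=r.d_unsafe,
            untestable=r.untestable,
        )
        rows.append(row)
    return pd.DataFrame(rows)
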