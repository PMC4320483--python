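"""Non-parametric discriminant analysis.

The default classifier is a class-conditional Gaussian-product kernel
density estimate combined with class priors through Bayes' rule: for a
query x in d dimensions (d in {1, 2, 3} selected speed metrics),

    score_c(x)  proportional to  prior_c * (1/m_c) * sum_j  prod_k
        N(x_k | t_jk, h_ck)

over class c's m_c training rows t_j, with per-dimension bandwidths
h_ck from Silverman's rule h = 1.06 * sigma_hat * m^(-1/5) (sigma_hat
the class sample SD in that dimension), floored at a small fraction of
the dimension's global SD so degenerate classes keep a positive
bandwidth.  Everything is evaluated in log space.

A k-nearest-neighbour discriminant (majority vote on standardised
features) ships as a configurable alternative for sensitivity analysis.
Ties are always broken by the fixed class order
walk < bike < train < bus < car < motorized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence as TySequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigError, DataError

#: Fixed class order used for deterministic tie-breaking.
MODE_ORDER = ("walk", "bike", "train", "bus", "car", "motorized", "unknown")

_LOG_2PI = math.log(2.0 * math.pi)


def class_sort_key(label: str) -> tuple[int, str]:
    try:
        return (MODE_ORDER.index(label), label)
    except ValueError:
        return (len(MODE_ORDER), label)


@dataclass(frozen=True)
class ClassifierConfig:
    """Knobs of the discriminant.

    variant:
        "kde" (default) or "knn".
    priors:
        "equal" (default) or "proportional" to class frequencies.
    bandwidth_floor_rel:
        Minimum bandwidth as a fraction of the dimension's global SD.
    bandwidth_floor_abs:
        Absolute fallback floor when the global SD is itself zero.
    knn_k:
        Neighbour count for the knn variant.
    """

    variant: str = "kde"
    priors: str = "equal"
    bandwidth_floor_rel: float = 1e-6
    bandwidth_floor_abs: float = 1e-6
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.variant not in ("kde", "knn"):
            raise ConfigError(f"unknown classifier variant {self.variant!r}")
        if self.priors not in ("equal", "proportional"):
            raise ConfigError(f"unknown prior setting {self.priors!r}")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")


def _extract(features, combination: tuple[str, ...]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in combination if c not in features.columns]
        if missing:
            raise ConfigError(f"metrics not in feature table: {missing}")
        return features[list(combination)].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(combination):
        raise DataError(
            f"feature matrix has {X.shape[1]} columns, combination has "
            f"{len(combination)}"
        )
    return X


@dataclass
class DiscriminantModel:
    """Fitted kernel discriminant: per-class training rows, bandwidths, priors."""

    classes: tuple[str, ...]
    combination: tuple[str, ...]
    priors: np.ndarray  # (k,)
    bandwidths: np.ndarray  # (k, d), all > 0
    train: tuple[np.ndarray, ...]  # per class, (m_c, d)
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def _as_matrix(self, x) -> tuple[np.ndarray, bool]:
        X = np.asarray(x, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != len(self.combination):
            raise DataError(
                f"query has {X.shape[1]} dimensions, model expects "
                f"{len(self.combination)}"
            )
        return X, single

    def log_likelihood(self, x) -> np.ndarray:
        """Per-class log density estimates, shape (q, k)."""
        X, _ = self._as_matrix(x)
        q, d = X.shape
        out = np.empty((q, len(self.classes)))
        for ci, T in enumerate(self.train):
            h = self.bandwidths[ci]
            z = (X[:, None, :] - T[None, :, :]) / h  # (q, m, d)
            expo = -0.5 * np.einsum("qmd,qmd->qm", z, z)
            out[:, ci] = (
                logsumexp(expo, axis=1)
                - math.log(T.shape[0])
                - np.sum(np.log(h))
                - 0.5 * d * _LOG_2PI
            )
        return out

    def posterior(self, x) -> np.ndarray:
        """Normalised per-class scores (rows sum to 1), shape (q, k)."""
        X, single = self._as_matrix(x)
        logp = self.log_likelihood(X) + np.log(self.priors)[None, :]
        top = np.max(logp, axis=1, keepdims=True)
        degenerate = ~np.isfinite(top[:, 0])
        with np.errstate(invalid="ignore"):
            w = np.exp(logp - top)
        w[degenerate] = 1.0  # all densities underflowed: fall back to priors
        scores = w / np.sum(w, axis=1, keepdims=True)
        return scores[0] if single else scores

    def predict(self, x) -> np.ndarray | str:
        """Mode label(s) with the highest posterior score.

        Exact ties go to the class earliest in the fixed order (classes
        are stored in that order, and argmax takes the first maximum).
        """
        X, single = self._as_matrix(x)
        scores = np.atleast_2d(self.posterior(X))
        idx = np.argmax(scores, axis=1)
        labels = np.array([self.classes[i] for i in idx], dtype=object)
        return labels[0] if single else labels


@dataclass
class KNNModel:
    """k-nearest-neighbour discriminant on standardised features."""

    classes: tuple[str, ...]
    combination: tuple[str, ...]
    train: np.ndarray  # (m, d) standardised
    labels: np.ndarray  # (m,) class indices
    center: np.ndarray
    scale: np.ndarray
    config: ClassifierConfig = field(default_factory=lambda: ClassifierConfig(variant="knn"))

    def _as_matrix(self, x):
        X = np.asarray(x, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != len(self.combination):
            raise DataError("query dimensionality mismatch")
        return X, single

    def posterior(self, x) -> np.ndarray:
        X, single = self._as_matrix(x)
        Z = (X - self.center) / self.scale
        k = min(self.config.knn_k, self.train.shape[0])
        d2 = ((Z[:, None, :] - self.train[None, :, :]) ** 2).sum(axis=2)
        # stable ordering: distance, then training row index
        nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
        votes = np.zeros((X.shape[0], len(self.classes)))
        for ci in range(len(self.classes)):
            votes[:, ci] = np.sum(self.labels[nn] == ci, axis=1)
        scores = votes / k
        return scores[0] if single else scores

    def predict(self, x):
        X, single = self._as_matrix(x)
        scores = np.atleast_2d(self.posterior(X))
        idx = np.argmax(scores, axis=1)
        labels = np.array([self.classes[i] for i in idx], dtype=object)
        return labels[0] if single else labels


def fit(
    features,
    labels: TySequence[str],
    combination: TySequence[str],
    config: ClassifierConfig | None = None,
):
    """Fit the discriminant on a feature table (or matrix) and labels.

    ``combination`` names 1-3 of the seven speed metrics; with a bare
    matrix it only fixes the dimensionality and column meaning.
    """
    config = config or ClassifierConfig()
    combination = tuple(combination)
    if not 1 <= len(combination) <= 3:
        raise ConfigError(
            f"combination must contain 1-3 metrics, got {len(combination)}"
        )
    if len(set(combination)) != len(combination):
        raise ConfigError("combination contains duplicate metrics")
    X = _extract(features, combination)
    y = np.asarray(labels, dtype=object)
    if y.shape[0] != X.shape[0]:
        raise DataError("features and labels length mismatch")
    classes = tuple(sorted(set(map(str, y)), key=class_sort_key))
    if len(classes) < 2:
        raise DataError("need at least two distinct class labels")
    counts = np.array([np.sum(y == c) for c in classes], dtype=float)
    if np.any(counts == 0):
        raise DataError("degenerate class with zero training rows")

    if config.variant == "knn":
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        scale = np.where(scale > 0, scale, 1.0)
        label_idx = np.array([classes.index(str(v)) for v in y])
        return KNNModel(
            classes=classes,
            combination=combination,
            train=(X - center) / scale,
            labels=label_idx,
            center=center,
            scale=scale,
            config=config,
        )

    d = X.shape[1]
    global_sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(d)
    floor = np.where(
        global_sd > 0,
        config.bandwidth_floor_rel * global_sd,
        config.bandwidth_floor_abs,
    )
    train: list[np.ndarray] = []
    bandwidths = np.empty((len(classes), d))
    for ci, c in enumerate(classes):
        Xc = X[y == c]
        m = Xc.shape[0]
        sigma = Xc.std(axis=0, ddof=1) if m > 1 else np.zeros(d)
        h = 1.06 * sigma * m ** (-0.2)
        bandwidths[ci] = np.maximum(h, floor)
        train.append(Xc.copy())
    if config.priors == "equal":
        priors = np.full(len(classes), 1.0 / len(classes))
    else:
        priors = counts / counts.sum()
    return DiscriminantModel(
        classes=classes,
        combination=combination,
        priors=priors,
        bandwidths=bandwidths,
        train=tuple(train),
        config=config,
    )


def posterior(model, x) -> np.ndarray:
    """Functional wrapper around ``model.posterior``."""
    return model.posterior(x)


def predict(model, x):
    """Functional wrapper around ``model.predict``."""
    return model.predict(x)


# ---------------------------------------------------------------------------
# JSON round trip

def to_json(model) -> str:
    """Serialise a fitted model to JSON (floats round-trip exactly)."""
    if isinstance(model, DiscriminantModel):
        doc = {
            "variant": "kde",
            "classes": list(model.classes),
            "combination": list(model.combination),
            "priors": model.priors.tolist(),
            "bandwidths": model.bandwidths.tolist(),
            "train": [T.tolist() for T in model.train],
            "config": asdict(model.config),
        }
    elif isinstance(model, KNNModel):
        doc = {
            "variant": "knn",
            "classes": list(model.classes),
            "combination": list(model.combination),
            "train": model.train.tolist(),
            "labels": model.labels.tolist(),
            "center": model.center.tolist(),
            "scale": model.scale.tolist(),
            "config": asdict(model.config),
        }
    else:
        raise ConfigError(f"cannot serialise {type(model).__name__}")
    return json.dumps(doc)


def from_json(text: str):
    """Rebuild a model serialised with :func:`to_json`."""
    doc = json.loads(text)
    config = ClassifierConfig(**doc["config"])
    if doc["variant"] == "kde":
        return DiscriminantModel(
            classes=tuple(doc["classes"]),
            combination=tuple(doc["combination"]),
            priors=np.array(doc["priors"], dtype=float),
            bandwidths=np.array(doc["bandwidths"], dtype=float),
            train=tuple(np.array(T, dtype=float) for T in doc["train"]),
            config=config,
        )
    if doc["variant"] == "knn":
        return KNNModel(
            classes=tuple(doc["classes"]),
            combination=tuple(doc["combination"]),
            train=np.array(doc["train"], dtype=float),
            labels=np.array(doc["labels"], dtype=int),
            center=np.array(doc["center"], dtype=float),
            scale=np.array(doc["scale"], dtype=float),
            config=config,
        )
    raise DataError(f"unknown model variant {doc.get('variant')!r}")
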