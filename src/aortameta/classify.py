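"""Binary logistic classification of aorta type.

Three feature families feed the same machinery: landmark diameters
(morphometric classifier), CFD-style hemodynamic features (direct
classifier), and surrogate-predicted hemodynamics (metamodel classifier).
The linear score ``z = a0 + sum_i a_i x_i`` is mapped to a coarctation
probability through the logistic function ``P(z) = 1 / (1 + exp(-z))``;
a record is called CoA when the probability is strictly above the
threshold (default 0.5).

Fitting is maximum likelihood by iteratively reweighted least squares
(IRLS), written out explicitly: each step solves the weighted normal
equations with weights ``P (1 - P)`` on the working response.  Perfect or
quasi-perfect separation — common when D0 splits the classes cleanly — is
detected and flagged; the fit at the iteration cap is still returned, since
its decision boundary is what the protocol needs.

Feature z-scoring (per-feature mean/sd stored in the classifier) is on by
default: it makes coefficient magnitudes comparable across mm- and
kPa-scaled features; a raw mode is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LogisticClassifier", "SplitPlan", "SeparationWarning",
    "MORPHO_FEATURES", "HEMO_FEATURES_LITERAL", "HEMO_FEATURES_PREDICTABLE",
    "PUBLISHED_TABLE1", "PUBLISHED_TABLE2", "PUBLISHED_TABLE3",
    "published_classifier", "split_80_20", "fit_logistic", "accuracy",
]

#: Diameters entering the morphometric classifier.
MORPHO_FEATURES: tuple[str, ...] = ("D1", "DBCA", "D3", "D0", "D5")

#: Literal hemodynamic feature set of the direct classifier.
HEMO_FEATURES_LITERAL: tuple[str, ...] = (
    "v_OBCA", "v_M3", "v_O5", "p_P1", "p_M1")

#: The feature set the surrogate chain can actually predict; used for the
#: like-for-like direct-vs-metamodel comparison in the pipeline.
HEMO_FEATURES_PREDICTABLE: tuple[str, ...] = (
    "v_OBCA", "v_M4", "v_O5", "p_P1", "p_M2")

# Reported coefficient tables.  Caveats: the morphometric table prints no
# intercept (exposed as configuration, default 0); in the metamodel table
# the three identical velocity coefficients look like a typesetting
# artifact and are shipped verbatim.
PUBLISHED_TABLE1: dict[str, float] = {
    "D1": -0.399, "DBCA": 0.999, "D3": 0.11, "D0": -1.726, "D5": 1.134}
PUBLISHED_TABLE2: dict[str, float] = {
    "v_OBCA": 1.377, "v_M3": -1.472, "v_O5": -1.914,
    "p_P1": 0.482, "p_M1": 0.414}
PUBLISHED_TABLE3: dict[str, float] = {
    "v_OBCA": -1.05, "v_M3": -1.05, "v_O5": -1.05,
    "p_P1": 1.138, "p_M1": 0.799}


class SeparationWarning(UserWarning):
    """Training data are (quasi-)perfectly separated; MLE diverges."""


@dataclass
class LogisticClassifier:
    """Logistic model: feature names, coefficients, optional z-scoring."""

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    threshold: float = 0.5
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None
    separation: bool = False
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float | None = None

    def _design(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise KeyError(f"missing features: {missing}")
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        if self.scale_mean is not None:
            X = (X - self.scale_mean) / self.scale_sd
        return X

    def decision_function(self, X) -> np.ndarray:
        return self.intercept + self._design(X) @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        """Coarctation probability, clamped into the open interval (0, 1)."""
        p = _sigmoid(self.decision_function(X))
        return np.clip(p, 5e-324, float(np.nextafter(1.0, 0.0)))

    def predict(self, X) -> np.ndarray:
        """Class labels; CoA iff probability strictly above the threshold."""
        return np.where(self.predict_proba(X) > self.threshold, "coa", "normal")

    def standardized_coef(self) -> dict[str, float]:
        """Coefficients on the z-scored feature scale (comparable magnitudes)."""
        if self.scale_mean is not None:
            return dict(zip(self.feature_names, map(float, self.coef)))
        raise ValueError("classifier was fitted on raw features")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coef": list(map(float, self.coef)),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "scale_mean": None if self.scale_mean is None
            else list(map(float, self.scale_mean)),
            "scale_sd": None if self.scale_sd is None
            else list(map(float, self.scale_sd)),
            "separation": self.separation,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticClassifier":
        return cls(
            feature_names=tuple(d["feature_names"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            threshold=float(d.get("threshold", 0.5)),
            scale_mean=None if d.get("scale_mean") is None
            else np.asarray(d["scale_mean"], dtype=float),
            scale_sd=None if d.get("scale_sd") is None
            else np.asarray(d["scale_sd"], dtype=float),
            separation=bool(d.get("separation", False)),
            converged=bool(d.get("converged", True)),
            n_iter=int(d.get("n_iter", 0)),
            log_likelihood=d.get("log_likelihood"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LogisticClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


def published_classifier(table: Mapping[str, float], intercept: float = 0.0,
                         threshold: float = 0.5) -> LogisticClassifier:
    """Wrap a printed coefficient table as an executable classifier.

    The reported tables carry no intercept and no standardization
    parameters, so the mapping from features to the linear score is exposed
    here as configuration rather than guessed.
    """
    names = tuple(table)
    return LogisticClassifier(feature_names=names,
                              coef=np.array([table[k] for k in names]),
                              intercept=intercept, threshold=threshold)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class SplitPlan:
    """A stratified 80:20 train/test partition of cohort record positions."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test overlap")


def split_80_20(labels: Sequence[str] | pd.Series, seed: int,
                test_fraction: float = 0.2) -> SplitPlan:
    """Stratified random split: round(test_fraction * n) records per class
    held out, reproducible from the seed.

    With the study-scale cohort (60 records) this holds out 12.
    """
    labels = pd.Series(list(labels))
    n = len(labels)
    if n < 5:
        raise ValueError("need at least 5 records to split 80:20")
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError(f"both classes must be present, got {list(classes)}")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in sorted(classes):
        idx = np.flatnonzero((labels == cls).to_numpy())
        k = int(round(test_fraction * len(idx)))
        k = min(k, len(idx) - 1)      # never empty a class's training side
        test_idx.extend(rng.permutation(idx)[:k].tolist())
    test = tuple(sorted(test_idx))
    train = tuple(i for i in range(n) if i not in set(test))
    return SplitPlan(train=train, test=test, seed=seed)


def fit_logistic(X: pd.DataFrame | np.ndarray, y: Sequence[str] | np.ndarray,
                 feature_names: Sequence[str] | None = None,
                 standardize: bool = True, threshold: float = 0.5,
                 tol: float = 1e-8, max_iter: int = 100,
                 ) -> LogisticClassifier:
    """Maximum-likelihood logistic fit by IRLS.

    ``y`` may be string labels ("coa" positive) or a 0/1 vector.  Iteration
    stops when the log-likelihood changes by less than ``tol`` or at
    ``max_iter``; separation is detected from diverging scores and reported
    via :class:`SeparationWarning` and the ``separation`` flag.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns) if feature_names is None \
            else tuple(feature_names)
        X = X[list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"x{j}" for j in range(X.shape[1]))
        feature_names = tuple(feature_names)
    y = np.asarray(y)
    if y.dtype.kind in "UOS":
        y01 = (y == "coa").astype(float)
    else:
        y01 = y.astype(float)
    if not (0 < y01.sum() < len(y01)):
        raise ValueError("both classes must be present in the training data")

    sd = X.std(axis=0, ddof=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(
            f"constant feature(s): {[feature_names[j] for j in const]}")
    mean = X.mean(axis=0)
    if standardize:
        Xs = (X - mean) / sd
    else:
        Xs = X

    n, p = Xs.shape
    A = np.column_stack([np.ones(n), Xs])
    beta = np.zeros(p + 1)
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = A @ beta
        mu = _sigmoid(z)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        # working response of the IRLS step
        u = z + (y01 - mu) / w
        Aw = A * w[:, None]
        try:
            beta = np.linalg.solve(A.T @ Aw, A.T @ (w * u))
        except np.linalg.LinAlgError:
            break
        ll = float(y01 @ np.log(np.clip(mu, 1e-300, None))
                   + (1 - y01) @ np.log(np.clip(1 - mu, 1e-300, None)))
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    z = A @ beta
    mu = _sigmoid(z)
    preds = mu > 0.5
    separated = bool(np.all(preds == y01.astype(bool))
                     and np.max(np.abs(z)) > 15.0)
    if separated:
        warnings.warn(
            "training data are (quasi-)separated; coefficients reported at "
            "the iteration cap", SeparationWarning, stacklevel=2)
    ll = float(y01 @ np.log(np.clip(mu, 1e-300, None))
               + (1 - y01) @ np.log(np.clip(1 - mu, 1e-300, None)))
    return LogisticClassifier(
        feature_names=feature_names, coef=beta[1:], intercept=float(beta[0]),
        threshold=threshold,
        scale_mean=mean if standardize else None,
        scale_sd=sd if standardize else None,
        separation=separated, converged=converged, n_iter=n_iter,
        log_likelihood=ll)


def accuracy(pred: Sequence[str], truth: Sequence[str]) -> dict:
    """Fraction correct plus confusion counts (CoA is the positive class)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    if len(pred) == 0:
        raise ValueError("empty prediction vector")
    correct = int((pred == truth).sum())
    conf = {
        "tp": int(((pred == "coa") & (truth == "coa")).sum()),
        "tn": int(((pred == "normal") & (truth == "normal")).sum()),
        "fp": int(((pred == "coa") & (truth == "normal")).sum()),
        "fn": int(((pred == "normal") & (truth == "coa")).sum()),
    }
    return {"accuracy": correct / len(pred), "n": len(pred),
            "correct": correct, "confusion": conf}
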