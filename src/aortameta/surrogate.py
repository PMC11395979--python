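"""Chained ratio-feature surrogate regressions for landmark hemodynamics.

The surrogate replaces a full CFD solve with five linear regressions on
morphometric features.  Pressure at the aortic inlet p(P1) and at the
pre-stenotic station p(M2) are modelled linearly in four diameters;
velocities v(OBCA), v(M4), v(O5) are modelled on squared-diameter ratio
features ``Di / Dj^2`` (a linearisation of volume-flow continuity, where
``j`` is the vessel in which the velocity is measured) with the *predicted*
inlet pressure injected as an extra regressor (chaining).

Two modes are supported everywhere:

* ``published`` — the printed coefficient sets ship as defaults, so the
  reported models are executable even though the patient data they were
  fitted on cannot be shared;
* ``fitted`` — the same functional forms re-estimated by ordinary least
  squares on a (synthetic) cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .config import DIAMETER_NAMES

__all__ = [
    "RatioTerm", "SurrogateSpec", "SurrogateModel", "PUBLISHED_MODELS",
    "SURROGATE_RESPONSES", "build_features", "fit_linear", "fit_surrogate",
    "fit_all_surrogates", "evaluate_published", "predict_pressure_P1",
    "predict_pressure_M2", "predict_velocity", "chain_predict",
    "correlation_report",
]


@dataclass(frozen=True)
class RatioTerm:
    """One regressor: a diameter, or a diameter over a squared diameter.

    ``RatioTerm("D1")`` is the plain linear term D1 (mm);
    ``RatioTerm("D1", "DBCA")`` is D1 / DBCA^2 (1/mm).
    """

    numerator: str
    denominator: str | None = None

    def __post_init__(self) -> None:
        for name in (self.numerator, self.denominator):
            if name is not None and name not in DIAMETER_NAMES:
                raise ValueError(f"unknown diameter {name!r}")

    @property
    def name(self) -> str:
        if self.denominator is None:
            return self.numerator
        return f"{self.numerator}/{self.denominator}^2"

    def evaluate(self, m: Mapping[str, float]) -> float:
        num = float(m[self.numerator])
        if self.denominator is None:
            return num
        den = float(m[self.denominator])
        if den == 0.0:
            raise ZeroDivisionError(
                f"zero denominator diameter {self.denominator} in {self.name}")
        return num / den ** 2


@dataclass(frozen=True)
class SurrogateSpec:
    """Functional form of one surrogate: response, terms, optional chaining."""

    response: str
    terms: tuple[RatioTerm, ...]
    chain_pressure: bool = False

    @property
    def term_names(self) -> tuple[str, ...]:
        names = tuple(t.name for t in self.terms)
        if self.chain_pressure:
            names = names + ("p_hat_P1",)
        return names


#: Functional forms of the five reported regressions.
SURROGATE_SPECS: dict[str, SurrogateSpec] = {
    "p_P1": SurrogateSpec("p_P1", tuple(
        RatioTerm(d) for d in ("D1", "DBCA", "D0", "D5"))),
    "p_M2": SurrogateSpec("p_M2", tuple(
        RatioTerm(d) for d in ("D2", "DBCA", "D0", "D5"))),
    "v_OBCA": SurrogateSpec("v_OBCA", tuple(
        RatioTerm(d, "DBCA") for d in ("D1", "D0", "D4")), chain_pressure=True),
    "v_M4": SurrogateSpec("v_M4", tuple(
        RatioTerm(d, "D4") for d in ("D1", "DBCA", "DLCCA", "D3")),
        chain_pressure=True),
    "v_O5": SurrogateSpec("v_O5", tuple(
        RatioTerm(d, "D5") for d in ("D1", "DBCA", "DLCCA", "D3")),
        chain_pressure=True),
}

SURROGATE_RESPONSES: tuple[str, ...] = ("p_P1", "p_M2", "v_OBCA", "v_M4", "v_O5")


def build_features(m: Mapping[str, float], terms: Iterable[RatioTerm],
                   p_hat_P1: float | None = None,
                   chain_pressure: bool = False) -> np.ndarray:
    """Evaluate the regressor vector for one morphometric profile.

    Ordering is the order of ``terms``, with the chained predicted inlet
    pressure appended last when requested.
    """
    x = [t.evaluate(m) for t in terms]
    if chain_pressure:
        if p_hat_P1 is None:
            raise ValueError("chained model needs p_hat_P1")
        x.append(float(p_hat_P1))
    return np.asarray(x, dtype=float)


@dataclass
class SurrogateModel:
    """A fitted (or published) linear surrogate with its diagnostics."""

    response: str
    spec: SurrogateSpec
    intercept: float
    coef: np.ndarray                       # aligned with spec.term_names
    r_squared: float | None = None
    p_level: float | None = None
    n: int | None = None
    stderr: np.ndarray | None = None       # intercept first, then terms
    source: str = "fitted"                 # "fitted" | "published"

    def predict(self, m: Mapping[str, float],
                p_hat_P1: float | None = None) -> float:
        x = build_features(m, self.spec.terms, p_hat_P1,
                           self.spec.chain_pressure)
        return float(self.intercept + x @ self.coef)

    def predict_table(self, df: pd.DataFrame,
                      p_hat_P1: np.ndarray | None = None) -> np.ndarray:
        rows = df[list(DIAMETER_NAMES)].to_dict("records")
        if self.spec.chain_pressure:
            if p_hat_P1 is None:
                raise ValueError("chained model needs p_hat_P1")
            return np.array([self.predict(m, p) for m, p in zip(rows, p_hat_P1)])
        return np.array([self.predict(m) for m in rows])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(p+1, 2) normal-theory confidence bounds, intercept first."""
        if self.stderr is None or self.n is None:
            raise ValueError("model carries no fit covariance")
        dof = self.n - len(self.coef) - 1
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
        est = np.concatenate([[self.intercept], self.coef])
        return np.stack([est - tcrit * self.stderr,
                         est + tcrit * self.stderr], axis=1)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": [[t.numerator, t.denominator] for t in self.spec.terms],
            "chain_pressure": self.spec.chain_pressure,
            "intercept": self.intercept,
            "coef": list(map(float, self.coef)),
            "r_squared": self.r_squared,
            "p_level": self.p_level,
            "n": self.n,
            "stderr": None if self.stderr is None else list(map(float, self.stderr)),
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurrogateModel":
        spec = SurrogateSpec(
            d["response"],
            tuple(RatioTerm(num, den) for num, den in d["terms"]),
            bool(d["chain_pressure"]))
        return cls(
            response=d["response"], spec=spec, intercept=float(d["intercept"]),
            coef=np.asarray(d["coef"], dtype=float),
            r_squared=d.get("r_squared"), p_level=d.get("p_level"),
            n=d.get("n"),
            stderr=None if d.get("stderr") is None
            else np.asarray(d["stderr"], dtype=float),
            source=d.get("source", "fitted"))


def _published(response: str, intercept: float, coef: Sequence[float],
               r2: float, p_level: float) -> SurrogateModel:
    spec = SURROGATE_SPECS[response]
    return SurrogateModel(response=response, spec=spec, intercept=intercept,
                          coef=np.asarray(coef, dtype=float), r_squared=r2,
                          p_level=p_level, source="published")


#: The printed coefficient sets, executable as-is.
PUBLISHED_MODELS: dict[str, SurrogateModel] = {
    "p_P1": _published("p_P1", 11.14, [0.34, -0.29, -0.55, 0.79],
                       0.224, 0.00839),
    "p_M2": _published("p_M2", 11.2, [0.45, -0.27, -0.53, 0.47],
                       0.255, 0.00319),
    "v_OBCA": _published("v_OBCA", -0.42, [0.07, -0.27, 0.1, 0.17],
                         0.23, 0.00695),
    "v_M4": _published("v_M4", 1.67, [0.39, -0.87, -2.17, 0.58, -0.04],
                       0.421, 0.00002),
    "v_O5": _published("v_O5", 1.7, [0.29, -0.87, -1.25, 0.75, -0.06],
                       0.521, 0.00001),
}


def evaluate_published(response: str, m: Mapping[str, float],
                       p_hat_P1: float | None = None) -> float:
    """Evaluate one published regression on a morphometric profile."""
    return PUBLISHED_MODELS[response].predict(m, p_hat_P1)


def predict_pressure_P1(m: Mapping[str, float],
                        model: SurrogateModel | None = None) -> float:
    """Inlet pressure (kPa) from four diameters; published mode by default."""
    return (model or PUBLISHED_MODELS["p_P1"]).predict(m)


def predict_pressure_M2(m: Mapping[str, float],
                        model: SurrogateModel | None = None) -> float:
    """Pre-stenotic pressure (kPa); differs from p(P1) only by using D2."""
    return (model or PUBLISHED_MODELS["p_M2"]).predict(m)


def predict_velocity(m: Mapping[str, float], which: str, p_hat_P1: float,
                     model: SurrogateModel | None = None) -> float:
    """Landmark velocity (m/s) from ratio features and the chained pressure."""
    key = which if which.startswith("v_") else f"v_{which}"
    if key not in ("v_OBCA", "v_M4", "v_O5"):
        raise ValueError(f"no velocity surrogate for {which!r}")
    return (model or PUBLISHED_MODELS[key]).predict(m, p_hat_P1)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in piv[rank:]]


def fit_linear(X: np.ndarray, y: np.ndarray,
               term_names: Sequence[str] | None = None,
               ) -> tuple[float, np.ndarray, dict]:
    """Ordinary least squares with an intercept, via QR decomposition.

    Returns ``(intercept, coef, diagnostics)`` where diagnostics carries
    R^2, the overall-F model p-level, n and the standard errors
    (intercept first).  Raises on rank deficiency, naming the collinear
    regressors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    names = list(term_names) if term_names is not None else [
        f"x{j}" for j in range(p)]
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        bad = _collinear_columns(A, ["intercept"] + names)
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0.0 else 1.0 - ssr / sst
    dof = n - p - 1
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    stderr = np.sqrt(np.diag(cov))
    if sst == 0.0 or ssr == 0.0:
        p_level = 0.0 if sst > ssr else 1.0
    else:
        f_stat = ((sst - ssr) / p) / sigma2
        p_level = float(stats.f.sf(f_stat, p, dof))
    diagnostics = {"r_squared": r2, "p_level": p_level, "n": n,
                   "stderr": stderr}
    return float(beta[0]), beta[1:], diagnostics


def fit_surrogate(df: pd.DataFrame, response: str,
                  p_hat_P1: np.ndarray | None = None) -> SurrogateModel:
    """Fit one surrogate form on a cohort table.

    For chained velocity models ``p_hat_P1`` must hold the predicted inlet
    pressure for every row (use the p_P1 surrogate fitted on the same data).
    """
    spec = SURROGATE_SPECS[response]
    rows = df[list(DIAMETER_NAMES)].to_dict("records")
    if spec.chain_pressure and p_hat_P1 is None:
        raise ValueError(f"{response} is chained: pass p_hat_P1")
    X = np.vstack([
        build_features(m, spec.terms,
                       None if p_hat_P1 is None else p_hat_P1[i],
                       spec.chain_pressure)
        for i, m in enumerate(rows)])
    y = df[response].to_numpy(dtype=float)
    intercept, coef, diag = fit_linear(X, y, spec.term_names)
    return SurrogateModel(response=response, spec=spec, intercept=intercept,
                          coef=coef, source="fitted", **diag)


def fit_all_surrogates(train: pd.DataFrame) -> dict[str, SurrogateModel]:
    """Fit the five surrogate forms, chaining the velocity models on the
    p(P1) model's in-sample predictions."""
    models: dict[str, SurrogateModel] = {}
    models["p_P1"] = fit_surrogate(train, "p_P1")
    p_hat = models["p_P1"].predict_table(train)
    models["p_M2"] = fit_surrogate(train, "p_M2")
    for resp in ("v_OBCA", "v_M4", "v_O5"):
        models[resp] = fit_surrogate(train, resp, p_hat_P1=p_hat)
    return models


def chain_predict(df: pd.DataFrame,
                  models: Mapping[str, SurrogateModel] | None = None,
                  ) -> pd.DataFrame:
    """Predict the five surrogate responses for every cohort record.

    The inlet-pressure model is evaluated first and its prediction is fed to
    the three velocity models; the M2 pressure model is independent.  With
    ``models=None`` the published coefficients are used.
    """
    models = dict(models) if models is not None else PUBLISHED_MODELS
    out = pd.DataFrame(index=df.index)
    p_hat = models["p_P1"].predict_table(df)
    out["p_P1"] = p_hat
    out["p_M2"] = models["p_M2"].predict_table(df)
    for resp in ("v_OBCA", "v_M4", "v_O5"):
        out[resp] = models[resp].predict_table(df, p_hat_P1=p_hat)
    return out


def chain_predict_record(m: Mapping[str, float],
                         models: Mapping[str, SurrogateModel] | None = None,
                         ) -> dict[str, float]:
    """Single-record version of :func:`chain_predict`."""
    models = dict(models) if models is not None else PUBLISHED_MODELS
    p_hat = models["p_P1"].predict(m)
    out = {"p_P1": p_hat, "p_M2": models["p_M2"].predict(m)}
    for resp in ("v_OBCA", "v_M4", "v_O5"):
        out[resp] = models[resp].predict(m, p_hat_P1=p_hat)
    return out


def correlation_report(observed: pd.DataFrame,
                       predicted: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between observed and surrogate-predicted responses.

    Returns one row per common response column with columns ``r`` and
    ``best`` (True on the most accurately predicted response).
    """
    common = [c for c in predicted.columns if c in observed.columns]
    if len(observed) < 3:
        raise ValueError("need at least 3 paired records")
    rows = []
    for c in common:
        r = stats.pearsonr(observed[c].to_numpy(dtype=float),
                           predicted[c].to_numpy(dtype=float)).statistic
        rows.append({"response": c, "r": float(r)})
    rep = pd.DataFrame(rows).set_index("response")
    rep["best"] = rep["r"] == rep["r"].max()
    return rep


def save_models(models: Mapping[str, SurrogateModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {k: v.to_dict() for k, v in models.items()}, indent=2))


def load_models(path: str | Path) -> dict[str, SurrogateModel]:
    data = json.loads(Path(path).read_text())
    return {k: SurrogateModel.from_dict(v) for k, v in data.items()}
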