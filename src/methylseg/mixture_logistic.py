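"""The k-mer mixture logistic regression model.

A methylation susceptibility predictor of the form

    y = 1 / (1 + exp(-f(x))),   f(x) = beta_0 + sum_i beta_i x_i

where the x_i are occurrence counts of a small set of pre-selected k-mers
and the beta_i are learned by maximizing the (optionally weighted) binomial
log-likelihood with a small L2 ridge on the slopes.  The logistic output is
the calibrated methylation level in (0, 1).

The ridge (default 1e-6) guarantees a finite optimum under complete
separation, which does occur with rare long k-mers; the intercept is never
penalized and can be disabled to recover the pure mixture form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "MixtureLogisticModel",
    "DegenerateLabelsError",
    "fit",
    "predict_probability",
    "decision_scores",
]

_EPS = 1e-12  # predictions are clipped into (0, 1) open


class DegenerateLabelsError(ValueError):
    """All training labels belong to one class."""


@dataclass
class MixtureLogisticModel:
    """Selected k-mers x_i and fitted coefficients beta_i."""

    kmers: list[str]
    betas: np.ndarray
    intercept: float
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.betas) != len(self.kmers):
            raise ValueError("betas and kmers must align")
        if not np.all(np.isfinite(self.betas)) or not np.isfinite(self.intercept):
            raise ValueError("coefficients must be finite")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.kmers):
            raise ValueError(
                f"design matrix has {X.shape[1]} columns, model expects "
                f"{len(self.kmers)}"
            )
        return self.intercept + X @ self.betas

    def to_json(self) -> str:
        return json.dumps(
            {
                "kmers": self.kmers,
                "betas": self.betas.tolist(),
                "intercept": self.intercept,
                "ridge": self.fit_meta.get("ridge"),
                "converged": self.fit_meta.get("converged"),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureLogisticModel":
        d = json.loads(text)
        return cls(
            kmers=list(d["kmers"]),
            betas=np.asarray(d["betas"], dtype=float),
            intercept=float(d["intercept"]),
            fit_meta={"ridge": d.get("ridge"), "converged": d.get("converged")},
        )


def _penalized_nll(theta, X, t, w, ridge, use_intercept):
    """Weighted negative binomial log-likelihood plus 0.5*ridge*||beta||^2.

    The intercept (theta[0] when present) is excluded from the penalty.
    Returns (value, gradient).
    """
    if use_intercept:
        b0, beta = theta[0], theta[1:]
    else:
        b0, beta = 0.0, theta
    f = b0 + X @ beta
    # log(1 + exp(f)) computed stably
    log1pexp = np.where(f > 30, f, np.log1p(np.exp(np.minimum(f, 30))))
    nll = float(np.sum(w * (log1pexp - t * f)) + 0.5 * ridge * beta @ beta)
    resid = w * (expit(f) - t)
    gbeta = X.T @ resid + ridge * beta
    if use_intercept:
        grad = np.concatenate(([resid.sum()], gbeta))
    else:
        grad = gbeta
    return nll, grad


def fit(
    X: np.ndarray,
    t: Sequence,
    kmers: Optional[Sequence[str]] = None,
    sample_weight: Optional[np.ndarray] = None,
    ridge: float = 1e-6,
    use_intercept: bool = True,
    warm_start: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MixtureLogisticModel:
    """Fit the mixture logistic model by penalized maximum likelihood.

    ``t`` may be {+,-} labels or {1,0}; ``sample_weight`` scales each
    instance's likelihood contribution.  Optimization is quasi-Newton
    (L-BFGS-B with analytic gradients) to gradient norm below ``tol``;
    ``warm_start`` supplies an initial (intercept, betas) vector, which the
    segment search exploits when refitting after a tentative merge.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    t = np.asarray([1 if v in ("+", 1, 1.0, True) else 0 for v in t], dtype=float)
    if len(t) != X.shape[0]:
        raise ValueError("labels do not align with X rows")
    if t.min() == t.max():
        raise DegenerateLabelsError("all labels belong to one class")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    w = (
        np.ones_like(t)
        if sample_weight is None
        else np.asarray(sample_weight, dtype=float)
    )
    if w.shape != t.shape or np.any(w < 0):
        raise ValueError("sample weights must be non-negative and align with t")

    n_par = X.shape[1] + (1 if use_intercept else 0)
    x0 = np.zeros(n_par)
    if warm_start is not None and len(warm_start) == n_par:
        x0 = np.asarray(warm_start, dtype=float)
    res = minimize(
        _penalized_nll,
        x0,
        args=(X, t, w, ridge, use_intercept),
        jac=True,
        method="L-BFGS-B",
        options={"gtol": tol, "ftol": 1e-14, "maxiter": max_iter},
    )
    theta = res.x
    if use_intercept:
        intercept, betas = float(theta[0]), theta[1:]
    else:
        intercept, betas = 0.0, theta
    return MixtureLogisticModel(
        kmers=list(kmers) if kmers is not None else [f"x{j}" for j in range(X.shape[1])],
        betas=betas,
        intercept=intercept,
        fit_meta={
            "optimizer": "L-BFGS-B",
            "ridge": ridge,
            "converged": bool(res.success or np.linalg.norm(res.jac) < 1e-5),
            "n_iter": int(res.nit),
            "use_intercept": use_intercept,
        },
    )


def predict_probability(model: MixtureLogisticModel, x: Sequence[float]) -> float:
    """Predicted methylation susceptibility of one instance, in (0, 1)."""
    f = model.linear_predictor(np.asarray(x, dtype=float).reshape(1, -1))[0]
    return float(np.clip(expit(f), _EPS, 1 - _EPS))


def decision_scores(model: MixtureLogisticModel, X: np.ndarray) -> np.ndarray:
    """Vectorized predictions; the logistic output is the calibrated level."""
    return np.clip(expit(model.linear_predictor(X)), _EPS, 1 - _EPS)
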