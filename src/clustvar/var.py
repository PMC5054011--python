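"""Single VAR(1) estimation and interrogation.

The first-order vector autoregression

    y_t = c + Phi y_{t-1} + u_t

regresses each of M variables on all M variables at the previous occasion.
Estimation is multivariate least squares on stacked lagged pairs,
B-hat = Y Z' (Z Z')^{-1} with B = (c, Phi), which coincides with ordinary
least squares applied to each equation separately.  Lagged pairs are formed
strictly within segments, so the first observation of every segment never
serves as an outcome.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, ParameterError, RankDeficiencyError
from .panel import TimeSeriesPanel

logger = logging.getLogger(__name__)

__all__ = [
    "VARModel",
    "lagged_pairs",
    "fit_var",
    "check_stationarity",
    "forecast",
    "r_squared",
    "quartile_states",
]

#: reciprocal condition number below which the normal equations are treated
#: as singular
RCOND_SINGULAR = 1e-12


@dataclass(frozen=True)
class VARModel:
    """A fitted (or specified) VAR(1) model for M variables.

    ``slopes[m, m2]`` is the effect of variable ``m2`` at t-1 on variable
    ``m`` at t.  ``innovation_cov`` is the residual-based estimate of the
    innovation covariance; it is diagnostic only and plays no role in the
    least-squares loss.
    """

    intercept: np.ndarray           # (M,)
    slopes: np.ndarray              # (M, M)
    innovation_cov: np.ndarray      # (M, M)
    n_pairs: int
    sse: float
    variable_names: tuple[str, ...] = ()

    def __post_init__(self):
        c = np.asarray(self.intercept, dtype=float)
        phi = np.asarray(self.slopes, dtype=float)
        if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
            raise ParameterError(f"slopes must be square, got {phi.shape}")
        if c.shape != (phi.shape[0],):
            raise ParameterError("intercept length must match slopes dimension")
        object.__setattr__(self, "intercept", c)
        object.__setattr__(self, "slopes", phi)
        object.__setattr__(self, "innovation_cov",
                           np.asarray(self.innovation_cov, dtype=float))

    @property
    def n_variables(self) -> int:
        return self.slopes.shape[0]

    def predict(self, y_prev: np.ndarray) -> np.ndarray:
        """One-step prediction(s) from previous state(s), shape (..., M)."""
        return self.intercept + y_prev @ self.slopes.T

    def to_json(self) -> str:
        return json.dumps({
            "variable_names": list(self.variable_names),
            "intercept": self.intercept.tolist(),
            "slopes": self.slopes.tolist(),
            "innovation_cov": self.innovation_cov.tolist(),
            "n_pairs": int(self.n_pairs),
            "sse": float(self.sse),
        })

    @classmethod
    def from_json(cls, text: str) -> "VARModel":
        d = json.loads(text)
        return cls(
            intercept=np.asarray(d["intercept"], dtype=float),
            slopes=np.asarray(d["slopes"], dtype=float),
            innovation_cov=np.asarray(d["innovation_cov"], dtype=float),
            n_pairs=int(d["n_pairs"]),
            sse=float(d["sse"]),
            variable_names=tuple(d.get("variable_names", ())),
        )


def lagged_pairs(segments: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack within-segment (predictor, outcome) pairs across segments.

    Returns ``(X, Y)`` with ``X[n] = y_{t-1}`` and ``Y[n] = y_t``; pairs
    never cross a segment boundary.
    """
    xs, ys = [], []
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.shape[0] >= 2:
            xs.append(seg[:-1])
            ys.append(seg[1:])
    if not xs:
        raise InsufficientDataError("no segment contributes a lagged pair")
    return np.vstack(xs), np.vstack(ys)


def fit_var(
    segments: Sequence[np.ndarray],
    include_intercept: bool = True,
    variable_names: tuple[str, ...] = (),
) -> VARModel:
    """Multivariate least-squares VAR(1) fit on stacked lagged pairs.

    All segments (possibly from several persons) are pooled; the solution
    minimizes the total squared one-step prediction error and equals
    per-equation OLS.  Raises :class:`InsufficientDataError` when the
    number of pairs is below the parameter count and
    :class:`RankDeficiencyError` when the regressor cross-product matrix
    is singular (reciprocal condition number below 1e-12) — typically a
    constant or duplicated variable; centering or removing variables helps.
    """
    X, Y = lagged_pairs(segments)
    n, m = X.shape
    n_params = m + 1 if include_intercept else m
    if n < n_params:
        raise InsufficientDataError(
            f"{n} lagged pairs < {n_params} parameters per equation "
            f"({n_params - n} more needed)"
        )
    if include_intercept:
        Z = np.column_stack([np.ones(n), X])
    else:
        Z = X
    G = Z.T @ Z
    if np.linalg.cond(G) > 1.0 / RCOND_SINGULAR:
        raise RankDeficiencyError(
            "regressor cross-product matrix is numerically singular; "
            "consider centering the data or removing redundant variables"
        )
    B = np.linalg.solve(G, Z.T @ Y)          # (n_params, M)
    resid = Y - Z @ B
    sse = float(np.sum(resid * resid))
    dof = max(n - m - 1, 1)
    sigma = resid.T @ resid / dof
    sigma = (sigma + sigma.T) / 2.0
    if include_intercept:
        intercept, slopes = B[0], B[1:].T
    else:
        intercept, slopes = np.zeros(m), B.T
    return VARModel(intercept, slopes, sigma, n_pairs=n, sse=sse,
                    variable_names=tuple(variable_names))


def check_stationarity(model: VARModel) -> tuple[bool, float]:
    """Largest eigenvalue modulus of the slope matrix and whether it is < 1."""
    max_mod = float(np.max(np.abs(np.linalg.eigvals(model.slopes))))
    return max_mod < 1.0, max_mod


def forecast(model: VARModel, state: np.ndarray, horizon: int) -> np.ndarray:
    """Innovation-free h-step-ahead trajectory from a starting state.

    Row ``h`` (1-based) is ``c + Phi @ row_{h-1}`` with row 0 the given
    state; for a stationary model the rows converge to the fixed point
    ``(I - Phi)^{-1} c``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_variables,):
        raise ParameterError(
            f"state must have shape ({model.n_variables},), got {state.shape}"
        )
    if not np.all(np.isfinite(state)):
        raise ParameterError("state contains non-finite values")
    if horizon < 1:
        raise ParameterError("horizon must be >= 1")
    out = np.empty((horizon, model.n_variables))
    y = state
    for h in range(horizon):
        y = model.intercept + model.slopes @ y
        out[h] = y
    return out


def r_squared(model: VARModel, segments: Sequence[np.ndarray]) -> np.ndarray:
    """Per-variable one-step explained variance on the given segments.

    For variable m, ``R2_m = 1 - SSE_m / SST_m`` where SSE_m is the squared
    one-step prediction error and SST_m the squared deviation of the
    outcome values from their mean, both over all pooled pairs.  Can be
    negative for a mis-specified model; NaN (with a warning) where a
    variable's outcomes are constant.
    """
    X, Y = lagged_pairs(segments)
    pred = model.predict(X)
    sse = np.sum((Y - pred) ** 2, axis=0)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    out = np.full(Y.shape[1], np.nan)
    ok = sst > 0
    out[ok] = 1.0 - sse[ok] / sst[ok]
    if not ok.all():
        bad = np.flatnonzero(~ok)
        warnings.warn(
            f"R^2 undefined for constant-outcome variable(s) {bad.tolist()}",
            RuntimeWarning, stacklevel=2,
        )
    return out


def quartile_states(panel: TimeSeriesPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variable quartiles of the pooled observations, as (Q1, Q2, Q3).

    These serve as realistic low / typical / high starting states for
    forecasting.  Quantiles use linear interpolation between order
    statistics.
    """
    pooled = panel.pooled()
    q1, q2, q3 = np.percentile(pooled, [25, 50, 75], axis=0)
    return q1, q2, q3
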