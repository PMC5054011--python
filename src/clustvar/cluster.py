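"""Clusterwise VAR(1) fitting by alternating least squares.

Persons are partitioned into K clusters; all persons in a cluster share one
VAR(1) coefficient set.  Fitting minimizes the pooled squared one-step
prediction error

    L_K = sum_i sum_t || y_it - yhat_it ||^2

by alternating (a) refitting each cluster's VAR(1) model on the vertically
concatenated data of its members (first observation of each segment
removed, so no person's data predicts another's) and (b) reassigning each
person to the cluster whose model yields the smallest prediction error on
that person's data.  Each person move triggers an immediate refit of the
two affected cluster models, so the loss is non-increasing step by step and
the procedure terminates at a partition fixed point.

Because the loss surface is combinatorial and multi-modal, a multi-start
strategy is used: many random initial partitions plus one "rational" start
obtained by Ward hierarchical clustering of per-person VAR(1) slope
matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .exceptions import (
    FitFailedError,
    InfeasiblePartitionError,
    InsufficientDataError,
    ParameterError,
    RankDeficiencyError,
)
from .panel import TimeSeriesPanel
from .var import RCOND_SINGULAR, VARModel, fit_var, lagged_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "ClusterwiseVARFit",
    "MultiStartResult",
    "person_sse",
    "random_start",
    "rational_start",
    "als_fit",
    "multistart_fit",
]

#: relative tolerance under which two run losses count as "the same optimum"
LOSS_TIE_RTOL = 1e-8


@dataclass(frozen=True)
class Partition:
    """Assignment of persons (by index) to clusters 0..K-1.

    Every cluster must be non-empty and every person assigned exactly once.
    """

    assignment: np.ndarray
    n_clusters: int

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        if a.ndim != 1 or a.size == 0:
            raise ParameterError("assignment must be a non-empty 1-D array")
        if a.min() < 0 or a.max() >= self.n_clusters:
            raise ParameterError("cluster labels must lie in [0, K)")
        counts = np.bincount(a, minlength=self.n_clusters)
        if (counts == 0).any():
            raise InfeasiblePartitionError(
                f"empty cluster(s): {np.flatnonzero(counts == 0).tolist()}"
            )

    @property
    def n_persons(self) -> int:
        return self.assignment.size

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)

    def relabeled_by_first_occurrence(self) -> "Partition":
        """Canonical labels: cluster of the first person is 0, etc."""
        mapping, new = {}, np.empty_like(self.assignment)
        for i, k in enumerate(self.assignment):
            if k not in mapping:
                mapping[k] = len(mapping)
            new[i] = mapping[k]
        return Partition(new, self.n_clusters)


@dataclass(frozen=True)
class ClusterwiseVARFit:
    """Result of one ALS run: a partition plus one VAR(1) model per cluster."""

    partition: Partition
    models: tuple[VARModel, ...]
    loss: float
    n_iterations: int
    converged: bool
    start_type: str = "unspecified"
    seed: int | None = None
    loss_history: tuple[float, ...] = field(default=())

    @property
    def n_clusters(self) -> int:
        return self.partition.n_clusters


@dataclass(frozen=True)
class MultiStartResult:
    """Best ALS run over a set of starts, with local-optimum diagnostics."""

    best: ClusterwiseVARFit
    all_losses: tuple[float, ...]
    attraction_rate: float
    n_failed: int = 0
    run_start_types: tuple[str, ...] = field(default=())


def person_sse(person_segments: Sequence[np.ndarray], model: VARModel) -> float:
    """Squared one-step prediction error of a model on one person's data.

    This is the person's contribution to the clusterwise loss: the sum over
    within-segment lagged pairs of the squared error, summed over the M
    variables.
    """
    X, Y = lagged_pairs(person_segments)
    resid = Y - model.predict(X)
    return float(np.sum(resid * resid))


def random_start(I: int, K: int, rng_seed: int | np.random.Generator) -> Partition:
    """Uniform random assignment, redrawn entirely until no cluster is empty."""
    if I < K:
        raise InfeasiblePartitionError(f"cannot place {I} persons in {K} clusters")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    while True:
        a = rng.integers(0, K, size=I)
        if np.bincount(a, minlength=K).min() > 0:
            return Partition(a, K)


def rational_start(panel: TimeSeriesPanel, K: int) -> Partition:
    """Ward hierarchical clustering of per-person VAR(1) slope matrices.

    Fits a separate VAR(1) to every person, vectorizes the M x M slope
    matrices (intercepts excluded), agglomerates with Ward's criterion on
    Euclidean distances and cuts the tree at K clusters.  Labels are
    canonicalized by first-person order.
    """
    if panel.n_persons < K:
        raise InfeasiblePartitionError(
            f"cannot place {panel.n_persons} persons in {K} clusters"
        )
    rows = []
    for p in panel.persons:
        try:
            rows.append(fit_var(p.segments).slopes.ravel())
        except (InsufficientDataError, RankDeficiencyError) as exc:
            raise FitFailedError(
                f"per-person VAR(1) fit failed for person {p.person_id!r}: {exc}"
            ) from exc
    if K == 1:
        return Partition(np.zeros(panel.n_persons, dtype=int), 1)
    Zlink = linkage(np.asarray(rows), method="ward")
    labels = fcluster(Zlink, t=K, criterion="maxclust") - 1
    if len(np.unique(labels)) != K:
        # maxclust can merge below K on degenerate (duplicate-point) inputs
        raise FitFailedError(
            f"Ward cut produced {len(np.unique(labels))} clusters instead of {K}"
        )
    return Partition(labels, K).relabeled_by_first_occurrence()


# ---------------------------------------------------------------------------
# cached per-person cross-products:  with Z_i the (n_i, M+1) matrix of
# [1, y_{t-1}] rows and Y_i the outcomes, a person's error under
# coefficients B is  tr(S_i) - 2 tr(B'C_i) + tr(B'G_i B)  with
# G_i = Z_i'Z_i, C_i = Z_i'Y_i, S_i = Y_i'Y_i — so reassignment sweeps and
# cluster refits never touch the raw series again.
# ---------------------------------------------------------------------------

class _PanelStats:
    def __init__(self, panel: TimeSeriesPanel):
        self.M = panel.n_variables
        P = self.M + 1
        I = panel.n_persons
        self.G = np.empty((I, P, P))
        self.C = np.empty((I, P, self.M))
        self.S = np.empty((I, self.M, self.M))
        self.trS = np.empty(I)
        self.n = np.empty(I, dtype=int)
        for i, person in enumerate(panel.persons):
            X, Y = lagged_pairs(person.segments)
            Z = np.column_stack([np.ones(X.shape[0]), X])
            self.G[i] = Z.T @ Z
            self.C[i] = Z.T @ Y
            self.S[i] = Y.T @ Y
            self.trS[i] = np.trace(self.S[i])
            self.n[i] = X.shape[0]

    def cluster_coefs(self, idx: np.ndarray) -> np.ndarray:
        """Pooled OLS coefficients (M+1, M) for the given member set."""
        G = self.G[idx].sum(axis=0)
        C = self.C[idx].sum(axis=0)
        n = int(self.n[idx].sum())
        if n < self.M + 1:
            raise InsufficientDataError(
                f"cluster has {n} lagged pairs < {self.M + 1} parameters"
            )
        if np.linalg.cond(G) > 1.0 / RCOND_SINGULAR:
            raise RankDeficiencyError("singular cluster cross-product matrix")
        return np.linalg.solve(G, C)

    def sse_all(self, B: np.ndarray) -> np.ndarray:
        """Prediction error of coefficients B for every person, shape (I,)."""
        lin = np.einsum("ipm,pm->i", self.C, B)
        quad = np.einsum("pm,ipq,qm->i", B, self.G, B)
        return self.trS - 2.0 * lin + quad

    def sse_one(self, i: int, B: np.ndarray) -> float:
        lin = float(np.sum(self.C[i] * B))
        quad = float(np.sum(B * (self.G[i] @ B)))
        return self.trS[i] - 2.0 * lin + quad

    def cluster_model(self, idx: np.ndarray, B: np.ndarray,
                      variable_names: tuple[str, ...]) -> VARModel:
        G = self.G[idx].sum(axis=0)
        C = self.C[idx].sum(axis=0)
        S = self.S[idx].sum(axis=0)
        n = int(self.n[idx].sum())
        R = S - B.T @ C - C.T @ B + B.T @ G @ B
        sse = float(np.trace(R))
        sigma = (R + R.T) / (2.0 * max(n - self.M - 1, 1))
        return VARModel(B[0].copy(), B[1:].T.copy(), sigma, n_pairs=n,
                        sse=max(sse, 0.0), variable_names=variable_names)


def _argmin_with_ties(row: np.ndarray, current: int) -> int:
    """Index of the smallest error; on exact ties keep `current`, else the
    lowest index (prevents assignment cycling)."""
    best = row.min()
    if row[current] == best:
        return current
    return int(np.argmin(row))


def als_fit(
    panel: TimeSeriesPanel,
    K: int,
    start: Partition,
    max_sweeps: int = 100,
    batch_refit: bool = False,
    debug_monotonic: bool = False,
    _stats: _PanelStats | None = None,
) -> ClusterwiseVARFit:
    """One alternating-least-squares run from a given initial partition.

    Sweeps persons in ascending index order; each person is moved to the
    cluster whose current model predicts it best, and (by default) the two
    affected cluster models are refitted immediately after every move.
    ``batch_refit=True`` instead refits only after a full sweep — exposed
    for comparison, the default follows the step-by-step update.  A move
    that would empty its source cluster is vetoed.  Terminates when a full
    sweep changes no membership, or at ``max_sweeps``.

    Raises :class:`FitFailedError` if a cluster refit becomes rank
    deficient; callers running many starts treat such a run as failed.
    """
    if start.n_persons != panel.n_persons or start.n_clusters != K:
        raise ParameterError("start partition does not match panel / K")
    stats = _stats if _stats is not None else _PanelStats(panel)
    I = panel.n_persons
    assign = start.assignment.copy()
    counts = np.bincount(assign, minlength=K)

    def refit(k: int) -> np.ndarray:
        try:
            return stats.cluster_coefs(np.flatnonzero(assign == k))
        except (InsufficientDataError, RankDeficiencyError) as exc:
            raise FitFailedError(f"refit of cluster {k} failed: {exc}") from exc

    B = [refit(k) for k in range(K)]
    sse_mat = np.column_stack([stats.sse_all(B[k]) for k in range(K)])

    def total_loss() -> float:
        return float(sum(sse_mat[assign == k, k].sum() for k in range(K)))

    loss_history = [total_loss()]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        changed_any = False
        touched: set[int] = set()
        for i in range(I):
            cur = int(assign[i])
            tgt = _argmin_with_ties(sse_mat[i], cur)
            if tgt == cur:
                continue
            if counts[cur] == 1:
                logger.debug("vetoed move of person %d: would empty cluster %d",
                             i, cur)
                continue
            if debug_monotonic:
                before = total_loss()
            assign[i] = tgt
            counts[cur] -= 1
            counts[tgt] += 1
            changed_any = True
            if batch_refit:
                touched.update((cur, tgt))
            else:
                for k in (cur, tgt):
                    B[k] = refit(k)
                    sse_mat[:, k] = stats.sse_all(B[k])
            if debug_monotonic and not batch_refit:
                after = total_loss()
                if after > before + 1e-7 * max(before, 1.0):
                    raise AssertionError(
                        f"loss increased {before} -> {after} at person {i}"
                    )
        if batch_refit and touched:
            for k in touched:
                B[k] = refit(k)
                sse_mat[:, k] = stats.sse_all(B[k])
        loss_history.append(total_loss())
        if not changed_any:
            converged = True
            break
    if not converged and max_sweeps > 0:
        logger.warning("ALS did not converge within %d sweeps", max_sweeps)

    models = tuple(
        stats.cluster_model(np.flatnonzero(assign == k), B[k],
                            panel.variable_names)
        for k in range(K)
    )
    # recompute the loss from the final models, independent of the sweep
    # bookkeeping, so the reported value is exactly sum_i person_sse
    loss = float(sum(m.sse for m in models))
    return ClusterwiseVARFit(
        partition=Partition(assign, K),
        models=models,
        loss=loss,
        n_iterations=sweeps,
        converged=converged,
        loss_history=tuple(loss_history),
    )


def multistart_fit(
    panel: TimeSeriesPanel,
    K: int,
    n_random_starts: int = 100,
    use_rational: bool = True,
    rng_seed: int | None = None,
    max_sweeps: int = 100,
    batch_refit: bool = False,
) -> MultiStartResult:
    """Run ALS from one rational and many random starts; keep the best.

    The attraction rate — the share of (non-failed) runs whose final loss
    ties the minimum within relative tolerance 1e-8 — diagnoses how prone
    the instance is to local optima.  Per-run seeds derive deterministically
    from ``rng_seed``, so results are bit-reproducible.
    """
    if n_random_starts < 1 and not use_rational:
        raise ParameterError("need at least one start")
    stats = _PanelStats(panel)
    rng = np.random.default_rng(rng_seed)
    runs: list[tuple[str, int | None]] = []
    if use_rational:
        runs.append(("rational", None))
    seeds = rng.integers(0, 2**31, size=max(n_random_starts, 0))
    runs.extend(("random", int(s)) for s in seeds)

    fits: list[ClusterwiseVARFit] = []
    start_types: list[str] = []
    n_failed = 0
    for start_type, seed in runs:
        try:
            if start_type == "rational":
                start = rational_start(panel, K)
            else:
                start = random_start(panel.n_persons, K, seed)
            fit = als_fit(panel, K, start, max_sweeps=max_sweeps,
                          batch_refit=batch_refit, _stats=stats)
        except (FitFailedError, InfeasiblePartitionError) as exc:
            logger.warning("%s start failed: %s", start_type, exc)
            n_failed += 1
            continue
        fits.append(ClusterwiseVARFit(
            partition=fit.partition, models=fit.models, loss=fit.loss,
            n_iterations=fit.n_iterations, converged=fit.converged,
            start_type=start_type, seed=seed, loss_history=fit.loss_history,
        ))
        start_types.append(start_type)
    if not fits:
        raise FitFailedError(f"all {len(runs)} starts failed for K={K}")
    losses = np.array([f.loss for f in fits])
    best_idx = int(np.argmin(losses))  # ties -> earliest run
    best_loss = losses[best_idx]
    # tiny absolute slack so exactly-solvable (zero-loss) instances tie cleanly
    attraction = float(np.mean(losses <= best_loss * (1.0 + LOSS_TIE_RTOL) + 1e-12))
    return MultiStartResult(
        best=fits[best_idx],
        all_losses=tuple(float(x) for x in losses),
        attraction_rate=attraction,
        n_failed=n_failed,
        run_start_types=tuple(start_types),
    )
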