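"""Synthetic panels with known cluster structure, and factorial recovery studies.

The generator produces I persons split over K clusters; each cluster has
its own stationary 6x6 VAR(1) slope matrix and zero intercepts.  Data are
driven by multivariate-normal innovations with unit variances and a common
off-diagonal covariance, starting from y_1 = u_1.  Three similarity
conditions control how distinguishable the clusters are:

* ``highly_similar`` — diagonals U[0.7, 0.9], all off-diagonals U[0.3, 0.5];
  clusters differ only through independent draws from the same intervals.
* ``similar`` — per cluster, a random half of the off-diagonals come from
  U[0.3, 0.5] and the rest from U[0, 0.2], so cross-effects differ in size.
* ``highly_dissimilar`` — as highly_similar, but after rescaling each
  off-diagonal entry's sign is flipped with probability 1/2, giving
  clusters with opposite-direction cross-effects.

Every matrix is rescaled by 0.99 / max |eigenvalue| so the spectral radius
is exactly 0.99: strongly persistent but stationary dynamics.  Sign
flipping can push the spectral radius back above 1; such draws are
rejected and redrawn, since the generated series must remain stationary.

Factor levels default to a full factorial recovery design: K in {2, 4},
T in {50, 100, 500}, I in {30, 60, 120}, three similarity conditions,
three cluster-size regimes, and an innovation regime that is either a
common covariance of 0.2 for everyone or a per-person mix of 0.2 and 0.4
(a controlled violation of the equal-covariance assumption).  With five
replications this yields 1620 data sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .cluster import Partition, als_fit, multistart_fit, rational_start
from .evaluate import adjusted_rand, coefficient_distance
from .exceptions import FitFailedError, GenerationError, ParameterError
from .panel import Person, TimeSeriesPanel
from .selection import select_k

logger = logging.getLogger(__name__)

__all__ = [
    "SIMILARITY_LEVELS",
    "SIZE_REGIMES",
    "INNOVATION_REGIMES",
    "DesignCell",
    "SimulationDesign",
    "SimulatedDataset",
    "cluster_sizes",
    "generate_phi",
    "generate_dataset",
    "run_study",
]

SIMILARITY_LEVELS = ("highly_similar", "similar", "highly_dissimilar")
SIZE_REGIMES = ("equal", "minority", "majority")
INNOVATION_REGIMES = ("equal", "unequal")

#: spectral radius every generated slope matrix is rescaled to
TARGET_SPECTRAL_RADIUS = 0.99


@dataclass(frozen=True)
class DesignCell:
    """One coordinate of the factorial design."""

    K: int
    T: int
    I: int
    similarity: str
    size_regime: str
    innovation_regime: str
    M: int = 6

    def label(self) -> str:
        return (f"K{self.K}_T{self.T}_I{self.I}_{self.similarity}_"
                f"{self.size_regime}_{self.innovation_regime}")


@dataclass(frozen=True)
class SimulationDesign:
    """Factor levels of a factorial recovery study.

    The default levels are the validated surface of the generator; passing
    other levels requires ``allow_custom_levels=True``.
    """

    K_levels: tuple[int, ...] = (2, 4)
    T_levels: tuple[int, ...] = (50, 100, 500)
    I_levels: tuple[int, ...] = (30, 60, 120)
    similarity_levels: tuple[str, ...] = SIMILARITY_LEVELS
    size_regimes: tuple[str, ...] = SIZE_REGIMES
    innovation_regimes: tuple[str, ...] = INNOVATION_REGIMES
    M: int = 6
    replications: int = 5
    rng_seed: int | None = None
    allow_custom_levels: bool = False

    def __post_init__(self):
        if not self.allow_custom_levels:
            checks = [
                (set(self.K_levels) <= {2, 4}, "K_levels"),
                (set(self.T_levels) <= {50, 100, 500}, "T_levels"),
                (set(self.I_levels) <= {30, 60, 120}, "I_levels"),
                (self.M == 6, "M"),
            ]
            for ok, name in checks:
                if not ok:
                    raise ParameterError(
                        f"{name} outside the validated design; "
                        "set allow_custom_levels=True to override"
                    )
        for levels, valid, name in [
            (self.similarity_levels, SIMILARITY_LEVELS, "similarity_levels"),
            (self.size_regimes, SIZE_REGIMES, "size_regimes"),
            (self.innovation_regimes, INNOVATION_REGIMES, "innovation_regimes"),
        ]:
            if not set(levels) <= set(valid):
                raise ParameterError(f"unknown {name}: {levels}")
        if self.replications < 1:
            raise ParameterError("replications must be >= 1")

    def cells(self) -> Iterator[DesignCell]:
        for K, T, I, sim, size, innov in itertools.product(
            self.K_levels, self.T_levels, self.I_levels,
            self.similarity_levels, self.size_regimes,
            self.innovation_regimes,
        ):
            yield DesignCell(K, T, I, sim, size, innov, self.M)

    @property
    def n_datasets(self) -> int:
        return sum(1 for _ in self.cells()) * self.replications


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated panel with its ground truth."""

    panel: TimeSeriesPanel
    true_partition: Partition
    true_phis: tuple[np.ndarray, ...]   # one M x M slope matrix per cluster
    cell: DesignCell
    replication: int = 0
    seed: int | None = None


def cluster_sizes(I: int, K: int, size_regime: str) -> np.ndarray:
    """Persons per cluster under a size regime; sizes sum to I.

    ``equal`` splits evenly; ``minority`` gives cluster 0 round(0.10 I);
    ``majority`` gives cluster 0 round(0.60 I); in both the remaining
    persons are split evenly over the other clusters.  Remainders from
    uneven division go to the lowest-index clusters involved in the split.
    """
    if size_regime not in SIZE_REGIMES:
        raise ParameterError(f"unknown size regime {size_regime!r}")
    if K < 1 or I < K:
        raise ParameterError(f"cannot split {I} persons into {K} clusters")

    def _even(total: int, parts: int) -> list[int]:
        base, extra = divmod(total, parts)
        return [base + (1 if j < extra else 0) for j in range(parts)]

    if size_regime == "equal":
        sizes = _even(I, K)
    else:
        share = 0.10 if size_regime == "minority" else 0.60
        first = int(round(share * I))
        sizes = [first] + _even(I - first, K - 1) if K > 1 else [I]
    sizes = np.asarray(sizes, dtype=int)
    if (sizes < 1).any():
        raise ParameterError(
            f"size regime {size_regime!r} leaves an empty cluster for I={I}, K={K}"
        )
    return sizes


def _spectral_radius(phi: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(phi))))


def generate_phi(M: int, similarity: str, rng: np.random.Generator,
                 max_redraws: int = 50) -> np.ndarray:
    """Draw one cluster slope matrix under a similarity condition.

    Diagonals (autoregressions) are U[0.7, 0.9]; off-diagonals
    (cross-regressions) follow the condition; the matrix is rescaled to
    spectral radius 0.99.  In the highly dissimilar condition each
    off-diagonal sign is then flipped with probability 1/2 (diagonals keep
    positive autoregression) and the draw is rejected and restarted if the
    flips push the spectral radius to 1 or beyond.
    """
    if M < 2:
        raise ParameterError("need M >= 2 variables")
    if similarity not in SIMILARITY_LEVELS:
        raise ParameterError(f"unknown similarity condition {similarity!r}")
    n_off = M * (M - 1)
    for _ in range(max_redraws):
        phi = np.empty((M, M))
        diag = rng.uniform(0.7, 0.9, size=M)
        if similarity == "similar":
            # exactly half the cross-effects are sizeable, half near zero
            n_big = n_off // 2 + (n_off % 2)
            vals = np.concatenate([
                rng.uniform(0.3, 0.5, size=n_big),
                rng.uniform(0.0, 0.2, size=n_off - n_big),
            ])
            vals = vals[rng.permutation(n_off)]
        else:
            vals = rng.uniform(0.3, 0.5, size=n_off)
        off_mask = ~np.eye(M, dtype=bool)
        phi[off_mask] = vals
        np.fill_diagonal(phi, diag)
        phi *= TARGET_SPECTRAL_RADIUS / _spectral_radius(phi)
        if similarity == "highly_dissimilar":
            signs = np.where(rng.random((M, M)) < 0.5, -1.0, 1.0)
            signs[np.eye(M, dtype=bool)] = 1.0
            phi = phi * signs
            if _spectral_radius(phi) >= 1.0:
                continue  # sign flips destroyed stationarity; redraw
        return phi
    raise GenerationError(
        f"no stationary draw in {max_redraws} attempts ({similarity}, M={M})"
    )


def _innovation_cov(M: int, off_cov: float) -> np.ndarray:
    sigma = np.full((M, M), off_cov)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def generate_dataset(
    cell: DesignCell,
    replication: int = 0,
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """Generate one panel for a design cell, with ground truth attached.

    Innovations have unit variances and a common off-diagonal covariance of
    0.2 (equal regime) or, per person, 0.2 or 0.4 with probability 1/2
    (unequal regime).  Each person's series starts at y_1 = u_1 and follows
    y_t = Phi_k y_{t-1} + u_t with zero intercepts; no burn-in is applied.
    Person order is shuffled so cluster membership is not encoded in
    position.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    sizes = cluster_sizes(cell.I, cell.K, cell.size_regime)
    phis = tuple(generate_phi(cell.M, cell.similarity, rng)
                 for _ in range(cell.K))
    labels = np.repeat(np.arange(cell.K), sizes)

    persons, data_by_person = [], []
    for i, k in enumerate(labels):
        if cell.innovation_regime == "equal":
            off = 0.2
        else:
            off = 0.2 if rng.random() < 0.5 else 0.4
        chol = np.linalg.cholesky(_innovation_cov(cell.M, off))
        u = rng.standard_normal((cell.T, cell.M)) @ chol.T
        y = np.empty_like(u)
        y[0] = u[0]
        for t in range(1, cell.T):
            y[t] = phis[k] @ y[t - 1] + u[t]
        data_by_person.append(y)

    order = rng.permutation(cell.I)
    for pos, i in enumerate(order):
        persons.append(Person(f"p{pos:03d}", (data_by_person[i],)))
    panel = TimeSeriesPanel(tuple(persons))
    truth = Partition(labels[order], cell.K)
    seed_out = seed if isinstance(seed, int) else None
    return SimulatedDataset(panel, truth, phis, cell, replication, seed_out)


def _analyze_study1(ds: SimulatedDataset, n_random_starts: int,
                    use_rational: bool, seed: int) -> dict:
    res = multistart_fit(ds.panel, ds.cell.K,
                         n_random_starts=n_random_starts,
                         use_rational=use_rational, rng_seed=seed)
    ari = adjusted_rand(ds.true_partition, res.best.partition)
    try:
        rat_ari = adjusted_rand(ds.true_partition,
                                rational_start(ds.panel, ds.cell.K))
    except FitFailedError:
        rat_ari = np.nan
    dist_gen = coefficient_distance(ds, res.best, reference="generating")
    dist_refit = coefficient_distance(ds, res.best,
                                      reference="refit_true_partition")
    # local-minimum check: the loss of an OLS refit under the true partition
    # (max_sweeps=0 stops before any reassignment) bounds the estimate
    truth_loss = als_fit(ds.panel, ds.cell.K, ds.true_partition,
                         max_sweeps=0).loss
    return {
        "loss": res.best.loss,
        "truth_refit_loss": truth_loss,
        "attraction_rate": res.attraction_rate,
        "ari": ari,
        "perfect": ari == 1.0,
        "rational_ari": rat_ari,
        "rational_perfect": rat_ari == 1.0,
        "coef_distance_generating": dist_gen.mean_distance,
        "coef_distance_refit": dist_refit.mean_distance,
        "coef_distance_generating_total": dist_gen.total_distance,
        "coef_distance_refit_total": dist_refit.total_distance,
    }


def _analyze_study2(ds: SimulatedDataset, n_random_starts: int,
                    use_rational: bool, seed: int,
                    k_min: int, k_max: int) -> dict:
    series, fits = select_k(ds.panel, k_min, k_max,
                            n_random_starts=n_random_starts,
                            use_rational=use_rational, rng_seed=seed)
    sel = series.selected_k
    out = {"selected_k": sel if sel is not None else -1,
           "correct_k": sel == ds.cell.K}
    if sel is not None:
        out["ari_selected"] = adjusted_rand(ds.true_partition,
                                            fits[sel].best.partition)
    else:
        out["ari_selected"] = np.nan
    return out


def run_study(
    design: SimulationDesign,
    mode: str = "study1",
    n_random_starts: int = 100,
    use_rational: bool = True,
    k_min: int = 1,
    k_max: int = 6,
    progress: bool = False,
) -> pd.DataFrame:
    """Generate and analyze every dataset of a factorial design.

    ``mode="study1"`` fits at the true K and scores partition, coefficient
    and attraction-rate recovery; ``mode="study2"`` additionally runs the
    scree-based selection of K over ``k_min..k_max``.  One row per dataset;
    per-dataset failures are logged and flagged, not fatal.  Fully
    deterministic given ``design.rng_seed``.
    """
    if mode not in ("study1", "study2"):
        raise ParameterError(f"unknown mode {mode!r}")
    master = np.random.default_rng(design.rng_seed)
    rows = []
    tasks = [(cell, rep) for cell in design.cells()
             for rep in range(design.replications)]
    for j, (cell, rep) in enumerate(tasks):
        gen_seed = int(master.integers(0, 2**31))
        fit_seed = int(master.integers(0, 2**31))
        row = {
            "K": cell.K, "T": cell.T, "I": cell.I,
            "similarity": cell.similarity, "size_regime": cell.size_regime,
            "innovation_regime": cell.innovation_regime,
            "replication": rep, "seed": gen_seed, "failed": False,
        }
        try:
            ds = generate_dataset(cell, rep, gen_seed)
            if mode == "study1":
                row.update(_analyze_study1(ds, n_random_starts, use_rational,
                                           fit_seed))
            else:
                row.update(_analyze_study2(ds, n_random_starts, use_rational,
                                           fit_seed, k_min, k_max))
        except (FitFailedError, GenerationError) as exc:
            logger.warning("dataset %s rep %d failed: %s", cell.label(), rep, exc)
            row["failed"] = True
        rows.append(row)
        if progress and (j + 1) % 25 == 0:
            logger.info("analyzed %d / %d datasets", j + 1, len(tasks))
    return pd.DataFrame(rows)
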