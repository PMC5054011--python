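"""Choosing the number of clusters with the CHull scree-test ratio.

Fit quality (the pooled squared prediction error L_K) always improves with
more clusters; the scree-test ratio

    st_K = (L_{K-1} - L_K) / (L_K - L_{K+1})

is large at the elbow where adding a further cluster stops paying off.
Before ratios are computed, the (K, L_K) points are reduced to their lower
convex hull: a K whose loss does not improve on K-1, or that lies above the
line joining its retained neighbours, cannot be an elbow and is discarded —
this guards against the non-monotonicity that finite multi-start
optimization can introduce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cluster import MultiStartResult, multistart_fit
from .exceptions import FitFailedError, ParameterError
from .panel import TimeSeriesPanel

logger = logging.getLogger(__name__)

__all__ = ["ScreeSeries", "scree_ratios", "select_k"]

#: relative floor for the ratio denominator, to avoid division blow-up when
#: two successive losses are numerically identical
DENOM_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class ScreeSeries:
    """Losses over a K range with scree ratios and the selected K."""

    k_values: tuple[int, ...]
    losses: tuple[float, ...]
    st_values: dict[int, float]
    selected_k: int | None
    hull_retained: tuple[bool, ...]
    no_elbow: bool = False
    notes: tuple[str, ...] = field(default=())


def _hull_filter(ks: np.ndarray, losses: np.ndarray) -> np.ndarray:
    """Boolean mask of points kept on the decreasing lower convex hull."""
    keep = np.ones(ks.size, dtype=bool)
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(keep)
        # drop any point that does not improve on the previous retained one
        for a, b in zip(idx[:-1], idx[1:]):
            if losses[b] >= losses[a]:
                keep[b] = False
                changed = True
                break
        if changed:
            continue
        idx = np.flatnonzero(keep)
        # drop interior points above the chord joining retained neighbours
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            frac = (ks[b] - ks[a]) / (ks[c] - ks[a])
            chord = losses[a] + frac * (losses[c] - losses[a])
            if losses[b] > chord:
                keep[b] = False
                changed = True
                break
    return keep


def scree_ratios(
    k_values: Sequence[int],
    losses: Sequence[float],
    hull_filter: bool = True,
) -> ScreeSeries:
    """Compute scree-test ratios over a fitted K range and pick the elbow.

    ``k_values`` must be consecutive integers (length >= 3) and losses
    strictly positive.  With ``hull_filter=False`` the raw ratio is
    evaluated at every interior K.  When the hull leaves gaps, loss
    decrements are scaled by the complexity difference they span.  Ties in
    the maximal ratio resolve to the smaller K (prefer parsimony).
    """
    ks = np.asarray(list(k_values), dtype=int)
    ls = np.asarray(list(losses), dtype=float)
    if ks.size != ls.size or ks.size < 3:
        raise ParameterError("need >= 3 (K, loss) points")
    if np.any(np.diff(ks) != 1):
        raise ParameterError("k_values must be consecutive integers")
    if np.any(ls <= 0):
        raise ParameterError("losses must be strictly positive")

    notes: list[str] = []
    keep = _hull_filter(ks, ls) if hull_filter else np.ones(ks.size, dtype=bool)
    idx = np.flatnonzero(keep)
    if idx.size < 3:
        logger.warning("fewer than 3 points retained; cannot select K")
        return ScreeSeries(tuple(ks), tuple(ls), {}, None, tuple(keep),
                           notes=("selection impossible: <3 retained points",))

    st: dict[int, float] = {}
    for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
        num = (ls[a] - ls[b]) / (ks[b] - ks[a])
        den = (ls[b] - ls[c]) / (ks[c] - ks[b])
        floor = DENOM_FLOOR_REL * ls[b]
        if den < floor:
            notes.append(f"denominator underflow at K={ks[b]}; floored")
            den = floor
        st[int(ks[b])] = float(num / den)

    best_st = max(st.values())
    selected = min(k for k, v in st.items() if v == best_st)
    # a maximal ratio below 2 means no decrement dominates the next: no elbow
    no_elbow = best_st < 2.0
    if no_elbow:
        notes.append("no clear elbow: maximal st below 2")
    return ScreeSeries(tuple(ks), tuple(ls), st, int(selected), tuple(keep),
                       no_elbow=no_elbow, notes=tuple(notes))


def select_k(
    panel: TimeSeriesPanel,
    k_min: int = 1,
    k_max: int = 6,
    hull_filter: bool = True,
    **multistart_kwargs,
) -> tuple[ScreeSeries, dict[int, MultiStartResult]]:
    """Fit the clusterwise model for each K in a range and pick K by scree.

    Returns the scree series plus every K's multi-start result so the
    top-ratio candidates can be inspected for interpretability rather than
    trusting the numeric selection blindly.
    """
    if k_min < 1 or k_max < k_min + 2:
        raise ParameterError("need k_min >= 1 and k_max >= k_min + 2")
    fits: dict[int, MultiStartResult] = {}
    seed = multistart_kwargs.pop("rng_seed", None)
    rng = np.random.default_rng(seed)
    for k in range(k_min, k_max + 1):
        k_seed = int(rng.integers(0, 2**31))
        try:
            fits[k] = multistart_fit(panel, k, rng_seed=k_seed,
                                     **multistart_kwargs)
        except FitFailedError as exc:
            logger.warning("K=%d excluded: %s", k, exc)
    if len(fits) < 3:
        raise FitFailedError("fewer than 3 cluster counts could be fitted")
    ks = sorted(fits)
    if any(b - a != 1 for a, b in zip(ks[:-1], ks[1:])):
        raise FitFailedError("fitted K values are not consecutive after failures")
    series = scree_ratios(ks, [fits[k].best.loss for k in ks],
                          hull_filter=hull_filter)
    return series, fits
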