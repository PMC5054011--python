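"""Person-level multivariate time-series panels.

A :class:`TimeSeriesPanel` holds, for every person, one or more contiguous
*segments* of equidistant multivariate observations.  Lagged (t-1, t) pairs
are only ever formed inside a segment, so irregular sampling is handled by
splitting a person's series wherever the spacing between adjacent
measurements differs from the nominal gap — no interpolation or imputation
is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    PanelFormatError,
    PanelParseError,
    PanelValidationError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Person",
    "TimeSeriesPanel",
    "read_panel",
    "write_panel",
    "panel_from_arrays",
    "center_panel",
    "screen_low_variance",
]


@dataclass(frozen=True)
class Person:
    """One person's retained observations, split into equidistant segments.

    Each segment is a ``(T_s, M)`` float array of observations at
    consecutive, equally spaced occasions.  Segments with fewer than two
    rows carry no lagged pair and are never stored.
    """

    person_id: str
    segments: tuple[np.ndarray, ...]

    @property
    def n_obs(self) -> int:
        return sum(s.shape[0] for s in self.segments)

    @property
    def usable_pairs(self) -> int:
        """Number of (t-1, t) pairs available for VAR(1) estimation."""
        return sum(s.shape[0] - 1 for s in self.segments)

    def stacked(self) -> np.ndarray:
        """All retained observations pooled across segments, (n_obs, M)."""
        return np.vstack(self.segments)


@dataclass(frozen=True)
class TimeSeriesPanel:
    """An ordered collection of persons sharing M variables."""

    persons: tuple[Person, ...]
    variable_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.persons:
            raise PanelValidationError("panel contains no persons")
        m = self.persons[0].segments[0].shape[1]
        names = self.variable_names or tuple(f"v{j}" for j in range(m))
        object.__setattr__(self, "variable_names", tuple(names))
        if len(self.variable_names) != m:
            raise PanelValidationError(
                f"{len(self.variable_names)} variable names for {m} variables"
            )
        ids = [p.person_id for p in self.persons]
        if len(set(ids)) != len(ids):
            raise PanelValidationError("duplicate person ids")
        for p in self.persons:
            if not p.segments:
                raise PanelValidationError(f"person {p.person_id!r} has no segments")
            for s in p.segments:
                if s.ndim != 2 or s.shape[1] != m:
                    raise PanelValidationError(
                        f"person {p.person_id!r}: segment shape {s.shape} "
                        f"inconsistent with M={m}"
                    )
                if s.shape[0] < 2:
                    raise PanelValidationError(
                        f"person {p.person_id!r}: segment of length {s.shape[0]} < 2"
                    )
            if p.usable_pairs < 1:
                raise PanelValidationError(
                    f"person {p.person_id!r} contributes no lagged pairs"
                )

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def person_ids(self) -> tuple[str, ...]:
        return tuple(p.person_id for p in self.persons)

    def pooled(self) -> np.ndarray:
        """All observations of all persons stacked, (sum n_obs, M)."""
        return np.vstack([p.stacked() for p in self.persons])


def panel_from_arrays(
    data: dict[str, np.ndarray | list[np.ndarray]],
    variable_names: tuple[str, ...] | None = None,
) -> TimeSeriesPanel:
    """Build a panel from ``{person_id: array or list of segment arrays}``."""
    persons = []
    for pid, arrs in data.items():
        if isinstance(arrs, np.ndarray):
            arrs = [arrs]
        segs = tuple(np.asarray(a, dtype=float) for a in arrs)
        persons.append(Person(str(pid), segs))
    return TimeSeriesPanel(tuple(persons), tuple(variable_names or ()))


def _split_segments(values: np.ndarray, times: np.ndarray, gap_unit: float,
                    pid: str) -> list[np.ndarray]:
    """Split a person's time-sorted block wherever spacing != gap_unit."""
    # relative tolerance 1e-9 on the nominal gap absorbs float time arithmetic
    gaps = np.diff(times)
    breaks = np.flatnonzero(np.abs(gaps - gap_unit) > 1e-9 * max(abs(gap_unit), 1.0))
    segments, dropped = [], 0
    for chunk in np.split(values, breaks + 1):
        if chunk.shape[0] >= 2:
            segments.append(chunk)
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "person %r: dropped %d length-1 segment(s) (no lagged pairs)",
            pid, dropped,
        )
    return segments


def read_panel(
    path,
    id_column: str,
    time_column: str,
    gap_unit: float = 1.0,
) -> TimeSeriesPanel:
    """Read a long-format delimited panel and segment it by sampling gaps.

    Rows are grouped by person and sorted by time; consecutive rows whose
    time difference equals ``gap_unit`` (relative tolerance 1e-9) join one
    segment, a larger or smaller gap starts a new one.  Rows containing a
    missing variable value are dropped and split the segment at that row.
    Persons left without any lagged pair are removed with a warning.
    """
    if gap_unit <= 0:
        raise ParameterError(f"gap_unit must be positive, got {gap_unit}")
    df = pd.read_csv(path)
    for col in (id_column, time_column):
        if col not in df.columns:
            raise PanelFormatError(f"column {col!r} not found in {path}")
    var_cols = [c for c in df.columns
                if c not in (id_column, time_column, "segment")]
    if not var_cols:
        raise PanelFormatError("no variable columns found")
    for c in var_cols + [time_column]:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()
                     & df[c].notna()]
            row = int(bad.index[0]) + 2 if len(bad) else "?"  # 1-based + header
            raise PanelParseError(
                f"non-numeric value in column {c!r} near file row {row}"
            ) from exc

    persons = []
    for pid, grp in df.groupby(id_column, sort=False):
        grp = grp.sort_values(time_column, kind="stable")
        times = grp[time_column].to_numpy(dtype=float)
        if np.any(np.diff(times) == 0):
            raise PanelValidationError(
                f"duplicate (person, time) rows for person {pid!r}"
            )
        values = grp[var_cols].to_numpy(dtype=float)
        # a row with any missing variable splits the segment at that row
        ok = np.isfinite(values).all(axis=1)
        if not ok.all():
            logger.warning(
                "person %r: dropped %d row(s) with missing values",
                pid, int((~ok).sum()),
            )
            # force a break on both sides of each dropped row by perturbing
            # the grouping: treat runs of valid rows independently
            segments = []
            for start, stop in _runs(ok):
                segments.extend(
                    _split_segments(values[start:stop], times[start:stop],
                                    gap_unit, str(pid))
                )
        else:
            segments = _split_segments(values, times, gap_unit, str(pid))
        if segments:
            persons.append(Person(str(pid), tuple(segments)))
        else:
            logger.warning("person %r removed: no usable lagged pairs", pid)
    if not persons:
        raise PanelValidationError("no persons with usable data remain")
    return TimeSeriesPanel(tuple(persons), tuple(var_cols))


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of consecutive True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    splits = np.flatnonzero(np.diff(idx) > 1)
    for chunk in np.split(idx, splits + 1):
        yield int(chunk[0]), int(chunk[-1]) + 1


def write_panel(panel: TimeSeriesPanel, path, id_column: str = "person",
                time_column: str = "time") -> None:
    """Write one row per retained observation, with a segment index column.

    Times are synthesized so that observations within a segment are one
    unit apart and segments are separated by a two-unit jump; reading the
    file back with ``gap_unit=1`` reproduces the panel exactly.
    """
    rows = []
    for p in panel.persons:
        t = 0.0
        for seg_idx, seg in enumerate(p.segments):
            for row in seg:
                rows.append((p.person_id, t, seg_idx, *row))
                t += 1.0
            t += 1.0  # leave a gap so segment boundaries survive round-trip
    df = pd.DataFrame(
        rows, columns=[id_column, time_column, "segment", *panel.variable_names]
    )
    df.to_csv(path, index=False)


def center_panel(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Subtract each person's own variable means (pooled across segments).

    Person-mean centering removes between-person differences in level so
    that a common intercept per cluster is tenable; it is idempotent.
    """
    persons = []
    for p in panel.persons:
        mean = p.stacked().mean(axis=0)
        persons.append(replace(p, segments=tuple(s - mean for s in p.segments)))
    return TimeSeriesPanel(tuple(persons), panel.variable_names)


def _mode_proportion(x: np.ndarray) -> float:
    """Proportion of entries equal to the modal value (ties -> smallest mode)."""
    vals, counts = np.unique(x, return_counts=True)
    # np.unique sorts, so the first argmax is the smallest modal value
    return counts[np.argmax(counts)] / x.size


def screen_low_variance(
    panel: TimeSeriesPanel, modus_threshold: float = 0.90
) -> tuple[TimeSeriesPanel, dict]:
    """Remove persons with a near-constant variable.

    A person is removed when, for at least one variable, the proportion of
    occasions equal to that person's modal value meets or exceeds
    ``modus_threshold``.  Such series carry too little within-person
    variance to inform dynamics.  Returns the screened panel and a report
    with the per-person, per-variable modal proportions.
    """
    if not (0 < modus_threshold <= 1):
        raise ParameterError(
            f"modus_threshold must be in (0, 1], got {modus_threshold}"
        )
    proportions: dict[str, dict[str, float]] = {}
    removed, kept = [], []
    for p in panel.persons:
        x = p.stacked()
        props = {
            name: _mode_proportion(x[:, j])
            for j, name in enumerate(panel.variable_names)
        }
        proportions[p.person_id] = props
        if any(v >= modus_threshold for v in props.values()):
            removed.append(p.person_id)
        else:
            kept.append(p)
    report = {
        "rule": "remove person if any variable equals its per-person modal "
                "value in at least a fraction `threshold` of occasions",
        "threshold": modus_threshold,
        "mode_proportions": proportions,
        "removed_persons": removed,
    }
    if removed:
        logger.info("screened out %d person(s): %s", len(removed), removed)
    if not kept:
        raise PanelValidationError("screening removed every person")
    return TimeSeriesPanel(tuple(kept), panel.variable_names), report
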