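"""Score detected beats against a reference annotation.

Two quality metrics, matching how wearable beat detectors are judged
against a clinical ECG:

* relative peak-to-peak **interval RMSE**, in percent of each reference
  interval — unit-free, so recordings at different heart rates pool;
* the **missed-beat count** — reference beats with no detected partner,
  visible as gaps spanning more than one reference interval.

Because the peripheral pulse wave lags cardiac electrical activation by
the pulse-transit time (plus processing), a constant offset between the
two series is physiological, not an error: matching removes the median
offset before pairing beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import BeatSeries

__all__ = [
    "MatchResult",
    "ValidationReport",
    "PooledSummary",
    "match_beats",
    "interval_rmse_percent",
    "count_missed_beats",
    "validate_beats",
    "pool_reports",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing of reference and measured beats.

    ``ref_idx``/``meas_idx`` index into the original series; ``offset_s``
    is the constant lag (median measured-minus-reference difference)
    removed before pairing. Unmatched reference beats are split into those
    interior to the measured record (candidate misses) and those before
    its first or after its last beat (edge-excluded).
    """

    ref_times: np.ndarray
    meas_times: np.ndarray
    ref_idx: np.ndarray
    meas_idx: np.ndarray
    unmatched_ref_idx: np.ndarray
    unmatched_meas_idx: np.ndarray
    edge_excluded_ref_idx: np.ndarray
    offset_s: float

    @property
    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.ref_times.tolist(), self.meas_times.tolist()))

    @property
    def n_matched(self) -> int:
        return int(self.ref_idx.size)


@dataclass(frozen=True)
class ValidationReport:
    """Interval RMSE and beat-count bookkeeping for one recording."""

    rmse_percent: float
    n_reference_beats: int
    n_missed: int
    n_extra: int
    matched_pairs: list[tuple[float, float]]
    n_edge_excluded: int = 0

    def __post_init__(self) -> None:
        if self.rmse_percent < 0:
            raise ValueError("rmse_percent must be non-negative")
        if (self.n_missed + len(self.matched_pairs) + self.n_edge_excluded
                != self.n_reference_beats):
            raise ValueError("matched + missed + edge-excluded must equal "
                             "n_reference_beats")


@dataclass(frozen=True)
class PooledSummary:
    """Across-recording summary: mean/SD of RMSE, beat and miss totals."""

    mean_rmse_percent: float
    sd_rmse_percent: float
    total_beats: int
    total_missed: int
    n_recordings: int
    sd_defined: bool = True


def _to_times(series) -> np.ndarray:
    if isinstance(series, BeatSeries):
        return series.times
    return np.asarray(series, dtype=float)


def match_beats(ref, meas, tol_s: float = 0.4) -> MatchResult:
    """Pair measured beats with reference beats within ``tol_s``.

    The median offset of measured minus nearest-reference times is removed
    first (constant pulse-transit / processing lag), then beats are paired
    greedily in time order: each reference beat takes the nearest still
    unclaimed measured beat within the tolerance. With ``tol_s`` below
    half the minimum plausible inter-beat interval the pairing is
    one-to-one and order-preserving.
    """
    ref_t = _to_times(ref)
    meas_t = _to_times(meas)
    if ref_t.size == 0:
        raise ValueError("reference beat series is empty")
    if tol_s <= 0:
        raise ValueError("tol_s must be positive")

    if meas_t.size == 0:
        return MatchResult(np.array([]), np.array([]),
                           np.array([], int), np.array([], int),
                           np.arange(ref_t.size), np.array([], int),
                           np.arange(ref_t.size), 0.0)

    # constant-lag estimate: median of measured minus nearest reference
    nearest = np.searchsorted(ref_t, meas_t)
    nearest = np.clip(nearest, 1, ref_t.size - 1) if ref_t.size > 1 else \
        np.zeros(meas_t.size, int)
    if ref_t.size > 1:
        left = ref_t[nearest - 1]
        right = ref_t[nearest]
        use_left = (meas_t - left) < (right - meas_t)
        near_ref = np.where(use_left, left, right)
    else:
        near_ref = ref_t[nearest]
    offset = float(np.median(meas_t - near_ref))
    shifted = meas_t - offset

    ref_match = np.full(ref_t.size, -1, int)
    j = 0
    for i, rt in enumerate(ref_t):
        # advance to the measured beat nearest this reference beat
        while (j + 1 < shifted.size
               and abs(shifted[j + 1] - rt) <= abs(shifted[j] - rt)):
            j += 1
        if abs(shifted[j] - rt) <= tol_s:
            ref_match[i] = j
            if j + 1 < shifted.size:
                j += 1

    matched_ref = np.flatnonzero(ref_match >= 0)
    matched_meas = ref_match[matched_ref]
    unmatched_ref = np.flatnonzero(ref_match < 0)
    unmatched_meas = np.setdiff1d(np.arange(meas_t.size), matched_meas)

    lo, hi = shifted[0], shifted[-1]
    interior = (ref_t[unmatched_ref] >= lo) & (ref_t[unmatched_ref] <= hi)
    edge_excluded = unmatched_ref[~interior]

    return MatchResult(ref_t[matched_ref], meas_t[matched_meas],
                       matched_ref, matched_meas,
                       unmatched_ref[interior], unmatched_meas,
                       edge_excluded, offset)


def interval_rmse_percent(matched) -> float:
    """Relative RMSE (%) of measured vs reference peak-to-peak intervals.

    For successive matched pairs with reference interval r_i and measured
    interval m_i,

        RMSE = 100 * sqrt( mean( ((m_i - r_i) / r_i)^2 ) ).

    Given a :class:`MatchResult`, intervals are formed only between beats
    matched at *consecutive* reference indices (a gap in the matching
    breaks the interval chain). A plain sequence of (ref_time, meas_time)
    pairs is treated as consecutively matched.
    """
    if isinstance(matched, MatchResult):
        ref_t, meas_t = matched.ref_times, matched.meas_times
        consecutive = np.diff(matched.ref_idx) == 1
    else:
        pairs = np.asarray(list(matched), dtype=float)
        if pairs.size == 0:
            raise ValueError("need at least 3 matched pairs (2 intervals)")
        ref_t, meas_t = pairs[:, 0], pairs[:, 1]
        consecutive = np.ones(ref_t.size - 1, bool) if ref_t.size else \
            np.array([], bool)

    r = np.diff(ref_t)[consecutive]
    m = np.diff(meas_t)[consecutive]
    if r.size < 2:
        raise ValueError("need at least 2 consecutive matched intervals")
    rel = (m - r) / r
    return float(100.0 * np.sqrt(np.mean(rel ** 2)))


def count_missed_beats(ref, meas, tol_s: float = 0.4) -> int:
    """Reference beats with no detected partner, interior to the record.

    A measured interval spanning k reference intervals contributes k-1
    misses; equivalently, the count of unmatched reference beats between
    the first and last measured beat. Beats before the first or after the
    last measured beat are edge effects, not misses.
    """
    return int(match_beats(ref, meas, tol_s).unmatched_ref_idx.size)


def validate_beats(ref, meas, tol_s: float = 0.4) -> ValidationReport:
    """Full scoring of one recording: RMSE, missed and extra counts."""
    m = match_beats(ref, meas, tol_s)
    try:
        rmse = interval_rmse_percent(m)
    except ValueError:  # fewer than 2 consecutive matched intervals
        rmse = float("nan")
    return ValidationReport(
        rmse_percent=rmse,
        n_reference_beats=int(_to_times(ref).size),
        n_missed=int(m.unmatched_ref_idx.size),
        n_extra=int(m.unmatched_meas_idx.size),
        matched_pairs=m.pairs,
        n_edge_excluded=int(m.edge_excluded_ref_idx.size),
    )


def pool_reports(reports) -> PooledSummary:
    """Pool per-recording reports: mean/SD of RMSE, summed totals.

    With a single report the sample SD is undefined; it is reported as 0.0
    with ``sd_defined=False``.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    rmses = np.array([r.rmse_percent for r in reports])
    sd_defined = len(reports) > 1
    return PooledSummary(
        mean_rmse_percent=float(np.mean(rmses)),
        sd_rmse_percent=float(np.std(rmses, ddof=1)) if sd_defined else 0.0,
        total_beats=int(sum(r.n_reference_beats for r in reports)),
        total_missed=int(sum(r.n_missed for r in reports)),
        n_recordings=len(reports),
        sd_defined=sd_defined,
    )
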