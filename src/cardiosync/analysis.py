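"""Outcome aggregation and paired testing for the stimulation study.

Covers the study's three outcome families:

* questionnaires — 3 usability items (SUS, 5-point) and 7 simulator
  sickness items (SSQ, 4-point), each summarised by the unweighted mean;
* pain measures — fixed-pressure pain ratings (Algopeg, 0-10 numerical
  rating scale at finger and earlobe) and pressure-pain thresholds
  (Somedic algometer, kPa at the finger), reduced to signed per-condition
  deltas with the convention that *positive = more pain-sensitive* for
  both instruments (ratings go up, thresholds come down);
* paired condition contrasts — normality-gated: Lilliefors-corrected
  Kolmogorov-Smirnov on the paired differences, then a one-sided paired
  t test if normal, otherwise the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "QuestionnaireSummary",
    "PairedTestReport",
    "MissingDataError",
    "SUS_RANGE",
    "SSQ_RANGE",
    "OWNERSHIP_RANGE",
    "aggregate_sus",
    "aggregate_ssq",
    "aggregate_ownership",
    "compute_pain_deltas",
    "paired_condition_test",
    "ownership_contrast",
    "signed_rank_statistic",
]

SUS_RANGE = (1, 5)
SSQ_RANGE = (1, 4)
OWNERSHIP_RANGE = (0, 6)


class MissingDataError(ValueError):
    """A required participant/block/phase/side cell is absent."""

    def __init__(self, missing_keys):
        self.missing_keys = list(missing_keys)
        super().__init__("missing study-table cells: "
                         + "; ".join(map(str, self.missing_keys)))


@dataclass(frozen=True)
class QuestionnaireSummary:
    """Item means, per-participant composites and the group composite."""

    item_means: np.ndarray
    participant_composites: np.ndarray
    group_mean: float
    group_sd: float
    scale: tuple[int, int]


def _aggregate_items(items, n_items: int, scale: tuple[int, int],
                     name: str) -> QuestionnaireSummary:
    arr = np.atleast_2d(np.asarray(items, dtype=float))
    if arr.shape[1] != n_items:
        raise ValueError(f"{name} expects {n_items} items per response, "
                         f"got {arr.shape[1]}")
    lo, hi = scale
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"{name} item scores must lie in [{lo}, {hi}]")
    composites = arr.mean(axis=1)
    return QuestionnaireSummary(
        item_means=arr.mean(axis=0),
        participant_composites=composites,
        group_mean=float(composites.mean()),
        group_sd=float(composites.std(ddof=1)) if composites.size > 1
        else 0.0,
        scale=scale,
    )


def aggregate_sus(responses) -> QuestionnaireSummary:
    """Composite usability score: unweighted mean of the 3 SUS items.

    ``responses`` is (n_participants, 3) — or a single row, e.g. the
    published item means, whose composite is then the group composite.
    """
    return _aggregate_items(responses, 3, SUS_RANGE, "SUS")


def aggregate_ssq(responses) -> QuestionnaireSummary:
    """Composite sickness score: unweighted mean of the 7 SSQ items."""
    return _aggregate_items(responses, 7, SSQ_RANGE, "SSQ")


def aggregate_ownership(responses) -> QuestionnaireSummary:
    """Per-condition ownership score: mean of the 7 items (0-6 scale)."""
    return _aggregate_items(responses, 7, OWNERSHIP_RANGE, "ownership")


# -- pain deltas --------------------------------------------------------

#: Sign convention: positive delta = increased pain sensitivity.
#: Algopeg reports pain (higher = worse) so delta = post - pre;
#: Somedic reports a threshold (lower = worse) so delta = pre - post.
_DELTA_SIGN = {"algopeg": ("post", "pre"), "somedic": ("pre", "post")}


def compute_pain_deltas(measures: pd.DataFrame) -> pd.DataFrame:
    """Reduce raw pain measurements to per-condition signed deltas.

    Expects long format with columns participant, block, condition, phase
    (pre|post), instrument (algopeg|somedic), site, side (left|right),
    value. Per block: bilateral (left/right) mean per phase, then the
    signed pre/post difference per the instrument's convention; per
    condition: the mean of its two block deltas.

    Raises :class:`MissingDataError` naming every absent phase/side cell.
    """
    df = measures.copy()
    required = {"participant", "block", "condition", "phase", "instrument",
                "site", "side", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    bad_inst = set(df["instrument"]) - set(_DELTA_SIGN)
    if bad_inst:
        raise ValueError(f"unknown instruments: {sorted(bad_inst)}")

    keys = ["participant", "condition", "instrument", "site", "block"]
    missing = []
    for key, grp in df.groupby(keys):
        for phase in ("pre", "post"):
            sides = set(grp.loc[grp["phase"] == phase, "side"])
            if sides != {"left", "right"}:
                missing.append(key + (phase, "sides=" + ",".join(sorted(sides))))
    if missing:
        raise MissingDataError(missing)

    bilateral = (df.groupby(keys + ["phase"])["value"].mean().unstack("phase"))
    inst = bilateral.index.get_level_values("instrument")
    hi = np.where(inst == "algopeg", bilateral["post"], bilateral["pre"])
    lo = np.where(inst == "algopeg", bilateral["pre"], bilateral["post"])
    block_delta = pd.Series(hi - lo, index=bilateral.index, name="delta")

    n_blocks = block_delta.groupby(
        ["participant", "condition", "instrument", "site"]).size()
    bad = n_blocks[n_blocks != 2]
    if len(bad):
        raise MissingDataError([k + ("expected 2 blocks, got %d" % v,)
                                for k, v in bad.items()])

    out = (block_delta.groupby(
        ["participant", "condition", "instrument", "site"]).mean()
        .reset_index())
    return out


# -- paired testing -----------------------------------------------------

@dataclass(frozen=True)
class PairedTestReport:
    """Outcome of a normality-gated paired contrast.

    ``branch`` is "t" (normal differences, one-sided paired t test),
    "wilcoxon" (signed-rank), or "degenerate" (all differences zero — no
    test is meaningful).
    """

    branch: str
    statistic: float
    p_value: float
    n: int
    alternative: str
    normality_stat: float | None = None
    normality_p: float | None = None
    z_statistic: float | None = None

    @property
    def significant(self) -> bool:
        return self.branch != "degenerate" and self.p_value < 0.05


def paired_condition_test(sync_values, async_values, alpha: float = 0.05,
                          alternative: str = "less") -> PairedTestReport:
    """Normality-gated paired contrast of the two conditions.

    Differences sync - async are checked for normality with the
    Lilliefors-corrected KS test (mean and SD estimated from the data).
    Normal (p > alpha): one-sided paired t test, default direction
    ``sync < async`` (the analgesia hypothesis: lower pain sensitivity
    under synchronous stimulation). Non-normal: Wilcoxon signed rank
    (Pratt zero handling, normal approximation).
    """
    x = np.asarray(sync_values, dtype=float)
    y = np.asarray(async_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    if np.all(d == 0):
        return PairedTestReport("degenerate", 0.0, 1.0, x.size, alternative)

    if np.ptp(d) == 0:
        # constant non-zero shift: trivially non-normal for KS purposes,
        # but the signed-rank test handles it exactly
        ks_stat, ks_p = np.inf, 0.0
    else:
        ks_stat, ks_p = lilliefors(d, dist="norm")

    if ks_p > alpha:
        res = stats.ttest_rel(x, y, alternative=alternative)
        return PairedTestReport("t", float(res.statistic),
                                float(res.pvalue), x.size, alternative,
                                ks_stat, ks_p)
    res = stats.wilcoxon(x, y, alternative=alternative,
                         zero_method="pratt", correction=False,
                         method="approx")
    return PairedTestReport("wilcoxon", float(res.statistic),
                            float(res.pvalue), x.size, alternative,
                            ks_stat, ks_p,
                            z_statistic=float(res.zstatistic))


def signed_rank_statistic(diffs) -> float:
    """W+ : sum of ranks of positive differences, Pratt zero handling.

    Zeros are ranked with everything else (average ranks on ties) and then
    discarded; W+ sums the ranks of the strictly positive differences.
    """
    d = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def ownership_contrast(sync_scores, async_scores,
                       alternative: str = "two-sided") -> PairedTestReport:
    """Wilcoxon signed-rank contrast of per-condition ownership scores.

    Zero differences are handled by the Pratt method (ranked, then
    dropped); ties get average ranks; the p-value uses the normal
    approximation, reported alongside Z. The statistic is W+ (sum of the
    positive-difference ranks).
    """
    x = np.asarray(sync_scores, dtype=float)
    y = np.asarray(async_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    d = x - y
    if np.all(d == 0):
        return PairedTestReport("degenerate", 0.0, 1.0, x.size, alternative)
    res = stats.wilcoxon(x, y, alternative=alternative,
                         zero_method="pratt", correction=False,
                         method="approx")
    return PairedTestReport("wilcoxon", signed_rank_statistic(d),
                            float(res.pvalue), x.size, alternative,
                            z_statistic=float(res.zstatistic))
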