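"""Synthetic study tables: questionnaires, ownership and pain measures.

Emulates the outcome data of a 20-participant within-subject session
(2 synchronous + 2 asynchronous 5-minute blocks in randomized order, pain
tested before and after every block). Defaults reflect the study
conditions: questionnaire item distributions centred on the published
item means, near-floor ownership ratings, and *no true condition effect*
on pain (the study's null result), with measurement noise at levels a
pressure-algometry session realistically shows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stimulation import plan_session

__all__ = [
    "SOMEDIC_REPETITIONS",
    "SUS_ITEM_MEANS",
    "SUS_ITEM_SDS",
    "SSQ_ITEM_MEANS",
    "SSQ_ITEM_SDS",
    "simulate_questionnaires",
    "simulate_ownership",
    "simulate_pain_measures",
]

#: Published per-item distributions of the merged questionnaire:
#: 3 usability items (5-point) and 7 simulator-sickness items (4-point).
SUS_ITEM_MEANS = (4.54, 4.36, 4.36)
SUS_ITEM_SDS = (0.52, 0.67, 0.5)
SSQ_ITEM_MEANS = (1.0, 1.0, 1.45, 1.09, 1.27, 1.0, 1.0)
SSQ_ITEM_SDS = (0.0, 0.0, 0.93, 0.3, 0.46, 0.0, 0.0)

N_PARTICIPANTS = 20
#: Each stored Somedic threshold is the mean of this many repetitions.
SOMEDIC_REPETITIONS = 3

# measurement noise per single reading; chosen to give block-to-block
# delta scatter of the order the algometers show in practice
ALGOPEG_NOISE_SD = 0.4       # NRS points
SOMEDIC_NOISE_SD = 30.0      # kPa, per repetition
ALGOPEG_BASELINE = (3.0, 1.2)   # mean, SD across participants (NRS)
SOMEDIC_BASELINE = (350.0, 80.0)  # mean, SD across participants (kPa)


def _likert(rng, mean, sd, lo, hi, size):
    vals = np.rint(rng.normal(mean, sd, size)) if sd > 0 else \
        np.full(size, round(mean))
    return np.clip(vals, lo, hi).astype(int)


def simulate_questionnaires(n_participants: int = N_PARTICIPANTS,
                            seed: int = 0) -> pd.DataFrame:
    """Per-participant SUS (3 items, 1-5) and SSQ (7 items, 1-4) scores.

    Items are discretised clipped normals around the published item
    means/SDs.
    """
    rng = np.random.default_rng(seed)
    data = {"participant": np.arange(1, n_participants + 1)}
    for i, (m, s) in enumerate(zip(SUS_ITEM_MEANS, SUS_ITEM_SDS), 1):
        data[f"sus_{i}"] = _likert(rng, m, s, 1, 5, n_participants)
    for i, (m, s) in enumerate(zip(SSQ_ITEM_MEANS, SSQ_ITEM_SDS), 1):
        data[f"ssq_{i}"] = _likert(rng, m, s, 1, 4, n_participants)
    return pd.DataFrame(data)


def simulate_ownership(n_participants: int = N_PARTICIPANTS,
                       seed: int = 0, n_items: int = 7) -> pd.DataFrame:
    """Per-participant, per-condition ownership items (0-6 scale).

    Ratings sit near the floor (median 0, upper quartile ~1.5) with no
    systematic condition difference, as the illusion questionnaires of
    seated minimal-movement setups typically show.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(1, n_participants + 1):
        for cond in ("sync", "async"):
            items = np.clip(rng.geometric(0.65, n_items) - 1, 0, 6)
            rows.append({"participant": p, "condition": cond,
                         **{f"own_{i+1}": v for i, v in enumerate(items)}})
    return pd.DataFrame(rows)


def simulate_pain_measures(n_participants: int = N_PARTICIPANTS,
                           seed: int = 0,
                           sync_effect_algopeg: float = 0.0,
                           sync_effect_somedic_kpa: float = 0.0
                           ) -> pd.DataFrame:
    """Long-format pain table for a full randomized session per participant.

    Per participant: a randomized block order (2 sync + 2 async), and for
    every block pre and post measurements of

    * Algopeg pain ratings (NRS 0-10) at finger and earlobe, both sides;
    * Somedic pressure-pain thresholds (kPa) at the finger, both sides,
      each stored value the mean of 3 repetitions.

    ``sync_effect_*`` inject a true synchronous-condition change on the
    post measurement (negative Algopeg effect = analgesia; positive
    Somedic effect = raised threshold = analgesia); both default to 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(1, n_participants + 1):
        plan = plan_session(seed=int(rng.integers(2 ** 31)))
        base_nrs = {site: np.clip(rng.normal(*ALGOPEG_BASELINE), 0.5, 9.5)
                    for site in ("finger", "earlobe")}
        base_kpa = max(rng.normal(*SOMEDIC_BASELINE), 100.0)
        for block, (cond, _) in enumerate(plan.blocks, start=1):
            for phase in ("pre", "post"):
                algo_shift = (sync_effect_algopeg
                              if phase == "post" and cond == "sync" else 0.0)
                som_shift = (sync_effect_somedic_kpa
                             if phase == "post" and cond == "sync" else 0.0)
                for site in ("finger", "earlobe"):
                    for side in ("left", "right"):
                        v = np.clip(base_nrs[site] + algo_shift
                                    + rng.normal(0, ALGOPEG_NOISE_SD),
                                    0.0, 10.0)
                        rows.append((p, block, cond, phase, "algopeg",
                                     site, side, round(float(v), 1)))
                for side in ("left", "right"):
                    reps = rng.normal(base_kpa + som_shift,
                                      SOMEDIC_NOISE_SD,
                                      SOMEDIC_REPETITIONS)
                    rows.append((p, block, cond, phase, "somedic",
                                 "finger", side, float(np.mean(reps))))
    return pd.DataFrame(rows, columns=["participant", "block", "condition",
                                       "phase", "instrument", "site",
                                       "side", "value"])
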