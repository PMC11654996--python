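"""Heartbeat-contingent flash scheduling for the cardiovisual illusion.

Two conditions drive the avatar's silhouette:

* **synchronous** — one flash per detected beat, delayed only by the
  constant sensing/transport lag (~50 ms);
* **asynchronous ("shuffling mode")** — flashes at 80, 90, 110 or 120 %
  of the actual heart rate, the active factor re-drawn periodically, so
  the rate is plausibly cardiac but never phase-locked to the heart.

The flash itself jumps immediately to peak brightness and decays
exponentially back to translucent; overlapping flashes take the maximum
of their envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import BeatSeries

__all__ = [
    "EnvelopeParams",
    "FlashSchedule",
    "SessionPlan",
    "ASYNC_FACTORS",
    "BLOCK_DURATION_S",
    "BLOCK_GAP_S",
    "DEFAULT_LAG_S",
    "schedule_sync",
    "schedule_async",
    "envelope_brightness",
    "render_envelope",
    "plan_session",
]

#: Asynchronous rate factors: 80/90/110/120 % of the actual heart rate.
ASYNC_FACTORS = (0.8, 0.9, 1.1, 1.2)
#: Stimulation block length (5 minutes) and inter-block rest (3 minutes).
BLOCK_DURATION_S = 300.0
BLOCK_GAP_S = 180.0
#: Constant sensing + transport lag between pulse wave and shown flash.
DEFAULT_LAG_S = 0.05
#: Epoch length after which the async factor is re-drawn.
FACTOR_EPOCH_S = 60.0


@dataclass(frozen=True)
class EnvelopeParams:
    """Flash brightness envelope: instant rise, exponential fade.

    ``brightness(t) = peak * exp(-t / decay_time_constant_s)`` for t >= 0.
    """

    peak_brightness: float = 1.0
    decay_time_constant_s: float = 0.4

    def __post_init__(self) -> None:
        if self.peak_brightness <= 0 or self.decay_time_constant_s <= 0:
            raise ValueError("envelope parameters must be positive")


@dataclass(frozen=True)
class FlashSchedule:
    """Timed flash onsets with mode, rate factor(s) and envelope.

    ``factor`` is 1.0 in the synchronous condition; in the asynchronous
    condition ``onset_factors`` records the factor active at each onset.
    """

    onsets: np.ndarray
    mode: str
    factor: float = 1.0
    onset_factors: np.ndarray | None = None
    envelope: EnvelopeParams = EnvelopeParams()

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if self.mode not in ("sync", "async"):
            raise ValueError("mode must be 'sync' or 'async'")
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.mode == "sync" and self.factor != 1.0:
            raise ValueError("synchronous schedules have factor 1.0")
        if self.mode == "async":
            facs = (self.onset_factors if self.onset_factors is not None
                    else [self.factor])
            if not set(np.round(np.unique(facs), 10)) <= set(ASYNC_FACTORS):
                raise ValueError(
                    f"async factors must come from {ASYNC_FACTORS}")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class SessionPlan:
    """Randomized order of 2 synchronous + 2 asynchronous 5-min blocks."""

    blocks: tuple[tuple[str, float], ...]
    seed: int
    gap_s: float = BLOCK_GAP_S

    def __post_init__(self) -> None:
        conditions = [c for c, _ in self.blocks]
        if sorted(conditions) != ["async", "async", "sync", "sync"]:
            raise ValueError("a session is exactly 2 sync + 2 async blocks")
        if any(d != BLOCK_DURATION_S for _, d in self.blocks):
            raise ValueError(f"each block lasts {BLOCK_DURATION_S} s")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.blocks)


def schedule_sync(beats: BeatSeries, lag_s: float = DEFAULT_LAG_S,
                  envelope: EnvelopeParams = EnvelopeParams()
                  ) -> FlashSchedule:
    """One flash onset per beat at ``beat_time + lag_s``.

    Causal by construction: each onset depends only on its own beat.
    """
    if lag_s < 0:
        raise ValueError("lag_s must be non-negative")
    times = beats.times if isinstance(beats, BeatSeries) else \
        np.asarray(beats, float)
    return FlashSchedule(times + lag_s, mode="sync", envelope=envelope)


def schedule_async(hr_estimate_bpm, duration_s: float,
                   factors=ASYNC_FACTORS, shuffle_seed: int = 0,
                   envelope: EnvelopeParams = EnvelopeParams(),
                   epoch_s: float = FACTOR_EPOCH_S) -> FlashSchedule:
    """Shuffled-rate flash onsets over ``duration_s`` seconds.

    The instantaneous inter-onset interval at time t is
    ``60 / (factor * hr(t))``; the active factor is re-drawn uniformly
    from ``factors`` at t=0 and at every ``epoch_s`` boundary.
    ``hr_estimate_bpm`` may be a scalar (constant heart rate) or a pair
    of arrays ``(times_s, bpm)`` interpolated linearly.

    A factor of 1.0 is rejected: it would flash in synchrony.
    """
    factors = tuple(float(f) for f in np.atleast_1d(factors))
    if any(abs(f - 1.0) < 1e-12 for f in factors):
        raise ValueError("factor 1.0 would be synchronous stimulation")
    if not factors:
        raise ValueError("need at least one rate factor")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")

    if np.isscalar(hr_estimate_bpm):
        hr_of = lambda t: float(hr_estimate_bpm)
        if hr_estimate_bpm <= 0:
            raise ValueError("heart-rate estimate must be positive")
    else:
        ht, hv = (np.asarray(a, float) for a in hr_estimate_bpm)
        if np.any(hv <= 0):
            raise ValueError("heart-rate estimate must be positive")
        hr_of = lambda t: float(np.interp(t, ht, hv))

    rng = np.random.default_rng(shuffle_seed)
    onsets, onset_factors = [], []
    t = 0.0
    epoch = -1
    factor = factors[0]
    while t < duration_s:
        cur_epoch = int(t // epoch_s)
        if cur_epoch != epoch:
            epoch = cur_epoch
            factor = float(rng.choice(factors))
        onsets.append(t)
        onset_factors.append(factor)
        t += 60.0 / (factor * hr_of(t))
    return FlashSchedule(np.asarray(onsets), mode="async",
                         factor=onset_factors[0] if onset_factors else
                         factors[0],
                         onset_factors=np.asarray(onset_factors),
                         envelope=envelope)


def envelope_brightness(t_since_onset_s, params: EnvelopeParams =
                        EnvelopeParams()):
    """Brightness of a single flash ``t`` seconds after onset.

    1.0 at onset (instant jump to the brightest appearance), exponential
    fade with the configured time constant. Negative times (before the
    flash) are 0.
    """
    t = np.asarray(t_since_onset_s, dtype=float)
    out = np.where(t >= 0,
                   params.peak_brightness
                   * np.exp(-np.maximum(t, 0.0)
                            / params.decay_time_constant_s),
                   0.0)
    return float(out) if np.isscalar(t_since_onset_s) else out


def render_envelope(schedule: FlashSchedule, t: np.ndarray) -> np.ndarray:
    """Combined brightness over time; overlapping flashes take the max."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    tau = schedule.envelope.decay_time_constant_s
    for onset in schedule.onsets:
        np.maximum(out, envelope_brightness(t - onset, schedule.envelope),
                   out=out)
    return out


def plan_session(seed: int) -> SessionPlan:
    """Uniformly random ordering of {sync, sync, async, async}.

    Unrestricted randomization: all 4! permutations are equally likely, so
    each of the 6 distinguishable condition orderings has probability 1/6.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    conditions = np.array(["sync", "sync", "async", "async"])
    order = rng.permutation(4)
    blocks = tuple((str(conditions[i]), BLOCK_DURATION_S) for i in order)
    return SessionPlan(blocks=blocks, seed=seed)
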