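"""Synthetic cardiac signals with known ground-truth beat times.

Every downstream component (the causal PPG detector, the ECG-referenced
validator, the flash scheduler) is exercised against traces rendered here,
so the generator keeps the ground truth explicit: a :class:`BeatSeries` of
cardiac event times drives both the ECG rendering (R spike at the beat) and
the PPG rendering (systolic peak delayed by the pulse-transit time).

Morphology is deliberately minimal. A PPG pulse is the sum of two Gaussians
(systolic peak plus a dicrotic bump); an ECG beat is a single narrow R
spike. That is enough to give each beat an unambiguous argmax, which is the
fiducial both detectors report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "BeatSeries",
    "SignalTrace",
    "NoiseSpec",
    "NOISE_PROFILES",
    "PPG_SAMPLING_RATE_HZ",
    "ECG_SAMPLING_RATE_HZ",
    "PTT_WRIST_S",
    "PTT_UPPER_ARM_S",
    "simulate_beat_times",
    "render_ppg",
    "render_ecg",
]

#: Default sampling rates of the two channels (Hz): the smartwatch PPG
#: samples at 134 Hz, the clinical reference ECG at 240 Hz.
PPG_SAMPLING_RATE_HZ = 134.0
ECG_SAMPLING_RATE_HZ = 240.0

#: Default pulse-transit times (s) emulating the two watch positions. The
#: peripheral pressure wave lags cardiac electrical activation by roughly
#: a quarter second at the wrist, slightly less at the upper arm.
PTT_WRIST_S = 0.25
PTT_UPPER_ARM_S = 0.20

# Physiological truncation bounds for inter-beat intervals (s): 30-200 bpm.
_IBI_LO_S = 0.3
_IBI_HI_S = 2.0


@dataclass(frozen=True)
class BeatSeries:
    """Strictly increasing cardiac event times in seconds.

    The unit of truth for all validation: ground-truth simulations, PPG
    detections and ECG reference annotations are all carried as a
    ``BeatSeries`` tagged with a ``source`` label.
    """

    times: np.ndarray
    source: str = "ground_truth"
    min_interval_s: float = 0.2

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("beat times must be a 1-D array")
        if times.size and times[0] < 0:
            raise ValueError("beat times must be non-negative")
        if times.size > 1:
            d = np.diff(times)
            if np.any(d <= 0):
                raise ValueError("beat times must be strictly increasing")
            if np.any(d <= self.min_interval_s):
                raise ValueError(
                    f"inter-beat interval below physiological floor "
                    f"({self.min_interval_s} s)"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def intervals(self) -> np.ndarray:
        """Successive inter-beat (peak-to-peak) intervals in seconds."""
        return np.diff(self.times)

    def shifted(self, dt: float, source: str | None = None) -> "BeatSeries":
        return BeatSeries(self.times + dt, source or self.source,
                          self.min_interval_s)


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled single-channel biosignal.

    ``channel`` is ``"ppg"`` or ``"ecg"``; amplitudes are arbitrary units.
    """

    samples: np.ndarray
    sampling_rate: float
    channel: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("trace must hold at least one sample")
        if self.channel not in ("ppg", "ecg"):
            raise ValueError(f"unknown channel kind {self.channel!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class NoiseSpec:
    """Additive corruption applied to a rendered trace.

    baseline_wander_amp/freq
        slow sinusoidal drift (skin contact, respiration-rate band).
    white_noise_sd
        Gaussian sensor noise, per sample.
    motion_artifact_times/amplitudes
        transient damped-oscillation bursts centred at the listed times,
        emulating brief motion of the sensor against the skin.
    """

    baseline_wander_amp: float = 0.0
    baseline_wander_freq_hz: float = 0.25
    white_noise_sd: float = 0.0
    motion_artifact_times: tuple[float, ...] = ()
    motion_artifact_amplitudes: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_wander_amp < 0 or self.white_noise_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if any(a < 0 for a in self.motion_artifact_amplitudes):
            raise ValueError("artifact amplitudes must be non-negative")
        if len(self.motion_artifact_times) != len(self.motion_artifact_amplitudes):
            raise ValueError("one amplitude per artifact time required")

    def with_seed(self, seed: int) -> "NoiseSpec":
        return replace(self, seed=seed)


#: Named noise profiles used throughout tests and the demo pipeline.
#: "clean" is noise-free; "moderate" carries baseline wander, sensor noise
#: and sparse motion bursts of the qualitative kind real wearable
#: recordings show (minor motion, breathing, sweating).
NOISE_PROFILES: dict[str, NoiseSpec] = {
    "clean": NoiseSpec(),
    "moderate": NoiseSpec(
        baseline_wander_amp=0.3,
        baseline_wander_freq_hz=0.25,
        white_noise_sd=0.05,
        motion_artifact_times=(),
        motion_artifact_amplitudes=(),
    ),
}


def moderate_noise(duration_s: float, seed: int = 0,
                   artifacts_per_minute: float = 0.6) -> NoiseSpec:
    """Moderate profile with motion bursts scattered over ``duration_s``.

    Burst times are drawn uniformly (seeded) so traces of any length get a
    proportionate number of artifacts.
    """
    rng = np.random.default_rng(seed)
    n_art = rng.poisson(artifacts_per_minute * duration_s / 60.0)
    times = tuple(np.sort(rng.uniform(2.0, max(duration_s - 2.0, 2.0), n_art)))
    amps = tuple(rng.uniform(0.5, 1.2, n_art))
    base = NOISE_PROFILES["moderate"]
    return replace(base, motion_artifact_times=times,
                   motion_artifact_amplitudes=amps, seed=seed)


def simulate_beat_times(mean_hr_bpm: float, hrv_sd_s: float,
                        duration_s: float, seed: int = 0) -> BeatSeries:
    """Draw ground-truth heartbeat times over ``duration_s`` seconds.

    Inter-beat intervals are i.i.d. truncated normal with mean
    ``60 / mean_hr_bpm`` and SD ``hrv_sd_s``, truncated to [0.3, 2.0] s.
    The first beat is at t = 0 and beats strictly before ``duration_s``
    are kept. Deterministic under ``seed``.
    """
    if not (30.0 <= mean_hr_bpm <= 220.0):
        raise ValueError("mean_hr_bpm must lie in [30, 220]")
    if hrv_sd_s < 0:
        raise ValueError("hrv_sd_s must be non-negative")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")

    mean_ibi = 60.0 / mean_hr_bpm
    n_guess = int(duration_s / mean_ibi * 1.5) + 10
    rng = np.random.default_rng(seed)

    times = [0.0]
    while times[-1] < duration_s:
        if hrv_sd_s == 0:
            ibis = np.full(n_guess, mean_ibi)
        else:
            a = (_IBI_LO_S - mean_ibi) / hrv_sd_s
            b = (_IBI_HI_S - mean_ibi) / hrv_sd_s
            ibis = stats.truncnorm.rvs(a, b, loc=mean_ibi, scale=hrv_sd_s,
                                       size=n_guess, random_state=rng)
        times.extend(times[-1] + np.cumsum(ibis))
    arr = np.asarray(times)
    return BeatSeries(arr[arr < duration_s], source="ground_truth")


# -- waveform templates -------------------------------------------------

def _ppg_pulse(t: np.ndarray) -> np.ndarray:
    # systolic peak at t=0 plus dicrotic bump 250 ms later
    return (np.exp(-0.5 * (t / 0.07) ** 2)
            + 0.35 * np.exp(-0.5 * ((t - 0.25) / 0.09) ** 2))


def _ecg_spike(t: np.ndarray) -> np.ndarray:
    # narrow dominant R spike (sigma 12 ms, support well under 0.1 s) with
    # small Q/S dips so the argmax near each beat is unambiguous
    return (np.exp(-0.5 * (t / 0.012) ** 2)
            - 0.15 * np.exp(-0.5 * ((t + 0.035) / 0.01) ** 2)
            - 0.2 * np.exp(-0.5 * ((t - 0.035) / 0.012) ** 2))


def _render(beats: BeatSeries, sampling_rate_hz: float, delay_s: float,
            pulse, noise: NoiseSpec | None, channel: str,
            duration_s: float | None, support_s: float) -> SignalTrace:
    if len(beats) == 0:
        raise ValueError("cannot render a trace from an empty BeatSeries")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    if duration_s is None:
        duration_s = beats.times[-1] + delay_s + 1.0
    n = math.ceil(duration_s * sampling_rate_hz)
    t = np.arange(n) / sampling_rate_hz

    x = np.zeros(n)
    for bt in beats.times:
        c = bt + delay_s
        lo = max(0, int((c - support_s) * sampling_rate_hz))
        hi = min(n, int((c + support_s) * sampling_rate_hz) + 1)
        if lo < hi:
            x[lo:hi] += pulse(t[lo:hi] - c)

    if noise is not None:
        x = x + _noise_component(noise, t, duration_s)
    return SignalTrace(x, sampling_rate_hz, channel)


def _noise_component(noise: NoiseSpec, t: np.ndarray,
                     duration_s: float) -> np.ndarray:
    for at in noise.motion_artifact_times:
        if not (0.0 <= at <= duration_s):
            raise ValueError(f"artifact time {at} s outside trace duration")
    rng = np.random.default_rng(noise.seed)
    out = np.zeros_like(t)
    if noise.baseline_wander_amp > 0:
        out += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq_hz * t)
    if noise.white_noise_sd > 0:
        out += rng.normal(0.0, noise.white_noise_sd, t.size)
    # damped 3 Hz oscillation under a 150 ms Gaussian window: transient
    # bursts that fall inside the pulse passband, as real motion does
    for at, amp in zip(noise.motion_artifact_times,
                       noise.motion_artifact_amplitudes):
        out += amp * np.exp(-0.5 * ((t - at) / 0.15) ** 2) * np.sin(
            2 * np.pi * 3.0 * (t - at))
    return out


def render_ppg(beats: BeatSeries,
               sampling_rate_hz: float = PPG_SAMPLING_RATE_HZ,
               ptt_s: float = PTT_WRIST_S,
               noise: NoiseSpec | None = None,
               duration_s: float | None = None) -> SignalTrace:
    """Render a PPG trace whose systolic peak trails each beat by ``ptt_s``.

    Each beat contributes a stereotyped two-Gaussian pulse; the global
    maximum of a single noise-free pulse sits at ``beat_time + ptt_s``
    (the pulse-transit delay of the peripheral pressure wave).
    """
    if ptt_s < 0:
        raise ValueError("ptt_s must be non-negative")
    return _render(beats, sampling_rate_hz, ptt_s, _ppg_pulse, noise,
                   "ppg", duration_s, support_s=0.8)


def render_ecg(beats: BeatSeries,
               sampling_rate_hz: float = ECG_SAMPLING_RATE_HZ,
               noise: NoiseSpec | None = None,
               duration_s: float | None = None) -> SignalTrace:
    """Render an ECG trace with a narrow R spike at each beat time."""
    return _render(beats, sampling_rate_hz, 0.0, _ecg_spike, noise,
                   "ecg", duration_s, support_s=0.15)
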