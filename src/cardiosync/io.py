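"""Readers/writers for traces, beat lists, schedules and run configuration.

Plain-text formats throughout: a trace is a two-column CSV
(``time_s,amplitude``) whose leading ``#`` comment lines carry the
sampling rate and channel kind; a beat list is one time (seconds) per
line with a ``# source:`` header; a flash schedule is
``onset_s,factor,mode``. All round-trips are lossless up to float
formatting (17 significant digits).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectorConfig
from .signals import (BeatSeries, SignalTrace, PPG_SAMPLING_RATE_HZ,
                      ECG_SAMPLING_RATE_HZ, PTT_WRIST_S)
from .stimulation import (ASYNC_FACTORS, DEFAULT_LAG_S, EnvelopeParams,
                          FlashSchedule)

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_config",
    "read_trace",
    "write_trace",
    "read_beats",
    "write_beats",
    "read_schedule",
    "write_schedule",
    "write_json_report",
]


class SchemaError(ValueError):
    """A file is missing required metadata or has an unknown layout."""


# -- traces -------------------------------------------------------------

def write_trace(trace: SignalTrace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# channel: {trace.channel}\n")
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate!r}\n")
        fh.write(f"# t0: {trace.t0!r}\n")
        fh.write("time_s,amplitude\n")
        for t, v in zip(trace.times, trace.samples):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta, n_comment


def read_trace(path) -> SignalTrace:
    path = Path(path)
    meta, skip = _read_header(path)
    for key in ("channel", "sampling_rate_hz"):
        if key not in meta:
            raise SchemaError(f"trace file {path} missing '{key}' header")
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if "amplitude" not in df.columns:
        raise SchemaError(f"trace file {path} missing 'amplitude' column")
    return SignalTrace(df["amplitude"].to_numpy(float),
                       float(meta["sampling_rate_hz"]), meta["channel"],
                       float(meta.get("t0", 0.0)))


# -- beat lists ---------------------------------------------------------

def write_beats(beats: BeatSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# source: {beats.source}\n")
        fh.write("time_s\n")
        for t in beats.times:
            fh.write(f"{float(t)!r}\n")


def read_beats(path, min_interval_s: float = 0.0) -> BeatSeries:
    path = Path(path)
    meta, skip = _read_header(path)
    if "source" not in meta:
        raise SchemaError(f"beat file {path} missing 'source' header")
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    return BeatSeries(df["time_s"].to_numpy(float), meta["source"],
                      min_interval_s=min_interval_s)


# -- schedules ----------------------------------------------------------

def write_schedule(schedule: FlashSchedule, path) -> None:
    path = Path(path)
    factors = (schedule.onset_factors if schedule.onset_factors is not None
               else np.full(len(schedule), schedule.factor))
    with path.open("w") as fh:
        fh.write(f"# mode: {schedule.mode}\n")
        fh.write(f"# decay_time_constant_s: "
                 f"{schedule.envelope.decay_time_constant_s!r}\n")
        fh.write("onset_s,factor,mode\n")
        for t, f in zip(schedule.onsets, factors):
            fh.write(f"{float(t)!r},{float(f)!r},{schedule.mode}\n")


def read_schedule(path) -> FlashSchedule:
    path = Path(path)
    meta, skip = _read_header(path)
    if "mode" not in meta:
        raise SchemaError(f"schedule file {path} missing 'mode' header")
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    env = EnvelopeParams(decay_time_constant_s=float(
        meta.get("decay_time_constant_s", 0.4)))
    factors = df["factor"].to_numpy(float)
    mode = meta["mode"]
    return FlashSchedule(df["onset_s"].to_numpy(float), mode=mode,
                         factor=float(factors[0]) if mode == "async"
                         and factors.size else 1.0,
                         onset_factors=factors if mode == "async" else None,
                         envelope=env)


# -- reports ------------------------------------------------------------

def write_json_report(report: dict, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# -- run configuration --------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level configuration binding all components.

    Defaults are the setup's printed constants: 134 Hz PPG / 240 Hz ECG
    sampling, ~50 ms display lag, asynchronous factors 80/90/110/120 %,
    5-minute blocks.
    """

    detector: DetectorConfig = DetectorConfig()
    fs_ppg: float = PPG_SAMPLING_RATE_HZ
    fs_ecg: float = ECG_SAMPLING_RATE_HZ
    ptt_s: float = PTT_WRIST_S
    factors: tuple[float, ...] = ASYNC_FACTORS
    envelope_decay_s: float = 0.4
    lag_s: float = DEFAULT_LAG_S
    alpha: float = 0.05
    alternative: str = "less"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_SECTIONS = {"detector", "simulator", "scheduler", "analysis"}


def load_config(path) -> RunConfig:
    """Load a TOML run configuration; unknown keys are rejected."""
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - _SECTIONS - {"seed"}
    if unknown:
        raise SchemaError(f"unknown config sections/keys: {sorted(unknown)}")

    det_fields = {f.name for f in dataclasses.fields(DetectorConfig)}
    det_raw = raw.get("detector", {})
    if not set(det_raw) <= det_fields:
        raise SchemaError(
            f"unknown detector keys: {sorted(set(det_raw) - det_fields)}")
    kwargs: dict = {"detector": DetectorConfig(**det_raw)}

    sim = raw.get("simulator", {})
    allowed_sim = {"fs_ppg", "fs_ecg", "ptt_s"}
    if not set(sim) <= allowed_sim:
        raise SchemaError(
            f"unknown simulator keys: {sorted(set(sim) - allowed_sim)}")
    kwargs.update(sim)

    sch = raw.get("scheduler", {})
    allowed_sch = {"factors", "envelope_decay_s", "lag_s"}
    if not set(sch) <= allowed_sch:
        raise SchemaError(
            f"unknown scheduler keys: {sorted(set(sch) - allowed_sch)}")
    if "factors" in sch:
        sch = dict(sch, factors=tuple(sch["factors"]))
    kwargs.update(sch)

    ana = raw.get("analysis", {})
    allowed_ana = {"alpha", "alternative"}
    if not set(ana) <= allowed_ana:
        raise SchemaError(
            f"unknown analysis keys: {sorted(set(ana) - allowed_ana)}")
    kwargs.update(ana)

    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)
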