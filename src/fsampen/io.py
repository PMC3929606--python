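"""CSV / YAML input-output and run configuration.

Signals travel as plain CSV — either a single ``value`` column with an
explicitly supplied sampling rate, or ``time_s,value`` pairs with the rate
inferred from the (uniform) time stamps. Synthesized records are written as
a directory of component CSVs plus an annotation table (0-based, half-open
sample intervals) and a YAML manifest capturing the protocol, the cardiac
model, the seed and the realized per-load SNRs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .entropy import EstimatorTrace, FSampEnParams, MovingWindowSpec
from .signal import Signal
from .synth import (
    DEFAULT_BACKGROUND_SD_FRACTION,
    EnvelopeProtocol,
    MCGModel,
    SynthesizedRecord,
)

__all__ = [
    "read_signal",
    "write_signal",
    "write_trace",
    "write_record",
    "read_record",
    "RunConfig",
]

#: Maximum relative deviation of time steps tolerated when inferring fs.
TIME_UNIFORMITY_TOL = 0.01


def read_signal(path, fs: Optional[float] = None) -> Signal:
    """Read a signal from CSV (``value`` column, or ``time_s,value`` pairs).

    With a ``time_s`` column the sampling rate is inferred from the mean
    time step; steps deviating by more than 1% from uniform are rejected.
    An explicit ``fs`` overrides nothing — it is required when only a
    ``value`` column is present and checked for consistency otherwise.
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "value" not in frame.columns:
        raise ValueError(f"{path}: expected a 'value' column, got {list(frame.columns)}")
    values = frame["value"].to_numpy(dtype=np.float64)
    if "time_s" in frame.columns:
        t = frame["time_s"].to_numpy(dtype=np.float64)
        if t.size < 2:
            raise ValueError(f"{path}: need at least 2 time stamps to infer fs")
        steps = np.diff(t)
        mean_step = steps.mean()
        if mean_step <= 0:
            raise ValueError(f"{path}: time stamps must be increasing")
        if np.max(np.abs(steps - mean_step)) > TIME_UNIFORMITY_TOL * mean_step:
            raise ValueError(f"{path}: non-uniform time stamps (>1% deviation)")
        inferred = 1.0 / mean_step
        if fs is not None and abs(inferred - fs) > TIME_UNIFORMITY_TOL * fs:
            raise ValueError(
                f"{path}: stated fs {fs} Hz conflicts with inferred {inferred:.6g} Hz"
            )
        fs = inferred
    if fs is None:
        raise ValueError(f"{path}: no time_s column and no sampling rate given")
    return Signal(values, fs)


def write_signal(signal: Signal, path) -> None:
    """Write a signal as ``time_s,value`` CSV (full float precision)."""
    frame = pd.DataFrame({"time_s": signal.times, "value": signal.samples})
    frame.to_csv(path, index=False, float_format="%.17g")


def write_trace(trace: EstimatorTrace, path) -> None:
    """Write an estimator trace as CSV with its parameter columns."""
    p = trace.params
    frame = pd.DataFrame(
        {
            "time_s": trace.times,
            "value": trace.values,
            "estimator": trace.estimator_name,
            "window_s": trace.window.window_length_s,
            "overlap": trace.window.overlap_fraction,
            "m": p.m if p else "",
            "r_mode": p.r_mode if p else "",
            "r_value": p.r_value if p else "",
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def write_record(record: SynthesizedRecord, out_dir) -> None:
    """Write a synthesized record as a directory of CSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, sig in (
        ("env", record.env),
        ("mmg_clean", record.mmg_clean),
        ("mcg", record.mcg),
        ("mmg_noisy", record.mmg_noisy),
    ):
        write_signal(sig, out / f"{name}.csv")

    # annotations: 0-based half-open sample intervals
    cyc = pd.DataFrame(
        record.cycle_bounds, columns=["insp_start", "insp_end", "cycle_end"]
    )
    cyc.insert(0, "kind", "cycle")
    cyc.insert(1, "index", np.arange(len(cyc)))
    loads = pd.DataFrame(record.load_bounds, columns=["insp_start", "cycle_end"]).rename(
        columns={"insp_start": "insp_start", "cycle_end": "cycle_end"}
    )
    loads["insp_end"] = -1
    loads.insert(0, "kind", "load")
    loads.insert(1, "index", np.arange(len(loads)))
    annotations = pd.concat([cyc, loads], ignore_index=True)[
        ["kind", "index", "insp_start", "insp_end", "cycle_end"]
    ]
    with open(out / "annotations.csv", "w") as fh:
        fh.write("# 0-based, half-open sample intervals; load rows use insp_end=-1\n")
        annotations.to_csv(fh, index=False)

    manifest = {
        "seed": int(record.seed),
        "background_sd_fraction": float(record.background_sd_fraction),
        "protocol": dataclasses.asdict(record.protocol),
        "mcg_model": {
            "heart_rate_bpm": record.mcg_model.heart_rate_bpm,
            "rr_jitter_fraction": record.mcg_model.rr_jitter_fraction,
        },
        "load_scales": [float(s) for s in record.load_scales],
        "realized_snr_db": [round(float(v), 6) for v in record.realized_snr_db()],
        "note": "load amplitudes calibrated to the SNR targets; background and "
        "cardiac-template defaults are synthetic stand-ins",
    }
    # tuples -> lists for clean YAML
    manifest["protocol"]["phase_fractions"] = list(record.protocol.phase_fractions)
    manifest["protocol"]["load_target_snr_db"] = list(record.protocol.load_target_snr_db)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_record(record_dir) -> SynthesizedRecord:
    """Read back a record directory written by :func:`write_record`."""
    d = Path(record_dir)
    with open(d / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    proto_dict = dict(manifest["protocol"])
    proto_dict["phase_fractions"] = tuple(proto_dict["phase_fractions"])
    proto_dict["load_target_snr_db"] = tuple(proto_dict["load_target_snr_db"])
    protocol = EnvelopeProtocol(**proto_dict)
    model = MCGModel(**manifest["mcg_model"])
    fs = protocol.fs

    signals = {
        name: read_signal(d / f"{name}.csv", fs=fs)
        for name in ("env", "mmg_clean", "mcg", "mmg_noisy")
    }
    annotations = pd.read_csv(d / "annotations.csv", comment="#")
    cyc = annotations[annotations["kind"] == "cycle"].sort_values("index")
    loads = annotations[annotations["kind"] == "load"].sort_values("index")
    cycle_bounds = cyc[["insp_start", "insp_end", "cycle_end"]].to_numpy(dtype=np.int64)
    load_bounds = loads[["insp_start", "cycle_end"]].to_numpy(dtype=np.int64)

    return SynthesizedRecord(
        env=signals["env"],
        mmg_clean=signals["mmg_clean"],
        mcg=signals["mcg"],
        mmg_noisy=signals["mmg_noisy"],
        cycle_bounds=cycle_bounds,
        load_bounds=load_bounds,
        load_scales=np.asarray(manifest["load_scales"], dtype=np.float64),
        seed=int(manifest["seed"]),
        protocol=protocol,
        mcg_model=model,
        background_sd_fraction=float(manifest["background_sd_fraction"]),
    )


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a simulation / evaluation run.

    Serialises to and from YAML; the defaults reproduce the reference
    setup (m = 1, tolerance factor 0.3 of the global SD, 1-s window with
    90% overlap, fs 200 Hz, four loads with the stated SNR targets).
    """

    protocol: EnvelopeProtocol = field(default_factory=EnvelopeProtocol)
    mcg_model: MCGModel = field(default_factory=MCGModel)
    background_sd_fraction: float = DEFAULT_BACKGROUND_SD_FRACTION
    params: FSampEnParams = field(default_factory=FSampEnParams)
    window: MovingWindowSpec = field(default_factory=MovingWindowSpec)
    sweep_r_values: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0001, 0.05), 2))
    seeds: tuple[int, ...] = (0,)

    def to_dict(self) -> dict:
        d = {
            "protocol": dataclasses.asdict(self.protocol),
            "mcg_model": {
                "heart_rate_bpm": self.mcg_model.heart_rate_bpm,
                "rr_jitter_fraction": self.mcg_model.rr_jitter_fraction,
            },
            "background_sd_fraction": self.background_sd_fraction,
            "params": dataclasses.asdict(self.params),
            "window": dataclasses.asdict(self.window),
            "sweep_r_values": [float(r) for r in self.sweep_r_values],
            "seeds": [int(s) for s in self.seeds],
        }
        d["protocol"]["phase_fractions"] = list(self.protocol.phase_fractions)
        d["protocol"]["load_target_snr_db"] = list(self.protocol.load_target_snr_db)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        proto = dict(d.get("protocol", {}))
        if "phase_fractions" in proto:
            proto["phase_fractions"] = tuple(proto["phase_fractions"])
        if "load_target_snr_db" in proto:
            proto["load_target_snr_db"] = tuple(proto["load_target_snr_db"])
        return cls(
            protocol=EnvelopeProtocol(**proto),
            mcg_model=MCGModel(**d.get("mcg_model", {})),
            background_sd_fraction=d.get(
                "background_sd_fraction", DEFAULT_BACKGROUND_SD_FRACTION
            ),
            params=FSampEnParams(**d.get("params", {})),
            window=MovingWindowSpec(**d.get("window", {})),
            sweep_r_values=tuple(d.get("sweep_r_values", cls.sweep_r_values)),
            seeds=tuple(d.get("seeds", (0,))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
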