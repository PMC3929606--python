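"""Figures of merit for amplitude estimators on synthesized records.

Two quantities summarise how well a moving-window estimator tracks
respiratory effort in the presence of cardiac interference:

* **Per-load Pearson correlation** between the estimator trace (on the
  noisy signal) and the modulation envelope, computed separately within
  each load segment — how well the breathing cycles are resolved at each
  SNR — and over the whole record, which mostly reflects tracking of the
  load increments.
* **Per-cycle mean relative error (MRE)** between traces computed on the
  clean and the noisy signal: for one inspiratory cycle with clean and
  noisy estimates Xc(n), Xn(n) over its N trace points,
  ``MRE = (1/N) * sum |Xc - Xn| / Xc`` — how much the cardiac component
  distorts the estimate, summarised as mean ± SD per load.

A tolerance sweep repeats both across a grid of fSampEn tolerance factors,
with ARV and RMS as r-independent baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .entropy import (
    EstimatorTrace,
    FSampEnParams,
    MovingWindowSpec,
    estimator_trace,
    fixed_tolerance,
)
from .signal import Signal
from .synth import SynthesizedRecord

__all__ = [
    "CycleMRE",
    "LoadCorrelation",
    "align_reference",
    "pearson_r",
    "load_correlations",
    "paired_traces",
    "mre_per_cycle",
    "tolerance_sweep",
    "cycle_maxima",
]


@dataclass(frozen=True)
class LoadCorrelation:
    """Pearson R between an estimator trace and a reference, per load and overall."""

    r_by_load: np.ndarray
    r_whole: float
    estimator_name: str
    tolerance_r: Optional[float] = None


@dataclass(frozen=True)
class CycleMRE:
    """Per-inspiratory-cycle mean relative errors and their per-load summary.

    ``per_cycle_errors[i]`` is the MRE of cycle i (NaN when the cycle holds
    no usable trace points); ``cycle_loads[i]`` the load the cycle belongs
    to (-1 when it straddles a boundary). ``n_excluded`` counts trace
    points dropped because the clean estimate was zero (relative error
    undefined) or the entropy was undefined.
    """

    per_cycle_errors: np.ndarray
    cycle_loads: np.ndarray
    load_means: np.ndarray
    load_sds: np.ndarray
    estimator_name: str
    r_value: Optional[float] = None
    n_excluded: int = 0


def align_reference(
    reference: Signal,
    trace: EstimatorTrace,
    mode: str = "window_mean",
) -> np.ndarray:
    """Resample a full-rate reference onto an estimator trace's time base.

    ``mode='window_mean'`` (default) averages the reference over each
    analysis window's support — the matched comparison, since every trace
    value is itself a 1-window aggregate; correlating against the
    instantaneous reference at the window center instead imposes a
    deterministic shape mismatch that deflates R. ``mode='center'`` takes
    the nearest reference sample to each window-center time. Trace times
    outside the reference record are an error.
    """
    times = np.asarray(trace.times)
    if mode == "center":
        idx = np.rint(times * reference.fs).astype(np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= len(reference)):
            raise ValueError("trace times fall outside the reference record")
        return reference.samples[idx]
    if mode != "window_mean":
        raise ValueError(f"unknown alignment mode {mode!r}")
    length = trace.window.window_samples(reference.fs)
    starts = np.rint(times * reference.fs - (length - 1) / 2.0).astype(np.int64)
    if starts.size and (starts.min() < 0 or starts.max() + length > len(reference)):
        raise ValueError("trace windows fall outside the reference record")
    csum = np.concatenate([[0.0], np.cumsum(reference.samples)])
    return (csum[starts + length] - csum[starts]) / length


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation of two equal-length sequences."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(spstats.pearsonr(a, b).statistic)


def _trace_indices(trace: EstimatorTrace, fs: float) -> np.ndarray:
    return np.rint(np.asarray(trace.times) * fs).astype(np.int64)


def load_correlations(
    trace: EstimatorTrace,
    record: SynthesizedRecord,
    reference: Optional[Signal] = None,
) -> LoadCorrelation:
    """Correlate a trace with the envelope per load segment and overall.

    Trace points are assigned to a load when their window-center sample
    falls inside the load's half-open interval; undefined-entropy (NaN)
    points are excluded.
    """
    reference = reference if reference is not None else record.env
    ref_vals = align_reference(reference, trace)
    idx = _trace_indices(trace, reference.fs)
    valid = ~np.isnan(trace.values)

    r_by_load = np.empty(record.load_bounds.shape[0])
    for l, (a, b) in enumerate(record.load_bounds):
        mask = valid & (idx >= a) & (idx < b)
        r_by_load[l] = pearson_r(trace.values[mask], ref_vals[mask])
    r_whole = pearson_r(trace.values[valid], ref_vals[valid])
    return LoadCorrelation(
        r_by_load=r_by_load,
        r_whole=r_whole,
        estimator_name=trace.estimator_name,
        tolerance_r=trace.resolved_r,
    )


def paired_traces(
    record: SynthesizedRecord,
    window: MovingWindowSpec,
    estimator: str,
    params: Optional[FSampEnParams] = None,
) -> tuple[EstimatorTrace, EstimatorTrace]:
    """Clean- and noisy-signal traces of one estimator parameterization.

    For fSampEn the tolerance is resolved **once** from the noisy signal
    (the signal one would actually record) and the identical absolute
    value is applied to the clean signal: the clean trace is the
    hypothetical noise-free output of the same estimator, which is what a
    clean-vs-noisy relative error compares.
    """
    if estimator == "fSampEn":
        params = params if params is not None else FSampEnParams()
        shared = FSampEnParams(
            m=params.m,
            r_mode="absolute",
            r_value=fixed_tolerance(record.mmg_noisy, params),
            sd_ddof=params.sd_ddof,
        )
        clean = estimator_trace(record.mmg_clean, window, "fSampEn", shared)
        noisy = estimator_trace(record.mmg_noisy, window, "fSampEn", shared)
    else:
        clean = estimator_trace(record.mmg_clean, window, estimator)
        noisy = estimator_trace(record.mmg_noisy, window, estimator)
    return clean, noisy


def mre_per_cycle(
    clean_trace: EstimatorTrace,
    noisy_trace: EstimatorTrace,
    record: SynthesizedRecord,
) -> CycleMRE:
    """Mean relative error between clean and noisy traces, per inspiratory cycle.

    Trace points enter cycle i when their window-center sample lies inside
    the cycle's inspiratory interval. Points whose clean estimate is zero
    (relative error undefined) or whose entropy was undefined are excluded
    and tallied. Per-load mean/SD use only cycles fully inside the load.
    """
    if clean_trace.times.shape != noisy_trace.times.shape or not np.allclose(
        clean_trace.times, noisy_trace.times
    ):
        raise ValueError("clean and noisy traces must share window times")
    if clean_trace.estimator_name != noisy_trace.estimator_name:
        raise ValueError("clean and noisy traces must use the same estimator")

    idx = _trace_indices(clean_trace, record.fs)
    xc = clean_trace.values
    xn = noisy_trace.values

    n_cycles = record.cycle_bounds.shape[0]
    errors = np.full(n_cycles, np.nan)
    cycle_loads = np.full(n_cycles, -1, dtype=np.int64)
    n_excluded = 0
    for i, (insp_start, insp_end, _cycle_end) in enumerate(record.cycle_bounds):
        in_cycle = (idx >= insp_start) & (idx < insp_end)
        usable = in_cycle & ~np.isnan(xc) & ~np.isnan(xn) & (xc != 0)
        n_excluded += int(in_cycle.sum() - usable.sum())
        if usable.any():
            errors[i] = float(np.mean(np.abs(xc[usable] - xn[usable]) / xc[usable]))
        for l, (a, b) in enumerate(record.load_bounds):
            if a <= insp_start and record.cycle_bounds[i, 2] <= b:
                cycle_loads[i] = l
                break

    n_loads = record.load_bounds.shape[0]
    load_means = np.empty(n_loads)
    load_sds = np.empty(n_loads)
    for l in range(n_loads):
        vals = errors[(cycle_loads == l) & ~np.isnan(errors)]
        load_means[l] = vals.mean() if vals.size else np.nan
        load_sds[l] = vals.std(ddof=1) if vals.size > 1 else np.nan

    return CycleMRE(
        per_cycle_errors=errors,
        cycle_loads=cycle_loads,
        load_means=load_means,
        load_sds=load_sds,
        estimator_name=clean_trace.estimator_name,
        r_value=noisy_trace.params.r_value if noisy_trace.params else None,
        n_excluded=n_excluded,
    )


def tolerance_sweep(
    record: SynthesizedRecord,
    r_values: Sequence[float],
    window: Optional[MovingWindowSpec] = None,
    m: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep the fSampEn tolerance factor; ARV/RMS ride along as baselines.

    Returns two tidy tables. ``correlations``: one row per (r_value,
    estimator, load) — loads ``1..n`` plus ``'all'`` for the whole-record
    correlation — of the noisy-signal trace against the envelope; ARV/RMS
    rows are repeated across r for table regularity. ``mre``: one row per
    (r_value, estimator, load, cycle) holding the per-cycle MRE between the
    clean- and noisy-signal traces.
    """
    window = window if window is not None else MovingWindowSpec()
    r_values = list(r_values)
    if not r_values or any(r <= 0 for r in r_values):
        raise ValueError("r_values must be a non-empty sequence of positive factors")

    corr_rows: list[dict] = []
    mre_rows: list[dict] = []

    def _corr_rows(lc: LoadCorrelation, r_value: float, estimator: str):
        for l, r_load in enumerate(lc.r_by_load):
            corr_rows.append(
                {"r_value": r_value, "estimator": estimator, "load": str(l + 1), "R": r_load}
            )
        corr_rows.append(
            {"r_value": r_value, "estimator": estimator, "load": "all", "R": lc.r_whole}
        )

    def _mre_rows(cm: CycleMRE, r_value: float, estimator: str):
        for i, err in enumerate(cm.per_cycle_errors):
            if cm.cycle_loads[i] < 0 or np.isnan(err):
                continue
            mre_rows.append(
                {
                    "r_value": r_value,
                    "estimator": estimator,
                    "load": str(cm.cycle_loads[i] + 1),
                    "cycle": i,
                    "mre": err,
                }
            )

    baselines = {}
    for name in ("ARV", "RMS"):
        clean, noisy = paired_traces(record, window, name)
        baselines[name] = (
            load_correlations(noisy, record),
            mre_per_cycle(clean, noisy, record),
        )

    for r in r_values:
        params = FSampEnParams(m=m, r_mode="global_sd_factor", r_value=r)
        clean, noisy = paired_traces(record, window, "fSampEn", params)
        _corr_rows(load_correlations(noisy, record), r, "fSampEn")
        _mre_rows(mre_per_cycle(clean, noisy, record), r, "fSampEn")
        for name, (lc, cm) in baselines.items():
            _corr_rows(lc, r, name)
            _mre_rows(cm, r, name)

    return pd.DataFrame(corr_rows), pd.DataFrame(mre_rows)


def cycle_maxima(
    trace: EstimatorTrace,
    reference: Signal,
    record: SynthesizedRecord,
) -> pd.DataFrame:
    """Per-cycle maxima of the aligned reference and of the estimator trace.

    One row per inspiratory cycle with columns ``load`` (1-based), ``cycle``,
    ``ref_max`` and ``est_max``; the basis of effort-vs-estimate scatter
    plots. A cycle whose inspiratory interval holds no trace point is an
    error.
    """
    ref_vals = align_reference(reference, trace)
    idx = _trace_indices(trace, reference.fs)
    rows = []
    for i, (insp_start, insp_end, cycle_end) in enumerate(record.cycle_bounds):
        mask = (idx >= insp_start) & (idx < insp_end) & ~np.isnan(trace.values)
        if not mask.any():
            raise ValueError(f"cycle {i} holds no usable trace points")
        load = -1
        for l, (a, b) in enumerate(record.load_bounds):
            if a <= insp_start and cycle_end <= b:
                load = l + 1
                break
        rows.append(
            {
                "load": load,
                "cycle": i,
                "ref_max": float(ref_vals[mask].max()),
                "est_max": float(trace.values[mask].max()),
            }
        )
    return pd.DataFrame(rows)
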