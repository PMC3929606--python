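"""Sample entropy, its fixed-tolerance variant, and moving-window amplitude estimators.

Sample entropy (SampEn) of a sequence ``x(1..N)`` with embedding dimension
``m`` and tolerance ``r`` is ``-ln(A/B)``, where ``B`` counts ordered pairs
of length-``m`` templates within Chebyshev distance ``r`` of each other
(self-matches excluded) and ``A`` counts the pairs that still match when the
templates are extended by one sample. Classical SampEn normalises ``r`` by
the standard deviation of each analysis window, which deliberately removes
amplitude information. The fixed-tolerance variant (fSampEn) instead holds a
single absolute ``r`` — typically a factor of the *whole signal's* SD —
across every moving window, which makes the statistic amplitude-sensitive:
a window whose excursions are large relative to ``r`` produces few matches
and high entropy. Applied over a moving window, fSampEn therefore acts as an
amplitude envelope estimator, comparable to the average rectified value
(ARV) and root mean square (RMS), but far less sensitive to quasi-periodic
deterministic transients such as cardiac vibration.

Conventions (Richman & Moorman): templates ``i = 1..N-m`` are used at both
lengths ``m`` and ``m+1`` so the counts are comparable; per-template counts
are normalised by ``N-m-1``; distances compare with ``<= r`` (inclusive);
the logarithm is natural (result in nats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .signal import Signal

__all__ = [
    "FSampEnParams",
    "MovingWindowSpec",
    "MatchStatistics",
    "EstimatorTrace",
    "UndefinedEntropyError",
    "sampen",
    "match_statistics",
    "fixed_tolerance",
    "arv",
    "rms",
    "estimator_trace",
    "max_attainable_sampen",
]


class UndefinedEntropyError(ValueError):
    """SampEn is undefined for this window (no matches at length m or m+1).

    Attributes
    ----------
    no_m_matches
        True when B = 0 (not even length-m matches exist); False when B > 0
        but A = 0 (no match survives extension to m+1).
    """

    def __init__(self, message: str, *, no_m_matches: bool):
        super().__init__(message)
        self.no_m_matches = no_m_matches


@dataclass(frozen=True)
class FSampEnParams:
    """Parameters governing a (f)SampEn computation.

    ``r_mode='global_sd_factor'`` resolves the tolerance as
    ``r_value * SD(entire signal)`` once per signal and holds it constant
    over every analysis window (the fixed-tolerance variant).
    ``r_mode='absolute'`` uses ``r_value`` directly in amplitude units.
    ``sd_ddof`` selects sample (1, default) or population (0) SD for the
    global-SD resolution.
    """

    m: int = 1
    r_mode: Literal["absolute", "global_sd_factor"] = "global_sd_factor"
    r_value: float = 0.3
    sd_ddof: int = 1

    def __post_init__(self):
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if not (self.r_value > 0):
            raise ValueError(f"tolerance r_value must be > 0, got {self.r_value}")
        if self.r_mode not in ("absolute", "global_sd_factor"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")
        if self.sd_ddof not in (0, 1):
            raise ValueError(f"sd_ddof must be 0 or 1, got {self.sd_ddof}")


@dataclass(frozen=True)
class MovingWindowSpec:
    """Moving analysis window: length in seconds and fractional overlap.

    The step is ``round(window_samples * (1 - overlap_fraction))`` samples
    (at least 1); only full windows are emitted, a trailing partial window
    is dropped.
    """

    window_length_s: float = 1.0
    overlap_fraction: float = 0.9

    def __post_init__(self):
        if not (self.window_length_s > 0):
            raise ValueError("window length must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap fraction must lie in [0, 1)")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_length_s * fs))

    def step_samples(self, fs: float) -> int:
        length = self.window_samples(fs)
        return max(1, int(round(length * (1.0 - self.overlap_fraction))))

    def n_windows(self, n_samples: int, fs: float) -> int:
        length = self.window_samples(fs)
        if n_samples < length:
            raise ValueError(
                f"signal of {n_samples} samples is shorter than the "
                f"{length}-sample analysis window"
            )
        return (n_samples - length) // self.step_samples(fs) + 1


@dataclass(frozen=True)
class MatchStatistics:
    """Per-template and mean template-match counts of one SampEn evaluation.

    ``b_counts[i]`` / ``a_counts[i]`` are the numbers of templates j != i
    within tolerance of template i at lengths m and m+1; ``b_mean`` and
    ``a_mean`` are their means normalised by ``N - m - 1`` (the B^m(r) and
    A^m(r) statistics).
    """

    b_counts: np.ndarray
    a_counts: np.ndarray
    b_mean: float
    a_mean: float


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Ordered-pair match counts per template at lengths m and m+1.

    O(N^2) memory/time; ample at the ~200-sample windows this package uses.
    """
    n = x.size
    n_templates = n - m
    within = np.abs(x[:, None] - x[None, :]) <= r
    match = within[:n_templates, :n_templates].copy()
    for k in range(1, m):
        match &= within[k : k + n_templates, k : k + n_templates]
    b_counts = match.sum(axis=1) - 1  # remove the self-match on the diagonal
    match &= within[m : m + n_templates, m : m + n_templates]
    a_counts = match.sum(axis=1) - 1
    return b_counts.astype(np.int64), a_counts.astype(np.int64)


def _as_samples(x) -> np.ndarray:
    if isinstance(x, Signal):
        return x.samples
    return np.asarray(x, dtype=np.float64)


def match_statistics(x, params: FSampEnParams, resolved_r: float) -> MatchStatistics:
    """Compute the template-match statistics underlying SampEn for one window."""
    samples = _as_samples(x)
    m = params.m
    if samples.size < m + 2:
        raise ValueError(
            f"need at least m + 2 = {m + 2} samples for one length-(m+1) "
            f"comparison, got {samples.size}"
        )
    if not (resolved_r > 0):
        raise ValueError(f"resolved tolerance must be > 0, got {resolved_r}")
    b_counts, a_counts = _match_counts(samples, m, resolved_r)
    denom = samples.size - m - 1
    return MatchStatistics(
        b_counts=b_counts,
        a_counts=a_counts,
        b_mean=float(b_counts.mean() / denom),
        a_mean=float(a_counts.mean() / denom),
    )


def sampen(x, params: FSampEnParams, resolved_r: float) -> float:
    """Sample entropy of one window at an already-resolved absolute tolerance.

    Parameters
    ----------
    x
        Window samples (array or :class:`Signal`), length >= m + 2.
    params
        Embedding dimension (``params.m``) is used; tolerance resolution is
        the caller's job (see :func:`fixed_tolerance`).
    resolved_r
        Absolute tolerance in amplitude units, > 0.

    Returns
    -------
    float
        ``-ln(A/B)`` in nats, >= 0.

    Raises
    ------
    UndefinedEntropyError
        When no length-m matches exist (B = 0) or no match survives
        extension to m+1 (A = 0); the moving-window caller decides the
        substitution policy.
    """
    stats = match_statistics(x, params, resolved_r)
    b_total = int(stats.b_counts.sum())
    a_total = int(stats.a_counts.sum())
    if b_total == 0:
        raise UndefinedEntropyError(
            "no template matches at length m; SampEn undefined", no_m_matches=True
        )
    if a_total == 0:
        raise UndefinedEntropyError(
            "no template matches at length m+1; SampEn undefined", no_m_matches=False
        )
    return float(-np.log(a_total / b_total))


def max_attainable_sampen(window_samples: int, m: int) -> float:
    """Largest finite SampEn value a window of this size can produce.

    Reached when exactly one ordered template pair matches at length m+1
    while every pair matches at length m: ``-ln(1 / ((N-m)(N-m-1)))``.
    Used as the bounded stand-in for windows where A = 0 but B > 0.
    """
    n_templates = window_samples - m
    return float(np.log(n_templates * (n_templates - 1)))


def fixed_tolerance(signal: Signal, params: FSampEnParams) -> float:
    """Resolve the absolute tolerance used for every window of a signal.

    In ``absolute`` mode, returns ``r_value`` unchanged. In
    ``global_sd_factor`` mode, returns ``r_value * SD(entire signal)`` —
    the fixed tolerance that makes moving-window SampEn amplitude-sensitive.
    """
    if len(signal) < 2:
        raise ValueError("need at least 2 samples to resolve a tolerance")
    if params.r_mode == "absolute":
        return float(params.r_value)
    sd = signal.sd(ddof=params.sd_ddof)
    if sd == 0.0:
        raise ValueError(
            "zero-variance signal: global-SD-factor tolerance would be 0"
        )
    return float(params.r_value * sd)


def arv(window: np.ndarray) -> float:
    """Average rectified value: mean absolute amplitude of a window."""
    return float(np.mean(np.abs(window)))


def rms(window: np.ndarray) -> float:
    """Root mean square amplitude of a window."""
    return float(np.sqrt(np.mean(np.square(window))))


@dataclass(frozen=True)
class EstimatorTrace:
    """Moving-window estimator outputs at window-center times.

    ``values`` is NaN for windows where SampEn had no length-m matches at
    all (flagged in ``no_match_mask``; such points are excluded from
    correlations downstream). Windows where only the (m+1)-extension found
    no match carry the bounded maximum attainable value; their count is
    ``n_max_substituted``.
    """

    times: np.ndarray
    values: np.ndarray
    estimator_name: Literal["fSampEn", "ARV", "RMS"]
    window: MovingWindowSpec
    fs: float
    params: Optional[FSampEnParams] = None
    resolved_r: Optional[float] = None
    no_match_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_max_substituted: int = 0

    def __post_init__(self):
        if self.no_match_mask is None:
            object.__setattr__(
                self, "no_match_mask", np.zeros(self.values.size, dtype=bool)
            )

    def __len__(self) -> int:
        return self.times.size


def estimator_trace(
    signal: Signal,
    window: MovingWindowSpec,
    estimator: Literal["fSampEn", "ARV", "RMS"],
    params: Optional[FSampEnParams] = None,
) -> EstimatorTrace:
    """Slide a window over a signal and evaluate one amplitude estimator.

    Emits one value per full window at the window-center time; the step is
    ``round(L * (1 - overlap))`` samples, trailing partial windows are
    dropped, so the trace holds ``floor((N - L)/step) + 1`` points.

    For ``fSampEn`` the tolerance is resolved **once** from the whole
    signal (see :func:`fixed_tolerance`) and reused in every window —
    windows are never renormalised, which is what makes the trace track
    amplitude. Undefined-entropy windows follow the documented
    substitution policy (see :class:`EstimatorTrace`).
    """
    x = signal.samples
    length = window.window_samples(signal.fs)
    step = window.step_samples(signal.fs)
    n_windows = window.n_windows(x.size, signal.fs)

    if estimator == "fSampEn":
        if params is None:
            params = FSampEnParams()
        if length < params.m + 2:
            raise ValueError(
                f"{length}-sample window too short for m = {params.m} "
                f"(need >= m + 2)"
            )
        resolved_r = fixed_tolerance(signal, params)
    elif estimator in ("ARV", "RMS"):
        resolved_r = None
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    starts = np.arange(n_windows) * step
    times = (starts + (length - 1) / 2.0) / signal.fs
    values = np.empty(n_windows)
    no_match = np.zeros(n_windows, dtype=bool)
    n_sub = 0

    for k, start in enumerate(starts):
        w = x[start : start + length]
        if estimator == "ARV":
            values[k] = arv(w)
        elif estimator == "RMS":
            values[k] = rms(w)
        else:
            try:
                values[k] = sampen(w, params, resolved_r)
            except UndefinedEntropyError as err:
                if err.no_m_matches:
                    values[k] = np.nan
                    no_match[k] = True
                else:
                    values[k] = max_attainable_sampen(length, params.m)
                    n_sub += 1

    return EstimatorTrace(
        times=times,
        values=values,
        estimator_name=estimator,
        window=window,
        fs=signal.fs,
        params=params if estimator == "fSampEn" else None,
        resolved_r=resolved_r,
        no_match_mask=no_match,
        n_max_substituted=n_sub,
    )
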