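"""Synthetic diaphragm mechanomyogram (MMGdi) records with cardiac interference.

The generator emulates an incremental inspiratory-load protocol:

* **ENV** — an amplitude-modulation envelope of ``n_loads`` blocks of
  respiratory cycles. Each cycle's inspiratory half rises with a
  half-Hanning taper (25% of the inspiration), holds a plateau at the
  load's amplitude (50%) and falls with a half-Hanning taper (25%); the
  expiratory half is zero.
* **MMGc** — the clean MMG: band-limited (5–25 Hz) unit-SD Gaussian noise
  multiplied by ENV (diaphragm vibration is random in nature and its power
  lies in that band), plus 5–50 Hz Gaussian background noise emulating
  non-cardiac biological noise at rest.
* **MCG** — the cardiac vibration train: a deterministic damped-sinusoid
  template convolved with an impulse train at jittered RR intervals.
* **MMGn** — MMGc + MCG, the signal an accelerometer on the chest wall
  would actually deliver.

Per-load envelope amplitudes are calibrated so the realized clean-to-cardiac
SNR of each load segment hits a stated target (defaults −8.7, −1.7, 0.6 and
3.8 dB): respiratory effort, and hence SNR, grows with the load while the
cardiac interference stays constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .signal import Signal

__all__ = [
    "EnvelopeProtocol",
    "MCGModel",
    "Envelope",
    "SynthesizedRecord",
    "bandpass_zero_phase",
    "make_envelope",
    "make_clean_mmg",
    "default_mcg_template",
    "make_mcg",
    "calibrate_load_scales",
    "synthesize",
    "segment_snr_db",
]

#: Pass band of the diaphragm vibration component, Hz.
MMG_BAND = (5.0, 25.0)
#: Pass band of the non-cardiac background noise, Hz.
BACKGROUND_BAND = (5.0, 50.0)
#: Default background-noise SD as a fraction of the smallest plateau amplitude.
DEFAULT_BACKGROUND_SD_FRACTION = 0.1


@dataclass(frozen=True)
class EnvelopeProtocol:
    """Incremental-load respiratory protocol for the modulation envelope.

    Defaults: four loads of ten cycles at 18 cycles/min (3.33-s cycles,
    133.33 s total), inspiration one half of the cycle split 25/50/25 into
    rise/plateau/fall, sampled at 200 Hz, with per-load SNR targets
    −8.7/−1.7/0.6/3.8 dB.
    """

    n_loads: int = 4
    cycles_per_load: int = 10
    respiratory_rate_cpm: float = 18.0
    inspiratory_fraction: float = 0.5
    phase_fractions: tuple[float, float, float] = (0.25, 0.50, 0.25)
    load_target_snr_db: tuple[float, ...] = (-8.7, -1.7, 0.6, 3.8)
    fs: float = 200.0

    def __post_init__(self):
        if self.n_loads < 1 or self.cycles_per_load < 1:
            raise ValueError("need at least one load and one cycle per load")
        if not (self.respiratory_rate_cpm > 0):
            raise ValueError("respiratory rate must be positive")
        if not (0 < self.inspiratory_fraction < 1):
            raise ValueError("inspiratory fraction must lie in (0, 1)")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("rise/plateau/fall fractions must sum to 1")
        if len(self.load_target_snr_db) != self.n_loads:
            raise ValueError(
                f"{self.n_loads} loads but {len(self.load_target_snr_db)} SNR targets"
            )
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")

    @property
    def cycle_duration_s(self) -> float:
        return 60.0 / self.respiratory_rate_cpm

    @property
    def n_cycles(self) -> int:
        return self.n_loads * self.cycles_per_load

    @property
    def total_duration_s(self) -> float:
        return self.n_cycles * self.cycle_duration_s

    @property
    def n_samples(self) -> int:
        # floor keeps len/fs within the protocol duration (a 60/18-s cycle
        # is not an integer number of samples at 200 Hz).
        return int(np.floor(self.total_duration_s * self.fs))


@dataclass(frozen=True)
class MCGModel:
    """Cardiac vibration model: template waveform plus beat timing.

    The impulse train uses RR intervals drawn as
    ``Normal(60/heart_rate_bpm, (rr_jitter_fraction * mean RR)^2)``,
    truncated positive. ``template=None`` resolves to
    :func:`default_mcg_template` at the record's sampling rate.
    """

    heart_rate_bpm: float = 72.0
    rr_jitter_fraction: float = 0.03
    template: Optional[Signal] = None

    def __post_init__(self):
        if not (self.heart_rate_bpm > 0):
            raise ValueError("heart rate must be positive")
        if self.rr_jitter_fraction < 0:
            raise ValueError("RR jitter fraction must be >= 0")

    @property
    def mean_rr_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def resolved_template(self, fs: float) -> Signal:
        tpl = self.template if self.template is not None else default_mcg_template(fs)
        if tpl.fs != fs:
            raise ValueError(
                f"template sampled at {tpl.fs} Hz but record uses {fs} Hz"
            )
        if tpl.duration_s >= self.mean_rr_s:
            raise ValueError(
                f"template of {tpl.duration_s:.3f} s is not shorter than the "
                f"mean RR interval of {self.mean_rr_s:.3f} s"
            )
        return tpl


@dataclass(frozen=True)
class Envelope:
    """Modulation envelope plus its ground-truth timing annotations.

    ``cycle_bounds[k] = (insp_start, insp_end, cycle_end)`` and
    ``load_bounds[l] = (start, end)`` are 0-based half-open sample indices
    tiling the record.
    """

    signal: Signal
    cycle_bounds: np.ndarray
    load_bounds: np.ndarray
    plateau_amplitudes: np.ndarray


@dataclass(frozen=True)
class SynthesizedRecord:
    """One synthesized MMGdi record and its ground truth.

    ``mmg_noisy`` is sample-exactly ``mmg_clean + mcg``; all component
    signals share length and sampling rate.
    """

    env: Signal
    mmg_clean: Signal
    mcg: Signal
    mmg_noisy: Signal
    cycle_bounds: np.ndarray
    load_bounds: np.ndarray
    load_scales: np.ndarray
    seed: int
    protocol: EnvelopeProtocol = field(default_factory=EnvelopeProtocol)
    mcg_model: MCGModel = field(default_factory=MCGModel)
    background_sd_fraction: float = DEFAULT_BACKGROUND_SD_FRACTION

    @property
    def fs(self) -> float:
        return self.env.fs

    def realized_snr_db(self) -> np.ndarray:
        """Realized clean-vs-cardiac SNR of each load segment, dB."""
        return np.array(
            [
                segment_snr_db(
                    self.mmg_clean.samples[a:b], self.mcg.samples[a:b]
                )
                for a, b in self.load_bounds
            ]
        )


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------


def bandpass_zero_phase(
    signal: Signal, low_hz: float, high_hz: float, order: int = 4
) -> Signal:
    """Zero-phase Butterworth band-pass (forward-backward application).

    The filter is designed once with :func:`scipy.signal.butter` at the
    given order and run with ``sosfiltfilt``, so the output has exactly the
    input's length and no phase shift.
    """
    nyquist = signal.fs / 2.0
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < fs/2 = {nyquist} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=signal.fs, output="sos")
    return Signal(sps.sosfiltfilt(sos, signal.samples), signal.fs)


def _rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Deterministic per-component RNG streams (MMG noise, background, RR jitter)."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)  # type: ignore[return-value]


def make_envelope(
    protocol: EnvelopeProtocol,
    load_scales: Optional[Sequence[float]] = None,
) -> Envelope:
    """Build the amplitude-modulation envelope and its timing annotations.

    ``load_scales`` sets each load's plateau amplitude (default 1.0 per
    load, the uncalibrated state). Cycle boundaries are the rounded
    continuous-time boundaries ``k * cycle_duration``; the record holds
    ``floor(total_duration * fs)`` samples.
    """
    if load_scales is None:
        load_scales = np.ones(protocol.n_loads)
    load_scales = np.asarray(load_scales, dtype=np.float64)
    if load_scales.shape != (protocol.n_loads,):
        raise ValueError(
            f"expected {protocol.n_loads} load scales, got shape {load_scales.shape}"
        )

    fs = protocol.fs
    n = protocol.n_samples
    tc = protocol.cycle_duration_s
    rise_f, plateau_f, _fall_f = protocol.phase_fractions
    insp_f = protocol.inspiratory_fraction

    def _idx(t: float) -> int:
        return min(int(round(t * fs)), n)

    env = np.zeros(n)
    cycle_bounds = np.empty((protocol.n_cycles, 3), dtype=np.int64)
    for k in range(protocol.n_cycles):
        amp = load_scales[k // protocol.cycles_per_load]
        t0 = k * tc
        i_start = _idx(t0)
        i_rise_end = _idx(t0 + insp_f * rise_f * tc)
        i_plateau_end = _idx(t0 + insp_f * (rise_f + plateau_f) * tc)
        i_insp_end = _idx(t0 + insp_f * tc)
        i_cycle_end = _idx(t0 + tc)

        n_rise = i_rise_end - i_start
        if n_rise > 0:
            # half-Hanning ramp 0 -> amp (reaches amp at the plateau start)
            env[i_start:i_rise_end] = amp * 0.5 * (
                1.0 - np.cos(np.pi * np.arange(n_rise) / n_rise)
            )
        env[i_rise_end:i_plateau_end] = amp
        n_fall = i_insp_end - i_plateau_end
        if n_fall > 0:
            env[i_plateau_end:i_insp_end] = amp * 0.5 * (
                1.0 + np.cos(np.pi * np.arange(n_fall) / n_fall)
            )
        # expiratory half stays 0
        cycle_bounds[k] = (i_start, i_insp_end, i_cycle_end)

    load_bounds = np.empty((protocol.n_loads, 2), dtype=np.int64)
    for l in range(protocol.n_loads):
        load_bounds[l] = (
            cycle_bounds[l * protocol.cycles_per_load, 0],
            cycle_bounds[(l + 1) * protocol.cycles_per_load - 1, 2],
        )

    return Envelope(
        signal=Signal(env, fs),
        cycle_bounds=cycle_bounds,
        load_bounds=load_bounds,
        plateau_amplitudes=load_scales.copy(),
    )


def _unit_mmg_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (5–25 Hz) Gaussian noise rescaled to unit SD."""
    raw = Signal(rng.standard_normal(n), fs)
    filtered = bandpass_zero_phase(raw, *MMG_BAND).samples
    return filtered / filtered.std()


def _unit_background_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (5–50 Hz) Gaussian noise rescaled to unit SD."""
    raw = Signal(rng.standard_normal(n), fs)
    filtered = bandpass_zero_phase(raw, *BACKGROUND_BAND).samples
    return filtered / filtered.std()


def make_clean_mmg(
    env: Envelope,
    background_sd_fraction: float = DEFAULT_BACKGROUND_SD_FRACTION,
    seed: int = 0,
) -> Signal:
    """Clean MMG: envelope-modulated band-limited noise plus background noise.

    The vibration component is unit-SD 5–25 Hz Gaussian noise multiplied by
    the envelope; the background is 5–50 Hz Gaussian noise with SD equal to
    ``background_sd_fraction`` times the smallest plateau amplitude.
    Deterministic given ``seed`` (the same per-component RNG streams are
    used by :func:`calibrate_load_scales` and :func:`synthesize`).
    """
    if background_sd_fraction < 0:
        raise ValueError("background SD fraction must be >= 0")
    rng_mmg, rng_bg, _ = _rng_streams(seed)
    n, fs = len(env.signal), env.signal.fs
    modulated = _unit_mmg_noise(n, fs, rng_mmg) * env.signal.samples
    bg_sd = background_sd_fraction * float(np.min(env.plateau_amplitudes))
    if bg_sd > 0:
        modulated = modulated + bg_sd * _unit_background_noise(n, fs, rng_bg)
    return Signal(modulated, fs)


def default_mcg_template(fs: float) -> Signal:
    """A synthetic cardiac-vibration waveform (no recorded data involved).

    A deterministic 0.5-s sum of three exponentially damped sinusoids at 5,
    9 and 16 Hz — frequency content below 20 Hz, like chest-wall cardiac
    vibrations — normalised to unit peak amplitude.
    """
    if not (fs > 40):
        raise ValueError(f"need fs > 40 Hz to represent the template, got {fs}")
    duration = 0.5
    t = np.arange(int(round(duration * fs))) / fs
    wave = (
        1.0 * np.exp(-t / 0.09) * np.sin(2 * np.pi * 9.0 * t)
        + 0.7 * np.exp(-t / 0.06) * np.sin(2 * np.pi * 16.0 * t + np.pi / 3)
        + 0.35 * np.exp(-t / 0.18) * np.sin(2 * np.pi * 5.0 * t + np.pi / 2)
    )
    # taper the onset so the discontinuity of the phase-shifted terms vanishes
    ramp = min(int(round(0.02 * fs)), t.size)
    wave[:ramp] *= np.linspace(0.0, 1.0, ramp, endpoint=False)
    return Signal(wave / np.max(np.abs(wave)), fs)


def make_mcg(
    duration_s: float,
    model: MCGModel,
    seed: int = 0,
    fs: float = 200.0,
) -> Signal:
    """Cardiac vibration train: jittered impulse train convolved with the template.

    Beat times are the cumulative sums of RR intervals drawn from the
    model's truncated-normal distribution; a unit impulse is placed at each
    beat sample and convolved with the template, then truncated to the
    requested duration. Deterministic given ``seed``.
    """
    if not (duration_s > model.mean_rr_s):
        raise ValueError("record must be longer than one RR interval")
    template = model.resolved_template(fs)
    _, _, rng_rr = _rng_streams(seed)
    n = int(round(duration_s * fs))

    mean_rr = model.mean_rr_s
    sd_rr = model.rr_jitter_fraction * mean_rr
    beat_times = []
    t = 0.0
    while True:
        rr = mean_rr if sd_rr == 0 else rng_rr.normal(mean_rr, sd_rr)
        while rr <= 0:  # truncate to positive intervals
            rr = rng_rr.normal(mean_rr, sd_rr)
        t += rr
        if t >= duration_s:
            break
        beat_times.append(t)

    impulses = np.zeros(n)
    idx = np.round(np.array(beat_times) * fs).astype(np.int64)
    impulses[idx[idx < n]] = 1.0
    mcg = np.convolve(impulses, template.samples)[:n]
    return Signal(mcg, fs)


def segment_snr_db(clean: np.ndarray, noise: np.ndarray) -> float:
    """SNR in dB between equal-length segments: 10*log10(P_clean / P_noise)."""
    clean = np.asarray(clean, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if clean.shape != noise.shape:
        raise ValueError("segments must have equal length")
    p_noise = float(np.mean(np.square(noise)))
    if p_noise == 0.0:
        raise ValueError("noise segment has zero power; SNR undefined")
    p_clean = float(np.mean(np.square(clean)))
    return 10.0 * np.log10(p_clean / p_noise)


def calibrate_load_scales(
    protocol: EnvelopeProtocol,
    mcg: Signal,
    seed: int = 0,
    background_sd_fraction: float = DEFAULT_BACKGROUND_SD_FRACTION,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Per-load envelope amplitudes that realize the protocol's SNR targets.

    Writes the clean MMG of load ``l`` as ``s_l * M + f * min(s) * G`` (M the
    unit-amplitude modulated component, G the unit background, f the
    background fraction) and solves, per load segment, the quadratic in
    ``s_l`` that makes the segment's clean power equal
    ``10^(SNR_target/10)`` times the MCG power — iterating the shared
    background amplitude ``f * min(s)`` to a fixed point. Because the exact
    noise realizations of :func:`make_clean_mmg` (same seed) are used, the
    realized SNRs match the targets to numerical precision.
    """
    env_unit = make_envelope(protocol)  # unit plateau amplitudes
    n, fs = len(env_unit.signal), protocol.fs
    if len(mcg) != n:
        raise ValueError(f"MCG length {len(mcg)} != envelope length {n}")
    rng_mmg, rng_bg, _ = _rng_streams(seed)
    modulated_unit = _unit_mmg_noise(n, fs, rng_mmg) * env_unit.signal.samples
    background_unit = _unit_background_noise(n, fs, rng_bg)

    targets = np.asarray(protocol.load_target_snr_db, dtype=np.float64)
    scales = np.zeros(protocol.n_loads)  # first pass ignores the background
    f = background_sd_fraction
    for _ in range(max_iter):
        prev = scales.copy()
        s_min = float(np.min(scales))
        for l, (a, b) in enumerate(env_unit.load_bounds):
            m_seg = modulated_unit[a:b]
            g_seg = background_unit[a:b]
            p_mcg = float(np.mean(np.square(mcg.samples[a:b])))
            if p_mcg == 0.0:
                raise ValueError(f"load segment {l} has a silent MCG; cannot calibrate")
            target_power = 10.0 ** (targets[l] / 10.0) * p_mcg
            pa = float(np.mean(np.square(m_seg)))
            pb = 2.0 * f * s_min * float(np.mean(m_seg * g_seg))
            pc = (f * s_min) ** 2 * float(np.mean(np.square(g_seg))) - target_power
            disc = pb * pb - 4.0 * pa * pc
            if disc < 0:
                raise ValueError(
                    f"load {l}: background noise alone exceeds the target clean "
                    f"power; no positive amplitude solves the SNR target"
                )
            scales[l] = (-pb + np.sqrt(disc)) / (2.0 * pa)
        if f == 0.0 or np.max(np.abs(scales - prev)) < tol:
            break
    return scales


def synthesize(
    protocol: Optional[EnvelopeProtocol] = None,
    mcg_model: Optional[MCGModel] = None,
    background_sd_fraction: float = DEFAULT_BACKGROUND_SD_FRACTION,
    seed: int = 0,
) -> SynthesizedRecord:
    """Generate one complete synthesized record (ENV, MMGc, MCG, MMGn).

    Orchestrates envelope construction, cardiac-train generation, per-load
    SNR calibration and clean-MMG synthesis; the noisy signal is the exact
    sum of the clean and cardiac components. Fully reproducible from
    ``(protocol, mcg_model, seed)``.
    """
    protocol = protocol if protocol is not None else EnvelopeProtocol()
    mcg_model = mcg_model if mcg_model is not None else MCGModel()

    n = protocol.n_samples
    mcg = make_mcg(n / protocol.fs, mcg_model, seed=seed, fs=protocol.fs)
    scales = calibrate_load_scales(
        protocol, mcg, seed=seed, background_sd_fraction=background_sd_fraction
    )
    env = make_envelope(protocol, load_scales=scales)
    mmg_clean = make_clean_mmg(env, background_sd_fraction, seed=seed)
    mmg_noisy = Signal(mmg_clean.samples + mcg.samples, protocol.fs)

    return SynthesizedRecord(
        env=env.signal,
        mmg_clean=mmg_clean,
        mcg=mcg,
        mmg_noisy=mmg_noisy,
        cycle_bounds=env.cycle_bounds,
        load_bounds=env.load_bounds,
        load_scales=scales,
        seed=seed,
        protocol=protocol,
        mcg_model=mcg_model,
        background_sd_fraction=background_sd_fraction,
    )
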