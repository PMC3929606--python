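"""Tests of correlations, per-cycle mean relative error, sweeps and maxima."""

import numpy as np
import pytest

from fsampen import (
    EstimatorTrace,
    FSampEnParams,
    MovingWindowSpec,
    Signal,
    align_reference,
    cycle_maxima,
    estimator_trace,
    load_correlations,
    mre_per_cycle,
    pearson_r,
    tolerance_sweep,
)
from fsampen.evaluation import paired_traces
from fsampen.synth import SynthesizedRecord, EnvelopeProtocol, MCGModel

from conftest import mre_oracle


def _make_trace(times, values, fs=1.0, window_s=1.0, overlap=0.0, name="ARV"):
    return EstimatorTrace(
        times=np.asarray(times, dtype=float),
        values=np.asarray(values, dtype=float),
        estimator_name=name,
        window=MovingWindowSpec(window_s, overlap),
        fs=fs,
    )


def _toy_record(n=60, fs=1.0, cycle_bounds=((0, 30, 60),), load_bounds=((0, 60),)):
    """A minimal hand-built record for plumbing tests (signals are dummies)."""
    z = Signal(np.arange(float(n)), fs)
    return SynthesizedRecord(
        env=z,
        mmg_clean=z,
        mcg=z,
        mmg_noisy=z,
        cycle_bounds=np.array(cycle_bounds, dtype=np.int64),
        load_bounds=np.array(load_bounds, dtype=np.int64),
        load_scales=np.ones(len(load_bounds)),
        seed=0,
    )


class TestAlignReference:
    def test_center_mode_identity(self):
        ref = Signal(np.arange(100.0), fs=1.0)
        trace = _make_trace([10.0, 20.0, 30.0], [0, 0, 0])
        assert np.array_equal(
            align_reference(ref, trace, mode="center"), [10.0, 20.0, 30.0]
        )

    def test_constant_reference(self):
        ref = Signal(np.full(100, 7.0), fs=1.0)
        trace = _make_trace([5.0, 50.0], [0, 0])
        for mode in ("center", "window_mean"):
            assert np.all(align_reference(ref, trace, mode=mode) == 7.0)

    def test_linear_ramp_window_centers(self):
        # on a ramp, both alignments equal the ramp at the window center
        fs = 200.0
        ref = Signal(np.arange(int(5 * fs)) / fs, fs)  # ramp with slope 1/s
        sig = ref
        trace = estimator_trace(sig, MovingWindowSpec(1.0, 0.9), "ARV")
        for mode in ("center", "window_mean"):
            vals = align_reference(ref, trace, mode=mode)
            assert np.all(np.abs(vals - trace.times) <= 1.0 / fs)

    def test_out_of_range_times_error(self):
        ref = Signal(np.arange(10.0), fs=1.0)
        trace = _make_trace([5.0, 20.0], [0, 0])
        with pytest.raises(ValueError, match="outside"):
            align_reference(ref, trace, mode="center")


class TestPearson:
    def test_affine_and_inverse(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_r(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_direct_formula_value(self):
        # 149 / sqrt(5 * 7205), computed by hand from the product-moment formula
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 100]) == pytest.approx(
            149.0 / np.sqrt(5.0 * 7205.0), rel=1e-12
        )

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.normal(size=(2, 30))
            r = pearson_r(a, b)
            assert r == pytest.approx(pearson_r(b, a))
            assert -1.0 <= r <= 1.0
            assert pearson_r(2 * a + 3, b) == pytest.approx(r)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMRE:
    def test_identical_traces_zero(self):
        rec = _toy_record()
        t = _make_trace(np.arange(5.0, 25.0, 5.0), [1.0, 2.0, 3.0, 4.0])
        cm = mre_per_cycle(t, t, rec)
        assert cm.per_cycle_errors[0] == 0.0

    def test_hand_example(self):
        # Xc=[1,2,4], Xn=[2,1,4] in one inspiratory cycle -> (1/1 + 1/2 + 0)/3 = 0.5
        rec = _toy_record()
        clean = _make_trace([5.0, 10.0, 15.0], [1.0, 2.0, 4.0])
        noisy = _make_trace([5.0, 10.0, 15.0], [2.0, 1.0, 4.0])
        cm = mre_per_cycle(clean, noisy, rec)
        assert cm.per_cycle_errors[0] == pytest.approx(0.5)

    def test_proportional_error(self):
        rec = _toy_record(cycle_bounds=((0, 30, 60),), n=60)
        times = np.arange(2.0, 28.0, 3.0)
        clean = _make_trace(times, np.linspace(1, 5, times.size))
        noisy = _make_trace(times, 1.1 * np.linspace(1, 5, times.size))
        cm = mre_per_cycle(clean, noisy, rec)
        assert cm.per_cycle_errors[0] == pytest.approx(0.1)

    def test_zero_clean_points_excluded_and_tallied(self):
        rec = _toy_record()
        clean = _make_trace([5.0, 10.0, 15.0], [0.0, 2.0, 4.0])
        noisy = _make_trace([5.0, 10.0, 15.0], [1.0, 1.0, 4.0])
        cm = mre_per_cycle(clean, noisy, rec)
        assert cm.n_excluded == 1
        assert cm.per_cycle_errors[0] == pytest.approx((0.5 + 0.0) / 2)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(7)
        bounds = [(0, 25, 50), (50, 80, 100), (100, 120, 150)]
        rec = _toy_record(n=150, cycle_bounds=bounds, load_bounds=((0, 150),))
        times = np.arange(1.0, 149.0, 2.5)
        for _ in range(10):
            clean = _make_trace(times, rng.uniform(0.1, 5.0, times.size))
            noisy = _make_trace(times, rng.uniform(0.1, 5.0, times.size))
            cm = mre_per_cycle(clean, noisy, rec)
            samples = np.rint(times * rec.fs).astype(int)
            expected = mre_oracle(clean.values, noisy.values, samples, bounds)
            assert np.allclose(cm.per_cycle_errors, expected, equal_nan=True)

    def test_load_summary_uses_only_contained_cycles(self):
        bounds = [(0, 20, 40), (40, 60, 80)]
        rec = _toy_record(n=80, cycle_bounds=bounds, load_bounds=((0, 40), (40, 80)))
        times = np.array([5.0, 10.0, 45.0, 50.0])
        clean = _make_trace(times, [1.0, 1.0, 2.0, 2.0])
        noisy = _make_trace(times, [1.5, 1.5, 3.0, 3.0])
        cm = mre_per_cycle(clean, noisy, rec)
        assert cm.load_means[0] == pytest.approx(0.5)
        assert cm.load_means[1] == pytest.approx(0.5)
        assert np.array_equal(cm.cycle_loads, [0, 1])


class TestToleranceSweep:
    def test_table_shape_and_baseline_invariance(self, small_record):
        r_grid = np.round(np.arange(0.1, 1.0001, 0.05), 2)
        corr, mre = tolerance_sweep(small_record, r_grid, MovingWindowSpec(1.0, 0.9))
        # 19 r values x 3 estimators x (4 loads + whole record)
        assert len(corr) == 19 * 3 * 5
        arv_rows = corr[corr.estimator == "ARV"]
        for load, group in arv_rows.groupby("load"):
            assert group["R"].nunique() == 1  # baselines do not depend on r
        assert set(mre.estimator) == {"fSampEn", "ARV", "RMS"}
        assert (mre.mre >= 0).all()

    def test_clean_beats_noisy_at_low_snr(self, default_record, window):
        # without cardiac noise every estimator tracks the envelope better
        # than the same estimator on the noisy signal at the lowest SNR
        for name in ("fSampEn", "ARV", "RMS"):
            params = FSampEnParams() if name == "fSampEn" else None
            clean_tr = estimator_trace(default_record.mmg_clean, window, name, params)
            noisy_tr = estimator_trace(default_record.mmg_noisy, window, name, params)
            r_clean = load_correlations(clean_tr, default_record).r_by_load
            r_noisy = load_correlations(noisy_tr, default_record).r_by_load
            assert np.all(r_clean[0] > r_noisy[0])

    def test_invalid_r_values(self, small_record):
        with pytest.raises(ValueError):
            tolerance_sweep(small_record, [], MovingWindowSpec())
        with pytest.raises(ValueError):
            tolerance_sweep(small_record, [0.3, -0.1], MovingWindowSpec())


class TestCycleMaxima:
    def test_reference_equals_trace(self, small_record, window):
        trace = estimator_trace(small_record.env, window, "ARV")
        table = cycle_maxima(trace, small_record.env, small_record)
        assert len(table) == small_record.cycle_bounds.shape[0]
        # ARV of the (non-negative) envelope differs from its aligned mean
        # only through windowing; maxima correlate essentially perfectly
        assert pearson_r(table.ref_max, table.est_max) > 0.99

    def test_load_means_increase_with_amplitude(self, default_record, window):
        trace = estimator_trace(default_record.env, window, "ARV")
        table = cycle_maxima(trace, default_record.env, default_record)
        means = table.groupby("load")["ref_max"].mean()
        assert np.all(np.diff(means[sorted(means.index)]) > 0)

    def test_whole_record_correlation_favors_fsampen(self, window):
        # against the instantaneous envelope (the windowed estimates are
        # correlated with the reference value at each window center, as one
        # would correlate a full-rate effort signal), whole-record R of
        # fSampEn with a tolerance factor in the 0.3-0.6 band exceeds ARV's
        # and RMS's across seeds: its trace is smoother, so it loses less
        # to the estimate-vs-instant mismatch
        wins_arv = wins_rms = 0
        n_seeds = 10
        from fsampen import synthesize

        for seed in range(201, 201 + n_seeds):
            rec = synthesize(seed=seed)
            r_whole = {}
            for name in ("fSampEn", "ARV", "RMS"):
                params = FSampEnParams(r_value=0.45) if name == "fSampEn" else None
                tr = estimator_trace(rec.mmg_noisy, window, name, params)
                ref = align_reference(rec.env, tr, mode="center")
                valid = ~np.isnan(tr.values)
                r_whole[name] = pearson_r(tr.values[valid], ref[valid])
            wins_arv += r_whole["fSampEn"] > r_whole["ARV"]
            wins_rms += r_whole["fSampEn"] > r_whole["RMS"]
        assert wins_arv >= 9
        assert wins_rms >= 9


class TestPairedTraces:
    def test_shared_absolute_tolerance(self, small_record, window):
        clean, noisy = paired_traces(small_record, window, "fSampEn", FSampEnParams())
        assert clean.params.r_mode == "absolute"
        assert clean.params.r_value == noisy.params.r_value
        from fsampen import fixed_tolerance

        assert clean.params.r_value == pytest.approx(
            fixed_tolerance(small_record.mmg_noisy, FSampEnParams())
        )
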