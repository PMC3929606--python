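"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (double loops, direct formula
transcription) and independent of the package's vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from fsampen import EnvelopeProtocol, MovingWindowSpec, synthesize


def sampen_match_counts_oracle(x, m: int, r: float) -> tuple[int, int]:
    """Brute-force ordered-pair template match counts (B, A).

    Templates i = 1..N-m at both lengths, Chebyshev distance <= r,
    self-matches excluded. O(N^2 m), trusted by inspection.
    """
    x = [float(v) for v in x]
    n = len(x)
    b_total = 0
    a_total = 0
    for i in range(n - m):
        for j in range(n - m):
            if j == i:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b_total += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a_total += 1
    return b_total, a_total


def sampen_oracle(x, m: int, r: float) -> float:
    """Brute-force SampEn; assumes both match counts are positive."""
    b_total, a_total = sampen_match_counts_oracle(x, m, r)
    return -math.log(a_total / b_total)


def mre_oracle(clean_vals, noisy_vals, point_samples, cycle_bounds):
    """Naive per-point mean relative error per inspiratory cycle.

    ``point_samples`` holds each trace point's window-center sample index;
    points with a zero clean value or NaNs are skipped.
    """
    errors = []
    for insp_start, insp_end, _ in cycle_bounds:
        terms = []
        for xc, xn, s in zip(clean_vals, noisy_vals, point_samples):
            if not (insp_start <= s < insp_end):
                continue
            if math.isnan(xc) or math.isnan(xn) or xc == 0:
                continue
            terms.append(abs(xc - xn) / xc)
        errors.append(sum(terms) / len(terms) if terms else math.nan)
    return errors


@pytest.fixture(scope="session")
def window():
    return MovingWindowSpec(window_length_s=1.0, overlap_fraction=0.9)


@pytest.fixture(scope="session")
def default_record():
    """One full-size synthesized record (4 loads x 10 cycles, 133.33 s)."""
    return synthesize(seed=11)


@pytest.fixture(scope="session")
def small_protocol():
    """A shortened protocol (4 loads x 3 cycles) for fast structural tests."""
    return EnvelopeProtocol(cycles_per_load=3)


@pytest.fixture(scope="session")
def small_record(small_protocol):
    return synthesize(protocol=small_protocol, seed=5)
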