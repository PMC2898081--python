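"""Shared fixtures: synthetic cohorts and independent brute-force oracles."""

from __future__ import annotations

import functools
import math

import numpy as np
import pytest

import rotasig as rs


@functools.lru_cache(maxsize=32)
def _cohort(n, amplitude, seed, upstream, downstream, cpg_fraction, nonisland_amplitude):
    cfg = rs.SynthConfig(
        n_promoters=n,
        upstream=upstream,
        downstream=downstream,
        planted_amplitude=amplitude,
        cpg_fraction=cpg_fraction,
        nonisland_amplitude=nonisland_amplitude,
        seed=seed,
    )
    return rs.generate_promoters(cfg)


@pytest.fixture(scope="session")
def make_cohort():
    """Factory for seed-fixed synthetic cohorts (cached across the session).

    The short default window (12 bp upstream, 200 bp downstream) covers the
    default statistic region plus the shift-null margin.
    """

    def factory(n=1000, amplitude=0.0, seed=0, upstream=12, downstream=200,
                cpg_fraction=0.0, nonisland_amplitude=0.0):
        return _cohort(n, amplitude, seed, upstream, downstream,
                       cpg_fraction, nonisland_amplitude)

    return factory


def direct_dft_power(series, include_dc=False):
    """O(N^2) reference periodogram: mean-subtract, Hamming, DFT sums, |X|^2/N.

    Written from the definitions, independent of any FFT routine; returns the
    raw (unnormalized) one-sided power.
    """
    x = [float(v) for v in series]
    n = len(x)
    mean = sum(x) / n
    x = [v - mean for v in x]
    w = [0.54 - 0.46 * math.cos(2.0 * math.pi * i / (n - 1)) for i in range(n)]
    xw = [a * b for a, b in zip(x, w)]
    k0 = 0 if include_dc else 1
    power = []
    for k in range(k0, n // 2 + 1):
        re = sum(xw[t] * math.cos(-2.0 * math.pi * k * t / n) for t in range(n))
        im = sum(xw[t] * math.sin(-2.0 * math.pi * k * t / n) for t in range(n))
        power.append((re * re + im * im) / n)
    return np.array(power)


def brute_force_pwm_scores(seq, probs):
    """Per-offset product-probability oracle (pure-python window loop)."""
    order = "ACGT"
    w = probs.shape[1]
    out = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if any(b not in order for b in window):
            out.append(float("nan"))
            continue
        score = 1.0
        for j, b in enumerate(window):
            score *= probs[order.index(b), j]
        out.append(score)
    return np.array(out)
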