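"""Null and sampling distributions for the periodicity statistic.

Three randomization schemes:

* **shift null** — every sequence is offset by a uniform random 1-9 bp at its
  5' end before the average class profile is formed, destroying the phase
  coherence with the TSS while leaving composition untouched.  The observed
  statistic is compared to the distribution of shifted-set statistics.
* **bootstrap** — the magnitude is not defined per sequence, so group
  comparisons resample promoters with replacement and recompute the statistic
  on each sample's average RR profile (RR serves as a proxy for the joint
  RR/YY signal).  Distributions of a few thousand replicates are
  approximately normal (checked with a Kolmogorov-Smirnov diagnostic) and are
  compared by Wilcoxon rank-sum tests.
* **label permutation** — association between two binary promoter properties
  is tested by shuffling one label vector and counting co-occurrences.

All operations are bit-for-bit reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .profiles import class_indicator
from .spectral import DEFAULT_STAT, StatConfig, _start_column, _windowed_smoothed_mean, batch_magnitudes
from .tss_io import AlignedSeqSet

__all__ = [
    "NullDistribution",
    "shift_null",
    "bootstrap_magnitudes",
    "normality_check",
    "compare_groups",
    "label_association_test",
    "empirical_p",
]


@dataclass
class NullDistribution:
    """Replicated statistic values from one randomization scheme."""

    values: np.ndarray
    kind: str  # shift | bootstrap | permutation
    n_iter: int
    seed: Optional[int]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_iter:
            raise ValueError("values length must equal n_iter")

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.values, q)

    def summary(self) -> dict:
        v = self.values
        return {
            "kind": self.kind,
            "n_iter": self.n_iter,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "q05": float(np.quantile(v, 0.05)),
            "median": float(np.median(v)),
            "q95": float(np.quantile(v, 0.95)),
        }


def empirical_p(observed: float, null_values, alternative: str = "greater") -> float:
    """Permutation-style p with the (b+1)/(n+1) correction."""
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    if alternative == "greater":
        b = int(np.sum(null_values >= observed))
    elif alternative == "less":
        b = int(np.sum(null_values <= observed))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (b + 1) / (n + 1)


# ---------------------------------------------------------------------------
# Shift null

def shift_null(seqs: AlignedSeqSet, config: StatConfig = DEFAULT_STAT,
               n_iter: int = 500, shift_min: int = 1, shift_max: int = 9,
               seed: Optional[int] = None, per_sequence: bool = True) -> NullDistribution:
    """Random 5'-shift null distribution of the periodicity magnitude.

    Each iteration draws a uniform random shift in [shift_min, shift_max] for
    every sequence (or one global shift with ``per_sequence=False``, a
    sensitivity mode), slides that sequence's analysis window upstream by the
    shift — equivalent to prepending bases at the 5' end — recomputes the
    average class series and its 10-bp magnitude.  A zero shift would be the
    observed statistic, not a null draw, so ``shift_min`` must be >= 1.
    """
    if shift_min < 1:
        raise ValueError("shift_min must be >= 1 (zero shift is the observed statistic)")
    if shift_max < shift_min:
        raise ValueError("shift_max must be >= shift_min")
    n = len(seqs)
    if n == 0:
        raise ValueError("empty sequence set")

    member, valid = class_indicator(seqs, config.cls)
    memberf = member.astype(np.float32)
    all_valid = bool(valid.all())
    validf = None if all_valid else valid.astype(np.float32)

    h = config.smooth_bp // 2
    start = _start_column(seqs, config)
    width = config.series_len + 2 * h
    if start - shift_max - h < 0:
        raise ValueError("sequences do not extend far enough upstream for the shift range")

    shifts_values = np.arange(shift_min, shift_max + 1)
    # Pre-sliced windows, one per possible shift.
    mem_by_shift = {int(s): memberf[:, start - s - h : start - s - h + width] for s in shifts_values}
    val_by_shift = (None if all_valid else
                    {int(s): validf[:, start - s - h : start - s - h + width] for s in shifts_values})

    rng = np.random.default_rng(seed)
    series = np.empty((n_iter, width))
    for it in range(n_iter):
        if per_sequence:
            shifts = rng.integers(shift_min, shift_max + 1, size=n)
        else:
            shifts = np.full(n, rng.integers(shift_min, shift_max + 1))
        num = np.zeros(width, dtype=np.float64)
        den = np.zeros(width, dtype=np.float64) if not all_valid else None
        for s in shifts_values:
            sel = shifts == s
            if not sel.any():
                continue
            self32 = sel.astype(np.float32)
            num += self32 @ mem_by_shift[int(s)]
            if den is not None:
                den += self32 @ val_by_shift[int(s)]
        if den is None:
            series[it] = num / n
        else:
            if np.any(den == 0):
                raise ValueError("shifted region contains positions with no informative sequence")
            series[it] = num / den

    from .profiles import moving_average

    if config.smooth_bp > 1:
        series = moving_average(series, config.smooth_bp, axis=-1)
    series = series[:, h : h + config.series_len]
    values = batch_magnitudes(series, config, presmoothed=True)
    return NullDistribution(
        values, "shift", n_iter, seed,
        params={"shift_min": shift_min, "shift_max": shift_max,
                "per_sequence": per_sequence, "feature": config.feature},
    )


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_magnitudes(seqs: AlignedSeqSet, sample_size: int = 1000,
                         n_boot: int = 5000, config: StatConfig = DEFAULT_STAT,
                         seed: Optional[int] = None,
                         chunk: int = 2000) -> NullDistribution:
    """Bootstrap distribution of the magnitude over with-replacement samples.

    Each replicate draws ``sample_size`` promoters with replacement (the
    sample may exceed the population size), averages their class profile and
    recomputes the statistic.
    """
    n = len(seqs)
    if n == 0:
        raise ValueError("empty sequence set")
    if sample_size < 50:
        raise ValueError("sample_size must be >= 50")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    member, valid = class_indicator(seqs, config.cls)
    h = config.smooth_bp // 2
    start = _start_column(seqs, config)
    lo = max(start - h, 0)
    hi = min(start + config.series_len + h, member.shape[1])
    memberf = member[:, lo:hi].astype(np.float32)
    all_valid = bool(valid[:, lo:hi].all())
    validf = None if all_valid else valid[:, lo:hi].astype(np.float32)

    rng = np.random.default_rng(seed)
    p = np.full(n, 1.0 / n)
    mags = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        counts = rng.multinomial(sample_size, p, size=m).astype(np.float32)
        num = counts @ memberf
        if all_valid:
            series = num / np.float32(sample_size)
        else:
            den = counts @ validf
            if np.any(den == 0):
                raise ValueError("bootstrap sample has positions with no informative sequence")
            series = num / den
        series = _trim_smooth(series.astype(float), start - lo, config)
        mags[done : done + m] = batch_magnitudes(series, config, presmoothed=True)
        done += m
    return NullDistribution(
        mags, "bootstrap", n_boot, seed,
        params={"sample_size": sample_size, "feature": config.feature},
    )


def _trim_smooth(series: np.ndarray, offset_in_slice: int, config: StatConfig) -> np.ndarray:
    from .profiles import moving_average

    if config.smooth_bp > 1:
        series = moving_average(series, config.smooth_bp, axis=-1)
    return series[:, offset_in_slice : offset_in_slice + config.series_len]


# ---------------------------------------------------------------------------
# Diagnostics and comparisons

def normality_check(d: NullDistribution):
    """KS comparison of the replicate values against N(mean, sd).

    Used as a stopping diagnostic for the number of bootstrap samplings (a few
    thousand replicates should not be rejected at p < 1e-5).
    """
    v = np.asarray(d.values, dtype=float)
    if v.size < 100:
        raise ValueError("need at least 100 replicates for the normality check")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (zero-variance) distribution")
    res = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def compare_groups(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value between two replicate distributions.

    ``alternative='less'`` tests that ``a`` is stochastically smaller than
    ``b``.  Accepts :class:`NullDistribution` objects or plain arrays.
    """
    va, vb = _values(a), _values(b)
    if va.size == 0 or vb.size == 0:
        raise ValueError("both distributions must be non-empty")
    return float(stats.mannwhitneyu(va, vb, alternative=alternative).pvalue)


def label_association_test(labels_a, labels_b, n_perm: int = 10000,
                           seed: Optional[int] = None, chunk: int = 2000) -> float:
    """Permutation p-value for co-occurrence of two binary promoter labels.

    Statistic: number of promoters positive for both.  One label vector is
    shuffled ``n_perm`` times; p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    a = np.asarray(labels_a).astype(bool)
    b = np.asarray(labels_b).astype(bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    for name, v in (("labels_a", a), ("labels_b", b)):
        if v.all() or not v.any():
            raise ValueError(f"{name} must contain both classes")
    observed = int(np.sum(a & b))
    rng = np.random.default_rng(seed)
    af = a.astype(np.float32)
    bf = b.astype(np.float32)
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(bf, (m, 1)), axis=1)
        stats_chunk = perm @ af
        exceed += int(np.sum(stats_chunk >= observed))
        done += m
    return (exceed + 1) / (n_perm + 1)
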