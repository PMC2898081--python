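"""Per-position composition profiles across a TSS-aligned sequence set.

A profile is the fraction of sequences carrying a given base (or a
dinucleotide from a given class) at each TSS-relative position — the aggregate
curves in which the 10-bp RR/YY periodicity becomes visible even though
individual promoters carry no detectable signal.  ``N`` bases are excluded
from denominators; a dinucleotide contributes only when both bases are non-N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import FrozenSet

import numpy as np

from .tss_io import AlignedSeqSet

__all__ = [
    "RR", "YY", "RY", "YR", "WW", "SS", "DINUCLEOTIDE_CLASSES",
    "PositionProfile",
    "nucleotide_profile", "dinucleotide_class_profile", "smooth_profile",
    "class_indicator", "moving_average",
]

#: Purine-purine and pyrimidine-pyrimidine dinucleotide classes.
RR: FrozenSet[str] = frozenset({"AA", "AG", "GA", "GG"})
YY: FrozenSet[str] = frozenset({"CC", "CT", "TC", "TT"})
RY: FrozenSet[str] = frozenset({"AC", "AT", "GC", "GT"})
YR: FrozenSet[str] = frozenset({"CA", "CG", "TA", "TG"})
WW: FrozenSet[str] = frozenset({"AA", "AT", "TA", "TT"})
SS: FrozenSet[str] = frozenset({"CC", "CG", "GC", "GG"})

DINUCLEOTIDE_CLASSES = {"RR": RR, "YY": YY, "RY": RY, "YR": YR, "WW": WW, "SS": SS}

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PositionProfile:
    """Per-position frequency series on the TSS-relative frame.

    ``offsets`` are internal 0-based offsets (offset 0 = the +1 base); for
    dinucleotide profiles an offset is the start position of the pair.
    ``n_effective`` counts the sequences contributing at each position
    (non-N); positions with ``n_effective == 0`` hold NaN.
    """

    values: np.ndarray
    offsets: np.ndarray
    feature: str
    n_effective: np.ndarray


def nucleotide_profile(seqs: AlignedSeqSet, base: str) -> PositionProfile:
    """Fraction of sequences with ``base`` at each position."""
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    if base not in _BASE_TO_CODE:
        raise ValueError(f"base must be one of A,C,G,T, got {base!r}")
    codes = seqs.codes
    valid = codes < 4
    num = (codes == _BASE_TO_CODE[base]).sum(axis=0)
    den = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    offsets = np.arange(seqs.length) - seqs.offset_of_tss
    return PositionProfile(values, offsets, base, den)


def class_indicator(seqs: AlignedSeqSet, cls: FrozenSet[str]):
    """Boolean (n, L-1) matrices (member, valid) for a dinucleotide class.

    ``member[i, j]`` is True when the pair starting at column j of sequence i
    belongs to ``cls``; ``valid`` requires both bases non-N.  This is the
    shared substrate for profiles and for the resampling machinery, which
    needs to re-window the same indicator under random shifts and bootstrap
    weights without re-reading sequence strings.
    """
    if not cls:
        raise ValueError("empty dinucleotide class")
    lut = np.zeros((5, 5), dtype=bool)
    for d in cls:
        if len(d) != 2 or d[0] not in _BASE_TO_CODE or d[1] not in _BASE_TO_CODE:
            raise ValueError(f"not a dinucleotide over ACGT: {d!r}")
        lut[_BASE_TO_CODE[d[0]], _BASE_TO_CODE[d[1]]] = True
    codes = seqs.codes
    first, second = codes[:, :-1], codes[:, 1:]
    member = lut[first, second]
    valid = (first < 4) & (second < 4)
    return member, valid


def dinucleotide_class_profile(seqs: AlignedSeqSet, cls, name: str | None = None) -> PositionProfile:
    """Fraction of sequences whose dinucleotide starting at each offset is in ``cls``.

    ``cls`` may be a set of dinucleotides or a named class ("RR", "YY", ...).
    """
    if isinstance(cls, str):
        name = name or cls
        cls = DINUCLEOTIDE_CLASSES[cls]
    cls = frozenset(cls)
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    member, valid = class_indicator(seqs, cls)
    num = member.sum(axis=0)
    den = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    offsets = np.arange(seqs.length - 1) - seqs.offset_of_tss
    label = name or "".join(sorted(cls))
    return PositionProfile(values, offsets, label, den)


def moving_average(a: np.ndarray, window: int, axis: int = -1) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges.

    For even ``window`` the span is asymmetric: ``window//2 - 1`` positions to
    the left and ``window//2`` to the right (relevant for the 70-bp tag-density
    smoothing; profile smoothing uses odd windows).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(a, dtype=float).copy()
    a = np.moveaxis(np.asarray(a, dtype=float), axis, -1)
    n = a.shape[-1]
    left, right = (window - 1) // 2, window // 2
    cs = np.cumsum(np.concatenate([np.zeros(a.shape[:-1] + (1,)), a], axis=-1), axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    out = (cs[..., hi] - cs[..., lo]) / (hi - lo)
    return np.moveaxis(out, -1, axis)


def smooth_profile(p: PositionProfile, window_bp: int = 3) -> PositionProfile:
    """Centered moving-average smoothing (odd window; edges shrink)."""
    if window_bp < 1 or window_bp % 2 == 0:
        raise ValueError("window_bp must be odd and >= 1")
    if window_bp == 1:
        return replace(p, values=p.values.copy())
    finite = np.isfinite(p.values)
    vals = np.where(finite, p.values, 0.0)
    sizes = _window_sizes(len(vals), window_bp)
    total = moving_average(vals, window_bp) * sizes  # windowed sums of finite values
    count = np.rint(moving_average(finite.astype(float), window_bp) * sizes)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return replace(p, values=smoothed, feature=f"{p.feature} (smoothed {window_bp} bp)")


def _window_sizes(n: int, window: int) -> np.ndarray:
    left, right = (window - 1) // 2, window // 2
    idx = np.arange(n)
    return np.minimum(idx + right + 1, n) - np.maximum(idx - left, 0)
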