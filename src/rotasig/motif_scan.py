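"""Sliding local-probability PWM scan over promoter windows.

A position weight matrix of width W is slid along the -500..+500 region
around each TSS; the score at a start offset is the product of the
per-column base probabilities (a "local probability", not a log-odds
ratio).  An offset is a match when its score exceeds the arithmetic mean of
all defined scores along the region, and a promoter is reported when the
region of interest immediately downstream of the TSS contains exactly one
such match (uniqueness is part of the call by default).  Specificity is
checked by shuffling the PWM columns and re-counting matches: column
shuffling preserves the composition of the matrix but destroys the motif's
positional structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
import warnings

import numpy as np

from .coords import display_to_offset
from .resampling import NullDistribution, empirical_p
from .tss_io import AlignedSeqSet

__all__ = [
    "Pwm",
    "MotifMatch",
    "ScanResult",
    "read_pwm",
    "write_pwm",
    "scan_local_probability",
    "scan_set",
    "call_matches",
    "column_shuffle_control",
]

_ROW_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ROW_ORDER)}


@dataclass
class Pwm:
    """Column-stochastic base probabilities, rows A, C, G, T."""

    probs: np.ndarray  # (4, W)
    id: str = ""
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x W matrix (rows A,C,G,T)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 0.01, id: str = "") -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x W matrix (rows A,C,G,T)")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if pseudocount == 0 and np.any(counts == 0):
            warnings.warn("zero counts with pseudocount 0 give hard-zero probabilities",
                          stacklevel=2)
        adj = counts + pseudocount
        return cls(adj / adj.sum(axis=0, keepdims=True), id=id, pseudocount=pseudocount)

    def consensus(self) -> str:
        return "".join(_ROW_ORDER[i] for i in self.probs.argmax(axis=0))

    def shuffled_columns(self, rng: np.random.Generator) -> "Pwm":
        """Column permutation that alters the positional structure.

        Permutations preserving the consensus string (possible when the
        consensus repeats letters) leave planted sites matching and would
        make the shuffle control vacuous; they are redrawn.
        """
        consensus = self.consensus()
        perm = rng.permutation(self.width)
        if len(set(consensus)) > 1:
            while "".join(consensus[j] for j in perm) == consensus:
                perm = rng.permutation(self.width)
        return Pwm(self.probs[:, perm], id=f"{self.id}|shuffled",
                   pseudocount=self.pseudocount)


@dataclass
class MotifMatch:
    tss_id: str
    offset: int  # TSS-relative internal start offset of the match
    local_prob: float
    regional_mean: float
    unique_in_window: bool


@dataclass
class ScanResult:
    """Per-offset local probabilities for one promoter window."""

    tss_id: str
    offsets: np.ndarray  # internal TSS-relative start offsets
    scores: np.ndarray  # NaN where the window contains N
    regional_mean: float


# ---------------------------------------------------------------------------
# TRANSFAC-like matrix file I/O

def read_pwm(path, pseudocount: float = 0.01) -> Pwm:
    """Read a TRANSFAC-style count block into a normalized PWM.

    Accepts the usual layout — an optional ``P0 A C G T`` header followed by
    numbered position rows with four counts (an optional trailing consensus
    letter is ignored); ``ID``/``NA``/``//``/``XX`` bookkeeping lines are
    skipped.  Counts are normalized per column after adding ``pseudocount``.
    """
    rows: list[list[float]] = []
    pwm_id = ""
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("//", "XX", "#")):
            continue
        tokens = line.split()
        tag = tokens[0].upper()
        if tag in {"ID", "NA", "AC", "DE", "BF"}:
            if len(tokens) > 1 and not pwm_id:
                pwm_id = tokens[1]
            continue
        if tag == "P0" or tag == "PO":
            continue
        def _floats(toks):
            out = []
            for t in toks:
                try:
                    out.append(float(t))
                except ValueError:
                    break
            return out

        nums = _floats(tokens)
        if tag[0].isdigit() and len(nums) != 4:
            nums = _floats(tokens[1:])  # leading position index
        if not nums:
            continue
        if len(nums) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 counts, got {len(nums)}")
        rows.append(nums)
    if not rows:
        raise ValueError(f"{path}: no matrix rows found")
    counts = np.asarray(rows, dtype=float).T  # positions-as-rows -> 4 x W
    return Pwm.from_counts(counts, pseudocount=pseudocount, id=pwm_id or Path(path).stem)


def write_pwm(counts, path, id: str = "matrix") -> None:
    """Write a 4 x W count (or probability) matrix as a TRANSFAC-like block."""
    counts = np.asarray(counts, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"ID {id}\nP0      A      C      G      T\n")
        for j in range(counts.shape[1]):
            vals = "  ".join(f"{counts[i, j]:6.2f}" for i in range(4))
            fh.write(f"{j + 1:02d}  {vals}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# Scanning

def _window_scores(codes: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Product-probability scores for every start offset of each row of codes."""
    w = pwm.width
    lut = np.vstack([pwm.probs, np.full((1, w), np.nan)])  # row 4 = N
    n_offsets = codes.shape[1] - w + 1
    if n_offsets < 1:
        raise ValueError(f"region shorter than the PWM width ({w})")
    scores = np.ones(codes.shape[:1] + (n_offsets,))
    for j in range(w):
        scores = scores * lut[codes[:, j : j + n_offsets], j]
    return scores


def scan_local_probability(seq: str, pwm: Pwm, start_offset: int = -500,
                           tss_id: str = "") -> ScanResult:
    """Scan one promoter window string; offsets are TSS-relative.

    ``start_offset`` is the internal offset of ``seq[0]`` (default -500, i.e.
    the string covers the -500..+500 display region).  The regional mean is
    the arithmetic mean of all defined scores along the scanned region.
    """
    from .tss_io import BASE_CODES

    codes = BASE_CODES[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)][None, :]
    scores = _window_scores(codes, pwm)[0]
    offsets = np.arange(scores.size) + start_offset
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("no defined scores in region (all windows contain N)")
    return ScanResult(tss_id, offsets, scores, float(scores[finite].mean()))


def scan_set(seqs: AlignedSeqSet, pwm: Pwm,
             region: tuple[int, int] = (-500, 500)) -> list[ScanResult]:
    """Scan every promoter of an aligned set over a display-coordinate region."""
    lo = seqs.offset_of_tss + display_to_offset(region[0])
    hi = seqs.offset_of_tss + display_to_offset(region[1]) + 1
    if lo < 0 or hi > seqs.length:
        raise ValueError("scan region exceeds sequence bounds")
    codes = seqs.codes[:, lo:hi]
    scores = _window_scores(codes, pwm)
    offsets = np.arange(scores.shape[1]) + (lo - seqs.offset_of_tss)
    out = []
    for i, sid in enumerate(seqs.source_ids):
        row = scores[i]
        finite = np.isfinite(row)
        mean = float(row[finite].mean()) if finite.any() else np.nan
        out.append(ScanResult(sid, offsets, row, mean))
    return out


def call_matches(scan: ScanResult, region_of_interest: tuple[int, int] = (0, 40),
                 require_unique: bool = True) -> list[MotifMatch]:
    """Matches in the region of interest (internal start offsets, closed).

    A match is an offset whose score strictly exceeds the regional mean.
    With ``require_unique`` the promoter is reported only when exactly one
    such offset lies in the region; otherwise all matching offsets are
    returned.
    """
    lo, hi = region_of_interest
    if not np.isfinite(scan.regional_mean):
        return []
    sel = (scan.offsets >= lo) & (scan.offsets <= hi)
    with np.errstate(invalid="ignore"):
        hit = sel & (scan.scores > scan.regional_mean)
    idx = np.flatnonzero(hit)
    unique = idx.size == 1
    if require_unique and not unique:
        return []
    return [
        MotifMatch(scan.tss_id, int(scan.offsets[i]), float(scan.scores[i]),
                   scan.regional_mean, unique)
        for i in idx
    ]


def _count_matched(scans: list[ScanResult], roi, require_unique: bool) -> int:
    if require_unique:
        return sum(1 for s in scans if call_matches(s, roi, require_unique=True))
    return sum(len(call_matches(s, roi, require_unique=False)) for s in scans)


def column_shuffle_control(pwm: Pwm, seqs: AlignedSeqSet, n_shuffles: int = 100,
                           seed: Optional[int] = None,
                           region: tuple[int, int] = (-500, 500),
                           region_of_interest: tuple[int, int] = (0, 40),
                           require_unique: bool = False):
    """Column-shuffle specificity control for the match count.

    Returns ``(observed_count, null, p_value)`` where ``null`` is the
    distribution of total occurrence counts in the region of interest over
    ``n_shuffles`` column permutations of the matrix and p is the empirical
    (b+1)/(n+1) value.  By default every above-mean occurrence is counted
    (``require_unique=False``); with ``require_unique=True`` the count is the
    number of promoters carrying exactly one match, the rule used to select
    promoters for downstream analysis.
    """
    if pwm.width < 3:
        raise ValueError("PWM too narrow to shuffle meaningfully")
    observed = _count_matched(scan_set(seqs, pwm, region), region_of_interest, require_unique)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = pwm.shuffled_columns(rng)
        counts[i] = _count_matched(scan_set(seqs, shuffled, region),
                                   region_of_interest, require_unique)
    null = NullDistribution(counts, "permutation", n_shuffles, seed,
                            params={"control": "pwm_column_shuffle"})
    return observed, null, empirical_p(observed, counts, "greater")
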