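"""Tag-density profiles around TSSs and periodicity-by-enrichment analyses.

ChIP-seq reads are reduced to their 5' ends ("tags"): forward- and
reverse-strand tag densities mark the two boundaries of nucleosome-protected
DNA, so around well-positioned +1 nucleosomes the two densities straddle the
periodic region.  Profiles are transcription-oriented: for a minus-strand TSS
the genomic strands swap roles and offsets mirror.  Enrichment scores (tag
counts in the +1-nucleosome region, or ChIP-chip log2 ratios) stratify
promoters into quantile groups whose bootstrap periodicity distributions are
compared and tested for a monotone trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .coords import display_to_offset
from .profiles import PositionProfile, moving_average
from .resampling import NullDistribution, bootstrap_magnitudes, compare_groups
from .spectral import DEFAULT_STAT, StatConfig
from .tss_io import AlignedSeqSet, TssSet, _open_text

__all__ = [
    "TagSet",
    "read_tags_bed",
    "tag_density_profile",
    "region_tag_counts",
    "quantile_partition",
    "periodicity_by_group",
    "GroupPeriodicityResult",
]


@dataclass
class TagSet:
    """Mapped tag 5' positions (1-based genomic) with strands."""

    chrom: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=object)
        if not (self.chrom.shape == self.pos.shape == self.strand.shape):
            raise ValueError("chrom, pos and strand must have equal length")
        if self.pos.size and self.pos.min() < 1:
            raise ValueError("tag positions are 1-based and must be >= 1")
        bad = set(np.unique(self.strand)) - {"+", "-"}
        if bad:
            raise ValueError(f"unknown strand symbols: {bad}")

    def __len__(self) -> int:
        return self.pos.size


def read_tags_bed(path, source: str = "") -> TagSet:
    """Read tag 5' ends from BED6: start+1 on '+', end on '-' (1-based)."""
    chroms, poss, strands = [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 requires 6 columns")
            start, end, strand = int(f[1]), int(f[2]), f[5]
            chroms.append(f[0])
            poss.append(start + 1 if strand == "+" else end)
            strands.append(strand)
    return TagSet(np.array(chroms, dtype=object), np.array(poss),
                  np.array(strands, dtype=object), source=source)


def _tags_by_chrom(tags: TagSet) -> dict:
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(tags.chrom):
        sel = tags.chrom == chrom
        pos = tags.pos[sel]
        strand = tags.strand[sel]
        order = np.argsort(pos, kind="stable")
        index[str(chrom)] = (pos[order], strand[order])
    return index


def _tss_offsets(tss_pos: int, tss_strand: str, pos: np.ndarray):
    """Transcription-oriented offsets of genomic tag positions."""
    if tss_strand == "+":
        return pos - tss_pos
    return tss_pos - pos


def tag_density_profile(tags: TagSet, tss: TssSet,
                        window: tuple[int, int] = (-1000, 1000),
                        strand: str = "forward", smooth_bp: int = 70,
                        per_tss_average: bool = True) -> PositionProfile:
    """Strand-separated tag 5'-end density around TSSs.

    ``window`` is in display coordinates.  A tag is transcription-forward when
    its genomic strand equals the TSS strand (for minus-strand TSSs the
    genomic strands swap roles and offsets mirror).  Counts are summed per
    offset, averaged per TSS (``per_tss_average``; a pooled raw-count mode is
    available), and smoothed with a sliding ``smooth_bp`` window whose span
    shrinks at the edges.
    """
    if strand not in {"forward", "reverse"}:
        raise ValueError("strand must be 'forward' or 'reverse'")
    if smooth_bp < 1:
        raise ValueError("smooth_bp must be >= 1")
    lo = display_to_offset(window[0])
    hi = display_to_offset(window[1])
    n_pos = hi - lo + 1
    counts = np.zeros(n_pos)
    index = _tags_by_chrom(tags)
    want_same = strand == "forward"
    for rec in tss:
        if rec.chrom not in index:
            continue
        pos, tag_strand = index[rec.chrom]
        if rec.strand == "+":
            g_lo, g_hi = rec.pos + lo, rec.pos + hi
        else:
            g_lo, g_hi = rec.pos - hi, rec.pos - lo
        a, b = np.searchsorted(pos, [g_lo, g_hi + 1])
        if b <= a:
            continue
        sub_pos = pos[a:b]
        same = tag_strand[a:b] == rec.strand
        sel = same if want_same else ~same
        offs = _tss_offsets(rec.pos, rec.strand, sub_pos[sel])
        np.add.at(counts, offs - lo, 1.0)
    if per_tss_average and len(tss) > 0:
        counts = counts / len(tss)
    density = moving_average(counts, smooth_bp) if smooth_bp > 1 else counts
    return PositionProfile(density, np.arange(lo, hi + 1),
                           f"{tags.source or 'tags'}:{strand}",
                           np.full(n_pos, len(tss)))


def region_tag_counts(tags: TagSet, tss: TssSet,
                      region: tuple[int, int] = (40, 200)) -> pd.Series:
    """Per-TSS count of tag 5' ends inside a closed display-coordinate region."""
    lo = display_to_offset(region[0])
    hi = display_to_offset(region[1])
    index = _tags_by_chrom(tags)
    out = {}
    for rec in tss:
        if rec.chrom not in index:
            out[rec.id] = 0
            continue
        pos, _ = index[rec.chrom]
        if rec.strand == "+":
            g_lo, g_hi = rec.pos + lo, rec.pos + hi
        else:
            g_lo, g_hi = rec.pos - hi, rec.pos - lo
        a, b = np.searchsorted(pos, [g_lo, g_hi + 1])
        out[rec.id] = int(b - a)
    return pd.Series(out, name="tag_count").rename_axis("tss_id")


def quantile_partition(scores: pd.Series, q: int) -> pd.Series:
    """Rank-based partition into ``q`` groups of near-equal size.

    Group 0 holds the lowest scores.  Ties break by stable input order; when
    n is not divisible by q the larger groups take the lower ranks, so sizes
    differ by at most 1.
    """
    n = len(scores)
    if q < 2:
        raise ValueError("q must be >= 2")
    if n < q:
        raise ValueError(f"need at least q={q} scores, got {n}")
    order = np.argsort(scores.to_numpy(), kind="stable")
    base, rem = divmod(n, q)
    sizes = [base + 1 if g < rem else base for g in range(q)]
    labels = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        labels[order[start : start + size]] = g
        start += size
    return pd.Series(labels, index=scores.index, name="group")


@dataclass
class GroupPeriodicityResult:
    distributions: dict  # group label -> NullDistribution
    trend_r: float
    trend_p: float
    pairwise: dict  # (low_label, high_label) -> one-sided rank-sum p (low < high)
    group_scores: dict  # group label -> mean enrichment score (or rank)


def periodicity_by_group(seqs: AlignedSeqSet, groups: pd.Series,
                         sample_size: int = 500, n_boot: int = 2000,
                         config: StatConfig = DEFAULT_STAT,
                         seed: Optional[int] = None,
                         scores: Optional[pd.Series] = None,
                         min_group_size: int = 100,
                         order: Optional[list] = None) -> GroupPeriodicityResult:
    """Bootstrap periodicity distributions per enrichment group, plus trend.

    ``groups`` maps tss_id -> group label.  Each group's bootstrap magnitude
    distribution is computed with an independently derived seed; the trend is
    the Pearson correlation between the group-level score (mean of ``scores``
    per group, or the group rank) and the bootstrap magnitudes, with pairwise
    one-sided rank-sum comparisons between consecutive and extreme groups.
    ``order`` fixes the low-to-high group ordering; by default labels are
    sorted (fine for numeric ranks, not for names like L_S/M_S/H_S).
    """
    labels = list(order) if order is not None else sorted(pd.unique(groups.dropna()))
    present = set(pd.unique(groups.dropna()))
    if order is not None and set(labels) != present:
        raise ValueError(f"order {labels} does not match groups present {sorted(present)}")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    id_to_idx = {sid: i for i, sid in enumerate(seqs.source_ids)}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(labels))]

    dists: dict = {}
    group_scores: dict = {}
    for rank, label in enumerate(labels):
        ids = groups.index[groups == label]
        idx = [id_to_idx[i] for i in ids if i in id_to_idx]
        if len(idx) < min_group_size:
            raise ValueError(f"group {label!r} has only {len(idx)} sequences "
                             f"(min {min_group_size})")
        dists[label] = bootstrap_magnitudes(seqs.subset(idx), sample_size=sample_size,
                                            n_boot=n_boot, config=config,
                                            seed=child_seeds[rank])
        if scores is not None:
            group_scores[label] = float(scores.loc[ids].mean())
        else:
            group_scores[label] = float(rank)

    xs = np.concatenate([np.full(dists[l].values.size, group_scores[l]) for l in labels])
    ys = np.concatenate([dists[l].values for l in labels])
    r, p = stats.pearsonr(xs, ys)

    pairwise = {}
    pairs = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
    if len(labels) > 2:
        pairs.append((labels[0], labels[-1]))
    for lo_l, hi_l in pairs:
        pairwise[(lo_l, hi_l)] = compare_groups(dists[lo_l], dists[hi_l],
                                                alternative="less")
    return GroupPeriodicityResult(dists, float(r), float(p), pairwise, group_scores)
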