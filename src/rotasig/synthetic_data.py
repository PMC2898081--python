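"""Synthetic promoter cohorts with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without genome downloads: the
generator emulates TSS-aligned promoter sequences with a plantable in-phase
10-bp RR/YY periodicity of tunable amplitude restricted to a tunable region,
optional CpG-island composition, planted motif instances, nucleosome-boundary
tag clouds, and bimodal expression with graded tissue specificity.

The periodic signal is planted on the purine/pyrimidine track: within the
planted region P(purine at offset i) = pR + a*cos(2*pi*(i - phase)/period),
and bases are then drawn within their class from the background frequencies.
Because P(pyrimidine) = 1 - P(purine), the YY dinucleotide profile is
automatically modulated in counter-phase with RR — one knob controls the
joint RR/YY signal, as observed in real promoter cohorts.  The induced
modulation of the RR start-probability is a*cos(pi/period) (about 0.95a for a
10-bp period) times the cosine at the pair's midpoint.

CpG-island composition is a composition shift, not an island-caller inverse:
island promoters use GC-rich base frequencies inside an island window and no
CpG depletion there, while non-island background suppresses the G that
follows a C (observed/expected CpG well below 1, as in bulk genome).

All sampling is reproducible bit-for-bit from the config seed.  Generative
truth is recorded for every cohort and bundle so recovery tests read truth
from the artifact, never from constants.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .coords import display_to_offset
from .motif_scan import Pwm, write_pwm
from .tss_io import AlignedSeqSet, TssRecord, TssSet, reverse_complement
from .chip_profiles import TagSet

__all__ = [
    "MotifSpec",
    "TagSpec",
    "ExpressionSpec",
    "SynthConfig",
    "default_motif_counts",
    "generate_promoters",
    "generate_tags",
    "generate_expression",
    "write_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_motif_counts() -> np.ndarray:
    """A synthetic 7-bp motif count matrix (consensus GGCAGTG, 20 sites/column).

    Invented for fixtures — not derived from any curated motif database.  The
    columns are near point-mass (all 20 sites carry the consensus base; the
    scan pseudocount floors the others), giving a sharply informative matrix
    whose background unique-match rate in a 41-bp region of interest is a few
    percent.
    """
    consensus = "GGCAGTG"
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 20.0
    return counts


@dataclass
class MotifSpec:
    """Planting spec: where and in what fraction of promoters to embed the motif."""

    counts: np.ndarray = field(default_factory=default_motif_counts)
    offset_range: tuple[int, int] = (10, 30)  # internal start offsets, closed
    fraction: float = 0.05

    def pwm(self, pseudocount: float = 0.01) -> Pwm:
        return Pwm.from_counts(self.counts, pseudocount=pseudocount, id="synthetic_motif")


@dataclass
class TagSpec:
    """Nucleosome-boundary tag clouds flanking the planted region.

    Forward tag 5' ends fall at Normal(center - half_span, jitter_sd) and
    reverse ends at Normal(center + half_span, jitter_sd), in internal
    offsets; ``center`` defaults to the middle of the default planted region
    (display +115) and half_span to 73 bp, the half-width of
    nucleosome-protected DNA.
    """

    center: int = 114
    half_span: int = 73
    jitter_sd: float = 20.0
    tags_per_promoter: int = 10


@dataclass
class ExpressionSpec:
    """Bimodal log2-scale expression with graded tissue specificity.

    Per-gene baselines come from two normal components whose means each sit
    3 sd from their midpoint (so a mixture classifier can recover labels
    near-perfectly); specificity is an "on-tissue lift" added in ``n_on``
    tissues, graded by group, so median level and specificity vary
    independently.  Component weights and group fractions default to splits
    typical of a curated human promoter cohort.
    """

    n_tissues: int = 72
    low_mean: float = 4.0
    high_mean: float = 8.0
    sd: float = 2.0 / 3.0
    frac_high: float = 0.578
    group_fracs: tuple[float, float, float] = (0.274, 0.494, 0.232)  # L_S, M_S, H_S
    lifts: tuple[float, float, float] = (0.3, 2.0, 8.0)
    n_on: int = 3
    noise_sd: float = 0.3


@dataclass
class SynthConfig:
    """Study-condition defaults for a synthetic promoter cohort."""

    n_promoters: int = 1000
    upstream: int = 1000
    downstream: int = 1000
    planted_period: float = 10.0
    planted_amplitude: float = 0.1  # purine-track modulation, in [0, 0.5]
    planted_phase: Optional[int] = None  # internal offset of a cosine peak; default region start
    planted_region: tuple[int, int] = (40, 190)  # display coordinates, closed
    nonisland_amplitude: float = 0.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A C G T
    cpg_fraction: float = 0.0  # fraction of island promoters; 0 = homogeneous cohort
    island_window: tuple[int, int] = (-300, 300)  # display coordinates
    island_gc: float = 0.64
    cpg_depletion: float = 0.25  # multiplier on P(G | prev C) outside islands
    motif: Optional[MotifSpec] = None
    tags: TagSpec = field(default_factory=TagSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    seed: int = 0

    @property
    def seq_len(self) -> int:
        return self.upstream + self.downstream

    @property
    def tss_offset(self) -> int:
        return self.upstream


def _rng(cfg: SynthConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def generate_promoters(cfg: SynthConfig, rng: Optional[np.random.Generator] = None):
    """Generate a TSS-aligned cohort; returns ``(AlignedSeqSet, truth)``.

    With ``cpg_fraction == 0`` the cohort is homogeneous and every promoter
    carries ``planted_amplitude``; otherwise island promoters carry
    ``planted_amplitude`` and the rest ``nonisland_amplitude`` (island
    cohorts carry the signal, mirroring real promoter populations).
    """
    rng = _rng(cfg, rng)
    n, L, ofs = cfg.n_promoters, cfg.seq_len, cfg.tss_offset
    fA, fC, fG, fT = cfg.base_freqs
    if not np.isclose(fA + fC + fG + fT, 1.0):
        raise ValueError("base_freqs must sum to 1")
    pR = fA + fG

    if cfg.cpg_fraction > 0:
        island = rng.random(n) < cfg.cpg_fraction
        amp = np.where(island, cfg.planted_amplitude, cfg.nonisland_amplitude)
    else:
        island = np.zeros(n, dtype=bool)
        amp = np.full(n, cfg.planted_amplitude)
    if np.any(pR + np.abs(amp) > 1.0) or np.any(pR - np.abs(amp) < 0.0):
        raise ValueError("planted amplitude pushes the purine probability outside [0, 1]")

    # Purine-track probability per (promoter, position).
    internal = np.arange(L) - ofs
    r_lo = display_to_offset(cfg.planted_region[0])
    r_hi = display_to_offset(cfg.planted_region[1])
    phase = cfg.planted_phase if cfg.planted_phase is not None else r_lo
    in_region = (internal >= r_lo) & (internal <= r_hi)
    cosine = np.cos(2.0 * np.pi * (internal - phase) / cfg.planted_period)
    p = pR + amp[:, None] * np.where(in_region, cosine, 0.0)[None, :]
    is_R = rng.random((n, L)) < p

    # Base assignment within class, with island composition and CpG depletion.
    pG_bg = fG / pR
    pC_bg = fC / (fC + fT)
    in_island_win = (internal >= display_to_offset(cfg.island_window[0])) & (
        internal <= display_to_offset(cfg.island_window[1]))
    codes = np.empty((n, L), dtype=np.uint8)
    for i in range(L):
        use_island = island & in_island_win[i]
        pG = np.where(use_island, cfg.island_gc, pG_bg)
        pC = np.where(use_island, cfg.island_gc, pC_bg)
        if i > 0:
            prev_c = codes[:, i - 1] == 1
            deplete = prev_c & ~use_island
            d = cfg.cpg_depletion
            pG = np.where(deplete, pG * d / (pG * d + (1.0 - pG)), pG)
        u = rng.random(n)
        col_r = is_R[:, i]
        codes[:, i] = np.where(col_r,
                               np.where(u < pG, 2, 0),   # G else A
                               np.where(u < pC, 1, 3))   # C else T

    motif_rows: list[int] = []
    motif_offsets: list[int] = []
    if cfg.motif is not None and cfg.motif.fraction > 0:
        pwm = cfg.motif.pwm()
        n_plant = int(round(cfg.motif.fraction * n))
        rows = rng.choice(n, size=n_plant, replace=False)
        lo_m, hi_m = cfg.motif.offset_range
        offs = rng.integers(lo_m, hi_m + 1, size=n_plant)
        for row, off in zip(rows, offs):
            col = ofs + int(off)
            for j in range(pwm.width):
                codes[row, col + j] = rng.choice(4, p=pwm.probs[:, j])
            motif_rows.append(int(row))
            motif_offsets.append(int(off))

    seq_bytes = _BASES[codes]
    sequences = [seq_bytes[i].tobytes().decode("ascii") for i in range(n)]
    ids = [f"syn{i:05d}" for i in range(n)]
    truth = {
        "n_promoters": n,
        "planted_amplitude": cfg.planted_amplitude,
        "nonisland_amplitude": cfg.nonisland_amplitude,
        "planted_period": cfg.planted_period,
        "planted_phase": int(phase),
        "planted_region": list(cfg.planted_region),
        "cpg_fraction": cfg.cpg_fraction,
        "island_gc": cfg.island_gc,
        "island": island.astype(int).tolist(),
        "amplitude": amp.tolist(),
        "motif_rows": motif_rows,
        "motif_offsets": motif_offsets,
    }
    return AlignedSeqSet(sequences, ofs, ids), truth


def generate_tags(cfg: SynthConfig, tss: TssSet,
                  rng: Optional[np.random.Generator] = None) -> TagSet:
    """Nucleosome-boundary tag clouds around each TSS of a fixture genome.

    Per promoter, ``tags_per_promoter`` forward and as many reverse tag 5'
    ends are drawn around the planted nucleosome boundaries and mapped back
    to genomic coordinates respecting the TSS strand.
    """
    rng = _rng(cfg, rng)
    spec = cfg.tags
    chroms, poss, strands = [], [], []
    for rec in tss:
        m = spec.tags_per_promoter
        fwd = np.rint(rng.normal(spec.center - spec.half_span, spec.jitter_sd, m)).astype(int)
        rev = np.rint(rng.normal(spec.center + spec.half_span, spec.jitter_sd, m)).astype(int)
        for offs, tx_forward in ((fwd, True), (rev, False)):
            if rec.strand == "+":
                gpos = rec.pos + offs
                strand = "+" if tx_forward else "-"
            else:
                gpos = rec.pos - offs
                strand = "-" if tx_forward else "+"
            gpos = np.maximum(gpos, 1)
            chroms.extend([rec.chrom] * m)
            poss.extend(gpos.tolist())
            strands.extend([strand] * m)
    return TagSet(np.array(chroms, dtype=object), np.array(poss),
                  np.array(strands, dtype=object), source="synthetic_nucleosome")


def generate_expression(cfg: SynthConfig, gene_ids: list[str],
                        rng: Optional[np.random.Generator] = None):
    """Bimodal expression matrix with graded specificity; returns (matrix, truth).

    Values are normalized log2-scale intensities clipped at 0.  Truth records
    each gene's level component (L_E/H_E) and specificity group (L_S/M_S/H_S).
    """
    rng = _rng(cfg, rng)
    spec = cfg.expression
    n = len(gene_ids)
    high = rng.random(n) < spec.frac_high
    base = np.where(high,
                    rng.normal(spec.high_mean, spec.sd, n),
                    rng.normal(spec.low_mean, spec.sd, n))
    fracs = np.asarray(spec.group_fracs, dtype=float)
    groups = rng.choice(3, size=n, p=fracs / fracs.sum())
    lifts = np.asarray(spec.lifts)[groups]

    x = np.tile(base[:, None], (1, spec.n_tissues)).astype(float)
    for g in range(n):
        on = rng.choice(spec.n_tissues, size=spec.n_on, replace=False)
        x[g, on] += lifts[g]
    x += rng.normal(0.0, spec.noise_sd, x.shape)
    x = np.clip(x, 0.0, None)

    tissues = [f"tissue{t + 1:02d}" for t in range(spec.n_tissues)]
    matrix = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene_id"), columns=tissues)
    truth = pd.DataFrame(
        {
            "level_group": np.where(high, "H_E", "L_E"),
            "specificity_group": np.asarray(["L_S", "M_S", "H_S"])[groups],
            "baseline_log2": base,
        },
        index=matrix.index,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Fixture bundle

_SPACER = 300  # N bases between placed promoters; > the 200-bp clustering rule


def write_fixtures(cfg: SynthConfig, outdir) -> dict:
    """Write a complete plain-text fixture bundle driven by ``cfg.seed``.

    Emits a FASTA genome with the promoters placed on random strands, a TSS
    table, nucleosome-boundary tag BED, an expression matrix, a per-TSS
    enrichment table (log2-ratio-style scores correlated with the planted
    signal), the motif count matrix, and a truth JSON.  Re-ingesting the
    genome + TSS table through the extraction path reproduces the in-memory
    aligned set exactly; two bundles from the same seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    r_prom, r_strand, r_support, r_tags, r_expr, r_enr = (
        np.random.default_rng(c) for c in ss.spawn(6))

    proms, truth = generate_promoters(cfg, rng=r_prom)
    n, L, ofs = len(proms), proms.length, proms.offset_of_tss
    strands = np.where(r_strand.random(n) < 0.5, "+", "-")
    support = r_support.integers(2, 51, size=n)

    parts: list[str] = []
    records: list[TssRecord] = []
    cursor = 0
    for i, seq in enumerate(proms.sequences):
        parts.append("N" * _SPACER)
        g = cursor + _SPACER + 1  # 1-based start of the placed window
        if strands[i] == "+":
            parts.append(seq)
            pos = g + ofs
        else:
            parts.append(reverse_complement(seq))
            pos = g + L - 1 - ofs
        records.append(TssRecord(proms.source_ids[i], "chrS", int(pos), str(strands[i]),
                                 int(support[i]), f"gene{i:05d}"))
        cursor += _SPACER + L
    parts.append("N" * _SPACER)
    genome_seq = "".join(parts)
    tss_set = TssSet(records, genome_id="synthetic")

    paths = {k: outdir / v for k, v in {
        "genome": "genome.fa", "tss": "tss.tsv", "tags": "tags.bed",
        "expression": "expression.tsv", "enrichment": "enrichment.tsv",
        "pwm": "pwm.txt", "truth": "truth.json"}.items()}

    with open(paths["genome"], "w") as fh:
        fh.write(">chrS\n")
        for i in range(0, len(genome_seq), 80):
            fh.write(genome_seq[i : i + 80] + "\n")

    with open(paths["tss"], "w") as fh:
        fh.write("id\tchrom\tpos\tstrand\tsupport\tgene_id\n")
        for r in records:
            fh.write(f"{r.id}\t{r.chrom}\t{r.pos}\t{r.strand}\t{r.support}\t{r.gene_id}\n")

    tags = generate_tags(cfg, tss_set, rng=r_tags)
    with open(paths["tags"], "w") as fh:
        for i in range(len(tags)):
            p = int(tags.pos[i])
            s = tags.strand[i]
            start, end = (p - 1, p) if s == "+" else (p - 1, p)
            fh.write(f"{tags.chrom[i]}\t{start}\t{end}\ttag{i:06d}\t0\t{s}\n")

    gene_ids = [r.gene_id for r in records]
    expr, expr_truth = generate_expression(cfg, gene_ids, rng=r_expr)
    expr.round(4).to_csv(paths["expression"], sep="\t")

    # Enrichment scores (log2-ratio style) correlated with the planted signal.
    amp = np.asarray(truth["amplitude"], dtype=float)
    rel = amp / max(cfg.planted_amplitude, 1e-12) if cfg.planted_amplitude > 0 else amp * 0
    enr = r_enr.normal(0.0, 0.5, n) + 1.5 * rel
    with open(paths["enrichment"], "w") as fh:
        fh.write("tss_id\tscore\n")
        for sid, v in zip(proms.source_ids, enr):
            fh.write(f"{sid}\t{v:.4f}\n")

    motif = cfg.motif if cfg.motif is not None else MotifSpec(fraction=0.0)
    write_pwm(motif.counts, paths["pwm"], id="synthetic_motif")

    bundle_truth = {
        "promoters": truth,
        "strands": strands.tolist(),
        "support": support.tolist(),
        "expression": expr_truth.reset_index().to_dict(orient="list"),
        "enrichment": {"scores": [round(float(v), 4) for v in enr]},
        "config": _config_dict(cfg),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(bundle_truth, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return paths


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    if d.get("motif") is not None:
        d["motif"]["counts"] = np.asarray(d["motif"]["counts"]).tolist()
    return d
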