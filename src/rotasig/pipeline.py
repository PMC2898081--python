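"""End-to-end orchestration: extract → classify → statistic → nulls → groups.

A single :class:`RunConfig` (serializable to YAML) drives the full analysis
on a bundle of inputs; every stochastic stage draws its seed from the run
seed through a documented derivation (``numpy.random.SeedSequence(seed).spawn``
in stage order), so stages are independently reproducible and a rerun with
the same config and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import resampling, tss_io
from .chip_profiles import (quantile_partition, periodicity_by_group,
                            read_tags_bed, region_tag_counts, tag_density_profile)
from .coords import offset_to_display
from .cpg_islands import classify_cpg, cpg_features, fit_cpg_gmm
from .expression_groups import (median_expression_partition, specificity_partition,
                                tissue_specificity)
from .motif_scan import call_matches, column_shuffle_control, read_pwm, scan_set
from .profiles import dinucleotide_class_profile, smooth_profile
from .spectral import StatConfig, periodicity_stat

logger = logging.getLogger("rotasig.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Inputs and parameters of a full run."""

    genome: str
    tss_table: str
    outdir: str
    tags_bed: Optional[str] = None
    expression_tsv: Optional[str] = None
    enrichment_tsv: Optional[str] = None
    pwm_file: Optional[str] = None
    upstream: int = 1000
    downstream: int = 1000
    min_support: int = 2
    cluster_bp: int = 200
    region_start: int = 40  # display coordinate
    series_len: int = 150
    smooth_bp: int = 3
    period_bp: float = 10.0
    cpg_window: tuple = (-500, 500)
    motif_region: tuple = (-500, 500)
    motif_roi: tuple = (0, 40)
    tag_region: tuple = (40, 200)
    shift_iters: int = 500
    n_boot: int = 2000
    sample_size: int = 500
    n_shuffles: int = 100
    n_perm: int = 10000
    min_group_size: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def stat_config(self) -> StatConfig:
        return StatConfig(region_start=self.region_start, series_len=self.series_len,
                          smooth_bp=self.smooth_bp, period_bp=self.period_bp)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(summary, name, seed, fn):
    t0 = time.perf_counter()
    logger.info("stage %s: start (seed=%s)", name, seed)
    try:
        out = fn()
    except Exception as exc:  # noqa: BLE001 - abort with stage name and cause
        raise PipelineError(name, exc) from exc
    dt = time.perf_counter() - t0
    logger.info("stage %s: done in %.2fs", name, dt)
    summary.setdefault("stages", {})[name] = {"seed": seed}
    return out


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the machine-readable summary dict.

    Writes ``summary.json``, per-stage TSVs and a text report under
    ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stat = cfg.stat_config()
    seeds = _child_seeds(cfg.seed, 9)
    summary: dict = {"config": asdict(cfg), "seed": cfg.seed}

    # --- extraction -------------------------------------------------------
    def s_extract():
        tss = tss_io.read_tss_table(cfg.tss_table)
        kept = tss_io.filter_tss(tss, cfg.min_support, cfg.cluster_bp)
        seqs = tss_io.extract_flanks(kept, cfg.genome, cfg.upstream, cfg.downstream)
        return tss, kept, seqs

    tss_all, tss, seqs = _stage(summary, "extract", None, s_extract)
    summary["n_tss_input"] = len(tss_all)
    summary["n_tss_retained"] = len(tss)

    # --- observed statistic and shift null --------------------------------
    def s_stat():
        prof = dinucleotide_class_profile(seqs, "RR")
        sm = smooth_profile(prof, cfg.smooth_bp)
        pd.DataFrame({
            "offset": offset_to_display(sm.offsets),
            "value": sm.values,
            "n_effective": sm.n_effective,
        }).to_csv(outdir / "profile_RR.tsv", sep="\t", index=False)
        obs = periodicity_stat(seqs, stat)
        null = resampling.shift_null(seqs, stat, n_iter=cfg.shift_iters,
                                     seed=seeds[0])
        pd.DataFrame({"magnitude10": null.values}).to_csv(
            outdir / "shift_null.tsv", sep="\t", index=False)
        return obs, null

    obs, null = _stage(summary, "periodicity", seeds[0], s_stat)
    summary["observed_magnitude10"] = obs.magnitude10
    summary["shift_null"] = null.summary()
    summary["shift_null_p"] = resampling.empirical_p(obs.magnitude10, null.values)

    # --- CpG islands ------------------------------------------------------
    def s_cpg():
        feats = cpg_features(seqs, cfg.cpg_window)
        fit = fit_cpg_gmm(feats, seed=seeds[1])
        table = classify_cpg(fit, feats, allow_unconverged=True)
        table.to_csv(outdir / "cpg.tsv", sep="\t")
        return fit, table

    cpg_fit, cpg_table = _stage(summary, "cpg_islands", seeds[1], s_cpg)
    island = cpg_table["cpg_island"]
    summary["cpg"] = {
        "n_island": int(island.sum()),
        "n_non_island": int((~island).sum()),
        "island_fraction": float(island.mean()),
        "gmm_means": [float(m) for m in cpg_fit.means],
        "gmm_converged": bool(cpg_fit.converged),
        "gmm_degenerate": bool(cpg_fit.degenerate),
    }

    def s_cpg_compare():
        out = {}
        idx_is = np.flatnonzero(island.to_numpy())
        idx_no = np.flatnonzero(~island.to_numpy())
        for name, idx in (("island", idx_is), ("non_island", idx_no)):
            if idx.size >= cfg.min_group_size:
                sub = seqs.subset(idx)
                out[name] = {
                    "n": int(idx.size),
                    "magnitude10": periodicity_stat(sub, stat).magnitude10,
                }
        if set(out) == {"island", "non_island"}:
            b_is = resampling.bootstrap_magnitudes(
                seqs.subset(idx_is), cfg.sample_size, cfg.n_boot, stat, seed=seeds[2])
            b_no = resampling.bootstrap_magnitudes(
                seqs.subset(idx_no), cfg.sample_size, cfg.n_boot, stat, seed=seeds[3])
            out["ranksum_p_island_gt"] = resampling.compare_groups(
                b_no, b_is, alternative="less")
        return out

    summary["cpg_periodicity"] = _stage(summary, "cpg_compare", seeds[2], s_cpg_compare)

    # --- motif scan -------------------------------------------------------
    if cfg.pwm_file:
        def s_motif():
            pwm = read_pwm(cfg.pwm_file)
            scans = scan_set(seqs, pwm, cfg.motif_region)
            matched = [m for s in scans
                       for m in call_matches(s, cfg.motif_roi, require_unique=True)]
            observed, null_counts, p = column_shuffle_control(
                pwm, seqs, n_shuffles=cfg.n_shuffles, seed=seeds[4],
                region=cfg.motif_region, region_of_interest=cfg.motif_roi)
            pd.DataFrame([{"tss_id": m.tss_id,
                           "offset": offset_to_display(m.offset),
                           "local_prob": m.local_prob,
                           "regional_mean": m.regional_mean} for m in matched]
                         ).to_csv(outdir / "motif_matches.tsv", sep="\t", index=False)
            return matched, observed, null_counts, p

        matched, m_obs, m_null, m_p = _stage(summary, "motif", seeds[4], s_motif)
        summary["motif"] = {
            "n_unique_match": len(matched),
            "n_occurrences": int(m_obs),
            "shuffle_max": float(m_null.values.max()),
            "shuffle_mean": float(m_null.values.mean()),
            "shuffle_p": float(m_p),
        }
        if cfg.enrichment_tsv:
            enr = pd.read_csv(cfg.enrichment_tsv, sep="\t", index_col=0)["score"]
            enr = enr.reindex(seqs.source_ids).dropna()
            has_match = pd.Series(False, index=enr.index)
            has_match.loc[[m.tss_id for m in matched if m.tss_id in has_match.index]] = True
            high_enr = enr > enr.median()
            if has_match.any() and not has_match.all():
                summary["motif"]["association_p_high_enrichment"] = (
                    resampling.label_association_test(
                        has_match.to_numpy(), high_enr.to_numpy(),
                        n_perm=cfg.n_perm, seed=seeds[4]))

    # --- ChIP tags --------------------------------------------------------
    if cfg.tags_bed:
        def s_tags():
            tags = read_tags_bed(cfg.tags_bed, source="tags")
            for strand in ("forward", "reverse"):
                prof = tag_density_profile(tags, tss, strand=strand)
                pd.DataFrame({"offset": offset_to_display(prof.offsets),
                              "density": prof.values}).to_csv(
                    outdir / f"tag_density_{strand}.tsv", sep="\t", index=False)
            counts = region_tag_counts(tags, tss, cfg.tag_region)
            groups = quantile_partition(counts, 4)
            res = periodicity_by_group(seqs, groups, cfg.sample_size, cfg.n_boot,
                                       stat, seed=seeds[5], scores=counts,
                                       min_group_size=cfg.min_group_size)
            return counts, res

        counts, chip_res = _stage(summary, "chip", seeds[5], s_tags)
        summary["chip"] = _group_summary(chip_res)

    # --- enrichment tertiles (ChIP-chip log2-ratio-style scores) ----------
    if cfg.enrichment_tsv:
        def s_enrichment():
            enr = pd.read_csv(cfg.enrichment_tsv, sep="\t", index_col=0)["score"]
            enr = enr.reindex(seqs.source_ids).dropna()
            groups = quantile_partition(enr, 3)
            return periodicity_by_group(seqs, groups, cfg.sample_size, cfg.n_boot,
                                        stat, seed=seeds[8], scores=enr,
                                        min_group_size=cfg.min_group_size)

        try:
            enr_res = _stage(summary, "enrichment", seeds[8], s_enrichment)
            summary["enrichment"] = _group_summary(enr_res)
        except PipelineError as exc:
            if isinstance(exc.cause, ValueError):
                summary["enrichment"] = {"skipped": str(exc.cause)}
            else:
                raise

    # --- expression -------------------------------------------------------
    if cfg.expression_tsv:
        def s_expr():
            expr = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
            gene_of = {r.id: r.gene_id for r in tss}
            levels, fit = median_expression_partition(expr, seed=seeds[6])
            tau = tissue_specificity(expr)
            spec_groups = specificity_partition(tau, 3)
            out = {"gmm_means": [float(m) for m in fit.means],
                   "n_L_E": int((levels == "L_E").sum()),
                   "n_H_E": int((levels == "H_E").sum())}
            id_groups_level = pd.Series(
                {sid: levels.get(g) for sid, g in gene_of.items()
                 if g in levels.index}).dropna()
            id_groups_spec = pd.Series(
                {sid: spec_groups.get(g) for sid, g in gene_of.items()
                 if g in spec_groups.index}).dropna()
            try:
                lvl = periodicity_by_group(seqs, id_groups_level, cfg.sample_size,
                                           cfg.n_boot, stat, seed=seeds[6],
                                           min_group_size=cfg.min_group_size,
                                           order=["L_E", "H_E"])
                out["by_level"] = _group_summary(lvl)
            except ValueError as exc:
                out["by_level"] = {"skipped": str(exc)}
            try:
                sp = periodicity_by_group(seqs, id_groups_spec, cfg.sample_size,
                                          cfg.n_boot, stat, seed=seeds[7],
                                          min_group_size=cfg.min_group_size,
                                          order=["L_S", "M_S", "H_S"])
                out["by_specificity"] = _group_summary(sp)
            except ValueError as exc:
                out["by_specificity"] = {"skipped": str(exc)}
            return out

        summary["expression"] = _stage(summary, "expression", seeds[6], s_expr)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")
    (outdir / "report.txt").write_text(report(summary))
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _group_summary(res) -> dict:
    return {
        "groups": {str(k): {"n_boot": int(v.n_iter),
                            "mean_magnitude10": float(v.values.mean()),
                            "median_magnitude10": float(np.median(v.values))}
                   for k, v in res.distributions.items()},
        "trend_r": res.trend_r,
        "trend_p": res.trend_p,
        "pairwise_p": {f"{a}<{b}": float(p) for (a, b), p in res.pairwise.items()},
        "group_scores": {str(k): float(v) for k, v in res.group_scores.items()},
    }


def report(summary: dict) -> str:
    """Human-readable text rendering of a run summary."""
    lines = []
    lines.append("10-bp RR/YY periodicity report")
    lines.append("=" * 34)
    lines.append(f"TSSs: {summary.get('n_tss_input', 0)} input, "
                 f"{summary.get('n_tss_retained', 0)} retained after filtering")
    if "observed_magnitude10" in summary:
        sn = summary.get("shift_null", {})
        lines.append(f"observed magnitude at 10 bp: {summary['observed_magnitude10']:.4f}")
        lines.append(f"shift null (n={sn.get('n_iter', 0)}): mean {sn.get('mean', float('nan')):.4f}, "
                     f"95th pct {sn.get('q95', float('nan')):.4f}; "
                     f"empirical p = {summary.get('shift_null_p', float('nan')):.3g}")
    if "cpg" in summary:
        c = summary["cpg"]
        lines.append(f"CpG islands: {c['n_island']} island / {c['n_non_island']} non-island "
                     f"({100 * c['island_fraction']:.1f}% islands)")
        cp = summary.get("cpg_periodicity", {})
        for name in ("island", "non_island"):
            grp = cp.get(name)
            if grp:
                lines.append(f"  {name}: n={grp['n']}, magnitude10={grp['magnitude10']:.4f}")
            else:
                lines.append(f"  {name}: n=0")
        if "ranksum_p_island_gt" in cp:
            lines.append(f"  island > non-island rank-sum p = {cp['ranksum_p_island_gt']:.3g}")
    if "motif" in summary:
        m = summary["motif"]
        lines.append(f"motif: {m['n_unique_match']} promoters with a unique match; "
                     f"{m['n_occurrences']} occurrences vs column-shuffle max "
                     f"{m['shuffle_max']:.0f} (p = {m['shuffle_p']:.3g})")
    for key, title in (("chip", "tag-count quartiles"),
                       ("enrichment", "enrichment tertiles")):
        if key in summary and "trend_r" in summary.get(key, {}):
            lines.append(f"{title}: trend r = {summary[key]['trend_r']:.3f} "
                         f"(p = {summary[key]['trend_p']:.3g})")
            for g, st in summary[key]["groups"].items():
                lines.append(f"  group {g}: median magnitude10 = {st['median_magnitude10']:.4f}")
    if "expression" in summary:
        e = summary["expression"]
        lines.append(f"expression: {e['n_L_E']} low / {e['n_H_E']} high median expression")
        for sub, title in (("by_level", "L_E/H_E"), ("by_specificity", "L_S/M_S/H_S")):
            if sub in e and "groups" in e.get(sub, {}):
                pair = ", ".join(f"{k}: p={v:.3g}" for k, v in e[sub]["pairwise_p"].items())
                lines.append(f"  {title}: {pair}")
            elif sub in e:
                lines.append(f"  {title}: n=0 ({e[sub].get('skipped', 'skipped')})")
    return "\n".join(lines) + "\n"
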