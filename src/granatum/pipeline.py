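"""Stage orchestration: run each analysis stage, or the full synthetic
end-to-end study, from one configuration.

Defaults mirror the study's stated parameters: 20% max missingness and
5% MAF for SNP filtering; 100-kb π/FST windows; 10-kb/5-kb Tajima's D
windows; 20-kb/2-kb sweep-scan FST windows; 200-kb LD cap; 80%
reciprocal overlap and >10-bp length for SV merging; 0.3 SNP-index
filter; 100-kb/10-kb BSA windows; top-5% quantiles; K=2 ancestry.
Every stage writes a parameter manifest and a machine-readable summary
next to its outputs and never mutates its inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsa, popgen, sv, sweeps, synthetic, variant_io
from .intervals import IntervalSet
from .synthetic import SimConfig, bsa_scenario, inversion_scenario, pop_labels
from .variant_io import GenomeLayout, make_windows

log = logging.getLogger(__name__)

STAGES = ("simulate", "merge-sv", "popgen", "sweep", "invscan", "bsa", "report")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    # site filters
    max_missing: float = 0.2
    min_maf: float = 0.05
    # windows (bp)
    pi_window: int = 100_000
    tajima_window: int = 10_000
    tajima_step: int = 5_000
    sweep_window: int = 20_000
    sweep_step: int = 2_000
    bsa_window: int = 100_000
    bsa_step: int = 10_000
    refprop_window: int = 100_000
    # thresholds
    ld_max_dist: int = 200_000
    sv_min_recip: float = 0.8
    sv_min_len: int = 10
    snp_index_min: float = 0.3
    top_fraction: float = 0.05
    admixture_k: int = 2
    # synthetic-study sizes
    n_sites_snp: int = 20_000
    n_sites_sv: int = 2_000
    n_sv: int = 1_000
    bsa_effect: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def out(self) -> Path:
        p = Path(self.outdir)
        p.mkdir(parents=True, exist_ok=True)
        return p


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


def _manifest(cfg: RunConfig, stage: str, extra: dict) -> dict:
    return {"stage": stage, "config": asdict(cfg), **extra}


def stage_simulate(cfg: RunConfig) -> dict:
    out = cfg.out()
    sim = SimConfig(seed=cfg.seed, n_sites=cfg.n_sites_snp)
    m, truth = synthetic.simulate_two_pop_snps(sim)
    variant_io.write_genotypes(m, out / "snp_panel.vcf", sim.layout)
    truth.to_csv(out / "snp_truth.tsv", sep="\t", index=False)
    sim.layout.to_tsv(out / "chrom_lengths.tsv")

    sv_sim = replace(sim, n_sites=cfg.n_sites_sv)
    msv, _ = synthetic.simulate_two_pop_snps(replace(sv_sim, seed=cfg.seed + 101))
    variant_io.write_genotypes(msv, out / "sv_panel.vcf", sim.layout)

    a, b, truth_sv, _ = synthetic.simulate_sv_callsets(replace(sim, n_sv=cfg.n_sv))
    sv.write_sv_tsv(a, out / "sv_source_asm.tsv")
    sv.write_sv_tsv(b, out / "sv_source_smrt.tsv")
    sv.write_sv_tsv(truth_sv, out / "sv_truth.tsv")

    inv_cfg = inversion_scenario(seed=cfg.seed)
    minv, labels, _ = synthetic.simulate_inversion_block(inv_cfg)
    variant_io.write_genotypes(minv, out / "inversion_panel.vcf", inv_cfg.layout)
    inv_cfg.layout.to_tsv(out / "inversion_chrom_lengths.tsv")

    truths = {}
    for cross in (1, 2):
        bc = bsa_scenario(seed=cfg.seed + cross, effect=cfg.bsa_effect)
        counts, t = synthetic.simulate_bulks(bc)
        counts.to_csv(out / f"bulks_cross{cross}.tsv", sep="\t", index=False)
        truths[f"cross{cross}"] = t
        bc.layout.to_tsv(out / "bsa_chrom_lengths.tsv")
    summary = {
        "n_snp_sites": int(m.n_sites),
        "n_sv_panel_sites": int(msv.n_sites),
        "n_truth_sv": len(truth_sv),
        "bsa_truth": truths,
        "inversion": list(inv_cfg.inversion),
    }
    _write_json(out / "simulate.json", _manifest(cfg, "simulate", summary))
    return summary


def stage_merge_sv(cfg: RunConfig) -> dict:
    out = cfg.out()
    a = sv.read_sv_tsv(out / "sv_source_asm.tsv")
    b = sv.read_sv_tsv(out / "sv_source_smrt.tsv")
    truth = sv.read_sv_tsv(out / "sv_truth.tsv")
    merged = sv.merge_callsets([a, b], min_recip=cfg.sv_min_recip, min_len=cfg.sv_min_len)
    sv.write_sv_tsv(merged.records, out / "sv_merged.tsv")
    n_a, n_b, n_matched, pct = sv.support_venn(a, b, min_recip=cfg.sv_min_recip)
    layout = GenomeLayout.from_tsv(out / "chrom_lengths.tsv")
    summary_stats = sv.summarize(merged.records)
    r2, p, slope = sv.chrom_count_regression(layout, summary_stats["by_chrom"])
    summary = {
        "n_source_asm": n_a,
        "n_source_smrt": n_b,
        "n_merged": len(merged.records),
        "n_truth": len(truth),
        "support_pct_of_asm": pct,
        "summary": summary_stats,
        "chrom_regression": {"r2": r2, "p": p, "slope": slope},
    }
    _write_json(out / "merge_sv.json", _manifest(cfg, "merge-sv", summary))
    return summary


def _load_panels(cfg: RunConfig):
    out = cfg.out()
    layout = GenomeLayout.from_tsv(out / "chrom_lengths.tsv")
    m = variant_io.read_genotypes(out / "snp_panel.vcf", layout)
    msv = variant_io.read_genotypes(out / "sv_panel.vcf", layout)
    sim = SimConfig(seed=cfg.seed)
    return layout, m, msv, pop_labels(sim)


def stage_popgen(cfg: RunConfig) -> dict:
    out = cfg.out()
    layout, m, msv, pop = _load_panels(cfg)
    m = variant_io.filter_sites(m, cfg.max_missing, cfg.min_maf)
    win100 = make_windows(layout, cfg.pi_window)
    win_d = make_windows(layout, cfg.tajima_window, cfg.tajima_step)

    results = {}
    for name, panel in (("snp", m), ("sv", msv)):
        pi = popgen.nucleotide_diversity(panel, win100)
        d = popgen.tajimas_d(panel, win_d)
        pi.to_csv(out / f"pi_{name}.tsv", sep="\t", index=False)
        d.to_csv(out / f"tajima_{name}.tsv", sep="\t", index=False)
        het = popgen.heterozygosity(panel)
        het.to_csv(out / f"het_{name}.tsv", sep="\t", header=["het"])
        fst_gw = popgen.weir_cockerham_fst(panel, pop)
        _, decay = popgen.ld_r2(panel, cfg.ld_max_dist)
        decay.to_csv(out / f"ld_decay_{name}.tsv", sep="\t", index=False)
        results[name] = {
            "genomewide_fst": fst_gw,
            "mean_pi": float(np.nanmean(pi["value"])),
            "mean_tajima_d": float(np.nanmean(d["value"])),
            "mean_het": float(het.mean()),
        }
    q_snp, _, trace_snp = popgen.admixture_em(m, cfg.admixture_k, seed=cfg.seed)
    q_sv, _, trace_sv = popgen.admixture_em(msv, cfg.admixture_k, seed=cfg.seed)
    r2, p = popgen.q_correlation(q_snp, q_sv)
    pd.DataFrame(q_snp, index=m.samples).to_csv(out / "q_snp.tsv", sep="\t")
    pd.DataFrame(q_sv, index=msv.samples).to_csv(out / "q_sv.tsv", sep="\t")
    coords, evr = popgen.pca(m)
    pd.DataFrame(coords, index=m.samples, columns=["PC1", "PC2"]).to_csv(
        out / "pca_snp.tsv", sep="\t"
    )
    summary = {
        **results,
        "q_correlation_r2": r2,
        "q_correlation_p": p,
        "pc1_var_ratio": float(evr[0]),
        "em_monotone": bool(
            np.all(np.diff(trace_snp) >= -1e-8) and np.all(np.diff(trace_sv) >= -1e-8)
        ),
    }
    _write_json(out / "popgen.json", _manifest(cfg, "popgen", summary))
    return summary


def stage_sweep(cfg: RunConfig) -> dict:
    out = cfg.out()
    layout, m, msv, pop = _load_panels(cfg)
    m = variant_io.filter_sites(m, cfg.max_missing, cfg.min_maf)
    win = make_windows(layout, cfg.sweep_window, cfg.sweep_step)
    sets = {}
    counts = {}
    for name, panel in (("snp", m), ("sv", msv)):
        fst = popgen.weir_cockerham_fst(panel, pop, win)
        sel, regions = sweeps.top_fraction_windows(fst, cfg.top_fraction)
        variant_io.write_intervals(regions, out / f"sweeps_{name}.bed")
        sel.to_csv(out / f"sweep_windows_{name}.tsv", sep="\t", index=False)
        sets[name] = regions
        counts[name] = len(sel)
    overlap_bp, pct_of_snp, pct_g_snp, pct_g_sv = sweeps.sweep_overlap(
        sets["snp"], sets["sv"], layout
    )
    summary = {
        "n_sweep_windows_snp": counts["snp"],
        "n_sweep_windows_sv": counts["sv"],
        "n_sweeps_snp": len(sets["snp"]),
        "n_sweeps_sv": len(sets["sv"]),
        "overlap_bp": overlap_bp,
        "overlap_pct_of_snp": pct_of_snp,
        "genome_pct_snp": pct_g_snp,
        "genome_pct_sv": pct_g_sv,
    }
    _write_json(out / "sweep.json", _manifest(cfg, "sweep", summary))
    return summary


def stage_invscan(cfg: RunConfig) -> dict:
    out = cfg.out()
    layout = GenomeLayout.from_tsv(out / "inversion_chrom_lengths.tsv")
    m = variant_io.read_genotypes(out / "inversion_panel.vcf", layout)
    inv_cfg = inversion_scenario(seed=cfg.seed)
    labels = pd.Series(pop_labels(inv_cfg), index=m.samples)
    win = make_windows(layout, cfg.refprop_window)
    profiles = sweeps.ref_genotype_proportion(m, win)
    profiles.to_csv(out / "ref_prop_profiles.tsv", sep="\t", index=False)
    region_set = sweeps.candidate_divergent_region(profiles, labels)
    variant_io.write_intervals(region_set, out / "divergent_regions.bed")
    chrom_i, start, end = inv_cfg.inversion
    truth_set = IntervalSet([(chrom_i, start, end)])
    recovered = region_set.intersect_bp(truth_set)
    classes = sweeps.classify_accessions(profiles, (chrom_i, start, end))
    expected = labels.map({"pop1": "reference_like", "pop2": "divergent"})
    acc = float((classes.reindex(expected.index) == expected).mean())
    summary = {
        "planted_bp": end - start,
        "recovered_bp": recovered,
        "recovered_frac": recovered / (end - start),
        "overhang_bp": region_set.total_bp - recovered,
        "classification_accuracy": acc,
    }
    _write_json(out / "invscan.json", _manifest(cfg, "invscan", summary))
    return summary


def stage_bsa(cfg: RunConfig) -> dict:
    out = cfg.out()
    layout = GenomeLayout.from_tsv(out / "bsa_chrom_lengths.tsv")
    sim_summary = json.loads((out / "simulate.json").read_text())
    qtls = {}
    per_cross = {}
    for cross in (1, 2):
        counts = pd.read_csv(out / f"bulks_cross{cross}.tsv", sep="\t")
        stats = bsa.site_stats(counts)
        kept = bsa.filter_low_index(stats, cfg.snp_index_min)
        dwin = bsa.delta_windows(kept, layout, cfg.bsa_window, cfg.bsa_step)
        ewin = bsa.window_smooth(stats, "ed2", layout, cfg.bsa_window, cfg.bsa_step)
        dwin.to_csv(out / f"delta_windows_cross{cross}.tsv", sep="\t", index=False)
        ewin.to_csv(out / f"ed2_windows_cross{cross}.tsv", sep="\t", index=False)
        snp_regions = bsa.candidate_regions(dwin, cfg.top_fraction)
        ed_regions = bsa.candidate_regions(ewin, cfg.top_fraction)
        qtl = bsa.intersect_methods(snp_regions, ed_regions)
        qtl.to_csv(out / f"qtl_cross{cross}.tsv", sep="\t", index=False)
        qtls[cross] = qtl
        truth = sim_summary["bsa_truth"][f"cross{cross}"]
        hit = bsa.qtl_region_set(qtl).contains(truth["qtl_chrom"], truth["qtl_pos"])
        per_cross[f"cross{cross}"] = {
            "n_sites_kept": len(kept),
            "n_qtl_regions": len(qtl),
            "qtl_recovered": bool(hit),
        }
    both = bsa.intersect_populations(qtls[1], qtls[2])
    both.to_csv(out / "qtl_both_crosses.tsv", sep="\t", index=False)
    truth = sim_summary["bsa_truth"]["cross1"]
    summary = {
        **per_cross,
        "n_qtl_both_crosses": len(both),
        "qtl_recovered_both": bool(
            bsa.qtl_region_set(both).contains(truth["qtl_chrom"], truth["qtl_pos"])
        ),
    }
    _write_json(out / "bsa.json", _manifest(cfg, "bsa", summary))
    return summary


def stage_report(cfg: RunConfig) -> dict:
    out = cfg.out()
    report = {}
    for name in ("simulate", "merge_sv", "popgen", "sweep", "invscan", "bsa"):
        path = out / f"{name}.json"
        if path.exists():
            report[name] = json.loads(path.read_text())
    _write_json(out / "report.json", report)
    return report


_STAGE_FNS = {
    "simulate": stage_simulate,
    "merge-sv": stage_merge_sv,
    "popgen": stage_popgen,
    "sweep": stage_sweep,
    "invscan": stage_invscan,
    "bsa": stage_bsa,
    "report": stage_report,
}


def run_stage(name: str, cfg: RunConfig) -> dict:
    if name not in _STAGE_FNS:
        raise ValueError(f"unknown stage {name!r}; available: {', '.join(STAGES)}")
    log.info("running stage %s (seed=%d)", name, cfg.seed)
    return _STAGE_FNS[name](cfg)


def run_all(cfg: RunConfig) -> dict:
    for name in STAGES:
        run_stage(name, cfg)
    return json.loads((cfg.out() / "report.json").read_text())
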