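"""Selective-sweep detection, sweep overlap arithmetic, and the
reference-genotype-proportion inversion scan.

Sweeps are the top tail (default 5%) of windowed FST; ties at the
quantile are included, and the selected windows are unioned into
intervals for Mb/percent arithmetic while the window list is kept for
sweep counts.  The inversion scan computes, per accession and window,
the fraction of sites called homozygous for the reference allele — a
bimodal track across accessions flags a non-recombining haplotype block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import Interval, IntervalSet, interval_span
from .variant_io import MISSING, GenomeLayout, GenotypeMatrix, window_site_slices

__all__ = [
    "top_fraction_windows", "sweep_overlap", "genes_in_regions",
    "ref_genotype_proportion", "classify_accessions",
    "candidate_divergent_region", "interval_span",
]


def top_fraction_windows(window_stats: pd.DataFrame, fraction: float = 0.05):
    """Windows at or above the (1-fraction) quantile of the statistic.

    NaN windows are excluded before the quantile; ties at the threshold
    are all kept (the selected count may exceed the nominal fraction).
    Returns (selected window frame, IntervalSet union of the selection).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    vals = window_stats["value"]
    scored = window_stats[vals.notna()]
    if scored.empty:
        raise ValueError("all windows are NaN; nothing to rank")
    thr = scored["value"].quantile(1.0 - fraction)
    sel = scored[scored["value"] >= thr]
    regions = IntervalSet(
        Interval(r.chrom, int(r.start), int(r.end)) for r in sel.itertuples()
    )
    return sel.reset_index(drop=True), regions


def sweep_overlap(a: IntervalSet, b: IntervalSet, genome: GenomeLayout):
    """Overlap arithmetic between two sweep sets.

    Returns (overlap_bp, pct_of_a, pct_genome_a, pct_genome_b); all
    percentages on the 0-100 scale.
    """
    overlap_bp = a.intersect_bp(b)
    g = genome.total_bp
    return (
        overlap_bp,
        100.0 * overlap_bp / a.total_bp if a.total_bp else 0.0,
        100.0 * a.total_bp / g,
        100.0 * b.total_bp / g,
    )


def genes_in_regions(genes, regions: IntervalSet) -> list[str]:
    """Ids of genes overlapping any region by >= 1 bp.

    ``genes`` is an iterable of (gene_id, chrom, start, end).
    """
    hits = []
    for gid, chrom, start, end in genes:
        g = Interval(chrom, start, end)
        if any(g.overlap_bp(iv) > 0 for iv in regions):
            hits.append(gid)
    return hits


def ref_genotype_proportion(m: GenotypeMatrix, windows) -> pd.DataFrame:
    """Per-sample, per-window fraction of sites called hom-ref (code 0).

    Heterozygous calls count as non-reference (the track contrasts each
    accession against the reference assembly).  NaN where a window holds
    no non-missing call for the sample.  Long format: sample, chrom,
    start, end, n_sites, ref_prop.
    """
    slices = window_site_slices(m.chrom, m.pos, windows)
    is_ref = (m.codes == 0).astype(np.int64)
    ok = (m.codes != MISSING).astype(np.int64)
    cs_ref = np.concatenate(
        [np.zeros((m.n_samples, 1), dtype=np.int64), np.cumsum(is_ref, axis=1)], axis=1
    )
    cs_ok = np.concatenate(
        [np.zeros((m.n_samples, 1), dtype=np.int64), np.cumsum(ok, axis=1)], axis=1
    )
    frames = []
    for (lo, hi), w in zip(slices, windows):
        n_ok = cs_ok[:, hi] - cs_ok[:, lo]
        n_ref = cs_ref[:, hi] - cs_ref[:, lo]
        with np.errstate(invalid="ignore"):
            prop = np.where(n_ok > 0, n_ref / np.maximum(n_ok, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "sample": m.samples,
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "n_sites": hi - lo,
                    "ref_prop": prop,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def classify_accessions(
    profiles: pd.DataFrame,
    region: tuple[str, int, int],
    low: float = 0.2,
    high: float = 0.8,
) -> pd.Series:
    """Label each sample by its reference-proportion track inside a region.

    ``reference_like`` if every non-NaN window proportion >= high,
    ``divergent`` if every one <= low, else ``ambiguous``.  Only windows
    fully contained in the region are used (edge windows mix block and
    background sites and would dilute every track); if none is fully
    contained, overlapping windows are used instead.
    """
    chrom, start, end = region
    sub = profiles[
        (profiles["chrom"] == chrom)
        & (profiles["start"] >= start)
        & (profiles["end"] <= end)
        & profiles["ref_prop"].notna()
    ]
    if sub.empty:
        sub = profiles[
            (profiles["chrom"] == chrom)
            & (profiles["start"] < end)
            & (profiles["end"] > start)
            & profiles["ref_prop"].notna()
        ]
    labels = {}
    for sample, grp in sub.groupby("sample"):
        v = grp["ref_prop"].to_numpy()
        if len(v) == 0:
            labels[sample] = "ambiguous"
        elif (v >= high).all():
            labels[sample] = "reference_like"
        elif (v <= low).all():
            labels[sample] = "divergent"
        else:
            labels[sample] = "ambiguous"
    return pd.Series(labels, name="class")


def candidate_divergent_region(
    profiles: pd.DataFrame,
    pop_by_sample: dict[str, str] | pd.Series,
    threshold: float = 0.6,
    max_gap_windows: int = 2,
) -> IntervalSet:
    """Windows where the between-group gap in mean ref-proportion exceeds
    ``threshold``, merged into maximal runs bridging <= max_gap_windows
    sub-threshold windows (to span sparse-SNP windows)."""
    prof = profiles.copy()
    prof["pop"] = prof["sample"].map(dict(pop_by_sample) if not isinstance(pop_by_sample, pd.Series) else pop_by_sample)
    mean = (
        prof.groupby(["chrom", "start", "end", "pop"])["ref_prop"]
        .mean()
        .unstack("pop")
    )
    if mean.shape[1] != 2:
        raise ValueError("expected exactly two groups")
    diff = (mean.iloc[:, 0] - mean.iloc[:, 1]).abs()
    flagged = diff[diff > threshold].index
    out: list[Interval] = []
    for chrom in diff.index.get_level_values("chrom").unique():
        wins = sorted(
            [(s, e) for c, s, e in diff.index if c == chrom],
            key=lambda w: w[0],
        )
        hot = {(s, e) for c, s, e in flagged if c == chrom}
        run_start = None
        gap = 0
        last_hot_end = None
        for s, e in wins:
            if (s, e) in hot:
                if run_start is None:
                    run_start = s
                last_hot_end = e
                gap = 0
            elif run_start is not None:
                gap += 1
                if gap > max_gap_windows:
                    out.append(Interval(chrom, run_start, last_hot_end))
                    run_start, last_hot_end, gap = None, None, 0
        if run_start is not None:
            out.append(Interval(chrom, run_start, last_hot_end))
    return IntervalSet(out)
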