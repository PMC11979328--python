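"""Dual-statistic bulked segregant analysis: QTL-seq SNP-index and the
per-site Euclidean distance between pool base-frequency vectors.

Per site, for each of two offspring pools:

* SNP-index = alt-read depth / total (ref+alt) depth; sites where both
  pools are below the index threshold (default 0.3) are discarded.
* ED = sqrt(sum over the four bases of (f_base,pool1 - f_base,pool2)^2),
  squared (ED²) to sharpen signal.

Per-site values are averaged in 100-kb windows with a 10-kb step; the
top 5% of windows per statistic are candidate regions, and the
interval intersection of the two statistics' candidates is the
candidate-QTL set (optionally intersected again across mapping crosses).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .sweeps import top_fraction_windows
from .variant_io import GenomeLayout, GenomicWindow, make_windows, window_site_slices

BASE_COLS = ["A", "C", "G", "T"]


def snp_index(ref_depth, alt_depth):
    """Alt-read fraction alt/(ref+alt); NaN at zero total depth."""
    ref_depth = np.asarray(ref_depth, dtype=float)
    alt_depth = np.asarray(alt_depth, dtype=float)
    total = ref_depth + alt_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, alt_depth / total, np.nan)


def site_stats(counts: pd.DataFrame, min_depth: int = 4) -> pd.DataFrame:
    """Per-site BSA statistics from a two-pool base-depth table.

    Expects columns chrom, pos, ref, alt and A/C/G/T depths suffixed _1
    and _2.  Sites with per-pool depth < min_depth in either pool are
    dropped (prevents index degeneracy at shallow sites).  Adds columns
    snp_index_1/2, delta_snp_index, ed, ed2.
    """
    df = counts.copy()
    d1 = df[[f"{b}_1" for b in BASE_COLS]].to_numpy(dtype=float)
    d2 = df[[f"{b}_2" for b in BASE_COLS]].to_numpy(dtype=float)
    tot1, tot2 = d1.sum(axis=1), d2.sum(axis=1)
    keep = (tot1 >= min_depth) & (tot2 >= min_depth)
    df, d1, d2 = df[keep].reset_index(drop=True), d1[keep], d2[keep]
    tot1, tot2 = tot1[keep], tot2[keep]

    base_idx = {b: i for i, b in enumerate(BASE_COLS)}
    ref_i = df["ref"].map(base_idx).to_numpy()
    alt_i = df["alt"].map(base_idx).to_numpy()
    rows = np.arange(len(df))
    ref1, alt1 = d1[rows, ref_i], d1[rows, alt_i]
    ref2, alt2 = d2[rows, ref_i], d2[rows, alt_i]
    df["snp_index_1"] = snp_index(ref1, alt1)
    df["snp_index_2"] = snp_index(ref2, alt2)
    df["delta_snp_index"] = (df["snp_index_1"] - df["snp_index_2"]).abs()
    f1 = d1 / tot1[:, None]
    f2 = d2 / tot2[:, None]
    ed = np.sqrt(((f1 - f2) ** 2).sum(axis=1))
    df["ed"] = ed
    df["ed2"] = ed**2
    return df


def filter_low_index(stats: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Drop sites whose SNP-index is < threshold in BOTH pools (strict <)."""
    low_both = (stats["snp_index_1"] < threshold) & (stats["snp_index_2"] < threshold)
    return stats[~low_both].reset_index(drop=True)


def window_smooth(
    stats: pd.DataFrame,
    statistic: str,
    layout: GenomeLayout,
    size: int = 100_000,
    step: int = 10_000,
    windows: list[GenomicWindow] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of a per-site statistic in sliding windows.

    Empty windows get NaN.  ``statistic`` must be a column of ``stats``
    (normally delta_snp_index or ed2).
    """
    if windows is None:
        windows = make_windows(layout, size, step)
    sub = stats.sort_values(["chrom", "pos"], kind="stable")
    chrom = sub["chrom"].to_numpy(dtype=object)
    # enforce layout chromosome order for the binary search
    order_key = {name: i for i, name in enumerate(layout.names)}
    ordi = np.argsort([order_key[c] for c in chrom], kind="stable")
    chrom = chrom[ordi]
    pos = sub["pos"].to_numpy()[ordi]
    vals = sub[statistic].to_numpy(dtype=float)[ordi]
    ok = ~np.isnan(vals)
    cs_val = np.concatenate([[0.0], np.cumsum(np.where(ok, vals, 0.0))])
    cs_n = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    slices = window_site_slices(chrom, pos, windows)
    values, n_sites = [], []
    for lo, hi in slices:
        n = int(cs_n[hi] - cs_n[lo])
        values.append((cs_val[hi] - cs_val[lo]) / n if n else np.nan)
        n_sites.append(hi - lo)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": n_sites,
            "statistic": statistic,
            "value": values,
        }
    )


def delta_windows(
    stats: pd.DataFrame,
    layout: GenomeLayout,
    size: int = 100_000,
    step: int = 10_000,
    mode: str = "site_delta",
) -> pd.DataFrame:
    """Windowed |ΔSNP-index| in either operation order.

    ``site_delta`` (default): average the per-site |Δ| values per
    window.  ``window_then_difference``: average each pool's SNP-index
    per window, then take the absolute difference of the window means.
    In an F1 pseudo-testcross the coupling/repulsion phase of each
    marker relative to the trait allele is random, so per-pool window
    means cancel across phases and only the per-site |Δ| order retains
    the QTL signal; the two orders agree when markers are consistently
    polarized (e.g. an F2 from inbred parents).
    """
    if mode == "site_delta":
        out = window_smooth(stats, "delta_snp_index", layout, size, step)
        out["statistic"] = "delta_snp_index"
        return out
    if mode != "window_then_difference":
        raise ValueError(f"unknown mode {mode!r}")
    w1 = window_smooth(stats, "snp_index_1", layout, size, step)
    w2 = window_smooth(stats, "snp_index_2", layout, size, step)
    out = w1.copy()
    out["value"] = (w1["value"] - w2["value"]).abs()
    out["statistic"] = "delta_snp_index"
    return out


def candidate_regions(window_stats: pd.DataFrame, fraction: float = 0.05) -> IntervalSet:
    """Top-fraction windows of one BSA statistic, unioned into intervals."""
    _, regions = top_fraction_windows(window_stats, fraction)
    return regions


def intersect_methods(snp_regions: IntervalSet, ed_regions: IntervalSet) -> pd.DataFrame:
    """Candidate QTLs: intersection of SNP-index and ED candidate regions.

    Returns a frame with chrom/start/end/methods rows (methods='both');
    empty intersection gives an empty frame.
    """
    inter = snp_regions.intersection(ed_regions)
    return pd.DataFrame(
        [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "methods": "both"}
            for iv in inter
        ],
        columns=["chrom", "start", "end", "methods"],
    )


def intersect_populations(qtls_a: pd.DataFrame, qtls_b: pd.DataFrame) -> pd.DataFrame:
    """QTLs supported by both mapping crosses (interval intersection)."""
    set_a = IntervalSet((r.chrom, int(r.start), int(r.end)) for r in qtls_a.itertuples())
    set_b = IntervalSet((r.chrom, int(r.start), int(r.end)) for r in qtls_b.itertuples())
    inter = set_a.intersection(set_b)
    return pd.DataFrame(
        [
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "methods": "both", "populations": "cross1,cross2",
            }
            for iv in inter
        ],
        columns=["chrom", "start", "end", "methods", "populations"],
    )


def qtl_region_set(qtls: pd.DataFrame) -> IntervalSet:
    return IntervalSet((r.chrom, int(r.start), int(r.end)) for r in qtls.itertuples())
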