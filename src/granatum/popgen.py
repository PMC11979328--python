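"""Windowed diversity/differentiation statistics and population structure.

All statistics operate on dosage matrices (0/1/2/missing), so SNP panels
and SV presence/absence tables are analysed identically — the study's
central methodological move.

Conventions:

* π per site is the unbiased estimator ``2n/(2n-1) * 2 p (1-p)`` over the
  2n non-missing haplotypes; a window's value is the per-site sum divided
  by the window's covered length (so invariant windows score 0).
* Tajima's D uses the 1989 constants (a1, a2, b1, b2, c1, c2, e1, e2) on
  segregating-site count and mean pairwise differences per window.
* FST is the Weir & Cockerham (1984) variance-components estimator;
  window values are ratio-of-sums (the "weighted" convention), negative
  estimates retained.
* r² is the squared Pearson correlation of unphased dosages, capped at a
  physical distance (default 200 kb), pairwise-complete over missing.
* Admixture ancestry is fitted by EM on the standard binomial likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import MISSING, GenomeLayout, GenomicWindow, GenotypeMatrix, window_site_slices

STAT_NAMES = {
    "pi", "tajima_d", "fst", "het", "delta_snp_index", "mean_ed2", "ref_prop",
}


def _window_frame(windows, values, n_sites, statistic: str) -> pd.DataFrame:
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


def per_site_pi(m: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site nucleotide diversity over non-missing haplotypes."""
    ok = m.codes != MISSING
    n_hap = 2 * ok.sum(axis=0)
    alt = np.where(ok, m.codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_hap
        pi = np.where(n_hap > 1, n_hap / (n_hap - 1.0) * 2.0 * p * (1.0 - p), np.nan)
    return pi


def nucleotide_diversity(m: GenotypeMatrix, windows) -> pd.DataFrame:
    """Windowed π: sum of per-site π divided by covered window length."""
    pi = np.nan_to_num(per_site_pi(m))
    slices = window_site_slices(m.chrom, m.pos, windows)
    csum = np.concatenate([[0.0], np.cumsum(pi)])
    values, n_sites = [], []
    for (lo, hi), w in zip(slices, windows):
        values.append((csum[hi] - csum[lo]) / w.length)
        n_sites.append(hi - lo)
    return _window_frame(windows, values, n_sites, "pi")


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(m: GenotypeMatrix, windows) -> pd.DataFrame:
    """Windowed Tajima's D; NaN where the window has no segregating site.

    Constants are computed for the panel's haplotype count (2 x samples);
    per-site pairwise differences use the observed allele counts.
    """
    n = 2 * m.n_samples
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    a1, e1, e2 = _tajima_constants(n)
    ok = m.codes != MISSING
    n_hap = 2 * ok.sum(axis=0)
    alt = np.where(ok, m.codes, 0).sum(axis=0)
    seg = (alt > 0) & (alt < n_hap)
    with np.errstate(invalid="ignore", divide="ignore"):
        # mean pairwise difference per site: 2 i (n-i) / (n (n-1))
        pair = np.where(
            n_hap > 1, 2.0 * alt * (n_hap - alt) / (n_hap * (n_hap - 1.0)), 0.0
        )
    slices = window_site_slices(m.chrom, m.pos, windows)
    cs_seg = np.concatenate([[0], np.cumsum(seg.astype(np.int64))])
    cs_pair = np.concatenate([[0.0], np.cumsum(pair)])
    values, n_sites = [], []
    for lo, hi in slices:
        S = int(cs_seg[hi] - cs_seg[lo])
        if S == 0:
            values.append(np.nan)
        else:
            theta_pi = cs_pair[hi] - cs_pair[lo]
            theta_w = S / a1
            var = e1 * S + e2 * S * (S - 1.0)
            values.append((theta_pi - theta_w) / np.sqrt(var))
        n_sites.append(hi - lo)
    return _window_frame(windows, values, n_sites, "tajima_d")


def heterozygosity(m: GenotypeMatrix) -> pd.Series:
    """Per-sample fraction of non-missing calls that are heterozygous."""
    ok = m.codes != MISSING
    het = (m.codes == 1).sum(axis=1)
    n = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return pd.Series(np.where(n > 0, het / n, np.nan), index=m.samples)


def wc_fst_components(m: GenotypeMatrix, pop: np.ndarray):
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    ``pop`` is a per-sample label array; any number of populations is
    accepted.  Sites where any population has < 1 non-missing diploid
    (or overall fewer than 2 populations with data) yield NaN components.
    """
    pops = pd.unique(pop)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i, p_i, h_i = [], [], []
    for g in pops:
        sub = m.codes[pop == g]
        ok = sub != MISSING
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, sub, 0).sum(axis=0) / (2.0 * n)
            h = ((sub == 1) & ok).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # (r, S) diploid counts
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    valid = (n_i >= 1).all(axis=0) & ((n_i >= 2).any(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def weir_cockerham_fst(m: GenotypeMatrix, pop: np.ndarray, windows=None):
    """Weighted (ratio-of-sums) windowed WC FST; negative values retained.

    With ``windows=None`` returns the single genome-wide estimate.
    """
    a, b, c = wc_fst_components(m, np.asarray(pop, dtype=object))
    ok = ~np.isnan(a)
    num = np.where(ok, a, 0.0)
    den = np.where(ok, a + b + c, 0.0)
    if windows is None:
        total = den.sum()
        return float(num.sum() / total) if total != 0 else float("nan")
    slices = window_site_slices(m.chrom, m.pos, windows)
    cs_num = np.concatenate([[0.0], np.cumsum(num)])
    cs_den = np.concatenate([[0.0], np.cumsum(den)])
    cs_ok = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    values, n_sites = [], []
    for lo, hi in slices:
        d = cs_den[hi] - cs_den[lo]
        n_ok = int(cs_ok[hi] - cs_ok[lo])
        values.append((cs_num[hi] - cs_num[lo]) / d if (n_ok > 0 and d != 0) else np.nan)
        n_sites.append(hi - lo)
    return _window_frame(windows, values, n_sites, "fst")


def ld_r2(
    m: GenotypeMatrix,
    max_dist_bp: int = 200_000,
    bin_width: int = 5_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise r² for same-chromosome site pairs within a distance cap.

    Returns (pairs, decay) where pairs has columns site_i/site_j/
    distance/r2 and decay is the mean r² per distance bin.  Missing
    dosages are handled pairwise-complete.
    """
    codes = m.codes.astype(float)
    ok_all = (m.codes != MISSING).astype(float)
    codes[m.codes == MISSING] = 0.0
    frames = []
    for chrom in pd.unique(m.chrom):
        idx = np.flatnonzero(m.chrom == chrom)
        pos = m.pos[idx]
        for ii in range(len(idx)):
            jmax = int(np.searchsorted(pos, pos[ii] + max_dist_bp, side="right"))
            if jmax <= ii + 1:
                continue
            i = idx[ii]
            J = idx[ii + 1 : jmax]
            x = codes[:, i]
            okx = ok_all[:, i]
            Y = codes[:, J]
            okp = okx[:, None] * ok_all[:, J]  # pairwise-complete mask
            n = okp.sum(axis=0)
            sx = (x[:, None] * okp).sum(axis=0)
            sy = (Y * okp).sum(axis=0)
            sxx = ((x**2)[:, None] * okp).sum(axis=0)
            syy = (Y**2 * okp).sum(axis=0)
            sxy = ((x[:, None] * Y) * okp).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                vx = n * sxx - sx**2
                vy = n * syy - sy**2
                r2 = (n * sxy - sx * sy) ** 2 / (vx * vy)
            good = (n >= 3) & (vx > 0) & (vy > 0)
            if good.any():
                frames.append(
                    pd.DataFrame(
                        {
                            "site_i": i,
                            "site_j": J[good],
                            "distance": (pos[ii + 1 : jmax][good] - pos[ii]).astype(int),
                            "r2": r2[good],
                        }
                    )
                )
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["site_i", "site_j", "distance", "r2"])
    )
    if len(pairs):
        pairs["bin"] = (pairs["distance"] // bin_width) * bin_width
        decay = (
            pairs.groupby("bin")["r2"].mean().rename("mean_r2").reset_index()
        )
    else:
        decay = pd.DataFrame(columns=["bin", "mean_r2"])
    return pairs.drop(columns=["bin"], errors="ignore"), decay


def pca(m: GenotypeMatrix, n_components: int = 2):
    """PCA of standardized dosages (GCTA-style (g-2p)/sqrt(2p(1-p))).

    Missing calls are mean-imputed (zero after centering).  Returns
    (coords [samples x k], explained_variance_ratio).
    """
    g = m.codes.astype(float)
    g[m.codes == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    keep = denom > 0
    z = (g[:, keep] - 2.0 * p[keep]) / denom[keep]
    z = np.nan_to_num(z)
    u, s, _ = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    k = min(n_components, len(s))
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return u[:, :k] * s[:k], ratio[:k]


def admixture_em(
    m: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
):
    """EM for the standard admixture binomial likelihood.

    Maximizes sum_ij [ g log(sum_k q_ik p_kj) + (2-g) log(sum_k q_ik (1-p_kj)) ]
    over ancestry fractions Q (rows on the simplex) and ancestral allele
    frequencies P.  Returns (Q, P, loglik_trace); the trace is
    non-decreasing, an EM guarantee used as a correctness check.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m.n_samples:
        raise ValueError("K exceeds the number of samples")
    g = m.codes.astype(float)
    ok = m.codes != MISSING
    g[~ok] = 0.0
    two = np.where(ok, 2.0, 0.0)
    N, S = g.shape
    freq = g.sum(axis=0) / np.maximum(two.sum(axis=0), 1.0)
    if K == 1:
        Q = np.ones((N, 1))
        P = freq[None, :]
        ll = _admix_loglik(g, two, Q, P)
        return Q, P, [ll]
    freq = np.clip(freq, 0.01, 0.99)
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=N)
    P = np.clip(freq[None, :] + rng.normal(0, 0.1, size=(K, S)), 0.01, 0.99)
    trace = []
    eps = 1e-12
    for _ in range(max_iter):
        f = Q @ P  # (N, S) expected alt-allele frequency
        f = np.clip(f, eps, 1 - eps)
        # responsibilities: expected allele-copy counts by ancestry
        # alt copies from k: g * q_ik p_kj / f ; ref copies: (2-g) * q_ik (1-p_kj) / (1-f)
        alt_w = g / f
        ref_w = (two - g) / (1.0 - f)
        A = Q[:, :, None] * P[None, :, :] * alt_w[:, None, :]  # (N, K, S)
        R = Q[:, :, None] * (1.0 - P)[None, :, :] * ref_w[:, None, :]
        Q = (A + R).sum(axis=2)
        Q /= Q.sum(axis=1, keepdims=True)
        denom = A.sum(axis=0) + R.sum(axis=0)
        P = np.where(denom > 0, A.sum(axis=0) / np.maximum(denom, eps), P)
        P = np.clip(P, eps, 1 - eps)
        ll = _admix_loglik(g, two, Q, P)
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    return Q, P, trace


def _admix_loglik(g, two, Q, P) -> float:
    f = np.clip(Q @ P, 1e-12, 1 - 1e-12)
    return float((g * np.log(f) + (two - g) * np.log(1.0 - f)).sum())


def q_correlation(q_a: np.ndarray, q_b: np.ndarray):
    """R² (and p-value) between two K=2 ancestry vectors, label-swap safe.

    Regresses component 1 of q_a on component 1 of q_b in both label
    orientations and keeps the orientation with the higher R².
    """
    a = np.asarray(q_a)[:, 0] if np.asarray(q_a).ndim == 2 else np.asarray(q_a)
    b = np.asarray(q_b)[:, 0] if np.asarray(q_b).ndim == 2 else np.asarray(q_b)
    best = None
    for bb in (b, 1.0 - b):
        res = stats.linregress(bb, a)
        r2 = res.rvalue**2
        if best is None or r2 > best[0]:
            best = (r2, res.pvalue)
    return best
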