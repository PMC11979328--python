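"""Independent brute-force oracles, coded separately from the package.

Everything here is written as plain per-element loops directly from the
defining formulas, deliberately ignoring the package's vectorized
implementations, so the two routes are independent.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def pi_per_site(codes: np.ndarray) -> list[float]:
    """Mean pairwise haplotype difference per site, enumerated over all
    haplotype pairs among non-missing diploids."""
    n_samples, n_sites = codes.shape
    out = []
    for j in range(n_sites):
        haps = []
        for i in range(n_samples):
            c = codes[i, j]
            if c == MISSING:
                continue
            haps.extend([1, 1] if c == 2 else [1, 0] if c == 1 else [0, 0])
        diff = pairs = 0
        for a in range(len(haps)):
            for b in range(a + 1, len(haps)):
                pairs += 1
                diff += haps[a] != haps[b]
        out.append(diff / pairs if pairs else float("nan"))
    return out


def tajimas_d(codes: np.ndarray) -> float:
    """Tajima's D over all sites of a complete-data diploid matrix."""
    n = 2 * codes.shape[0]
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    S = 0
    theta_pi = 0.0
    for j in range(codes.shape[1]):
        c = int(codes[:, j].sum())
        if 0 < c < n:
            S += 1
        theta_pi += 2.0 * c * (n - c) / (n * (n - 1))
    if S == 0:
        return float("nan")
    return (theta_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def wc_fst_per_site(codes: np.ndarray, pop: list[str]):
    """Weir & Cockerham (1984) a, b, c per site, scalar transcription."""
    groups = sorted(set(pop))
    r = len(groups)
    out = []
    for j in range(codes.shape[1]):
        n_i, p_i, h_i = [], [], []
        for g in groups:
            vals = [codes[i, j] for i in range(codes.shape[0]) if pop[i] == g]
            vals = [v for v in vals if v != MISSING]
            if not vals:
                out.append((float("nan"),) * 3)
                break
            n = len(vals)
            p = sum(vals) / (2.0 * n)
            h = sum(1 for v in vals if v == 1) / n
            n_i.append(n)
            p_i.append(p)
            h_i.append(h)
        else:
            nbar = sum(n_i) / r
            if nbar <= 1 or max(n_i) < 2:
                out.append((float("nan"),) * 3)
                continue
            nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
            b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2.0
            out.append((a, b, c))
    return out


def wc_fst_global(codes: np.ndarray, pop: list[str]) -> float:
    num = den = 0.0
    for a, b, c in wc_fst_per_site(codes, pop):
        if not math.isnan(a):
            num += a
            den += a + b + c
    return num / den


def r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete dosages."""
    ok = (x != MISSING) & (y != MISSING)
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if len(xs) < 3 or xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1] ** 2)


def snp_index(ref: float, alt: float) -> float:
    return alt / (ref + alt)


def euclidean_distance(d1: dict, d2: dict) -> float:
    t1, t2 = sum(d1.values()), sum(d2.values())
    return math.sqrt(
        sum((d1.get(b, 0) / t1 - d2.get(b, 0) / t2) ** 2 for b in "ACGT")
    )


def window_mean(positions, values, start, end) -> float:
    inside = [
        v
        for p, v in zip(positions, values)
        if start <= p < end and not math.isnan(v)
    ]
    return sum(inside) / len(inside) if inside else float("nan")
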