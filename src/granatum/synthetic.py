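"""Synthetic data with the statistical structure the analyses assume.

Four generators stand in for the study's sequencing data:

* ``simulate_two_pop_snps`` — a 19 + 19 accession diploid SNP panel from
  the Balding–Nichols model, whose parameter F is the target genome-wide
  Weir–Cockerham FST (used to calibrate the differentiation estimator).
* ``simulate_inversion_block`` — overlays a long haplotype block fixed
  for opposite alleles in the two subpopulations, the genotype signature
  of a non-recombining inversion.
* ``simulate_sv_callsets`` — two jittered SV call sources (emulating an
  assembly-comparison route and a long-read-mapping route) over a common
  truth set, for merge/Venn testing.
* ``simulate_bulks`` — pooled read depths for two phenotype-extreme F1
  bulks from an Aa x aa pseudo-testcross with one planted QTL, with
  linkage decay by Haldane's map function.

All generators are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sv import SVRecord, reciprocal_overlap
from .variant_io import MISSING, GenomeLayout, GenotypeMatrix

BASES = np.array(["A", "C", "G", "T"])

# 1/10-scale eight-chromosome layout (31.9 Mb total)
SCALED_LAYOUT = GenomeLayout(
    (
        ("chr1", 5_600_000),
        ("chr2", 4_800_000),
        ("chr3", 4_400_000),
        ("chr4", 4_000_000),
        ("chr5", 3_600_000),
        ("chr6", 3_400_000),
        ("chr7", 3_200_000),
        ("chr8", 2_900_000),
    )
)

# SV type mix of the published 28 607-variant catalog
SV_TYPE_PROPORTIONS = {
    "DEL": 11043 / 28607,
    "INS": 16197 / 28607,
    "DUP": 650 / 28607,
    "INV": 117 / 28607,
    "CNV": 205 / 28607,
    "TRA": 395 / 28607,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all synthetic generators."""

    seed: int = 0
    layout: GenomeLayout = SCALED_LAYOUT
    n_pop1: int = 19
    n_pop2: int = 19
    n_sites: int = 20_000
    fst_target: float = 0.2
    # pooled-bulk parameters
    depth_mean: float = 50.0
    bulk_size: int = 30
    n_f1: int = 100
    qtl: tuple[str, int, float] = ("chr1", 5_030_000, 1.0)
    cm_per_mb: float = 4.0
    seq_error: float = 0.002
    # inversion proxy
    inversion: tuple[str, int, int] = ("chr1", 1_800_000, 2_350_000)
    # SV call-source parameters
    n_sv: int = 1000
    p_detect: float = 0.9
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_pop1, self.n_pop2, self.n_sites, self.bulk_size, self.n_f1) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        if self.bulk_size * 2 > self.n_f1:
            raise ValueError("two bulks cannot exceed the F1 population size")

    def rng(self, stream: str) -> np.random.Generator:
        tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)


def inversion_scenario(seed: int = 0, **kw) -> SimConfig:
    """Full-scale chromosome 1 hosting the reported ~5.4-Mb divergent block."""
    layout = GenomeLayout((("chr1", 56_000_000),))
    defaults = dict(
        seed=seed,
        layout=layout,
        n_sites=30_000,
        inversion=("chr1", 18_658_790, 24_069_667),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def bsa_scenario(seed: int = 0, effect: float = 1.0, **kw) -> SimConfig:
    """Whole scaled genome with one planted QTL for pool-seq BSA.

    The recombination rate is 10x the full-scale default so that each
    1/10-scale chromosome keeps a realistic genetic length (the QTL's
    linkage halo then occupies the same fraction of the genome as at
    full scale).
    """
    defaults = dict(
        seed=seed,
        layout=SCALED_LAYOUT,
        n_sites=6_000,
        qtl=("chr1", 2_800_000, effect),
        cm_per_mb=40.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def _random_positions(rng: np.random.Generator, layout: GenomeLayout, n: int):
    """n distinct sites placed uniformly over the genome, sorted."""
    lengths = np.array([c[1] for c in layout.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[chrom_idx]).astype(np.int64)
    # dedupe collisions by nudging (genome >> n, so a few steps suffice)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    for i in range(1, n):
        if chrom_idx[i] == chrom_idx[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    chrom = np.array([layout.chromosomes[i][0] for i in chrom_idx], dtype=object)
    return chrom, pos


def _random_alleles(rng: np.random.Generator, n: int):
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    return BASES[ref_i].astype(object), BASES[alt_i].astype(object)


def _genotypes_from_freqs(rng, p_by_pop, n_by_pop) -> np.ndarray:
    rows = []
    for p, n in zip(p_by_pop, n_by_pop):
        rows.append(rng.binomial(2, np.broadcast_to(p, (n, len(p)))).astype(np.int8))
    return np.concatenate(rows, axis=0)


def pop_labels(cfg: SimConfig) -> np.ndarray:
    return np.array(["pop1"] * cfg.n_pop1 + ["pop2"] * cfg.n_pop2, dtype=object)


def _sample_names(cfg: SimConfig) -> list[str]:
    return [f"P1_{i:02d}" for i in range(cfg.n_pop1)] + [
        f"P2_{i:02d}" for i in range(cfg.n_pop2)
    ]


def simulate_two_pop_snps(cfg: SimConfig):
    """Balding–Nichols two-population SNP panel.

    Ancestral frequency p ~ U(0.05, 0.95); each subpopulation frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (identical when F = 0); genotypes
    Binomial(2, p_pop).  Returns (GenotypeMatrix, truth DataFrame with
    per-site subpopulation frequencies).
    """
    rng = cfg.rng("two_pop_snps")
    chrom, pos = _random_positions(rng, cfg.layout, cfg.n_sites)
    ref, alt = _random_alleles(rng, cfg.n_sites)
    p_anc = rng.uniform(0.05, 0.95, cfg.n_sites)
    if cfg.fst_target == 0.0:
        p1, p2 = p_anc.copy(), p_anc.copy()
    else:
        c = (1.0 - cfg.fst_target) / cfg.fst_target
        p1 = rng.beta(p_anc * c, (1.0 - p_anc) * c)
        p2 = rng.beta(p_anc * c, (1.0 - p_anc) * c)
    codes = _genotypes_from_freqs(rng, [p1, p2], [cfg.n_pop1, cfg.n_pop2])
    m = GenotypeMatrix(_sample_names(cfg), chrom, pos, ref, alt, codes)
    truth = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "p_anc": p_anc, "p_pop1": p1, "p_pop2": p2}
    )
    # GenotypeMatrix sorts sites; positions were generated sorted, so truth aligns
    return m, truth


def simulate_inversion_block(cfg: SimConfig):
    """Two-population panel with a planted divergent haplotype block.

    Inside ``cfg.inversion`` the subpopulation alt frequencies are pushed
    to opposite near-fixation (pop1 ~ U(0, .05), pop2 ~ U(.95, 1)), so
    pop1 accessions are near-fixed hom-ref and pop2 near-fixed hom-alt;
    outside, background Balding–Nichols divergence at ``fst_target``.

    Returns (GenotypeMatrix, labels, truth DataFrame).
    """
    m, truth = simulate_two_pop_snps(cfg)
    rng = cfg.rng("inversion_block")
    chrom_i, start, end = cfg.inversion
    inside = (m.chrom == chrom_i) & (m.pos >= start) & (m.pos < end)
    n_in = int(inside.sum())
    p1 = rng.uniform(0.0, 0.05, n_in)
    p2 = rng.uniform(0.95, 1.0, n_in)
    codes = m.codes.copy()
    codes[: cfg.n_pop1, inside] = rng.binomial(
        2, np.broadcast_to(p1, (cfg.n_pop1, n_in))
    ).astype(np.int8)
    codes[cfg.n_pop1 :, inside] = rng.binomial(
        2, np.broadcast_to(p2, (cfg.n_pop2, n_in))
    ).astype(np.int8)
    m2 = GenotypeMatrix(m.samples, m.chrom, m.pos, m.ref, m.alt, codes)
    truth = truth.copy()
    truth.loc[inside, "p_pop1"] = p1
    truth.loc[inside, "p_pop2"] = p2
    truth["in_block"] = inside
    return m2, pop_labels(cfg), truth


def _draw_truth_svs(rng: np.random.Generator, cfg: SimConfig) -> list[SVRecord]:
    types = rng.choice(
        list(SV_TYPE_PROPORTIONS), size=cfg.n_sv, p=list(SV_TYPE_PROPORTIONS.values())
    )
    # log-uniform lengths; lower bound just above the 10-bp reporting floor
    lengths = np.round(10 ** rng.uniform(np.log10(10.5), 6.0, cfg.n_sv)).astype(np.int64)
    chrom_sizes = dict(cfg.layout.chromosomes)
    lens = np.array([c[1] for c in cfg.layout.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(lens), size=cfg.n_sv, p=lens / lens.sum())
    records = []
    placed: dict[tuple[str, str], list[SVRecord]] = {}
    for k in range(cfg.n_sv):
        chrom = cfg.layout.chromosomes[chrom_idx[k]][0]
        L = chrom_sizes[chrom]
        sv_len = int(min(lengths[k], L // 2))
        t = str(types[k])
        stratum = placed.setdefault((chrom, t), [])
        # a truth catalog is non-redundant: re-place (shrinking if the
        # chromosome is saturated) any draw that would itself satisfy the
        # merge criterion against an earlier truth SV
        cand = None
        while cand is None:
            for _try in range(50):
                if t in ("INS", "TRA"):
                    start = int(rng.integers(0, L))
                    trial = SVRecord(
                        id=f"truth_{k:05d}", chrom=chrom, start=start, end=start,
                        svtype=t, length=sv_len if t == "INS" else 0, source="truth",
                    )
                    ok = not any(_point_conflict(trial, o) for o in stratum)
                else:
                    start = int(rng.integers(0, L - sv_len))
                    trial = SVRecord(
                        id=f"truth_{k:05d}", chrom=chrom, start=start,
                        end=start + sv_len, svtype=t, length=sv_len, source="truth",
                    )
                    ok = not any(
                        reciprocal_overlap((trial.start, trial.end), (o.start, o.end))
                        >= 0.5
                        for o in stratum
                    )
                if ok:
                    cand = trial
                    break
            else:
                sv_len = max(11, sv_len // 2)
        stratum.append(cand)
        records.append(cand)
    return records


def _point_conflict(a: SVRecord, b: SVRecord) -> bool:
    # conservative spacing: twice the 1-kb breakpoint-matching radius
    return abs(a.start - b.start) <= 2000


def _jittered_copy(rng, rec: SVRecord, source: str, sd: float, idx: int) -> SVRecord:
    if sd == 0.0:
        d_start = d_end = 0
    else:
        d_start = int(round(rng.normal(0.0, sd)))
        d_end = int(round(rng.normal(0.0, sd)))
    if rec.svtype in ("INS", "TRA"):
        start = max(0, rec.start + d_start)
        return replace(rec, id=f"{source}_{idx:05d}", source=source, start=start, end=start)
    start = max(0, rec.start + d_start)
    end = max(start + 1, rec.end + d_end)
    return replace(
        rec, id=f"{source}_{idx:05d}", source=source,
        start=start, end=end, length=end - start,
    )


def simulate_sv_callsets(cfg: SimConfig):
    """Two call sources over a common SV truth set.

    Each source reports each truth SV with probability ``p_detect`` and
    breakpoint jitter round(N(0, jitter_sd)).  Returns
    (source_a, source_b, truth, groups) where groups maps truth id ->
    list of reporting record ids.
    """
    rng = cfg.rng("sv_callsets")
    truth = _draw_truth_svs(rng, cfg)
    source_a, source_b = [], []
    groups: dict[str, list[str]] = {t.id: [] for t in truth}
    for name, sink in (("asm", source_a), ("smrt", source_b)):
        for i, rec in enumerate(truth):
            if rng.random() < cfg.p_detect:
                cp = _jittered_copy(rng, rec, name, cfg.jitter_sd, i)
                sink.append(cp)
                groups[rec.id].append(cp.id)
    return source_a, source_b, truth, groups


def _haldane_r(dist_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    morgans = dist_bp * cm_per_mb * 1e-8
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def simulate_bulks(cfg: SimConfig):
    """Pool-seq base depths for tolerant/sensitive F1 bulks.

    Cross is Aa x aa at every marker (pseudo-testcross, coupling or
    repulsion phase at random per site); the QTL allele A raises the
    probability of landing in the tolerant bulk by ``effect`` (0 = none,
    1 = deterministic sorting).  Site depth is Poisson(depth_mean) per
    pool, base composition multinomial on true pool frequencies with a
    symmetric sequencing-error rate.

    Returns (counts DataFrame, truth dict).  The counts frame has one
    row per site with columns chrom, pos, ref, alt and per-pool A/C/G/T
    depths (suffix _1 = tolerant, _2 = sensitive).
    """
    chrom_q, pos_q, effect = cfg.qtl
    if chrom_q not in cfg.layout.names:
        raise ValueError(f"QTL chromosome {chrom_q!r} not in layout")
    rng = cfg.rng("bulks")
    chrom, pos = _random_positions(rng, cfg.layout, cfg.n_sites - 1)
    # plant a marker at the QTL itself
    chrom = np.append(chrom, chrom_q)
    pos = np.append(pos, pos_q)
    order = np.lexsort((pos, np.array([cfg.layout.names.index(c) for c in chrom])))
    chrom, pos = chrom[order], pos[order]
    ref, alt = _random_alleles(rng, cfg.n_sites)

    # F1 gametes from the heterozygous parent
    x = rng.integers(0, 2, cfg.n_f1)  # 1 = carries QTL allele A
    p_tol = 0.5 + effect * (x - 0.5)
    tolerant = rng.random(cfg.n_f1) < p_tol
    tol_idx = np.flatnonzero(tolerant)
    sen_idx = np.flatnonzero(~tolerant)
    if len(tol_idx) < cfg.bulk_size or len(sen_idx) < cfg.bulk_size:
        raise ValueError("phenotype classes too small for requested bulk_size")
    bulk1 = rng.choice(tol_idx, cfg.bulk_size, replace=False)
    bulk2 = rng.choice(sen_idx, cfg.bulk_size, replace=False)

    same_chr = chrom == chrom_q
    dist = np.where(same_chr, np.abs(pos - pos_q), np.inf)
    r = np.where(same_chr, _haldane_r(np.where(same_chr, dist, 0), cfg.cm_per_mb), 0.5)
    phase = rng.integers(0, 2, cfg.n_sites)  # coupling/repulsion per site
    flips = rng.random((cfg.n_f1, cfg.n_sites)) < r[None, :]
    marker = (x[:, None] ^ flips) ^ phase[None, :]  # alt-allele indicator per gamete

    out = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
    e = cfg.seq_error
    base_order = list(BASES)
    for suffix, bulk in (("1", bulk1), ("2", bulk2)):
        freq = marker[bulk].mean(axis=0) / 2.0  # other parent contributes ref
        depth = rng.poisson(cfg.depth_mean, cfg.n_sites)
        alt_reads = rng.binomial(depth, np.clip(freq, 0, 1))
        ref_reads = depth - alt_reads
        counts = np.zeros((cfg.n_sites, 4), dtype=np.int64)
        ref_col = np.array([base_order.index(b) for b in ref])
        alt_col = np.array([base_order.index(b) for b in alt])
        # sequencing error scatters reads uniformly over the other 3 bases
        for true_reads, col in ((ref_reads, ref_col), (alt_reads, alt_col)):
            errs = rng.binomial(true_reads, e)
            np.add.at(counts, (np.arange(cfg.n_sites), col), true_reads - errs)
            scatter = rng.multinomial(1, [1 / 3] * 3, size=cfg.n_sites) * errs[:, None]
            for k in range(3):
                other = (col + 1 + k) % 4
                np.add.at(counts, (np.arange(cfg.n_sites), other), scatter[:, k])
        for b, base in enumerate(base_order):
            out[f"{base}_{suffix}"] = counts[:, b]
    counts_df = pd.DataFrame(out)
    truth = {
        "qtl_chrom": chrom_q,
        "qtl_pos": int(pos_q),
        "effect": float(effect),
        "n_tolerant": int(tolerant.sum()),
    }
    return counts_df, truth


def sample_neutral_sfs(n_haplotypes: int, n_sites: int, seed: int) -> GenotypeMatrix:
    """Diploid matrix whose derived-allele counts follow the neutral SFS.

    Counts i in [1, n-1] are drawn with probability proportional to 1/i
    and assigned to random haplotypes; haplotypes are paired into
    n_haplotypes/2 diploids.  Tajima's D over such sites is ~0 in
    expectation.
    """
    if n_haplotypes < 4 or n_haplotypes % 2:
        raise ValueError("need an even number of haplotypes >= 4")
    rng = np.random.default_rng(seed)
    n_dip = n_haplotypes // 2
    samples = [f"S{i:02d}" for i in range(n_dip)]
    if n_sites == 0:
        return GenotypeMatrix(
            samples, [], [], [], [], np.zeros((n_dip, 0), dtype=np.int8)
        )
    i_vals = np.arange(1, n_haplotypes)
    p = (1.0 / i_vals) / (1.0 / i_vals).sum()
    counts = rng.choice(i_vals, size=n_sites, p=p)
    hap = np.zeros((n_haplotypes, n_sites), dtype=np.int8)
    for j, c in enumerate(counts):
        hap[rng.choice(n_haplotypes, c, replace=False), j] = 1
    codes = hap[0::2] + hap[1::2]
    pos = np.arange(n_sites, dtype=np.int64) * 100
    chrom = np.full(n_sites, "chr1", dtype=object)
    ref, alt = _random_alleles(rng, n_sites)
    return GenotypeMatrix(samples, chrom, pos, ref, alt, codes)
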