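"""Genotype/interval I/O, site filters, and sliding-window construction.

All coordinates are internally 0-based half-open; VCF positions are
converted on read (``POS - 1``) and back on write.  Genotypes are stored
as diploid dosage codes: 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
Every downstream module (diversity scans, sweep detection, SV genotyping,
BSA) consumes the containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .intervals import Interval, IntervalSet

log = logging.getLogger(__name__)

MISSING = -1

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_TO_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(c[1] <= 0 for c in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(c[1] for c in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, size in self.chromosomes:
            if name == chrom:
                return size
        raise KeyError(f"unknown chromosome {chrom!r}")

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, size = line.split("\t")[:2]
                chroms.append((name, int(size)))
        return cls(tuple(chroms))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, size in self.chromosomes:
                fh.write(f"{name}\t{size}\n")


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open window [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class GenotypeMatrix:
    """Samples x sites diploid dosage matrix with per-site metadata.

    Sites are kept sorted by (chromosome order of first appearance, pos);
    the dosage array uses int8 with -1 for missing calls.
    """

    def __init__(self, samples, chrom, pos, ref, alt, codes):
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        self._sort_sites()

    def _sort_sites(self) -> None:
        # stable sort by (chrom in order of first appearance, pos)
        order_of = {}
        for c in self.chrom:
            order_of.setdefault(c, len(order_of))
        key = np.lexsort((self.pos, np.array([order_of[c] for c in self.chrom])))
        if not np.array_equal(key, np.arange(len(key))):
            self.chrom = self.chrom[key]
            self.pos = self.pos[key]
            self.ref = self.ref[key]
            self.alt = self.alt[key]
            self.codes = self.codes[:, key]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        return GenotypeMatrix(
            self.samples,
            self.chrom[idx],
            self.pos[idx],
            self.ref[idx],
            self.alt[idx],
            self.codes[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.codes[idx],
        )

    def missing_fraction(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per site among non-missing calls (NaN if none)."""
        ok = self.codes != MISSING
        n = ok.sum(axis=0)
        alt = np.where(ok, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)


def read_genotypes(vcf_path, layout: GenomeLayout | None = None) -> GenotypeMatrix:
    """Read a VCF with GT fields into a GenotypeMatrix.

    Multiallelic records are skipped with a warning; positions are
    converted to 0-based.  If *layout* is given, records on chromosomes
    absent from it raise ``ValueError``.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, cols = [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if layout is not None and v.CHROM not in layout.names:
            raise ValueError(f"unknown chromosome {v.CHROM!r} at {v.CHROM}:{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS - 1)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        cols.append(_GT_TYPE_TO_CODE[np.asarray(v.gt_types)])
    vcf.close()
    if n_multi:
        log.warning("skipped %d multiallelic record(s)", n_multi)
    codes = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, chrom, pos, ref, alt, codes)


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(m: GenotypeMatrix, path, layout: GenomeLayout | None = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if layout is not None:
            for name, size in layout.chromosomes:
                fh.write(f"##contig=<ID={name},length={size}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        for j in range(m.n_sites):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in m.codes[:, j])
            fh.write(
                f"{m.chrom[j]}\t{m.pos[j] + 1}\t.\t{m.ref[j]}\t{m.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_sites(
    m: GenotypeMatrix, max_missing: float = 0.2, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Keep sites with missingness <= max_missing and MAF >= min_maf.

    MAF is computed over non-missing alleles only; both bounds are
    inclusive.  Idempotent.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    with np.errstate(invalid="ignore"):
        keep = (m.missing_fraction() <= max_missing) & (m.maf() >= min_maf)
    keep &= ~np.isnan(m.maf())
    if not keep.any():
        log.warning("filter_sites removed every site")
    return m.take_sites(keep)


def make_windows(layout: GenomeLayout, size: int, step: int | None = None) -> list[GenomicWindow]:
    """Sliding windows over every chromosome; the last window is truncated.

    Starts are 0, step, 2*step, ...; every base of [0, L) is covered.
    ``step`` defaults to ``size`` (non-overlapping tiling).
    """
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step > size would leave uncovered gaps")
    windows = []
    for name, length in layout.chromosomes:
        start = 0
        while start < length:
            windows.append(GenomicWindow(name, start, min(start + size, length)))
            start += step
    return windows


def window_site_slices(
    chrom: np.ndarray, pos: np.ndarray, windows: list[GenomicWindow]
) -> list[tuple[int, int]]:
    """For each window, the (lo, hi) slice of sorted site indices inside it.

    Sites must already be sorted by (chrom, pos), as GenotypeMatrix
    guarantees; uses per-chromosome binary search.
    """
    bounds: dict[str, tuple[int, int]] = {}
    i = 0
    while i < len(chrom):
        j = i
        while j < len(chrom) and chrom[j] == chrom[i]:
            j += 1
        bounds[chrom[i]] = (i, j)
        i = j
    out = []
    for w in windows:
        lo_c, hi_c = bounds.get(w.chrom, (0, 0))
        sub = pos[lo_c:hi_c]
        lo = lo_c + int(np.searchsorted(sub, w.start, side="left"))
        hi = lo_c + int(np.searchsorted(sub, w.end, side="left"))
        out.append((lo, hi))
    return out


def read_intervals(bed_path, merge: bool = False) -> IntervalSet | list[Interval]:
    """Read BED3+ intervals; returns an IntervalSet when merge=True, else
    the raw interval list in file order."""
    raw = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{bed_path}:{ln}: start >= end")
            raw.append(Interval(chrom, start, end))
    return IntervalSet(raw) if merge else raw


def write_intervals(intervals, path) -> None:
    """Write intervals (IntervalSet or iterable) as BED3."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gff_genes(gff_path) -> list[tuple[str, str, int, int]]:
    """Extract (gene_id, seqid, start0, end) for gene features from GFF3.

    Only seqid/start/end/ID are used; GFF 1-based inclusive coordinates
    are converted to 0-based half-open.
    """
    genes = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            gid = None
            for kv in f[8].split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
                    break
            genes.append((gid or f"{f[0]}:{f[3]}", f[0], int(f[3]) - 1, int(f[4])))
    return genes
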