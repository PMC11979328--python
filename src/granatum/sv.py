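"""Structural-variant records: merging by reciprocal overlap, cross-source
support, summaries, and presence/absence genotyping.

Merging follows the standard multi-caller deduplication recipe: within
each (chromosome, type) stratum, records whose reciprocal overlap is at
least the threshold (default 80%) are single-linkage clustered and the
longest member represents the cluster.  Point events (INS, TRA) have no
span, so they match by breakpoint proximity (<= 1 kb) plus, for INS, an
inserted-length ratio >= 0.8.  Records no longer than 10 bp are dropped
before merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import MISSING, GenomeLayout, GenotypeMatrix

log = logging.getLogger(__name__)

SPAN_TYPES = frozenset({"DEL", "DUP", "INV", "CNV"})
POINT_TYPES = frozenset({"INS", "TRA"})
SV_TYPES = SPAN_TYPES | POINT_TYPES


@dataclass(frozen=True)
class SVRecord:
    """One structural variant; start/end are 0-based half-open
    (end == start for insertion points and translocation breakpoints)."""

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    source: str = ""
    partner: tuple[str, int] | None = None  # TRA second breakpoint

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.length < 0 or self.start < 0:
            raise ValueError("negative length or coordinate")
        if self.svtype in SPAN_TYPES and self.length != self.end - self.start:
            raise ValueError(
                f"{self.svtype} length {self.length} != end-start "
                f"{self.end - self.start}"
            )


@dataclass
class MergedSVSet:
    records: list[SVRecord]
    provenance: dict[str, list[str]]  # merged id -> contributing source record ids


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|) for two half-open spans on one chromosome."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("zero-length interval in reciprocal overlap")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def _canonical_order(records: list[SVRecord]) -> list[SVRecord]:
    return sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.length, r.id))


def _point_match(a: SVRecord, b: SVRecord, max_dist: int, min_len_ratio: float) -> bool:
    if abs(a.start - b.start) > max_dist:
        return False
    if a.svtype == "INS":
        lo, hi = sorted((a.length, b.length))
        return hi == 0 or lo / hi >= min_len_ratio
    # TRA: both breakpoints must be close
    pa = a.partner or (a.chrom, a.start)
    pb = b.partner or (b.chrom, b.start)
    return pa[0] == pb[0] and abs(pa[1] - pb[1]) <= max_dist


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_callsets(
    callsets,
    min_recip: float = 0.8,
    min_len: int = 10,
    point_max_dist: int = 1000,
    point_len_ratio: float = 0.8,
) -> MergedSVSet:
    """Merge SV call sets by single-linkage clustering within type.

    Records with length <= ``min_len`` bp are dropped first (strict
    "greater than" rule).  Within each (chromosome, type) stratum, span
    types link at reciprocal overlap >= ``min_recip``; point types link
    by breakpoint proximity.  Each cluster is represented by its longest
    member (ties broken by coordinates then id), so the operation is
    input-order independent and idempotent.
    """
    pool: list[SVRecord] = []
    for cs in callsets:
        pool.extend(cs)
    pool = [r for r in pool if r.length > min_len or (r.svtype == "TRA")]
    merged: list[SVRecord] = []
    provenance: dict[str, list[str]] = {}
    by_stratum: dict[tuple[str, str], list[SVRecord]] = {}
    for r in pool:
        by_stratum.setdefault((r.chrom, r.svtype), []).append(r)

    for (chrom, svtype), recs in sorted(by_stratum.items()):
        recs = _canonical_order(recs)
        dsu = _DSU(len(recs))
        reach = max(point_max_dist, 1)
        for i, a in enumerate(recs):
            for j in range(i + 1, len(recs)):
                b = recs[j]
                if svtype in SPAN_TYPES:
                    if b.start >= a.end:  # sorted by start: no later overlap with a
                        break
                    if reciprocal_overlap((a.start, a.end), (b.start, b.end)) >= min_recip:
                        dsu.union(i, j)
                else:
                    if b.start - a.start > reach:
                        break
                    if _point_match(a, b, point_max_dist, point_len_ratio):
                        dsu.union(i, j)
        clusters: dict[int, list[SVRecord]] = {}
        for i, r in enumerate(recs):
            clusters.setdefault(dsu.find(i), []).append(r)
        for members in clusters.values():
            rep = max(members, key=lambda r: (r.length, -r.start, -r.end, r.id))
            merged.append(rep)
            provenance[rep.id] = sorted(m.id for m in members)
    merged = _canonical_order(merged)
    return MergedSVSet(merged, {r.id: provenance[r.id] for r in merged})


def support_venn(a, b, min_recip: float = 0.8, point_max_dist: int = 1000,
                 point_len_ratio: float = 0.8):
    """Cross-source support: how many records of a have a same-type match in b.

    Returns (n_a, n_b, n_matched, pct_of_a) with pct on the 0-100 scale.
    """
    a, b = list(a), list(b)
    if not a:
        raise ValueError("support percentage undefined for empty first set")
    by_stratum: dict[tuple[str, str], list[SVRecord]] = {}
    for r in b:
        by_stratum.setdefault((r.chrom, r.svtype), []).append(r)
    n_matched = 0
    for r in a:
        partners = by_stratum.get((r.chrom, r.svtype), ())
        for p in partners:
            if r.svtype in SPAN_TYPES:
                hit = reciprocal_overlap((r.start, r.end), (p.start, p.end)) >= min_recip
            else:
                hit = _point_match(r, p, point_max_dist, point_len_ratio)
            if hit:
                n_matched += 1
                break
    return len(a), len(b), n_matched, 100.0 * n_matched / len(a)


def summarize(records, large_threshold: int = 1000) -> dict:
    """Per-type and per-chromosome counts, length stats, and the fraction
    of variants longer than ``large_threshold`` bp."""
    records = list(records)
    by_type: dict[str, int] = {}
    by_chrom: dict[str, int] = {}
    lengths = []
    for r in records:
        by_type[r.svtype] = by_type.get(r.svtype, 0) + 1
        by_chrom[r.chrom] = by_chrom.get(r.chrom, 0) + 1
        lengths.append(r.length)
    lengths = np.asarray(lengths, dtype=float)
    n_large = int((lengths > large_threshold).sum()) if len(lengths) else 0
    return {
        "total": len(records),
        "by_type": dict(sorted(by_type.items())),
        "by_chrom": dict(sorted(by_chrom.items())),
        "n_large": n_large,
        "pct_large": 100.0 * n_large / len(records) if records else 0.0,
        "mean_length": float(lengths.mean()) if len(lengths) else 0.0,
        "max_length": int(lengths.max()) if len(lengths) else 0,
        # square-root-scale length histogram export (for plotting)
        "sqrt_length_quartiles": (
            [float(q) for q in np.percentile(np.sqrt(lengths), [25, 50, 75])]
            if len(lengths)
            else [0.0, 0.0, 0.0]
        ),
    }


def chrom_count_regression(layout: GenomeLayout, counts: dict[str, int]):
    """OLS of per-chromosome SV count on chromosome length.

    Returns (r_squared, p_value, slope); the p-value is the two-sided
    t-test on the slope with n-2 df.
    """
    if len(layout.chromosomes) < 3:
        raise ValueError("need at least 3 chromosomes for a regression")
    x = np.array([size for _, size in layout.chromosomes], dtype=float)
    y = np.array([counts.get(name, 0) for name, _ in layout.chromosomes], dtype=float)
    if np.ptp(y) == 0:  # constant counts: no association
        return 0.0, 1.0, 0.0
    res = stats.linregress(x, y)
    return res.rvalue**2, res.pvalue, res.slope


def genotype_psv(merged: MergedSVSet, presence: GenotypeMatrix) -> GenotypeMatrix:
    """Drop monomorphic SVs from a presence-dosage matrix.

    An SV is polymorphic when both the reference and the variant allele
    are observed among non-missing calls (a het call carries both).
    Returns a GenotypeMatrix restricted to polymorphic SVs, directly
    usable by the diversity/differentiation statistics.
    """
    codes = presence.codes
    ok = codes != MISSING
    has_var = ((codes > 0) & ok).any(axis=0)
    has_ref = ((codes < 2) & ok).any(axis=0)
    keep = has_var & has_ref
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("genotype_psv: dropped %d monomorphic SV(s)", n_drop)
    return presence.take_sites(keep)


def read_sv_tsv(path) -> list[SVRecord]:
    """Read 6-column TSV (chrom, start, end, type, length, source)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "type", "length", "source", "id"]
    df.columns = names[: df.shape[1]]
    if "id" not in df.columns:
        df["id"] = [f"{s}_{i:06d}" for i, s in enumerate(df["source"])]
    return [
        SVRecord(
            id=str(row.id), chrom=str(row.chrom), start=int(row.start),
            end=int(row.end), svtype=str(row.type), length=int(row.length),
            source=str(row.source),
        )
        for row in df.itertuples()
    ]


def write_sv_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttype\tlength\tsource\tid\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.svtype}\t{r.length}"
                f"\t{r.source}\t{r.id}\n"
            )


def read_sv_vcf(path, source: str = "vcf") -> list[SVRecord]:
    """Read SVs from a VCF using SVTYPE/SVLEN/END INFO keys."""
    from cyvcf2 import VCF

    records = []
    for i, v in enumerate(VCF(str(path))):
        svtype = v.INFO.get("SVTYPE")
        if svtype is None or svtype not in SV_TYPES:
            continue
        start = v.POS - 1
        svlen = v.INFO.get("SVLEN")
        end_info = v.INFO.get("END")
        if svtype in SPAN_TYPES:
            end = int(end_info) if end_info is not None else start + abs(int(svlen))
            length = end - start
        else:
            end = start
            length = abs(int(svlen)) if svlen is not None and svtype == "INS" else 0
        records.append(
            SVRecord(
                id=v.ID or f"{source}_{i:06d}", chrom=v.CHROM, start=start,
                end=end, svtype=svtype, length=length, source=source,
            )
        )
    return records
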