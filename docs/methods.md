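# Methods

## Scope and data model

The package reimplements the population-genomic and QTL-mapping layer of
a pomegranate cold-tolerance study design: everything downstream of
variant calling (SV call sets, genotype matrices, pooled base depths)
and upstream of wet-lab validation. Internal coordinates are uniformly
0-based half-open; VCF positions are shifted on read/write and BED is
used natively. Genotypes are diploid dosage codes 0/1/2 with −1 for
missing, in a samples × sites matrix kept sorted by (chromosome,
position). Because every statistic consumes dosage matrices, SV
presence/absence panels flow through the same π/D/FST/LD/PCA/ancestry
code as SNP panels — the comparison of the two marker classes is the
analytical point, not a special case.

## Statistics

**π** per site is the unbiased estimator `2n/(2n−1) · 2p̂(1−p̂)` over the
2n non-missing haplotypes; a window's value is the per-site sum divided
by the window's *covered* length, so invariant windows score 0 and
truncated chromosome-end windows are normalized by their actual span.
Both `n_sites` and covered length are recorded so either normalization
can be reproduced.

**Tajima's D** uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
computed for the panel's haplotype count 2N; per-site pairwise
differences use observed allele counts among non-missing calls, the
segregating-site count S is per window, and windows with S = 0 are NaN.
Fewer than 4 haplotypes is an error.

**FST** is the Weir & Cockerham (1984) variance-components estimator
(a, b, c per site); windows report the ratio of summed numerators to
summed denominators (the "weighted" convention of standard VCF
tooling), negative estimates retained. Monomorphic sites contribute
zero to both sums. Per-site components are exposed for reuse.

**LD r²** is the squared Pearson correlation of unphased dosages for
same-chromosome pairs within a physical cap (default 200 kb), computed
pairwise-complete over missing calls; the decay curve is mean r² per
distance bin (5 kb). Phasing is never attempted.

**PCA** standardizes dosages as `(g − 2p̂)/√(2p̂(1−p̂))` with
mean-imputation of missing values (zero after centering) and takes the
SVD; monomorphic sites are dropped.

**Ancestry** maximizes the standard admixture binomial likelihood by EM.
The log-likelihood is non-decreasing by construction (asserted in
tests); iteration stops at a gain below `tol` (1e-6) or at `max_iter`
(300). In near-separated panels the allele-frequency parameters drift
asymptotically toward the boundary with per-iteration gains slightly
above the tolerance, so the iteration cap is the effective stop; the
ancestry fractions Q are stable long before it. EM was chosen over the
quasi-Newton block relaxation of dedicated ancestry software for
clarity; for K = 2 and dozens of samples the difference is runtime, not
results. Label switching in Q-vector comparisons is resolved by taking
the orientation with the higher R².

## SV merging

Within each (chromosome, type) stratum, span records (DEL/DUP/INV/CNV)
link when reciprocal overlap ≥ 0.8 and are clustered by single linkage
(union-find over a start-sorted sweep). Insertions match when their
breakpoints are ≤ 1 kb apart and inserted lengths have ratio ≥ 0.8;
translocations when both breakpoints are ≤ 1 kb apart. Records with
length ≤ 10 bp are dropped beforehand ("greater than 10 bp" read
strictly); translocations carry length 0 by convention and are exempt.
The longest member represents a cluster, with coordinate/id tie-breaks,
which together with canonical pre-sorting makes merging input-order
independent and idempotent. Polymorphic-SV filtering keeps a variant
when both the reference and the variant allele are observed among
non-missing presence calls (a het call carries both).

## Sweep and inversion scans

Sweeps are windows at or above the (1−f) quantile of windowed FST
(default f = 0.05, 20-kb windows / 2-kb step), ties included — the
selection may exceed the nominal fraction but is deterministic. Selected
windows are reported both as a window list (for sweep counts) and
unioned into intervals (for Mb/percent arithmetic), since the two
conventions answer different questions.

The inversion scan computes, per accession and 100-kb window, the
fraction of non-missing calls that are homozygous-reference;
heterozygous calls count as non-reference because the track contrasts
each accession against the reference assembly (configurable). Candidate
divergent regions are maximal runs of windows where the between-group
difference of mean reference proportion exceeds 0.6, bridging up to two
sub-threshold windows to span sparse-SNP gaps. Accession classification
("reference_like" ≥ 0.8 everywhere / "divergent" ≤ 0.2 everywhere /
else "ambiguous") uses only windows fully contained in the queried
region: edge windows mix block and background sites and would otherwise
push every sample to "ambiguous".

## BSA

SNP-index is the alt-read fraction per pool; sites with total per-pool
depth < 4 reads are dropped (prevents index degeneracy; configurable),
and sites with index < 0.3 in *both* pools are removed (strict "<").
ED is computed over the four-base frequency vectors, as squared ED for
signal sharpening; on biallelic sites this equals the ref/alt-only
definition. Window statistics are arithmetic means of per-site values in
100-kb/10-kb sliding windows, NaN when empty, with quantiles taken over
non-NaN windows only.

ΔSNP-index windows are smoothed from per-site |Δ| values by default.
The alternative order — average each pool's index per window, then
difference — is implemented behind a flag, but it is not usable for the
default cross design: in an Aa × aa F1 pseudo-testcross each marker's
coupling/repulsion phase relative to the trait allele is random, so
per-pool window means average over phases and cancel even at a fully
penetrant QTL, while per-site |Δ| is phase-invariant. The two orders
agree whenever markers are consistently polarized (e.g. an F2 from
inbred parents).

Candidate QTL regions are the interval intersection of the two
statistics' top-5% window unions; regions supported by both mapping
crosses are the final candidates.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume,
at desk scale:

* **Two-population SNP panel** — 19 + 19 diploid accessions;
  ancestral frequencies U(0.05, 0.95); subpopulation frequencies from
  the Balding–Nichols Beta distribution with parameter F (default 0.2),
  chosen because it gives a closed-form target for calibrating the FST
  estimator. Default 20 000 sites on a 1/10-scale eight-chromosome
  layout (31.9 Mb), i.e. ~630 sites/Mb vs ~1 350/Mb in a real 428 815-SNP
  panel over 318.59 Mb — the same order of magnitude per analysis
  window.
* **Inversion block** — a full-scale 56-Mb chromosome 1 carrying a
  5.41-Mb block (the reported breakpoints) where subpopulation alt
  frequencies are pushed to opposite near-fixation (≥ 0.9 divergence);
  background divergence at F = 0.2. 30 000 sites give ~54 per 100-kb
  window.
* **SV call sources** — a non-redundant truth catalog (type mix taken
  from the published 28 607-variant catalog; lengths log-uniform from
  just above the 10-bp floor to 1 Mb, shrunk only when a chromosome
  saturates) reported by each of two sources with probability
  `p_detect` and breakpoint jitter round(N(0, σ)). Truth records are
  re-placed rather than allowed to overlap at ≥ 0.5 reciprocal, because
  a merged catalog is non-redundant by construction and zero-jitter
  merging must recover it exactly.
* **Bulks** — Aa × aa pseudo-testcross (woody-perennial F1 design;
  Aa × Aa configurable), 100 F1 individuals, bulks of 30, pool depth
  Poisson(50), base composition multinomial with 0.2% symmetric
  sequencing error (which exercises the 0.3-index filter). Linkage
  follows Haldane's map function; the BSA scenario uses 40 cM/Mb on the
  1/10-scale genome so each chromosome keeps the genetic length it
  would have at full scale under the 4 cM/Mb default (the study gives
  no genetic map). The QTL allele raises the probability of assignment
  to the tolerant bulk by `effect` (0 = null, 1 = deterministic
  sorting).
* **Neutral SFS** — derived-allele counts ∝ 1/i for Tajima's D
  calibration.

Not emulated: sequencing/alignment artifacts with spatial structure
(mappability, paralogy), LD beyond the single-QTL linkage model (the
SNP panel's sites are exchangeable draws, so LD decay curves from it are
flat by design and only exercise the r² machinery), selfing/clonal
relatedness within subpopulations, SV false-positive calls, and
multi-QTL genetic architectures. Passing recovery tests therefore shows
the estimators and the scan logic are correct under the stated models,
not that the pipeline is robust to real-data artifacts.

## Numerical and policy choices

* MAF and missingness filters are inclusive at the boundary (≥ 5% MAF,
  ≤ 20% missing), MAF over non-missing alleles only; filtering is
  idempotent.
* Sliding windows start at 0, step, 2·step, …; the terminal window is
  truncated at the chromosome end so every base is covered exactly;
  step > size is rejected.
* Multiallelic VCF records are skipped with a logged warning.
* Quantile ties at the top-fraction threshold are all kept.
* Degenerate inputs error early and explicitly: empty support-Venn
  first set, all-NaN window statistics, < 3 chromosomes for the
  count-length regression, zero-length spans in reciprocal overlap,
  K > samples in the ancestry model.
* Interval sets are normalized (sorted, disjoint, adjacent runs merged)
  on construction; union/intersection respect inclusion–exclusion,
  which the property tests assert.

## Problem sizes

Default analysis sizes (20 000-site panel, 30 000-site inversion panel,
1 000-SV catalog, 6 000-site bulks, 20-seed calibration, 200-replicate
neutrality and null-rate checks, 50-seed QTL power) were chosen so the
complete test suite and the acceptance script each run in well under a
minute of simulation time while keeping per-window site counts in the
regime the real study operated in. They are package defaults, not
statistical necessities; every size is a `SimConfig`/`RunConfig` field.

## Known limitations

* Tajima's D constants use the panel-wide haplotype count; with heavy
  missingness the per-window effective n is smaller than assumed.
* The EM ancestry model ignores LD and inbreeding, as the standard
  admixture likelihood does.
* The reference-genotype-proportion scan assumes the reference assembly
  belongs to one haplotype class; a reference recombinant inside the
  block would blur both modes.
* `support_venn` counts a source-A record as supported if *any*
  same-type B record matches; reciprocal best-hit matching is not
  implemented.
* The deduplication path between mapping-genotyped and
  reference-aligned polymorphic SV sets is exposed via `merge_callsets`
  but the original study's exact union procedure is underspecified.
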