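#!/usr/bin/env python
"""Generate the synthetic study inputs: a 19+19 accession SNP panel, an
SV presence panel, two jittered SV call sources over a truth catalog, a
full-scale chromosome-1 panel carrying the divergent inversion block,
and pooled bulk depths for two mapping crosses."""

import argparse

from granatum.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed, outdir=args.outdir)
    summary = run_stage("simulate", cfg)
    print(f"simulated {summary['n_snp_sites']} SNP sites, "
          f"{summary['n_truth_sv']} truth SVs, two bulk crosses "
          f"(QTL at {summary['bsa_truth']['cross1']['qtl_chrom']}:"
          f"{summary['bsa_truth']['cross1']['qtl_pos']})")


if __name__ == "__main__":
    main()
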