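#!/usr/bin/env python
"""Selective sweeps: top-5% windowed FST (20 kb / 2 kb) on SNPs and SVs,
and the bp/percent overlap between the two sweep sets."""

import argparse

from granatum.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()
    s = run_stage("sweep", RunConfig(seed=args.seed, outdir=args.outdir))
    print(f"sweeps: {s['n_sweeps_snp']} SNP-based ({s['genome_pct_snp']:.2f}% of "
          f"genome), {s['n_sweeps_sv']} SV-based ({s['genome_pct_sv']:.2f}%)")
    print(f"overlap: {s['overlap_bp']/1e6:.2f} Mb = "
          f"{s['overlap_pct_of_snp']:.1f}% of SNP-based signal")


if __name__ == "__main__":
    main()
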