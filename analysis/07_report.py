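#!/usr/bin/env python
"""Collect every stage summary into one report.json with the
planted-truth recovery flags."""

import argparse
import json

from granatum.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()
    report = run_stage("report", RunConfig(seed=args.seed, outdir=args.outdir))
    print(json.dumps({k: sorted(v) for k, v in report.items()}, indent=2))


if __name__ == "__main__":
    main()
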