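#!/usr/bin/env python
"""Quality control of the query samples.

Scores doublets with the synthetic-doublet kNN classifier, removes the top
1% (LSK) / 4.5% (LK) per sample, applies the >10%-mito / <500-gene / 3-SD
UMI filters, and writes the filtered triplets plus a QC accounting table to
results/.
"""

import argparse
import os

import pandas as pd

from mklandscape import qc
from mklandscape.config import PipelineConfig
from mklandscape.containers import read_counts, write_counts

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    data = os.path.join(BASE, "data")
    if not os.path.isdir(os.path.join(data, "WT")):
        raise SystemExit("no simulated data found; run analysis/01_simulate.py first")
    cfg = PipelineConfig(seed=args.seed)
    reports = []
    for geno in ("WT", "MUT"):
        cm = read_counts(os.path.join(data, geno))
        filtered, report, scores, kept = qc.run_qc(cm, cfg, seed=args.seed)
        truth = pd.read_csv(os.path.join(data, f"{geno}_truth.tsv"), sep="\t")
        spiked = truth["is_doublet"].sum() + truth["is_low_quality"].sum()
        print(f"{geno}: {cm.n_cells} -> {filtered.n_cells} cells "
              f"({spiked} artifacts were spiked in)")
        write_counts(filtered, os.path.join(data, f"{geno}_filtered"))
        t = report.table.copy()
        t.insert(0, "genotype", geno)
        reports.append(t)
    out = pd.concat(reports, ignore_index=True)
    out.to_csv(os.path.join(BASE, "qc_report.tsv"), sep="\t", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
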