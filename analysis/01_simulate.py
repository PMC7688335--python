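#!/usr/bin/env python
"""Simulate the demo landscape: reference + WT/MUT query samples.

Generates the 13-cluster hematopoietic-landscape demo (HSC, MK, a pMKP-like
bridge cluster midway between them with a 3x mutant abundance multiplier, and
ten further lineage clusters), spikes doublets and low-quality cells into the
query samples, and writes CellRanger-style triplets plus ground-truth tables
under results/data/.
"""

import argparse
import os

from mklandscape import datagen
from mklandscape.containers import write_counts

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-reference", type=int, default=3000)
    ap.add_argument("--n-query", type=int, default=1500)
    args = ap.parse_args()

    spec = datagen.demo_landscape(n_reference_cells=args.n_reference,
                                  seed=args.seed)
    ref, ref_truth = datagen.generate_reference(spec)
    write_counts(ref, os.path.join(OUT, "reference"))
    datagen.write_ground_truth(ref_truth, os.path.join(OUT, "reference_truth.tsv"))
    print(f"reference: {ref.n_cells} cells x {ref.n_genes} genes, "
          f"{len(set(ref_truth.fine_label.tolist()))} planted fine clusters")

    for geno, offset in [("WT", 10_000), ("MUT", 20_000)]:
        cm, truth = datagen.generate_query(spec, geno, args.n_query,
                                           seed=offset + args.seed)
        cm, truth = datagen.spike_artifacts(cm, truth, doublet_rate=0.03,
                                            low_quality_rate=0.02,
                                            seed=offset + args.seed + 1)
        write_counts(cm, os.path.join(OUT, geno))
        datagen.write_ground_truth(truth, os.path.join(OUT, f"{geno}_truth.tsv"))
        print(f"{geno}: {cm.n_cells} cells "
              f"({int(truth.is_doublet.sum())} spiked doublets, "
              f"{int(truth.is_low_quality.sum())} spiked low-quality)")
    print(f"wrote triplets under {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
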