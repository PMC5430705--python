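#!/usr/bin/env python
"""Normalize counts, compute m/a values, apply the empirical 2.58xSD
cutoff with BH-adjusted p-values, and join operons from spanning reads.

Usage: python analysis/05_transcriptome.py --data results/data --out results/transcriptome
"""

import argparse
import logging
import sys
from pathlib import Path

import pandas as pd

from redoxpipe import transcriptome as tx
from redoxpipe.tables import read_table, write_table

log = logging.getLogger("transcriptome")


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/transcriptome"))
    parser.add_argument("--alpha", type=float, default=0.01)
    args = parser.parse_args(argv)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="[%(name)s] %(message)s")
    args.out.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.data / "counts.tsv", sep="\t").set_index("gene_id")
    groups = {c: ("stress" if c.startswith("stress") else "control") for c in counts.columns}
    factors = tx.size_factors(counts)
    expr = tx.ma_values(counts, factors, groups)
    expr["p_adj"] = tx.diff_test(counts, factors, groups)
    cutoff = tx.empirical_cutoff(expr["m_value"])
    expr = tx.call_de(expr, cutoff, args.alpha)
    write_table(expr.reset_index(names="gene_id"), args.out / "expression.tsv")
    log.info("m-value cutoff %.3f; %d/%d genes differentially expressed",
             cutoff, int(expr["de_flag"].sum()), len(expr))

    genes = read_table(args.data / "genes.tsv", {"gene_id": str, "strand": str, "start": int})
    spanning = read_table(
        args.data / "spanning_reads.tsv",
        {"gene_a": str, "gene_b": str, "n_spanning": int},
    )
    junctions = {(r.gene_a, r.gene_b): int(r.n_spanning) for r in spanning.itertuples(index=False)}
    operons = tx.call_operons(genes, junctions)
    op_df = pd.DataFrame(
        {
            "genes": [",".join(o.genes) for o in operons],
            "strand": [o.strand for o in operons],
            "n_genes": [len(o.genes) for o in operons],
        }
    )
    write_table(op_df, args.out / "operons.tsv")
    multi = int((op_df["n_genes"] > 1).sum())
    log.info("%d operons (%d multi-gene)", len(op_df), multi)


if __name__ == "__main__":
    main()
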