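#!/usr/bin/env python
"""Simulate all study-shaped inputs: ICAT features, Cys mass increments,
RNA-seq counts with operon junctions, and a genome with planted promoters.

Usage: python analysis/01_simulate.py --seed 1 --out results/data
"""

import argparse
import logging
import sys
from pathlib import Path

import numpy as np

from redoxpipe import synth
from redoxpipe.tables import write_table

log = logging.getLogger("simulate")


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args(argv)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="[%(name)s] %(message)s")
    args.out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(args.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]

    features, truth = synth.gen_redox_features(
        synth.RedoxSimConfig(n_sites=1000, n_replicates=3, noise_cv=0.2, seed=seeds[0])
    )
    write_table(features, args.out / "icat_features.tsv")
    synth.save_truth(truth, args.out / "redox_truth.json")
    log.info("ICAT features: %d rows", len(features))

    matches, mod_truth = synth.gen_mod_deltas(300, seed=seeds[1])
    write_table(mod_truth, args.out / "mod_truth.tsv")
    import pandas as pd

    obs = pd.DataFrame(
        {
            "protein_id": [m.protein_id for m in matches],
            "peptide": [m.peptide for m in matches],
            "cys_position": [m.cys_position for m in matches],
            "observed_delta": [m.observed_delta for m in matches],
        }
    )
    write_table(obs, args.out / "mod_observations.tsv")
    log.info("Cys mass increments: %d", len(obs))

    counts, genes, spanning, ctruth = synth.gen_counts(synth.CountSimConfig(seed=seeds[2]))
    write_table(counts.reset_index(names="gene_id"), args.out / "counts.tsv")
    write_table(genes, args.out / "genes.tsv")
    write_table(spanning, args.out / "spanning_reads.tsv")
    synth.save_truth(ctruth, args.out / "counts_truth.json")
    log.info("counts: %d genes x %d samples", *counts.shape)

    genome, gene_models, motif_truth = synth.gen_genome_with_motifs(
        synth.GenomeSimConfig(seed=seeds[3])
    )
    (args.out / "genome.fasta").write_text(
        "".join(f">{c}\n{s}\n" for c, s in genome.items())
    )
    gm = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in gene_models],
            "contig": [g.contig for g in gene_models],
            "strand": [g.strand for g in gene_models],
            "start_codon": [g.start_codon for g in gene_models],
        }
    )
    write_table(gm, args.out / "gene_models.tsv")
    write_table(motif_truth, args.out / "motif_truth.tsv")
    log.info("genome: %d bp, %d genes, %d planted elements",
             sum(map(len, genome.values())), len(gene_models), len(motif_truth))


if __name__ == "__main__":
    main()
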