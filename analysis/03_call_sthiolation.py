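#!/usr/bin/env python
"""Call S-thiolation adducts (MSH, Cys, ...) from observed Cys mass
increments and score agreement with the simulation truth.

Usage: python analysis/03_call_sthiolation.py --data results/data --out results/sthiolation
"""

import argparse
import dataclasses
import logging
import sys
from pathlib import Path

import pandas as pd

from redoxpipe.sthiolation import PeptideMatch, call_sthiolation
from redoxpipe.tables import read_table, write_table

log = logging.getLogger("sthiolate")


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/sthiolation"))
    args = parser.parse_args(argv)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="[%(name)s] %(message)s")
    args.out.mkdir(parents=True, exist_ok=True)

    obs = read_table(
        args.data / "mod_observations.tsv",
        {"protein_id": str, "peptide": str, "cys_position": int, "observed_delta": float},
    )
    matches = [
        PeptideMatch(r.protein_id, r.peptide, int(r.cys_position), float(r.observed_delta))
        for r in obs.itertuples(index=False)
    ]
    calls = call_sthiolation(matches)
    calls_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    write_table(calls_df, args.out / "calls.tsv")

    truth = read_table(
        args.data / "mod_truth.tsv",
        {"site_id": str, "modification": str, "true_delta": float},
    )
    merged = calls_df.merge(truth, on="site_id", suffixes=("_called", "_true"))
    agree = (merged["modification_called"] == merged["modification_true"]).mean()
    log.info("%d calls, %.1f%% agree with simulation truth", len(calls), 100 * agree)
    summary = merged.groupby("modification_called").size().rename("n").reset_index()
    write_table(summary, args.out / "call_counts.tsv")


if __name__ == "__main__":
    main()
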