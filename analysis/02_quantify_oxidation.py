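#!/usr/bin/env python
"""Pair light/heavy ICAT features, compute %oxidation per site and the
stress-minus-control delta table.

Usage: python analysis/02_quantify_oxidation.py --data results/data --out results/redox
"""

import argparse
import dataclasses
import logging
import sys
from pathlib import Path

import pandas as pd

from redoxpipe import oxicat, synth
from redoxpipe.tables import read_table, write_table

log = logging.getLogger("quantify")


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/redox"))
    parser.add_argument("--tol-ppm", type=float, default=10.0)
    args = parser.parse_args(argv)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="[%(name)s] %(message)s")
    args.out.mkdir(parents=True, exist_ok=True)

    features = read_table(
        args.data / "icat_features.tsv",
        {"site_id": str, "neutral_mass": float, "intensity": float,
         "n_cys": int, "replicate_id": str, "condition": str},
    )
    pairs, unpaired = oxicat.pair_icat_features(
        synth.features_to_objects(features), tol_ppm=args.tol_ppm
    )
    log.info("%d pairs, %d unpaired features", len(pairs), len(unpaired))

    measurements = oxicat.quantify_pairs(pairs)
    meas_df = pd.DataFrame([dataclasses.asdict(m) for m in measurements])
    write_table(meas_df, args.out / "measurements.tsv")

    states = oxicat.aggregate_replicates(
        [m for m in measurements if m.confidence == "normal"]
    )
    write_table(pd.DataFrame([dataclasses.asdict(s) for s in states]),
                args.out / "site_redox_states.tsv")

    deltas, skipped = oxicat.delta_table(states, "control", "stress")
    if skipped:
        log.warning("%d sites present in one condition only", len(skipped))
    write_table(pd.DataFrame([dataclasses.asdict(d) for d in deltas]),
                args.out / "delta_oxidation.tsv")
    log.info("%d site states, %d deltas", len(states), len(deltas))


if __name__ == "__main__":
    main()
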