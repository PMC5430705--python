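#!/usr/bin/env python
"""Summarize the redox landscape: oxidation bins per condition, delta
classes, RSA exposure and a treemap-style category roll-up.

Usage: python analysis/04_summarize_redox.py --redox results/redox --out results/summary
"""

import argparse
import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from redoxpipe import summary, synth
from redoxpipe.tables import read_table, write_table

log = logging.getLogger("summarize")


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--redox", type=Path, default=Path("results/redox"))
    parser.add_argument("--out", type=Path, default=Path("results/summary"))
    parser.add_argument("--seed", type=int, default=1, help="seed for the simulated RSA table")
    args = parser.parse_args(argv)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="[%(name)s] %(message)s")
    args.out.mkdir(parents=True, exist_ok=True)

    states = read_table(
        args.redox / "site_redox_states.tsv",
        {"site_id": str, "condition": str, "mean_percent_ox": float, "n_replicates": int},
    )
    rows = []
    for cond, grp in states.groupby("condition"):
        for b in summary.summarize_bins(grp["mean_percent_ox"]):
            rows.append({"condition": cond, **dataclasses.asdict(b)})
    write_table(pd.DataFrame(rows), args.out / "bins.tsv")
    ctrl = states[states["condition"] == "control"]["mean_percent_ox"]
    below25 = {b.label: b for b in summary.summarize_bins(ctrl)}["below-25"]
    log.info("control: %d/%d (%.1f%%) sites below 25%% oxidation",
             below25.count, len(ctrl), below25.percent)

    deltas = read_table(
        args.redox / "delta_oxidation.tsv",
        {"site_id": str, "delta": float},
    )
    dsum = summary.summarize_deltas(deltas["delta"])
    write_table(
        pd.DataFrame([dataclasses.asdict(b) for b in dsum.values()]),
        args.out / "delta_classes.tsv",
    )
    log.info("%d/%d sites gain >10 pp oxidation under stress",
             dsum["sensitive"].count, len(deltas))

    rsa = synth.gen_rsa(deltas["site_id"], seed=args.seed)
    rsa["rsa_class"] = [summary.rsa_classify(v) for v in rsa["rsa"]]
    write_table(rsa, args.out / "rsa_classes.tsv")
    n_exp = int((rsa["rsa_class"] == "exposed").sum())
    log.info("RSA: %d/%d (%.1f%%) exposed", n_exp, len(rsa),
             summary.percent_of(n_exp, len(rsa)))

    values = dict(zip(deltas["site_id"], deltas["delta"]))
    category_of = {sid: f"category{sum(sid.encode()) % 6}" for sid in values}
    tree = summary.rollup_categories(values, category_of)
    (args.out / "treemap.json").write_text(json.dumps(tree.to_dict(), indent=1))
    log.info("treemap over %d sites, %d categories", tree.count, len(tree.children))


if __name__ == "__main__":
    main()
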