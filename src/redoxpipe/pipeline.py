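"""End-to-end orchestration of the synthetic-data analysis pipeline.

One configured, seeded run simulates every input, executes the stages in
dependency order (simulate -> quantify -> S-thiolation -> summarize;
counts -> m/a analysis -> operons; genome -> promoter scan) and writes
all outputs plus a manifest sufficient to re-execute identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from redoxpipe import oxicat, promoters, sthiolation, summary, synth, transcriptome
from redoxpipe.tables import write_table

log = logging.getLogger("redoxpipe")


@dataclass
class RunConfig:
    """Thresholds and stage toggles for one pipeline run."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    pairing_tol_ppm: float = 10.0
    rsa_threshold: float = 20.0
    operon_min_spanning: int = 20
    induction_m_min: float = 1.0
    alpha: float = 0.01
    cutoff_multiplier: float = 2.58
    run_redox: bool = True
    run_transcriptome: bool = True
    run_promoters: bool = True
    redox: synth.RedoxSimConfig = field(default_factory=synth.RedoxSimConfig)
    counts: synth.CountSimConfig = field(default_factory=synth.CountSimConfig)
    genome: synth.GenomeSimConfig = field(default_factory=synth.GenomeSimConfig)

    def validate(self) -> None:
        for name in (
            "pairing_tol_ppm",
            "rsa_threshold",
            "induction_m_min",
            "alpha",
            "cutoff_multiplier",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, name: str, path: Path, n_rows: int | None = None) -> None:
        self.outputs[name] = {
            "path": str(path),
            "sha256": _sha256(path),
            "n_rows": n_rows,
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def _derive_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["redox", "mods", "rsa", "counts", "genome"]
    return {n: int(child.generate_state(1)[0] % (2**31)) for n, child in zip(names, ss.spawn(5))}


def run_pipeline(config: RunConfig) -> RunManifest:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed)
    log.info("[run] seed=%d out=%s", config.seed, out)

    if config.run_redox:
        _redox_stage(config, seeds, out, manifest)
    if config.run_transcriptome or config.run_promoters:
        expr = _transcriptome_stage(config, seeds, out, manifest)
        if config.run_promoters:
            _promoter_stage(config, seeds, out, manifest, expr)

    manifest.write(out / "manifest.json")
    return manifest


def _redox_stage(config: RunConfig, seeds, out: Path, manifest: RunManifest) -> None:
    rconf = dataclasses.replace(config.redox, seed=seeds["redox"])
    features, truth = synth.gen_redox_features(rconf)
    write_table(features, out / "icat_features.tsv")
    manifest.record("icat_features", out / "icat_features.tsv", len(features))
    synth.save_truth(truth, out / "redox_truth.json")
    manifest.record("redox_truth", out / "redox_truth.json")

    pairs, unpaired = oxicat.pair_icat_features(
        synth.features_to_objects(features), tol_ppm=config.pairing_tol_ppm
    )
    if unpaired:
        manifest.warnings.append(f"{len(unpaired)} unpaired ICAT features")
    measurements = oxicat.quantify_pairs(pairs)
    states = oxicat.aggregate_replicates(
        [m for m in measurements if m.confidence == "normal"]
    )
    ctrl, stress = rconf.conditions
    deltas, skipped = oxicat.delta_table(states, ctrl, stress)
    if skipped:
        manifest.warnings.append(f"{len(skipped)} sites present in one condition only")

    states_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in states]
    )
    write_table(states_df, out / "site_redox_states.tsv")
    manifest.record("site_redox_states", out / "site_redox_states.tsv", len(states_df))

    delta_df = pd.DataFrame([dataclasses.asdict(d) for d in deltas])
    if len(delta_df):
        delta_df["delta_class"] = [summary.classify_delta(d.delta) for d in deltas]
    write_table(delta_df, out / "delta_oxidation.tsv")
    manifest.record("delta_oxidation", out / "delta_oxidation.tsv", len(delta_df))

    # bin summaries per condition + delta classes
    rows = []
    for cond in rconf.conditions:
        vals = [s.mean_percent_ox for s in states if s.condition == cond]
        for b in summary.summarize_bins(vals):
            rows.append({"condition": cond, **dataclasses.asdict(b)})
    bins_df = pd.DataFrame(rows)
    write_table(bins_df, out / "redox_bins.tsv")
    manifest.record("redox_bins", out / "redox_bins.tsv", len(bins_df))

    # S-thiolation calling on simulated mass increments
    matches, mod_truth = synth.gen_mod_deltas(200, seed=seeds["mods"])
    calls = sthiolation.call_sthiolation(matches)
    calls_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    write_table(calls_df, out / "sthiolation_calls.tsv")
    manifest.record("sthiolation_calls", out / "sthiolation_calls.tsv", len(calls_df))
    write_table(mod_truth, out / "sthiolation_truth.tsv")
    manifest.record("sthiolation_truth", out / "sthiolation_truth.tsv", len(mod_truth))

    # RSA classification
    site_ids = sorted({s.site_id for s in states})
    rsa = synth.gen_rsa(site_ids, seed=seeds["rsa"])
    rsa["rsa_class"] = [
        summary.rsa_classify(v, config.rsa_threshold) for v in rsa["rsa"]
    ]
    write_table(rsa, out / "rsa_classes.tsv")
    manifest.record("rsa_classes", out / "rsa_classes.tsv", len(rsa))

    # treemap-style roll-up over a coarse functional annotation
    values = {d.site_id: d.delta for d in deltas}
    category_of = {
        sid: f"category{sum(sid.encode()) % 6}" for sid in values
    }
    tree = summary.rollup_categories(values, category_of)
    (out / "treemap.json").write_text(json.dumps(tree.to_dict(), indent=1))
    manifest.record("treemap", out / "treemap.json")


def _transcriptome_stage(config: RunConfig, seeds, out: Path, manifest: RunManifest):
    cconf = dataclasses.replace(config.counts, seed=seeds["counts"])
    counts, genes, spanning, truth = synth.gen_counts(cconf)
    write_table(counts.reset_index(names="gene_id"), out / "counts.tsv")
    manifest.record("counts", out / "counts.tsv", len(counts))
    write_table(spanning, out / "spanning_reads.tsv")
    manifest.record("spanning_reads", out / "spanning_reads.tsv", len(spanning))
    synth.save_truth(truth, out / "counts_truth.json")
    manifest.record("counts_truth", out / "counts_truth.json")

    groups = {s: ("stress" if s.startswith("stress") else "control") for s in counts.columns}
    factors = transcriptome.size_factors(counts)
    expr = transcriptome.ma_values(counts, factors, groups)
    cutoff = transcriptome.empirical_cutoff(expr["m_value"], config.cutoff_multiplier)
    expr["p_adj"] = transcriptome.diff_test(counts, factors, groups)
    expr = transcriptome.call_de(expr, cutoff, config.alpha)
    write_table(expr.reset_index(names="gene_id"), out / "expression.tsv")
    manifest.record("expression", out / "expression.tsv", len(expr))
    manifest.outputs["expression"]["m_cutoff"] = cutoff

    junctions = {
        (r.gene_a, r.gene_b): int(r.n_spanning) for r in spanning.itertuples(index=False)
    }
    operons = transcriptome.call_operons(genes, junctions, config.operon_min_spanning)
    op_df = pd.DataFrame(
        {
            "genes": [",".join(o.genes) for o in operons],
            "strand": [o.strand for o in operons],
            "junctions": [",".join(map(str, o.junction_counts)) for o in operons],
        }
    )
    write_table(op_df, out / "operons.tsv")
    manifest.record("operons", out / "operons.tsv", len(op_df))
    return expr


def _promoter_stage(config: RunConfig, seeds, out: Path, manifest: RunManifest, expr) -> None:
    gconf = dataclasses.replace(config.genome, seed=seeds["genome"])
    genome, genes, motif_truth = synth.gen_genome_with_motifs(gconf)
    (out / "genome.fasta").write_text(
        "".join(f">{c}\n{s}\n" for c, s in genome.items())
    )
    manifest.record("genome", out / "genome.fasta")
    write_table(motif_truth, out / "motif_truth.tsv")
    manifest.record("motif_truth", out / "motif_truth.tsv", len(motif_truth))

    # map simulated genes onto expression records (first n_genes of the matrix)
    expr_named = expr.copy()
    name_map = dict(zip(expr_named.index[: len(genes)], [g.gene_id for g in genes]))
    expr_named = expr_named.rename(index=name_map)
    hits, skipped = promoters.scan_induced_genes(
        expr_named,
        genes,
        genome,
        induction_m_min=config.induction_m_min,
        alpha=config.alpha,
    )
    if skipped:
        manifest.warnings.append(f"{len(skipped)} genes skipped in promoter scan")
    write_table(hits, out / "promoter_hits.tsv")
    manifest.record("promoter_hits", out / "promoter_hits.tsv", len(hits))
    bed = promoters.hits_to_bed(hits, {g.gene_id: g for g in genes})
    write_table(bed, out / "promoter_hits.bed")
    manifest.record("promoter_hits_bed", out / "promoter_hits.bed", len(bed))
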