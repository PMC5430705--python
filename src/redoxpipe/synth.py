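"""Synthetic inputs with recorded ground truth for every pipeline stage.

Generators emulate the structure of the study's real inputs: light/heavy
ICAT feature pairs offset by ~9 Da per cysteine with multiplicative
lognormal intensity noise around a true per-site oxidation fraction;
Cys-peptide mass increments for S-thiolation calling; a GC-rich genome
with SigH/SigE elements embedded upstream of chosen genes;
negative-binomial count matrices with known log2 fold changes; and
junction spanning-read tables defining operons.  Every generator routes
all randomness through one seeded ``numpy`` generator and returns the
truth needed to score downstream recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from redoxpipe.oxicat import IcatFeature, LabelMassRegistry
from redoxpipe.promoters import GeneModel, SIGE, SIGH, _rel_to_genomic, reverse_complement
from redoxpipe.sthiolation import PeptideMatch, ThiolModRegistry

_COMP = str.maketrans("ACGT", "TGCA")


def _validate_finite(**params: float) -> None:
    for name, val in params.items():
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val}")


# ---------------------------------------------------------------------------
# OxICAT feature simulation


@dataclass
class RedoxSimConfig:
    """Design of a simulated OxICAT experiment.

    Defaults mirror the study design: two conditions (untreated control
    and hypochlorite stress), three biological replicates, ~1000
    quantifiable Cys sites, and a mostly-reduced control state in which
    roughly a third of sites gain >10 percentage points of oxidation
    under stress.
    """

    n_sites: int = 1000
    conditions: tuple[str, str] = ("control", "stress")
    n_replicates: int = 3
    true_ox: pd.DataFrame | None = None  # columns: site index x condition
    intensity_mu: float = 10.0  # lognormal log-mean of the total intensity
    intensity_sigma: float = 1.0
    noise_cv: float = 0.2  # multiplicative channel noise CV
    p_two_cys: float = 0.2
    dropout_prob: float = 0.0
    frac_sensitive: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        _validate_finite(
            intensity_mu=self.intensity_mu,
            intensity_sigma=self.intensity_sigma,
            noise_cv=self.noise_cv,
            dropout_prob=self.dropout_prob,
            frac_sensitive=self.frac_sensitive,
        )
        if self.n_sites < 1 or self.n_replicates < 1:
            raise ValueError("n_sites and n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for p in (self.p_two_cys, self.dropout_prob, self.frac_sensitive):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.true_ox is not None:
            arr = self.true_ox.to_numpy(dtype=float)
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("true oxidation fractions must lie in [0,1]")


def _channel_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _draw_true_ox(config: RedoxSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ctrl = np.clip(rng.beta(1.5, 8.0, size=config.n_sites), 0.0, 1.0)
    sensitive = rng.random(config.n_sites) < config.frac_sensitive
    bump = np.where(
        sensitive,
        rng.uniform(0.12, 0.5, size=config.n_sites),
        rng.normal(0.0, 0.02, size=config.n_sites),
    )
    stress = np.clip(ctrl + bump, 0.0, 1.0)
    return pd.DataFrame({config.conditions[0]: ctrl, config.conditions[1]: stress})


def gen_redox_features(
    config: RedoxSimConfig, registry: LabelMassRegistry | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate light/heavy ICAT feature tables around true oxidation fractions.

    For each site, replicate and condition, a total intensity T is drawn
    lognormally; the light channel reads ~T*(1-p) and the heavy channel
    ~T*p, each perturbed by independent mean-1 lognormal noise of the
    configured CV.  Channel masses are the unlabeled peptide mass plus
    the tag mass times the Cys count, so the heavy-light difference is
    the per-Cys tag delta times n_cys.  Dropout replaces an intensity
    with missing (not zero).  The returned truth records the per-site
    true oxidation fraction per condition.
    """
    config.validate()
    reg = registry or LabelMassRegistry()
    rng = np.random.default_rng(config.seed)

    n = config.n_sites
    site_ids = [f"prot{i:04d}:C{30 + (i % 5)}" for i in range(n)]
    n_cys = np.where(rng.random(n) < config.p_two_cys, 2, 1)
    base_mass = rng.uniform(800.0, 3000.0, size=n)
    true_ox = (
        config.true_ox.copy()
        if config.true_ox is not None
        else _draw_true_ox(config, rng)
    )

    rows = []
    for cond in config.conditions:
        p = true_ox[cond].to_numpy(dtype=float)
        for rep in range(1, config.n_replicates + 1):
            total = rng.lognormal(config.intensity_mu, config.intensity_sigma, size=n)
            eps_l = _channel_noise(rng, config.noise_cv, n)
            eps_h = _channel_noise(rng, config.noise_cv, n)
            drop_l = rng.random(n) < config.dropout_prob
            drop_h = rng.random(n) < config.dropout_prob
            light_int = total * (1.0 - p) * eps_l
            heavy_int = total * p * eps_h
            for i in range(n):
                common = dict(
                    site_id=site_ids[i],
                    n_cys=int(n_cys[i]),
                    replicate_id=f"rep{rep}",
                    condition=cond,
                )
                rows.append(
                    dict(
                        neutral_mass=base_mass[i] + reg.light_tag_da * n_cys[i],
                        intensity=np.nan if drop_l[i] else light_int[i],
                        **common,
                    )
                )
                rows.append(
                    dict(
                        neutral_mass=base_mass[i] + reg.heavy_tag_da * n_cys[i],
                        intensity=np.nan if drop_h[i] else heavy_int[i],
                        **common,
                    )
                )
    features = pd.DataFrame(rows)[
        ["site_id", "neutral_mass", "intensity", "n_cys", "replicate_id", "condition"]
    ]
    truth_df = true_ox.copy()
    truth_df.insert(0, "site_id", site_ids)
    truth = {
        "true_ox": truth_df,
        "n_cys": pd.Series(n_cys, index=site_ids, name="n_cys"),
        "seed": config.seed,
    }
    return features, truth


def features_to_objects(features: pd.DataFrame) -> list[IcatFeature]:
    """Convert a feature table to :class:`IcatFeature` records (NaN -> missing)."""
    return [
        IcatFeature(
            site_id=r.site_id,
            neutral_mass=float(r.neutral_mass),
            intensity=None if pd.isna(r.intensity) else float(r.intensity),
            n_cys=int(r.n_cys),
            replicate_id=r.replicate_id,
            condition=r.condition,
        )
        for r in features.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# S-thiolation delta simulation


def gen_mod_deltas(
    n_sites: int,
    mod_probs: Mapping[str, float] | None = None,
    noise_da: float = 0.01,
    registry: ThiolModRegistry | None = None,
    seed: int = 0,
) -> tuple[list[PeptideMatch], pd.DataFrame]:
    """Simulate observed Cys mass increments with known adduct truth.

    Each site draws an adduct ("none" or a registry name) and an observed
    delta equal to the adduct's monoisotopic mass plus Gaussian noise.
    """
    reg = registry or ThiolModRegistry.default()
    probs = dict(mod_probs or {"none": 0.6, "MSH": 0.3, "Cys": 0.1})
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("modification probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    names = list(probs)
    choice = rng.choice(len(names), size=n_sites, p=[probs[k] for k in names])
    matches, truth_rows = [], []
    for i in range(n_sites):
        mod = names[choice[i]]
        true_delta = 0.0 if mod == "none" else reg.lookup(mod).monoisotopic_da
        obs = true_delta + rng.normal(0.0, noise_da)
        m = PeptideMatch(
            protein_id=f"prot{i:04d}",
            peptide="AVLCDK",
            cys_position=30 + (i % 5),
            observed_delta=float(obs),
            condition="stress",
        )
        matches.append(m)
        truth_rows.append({"site_id": m.site_id, "modification": mod, "true_delta": true_delta})
    return matches, pd.DataFrame(truth_rows)


def gen_rsa(site_ids: Sequence[str], exposed_frac: float = 0.135, seed: int = 0) -> pd.DataFrame:
    """Per-site relative surface accessibility with a set exposed fraction."""
    rng = np.random.default_rng(seed)
    exposed = rng.random(len(site_ids)) < exposed_frac
    rsa = np.where(
        exposed, rng.uniform(20.5, 75.0, len(site_ids)), rng.uniform(0.0, 19.9, len(site_ids))
    )
    return pd.DataFrame({"site_id": list(site_ids), "rsa": rsa, "true_exposed": exposed})


# ---------------------------------------------------------------------------
# Genome + embedded promoter motifs


@dataclass
class GenomeSimConfig:
    """A random GC-rich genome with sigma-factor elements planted upstream
    of selected genes."""

    n_genes: int = 60
    genome_length: int = 120_000
    n_motif_genes: int = 20
    sige_fraction: float = 0.3  # fraction of planted elements that are SigE-type
    embed_window: tuple[int, int] = (-250, -30)  # allowed -35 start offsets
    gc_content: float = 0.65
    gene_length: int = 600
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must lie in [0,1]")
        if self.n_motif_genes > self.n_genes:
            raise ValueError("motif genes must be a subset of genes")
        lo, hi = self.embed_window
        if not (lo < hi < 0):
            raise ValueError("embed window must be strictly upstream (negative offsets)")
        spacing = self.genome_length // (self.n_genes + 1)
        if spacing < self.gene_length - lo + 150:
            raise ValueError("genome too short for the requested gene layout")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=probs))


def _element_string(rng: np.random.Generator, sigma: str, gc: float) -> tuple[str, int]:
    """An exact consensus instance: (-35 + spacer + -10, spacer length)."""
    if sigma == "SigH":
        m35 = "GGAA" + ("C" if rng.random() < 0.5 else "T")
        spacer = int(rng.choice([18, 19]))
        m10 = "GTT"
    elif sigma == "SigE":
        m35 = "GGAAC" + ("C" if rng.random() < 0.5 else "T")
        spacer = int(rng.choice([16, 17]))
        m10 = "CGTT"
    else:
        raise ValueError(f"unknown sigma class {sigma!r}")
    filler = "".join(_random_seq(rng, spacer, gc))
    return m35 + filler + m10, spacer


def gen_genome_with_motifs(
    config: GenomeSimConfig,
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Random genome, non-overlapping gene models, and planted elements.

    Genes are laid out on alternating strands with generous intergenic
    space; each motif gene receives one exact SigH or SigE element whose
    -35 element starts at a recorded offset (relative, gene-strand
    coordinates) inside the embedding window.  Returns the genome (one
    contig), the gene models, and a truth table of embedded elements.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, config.genome_length, config.gc_content)
    contig = "chr1"

    spacing = config.genome_length // (config.n_genes + 1)
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        lo = (i + 1) * spacing
        # anchor placed so the full embed window stays inside the gene's slot
        start = lo if strand == "+" else lo + config.gene_length
        genes.append(
            GeneModel(
                gene_id=f"gene{i:03d}",
                contig=contig,
                strand=strand,
                start_codon=start,
                tss=start,
            )
        )

    motif_idx = sorted(rng.choice(config.n_genes, size=config.n_motif_genes, replace=False))
    truth_rows = []
    for gi in motif_idx:
        gene = genes[gi]
        sigma = "SigE" if rng.random() < config.sige_fraction else "SigH"
        element, spacer = _element_string(rng, sigma, config.gc_content)
        lo, hi = config.embed_window
        offset35 = int(rng.integers(lo, hi - len(element)))  # -35 start, rel coordinate
        rels = [r for r in range(offset35, offset35 + len(element))]
        for base, rel in zip(element, rels):
            g = _rel_to_genomic(gene.start_codon, rel, gene.strand)
            seq[g - 1] = base if gene.strand == "+" else base.translate(_COMP)
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "sigma": sigma,
                "offset35": offset35,
                "spacer": spacer,
                "element": element,
                "abs_start35": _rel_to_genomic(gene.start_codon, offset35, gene.strand),
            }
        )
    genome = {contig: "".join(seq)}
    return genome, genes, pd.DataFrame(
        truth_rows, columns=["gene_id", "sigma", "offset35", "spacer", "element", "abs_start35"]
    )


# ---------------------------------------------------------------------------
# RNA-seq count matrices and operon junctions


@dataclass
class CountSimConfig:
    """Negative-binomial count matrices with planted fold changes and operons.

    Defaults follow the study design of three biological replicates per
    condition; 20 genes carry strong (|log2FC| = 5) effects against a
    baseline mean of 200.
    """

    n_genes: int = 500
    n_replicates: int = 3
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    n_de: int = 20
    effect_log2fc: float = 5.0
    true_log2fc: np.ndarray | None = None
    size_factors: np.ndarray | None = None  # one per sample, control then stress
    operon_prob: float = 0.25
    junction_min: int = 20
    seed: int = 0

    def validate(self) -> None:
        _validate_finite(
            baseline_mean=self.baseline_mean,
            dispersion=self.dispersion,
            effect_log2fc=self.effect_log2fc,
        )
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson sampling: Var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def gen_counts(
    config: CountSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate counts, a gene layout, junction spanning reads and truth.

    Returns (counts, genes, spanning, truth): counts is genes x samples
    with control/stress replicate columns; genes carries gene_id, strand
    and genomic start; spanning lists adjacent-gene junctions with their
    spanning-read counts (internal operon junctions >= ``junction_min``,
    others below it); truth holds per-gene log2 fold changes and the
    operon membership chains.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]

    if config.true_log2fc is not None:
        lfc = np.asarray(config.true_log2fc, dtype=float)
        if lfc.shape != (n,):
            raise ValueError("true_log2fc must have one entry per gene")
    else:
        lfc = np.zeros(n)
        de_idx = rng.choice(n, size=config.n_de, replace=False)
        lfc[de_idx] = config.effect_log2fc * rng.choice([-1.0, 1.0], size=config.n_de)

    n_samples = 2 * config.n_replicates
    sf = (
        np.ones(n_samples)
        if config.size_factors is None
        else np.asarray(config.size_factors, dtype=float)
    )
    if sf.shape != (n_samples,) or (sf <= 0).any():
        raise ValueError("size_factors must be positive, one per sample")

    samples = [f"control_{r+1}" for r in range(config.n_replicates)] + [
        f"stress_{r+1}" for r in range(config.n_replicates)
    ]
    base = config.baseline_mean * rng.lognormal(0.0, 0.5, size=n)
    counts = np.empty((n, n_samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = base * sf[j]
        if sample.startswith("stress"):
            mu = mu * np.power(2.0, lfc)
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)

    # operon layout: chains of adjacent same-strand genes
    operons: list[tuple[str, ...]] = []
    strands = np.empty(n, dtype=object)
    i = 0
    while i < n:
        if rng.random() < config.operon_prob and i + 1 < n:
            size = int(min(rng.integers(2, 5), n - i))
        else:
            size = 1
        strand = "+" if rng.random() < 0.5 else "-"
        strands[i : i + size] = strand
        operons.append(tuple(gene_ids[i : i + size]))
        i += size
    genes_df = pd.DataFrame(
        {"gene_id": gene_ids, "strand": strands, "start": np.arange(n) * 1000 + 1}
    )

    in_operon: dict[tuple[str, str], bool] = {}
    for chain in operons:
        for a, b in zip(chain, chain[1:]):
            in_operon[(a, b)] = True
    span_rows = []
    for a, b in zip(gene_ids, gene_ids[1:]):
        if in_operon.get((a, b), False):
            c = int(rng.integers(config.junction_min, 6 * config.junction_min))
        else:
            c = int(rng.integers(0, config.junction_min))
        span_rows.append({"gene_a": a, "gene_b": b, "n_spanning": c})
    spanning_df = pd.DataFrame(span_rows)

    truth = {
        "log2fc": pd.Series(lfc, index=gene_ids, name="true_log2fc"),
        "operons": operons,
        "seed": config.seed,
    }
    return counts_df, genes_df, spanning_df, truth


# ---------------------------------------------------------------------------
# Truth serialization


def save_truth(truth: Mapping, path) -> None:
    """Serialize a truth mapping (DataFrames, Series, arrays) to JSON."""

    def convert(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="list")
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [convert(v) for v in obj]
        return obj

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(convert(dict(truth)), fh, indent=1)
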