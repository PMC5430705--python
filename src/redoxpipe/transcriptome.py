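"""m/a-value expression analysis, empirical cutoff, DE flags and operons.

For each gene the m-value is the log2 fold change of normalized read
counts (stress vs control) and the a-value the log2 mean normalized
count.  Significance uses an empirical cutoff of 2.58 standard
deviations of all m-values — under a mostly-null normal assumption 99%
of genes fall inside +-cutoff — combined with an adjusted p-value
threshold.  Same-strand neighbouring genes connected by at least 20
junction-spanning reads are joined into operons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

DEFAULT_CUTOFF_MULTIPLIER = 2.58
DEFAULT_ALPHA = 0.01
DEFAULT_OPERON_MIN_SPANNING = 20


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Only genes with strictly positive counts in every sample enter the
    median; this is the standard count-normalization estimator for
    sequencing depth.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in all samples; cannot form the "
            "geometric-mean reference (consider a pseudo-reference)"
        )
    kept = arr[allpos]
    ref = np.exp(np.log(kept).mean(axis=1))  # geometric mean per gene
    factors = np.median(kept / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors


def ma_values(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: Mapping[str, str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene m (log2 FC stress/control) and a (log2 mean normalized count).

    ``groups`` maps sample id -> "control" | "stress".  All-zero genes get
    m = 0 by construction and are flagged ``low_signal``.
    """
    norm = normalize(counts, factors)
    ctrl = [s for s in counts.columns if groups[s] == "control"]
    strs = [s for s in counts.columns if groups[s] == "stress"]
    if not ctrl or not strs:
        raise ValueError("both a control and a stress group are required")
    mean_c = norm[ctrl].mean(axis=1)
    mean_s = norm[strs].mean(axis=1)
    m = np.log2(mean_s + pseudocount) - np.log2(mean_c + pseudocount)
    a = np.log2(norm.mean(axis=1) + pseudocount)
    return pd.DataFrame(
        {
            "m_value": m,
            "a_value": a,
            "low_signal": (counts.sum(axis=1) == 0),
        },
        index=counts.index,
    )


def empirical_cutoff(
    m_values: Iterable[float], multiplier: float = DEFAULT_CUTOFF_MULTIPLIER
) -> float:
    """multiplier x sample SD of all finite m-values (2.58 ~ central 99%)."""
    arr = np.asarray([m for m in m_values if np.isfinite(m)], dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 finite m-values for an empirical cutoff")
    return float(multiplier * arr.std(ddof=1))


def welch_log_test(x: np.ndarray, y: np.ndarray) -> float:
    """Welch two-sample t-test on log2(normalized count + 1)."""
    if np.allclose(x, x[0]) and np.allclose(y, y[0]) and np.isclose(x[0], y[0]):
        return 1.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to per-gene variances.

    Returns (prior df d0, prior variance s0^2); d0 = inf means all
    genes share one variance.  Matching is on log s^2, whose mean and
    variance under the model involve digamma/trigamma terms.
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * optimize.brentq(
        lambda x: special.polygamma(1, x) - excess, 1e-6, 1e7
    )
    s02 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def moderated_t_test(lc: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Empirical-Bayes moderated t-test on log-scale replicate matrices.

    Per-gene pooled variances are shrunk toward a prior fitted across
    genes, raising the residual degrees of freedom — the standard remedy
    for testing with very few replicates.
    """
    n1, n2 = lc.shape[1], ls.shape[1]
    df = n1 + n2 - 2
    v1 = lc.var(axis=1, ddof=1)
    v2 = ls.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    d0, s02 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_mod = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ls.mean(axis=1) - lc.mean(axis=1)) / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return np.where(np.isfinite(t), p, 1.0)


def diff_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: Mapping[str, str],
    test: str | Callable[[np.ndarray, np.ndarray], float] = "moderated",
) -> pd.Series:
    """Per-gene BH-adjusted p-values from a pluggable two-group test.

    The default compares log2(normalized + 1) between groups with a
    moderated t-test (variance shrinkage across genes); ``test="welch"``
    uses an unmoderated Welch t, and any callable mapping two replicate
    vectors to a p-value can be substituted (e.g. an exact
    negative-binomial test).
    """
    ctrl = [s for s in counts.columns if groups[s] == "control"]
    strs = [s for s in counts.columns if groups[s] == "stress"]
    if len(ctrl) < 2 or len(strs) < 2:
        raise ValueError("at least 2 replicates per group are required for testing")
    norm = normalize(counts, factors)
    lc = np.log2(norm[ctrl].to_numpy(dtype=float) + 1.0)
    ls = np.log2(norm[strs].to_numpy(dtype=float) + 1.0)
    if test == "moderated":
        pvals = moderated_t_test(lc, ls)
    else:
        fn = welch_log_test if test == "welch" else test
        pvals = np.array([fn(lc[i], ls[i]) for i in range(len(counts))])
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.Series(padj, index=counts.index, name="p_adj")


def call_de(
    records: pd.DataFrame, cutoff: float, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Flag genes with |m| >= cutoff and p_adj <= alpha (both boundaries inclusive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    out = records.copy()
    out["de_flag"] = (out["m_value"].abs() >= cutoff) & (out["p_adj"] <= alpha)
    return out


@dataclass(frozen=True)
class OperonCall:
    genes: tuple[str, ...]
    strand: str
    junction_counts: tuple[int, ...]  # spanning reads per internal junction


def call_operons(
    genes: pd.DataFrame,
    junctions: Mapping[tuple[str, str], int],
    threshold: int = DEFAULT_OPERON_MIN_SPANNING,
) -> list[OperonCall]:
    """Join same-strand neighbouring genes with >= threshold spanning reads.

    ``genes`` needs columns gene_id, strand and start (genomic
    coordinate; rows may arrive in any order).  Joining is transitive
    over adjacent genes; a missing junction counts as 0.  Unjoined genes
    become singleton operons.
    """
    ordered = genes.sort_values("start").reset_index(drop=True)
    calls: list[OperonCall] = []
    chain = [ordered.loc[0, "gene_id"]]
    counts: list[int] = []
    strand = ordered.loc[0, "strand"]
    for i in range(1, len(ordered)):
        gid, st = ordered.loc[i, "gene_id"], ordered.loc[i, "strand"]
        span = junctions.get((chain[-1], gid), junctions.get((gid, chain[-1]), 0))
        if st == strand and span >= threshold:
            chain.append(gid)
            counts.append(int(span))
        else:
            calls.append(OperonCall(tuple(chain), strand, tuple(counts)))
            chain, counts, strand = [gid], [], st
    calls.append(OperonCall(tuple(chain), strand, tuple(counts)))
    return calls


def operon_partition(calls: Iterable[OperonCall]) -> list[tuple[str, ...]]:
    """The operon membership partition, order-normalized for comparison."""
    return sorted(tuple(sorted(c.genes)) for c in calls)


def regulon_aggregate(
    records: pd.DataFrame, regulon_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-regulon median m-value and DE fraction.

    Genes absent from every regulon are summarized under "unassigned";
    genes may belong to several regulons.
    """
    mapped: set[str] = set()
    rows = []
    for name, gene_ids in sorted(regulon_map.items()):
        sub = records.loc[records.index.intersection(list(gene_ids))]
        mapped.update(sub.index)
        rows.append(_regulon_row(name, sub))
    unassigned = records.loc[~records.index.isin(mapped)]
    if len(unassigned):
        rows.append(_regulon_row("unassigned", unassigned))
    return pd.DataFrame(rows).set_index("regulon")


def _regulon_row(name: str, sub: pd.DataFrame) -> dict:
    return {
        "regulon": name,
        "n_genes": len(sub),
        "median_m": float(sub["m_value"].median()) if len(sub) else np.nan,
        "de_fraction": float(sub["de_flag"].mean()) if len(sub) else np.nan,
        "genes": ",".join(sub.index),
    }
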