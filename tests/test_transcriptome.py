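"""Normalization, m/a values, empirical cutoff, DE flags and operon joining."""

import numpy as np
import pandas as pd
import pytest

from redoxpipe import synth, transcriptome as tx


def toy_counts():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(50, 6)),
        index=[f"g{i}" for i in range(50)],
        columns=["control_1", "control_2", "control_3", "stress_1", "stress_2", "stress_3"],
    )
    groups = {c: ("stress" if c.startswith("stress") else "control") for c in counts.columns}
    return counts, groups


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts, _ = toy_counts()
        same = pd.concat([counts["control_1"]] * 4, axis=1)
        same.columns = list("abcd")
        assert np.allclose(tx.size_factors(same), 1.0)

    def test_doubled_column_has_double_factor(self):
        counts, _ = toy_counts()
        dbl = counts.copy()
        dbl["stress_3"] = dbl["control_1"] * 2
        f = tx.size_factors(dbl)
        assert f["stress_3"] / f["control_1"] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        counts, _ = toy_counts()
        f = tx.size_factors(counts)
        arr = counts.to_numpy(dtype=float)
        keep = (arr > 0).all(axis=1)
        gm = np.exp(np.mean(np.log(arr[keep]), axis=1))
        for j, col in enumerate(counts.columns):
            assert f[col] == pytest.approx(np.median(arr[keep, j] / gm))

    def test_no_all_positive_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            tx.size_factors(counts)


class TestMaValues:
    def test_equal_group_means_give_zero_m(self):
        counts = pd.DataFrame(
            {"control_1": [8, 100], "control_2": [8, 100], "stress_1": [8, 100], "stress_2": [8, 100]},
            index=["g1", "g2"],
        )
        groups = {c: ("stress" if "stress" in c else "control") for c in counts.columns}
        ma = tx.ma_values(counts, pd.Series(1.0, index=counts.columns), groups)
        assert np.allclose(ma["m_value"], 0.0)

    def test_fourfold_mean_gives_m_two_and_a_from_overall_mean(self):
        counts = pd.DataFrame(
            {"control_1": [1000], "control_2": [1000], "stress_1": [4000], "stress_2": [4000]},
            index=["g1"],
        )
        groups = {c: ("stress" if "stress" in c else "control") for c in counts.columns}
        ma = tx.ma_values(counts, pd.Series(1.0, index=counts.columns), groups, pseudocount=0.0)
        assert ma.loc["g1", "m_value"] == pytest.approx(2.0)
        # overall normalized mean 2500 -> a = log2(2500)
        assert ma.loc["g1", "a_value"] == pytest.approx(np.log2(2500))

    def test_all_zero_gene_flagged_low_signal_with_zero_m(self):
        counts = pd.DataFrame(
            {"control_1": [0, 5], "control_2": [0, 5], "stress_1": [0, 5], "stress_2": [0, 5]},
            index=["dead", "ok"],
        )
        groups = {c: ("stress" if "stress" in c else "control") for c in counts.columns}
        ma = tx.ma_values(counts, pd.Series(1.0, index=counts.columns), groups)
        assert ma.loc["dead", "m_value"] == 0.0
        assert bool(ma.loc["dead", "low_signal"]) is True

    def test_scale_invariance_of_m_values(self):
        counts, groups = toy_counts()
        f1 = tx.size_factors(counts)
        scaled = counts.copy()
        scaled["stress_1"] = scaled["stress_1"] * 3
        f2 = tx.size_factors(scaled)
        # size factors are defined up to overall scaling: compare ratios
        assert (f2["stress_1"] / f2["control_1"]) / (
            f1["stress_1"] / f1["control_1"]
        ) == pytest.approx(3.0)
        # exact at pseudocount 0 (all normalized values rescale uniformly)
        m1 = tx.ma_values(counts, f1, groups, pseudocount=0.0)["m_value"]
        m2 = tx.ma_values(scaled, f2, groups, pseudocount=0.0)["m_value"]
        assert np.allclose(m1, m2, atol=1e-10)


class TestCutoff:
    def test_sd_one_gives_258(self):
        rng = np.random.default_rng(1)
        m = rng.normal(0, 1, 5000)
        m = (m - m.mean()) / m.std(ddof=1)  # exact unit sample SD
        assert tx.empirical_cutoff(m) == pytest.approx(2.58)

    def test_constant_values_give_zero(self):
        assert tx.empirical_cutoff([1.5, 1.5, 1.5]) == 0.0

    def test_linear_in_scale(self, rng):
        m = rng.normal(0, 2, 1000)
        assert tx.empirical_cutoff(2 * m) == pytest.approx(2 * tx.empirical_cutoff(m))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tx.empirical_cutoff([1.0])

    def test_monte_carlo_matches_reported_cutoff_scale(self):
        # sigma chosen so 2.58*sigma = 4.47, the study-scale cutoff
        rng = np.random.default_rng(123)
        m = rng.normal(0, 4.47 / 2.58, size=10_000)
        assert tx.empirical_cutoff(m) == pytest.approx(4.47, rel=0.02)


class TestDiffTest:
    def test_null_data_rarely_significant(self):
        cfg = synth.CountSimConfig(n_genes=300, n_de=0, seed=4)
        counts, _, _, _ = synth.gen_counts(cfg)
        groups = {c: ("stress" if "stress" in c else "control") for c in counts.columns}
        padj = tx.diff_test(counts, tx.size_factors(counts), groups)
        assert (padj <= 0.01).mean() <= 0.02

    def test_planted_strong_effects_recovered(self):
        cfg = synth.CountSimConfig(n_genes=500, n_de=20, effect_log2fc=5.0, seed=7)
        counts, _, _, truth = synth.gen_counts(cfg)
        groups = {c: ("stress" if "stress" in c else "control") for c in counts.columns}
        factors = tx.size_factors(counts)
        ma = tx.ma_values(counts, factors, groups)
        ma["p_adj"] = tx.diff_test(counts, factors, groups)
        cutoff = tx.empirical_cutoff(ma["m_value"])
        flagged = tx.call_de(ma, cutoff)
        de_true = truth["log2fc"][truth["log2fc"] != 0].index
        recovered = flagged.loc[de_true, "de_flag"].mean()
        assert recovered >= 0.9

    def test_bh_matches_independent_step_up_oracle(self, rng):
        pvals = rng.uniform(0, 1, 200) ** 2
        from statsmodels.stats.multitest import multipletests

        got = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(got, _bh_oracle(pvals))

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"control_1": [5], "stress_1": [9]})
        with pytest.raises(ValueError):
            tx.diff_test(counts, pd.Series(1.0, index=counts.columns),
                         {"control_1": "control", "stress_1": "stress"})


def _bh_oracle(pvals):
    """Step-up BH written independently: p_(i) * n / i with reverse cummin."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adj[i] = running
    return np.array(adj)


class TestCallDe:
    def test_boundaries_inclusive(self):
        df = pd.DataFrame(
            {"m_value": [4.47, 4.5, -5.0], "p_adj": [0.01, 0.02, 0.001]},
            index=["a", "b", "c"],
        )
        out = tx.call_de(df, cutoff=4.47, alpha=0.01)
        assert out["de_flag"].tolist() == [True, False, True]


class TestOperons:
    def genes(self, strands, order=None):
        ids = [f"g{i}" for i in range(len(strands))]
        df = pd.DataFrame(
            {"gene_id": ids, "strand": list(strands), "start": np.arange(len(ids)) * 100}
        )
        return df if order is None else df.iloc[order].reset_index(drop=True)

    def test_threshold_is_at_least_20(self):
        g = self.genes("++")
        assert len(tx.call_operons(g, {("g0", "g1"): 20})) == 1
        assert len(tx.call_operons(g, {("g0", "g1"): 19})) == 2

    def test_transitive_chain_with_break(self):
        g = self.genes("++++")
        calls = tx.call_operons(g, {("g0", "g1"): 25, ("g1", "g2"): 30, ("g2", "g3"): 5})
        assert tx.operon_partition(calls) == [("g0", "g1", "g2"), ("g3",)]

    def test_strand_switch_breaks_operon(self):
        g = self.genes("++-")
        calls = tx.call_operons(g, {("g0", "g1"): 50, ("g1", "g2"): 50})
        assert tx.operon_partition(calls) == [("g0", "g1"), ("g2",)]

    def test_missing_junction_treated_as_zero(self):
        calls = tx.call_operons(self.genes("++"), {})
        assert len(calls) == 2

    def test_partition_independent_of_input_order(self, rng):
        strands = "".join(rng.choice(["+", "-"], size=12))
        junctions = {
            (f"g{i}", f"g{i+1}"): int(rng.integers(0, 40)) for i in range(11)
        }
        ref = tx.operon_partition(tx.call_operons(self.genes(strands), junctions))
        shuffled = self.genes(strands, order=rng.permutation(12))
        assert tx.operon_partition(tx.call_operons(shuffled, junctions)) == ref

    def test_matches_union_find_oracle(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 30
            strands = "".join(r.choice(["+", "-"], size=n))
            junctions = {
                (f"g{i}", f"g{i+1}"): int(r.integers(0, 40)) for i in range(n - 1)
            }
            calls = tx.call_operons(self.genes(strands), junctions)
            assert tx.operon_partition(calls) == _union_find_oracle(strands, junctions)


def _union_find_oracle(strands, junctions):
    n = len(strands)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - 1):
        if strands[i] == strands[i + 1] and junctions.get((f"g{i}", f"g{i+1}"), 0) >= 20:
            parent[find(i)] = find(i + 1)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(f"g{i}")
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestRegulons:
    def records(self):
        return pd.DataFrame(
            {"m_value": [5.0, 0.5, -4.8, 0.0], "de_flag": [True, False, True, False]},
            index=["a", "b", "c", "d"],
        )

    def test_single_gene_regulon_equals_record(self):
        out = tx.regulon_aggregate(self.records(), {"SigH": ["a"]})
        assert out.loc["SigH", "median_m"] == 5.0
        assert out.loc["SigH", "de_fraction"] == 1.0

    def test_unmapped_genes_grouped_unassigned(self):
        out = tx.regulon_aggregate(self.records(), {"SigH": ["a"], "Zur": ["c"]})
        assert set(out.loc["unassigned", "genes"].split(",")) == {"b", "d"}

    def test_matches_flat_recomputation(self, rng):
        rec = pd.DataFrame(
            {
                "m_value": rng.normal(0, 2, 40),
                "de_flag": rng.random(40) < 0.3,
            },
            index=[f"g{i}" for i in range(40)],
        )
        regmap = {f"R{k}": [f"g{i}" for i in range(40) if rng.random() < 0.2] for k in range(4)}
        out = tx.regulon_aggregate(rec, regmap)
        for name, genes in regmap.items():
            if genes:
                sub = rec.loc[genes]
                assert out.loc[name, "median_m"] == pytest.approx(sub["m_value"].median())
                assert out.loc[name, "de_fraction"] == pytest.approx(sub["de_flag"].mean())
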