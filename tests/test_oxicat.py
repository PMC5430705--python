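"""ICAT pair matching and percent thiol-oxidation quantification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxpipe import oxicat, synth
from redoxpipe.oxicat import (
    IcatFeature,
    LabelMassRegistry,
    PER_CYS_DELTA_DA,
    RedoxMeasurement,
    SiteRedoxState,
    aggregate_replicates,
    delta_oxidation,
    delta_paired,
    delta_table,
    pair_icat_features,
    percent_oxidation,
    quantify_pairs,
)


def feat(mass, intensity=100.0, site="p1:C10", n_cys=1, rep="rep1", cond="control"):
    return IcatFeature(site, mass, intensity, n_cys, rep, cond)


class TestPairing:
    def test_nine_dalton_pair_within_tolerance(self):
        pairs, unpaired = pair_icat_features([feat(1500.0), feat(1509.0302)], tol_ppm=10)
        assert len(pairs) == 1 and not unpaired
        assert pairs[0].light.neutral_mass == 1500.0
        assert abs(pairs[0].mass_error_ppm) < 1e-9

    def test_registry_nominal_delta_displays_as_9(self):
        assert LabelMassRegistry().nominal_delta_da == 9
        assert LabelMassRegistry().per_cys_delta_da == pytest.approx(PER_CYS_DELTA_DA)

    def test_two_cys_peptide_needs_double_delta(self):
        two = [feat(1500.0, n_cys=2), feat(1500.0 + 2 * PER_CYS_DELTA_DA, n_cys=2)]
        pairs, _ = pair_icat_features(two)
        assert len(pairs) == 1
        wrong = [feat(1500.0, n_cys=2), feat(1500.0 + PER_CYS_DELTA_DA, n_cys=2)]
        pairs, unpaired = pair_icat_features(wrong)
        assert not pairs and len(unpaired) == 2

    def test_singleton_reported_unpaired(self):
        pairs, unpaired = pair_icat_features([feat(1500.0)])
        assert not pairs and len(unpaired) == 1

    def test_never_pairs_across_replicates_or_conditions(self):
        feats = [
            feat(1500.0, rep="rep1"),
            feat(1509.0302, rep="rep2"),
            feat(2000.0, cond="stress"),
            feat(2009.0302, cond="control"),
        ]
        pairs, unpaired = pair_icat_features(feats)
        assert not pairs and len(unpaired) == 4

    def test_exact_tie_is_ambiguous_and_unquantified(self):
        # two lights equidistant (exactly) from one heavy
        feats = [
            feat(1500.0 - 0.001),
            feat(1500.0 + 0.001),
            feat(1500.0 + PER_CYS_DELTA_DA),
        ]
        pairs, unpaired = pair_icat_features(feats, tol_ppm=10)
        assert not pairs and len(unpaired) == 3

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            feats = _random_features(rng, n=20)
            pairs, _ = pair_icat_features(feats, tol_ppm=10)
            got = {(p.light.neutral_mass, p.heavy.neutral_mass) for p in pairs}
            assert got == _oracle_pairs(feats, tol_ppm=10)

    def test_symmetric_under_input_permutation(self):
        rng = np.random.default_rng(3)
        feats = _random_features(rng, n=20)
        ref, _ = pair_icat_features(feats)
        keyset = {(p.light.neutral_mass, p.heavy.neutral_mass) for p in ref}
        for perm_seed in range(5):
            perm = list(feats)
            np.random.default_rng(perm_seed).shuffle(perm)
            pairs, _ = pair_icat_features(perm)
            assert {(p.light.neutral_mass, p.heavy.neutral_mass) for p in pairs} == keyset


def _random_features(rng, n):
    feats = []
    for i in range(n):
        base = rng.uniform(800, 1200)
        feats.append(feat(base, site="p1:C10"))
        if rng.random() < 0.6:
            feats.append(feat(base + PER_CYS_DELTA_DA + rng.normal(0, 2e-3), site="p1:C10"))
    return feats[:n]


def _oracle_pairs(feats, tol_ppm):
    """All-pairs matcher: smallest |ppm| first, exact ties dropped."""
    cands = []
    for a, b in itertools.permutations(range(len(feats)), 2):
        fa, fb = feats[a], feats[b]
        if fb.neutral_mass <= fa.neutral_mass:
            continue
        if (fa.site_id, fa.replicate_id, fa.condition, fa.n_cys) != (
            fb.site_id, fb.replicate_id, fb.condition, fb.n_cys
        ):
            continue
        err = (fb.neutral_mass - fa.neutral_mass - PER_CYS_DELTA_DA * fa.n_cys)
        ppm = err / fb.neutral_mass * 1e6
        if abs(ppm) <= tol_ppm:
            cands.append((abs(ppm), a, b))
    cands.sort()
    used, out = set(), set()
    i = 0
    while i < len(cands):
        j = i
        while j < len(cands) and abs(cands[j][0] - cands[i][0]) <= 1e-9:
            j += 1
        batch = [c for c in cands[i:j] if c[1] not in used and c[2] not in used]
        touched = [x for _, a, b in batch for x in (a, b)]
        amb = {x for x in touched if touched.count(x) > 1}
        for _, a, b in batch:
            if a in amb or b in amb or a in used or b in used:
                used |= {a, b} if (a in amb or b in amb) else set()
                continue
            out.add((feats[a].neutral_mass, feats[b].neutral_mass))
            used |= {a, b}
        used |= amb
        i = j
    return out


class TestPercentOxidation:
    @pytest.mark.parametrize(
        "light, heavy, expected",
        [(100, 100, 50.0), (0, 42, 100.0), (900, 100, 10.0), (None, 42, 100.0), (42, None, 0.0)],
    )
    def test_closed_form(self, light, heavy, expected):
        assert percent_oxidation(light, heavy) == pytest.approx(expected)

    def test_unquantifiable_when_both_channels_absent(self):
        with pytest.raises(ValueError):
            percent_oxidation(0, 0)
        with pytest.raises(ValueError):
            percent_oxidation(None, None)

    @settings(deadline=None, max_examples=200)
    @given(
        a=st.floats(min_value=1e-6, max_value=1e9),
        b=st.floats(min_value=1e-6, max_value=1e9),
    )
    def test_complementarity_and_range(self, a, b):
        p, q = percent_oxidation(a, b), percent_oxidation(b, a)
        assert 0.0 <= p <= 100.0
        assert p + q == pytest.approx(100.0)


class TestAggregation:
    def test_mean_and_n(self):
        ms = [RedoxMeasurement("s", f"rep{i}", "control", v) for i, v in enumerate([10, 12, 14])]
        (state,) = aggregate_replicates(ms)
        assert state.mean_percent_ox == pytest.approx(12.0)
        assert state.n_replicates == 3
        assert state.sd == pytest.approx(2.0)

    def test_single_measurement_has_no_sd(self):
        (state,) = aggregate_replicates([RedoxMeasurement("s", "rep1", "control", 33.3)])
        assert state.mean_percent_ox == pytest.approx(33.3)
        assert state.sd is None and state.n_replicates == 1

    def test_matches_streaming_recomputation(self, rng):
        ms = [
            RedoxMeasurement(f"s{rng.integers(200)}", f"rep{r}", "control", float(v))
            for r, v in enumerate(rng.uniform(0, 100, size=2000))
        ]
        states = aggregate_replicates(ms)
        for s in states:
            vals = [m.percent_ox for m in ms if (m.site_id, m.condition) == (s.site_id, s.condition)]
            mean = sum(vals) / len(vals)
            assert s.mean_percent_ox == pytest.approx(mean)
            if len(vals) >= 2:
                var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
                assert s.sd == pytest.approx(var**0.5)


class TestDelta:
    def test_worked_example_adhe1(self):
        ctrl = SiteRedoxState("MSMEG_0127:C48", "control", 13.5, None, 3)
        strs = SiteRedoxState("MSMEG_0127:C48", "stress", 45.5, None, 3)
        assert delta_oxidation(ctrl, strs).delta == pytest.approx(32.0)

    def test_zero_when_conditions_agree(self):
        s = SiteRedoxState("x", "control", 20.0, None, 3)
        t = SiteRedoxState("x", "stress", 20.0, None, 3)
        assert delta_oxidation(s, t).delta == 0.0

    def test_single_condition_sites_are_excluded_and_reported(self):
        states = [
            SiteRedoxState("a", "control", 10, None, 3),
            SiteRedoxState("a", "stress", 30, None, 3),
            SiteRedoxState("b", "control", 10, None, 3),
        ]
        deltas, skipped = delta_table(states, "control", "stress")
        assert [d.site_id for d in deltas] == ["a"] and skipped == ["b"]

    def test_difference_of_means_matches_recomputation(self, rng):
        states = []
        for i in range(100):
            c, s = rng.uniform(0, 100, 2)
            states += [
                SiteRedoxState(f"s{i}", "control", float(c), None, 3),
                SiteRedoxState(f"s{i}", "stress", float(s), None, 3),
            ]
        deltas, _ = delta_table(states, "control", "stress")
        lut = {(x.site_id, x.condition): x.mean_percent_ox for x in states}
        for d in deltas:
            assert d.delta == pytest.approx(lut[(d.site_id, "stress")] - lut[(d.site_id, "control")])

    def test_paired_policy_agrees_with_means_when_replicates_balanced(self):
        ms = []
        for rep in range(3):
            ms.append(RedoxMeasurement("s", f"rep{rep}", "control", 10.0 + rep))
            ms.append(RedoxMeasurement("s", f"rep{rep}", "stress", 30.0 + 2 * rep))
        (d,) = delta_paired(ms, "control", "stress")
        assert d.delta == pytest.approx((30 + 32 + 34) / 3 - (10 + 11 + 12) / 3)
        assert d.n_paired_replicates == 3


class TestEndToEnd:
    def test_noise_free_recovery_is_exact(self, noisefree_redox):
        cfg, features, truth = noisefree_redox
        pairs, _ = pair_icat_features(synth.features_to_objects(features))
        states = aggregate_replicates(quantify_pairs(pairs))
        lut = truth["true_ox"].set_index("site_id")
        for s in states:
            assert s.mean_percent_ox == pytest.approx(
                100 * lut.loc[s.site_id, s.condition], abs=1e-9
            )

    def test_noisy_recovery_mae_below_3_points(self, noisy_redox):
        cfg, features, truth = noisy_redox
        pairs, _ = pair_icat_features(synth.features_to_objects(features))
        states = aggregate_replicates(quantify_pairs(pairs))
        lut = truth["true_ox"].set_index("site_id")
        errs = [
            abs(s.mean_percent_ox - 100 * lut.loc[s.site_id, s.condition]) for s in states
        ]
        assert len(errs) >= 2000
        assert np.mean(errs) < 3.0

    def test_dropout_yields_missing_partner_measurements(self):
        cfg = synth.RedoxSimConfig(n_sites=50, noise_cv=0.1, dropout_prob=0.3, seed=2)
        features, _ = synth.gen_redox_features(cfg)
        pairs, _ = pair_icat_features(synth.features_to_objects(features))
        ms = quantify_pairs(pairs)
        flags = {m.confidence for m in ms}
        assert "missing-partner" in flags and "normal" in flags
        for m in ms:
            if m.confidence == "missing-partner":
                assert m.percent_ox in (0.0, 100.0)
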