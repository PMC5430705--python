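"""OxICAT quantification: ICAT pair matching and percent thiol-oxidation.

In the OxICAT workflow reduced cysteines carry the light (12C) ICAT tag and
reversibly oxidized cysteines, after reduction, the heavy (13C) tag.  The
two labelled forms of a peptide differ by ~9 Da per cysteine (nine
12C -> 13C substitutions; 9.0302 Da monoisotopic), and the percent
oxidation of a site is the heavy intensity over the summed light + heavy
intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from redoxpipe.tables import round_half_up

#: monoisotopic mass shift of nine 12C -> 13C substitutions, Da per cysteine
PER_CYS_DELTA_DA = 9.0302
#: added mass of the light (12C) ICAT tag, Da per cysteine
LIGHT_TAG_DA = 227.1270

NOMINAL_PAIR_DELTA_DA = 9  # displayed nominal light/heavy difference

#: |ppm| differences below this are treated as an exact tie (ambiguous pairing)
TIE_TOL_PPM = 1e-9


@dataclass(frozen=True)
class LabelMassRegistry:
    """Masses added by the light and heavy ICAT reagents, per cysteine."""

    light_tag_da: float = LIGHT_TAG_DA
    heavy_tag_da: float = LIGHT_TAG_DA + PER_CYS_DELTA_DA

    def __post_init__(self) -> None:
        if not self.per_cys_delta_da > 0:
            raise ValueError("heavy tag must be heavier than light tag")

    @property
    def per_cys_delta_da(self) -> float:
        return self.heavy_tag_da - self.light_tag_da

    @property
    def nominal_delta_da(self) -> int:
        """Nominal (displayed) per-cysteine pair mass difference."""
        return round(self.per_cys_delta_da)


@dataclass(frozen=True)
class IcatFeature:
    """One MS feature: a labelled Cys-peptide observed in one channel."""

    site_id: str
    neutral_mass: float
    intensity: float | None  # arbitrary units, None when unobserved
    n_cys: int
    replicate_id: str
    condition: str

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError(f"neutral_mass must be > 0, got {self.neutral_mass}")
        if self.n_cys < 1:
            raise ValueError(f"n_cys must be >= 1, got {self.n_cys}")


@dataclass(frozen=True)
class LabeledPair:
    light: IcatFeature
    heavy: IcatFeature
    mass_error_ppm: float


@dataclass(frozen=True)
class RedoxMeasurement:
    site_id: str
    replicate_id: str
    condition: str
    percent_ox: float
    confidence: str = "normal"  # "normal" | "missing-partner"


@dataclass(frozen=True)
class SiteRedoxState:
    site_id: str
    condition: str
    mean_percent_ox: float
    sd: float | None
    n_replicates: int


@dataclass(frozen=True)
class DeltaRecord:
    site_id: str
    percent_ox_control: float
    percent_ox_stress: float
    delta: float
    n_paired_replicates: int | None = None


def pair_icat_features(
    features: Sequence[IcatFeature],
    registry: LabelMassRegistry | None = None,
    tol_ppm: float = 10.0,
) -> tuple[list[LabeledPair], list[IcatFeature]]:
    """Match light/heavy features within each (site, replicate, condition, n_cys) group.

    Two features pair iff the heavier minus the lighter mass equals the
    per-Cys tag delta times ``n_cys`` within ``tol_ppm`` (ppm relative to
    the heavier mass).  Competing candidates are resolved by smallest
    absolute ppm error; an exact tie leaves the contested features
    unpaired (ambiguous).  Each feature joins at most one pair.
    """
    if registry is None:
        registry = LabelMassRegistry()
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be > 0")

    pairs: list[LabeledPair] = []
    unpaired: list[IcatFeature] = []
    groups: dict[tuple, list[IcatFeature]] = {}
    for f in features:
        groups.setdefault((f.site_id, f.replicate_id, f.condition, f.n_cys), []).append(f)

    for key, group in sorted(groups.items()):
        expected = registry.per_cys_delta_da * key[3]
        cands: list[tuple[float, int, int]] = []
        for i, a in enumerate(group):
            for j, b in enumerate(group):
                if b.neutral_mass <= a.neutral_mass:
                    continue
                err = (b.neutral_mass - a.neutral_mass - expected) / b.neutral_mass * 1e6
                if abs(err) <= tol_ppm:
                    cands.append((err, i, j))
        cands.sort(key=lambda c: (abs(c[0]), c[1], c[2]))
        used: set[int] = set()
        ambiguous: set[int] = set()
        k = 0
        while k < len(cands):
            # batch of candidates with identical |ppm error|
            m = k
            while m < len(cands) and math.isclose(
                abs(cands[m][0]), abs(cands[k][0]), rel_tol=0, abs_tol=TIE_TOL_PPM
            ):
                m += 1
            batch = [c for c in cands[k:m] if c[1] not in used and c[2] not in used]
            counts: dict[int, int] = {}
            for _, i, j in batch:
                counts[i] = counts.get(i, 0) + 1
                counts[j] = counts.get(j, 0) + 1
            for err, i, j in batch:
                if counts[i] > 1 or counts[j] > 1:  # exact tie over a shared feature
                    ambiguous.update((i, j))
            for err, i, j in batch:
                if i in used or j in used or i in ambiguous or j in ambiguous:
                    continue
                pairs.append(LabeledPair(light=group[i], heavy=group[j], mass_error_ppm=err))
                used.update((i, j))
            used |= ambiguous
            k = m
        unpaired.extend(f for i, f in enumerate(group) if i not in used or i in ambiguous)
    return pairs, unpaired


def percent_oxidation(light_intensity: float | None, heavy_intensity: float | None) -> float:
    """Percent oxidation = 100 * heavy / (light + heavy).

    A missing light channel means no reduced form was observed (100%
    oxidized); a missing heavy channel means fully reduced (0%).  Both
    channels absent or zero is unquantifiable and raises ``ValueError``.
    """
    light = 0.0 if light_intensity is None else float(light_intensity)
    heavy = 0.0 if heavy_intensity is None else float(heavy_intensity)
    if light < 0 or heavy < 0:
        raise ValueError("intensities must be non-negative")
    total = light + heavy
    if total == 0:
        raise ValueError("both channel intensities missing or zero: site unquantifiable")
    return 100.0 * (heavy / total)


def quantify_pairs(pairs: Iterable[LabeledPair]) -> list[RedoxMeasurement]:
    """Turn matched pairs into per-replicate percent-oxidation measurements.

    The missing-partner policy: a pair whose light intensity is absent
    reads 100% oxidized, one whose heavy intensity is absent reads 0%,
    both flagged ``missing-partner`` (downstream delta classification
    excludes them by default).  Pairs with neither channel observed are
    unquantifiable and dropped.  Unpaired singleton features carry no
    channel assignment and are never quantified.
    """
    out: list[RedoxMeasurement] = []
    for p in pairs:
        li, hi = p.light.intensity, p.heavy.intensity
        if (li is None or li == 0) and (hi is None or hi == 0):
            continue
        flag = "normal" if (li is not None and hi is not None) else "missing-partner"
        out.append(
            RedoxMeasurement(
                site_id=p.light.site_id,
                replicate_id=p.light.replicate_id,
                condition=p.light.condition,
                percent_ox=percent_oxidation(li, hi),
                confidence=flag,
            )
        )
    return out


def aggregate_replicates(measurements: Iterable[RedoxMeasurement]) -> list[SiteRedoxState]:
    """Arithmetic mean and sample SD of percent oxidation per (site, condition)."""
    groups: dict[tuple[str, str], list[float]] = {}
    for m in measurements:
        groups.setdefault((m.site_id, m.condition), []).append(m.percent_ox)
    states = []
    for (site, cond), vals in sorted(groups.items()):
        arr = np.asarray(vals, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
        states.append(
            SiteRedoxState(
                site_id=site,
                condition=cond,
                mean_percent_ox=float(arr.mean()),
                sd=sd,
                n_replicates=int(arr.size),
            )
        )
    return states


def delta_oxidation(control: SiteRedoxState, stress: SiteRedoxState) -> DeltaRecord:
    """Stress-minus-control change in mean percent oxidation (difference of means)."""
    if control.site_id != stress.site_id:
        raise ValueError(
            f"site mismatch: {control.site_id!r} vs {stress.site_id!r}"
        )
    return DeltaRecord(
        site_id=control.site_id,
        percent_ox_control=control.mean_percent_ox,
        percent_ox_stress=stress.mean_percent_ox,
        delta=stress.mean_percent_ox - control.mean_percent_ox,
    )


def delta_table(
    states: Iterable[SiteRedoxState], control_label: str, stress_label: str
) -> tuple[list[DeltaRecord], list[str]]:
    """Difference-of-means deltas for every site present in both conditions.

    Returns the delta records and the ids of sites seen in only one
    condition (excluded, reported for logging).
    """
    by_site: dict[str, dict[str, SiteRedoxState]] = {}
    for s in states:
        by_site.setdefault(s.site_id, {})[s.condition] = s
    deltas, skipped = [], []
    for site, conds in sorted(by_site.items()):
        if control_label in conds and stress_label in conds:
            deltas.append(delta_oxidation(conds[control_label], conds[stress_label]))
        else:
            skipped.append(site)
    return deltas, skipped


def delta_paired(
    measurements: Iterable[RedoxMeasurement], control_label: str, stress_label: str
) -> list[DeltaRecord]:
    """Alternative policy: average per-replicate (stress - control) differences.

    Only replicates quantified in both conditions contribute.  Differs
    from the difference-of-means policy when replicate sets are unequal.
    """
    by: dict[tuple[str, str], dict[str, float]] = {}
    for m in measurements:
        by.setdefault((m.site_id, m.replicate_id), {})[m.condition] = m.percent_ox
    per_site: dict[str, list[float]] = {}
    ctrl_means: dict[str, list[float]] = {}
    stress_means: dict[str, list[float]] = {}
    for (site, _rep), conds in by.items():
        if control_label in conds and stress_label in conds:
            per_site.setdefault(site, []).append(conds[stress_label] - conds[control_label])
            ctrl_means.setdefault(site, []).append(conds[control_label])
            stress_means.setdefault(site, []).append(conds[stress_label])
    return [
        DeltaRecord(
            site_id=site,
            percent_ox_control=float(np.mean(ctrl_means[site])),
            percent_ox_stress=float(np.mean(stress_means[site])),
            delta=float(np.mean(diffs)),
            n_paired_replicates=len(diffs),
        )
        for site, diffs in sorted(per_site.items())
    ]


def format_percent(x: float) -> float:
    """One-decimal half-up rounding used for all reported percentages."""
    return round_half_up(x, 1)
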