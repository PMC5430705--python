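"""Redox bins, delta-oxidation classes, surface accessibility and roll-ups.

Sites are binned by mean percent oxidation into reduced (<10%, 10-25%),
oxidized (>=25%) and highly oxidized (>75%) classes; the stress-induced
change classifies sites as oxidation-sensitive (delta > 10 percentage
points) or strongly sensitive (delta > 20).  A relative surface
accessibility (RSA) above 20% marks a residue surface-exposed.  Category
roll-ups aggregate sites over a hierarchical functional annotation
(TIGRfam-style) for treemap export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from redoxpipe.tables import round_half_up

BIN_LABELS = ("reduced-low", "reduced-mid", "oxidized", "highly-oxidized")


@dataclass(frozen=True)
class RedoxBinScheme:
    """Bin edges over [0, 100] percent oxidation and delta-class thresholds.

    Boundary policy mirrors the strict inequalities of the source
    convention: <10 and 10-25 are left-closed/right-open, >75 is strict,
    and the delta thresholds are strict (delta = 10.0 is not sensitive).
    """

    edge_low: float = 10.0
    edge_mid: float = 25.0
    edge_high: float = 75.0
    delta_sensitive: float = 10.0
    delta_strong: float = 20.0


DEFAULT_SCHEME = RedoxBinScheme()


def classify_site(percent_ox: float, scheme: RedoxBinScheme = DEFAULT_SCHEME) -> str:
    if not 0 <= percent_ox <= 100:
        raise ValueError(f"percent oxidation out of range: {percent_ox}")
    if percent_ox < scheme.edge_low:
        return "reduced-low"
    if percent_ox < scheme.edge_mid:
        return "reduced-mid"
    if percent_ox > scheme.edge_high:
        return "highly-oxidized"
    return "oxidized"


def classify_delta(delta: float, scheme: RedoxBinScheme = DEFAULT_SCHEME) -> str:
    """Strictly-greater-than thresholds; strongly-sensitive implies sensitive."""
    if not np.isfinite(delta):
        raise ValueError(f"delta must be finite, got {delta}")
    if delta > scheme.delta_strong:
        return "strongly-sensitive"
    if delta > scheme.delta_sensitive:
        return "sensitive"
    return "not-sensitive"


def percent_of(count: int, total: int) -> float:
    """One-decimal half-up percentage of a count over a total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, 1)


@dataclass(frozen=True)
class BinSummary:
    label: str
    count: int
    percent: float


def summarize_bins(
    percents: Sequence[float], scheme: RedoxBinScheme = DEFAULT_SCHEME
) -> list[BinSummary]:
    """Counts and one-decimal percentages per bin, plus cumulative classes.

    Besides the four partition bins, the cumulative claims used in
    reporting are included: below-25 (= reduced-low + reduced-mid),
    below-10 and above-25.
    """
    if len(percents) == 0:
        return []
    labels = [classify_site(p, scheme) for p in percents]
    total = len(labels)
    out = [
        BinSummary(lab, labels.count(lab), percent_of(labels.count(lab), total))
        for lab in BIN_LABELS
    ]
    n_lt10 = labels.count("reduced-low")
    n_lt25 = n_lt10 + labels.count("reduced-mid")
    out.append(BinSummary("below-10", n_lt10, percent_of(n_lt10, total)))
    out.append(BinSummary("below-25", n_lt25, percent_of(n_lt25, total)))
    out.append(BinSummary("above-25", total - n_lt25, percent_of(total - n_lt25, total)))
    return out


def summarize_deltas(
    deltas: Sequence[float], scheme: RedoxBinScheme = DEFAULT_SCHEME
) -> dict[str, BinSummary]:
    """Counts/percentages of oxidation-sensitive (delta>10) and strongly (>20) sites."""
    total = len(deltas)
    n_sens = sum(1 for d in deltas if d > scheme.delta_sensitive)
    n_strong = sum(1 for d in deltas if d > scheme.delta_strong)
    return {
        "sensitive": BinSummary("sensitive", n_sens, percent_of(n_sens, total)),
        "strongly-sensitive": BinSummary(
            "strongly-sensitive", n_strong, percent_of(n_strong, total)
        ),
    }


def rsa_classify(rsa_percent: float | None, threshold: float = 20.0) -> str:
    """Exposed iff RSA strictly exceeds the threshold; missing RSA unclassified."""
    if rsa_percent is None or (isinstance(rsa_percent, float) and np.isnan(rsa_percent)):
        return "unclassified"
    if not 0 <= rsa_percent <= 100:
        raise ValueError(f"RSA out of range: {rsa_percent}")
    return "exposed" if rsa_percent > threshold else "buried"


@dataclass
class CategoryNode:
    """One node of the functional-category tree used for treemap export."""

    name: str
    members: list[str] = field(default_factory=list)  # ids at this leaf
    children: dict[str, "CategoryNode"] = field(default_factory=dict)
    count: int = 0
    mean_value: float | None = None
    color: tuple[float, float, float] | None = None

    def all_values(self, values: Mapping[str, float]) -> list[float]:
        vals = [values[m] for m in self.members if m in values]
        for child in self.children.values():
            vals.extend(child.all_values(values))
        return vals

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "count": self.count}
        if self.mean_value is not None:
            d["mean_value"] = self.mean_value
        if self.color is not None:
            d["color"] = list(self.color)
        if self.members:
            d["members"] = sorted(self.members)
        if self.children:
            d["children"] = [c.to_dict() for _, c in sorted(self.children.items())]
        return d


def _check_acyclic(parents: Mapping[str, str | None]) -> None:
    for start in parents:
        seen = set()
        node: str | None = start
        while node is not None:
            if node in seen:
                raise ValueError(f"cyclic category map at {node!r}")
            seen.add(node)
            node = parents.get(node)


def rollup_categories(
    values: Mapping[str, float],
    category_of: Mapping[str, str],
    parents: Mapping[str, str | None] | None = None,
) -> CategoryNode:
    """Aggregate per-entity values over a category hierarchy.

    ``category_of`` maps each entity to its leaf category; entities
    missing from the map fall into an "unclassified" leaf.  ``parents``
    maps categories to their parent (``None`` = below the root); a cycle
    is rejected.  Each node carries the member count and mean value over
    all members in its subtree.
    """
    parents = dict(parents or {})
    _check_acyclic(parents)

    def path_of(cat: str) -> list[str]:
        path = [cat]
        while parents.get(path[-1]) is not None:
            path.append(parents[path[-1]])  # type: ignore[arg-type]
        return path[::-1]

    root = CategoryNode("root")
    for entity in values:
        cat = category_of.get(entity, "unclassified")
        node = root
        for part in path_of(cat):
            node = node.children.setdefault(part, CategoryNode(part))
        node.members.append(entity)

    def finalize(node: CategoryNode) -> None:
        vals = node.all_values(values)
        node.count = len(vals)
        node.mean_value = float(np.mean(vals)) if vals else None
        for child in node.children.values():
            finalize(child)

    finalize(root)
    return root


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear color gradient over anchor values, clamped at the ends."""

    anchors: tuple[tuple[float, tuple[float, float, float]], ...]

    def __post_init__(self) -> None:
        vals = [v for v, _ in self.anchors]
        if len(vals) < 2 or vals != sorted(vals):
            raise ValueError("scale needs >= 2 anchors with increasing values")


# grey-yellow-red over 0-100% oxidation; blue-white-red over -60..+60 delta
OXIDATION_SCALE = ColorScale(
    ((0.0, (0.7, 0.7, 0.7)), (50.0, (1.0, 1.0, 0.0)), (100.0, (1.0, 0.0, 0.0)))
)
DELTA_SCALE = ColorScale(
    ((-60.0, (0.0, 0.0, 1.0)), (0.0, (1.0, 1.0, 1.0)), (60.0, (1.0, 0.0, 0.0)))
)


def map_gradient(value: float, scale: ColorScale) -> tuple[float, float, float]:
    """Linear interpolation between anchor colors, clamped at the endpoints."""
    anchors = scale.anchors
    if value <= anchors[0][0]:
        return anchors[0][1]
    if value >= anchors[-1][0]:
        return anchors[-1][1]
    for (v0, c0), (v1, c1) in zip(anchors, anchors[1:]):
        if v0 <= value <= v1:
            t = (value - v0) / (v1 - v0)
            return tuple(a + t * (b - a) for a, b in zip(c0, c1))  # type: ignore[return-value]
    raise AssertionError("unreachable")
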