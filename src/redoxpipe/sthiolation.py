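"""S-thiolation calling from cysteine mass increments.

Mixed disulfides between a protein cysteine and a low-molecular-weight
thiol add the thiol's mass minus 2 H to the Cys-peptide: mycothiol
(S-mycothiolation) adds a nominal +484 Da, free cysteine
(S-cysteinylation) +119 Da.  Calls match an observed per-Cys mass delta
against a registry of known adducts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

# monoisotopic atomic masses (Da)
_MONO = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196, "S": 31.97207100}
_H2 = 2 * _MONO["H"]


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition."""
    return sum(_MONO[el] * n for el, n in formula.items())


# mycothiol AcCys-GlcN-Ins, C17H30N2O12S
MSH_MONO = formula_mass({"C": 17, "H": 30, "N": 2, "O": 12, "S": 1})
# free cysteine C3H7NO2S
CYS_MONO = formula_mass({"C": 3, "H": 7, "N": 1, "O": 2, "S": 1})
# N-ethylmaleimide cap C6H7NO2 (irreversible alkylation, not a disulfide)
NEM_MONO = formula_mass({"C": 6, "H": 7, "N": 1, "O": 2})


@dataclass(frozen=True)
class ThiolMod:
    name: str
    nominal_da: int
    monoisotopic_da: float
    reversible: bool

    def __post_init__(self) -> None:
        if abs(self.monoisotopic_da - self.nominal_da) > 0.5:
            raise ValueError(
                f"{self.name}: monoisotopic delta {self.monoisotopic_da} "
                f"not within 0.5 Da of nominal {self.nominal_da}"
            )


@dataclass
class ThiolModRegistry:
    """Named Cys adducts with nominal and monoisotopic mass deltas."""

    entries: dict[str, ThiolMod] = field(default_factory=dict)

    def add(self, mod: ThiolMod) -> None:
        if mod.name in self.entries:
            raise ValueError(f"duplicate modification name {mod.name!r}")
        self.entries[mod.name] = mod

    def lookup(self, name: str) -> ThiolMod:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(f"unknown modification {name!r}") from None

    @classmethod
    def default(cls) -> "ThiolModRegistry":
        reg = cls()
        # disulfide adducts lose 2 H relative to the free thiol
        reg.add(ThiolMod("MSH", 484, round(MSH_MONO - _H2, 4), reversible=True))
        reg.add(ThiolMod("Cys", 119, round(CYS_MONO - _H2, 4), reversible=True))
        reg.add(ThiolMod("NEM", 125, round(NEM_MONO, 4), reversible=False))
        return reg


def lookup_mod(name: str, registry: ThiolModRegistry | None = None) -> tuple[int, float]:
    """Return (nominal Da, monoisotopic Da) for a registered adduct."""
    reg = registry or ThiolModRegistry.default()
    mod = reg.lookup(name)
    return mod.nominal_da, mod.monoisotopic_da


@dataclass(frozen=True)
class PeptideMatch:
    """An identified Cys-peptide with its observed mass delta on the Cys."""

    protein_id: str
    peptide: str
    cys_position: int  # 1-based position within the protein
    observed_delta: float
    condition: str = ""
    strain: str = ""

    def __post_init__(self) -> None:
        if "C" not in self.peptide.upper():
            raise ValueError(f"peptide {self.peptide!r} contains no cysteine")

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}:C{self.cys_position}"


@dataclass(frozen=True)
class ModifiedSite:
    site_id: str
    modification: str  # adduct name, "none", or "ambiguous"/"unknown"
    observed_delta: float
    error_da: float | None = None
    ppm_error: float | None = None


def call_sthiolation(
    matches: Sequence[PeptideMatch],
    registry: ThiolModRegistry | None = None,
    tol_da: float = 0.5,
    tol_ppm: float | None = None,
    reference_mass: float = 1500.0,
) -> list[ModifiedSite]:
    """Assign each observed Cys mass delta to the unique adduct within tolerance.

    Default matching is nominal (+-0.5 Da), since adduct deltas are
    conventionally reported as nominal integers; passing ``tol_ppm``
    switches to monoisotopic ppm matching relative to ``reference_mass``.
    A delta of ~0 is called unmodified; a delta near no registry entry is
    "unknown"; two entries within tolerance of one observation yield an
    "ambiguous" non-call.
    """
    reg = registry or ThiolModRegistry.default()
    if tol_ppm is not None and not tol_ppm > 0:
        raise ValueError("tol_ppm must be > 0")
    if tol_ppm is None and not tol_da > 0:
        raise ValueError("tol_da must be > 0")
    calls: list[ModifiedSite] = []
    for m in matches:
        hits: list[tuple[str, float]] = []
        for mod in reg.entries.values():
            if tol_ppm is not None:
                err = m.observed_delta - mod.monoisotopic_da
                if abs(err) / reference_mass * 1e6 <= tol_ppm:
                    hits.append((mod.name, err))
            else:
                err = m.observed_delta - mod.nominal_da
                if abs(err) <= tol_da:
                    hits.append((mod.name, err))
        zero_tol = tol_da if tol_ppm is None else tol_ppm * reference_mass / 1e6
        if abs(m.observed_delta) <= zero_tol:
            calls.append(ModifiedSite(m.site_id, "none", m.observed_delta))
        elif len(hits) == 1:
            name, err = hits[0]
            calls.append(
                ModifiedSite(
                    m.site_id,
                    name,
                    m.observed_delta,
                    error_da=err,
                    ppm_error=err / reference_mass * 1e6,
                )
            )
        elif len(hits) > 1:
            calls.append(ModifiedSite(m.site_id, "ambiguous", m.observed_delta))
        else:
            calls.append(ModifiedSite(m.site_id, "unknown", m.observed_delta))
    return calls


def site_to_protein(site_id: str) -> str:
    """Collapse a "protein:C<pos>" site identifier to its protein id."""
    return site_id.rsplit(":", 1)[0]


def overlap_sites(
    set_a: Iterable[str], set_b: Iterable[str], by_protein: bool = False
) -> tuple[set[str], dict[str, int]]:
    """Exact intersection of two site (or protein) identifier sets.

    With ``by_protein=True`` site ids are collapsed to protein ids before
    intersecting, as done when comparing an S-thiolated protein list with
    an oxidation-sensitive protein list.
    """
    a = {site_to_protein(s) for s in set_a} if by_protein else set(set_a)
    b = {site_to_protein(s) for s in set_b} if by_protein else set(set_b)
    inter = a & b
    return inter, {"n_a": len(a), "n_b": len(b), "n_intersection": len(inter)}
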