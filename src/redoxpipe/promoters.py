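"""SigH/SigE promoter-consensus scanning.

ECF sigma factors SigH and SigE recognize bipartite promoters: a -35
element, a spacer of fixed length range, and a -10 element.  The SigH
consensus is GGAAY-N18/19-GTT and the SigE consensus GGAACY-N16/17-CGTT
(IUPAC Y = C or T).  Matching allows one mismatch at position 1 or 2 of
the -35 element and one more anywhere in the -10 element.  Scanning is
restricted to upstream windows of genes induced under stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MismatchPolicy:
    max_mismatches: int = 1
    allowed_positions: frozenset[int] | None = None  # 1-based; None = anywhere


@dataclass(frozen=True)
class SigmaModel:
    name: str
    minus35: str
    spacers: frozenset[int]
    minus10: str
    policy35: MismatchPolicy = MismatchPolicy(1, frozenset({1, 2}))
    policy10: MismatchPolicy = MismatchPolicy(1, None)

    def __post_init__(self) -> None:
        for cons in (self.minus35, self.minus10):
            if any(b not in IUPAC for b in cons):
                raise ValueError(f"non-IUPAC base in consensus {cons!r}")
        if not self.spacers:
            raise ValueError("spacer length set must be non-empty")


SIGH = SigmaModel("SigH", "GGAAY", frozenset({18, 19}), "GTT")
SIGE = SigmaModel("SigE", "GGAACY", frozenset({16, 17}), "CGTT")


def match_element(
    subseq: str, consensus: str, policy: MismatchPolicy
) -> tuple[bool, list[int]]:
    """IUPAC-degenerate comparison of a subsequence against a consensus.

    Returns (match?, 1-based mismatch positions).  A non-ACGT base in the
    subsequence counts as a mismatch.  The element matches iff the
    mismatch count is within the policy maximum and — when the policy
    restricts positions — every mismatch sits at an allowed position.
    """
    if len(subseq) != len(consensus):
        raise ValueError("subsequence and consensus lengths differ")
    mism = [
        i + 1
        for i, (b, c) in enumerate(zip(subseq.upper(), consensus.upper()))
        if b not in IUPAC.get(c, "")
    ]
    ok = len(mism) <= policy.max_mismatches and (
        policy.allowed_positions is None
        or all(p in policy.allowed_positions for p in mism)
    )
    return ok, mism


@dataclass(frozen=True)
class PromoterHit:
    """A -35/spacer/-10 consensus match within a scanned window.

    Positions are 0-based offsets within the scanned sequence (gene
    strand, 5'->3'); absolute genomic coordinates are attached when the
    window's coordinate map is known.
    """

    sigma: str
    start35: int
    seq35: str
    mismatches35: tuple[int, ...]
    spacer: int
    start10: int
    seq10: str
    mismatches10: tuple[int, ...]
    gene_id: str = ""
    sigma_classes: tuple[str, ...] = ()
    abs_start35: int | None = None
    abs_end10: int | None = None

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches35) + len(self.mismatches10)

    @property
    def end10(self) -> int:
        """0-based exclusive end of the -10 element within the window."""
        return self.start10 + len(self.seq10)


def scan_sequence(seq: str, model: SigmaModel, gene_id: str = "") -> list[PromoterHit]:
    """All policy-compliant -35/spacer/-10 matches in a sequence.

    Every offset and spacer-length combination is tested; overlapping
    hits are all returned, ranked by fewest total mismatches, then by
    -10 element closest to the downstream end (the anchor side).
    """
    seq = seq.upper()
    n35, n10 = len(model.minus35), len(model.minus10)
    hits: list[PromoterHit] = []
    for i in range(len(seq) - n35 + 1):
        ok35, mm35 = match_element(seq[i : i + n35], model.minus35, model.policy35)
        if not ok35:
            continue
        for spacer in sorted(model.spacers):
            j = i + n35 + spacer
            if j + n10 > len(seq):
                continue
            ok10, mm10 = match_element(seq[j : j + n10], model.minus10, model.policy10)
            if not ok10:
                continue
            hits.append(
                PromoterHit(
                    sigma=model.name,
                    start35=i,
                    seq35=seq[i : i + n35],
                    mismatches35=tuple(mm35),
                    spacer=spacer,
                    start10=j,
                    seq10=seq[j : j + n10],
                    mismatches10=tuple(mm10),
                    gene_id=gene_id,
                )
            )
    hits.sort(key=lambda h: (h.n_mismatches, -h.end10, h.start35, h.spacer))
    return hits


def classify_sigma(
    hit: PromoterHit, seq: str, models: Sequence[SigmaModel] = (SIGH, SIGE)
) -> tuple[str, ...]:
    """Sigma classes recognizing the locus of a hit.

    A SigH site whose locus also satisfies the SigE consensus (the SigE
    -10 CGTT extends the SigH GTT one base upstream, and the SigE -35
    GGAACY the SigH GGAAY one base downstream, so both models span the
    same 26-nt locus) is recognized by both holoenzymes.
    """
    classes = []
    for model in models:
        for other in scan_sequence(seq, model):
            if other.end10 == hit.end10 and other.start35 == hit.start35:
                classes.append(model.name)
                break
    return tuple(dict.fromkeys(classes))


def scan_with_classes(seq: str, gene_id: str = "") -> list[PromoterHit]:
    """SigH scan with each hit annotated SigH-only or SigH+SigE."""
    sige_hits = scan_sequence(seq, SIGE)
    out = []
    for h in scan_sequence(seq, SIGH, gene_id):
        classes = ["SigH"]
        if any(
            e.end10 == h.end10 and e.start35 == h.start35 for e in sige_hits
        ):
            classes.append("SigE")
        out.append(replace(h, sigma_classes=tuple(classes)))
    return out


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    start_codon: int  # 1-based genomic coordinate of the translation start base
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def anchor(self, kind: str) -> int | None:
        if kind == "tss":
            return self.tss
        if kind == "start_codon":
            return self.start_codon
        raise ValueError(f"unknown anchor {kind!r}")


@dataclass(frozen=True)
class Window:
    """An extracted upstream/downstream window on the gene strand.

    ``genomic_positions[i]`` is the 1-based genomic coordinate of
    sequence character ``i``.
    """

    seq: str
    genomic_positions: tuple[int, ...]
    clipped: bool


def _rel_to_genomic(anchor: int, rel: int, strand: str) -> int:
    # relative coordinates skip 0: -1 abuts +1 (= the anchor base)
    if rel == 0:
        raise ValueError("relative position 0 does not exist")
    off = rel - 1 if rel > 0 else rel
    return anchor + off if strand == "+" else anchor - off


def extract_window(
    gene: GeneModel,
    genome: Mapping[str, str],
    lo: int,
    hi: int,
    anchor: str = "tss",
) -> Window:
    """Gene-strand sequence covering relative positions ``lo``..``hi``.

    Position +1 is the anchor base (TSS or translation start), -1 the
    base immediately upstream; there is no position 0.  Minus-strand
    windows are reverse-complemented.  Windows reaching past a contig
    end are clipped and flagged.
    """
    if lo >= hi:
        raise ValueError("window requires lo < hi")
    a = gene.anchor(anchor)
    if a is None:
        raise ValueError(f"gene {gene.gene_id}: anchor {anchor!r} undefined")
    contig = genome[gene.contig]
    rels = [r for r in range(lo, hi + 1) if r != 0]
    coords = [_rel_to_genomic(a, r, gene.strand) for r in rels]
    if gene.strand == "-":
        pass  # coords already run 5'->3' on the gene strand (decreasing genomic)
    kept = [c for c in coords if 1 <= c <= len(contig)]
    clipped = len(kept) != len(coords)
    if gene.strand == "+":
        seq = "".join(contig[c - 1] for c in kept)
    else:
        seq = "".join(reverse_complement(contig[c - 1]) for c in kept)
    return Window(seq=seq.upper(), genomic_positions=tuple(kept), clipped=clipped)


def scan_induced_genes(
    expression: pd.DataFrame,
    genes: Iterable[GeneModel],
    genome: Mapping[str, str],
    models: Sequence[SigmaModel] = (SIGH,),
    induction_m_min: float = 1.0,
    alpha: float = 0.01,
    window: tuple[int, int] = (-300, 100),
    anchor: str = "start_codon",
) -> tuple[pd.DataFrame, list[str]]:
    """Scan upstream windows of induced genes for sigma-factor promoters.

    Only genes with m-value >= ``induction_m_min`` and adjusted p-value
    <= ``alpha`` are scanned.  Returns the hit table (with absolute
    genomic coordinates of the -35 start and -10 end, mismatch counts
    and the gene's m-value) and the ids of genes skipped for missing
    anchors or sequence context.
    """
    rows, skipped = [], []
    for gene in genes:
        if gene.gene_id not in expression.index:
            continue
        rec = expression.loc[gene.gene_id]
        if rec["m_value"] < induction_m_min or rec.get("p_adj", 0.0) > alpha:
            continue
        if gene.anchor(anchor) is None or gene.contig not in genome:
            skipped.append(gene.gene_id)
            continue
        win = extract_window(gene, genome, window[0], window[1], anchor=anchor)
        hits = []
        for m in models:
            if m.name == "SigH":
                hits.extend(scan_with_classes(win.seq, gene.gene_id))
            else:
                hits.extend(
                    replace(h, sigma_classes=(m.name,))
                    for h in scan_sequence(win.seq, m, gene.gene_id)
                )
        for h in hits:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "sigma": h.sigma,
                    "sigma_classes": "+".join(h.sigma_classes) or h.sigma,
                    "m_value": float(rec["m_value"]),
                    "win_start35": h.start35,
                    "spacer": h.spacer,
                    "seq35": h.seq35,
                    "seq10": h.seq10,
                    "n_mismatches": h.n_mismatches,
                    "abs_start35": win.genomic_positions[h.start35],
                    "abs_end10": win.genomic_positions[h.end10 - 1],
                }
            )
    cols = [
        "gene_id", "sigma", "sigma_classes", "m_value", "win_start35", "spacer",
        "seq35", "seq10", "n_mismatches", "abs_start35", "abs_end10",
    ]
    return pd.DataFrame(rows, columns=cols), skipped


def hits_to_bed(hits: pd.DataFrame, genes: Mapping[str, GeneModel]) -> pd.DataFrame:
    """BED-like intervals (0-based half-open) spanning -35 through -10."""
    rows = []
    for _, h in hits.iterrows():
        gene = genes[h["gene_id"]]
        lo = min(h["abs_start35"], h["abs_end10"])
        hi = max(h["abs_start35"], h["abs_end10"])
        rows.append(
            {
                "chrom": gene.contig,
                "start": int(lo) - 1,
                "end": int(hi),
                "name": f"{h['gene_id']}:{h['sigma_classes']}",
                "score": int(h["n_mismatches"]),
                "strand": gene.strand,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
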