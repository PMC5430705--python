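# Methods

Models, default parameters, generator design and numerical choices for
each module. Empirical claims below are limited to what the test suite
and the reproduction script actually compute.

## OxICAT quantification (`redoxpipe.oxicat`)

**Model.** A Cys site measured under OxICAT yields a light feature
(reduced thiols, ¹²C tag) and a heavy feature (reversibly oxidized
thiols, ¹³C tag) whose neutral masses differ by 9.0302 Da per Cys in
the peptide (`PER_CYS_DELTA_DA`; displays as the nominal 9 Da). The
oxidation percentage is `100 · (heavy / (light + heavy))`, computed as
one division before the multiplication so that a pair with a missing
light channel yields exactly 100.0.

**Pairing.** Features are grouped by (site, replicate, condition,
n_cys); candidate light/heavy pairs within `tol_ppm` (default 10 ppm,
relative to the heavy mass) of the expected `n_cys × 9.0302 Da` gap are
accepted greedily by smallest absolute ppm error. Candidates whose
|ppm| errors agree within `TIE_TOL_PPM = 1e-9` ppm form a tie batch;
ties that share a feature are unresolvable and all their participants
are left unpaired (ambiguity is surfaced, not silently broken). The
tie tolerance exists because symmetric mass errors that are equal in
exact arithmetic differ by ~1e-10 ppm in floating point.

**Missing data.** A pair with one missing intensity is quantified
(0% or 100%) but flagged `missing-partner` and excluded from replicate
aggregation by default. Features with no mass partner at all are never
quantified: with one channel absent from the feature list there is no
evidence which channel was observed.

**Deltas.** The default policy is difference of replicate means,
Δ = mean %ox(stress) − mean %ox(control), matching the worked example
AdhE1 Cys48: 13.5 → 45.5 gives 32.0. `delta_paired` implements the
per-replicate alternative (mean of per-replicate differences) for
designs with matched replicates. Replicate SDs use ddof = 1 and are
undefined (None) for n < 2.

## S-thiolation calling (`redoxpipe.sthiolation`)

The default registry holds mycothiolation (MSH: nominal +484 Da,
monoisotopic 484.1363 = C₁₇H₃₀N₂O₁₂S − 2H), cysteinylation (+119,
119.0041 = C₃H₅NOS − H) and the NEM alkylation cap (125.0477), each
derived from elemental compositions with standard monoisotopic atomic
masses. Calling compares an observed Cys mass increment against every
registry entry within ±0.5 Da by default (`tol_ppm` mode available,
scaled by a 1500 Da reference peptide mass): zero matches near zero
delta → "none", zero matches elsewhere → "unknown", one match → that
adduct, several → "ambiguous". Site identifiers are
`protein:C<position>` so site- and protein-level overlaps between
datasets are exact set operations.

## Redox summaries (`redoxpipe.summary`)

Oxidation bins follow the convention [0,10), [10,25), [25,75],
(75,100]: 25% is "oxidized", 75% still "oxidized", 75.01% "highly
oxidized". Delta classes are strict: sensitive iff Δ > 10 pp, strongly
sensitive iff Δ > 20 pp. RSA classifies exposed iff RSA > 20%
(strict), buried otherwise, unclassified for missing values.
Percentages round half-up to one decimal (`round_half_up` uses
`decimal` on the value's repr, so 78.05 → 78.1 rather than banker's
rounding); this reproduces every printed summary percentage exactly
from its printed numerator/denominator. Category roll-ups build a
treemap-style tree (counts, mean values, members per node) over an
explicit leaf→parent map and reject cyclic maps.

## Transcriptome analysis (`redoxpipe.transcriptome`)

**Normalization.** Median-of-ratios size factors: per sample, the
median over all-positive genes of the ratio to the per-gene geometric
mean. The median is taken in linear ratio space (not as
exp(median log)) — the two differ at even counts, where the standard
estimator averages the two central ratios arithmetically.

**m/a values.** m = log₂(mean normalized stress + pc) −
log₂(mean normalized control + pc), a = log₂(overall normalized mean +
pc), pseudocount pc = 1 by default; all-zero genes get m = 0 and a
`low_signal` flag. The cutoff is `2.58 × SD(m)` over all finite
m-values (ddof = 1); with normal null m-values ~99% fall inside
±cutoff. 2.58 × SD applied to σ = 1.733 reproduces the study-scale
cutoff of ≈ 4.47.

**Testing.** The default test is an empirical-Bayes moderated t-test
on log₂(normalized + 1): per-gene pooled variances are shrunk toward a
scaled inverse-χ² prior fitted across genes by moment matching on
log s² (digamma/trigamma, Brent root-finding for the prior df). This
is a documented stand-in for a count-model DE test — with 3 vs 3
replicates an unmoderated Welch t cannot reach p_adj ≤ 0.01 regardless
of effect size, while variance moderation restores power without
touching thresholds. The test is pluggable: `test="welch"` or any
callable (e.g. an exact negative-binomial test) can be substituted.
P-values are BH-adjusted (`statsmodels`), and a gene is DE iff
|m| ≥ cutoff AND p_adj ≤ α = 0.01, both boundaries inclusive.

**Operons.** Genes sorted by genomic start are joined transitively
when adjacent, same-strand and connected by ≥ 20 junction-spanning
reads (missing junction = 0). The partition is invariant to input row
order and equals an independent union-find oracle in tests.

## Promoter scanning (`redoxpipe.promoters`)

Consensi: SigH GGAAY–N18/19–GTT, SigE GGAACY–N16/17–CGTT. Matching is
IUPAC-degenerate with ≤ 1 mismatch restricted to positions 1–2 of the
−35 element and ≤ 1 mismatch anywhere in the −10 element; the SigE
policy mirrors SigH's (the source rule names only the −35 positions,
which are positions 1–2 for both consensi). Non-ACGT bases count as
mismatches. Every offset × spacer combination is enumerated;
overlapping hits are all reported, ranked by mismatch count then
proximity of the −10 element to the anchored (downstream) end.

A SigE-consensus locus necessarily contains a SigH match with the same
−35 start and −10 end (GGAAC[Y]…, …[C]GTT; spacer 16↔18, 17↔19 — both
span 26 nt), so SigH hits whose locus also satisfies the SigE
consensus are classified SigH+SigE.

Windows use anchor-relative coordinates without a position 0 (−1 abuts
+1 = the anchor base). The default scan window is −300..+100 around
the start codon — TSSs are not annotated for most genes, so the start
codon is the default anchor, with `anchor="tss"` available when a TSS
is known. Windows are extracted on the gene strand (reverse-
complemented for minus-strand genes) and only the gene strand is
scanned; clipping at contig ends is flagged. Only genes passing the
induction prefilter (m ≥ 1.0 and p_adj ≤ 0.01 by default) are scanned.

## Synthetic data (`redoxpipe.synth`)

All generators draw from one `numpy.random.default_rng(seed)` and
return the planted truth.

- **ICAT features.** True control oxidation ~ Beta(1.5, 8) (mostly
  reduced); a configurable fraction of sites (default 0.35) gains
  Uniform(0.12, 0.5) under stress, the rest Normal(0, 0.02) jitter,
  clipped to [0,1]. Total intensity is lognormal (μ=10, σ=1); each
  channel is the true fraction times independent mean-one lognormal
  noise with the configured CV (σ² = ln(1+cv²)). Dropout replaces an
  intensity with missing, never zero — zero would fabricate a
  confident 0%/100% measurement. Realism limits: no peptide-level
  interference, no correlated channel noise, no mass drift beyond the
  configured ±2 mDa in pairing tests.
- **Adduct deltas.** Mixture over {none, MSH, Cys} (0.6/0.3/0.1) plus
  Gaussian mass noise (default 0.01 Da), far inside the 0.5 Da calling
  tolerance so truth recovery is exact by construction.
- **Genome.** GC-rich (0.65) random contig; genes on alternating
  random strands with generous spacing; each motif gene gets one exact
  SigH or SigE element written at a recorded upstream offset
  (−250..−30) on the gene strand. Chance consensus matches in random
  sequence are possible and expected; recovery is scored as zero false
  negatives at the planted coordinates, not zero extra hits.
- **Counts.** Gamma-Poisson (negative binomial, Var = μ + φμ²,
  Poisson at φ = 0) around lognormal per-gene baselines (default mean
  200, dispersion 0.05, 3 vs 3); 20 genes carry |log₂FC| = 5 effects
  with random sign. Operon chains (2–4 genes, same strand) define the
  junction table: internal junctions ≥ 20 spanning reads, others < 20.

## Pipeline (`redoxpipe.pipeline`) and I/O (`redoxpipe.tables`)

`run_pipeline` derives independent per-stage seeds from the single run
seed via `numpy.random.SeedSequence.spawn` (reduced mod 2³¹), executes
the stages in dependency order and writes a JSON manifest with SHA-256
checksums of every output; identical seeds give byte-identical runs.
Tables are TSV, UTF-8, header row, `.` for missing — the prevailing
convention of proteomics/transcriptomics supplementary tables. Reading
validates a declared column schema and reports malformed cells with
1-based row/column coordinates; unknown columns pass through.

## Limitations

- The moderated t-test is a variance-shrinkage stand-in, not a count
  likelihood model; at very low counts its log-transform
  approximation is crude.
- Synthetic OxICAT noise is unbiased and multiplicative; real ICAT
  ratios show compression and peptide-dependent bias that the MAE
  recovery number does not capture.
- Promoter scanning is purely consensus-based (no PWM scores, no
  energy model) and scans only the gene strand of a fixed window.
- Genome-scale published counts (site inventories, promoter and
  transcript totals) depend on deposited raw data and are outside the
  scope of desk-scale reproduction; the package reproduces printed
  arithmetic and recovers planted synthetic truth instead.
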