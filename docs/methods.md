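# Methods

`auxoactivity` analyses genome-resolved metagenome/metatranscriptome data
from anaerobic hydrocarbon-degrading communities (the motivating system is
an oil reservoir under secondary recovery, where injection water mixes
active degraders with a large inactive background). It deliberately starts
*after* the heavy upstream machinery — assembly, binning, annotation, read
alignment — and consumes only their tabular products. This note records the
models, the operational definitions chosen where the underlying rules are
qualitative, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Relative abundance and transcriptional activity

For a DNA library with `mapped_i` reads on bin *i* of genome size `L_i`
(bp), relative abundance is genome-size-normalised:

    a_i = (mapped_i / L_i) / Σ_j (mapped_j / L_j)

Reads from a genome scale with both cell number and genome length, so the
division by `L_i` converts read share into organism share. The vector sums
to 1 over the bins in the summary (bins without mapped reads get 0) and is
invariant under uniform depth scaling.

Transcriptional activity of a bin is the ratio of its cDNA mapping rate to
its DNA mapping rate, each computed against the bin's own library total:

    r_i = (cdna_i / N_cdna) / (dna_i / N_dna)

A bin is called **active** when `r_i > 0.5`, strictly: a member transcribing
at least half as much as its DNA share predicts is treated as metabolically
engaged, and ties at the threshold are inactive. Bins with DNA rate 0 get an
undefined ratio (reported as missing, never infinity) and are never active.
Both rates are computed against the same target set supplied in the mapping
file; if upstream mapping used asymmetric targets (e.g. cDNA against coding
sequences only), that is a property of the inputs which the package records
but cannot undo.

## FPKM and the top-quartile rule

    FPKM = fragments / ((length / 1000) · (total_mapped_fragments / 10⁶))

Gene lengths are in base pairs; effective-length corrections are an upstream
concern. A gene is **highly transcribed** when its FPKM is strictly above
the sample-wide 75th percentile of all gene FPKM values — the threshold is
one number per metatranscriptome, not per bin, because the cumulative FPKM
distribution is a property of the whole sample. The quantile uses the
*lower nearest-rank* convention: with `n` sorted values the threshold is the
`ceil(0.75 n)`-th smallest. On integer ranks 1..100 this gives threshold 75
and exactly 25 flagged genes; no interpolation rule can produce a value that
is not an observed FPKM. Ties at the threshold are not flagged.

## Auxotrophy calling

A biosynthetic pathway for a compound (amino acid or vitamin) is an ordered
list of steps; each step is an OR-group of alternative genes (isoenzymes).
Counting is **step-level**: a step is satisfied if any member is present, so
alternative enzymes for one reaction never create a false auxotrophy.

* 0 missing steps → **prototroph**.
* ≥ 2 missing steps → **auxotroph**, regardless of expression.
* Exactly 1 missing step → the expression-rescue rule. A single absent gene
  in a draft genome is as likely an assembly/annotation gap as a real loss,
  so the pathway's transcription decides: if the pathway is transcribed
  similarly to bins that carry it completely, the gap is treated as
  artefactual and the bin is a prototroph (`rescue_applied`); if clearly
  lower, an auxotroph; if no expression data or no complete-pathway
  reference bin exists, **indeterminate** — the rule is inapplicable and the
  call is not forced either way.

Operational definitions (the qualitative rule gives none):

* *pathway expression score* = median FPKM over the pathway genes present in
  the bin (robust to a single outlier gene); genes without an FPKM entry
  count as 0.
* *similar or higher* = `score ≥ α · median(reference scores)` with
  `α = 0.75` by default (configurable). The reference scores come from bins
  with zero missing steps for that pathway. α < 1 encodes "similar", not
  only "higher".

Transporter presence is recorded next to each call but never changes the
status — it is display information about potential uptake, not evidence
about biosynthesis. Vitamins B2 and B3 need no dedicated transport system,
so their transporter field is "not applicable". Genome completeness is
reported but does not modify calls; probabilistic absence correction would
be an extension, not part of this rule set. A compound is **covered** at
community level iff at least one bin is prototrophic for it; compounds
blocked only by indeterminate calls are flagged data-limited.

## Thermodynamic feasibility window

In-situ Gibbs energy is `ΔG = ΔG°(T) + RT ln Q` with
`R = 8.314·10⁻³ kJ mol⁻¹ K⁻¹`. Activity conventions: molar concentrations
for aqueous solutes (activity coefficients 1 — the ideal dilute level of
theory of the classical method this follows), partial pressures in atm for
gases, activity 1 for water and for the excess pure hexadecane phase, and
`a(H⁺) = 10^(−pH)`. Formation energies are tabulated at 298.15 K; at other
temperatures `ΔG°(T) = (T/T₀)ΔG°(T₀) + (1 − T/T₀)ΔH°` (Gibbs–Helmholtz with
temperature-independent enthalpies). The bundled reaction set:

* R1 `C₁₆H₃₄ + 16 H₂O → 8 CH₃COO⁻ + 8 H⁺ + 17 H₂`
* R2 `4 H₂ + 2 HCO₃⁻ + H⁺ → CH₃COO⁻ + 4 H₂O` (reductive acetogenesis)
* R1′ `= R1 + (17/4)·R2` — hexadecane fermented with acetate as sole
  product (H₂-free net reaction; built by exact rational combination)
* R3 `CH₃COO⁻ + H₂O → CH₄ + HCO₃⁻` (acetoclastic methanogenesis)

Reactions and species are data (`reactions.json`, `species.json`), checked
for C/H/O and charge balance before every evaluation, and user-replaceable.
`ΔGf°(hexadecane, l) = +58.7 kJ/mol` was derived from its standard enthalpy
of formation (−456.3 kJ/mol) and entropy (586.2 J mol⁻¹ K⁻¹) against the
elements; the other values are standard aqueous-biochemistry compilation
numbers. They reproduce the familiar anchors: R3 ΔG° = −31.0 kJ/mol, R2
ΔG°′(pH 7) ≈ −104.5 kJ/mol, R1 ΔG°′(pH 7) ≈ +461 kJ/mol.

Because acetate appears on one side of each bundled reaction, ΔG is strictly
monotone in ln[acetate] (`∂ΔG/∂ln[ac] = ν_ac RT`), so the `ΔG = 0`
**equilibrium acetate concentration** is the unique root; it is found by
Brent's method in ln-concentration space to |ΔG| < 10⁻⁶ kJ/mol. The
**window of opportunity** at a given pH is the open interval between the
methanogenesis equilibrium (acetate floor: below it, acetate consumption is
endergonic) and the fermentation equilibrium (acetate ceiling: above it,
alkane fermentation is endergonic). Fermentation releases protons, so the
ceiling falls as pH drops and the window narrows in acid waters. Wells are
classified by the strict signs of both ΔG values at their measured (pH,
acetate); a point exactly on a boundary is not feasible for that reaction.

Default background conditions — 10 mM HCO₃⁻, 1 atm CH₄, 10⁻⁴ atm H₂,
298.15 K — are explicit configuration, chosen as ordinary reservoir-water
assumptions, and should be replaced by site measurements where available
(the method's original applications do not publish a single canonical set).

## Synthetic data generator

The generator fabricates the upstream tabular products with planted truth:

* **Statuses.** Per bin × compound: auxotroph (default rate 0.3; all
  alternatives of ≥ 2 random steps removed), "annotation-gap" prototroph
  (rate 0.1; exactly one step removed, pathway transcribed normally —
  exercising the rescue rule), optional low-expression auxotroph (exactly
  one step removed and the pathway transcribed at 0.1× the reference level),
  otherwise full prototroph. Present steps keep a random non-empty subset of
  their alternatives.
* **Expression.** Each pathway draws one log-normal mean FPKM
  (median 30, σ = 0.8) shared by all of its genes; each bin also carries
  background genes (default 30, log-normal median 10, σ = 1). Residual genes
  of broken pathways are silenced (mean 0). The shared per-pathway mean is a
  deliberate idealisation: it makes the rescue comparison exact in the
  noiseless limit, so recovery failures indicate logic errors rather than
  sampling accidents. Expected fragments per gene = mean FPKM ×
  (length/1000) × (depth/10⁶); multiplicative log-normal noise
  (σ = `expression_noise_sd`, default 0.5) then Poisson counting noise are
  applied. Setting the noise σ to 0 (or `expectation_counts`) replaces every
  count by its expectation — "noiseless" means fully deterministic here,
  which is what makes exact-recovery tests well-posed.
* **Mapping.** Bin abundances are Dirichlet(1); activity multipliers
  log-normal(0, 0.7). DNA reads are multinomial with weights
  abundance × genome size, cDNA with weights abundance × activity, each with
  an unmapped remainder category (default fraction 0.3, emulating the large
  unbinned/inactive fraction of injection-water communities). Genome sizes
  are uniform on 1–6 Mb; completeness 85–100% and contamination 0–3% on the
  4-decimal percentage grid the TSV format stores.
* **Reproducibility.** Each stage (community, DNA, cDNA, expression) draws
  from `SeedSequence([seed, stage])`, so stages can be regenerated
  independently and identical (config, seed) give byte-identical files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequence content and mapping ambiguity,
per-gene expression heterogeneity within a pathway, operon structure,
compositional coupling between bins beyond the multinomial constraint,
contamination of bins with foreign genes, and any correlation between
activity multipliers and genome content. Recovery rates on synthetic data
measure the calling logic under its own model, not annotation quality of
real genome bins.

## Numerical conventions and degenerate inputs

* Percentages on disk (CheckM convention), fractions in memory; 4-decimal
  serialization keeps write→read an exact identity.
* All writers sort rows canonically; outputs are byte-stable under input
  permutation.
* Zero mapped reads in every bin, empty expression tables, unknown
  bin/gene references, unbalanced reactions, and missing activities all
  raise `ValidationError` with the offending name/line rather than
  propagating NaNs.
* Rational stoichiometry (`fractions.Fraction`) keeps reaction combinations
  exact; Hess additivity holds to < 10⁻⁹ kJ/mol.
* Seeds derived from a base seed stay below 2³¹.

## Problem sizes

Default analyses and checks run at the scale the package targets: 20 bins ×
20 compounds (400 calls) for recovery, sequencing depth 10⁶ for mapping
simulations, ~10⁴ genes for quantile behaviour, and 50 × 50 grids for the
feasibility window. The full test suite and the acceptance script each
complete in seconds on one CPU.

## Known limitations

* The rescue rule's α and the median aggregate are operational choices; the
  underlying qualitative rule admits others (mean, trimmed mean, rank test).
* Indeterminate calls are honest refusals, not probabilities; a completeness-
  aware probabilistic caller would be a natural extension.
* Ideal-solution activities and bicarbonate-only carbonate handling bound
  the thermodynamic accuracy; full speciation and activity-coefficient
  models (e.g. Davies/Pitzer) are out of scope.
* The cDNA/DNA ratio inherits whatever target asymmetry the upstream mapping
  had; cross-study comparability requires consistent upstream choices.
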