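# Methods

## Data model

All intensities are log2-transformed protein-level quantities (LFQ-style;
the package is agnostic to the upstream quantification method). An
`IntensityTable` is a proteins × samples matrix with NaN marking
unquantified cells, sample metadata (bait variant, ±EGF, ±inhibitor,
replicate), and a per-cell imputation flag. Protein identifiers are opaque
strings (gene symbols or accessions); no identifier mapping is performed.
Raw-scale input is converted at read time, with 0 treated as missing —
the convention of common search-engine exports.

## Differential enrichment

1. **Normalization.** Each sample column is shifted so its median over
   observed values equals the median of column medians. This removes
   loading/acquisition offsets without touching the missingness mask.
2. **Imputation.** Missing values in proximity-labeling data are strongly
   missing-not-at-random: a protein absent from the control but abundant in
   the bait samples is informative, not ignorable. Missing cells are drawn
   per sample from a down-shifted normal, mean = observed mean − 1.8 ×
   observed sd, sd = 0.3 × observed sd. These defaults are the established
   practice for label-free MNAR imputation; the experiment's own test and
   publication pipelines do not prescribe alternatives strongly enough to
   change them. Samples with fewer than two observed values fall back to
   global moments with a logged warning.
3. **Testing.** Per protein, a two-sided Welch t-test on the completed
   matrix; the effect size is the difference of group means (log2
   fold-change). No multiple-testing correction is applied by default —
   hit calling mirrors the raw p < 0.05 convention of the assay class; a
   Benjamini–Hochberg column is available (`add_bh=True`) but does not
   drive the hit flag. Proteins observed in fewer than 2 samples across
   the whole contrast are dropped before testing, so no test compares
   imputed values against imputed values only. Degenerate zero-variance
   cases: equal means give p = 1; perfectly separated constants get the
   machine-minimum p (logged), preserving p ∈ (0, 1].
4. **Hit calling.** A protein is an enrichment hit iff log2fc > 1 AND
   p < 0.05, both strict inequalities (ties at the boundary are excluded;
   the convention is declared rather than inferred, since printed cutoffs
   rarely state strictness). Depletion hits (log2fc < −1) form a separate
   set — enrichment and loss are reported independently, never pooled.

## Set statistics

Overlap matrices, k-of-n core interactomes and the relaxed pairwise overlap
are exact enumerations. The relaxed overlap applies both cutoffs to the
first contrast and only one of the two (fold-change OR p) to the second;
it is deliberately asymmetric and is a sparsity-tolerant overlap measure,
useful when replicate dropout deflates significance in one dataset.
Proteins absent from a contrast table count as non-hits, matching the
presence/absence semantics of supplementary hit tables.

## Phosphoprotein bias curves

For a contrast, at each threshold t of a strictly increasing grid (default
0…5 in 0.25 log2 steps), the curve reports the number of proteins with
log2fc > t and the fraction of them annotated as phosphoproteins. Proteins
missing from the annotation table count as unannotated (database absence is
the operational negative). Two curves on the same grid are compared by
signed per-threshold differences and their trapezoidal area; no further
test statistic is attached — the comparison is descriptive.

## SH2 specificity matrices and site scoring

From a degenerate peptide library with fixed central phosphotyrosine
(written `y`), screened against a domain, with deep-sequencing counts of
the input and selected pools:

* positional residue counts are read-weighted sums over peptides;
* frequencies are Laplace-smoothed with a pseudocount of 1 read per
  (position, residue) cell — the smoothing is applied to counts, not to
  frequencies, so a null screen yields exactly zero weights and weights are
  scale-invariant in the read depth up to pseudocount perturbation;
* the weight is w(p,a) = log2(f_sel/f_in), zero-centered within each
  position so a uniformly random peptide scores 0 and scores are comparable
  across positions.

A phosphosite window (default ±5 residues, 11-mer) is scored by summing
the weights of its flanking residues; padding beyond protein termini
contributes 0. Percentile ranks over a scored collection are linear in rank
(best site 100, worst 0; a lone site ranks 100; ties share the larger
rank). "Tight binders" are sites whose better domain percentile is at or
above a cutoff (default 99), optionally restricted to an interactome's
proteins. The additive log-enrichment (PSSM) convention and these defaults
are declared package conventions; they are the field standard for
selection-screen-derived matrices.

## Compartment statistics

* **Shift test:** one-sided Mann–Whitney U of labeled proteins' log2fc
  against all other quantified proteins (alternative: labeled > background).
  One-sided because the scientific claim is directional (enhanced labeling
  of a compartment). Exact null distribution for small tie-free inputs.
* **Complex counts:** exact membership intersections; complex I is
  subdivided into core/accessory/assembly subunit classes when those labels
  exist in the vocabulary.
* **Sub-mitochondrial profile:** per variant, mean log2fc of
  matrix-annotated vs intermembrane-space-annotated proteins and their
  difference. The mean (rather than a fraction-of-hits) was chosen because
  it uses all quantified members and degrades gracefully at small
  annotation sets; an empty sub-compartment yields NaN with a warning.
* **ORA:** hypergeometric upper tail of the overlap between a hit set and
  each gene set, BH-adjusted across sets. The background is the quantified
  proteins of the contrast, not the annotation universe — detectability by
  proximity labeling defines the sampling frame. Gene sets are flat GMT
  collections; no ontology DAG handling.

Annotation sources (mitochondrial, sub-compartments, ETC complexes,
phosphoprotein status) are user-supplied GMT files against a declared
controlled vocabulary; nothing is hard-coded. Sub-mitochondrial and
complex labels imply the parent mitochondrial label.

## Synthetic data generator

The generator emulates the panel design: 11 bait variants plus a
TurboID-only control, ±EGF, optionally ±inhibitor, 3 replicates per group
(replicate count is a convention, configurable). Per protein, a log2
baseline ~ N(25, 2²); per bait × EGF state, an independent interactor set
(5% of proteins by default) with effects ~ N(3, 0.5²) log2 units; replicate
noise sd 0.5. The inhibitor state retains each interactor with probability
0.3, emulating the loss of interactions when the bait is locked in an
auto-inhibited conformation. Dropout is logistic in the underlying value:
P(missing) = logistic((midpoint − value)/slope), midpoint defaulting to
baseline mean − 1 sd and slope 0.5, which reproduces the hallmark of real
data that low-signal groups lose proteins entirely. Proteins receive
phosphoprotein (30%) and mitochondrial (10%, with sub-compartment and ETC
sub-labels) annotations; `interactor_bias` lets a bait draw its interactors
preferentially from a labeled class, planting compartment- or
phospho-biased ground truth.

Selection screens draw a uniform random library (Cys optionally excluded,
as display libraries often do), multinomial input reads, and selected reads
with probability ∝ exp(sharpness × true additive score); the positional
marginals of that softmax model are exactly proportional to
exp(sharpness × w), so the log-ratio estimator recovers the true matrix up
to a scale factor — Pearson r between true and rebuilt weights is the
recovery metric. Phosphosite tables mix uniform background windows with a
planted fraction sampled position-wise ∝ 2^w under the true matrices.

What the generator does **not** emulate: peptide-level acquisition,
spectral interference, shared-peptide protein inference, batch structure,
or correlated interactor sets across variants (each bait's set is drawn
independently, so synthetic k-of-n cores are small by construction).
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the declared model, not performance on any
particular real dataset.

## Calibration and numerical choices

* Hit-calling false positives among effect-free proteins run far below the
  nominal 5% because the dual cutoff compounds the p-value and fold-change
  conditions (measured ≈ 0.2% under default noise).
* The compartment-shift test is calibrated: under label-neutral simulation
  its type-I error at nominal 5% measures ≈ 5% (the acceptance suite checks
  ≤ 7% over 400 simulated contrasts; 400 keeps the Monte-Carlo standard
  error of the rate near one percentage point).
* Sensitivity/FDP of default hit calling: ≈ 0.93 / ≈ 0.03 averaged over
  seeds at 1000 proteins — properties of the default effect size (3 log2
  units) and noise, not tuned targets.
* All randomness flows through explicit integer seeds; pipeline runs spawn
  per-stage seeds from the config seed, making every output table a pure
  function of (inputs, config, seed). Problem sizes in the test and
  acceptance runs (10³ proteins, 10⁵-peptide libraries, 10⁶ reads, ≥200
  null contrasts) were chosen as the smallest sizes at which the measured
  quantities are stable; they are stated in each script.

## Known limitations

* The Welch test on singly-imputed data understates imputation uncertainty;
  a moderated/multiple-imputation variant is a natural extension.
* Percentile ranks depend on the composition of the scored site collection;
  comparisons across collections require a shared background.
* The ORA treats gene sets as flat and independent; BH across overlapping
  sets is conservative in the usual ways.
* Published hit-count reproduction requires the original per-protein
  supplementary tables, which are not redistributable with the package; the
  corresponding acceptance test documents the expected file format and
  fails (rather than skips) when the file is absent.
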