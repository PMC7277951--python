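# Methods

This note documents the models, defaults and numerical choices behind
`mzldt`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Preprocessing

**Intensity recalibration.** Each spectrum's intensities are divided by
the intensity of the peak nearest the internal standard (losartan,
*m/z* 423.169, positive mode) within a tolerance (default 0.005 Da). This
is intensity normalization only; the *m/z* axis is assumed already
calibrated by the instrument software. A missing standard is a hard error
naming the sample, because every downstream intensity comparison assumes
it. The normalizer is pluggable (`preprocess_spectra(normalizer=...)`);
total-intensity normalization is provided as an alternative.

**Alignment.** Cross-sample alignment is greedy single-linkage with a gap
cut: all peaks are pooled, sorted by *m/z*, and the sorted sequence is cut
wherever two adjacent peaks are more than `tol` apart (default 0.005 Da,
matching the search tolerance; appropriate for 1–2 ppm instruments below
*m/z* 1000). This is deterministic, independent of sample order, and
every input peak lands in exactly one feature. The consensus *m/z* is the
intensity-weighted mean of member peaks. Two peaks from one sample in one
feature are intensity-summed (vendor exports commonly split peaks). The
gap-cut rule bounds any within-feature gap by `tol`, but a chain of close
peaks can make a feature wider than `tol` overall; at direct-infusion
peak densities this is rare and accepted.

**Prevalence filter.** Features detected (intensity > 0) in fewer than 10
samples are dropped: with cohorts of tens of subjects, rarer features
cannot support the correlation computations downstream. Zeros mean "not
detected", participate in prevalence counting, and are excluded pairwise
from correlations — an absence is not a measured level.

**Isotopologue linking.** A feature is marked an isotopologue of a
lighter feature when their *m/z* spacing is within `tol` of k·1.00336 Da
(k = 1, 2; the ¹³C–¹²C mass difference) and their across-sample intensity
correlation is at least 0.7 on raw intensities (isotopologue intensities
are near-proportional to their parent, so 0.7 is conservative).
Isotopologues stay in the matrix but are excluded from identification,
which avoids double-annotating isotope peaks; the alternative of
expanding the search to M+1 masses was rejected for that reason.

## Candidate search

Features are matched to metabolites under the three singly charged
positive-mode adducts, with offsets +1.007276 ([M+H]⁺), +22.989218
([M+Na]⁺) and +38.963158 Da ([M+K]⁺) — cation mass minus one electron.
The mass tolerance (default 0.005 Da) is inclusive: an error of exactly
0.005 Da is a match. Multimers, in-source fragments and multiply charged
species are out of scope.

## Context-driven annotation

Accurate mass alone rarely identifies a metabolite — several database
entries typically fit one *m/z* within tolerance. The annotation exploits
the empirical fact that concentrations of metabolites in the same pathway
correlate across subjects. For feature *i* with candidate *c*:

- *neighbors(i)* = features whose intensity profile correlates with
  feature *i* at ≥ ρ (default 0.7), Pearson on log-transformed
  intensities, computed pairwise on samples where both features are
  detected; pairs with fewer than 10 complete observations are skipped.
- *context(c, i)* = the number of neighbor features holding at least one
  candidate that shares a pathway with *c*, each neighbor counted at most
  once. The per-neighbor cap stops one promiscuous neighbor with many
  candidates from dominating the score.
- The maximal-scoring candidate(s) with context ≥ 2 are accepted;
  requiring two independent supporting neighbors means a single
  coincidental correlation never annotates. Ties are all accepted and
  flagged ambiguous — putative (level-2) annotation tolerates
  multiplicity, and downstream projection uses each accepted id once.

Pathway co-membership (not reaction-graph distance) defines "bunched
together": it needs no reaction network, only the pathway table. Spearman
correlation is available as an option; it uses per-feature mid-ranks of
the nonzero cells ranked once, not re-ranked per pair.

## Pathway overrepresentation

A selected metabolite set *S* is projected onto the pathway table:
*k_p* = |S ∩ members(p)|. The null draws |S| metabolites uniformly
without replacement (a metabolite set has no duplicates) from the
**annotated universe** — the union of accepted annotations across the
experiment — because the null should condition on what the platform can
detect, not on the whole database (whole-database nulls are available via
the `universe` argument). R = 30,000 draws by default; per-pathway count
histograms give the null mean, sd and tail.

The representation score is the observed-to-expected fold
*s_p = k_p / max(null mean, 1/R)*; the 1/R floor keeps pathways never hit
in the null at a finite score. A ratio-type score keeps the group-level
"fold overrepresentation" (mean case score / mean control score)
interpretable as a ratio of enrichments. The scorer is pluggable; z-type
(k − mean)/sd and −log₁₀ p are the obvious alternatives. The empirical
p-value is add-one, (1 + #{draws ≥ k_p})/(R + 1), hence never exactly 0.
Empirical p-values are reported raw; a Benjamini–Hochberg column is
emitted alongside but does not enter the diagnostic score.

**Rank-sum test.** Case–control pathway scores are compared two-sided;
exact enumeration when the combined sample size is ≤ 12 with no ties,
otherwise the normal approximation with tie and continuity corrections.
Two identical constant groups give p = 1 by convention. Group scores are
means of per-sample scores (not scores of pooled group selections).

## Diagnosis

Per-subject *z* = (x − mean_controls)/sd_controls per feature, with the
sample (n−1) sd since controls are a sample of the control population. A
control subject is excluded from its own reference statistics
(leave-one-out). |z| > 1.64 — the one-sided 5% point of the normal —
selects the deviating features, which map through accepted annotations to
metabolites (a metabolite selected by several features counts once).
Features with zero control sd are skipped and logged.

The diagnostic score *D* sums the representation scores of a fixed
20-pathway panel. The PD panel ships as an editable list of pathway
names (`diagnose.PD_PANEL_NAMES`) to be mapped onto the user's pathway
table; alternatively `derive_panel` takes the cohort's top 20 by mean
case score. Classification is strict: *D* > threshold flags the pattern
(boundary behavior is a convention; the strict form is the conservative
choice). Default thresholds 12 (screening) and 340 (high confidence) are
on the original assay's score scale and should be recalibrated for other
platforms or for synthetic data. Confusion metrics use the standard
definitions, reported as rounded percentages with unrounded values
retained.

## Names cloud

Pathways scoring above a display floor (default 1.0 — the null
expectation) are drawn once each, font size proportional to √score by
default (any monotone map is acceptable; √ compresses the dynamic range
so minor pathways stay legible), top five scores in red, and a
constant-size reference glyph in the corner so clouds of different
subjects are comparable. Words are placed greedily on a seeded
Archimedean spiral with estimated bounding boxes; output SVG is
deterministic given the seed.

## Synthetic data generator

The generator produces the complete input set — peak lists, metabolite
table, pathway table, manifest — plus ground truth, so every stage is
testable without external downloads.

**Mass model.** Neutral masses sit on a 0.02 Da grid in [80, 900] Da
(minimum spacing 0.02 Da), each emitting one adduct peak (probabilities
0.7/0.2/0.1 for H/Na/K) and, with probability 0.3, a ¹³C isotopologue at
+1.00336 Da with a per-metabolite proportionality ratio in [0.05, 0.3].
Emitted *m/z* values are kept ≥ 0.011 Da apart so alignment at 0.005 Da
never merges distinct species, and carry **no measurement jitter**: peak
*m/z* equals neutral mass plus adduct offset exactly, keeping ground
truth unambiguous. For each true metabolite, two **decoy** database
entries are added at the neutral masses that match the same observed peak
through the other two adducts (cross-adduct coincidences, exact to the
search), assigned to random other pathways. Decoys emulate the
many-candidates-per-mass reality of real databases (≈ 2–3 candidates per
feature) and are what makes annotation non-trivial: mass cannot separate
them from the truth, biochemical context can.

**Intensity model.** ln I = μ_m + σ_s(√w·f_{p} + √(1−w)·g) + σ_n·e +
case effect + sample scale, with μ_m ~ U(ln 200, ln 5000), pathway factor
f shared by a pathway's members, biological signal sd σ_s = 0.4 (≈ 40%
CV, typical of plasma metabolites), within-pathway signal correlation
w = 0.8, technical noise sd σ_n = 0.15, and a per-sample global scale
with log-sd 0.25 that also multiplies the internal-standard peak (so
recalibration removes it exactly). The observed within-pathway
correlation is w·σ_s²/(σ_s² + σ_n²) ≈ 0.70 at the defaults and falls as
σ_n grows — the handle used to probe annotation robustness to noise. In
case subjects, members of the perturbed pathways (defaults: 2 of 40) have
their means multiplied by the effect size (default 3). 150 unassignable
noise peaks per sample are drawn uniformly in [50, 1000] Da at least
0.05 Da from any true signal.

**What it does not emulate:** instrument physics (peak shape, resolution
decay, mass error, ion suppression), missing values from detection
limits (every planted metabolite is detected in every sample),
correlated noise between pathways, overlapping pathway membership for
planted metabolites, and real pathway topology. Passing tests therefore
demonstrate the statistical machinery under the stated model, not
performance on real spectra.

## Problem sizes used in validation

The reference fixture is 40 pathways × 8 metabolites, 20 + 20 subjects,
2 perturbed pathways at 3-fold — large enough for stable correlation
estimates at ρ = 0.7 and a non-degenerate null, small enough for
interactive runs. End-to-end replicate checks use 2,000 permutation
draws per null: pathway *ranking* by observed/expected fold is
insensitive to R, which only sharpens the empirical p tail; the
hypergeometric calibration check runs at the production default
R = 30,000 on a toy universe. The rank-sum type-I simulation uses two
groups of 20 (the discrete exact size of the corrected normal
approximation is ≈ 0.048 there, close to nominal; at n = 10 it is a
conservative ≈ 0.044). The Z-score tail calibration uses 200 controls:
with few controls, (x − x̄)/s is t-distributed and the 1.64 tail is
inflated (≈ 6.3% at 28 controls), which is a property of the z-score
procedure itself, not of this implementation.

## Known limitations

- The alignment is a documented substitute for the original in-house
  algorithm, whose exact form is not public; likewise the context-scoring
  rule (per-neighbor-capped co-membership count) reconstructs the stated
  principle, not the original code.
- Mass-error-free synthetic peaks make the search's tolerance boundary
  untested against calibration drift; real data should use instrument-
  appropriate tolerances.
- Published performance summaries of the original assay state its
  sensitivity and specificity at the screening threshold with the two
  labels interchanged in one place (64%/86% vs 86%/64%);
  `confusion_metrics` applies the standard formulas to the confusion
  counts, which yields sensitivity 64% and specificity 86%. The
  discrepancy is documented here, not resolved.
- The detection mass range is a configuration bound (default
  [45, 1000] Da) rather than a fixed constant, because reported
  acquisition ranges for such assays vary (50–1000 vs 45–900).
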