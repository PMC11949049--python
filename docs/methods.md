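# Methods

## Overview

`consensusdeg` implements a consensus strategy for finding reproducibly
dysregulated genes across K independent tumor/normal expression cohorts.
Cohorts are never pooled: each is tested separately and a gene's evidence
is the *count* of cohorts supporting it in a consistent direction. This
trades meta-analytic efficiency for robustness to platform and cohort
heterogeneity — a gene called in ≥ m of K independent datasets is unlikely
to be a single-cohort artifact. Downstream layers (tissue specificity,
subtype/proliferation association, survival, screen essentiality) are all
expressed as set logic over per-layer calls, mirroring how such evidence is
combined in practice.

## Per-cohort differential expression

Input matrices are log2 scale. Optional preprocessing: quantile
normalization (each column replaced by the rank-wise across-column means;
within-column ties get the mean of their rank-slot values via fractional
ranks) and probe collapsing (arithmetic mean of probe rows per gene;
unmapped probes dropped).

The two-group test is a moderated t. For gene g with pooled residual
variance s²_g on d degrees of freedom, the ensemble of variances is modeled
as s² ~ s₀²·F(d, d₀). The prior (d₀, s₀²) is estimated by
method-of-moments on e_g = log s²_g − ψ(d/2) + log(d/2): the excess of
Var(e) over ψ′(d/2) determines d₀ through a trigamma inversion (Newton
iteration), and the mean of e determines s₀². If the moment estimate is
non-positive — as happens when the data are genuinely homoskedastic, which
the default synthetic generator is — the implementation falls back to d₀ =
∞ (every gene uses s₀², t referred to a normal) with a logged warning.
Posterior variances are s̃² = (d₀s₀² + d s²)/(d₀ + d) and t̃ = Δ/(s̃·c) has
d + d₀ degrees of freedom, where Δ is the mean difference and c² = 1/n_A +
1/n_B (paired designs test within-pair differences one-sample, c² = 1/n,
d = n − 1). `prior_df` can be forced: 0 recovers the ordinary pooled t
(verified exactly against scipy), ∞ the common-variance limit. The
implementation agrees with the Bioconductor limma reference to ~1e−5
relative on heteroskedastic data (tested via Rscript).

Degenerate genes with zero sample variance receive the smallest positive
observed variance before shrinkage, keeping t finite without distorting the
ranking; if *every* gene is degenerate (identical compared samples) unit
variance is substituted so that Δ = 0 yields t = 0, p = 1.

Multiple testing uses Benjamini–Hochberg step-up (the conventional default
for expression screens), implemented directly and verified against both the
literal step-up definition and statsmodels. Direction calls: up iff
p_adj < α and Δ > 0; down iff p_adj < α and Δ < 0; else ns. The discovery α
is 0.05 (adjusted); the epithelium/stroma contrast uses 0.01 (adjusted);
stratum contrasts use raw p < 0.05 — three independently configurable
cutoffs, reflecting that the consensus layer already controls
reproducibility for stratum overlaps.

## Consensus calling and rank score

Support is counted over all K cohorts; a gene missing from a cohort's
platform contributes nothing there, so a gene absent from ≥ K − m + 1
platforms can never reach primary support (this designed-in exclusion
matters for interpreting recovery rates; see below). Classes: CUG iff
n_up ≥ m, CDG iff n_down ≥ m, with m > K/2 enforced so the classes are
exclusive. Genes reaching only the secondary level (default m − 1) form a
lower-confidence tier without a class; genes secondary in *both* directions
are flagged discordant and excluded.

The rank score sums, over cohorts, log2FC × (−log₁₀ p) with p floored at
1e−300 and raw p by default (adjusted p and the log base are configurable;
a rank-sum variant — summing within-cohort ranks of the per-cohort
components — is provided for users who prefer rank aggregation). The score
is odd under global sign flips and monotone in |log2FC| at fixed p and in
−log p at fixed log2FC. Top-gene extraction sorts CUGs by descending (CDGs
by ascending) score with alphabetical tie-breaks, logged.

Concordance against an independent cohort is the fraction of CUGs (CDGs)
that are significantly up (down) there, restricted to genes on the
independent platform, reported with numerator and denominator.

## Tumor specificity

Tissue panels are reduced to one aggregate value per tissue. A panel votes
"pancreas-low" for a gene when the pancreas value is *strictly* below the
across-tissue median of that panel (strictly above, for the CDG-mirrored
test). The criterion depends only on within-panel ranks, hence is invariant
to monotone per-panel transformations — important when panels come from
heterogeneous sources (protein atlases, RNA-seq consortia, microarrays).
The "low in normal pancreas" notion has no canonical definition; the median
criterion is the most assumption-free choice and min_votes (default 2 of 3)
buffers single-panel quirks.

Categories for CUGs: core_tumor_specific (≥ min_votes AND
epithelium-high in the paired compartment test), epithelium_only,
normal_low_only, none — an exhaustive, disjoint partition verified against
truth-table enumeration; mirrored for CDGs (pancreas-high, stroma-high).

## Stratification

Signature scores are per-sample means of per-gene z-scores over the
signature genes present (zero-variance genes excluded, logged). Subtype
assignment is score-argmax between the basal-like and classical signatures;
exact ties go to classical with a warning — argmax was chosen over
consensus clustering for determinism and auditability. Proliferation and
expression-based cell-line strata use a median split: strictly above the
median is "high", median-tied samples go "low"; when ties place the median
at the maximum the cut falls back to ≥ median so both strata stay populated
on any non-degenerate input (all-identical scores are an error).

Stratum overlap counts, per gene and direction, cohorts whose contrast has
raw p < α with the matching fold-change sign; "qualified" requires the
configured support (2 by default; 1 for single-cohort contrasts such as
metastasis, grade or mutation comparisons). Over-representation of a gene
list in GMT sets uses the upper-tail hypergeometric probability
P(X ≥ k) with BH across sets; sets are intersected with the analysis
universe first.

## Survival

Per gene and cohort: samples are median-split on expression (shared split
convention as above), each group summarized by the product-limit estimator,
groups compared by the log-rank test (χ² = (O−E)²/V with the hypergeometric
variance summed over distinct event times, 1 df), and the gene fit as a
continuous covariate in a univariate Cox model. The Cox fit maximizes the
Breslow partial likelihood by Newton–Raphson (internally standardized
covariate, tolerance 1e−8, ≤ 25 iterations); diverging |β| raises a
convergence error with the iteration trace (monotone likelihood /
perfect separation). Breslow tie handling was chosen as the simplest
correct default; with continuous times it coincides with Efron, and the fit
matches lifelines to ~1e−5. The score test at β = 0 equals the log-rank
statistic for a binary covariate with distinct event times (verified to
1e−6). The worse-outcome direction label comes from the KM group medians,
falling back to the Cox β sign when a median is undefined. The cross-cohort
summary counts cohorts with log-rank p < 0.05 per direction and flags genes
significant in ≥ 3 and in all cohorts.

## Priority targets

Per screen, a gene is essential when its dependency score passes the
screen's threshold in ≥ 50% of measured lines — ≤ −0.5 for CERES-like
screens (negative = essential), ≥ 0 for scaled-Bayes-factor screens
(positive = essential); thresholds and the line fraction are configurable
because no single criterion is standard across screen types. The
interference consensus is CUGs essential in ≥ 3 of 4 screens. The
multi-criteria set is CUGs that are pancreas-low (≥ 2 votes) AND
proliferation-upregulated (qualified) AND (basal-like-upregulated OR
survival-predictive, worse-when-high, in ≥ 1 cohort); the union of both
sets is the priority list, with per-gene provenance flags. Drug-response
stratification scores cell lines by mean z over the priority genes,
median-splits them, and compares each drug's sensitivity between groups
with a two-sided rank-sum test (robust at the small line counts typical of
a single tumor type) and BH across drugs.

## Synthetic data generator

The generator emulates the study design, not microarray physics. Defaults
(the study conditions): K = 5 discovery cohorts plus 1 independent
validation cohort, 2,000 genes, per-gene baseline ~ N(7, 2) log2 units
(quantile-normalized-intensity-like), 200 planted up + 200 down genes with
per-cohort effect |N(1.5, 0.3)| log2 units of consistent sign, 100
inconsistent genes (random sign per cohort), sample noise N(0, 1), 40
tumors + 40 normals per cohort, and 10% of genes dropped uniformly per
cohort (platforms differ in gene content). Tumor samples carry latent
structure: half basal-like / half classical (disjoint 25-gene signatures
from the planted up set, +1 log2 in the matching cluster) and a
proliferation axis (10 marker genes, slope 0.8 per latent unit). The
latent proliferation mean is +1 in basal-like tumors
(`proliferation_subtype_coupling`): with independent axes the conjunctive
priority rule would be unsatisfiable by construction, whereas in real
tumors the aggressive subtype is also the proliferative one — the coupling
is what makes the multi-criteria rule exercisable.

Further layers: 3 tissue panels (pancreas + 11 tissues) where 60% of
planted up genes sit strictly below the across-tissue minimum for pancreas
(mirrored for down genes); 65 epithelium/stroma pairs with a N(0, 0.7)
shared pair effect and half of the planted up (down) genes elevated in
epithelium (stroma); 4 dependency screens (24/24/8/20 lines, the last a
Bayes-factor screen) with 60 essential genes active in 3–4 screens and 30
non-CUG "common-essential" genes active in all (these exercise the CUG
restriction); survival tables with exponential event times, log-hazard
linear in the standardized expression of 10 prognostic genes (β = 0.7),
baseline rate 1/500 per day and independent exponential censoring
calibrated to a 30% marginal censoring probability; and a 16-line × 8-drug
response table with 2 drugs more effective in the high-expressing lines.

Reproducibility: one global seed expands to per-operation substreams via
`default_rng([OP_CODE, seed])` with fixed codes (survival additionally
hashes the cohort name with CRC-32), so adding operations never perturbs
existing streams; identical config + seed gives byte-identical files.

What the generator does *not* model — and hence what passing tests do not
show about real data: probe-level effects, batch and lab effects,
normalization failures, correlated gene modules beyond the planted axes,
non-proportional hazards, informative censoring, and realistic screen
noise structure (off-target effects, copy-number artifacts). Recovery
rates on synthetic data are upper bounds on real-data behavior.

## Interpreting recovery under dropout

With 10% per-cohort dropout and a 4-of-5 support rule, the probability a
planted gene is even *testable* (present on ≥ 4 platforms) is 0.918; genes
absent from 2+ platforms are excluded by the method's definition no matter
how real their signal. Recovery is therefore reported two ways: among all
planted genes (≈ 0.90, dominated by designed-in missingness) and among
testable planted genes (≈ 0.99, the testing machinery's sensitivity). The
false-discovery proportion against the planted truth is ≈ 0.07 at the
defaults.

## Numerical and edge-case conventions

* Score p-values floored at 1e−300 before logs; p = 0 never produces ±inf.
* Quantile normalization requires finite values and ≥ 2 columns.
* `NA` cells in input TSVs drop the gene from that cohort's universe; a
  bare `.` (or any other non-numeric token) is an error naming the gene
  and sample.
* Gene identifiers are case-sensitive symbols; no alias resolution.
* Survival input requires positive times and binary events; Cox requires
  ≥ 10 samples, ≥ 3 events, non-constant expression.
* All output tables are written with `%.10g` floats in sorted order so
  repeated runs are byte-identical; `run.log` (timings, hashes) is the one
  intentionally non-reproducible output.

## Known limitations

Single-factor designs only (no covariate adjustment or array weights);
no meta-analytic effect pooling (the count rule ignores effect-size
magnitude across cohorts); no GSEA-style weighted enrichment (ORA only);
subtype assignment assumes the two signatures are comparable after
z-scoring; the survival module is univariate by design.
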