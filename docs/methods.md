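# Methods

This note documents the models, numerical choices and known limitations of
the `sterolome` package, in the order data flows through it.

## Mass spectrometry model

Sterols ionise under APCI predominantly as the dehydrated protonated ion
[M − H₂O + H]⁺, so a neutral sterol C_cH_hO is observed as the cation
C_cH_(h−1). All theoretical masses are monoisotopic sums (C 12.000000,
H 1.0078250319, D 2.0141018, O 15.9949146 Da) minus one electron mass
(0.00054858 Da) for a +1 cation; a radical cation such as the fluoranthene
lock mass keeps its hydrogen count as given.

**Composition grid.** Accurate-mass decomposition searches carbons
c ∈ [26, 32] and double-bond equivalents beyond the four fused rings
d ∈ [0, 7] for the cation C_cH_(2c+1−2(4+d))⁺. At the default 3 ppm
tolerance the grid is unambiguous and decomposition exactly inverts
composition (a property test covers the whole grid); when two grid points
ever fall inside a wider tolerance the closer one is returned with an
ambiguity flag and a logged warning.

**Annotation levels.** Level 1 requires both mass (ppm tolerance, default
3) and retention time (default 0.1 min) to match an authenticated
reference; a feature matching several references resolves to the nearest
retention time. Everything else gets a level-2 `ST(c:d)` code from the
grid; isomer groups sharing (c, d) receive letters in ascending
retention-time order — the assay itself fixes no lettering rule, so
retention-time order was chosen as the deterministic, reproducible one.
All window bounds are inclusive.

**Quantification.** Per sterol,
mg/kg = MW × signal × n_IS × 10⁶ / (weight_mg / 1000), with
signal = analyte area / internal-standard area and n_IS = 5.08 nmol of
d₇-cholesterol by default. Level-1 analytes use the reference's
monoisotopic mass; level-2 analytes use the mass implied by their (c, d)
composition, so un-named sterols still contribute to the total (they can
be excluded by omitting their masses). Samples whose IS is missing or
zero are excluded with a logged reason.

**QC and blanks.** The QC rule retains a variable only when the Pearson
correlation between nominal dilution load (1.0/0.5/0.25) and its
IS-normalised signal is ≥ 0.75; a variable absent from, or constant
across, the QC series has an undefined correlation and is discarded. The
intent of blank subtraction is stated by the assay design but no explicit
rule; this package uses a 3× median rule (feature kept only if its median
sample signal is at least 3× its median blank signal), with the factor
configurable. Blank comparison runs on raw areas because method blanks
carry no internal standard in the simulated design.

## Compositional statistics

Proportions live on the 0–1 scale everywhere inside the package;
percentages appear only in presentation. Outlier screening uses raw
proportions (a sample is removed when its minimum Bray–Curtis
dissimilarity to every other sample exceeds 0.5), while ordination-bound
dissimilarities are computed from arcsine-square-root transformed
proportions — two distinct code paths, both exposed. Taxon means are
arithmetic means of per-sample proportions renormalised to 1, guarding
against per-sample rounding drift. Simpson diversity defaults to
taxon-mean inputs (sample-level inputs are available by calling it on the
sample table). Dominance ranks by descending proportion with alphabetical
tie-break; the single-sterol dominance flag fires at ≥ 65 %.

## Ordination and permutation tests

**NMDS** minimises Kruskal stress-1,
√(Σ(d_ij − d̂_ij)² / Σ d_ij²), alternating isotonic regression of
configuration distances on the input dissimilarities (ties averaged — the
primary approach) with Guttman majorization steps. A principal-coordinate
seeded start is always tried first — it lands exactly on perfect
embeddings — followed by random restarts (200 by default, as in standard
ordination practice); dimensionality escalates from k = 2 only while
stress exceeds 0.2. Stress is reported for the best configuration;
coordinates are centred. Degenerate input (all points identical) is an
error.

**PERMANOVA** partitions SS_total = Σ_{i<j} d²_ij / n into within- and
between-group components; pseudo-F = (SS_B/df_B)/(SS_W/df_W) and
R² = SS_B/SS_total. The permutation p-value shuffles group labels and
uses the (1 + b)/(1 + m) estimator so p is never 0; 999 permutations by
default. Pairwise contrasts run PERMANOVA on each group pair's submatrix
with Benjamini–Hochberg adjustment. The dispersion test embeds the
dissimilarities by principal coordinates, measures each sample's distance
to its group centroid (squared contributions of negative-eigenvalue axes
subtracted, clipped at zero) and applies a one-way F with a permutation
p-value; the group-centroid variant is implemented, not the spatial
median.

**IndVal** for single groups only: A (specificity) = group mean abundance
/ sum of group means, B (fidelity) = within-group occurrence fraction,
stat = √(A·B) ∈ [0, 1] with Σ_g A = 1 per variable. Each variable's
p-value attaches to its best group by permuting labels and comparing
maximum-group statistics. The "strong association" convention for biplots
is exposed as a threshold (default |stat| > 0.7); whether biplot arrows
should come from the IndVal statistic or from axis correlations is left
to the caller — both quantities are available.

**Kruskal–Wallis** uses the rank-sum H with tie correction
1 − ΣT/(N³ − N); Dunn z-statistics use tie-corrected variance
(N(N+1)/12 − ΣT/(12(N−1)))(1/nᵢ + 1/nⱼ) with two-sided normal p-values,
BH-adjusted across pairs. All-identical data returns H = 0, p = 1.

## Phylogenetic signal

With phylogenetic covariance C (C_ij = shared root-to-MRCA path length;
any stem edge above the root is ignored):

* **Blomberg's K** = (MSE₀/MSE) / [(tr C − n/(1ᵀC⁻¹1))/(n−1)], with the
  phylogenetic mean â = (1ᵀC⁻¹z)/(1ᵀC⁻¹1), MSE₀ the ordinary and MSE the
  C⁻¹-weighted residual mean square. K = 1 on a star tree for any trait,
  and ≈ 1 on average under Brownian motion. Inference is by tip-shuffling
  permutation of K itself (999 by default), p = (1 + b)/(1 + m).
* **Pagel's λ** scales the off-diagonal of C; the likelihood is a
  multivariate normal with â(λ) and the Brownian rate σ² profiled out,
  maximised by bounded scalar optimisation (tolerance 1e-6) over
  [0, λ_max], where λ_max is the largest multiplier keeping C(λ) positive
  definite, found by bisection and capped at 3 (not fixed at 1). Reported
  λ̂ may exceed 1; a display value capped at 1 is provided alongside. The
  p-value is a likelihood-ratio test against λ = 0 on a χ²₁ reference;
  the 50:50 boundary-mixture correction is available as an option but off
  by default, since the plain χ²₁ is the conservative, conventional
  choice. Both estimators were cross-checked against an independent ML
  implementation (phytools) and agree to ≥ 4 decimals on shared fixtures;
  those values are frozen into the test suite.

Traits enter the screen as untransformed proportions; per-sterol traits
must exceed a 1 % maximum proportion to be screened, while total sterol
content (mg/kg) and the class-sum traits are always included. Constant
traits are skipped with a warning. Tips absent from the trait table are
pruned; genus-level units lacking species identity are expected to be
excluded by the caller before screening.

Tree preparation applies rename rules in order (synonyms,
subspecies→species, hybrid→parent, congeneric substitutes), refusing a
congeneric substitution whenever the genus already holds a directly
matched species, then prunes to the placed taxa and reports the rest as
unplaced. Family monophyly is classified per family as monophyletic /
not monophyletic / singleton from the smallest containing clade.

## Synthetic data generator

The generator emulates the study design, not the instrument physics:

* **Tree**: birth–death process (default birth 1.0, death 0.0)
  conditioned on tip count via the general sampling approach, which
  avoids the zero-length terminal cherry of cutting exactly at the n-th
  speciation and keeps C comfortably positive definite.
* **Compositions**: latent traits evolve as zero-mean Gaussians with
  covariance σ²C(λ) — off-diagonals scaled by the target λ — and are
  mapped to the simplex by a per-taxon softmax. Simulating on the latent
  scale and transforming is the standard way to get valid compositions
  with controllable signal; the softmax warps λ slightly on the
  proportion scale, which is why estimator calibration (the acceptance
  checks) runs on the latent traits directly.
* **Areas**: area = per-sterol mg/kg × (weight/1000) / (MW · n_IS · 10⁶)
  × IS_area × ε, with ε mean-one lognormal at coefficient of variation
  `noise_cv` (default 0.15, a typical LC–MS area CV; the source assay
  states no per-sample noise magnitude). At noise_cv = 0 the
  quantification formula inverts the generator exactly — verified to
  1e-9 relative — *provided the detection threshold does not truncate
  trace components*; the algebraic round-trip test therefore runs with
  the area threshold disabled, and a companion test verifies that with
  the threshold active the recovered total equals the truth restricted
  to detectable components.
* **Sample weights** are uniform on 9.5–16.5 mg, the realistic range for
  hand-collected pollen aliquots.
* **QC/blanks**: QC samples carry the pooled-stock profile at relative
  loads 1.0/0.5/0.25; blanks carry only two background features (one on
  the sterol composition grid, one off it) and no internal standard.
* **Bee samples**: Dirichlet draws around a configurable mean six-sterol
  composition (default cohort size 18). The shipped default bee mean is a
  synthetic stand-in — the published prepupal measurements are not
  reprinted in the package — constructed so every component lies strictly
  above its sufficiency threshold, consistent with the thresholds having
  been set below the bee means.

What the generator does **not** model: chromatographic peak shapes,
isotope patterns, retention-time drift, ion suppression, missing-at-random
dropout, or compositional zeros from true absence vs. non-detection.
Passing tests demonstrate the pipeline's internal consistency and the
estimators' calibration under the stated noise model, not robustness to
those real-data artefacts.

## Problem sizes and determinism

The test suite runs its heavier calibrations on one 100-tip tree with
30–60 trait replicates, and the acceptance script uses 100 replicates —
sizes at which the Monte-Carlo error of mean λ̂ and mean K is comfortably
inside the documented ±0.1 / ±0.15 recovery bands. Every stochastic stage
(tree simulation, trait simulation, permutation tests, NMDS restarts)
takes an explicit seed and logs it; a fixed seed makes the full pipeline
byte-identical, which the suite asserts on the JSON result document.

## Known limitations

* No MS/MS evidence is used; isomers are separated only by retention time.
* The QC "ratio" rule is implemented as a Pearson correlation threshold
  between nominal load and signal, which is how the dilution-series
  design reads most naturally; a fold-change interpretation would need a
  different QC design.
* PERMANOVA assumes exchangeability under the null; with strongly
  heterogeneous dispersions (flagged by the dispersion test) location
  p-values are confounded.
* The λ likelihood surface can be flat on small trees (< ~20 tips);
  estimates there are reported but weakly identified.
* The linear mixed-effects modelling of site effects on totals is out of
  scope; only descriptive per-county summaries can be assembled from the
  metadata.
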