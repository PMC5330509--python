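# Methods

This note documents the models implemented in `isotroph`, the conventions
chosen where the underlying field practice is genuinely ambiguous, and what
the synthetic-data generator does and does not emulate.

## Isotope deltas and normalization

Isotopic composition is expressed in delta notation,
δ = ((R_sample − R_standard)/R_standard) × 1000 (‰), with R the
heavy/light ratio (¹³C/¹²C against V-PDB, ¹⁵N/¹⁴N against atmospheric N₂).
Instrument linearity errors are corrected by two-point normalization: for
each isotope independently, the unique line mapping the measured deltas of
two in-house standards onto their known values is fitted and applied to all
samples. By construction the model returns the known standard values
exactly; a degenerate fit (identical measured standards) is an error.
Run-order drift correction is out of scope — inputs are assumed
drift-stable, since per-run sequence data are rarely archived alongside
published deltas.

Ethanol preservation of liver tissue can inflate δ¹³C by roughly 1.5‰; the
configuration exposes `ethanol_d13C_offset` (default 0, i.e. off) which is
subtracted from every δ¹³C before analysis, leaving δ¹⁵N untouched.

## Species summaries and trophic transfers

Per species and site: mean and max−min range of each isotope over
individuals (range 0 for singletons). The community range is the spread of
the *species means*, not of individuals. Trophic transfers between two
δ¹⁵N values are (high − low)/enrichment, with enrichment 2.5‰ per transfer
by default (2.54‰ as the common meta-analytic alternative); levels spanned
is transfers + 1. Whether a "levels spanned" statement should use species
means or individual extremes is ambiguous in field usage; both are
available (`trophic_transfers` on any pair of values), and the pipeline
reports the species-mean version by default.

Display rounding is 2 decimals; all computation keeps full precision.

## Weighted trophic rank

WTR = Σᵢ pᵢTᵢ over the prey categories a species eats, ranks on the 1–5
coding (1 producer; 2 primary grazer; 3 omnivorous consumer; 4 predator of
omnivores; 5 predator of vertebrates), with midpoints (e.g. 3.5 for
spiders and centipedes) for higher taxa spanning two adjacent ranks.
Published percent-stomach-volume rows rarely sum exactly to one, so
proportions are renormalized to sum 1 by default and the result records
which convention produced it (`normalized` flag). Species below the
minimum sample size (5 stomachs by default) are excluded from diet
analyses.

The bundled 63-category coding CSV is a **reconstruction**: only exemplar
ranks are published for this system, so the remaining categories were
assigned once from the scheme's definitions and are user-editable. Rank
concordance between δ¹⁵N ordering and WTR is product-moment correlation
with a two-sided t-based p (a rank-based option exists); the bundled
diet-summary table carries the published WTR values as data because they
are not reconstructible from the published marginals alone.

Diet-space distance is the Euclidean distance between species' proportion
vectors, optionally restricted to a category subset (the termite-only
analysis uses `["Isoptera"]`). Whether raw or transformed proportions
should enter this distance is unstated in field practice; raw mean
proportions are used.

## Habitat scores

A species' raw score for each of the 14 trap-level variables is the
unweighted mean over the *distinct* traps where it was captured (a trap
caught ten times counts once); a capture-weighted mode exists. Transforms
(log, logit, arcsine-square-root) are selected per variable by the highest
Shapiro–Wilk W of the transformed species means; logit and arcsine-√ are
only offered for variables representable on [0, 1] (percent covers are
scaled by 100); ties break in the fixed order log > logit > arcsine-√, and
identity ("none") is used when no transform is admissible. Zeros (and ones,
for logit) are shifted by half the smallest nonzero observed value before
log/logit; the shift is recorded.

Habitat distance is Euclidean over the transformed matrix, with columns
z-scored by default because the 14 variables mix percentages, counts and
volumes; a constant column is then an error. Whether the original field
analyses standardized before computing distances is not recoverable, so the
flag makes both conventions reproducible.

## Mantel machinery

The Mantel statistic is the product-moment correlation between the
strictly-lower triangles of two species distance matrices on a shared
label order. The null jointly permutes rows and columns of the second
matrix; p = (1 + #{permuted r ≥ observed})/(n_perm + 1), so the identity
permutation is always counted and p ≥ 1/(n_perm + 1). The default tail is
**upper** (positive association): a strongly negative observed r therefore
yields p near 1, which is the convention consistent with reporting p = 0.98
for r = −0.35. Lower and two-sided tails are available. 999 permutations
by default, all draws from one seeded generator per call.

The "three-way" test is implemented as a partial Mantel: r₁₂·₃ =
(r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²)) over lower triangles, with the third
matrix controlled linearly. Phylogenetically informed nulls use restricted
permutations: starting from the identity, n sequential pair swaps where the
first index is uniform and its partner j is drawn with probability
∝ 1/(d_patristic(i, j) + δ), δ = 0.1 × mean off-diagonal patristic
distance. Closely related species thus trade places readily while distant
ones rarely do, which preserves phylogenetic autocorrelation under the null
and makes the test conservative relative to free permutation when both
matrices inherit tree structure (verified as a rejection-rate ordering in
the test suite). The exact permutation algorithm used in earlier published
analyses of this system is not described in print; this scheme is the
package's own documented choice, and its p-values should be compared
qualitatively, not digit-for-digit, with such analyses. Passing the
patristic distance matrix itself as the control matrix combines both forms
of phylogenetic control.

For n ≤ 7 an exact p by full enumeration of all n! relabelings is
available and serves as the oracle for the permutation implementation.

## Pagel's λ

The trait is modelled as multivariate normal with mean μ·1 and covariance
σ²·C(λ), where C is the shared branch-length (Brownian-motion) matrix and
C(λ) multiplies its off-diagonal by λ ∈ [0, 1]. μ and σ² are profiled
analytically by GLS; λ is maximized on a 1001-point grid followed by
bounded scalar refinement. On ultrametric trees C(λ) = λC + (1−λ)T·I
shares C's eigenvectors, so a single eigendecomposition serves every λ
(non-ultrametric trees fall back to a Cholesky per λ). A tiny ridge
(10⁻⁹ × mean tip depth) keeps the covariance factorizable when near-zero
terminal branches make tips almost collinear; it is identical at every λ
and cancels from likelihood comparisons.

The likelihood-ratio test against λ = 0 uses χ²(1), matching the common
package convention for this boundary test; the conservative 50:50
point-mass/χ² mixture is available by flag. Estimates below 10⁻³ are
flagged "effectively zero" — external optimizers bounded away from zero
report values of magnitude ~10⁻⁵–10⁻⁴ in exactly these cases (the
implementation was cross-checked against an independent R implementation
to 4–5 decimals, including such boundary cases).

## Univariate tests

The species × site ANOVA uses sequential (type-I) sums of squares with
species entered first, computed by nested least-squares fits, so it
handles the unbalanced design in which most species occur at one site
only: the interaction automatically carries just the degrees of freedom
the observed cells support (e.g. 14 species, 2 sites, 7 shared species →
df 13, 1, 6). Welch's one-way F uses the standard unequal-variance
formula with Satterthwaite-type denominator df; Bartlett's K² and Welch's
t come from scipy; between-site correlation is Pearson's r with an
optional leave-one-out report that names the single species whose removal
maximizes |r| (an influence diagnostic for outlier species).

## Synthetic communities

The generator plants known structure so every stage is testable
end-to-end:

* **Tree** — pure-birth with the requested number of tips, rescaled to
  unit depth (a stand-in for a time-calibrated phylogeny).
* **Trophic positions** — Brownian motion with λ-scaled covariance
  (`lambda_true`, `sigma2_true`), mapped into [1.5, 4.5] by
  3 + 1.5·tanh(z/2σ) — near-linear over ±2σ so phylogenetic signal is
  essentially preserved through the map.
* **Diets** — a Gaussian kernel over category ranks centred on the
  position, exponentially tilted so the kernel's expected rank equals the
  position *exactly*, then a Dirichlet draw with concentration 50 around
  that mean. E[WTR] therefore equals the planted position, which is what
  the recovery tests exploit.
* **Isotopes** — species mean δ¹⁵N = baseline + enrichment × (position −
  1) with enrichment 2.5‰; species mean δ¹³C mixes C3 (−27‰) and C4
  (−13‰) baselines through a latent habitat preference restricted to the
  central half of the interval (consumers integrate both pathways), giving
  species-mean spreads of roughly 5–8‰ (δ¹⁵N) and 4–7‰ (δ¹³C) under the
  defaults — the magnitudes observed in the field tables. Individuals
  (2–20 per species) are normal around species means with
  `within_species_sd` = 1‰.
* **Habitat** — 928 traps by default, one latent spinifex-vs-*Acacia*
  axis driving several of the 14 variables, species capture placement
  weighted by a preference correlated with species δ¹⁵N at
  `habitat_coupling` (default 0.9); the remaining variables are noise.

Everything is driven by one scenario seed through deterministically
spawned child streams, so a fixed seed reproduces every file byte-for-byte.

What the generator does **not** emulate: spatial autocorrelation among
traps, fire-succession dynamics, between-site baseline shifts in δ¹⁵N,
prey-specific fractionation, measurement error in stomach-volume
estimation, and non-Brownian trait evolution. Passing tests therefore
demonstrate statistical correctness and calibration of the machinery under
the stated generative model, not ecological realism of any particular
field system.

## Problem sizes used in validation

The test suite and acceptance script validate at sizes chosen to make
Monte Carlo error small relative to the properties asserted: Mantel
exactness at n = 4 against full 24-permutation enumeration; type-I error
over 2000 null datasets (8 species, 199 permutations, exact 0.05 test
level); λ recovery on 128-tip trees (400 replicates in the suite, where
the Monte Carlo margin matters; 100 in the quicker acceptance script); WTR
recovery over 200 Dirichlet draws; and power at coupling 0.9 over 100
replicates of 30-species communities with 200 traps.

## Known limitations

* The restricted-permutation null is a documented stand-in for an
  undescribed published algorithm; treat its p-values as scheme-specific.
* The λ LRT at the boundary uses plain χ²(1) by default, which is
  anti-conservative relative to the mixture reference.
* Two-point normalization assumes the two standards bracket the samples;
  extrapolation is silent.
* Habitat transform selection scores normality only; it does not consider
  variance stabilization or interpretability.
* The 63-category trophic coding is a reconstruction and should be edited
  to match any real dataset's category definitions before use.
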