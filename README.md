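# isotroph

Community stable-isotope trophic ecology for terrestrial vertebrate
assemblages — built around the analysis of a hyper-diverse arid-Australian
skink community (genera *Ctenotus*, *Lerista*, *Eremiascincus*) sampled at
two Great Victoria Desert sites, Lorna Glen and Yamarna.

The package is aimed at ecologists who have per-individual δ¹³C/δ¹⁵N
measurements, stomach-content proportions, trap-level habitat data and a
time-calibrated phylogeny, and want to ask: are species differentiated in
isotopic space, does that differentiation track diet and habitat, and does
it carry phylogenetic signal?

## What it computes

* **Deltas and normalization** — isotope ratios expressed in per mil,
  δ = ((R_sample − R_standard)/R_standard) × 1000, with two-point standard
  normalization (the unique line mapping two measured in-house standards
  onto their known values) and an optional ethanol-preservation δ¹³C
  correction.
* **Species and community summaries** — per-species means and max−min
  ranges per site; community range as the spread of species means; trophic
  transfers implied by a δ¹⁵N difference at a fixed enrichment
  (Δδ¹⁵N / 2.5‰ per transfer by default).
* **Weighted trophic rank (WTR)** — Σᵢ pᵢTᵢ over prey categories, where pᵢ
  is the proportion of category *i* in the diet and Tᵢ its trophic rank on
  a 1–5 coding (1 producer … 5 predator of vertebrates, midpoints for
  ambiguous higher taxa), plus diet-space Euclidean distances (optionally
  termite-only).
* **Habitat scores** — per-species means of 14 trap-level habitat
  variables over the distinct pitfall traps where the species was caught,
  per-variable log/logit/arcsine-√ transforms selected by Shapiro–Wilk
  normality, and habitat-space distances.
* **Comparative tests, from first principles** — Mantel tests (lower
  triangle product-moment r, joint row/column permutation null, upper-tail
  p by default), partial and phylogenetically permuted Mantel (restricted
  pair swaps with probability ∝ 1/(patristic distance + δ)), and Pagel's λ
  by maximum likelihood (GLS-profiled mean and rate, λ grid + bounded
  refinement on [0, 1], likelihood-ratio test against λ = 0).
* **Classical tests** — sequential-SS two-way ANOVA on unbalanced
  species × site designs, Welch one-way F, Bartlett's K², Welch's t,
  between-site Pearson correlations with leave-one-out influence.
* **Synthetic communities** — pure-birth trees, trophic positions evolving
  under λ-scaled Brownian motion, Dirichlet diets whose expected WTR equals
  the planted position, isotope means from enrichment and C3/C4 mixing, and
  trap/capture tables with a tunable habitat–isotope coupling.

## Worked example

The package ships the published per-site species summary tables. Feeding
the species means back through the summary machinery reproduces the
community ranges, and correlating δ¹⁵N ordering with weighted trophic rank
shows the reported mismatch between isotopic and stomach-content trophic
estimates:

```python
from isotroph import IsotopeMeasurement, summarize_species, rank_concordance
from isotroph.datasets import load_species_isotope_means, load_diet_summary

df = load_species_isotope_means()
sub = df[df.site == "Lorna Glen"]
ms = [IsotopeMeasurement(r.species, r.species, "Lorna Glen", r.mean_d13C, r.mean_d15N)
      for r in sub.itertuples()]
s = summarize_species(ms, "Lorna Glen")
print(f"range d15N={s.community_range_d15N:.2f} d13C={s.community_range_d13C:.2f}")

diet = load_diet_summary().dropna(subset=["mean_d15N_lorna_glen"])
c = rank_concordance(diet.mean_d15N_lorna_glen.to_numpy(),
                     diet.weighted_trophic_rank.to_numpy())
print(f"concordance r={c.r:.2f} p={c.p:.2f} n={c.n}")
```

prints

```
range d15N=7.60 d13C=4.61
concordance r=-0.20 p=0.70 n=6
```

i.e. the nine Lorna Glen species means span 7.60‰ in δ¹⁵N (≈ 3 trophic
transfers at 2.5‰ per transfer, so 4 levels) and 4.61‰ in δ¹³C, while the
δ¹⁵N ordering of the six diet-sampled species is uncorrelated with their
stomach-content trophic rank.

The command line runs the same stages over files:

```bash
isotroph --seed 7 --out-dir demo simulate --n-species 30
isotroph --seed 7 --out-dir demo run-all demo
```

which writes a complete synthetic dataset (isotopes.csv, diet.csv,
coding.csv, traps.csv, captures.csv, tree.nwk, truth.json) and then
results.json with summaries, WTR, Mantel and phylogenetically permuted
Mantel tests, Pagel's λ for both isotopes, and a run report recording seed
and configuration. On that scenario (habitat coupling 0.9) the
habitat–isotope Mantel test gives r = 0.64, p = 0.001, and λ for species
mean δ¹⁵N is ≈ 1.0.

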