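# Methods

## The question and the pipeline

Eukaryotic transcription and translation are decoupled, and mRNA and protein
abundances measured in the same cell line correlate only moderately.  This
package treats a panel of cancer cell lines as entities with a shared origin
and divergent histories, and the ten cancer hallmarks as *tasks* each cell
may specialize in.  The pipeline quantifies, per cell line:

1. **Concordance** — correlations between each cell's mRNA profile and each
   cell's protein profile over the shared gene universe.  Diagonal entries of
   this cells x cells matrix are same-cell correlations; off-diagonal entries
   measure how much concordance is generic rather than cell-specific.
   Correlations are recomputed within each hallmark set and compared with a
   random gene set.
2. **Enrichment** — for each cell and modality, gene products are ranked by
   abundance and each hallmark's enrichment score (ES) is the signed extreme
   of a weighted Kolmogorov–Smirnov running sum (hit increment
   |score|^p / Σ|score|^p over members, miss decrement 1/(N − N_hit)).  The
   null is gene-label permutation: random member sets of the same effective
   size.  NES = ES / mean(|null ES| of the same sign), normalizing positive
   and negative sides separately; the permutation p is the add-one-smoothed
   same-sign tail fraction, and q-values are Benjamini–Hochberg across the
   sets of one ranked list (significance threshold FDR < 0.2).
3. **Task statistics** — the decoupling statistic Δ(cell, hallmark) =
   NES_mRNA − NES_protein (sign configurable; positive = transcribed more
   than translated) and the range statistic max NES − min NES per
   (cell, modality), a proxy for concentration of resources on few tasks.
   Each hallmark's mean Δ (MD) is tested against a bootstrap null that pools
   both modalities' per-cell NES, draws two samples of the panel size with
   replacement, and records their difference of means (default 10 000 draws;
   p has an add-one correction and is never exactly zero).
4. **Growth associations** — Pearson correlations of Δ and range with the
   nominal division rate and with per-(cell, drug) maximum growth
   inhibition; the *fixed effect* of Δ on division rate, i.e. the common
   slope of an OLS with one intercept per hallmark; and per-hallmark simple
   regressions.  A mixed model is not attempted: a panel of ~11–32 cells
   cannot support random-effect estimation, and a single pooled slope is the
   quantity of interest.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
these defaults as the study conditions: 32 cell lines, 3000 genes, 10
hallmark sets whose sizes scale the published hallmark list sizes (232–1314
genes out of an assumed ~20 000-gene genome, floor 5), a 101-drug inhibition
panel, and an 11-cell sub-panel for growth modelling where stated.

* **mRNA.**  log2 abundance x_gc = μ_g + Σ_{s∋g} t_sc + σ_g z_gc with
  μ_g ~ N(5, 1.5²) (log2 RPKM-like), σ_g ~ U(0.4, 1.2), and a transcription
  boost t_sc for hallmark sets: t_sc = b_c + η_sc with b_c ~ N(0.5, 0.3²)
  (a per-cell investment level, log2 units) and η_sc ~ N(0, 0.02²).
* **Translation selectivity.**  A fraction (default 0.5) of hallmark sets
  withhold their boost from the protein side: protein tracks
  x̃ = x − (withheld boosts).  These sets are transcribed but not translated
  — the decoupling signal.
* **Protein.**  y = x̃ + ε with ε ~ N(0, v); v is solved per gene class
  (hallmark / background) from the empirical moments of x and x̃ so that the
  expected same-cell across-gene Pearson correlation equals the coupling
  target (defaults 0.6 inside hallmarks, 0.25 outside) — the simplest model
  reproducing an arbitrary target correlation.  Abundances are exported as
  2^log2 on a nonnegative linear scale with 2-decimal TSV rounding.
* **Growth.**  division rate = 2.5 − 1.88 · proxy_c + N(0, 0.15²), where
  proxy_c is the cell's mean *true* decoupling offset (mean of t_sc over
  withheld sets).  The generative link uses the truth, not the realized Δ,
  because the realized Δ is an estimate on the NES scale with an
  uncontrolled gain.  Inhibition values are N(0.5, 0.2²), independent of
  everything else, so any delta–inhibition association is a false positive.
* **Determinism.**  One master seed; every stream (gene baselines, set
  sampling, mRNA noise, protein noise, growth) derives from it by fixed
  offsets, so identical parameters give byte-identical outputs.

What the generator does **not** emulate: read-count or peptide-spectrum
noise, mass-spec missingness, cell-cycle structure, batch effects, or gene
symbol ambiguity.  Passing tests therefore show that the statistics recover
the structure they target under a clean Gaussian log-scale world, not that
they are robust to real-data artifacts.

## Numerical and design choices

* Pearson correlations use log2(x + 1)-transformed abundances (configurable):
  raw RPKM-like values are heavy-tailed, and rank (Spearman) results are
  transform-invariant anyway.  Spearman uses average ranks for ties.
* Ranking for enrichment uses raw abundance (ranks are transform-invariant);
  ties break by ascending gene ID for determinism.  Default exponent p = 1
  (the established preranked default), minimum effective set size 5, no
  maximum (the hallmark sets are large by design; a cap would drop them).
* ES sign ties (positive and negative extremes of equal magnitude) resolve
  positive, with a 1e-12 tolerance absorbing float noise.
* The bootstrap null pools both modalities before resampling — the
  exchangeability null for "no modality effect" — rather than resampling
  each modality separately.
* The delta sign convention is configurable because the two natural
  definitions (mRNA − protein vs protein − mRNA) are both in circulation;
  everything downstream reports the convention used.
* The pooled delta–inhibition "cloud" pairs each cell's per-hallmark Δ with
  every (cell, drug) inhibition value.  This is descriptive: each inhibition
  value appears once per hallmark, so the nominal n overstates the
  information and the correlation p-value is anti-conservative.  The
  calibration test of the independence property instead pairs the per-cell
  mean Δ with each inhibition measurement (one row per (cell, drug)), where
  the t-based p-value is exact for iid Gaussian responses.
* The two-sample KS statistic is reported both as the standard D ∈ [0, 1]
  and as the scaled variant √(nm/(n+m))·D, since published "D" values above
  1 can only be the scaled form.  One-sided p-values use exp(−2z²), the
  two-sided the Kolmogorov limit distribution.
* Rank-sum tests (hallmark vs random set) use exact enumeration for small
  tie-free groups and the continuity-corrected normal approximation
  otherwise; the reported W is the Mann–Whitney U.

## Problem sizes used by the test suite

Replicated recovery checks scale the cohort down so the suite stays fast
while keeping the contrasts identifiable: concordance-contrast replicates
use 8 cells x 1000 genes (100 replicates); delta-direction replicates 12
cells x 800 genes with 150 permutations (50 replicates); the division-slope
recovery fits 11 cells x 10 hallmarks on the generative decoupling table
(200 replicates; the NES-scale gain makes a slope-magnitude check against
the realized Δ ill-posed, so the realized Δ contributes the direction
check); the independence calibration uses 11 cells x 600 genes x 101 drugs
with 120 permutations (200 replicates).  Single-cohort checks and the
end-to-end run use the full default conditions.

## Known limitations

* Enrichment p-values are bounded below by 1/(n_perm + 1); very small FDRs
  need more permutations than the default 1000.
* The per-gene coupling calibration is exact in expectation per gene class,
  not per gene; individual genes scatter around the class target.
* With strong translation selectivity the protein-side noise calibration and
  the withheld boosts interact; the solved noise variance keeps the class
  correlation on target, but hallmark-set protein enrichment is attenuated
  (deliberately — that is the decoupling phenotype).
* No alias resolution is attempted when matching gene identifiers across
  modalities; genes absent from one modality are dropped with a logged count.
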