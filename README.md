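# hallmarktasks

Do cancer cells transcribe genes they do not bother translating?  This
package quantifies transcription–translation decoupling in panels of cancer
cell lines with paired mRNA (RNA-seq, RPKM-like) and protein (MS intensity)
profiles, using the ten cancer hallmarks as the *tasks* a cell may
specialize in.  It is written for computational biologists analysing paired
proteogenomic panels (e.g. LINCS-style breast-cancer cell-line data reshaped
to plain TSV), and ships a synthetic-cohort generator so every statistic can
be validated against known ground truth.

## The statistics

For cell lines *c* and hallmark gene sets *S*:

* **Concordance** — the cells x cells matrix R with
  R_ij = corr(mRNA profile of cell i, protein profile of cell j) over shared
  genes (Pearson on log2(x+1), or Spearman).  Same-cell (diagonal) vs
  other-cell entries are contrasted with a Welch t and a one-sided KS test;
  per-hallmark correlations are compared against a random gene set
  (rank-sum per hallmark, one-way ANOVA overall).
* **Enrichment** — per cell and modality, a preranked gene-set enrichment:
  weighted running-sum ES, gene-label permutation null, NES = ES divided by
  the mean same-sign null magnitude, permutation p, BH FDR (threshold 0.2).
* **Delta** — Δ(c, S) = NES_mRNA − NES_protein, the decoupling statistic;
  each hallmark's mean Δ (MD) is tested against a pooled bootstrap null
  (10 000 resamples of the panel size).
* **Range** — max NES − min NES per cell and modality, the
  task-concentration statistic.
* **Growth associations** — PCC of Δ and range with nominal division rate
  and per-(cell, drug) growth inhibition; the fixed effect (FE) of Δ on
  division rate, i.e. the common slope of an OLS with hallmark-indicator
  intercepts; per-hallmark linear models; ECDF/KS comparisons of the range
  statistic between modalities.

See `docs/methods.md` for the model the synthetic cohort implements and the
numerical conventions.

## Worked example

Run the numbered analysis drivers (each is a thin wrapper over the library
in `src/hallmarktasks/`), or the equivalent CLI:

```sh
python analysis/01_simulate_cohort.py --seed 7
python analysis/02_concordance.py
python analysis/03_enrichment.py
python analysis/04_task_statistics.py
python analysis/05_growth_association.py
```

With seed 7 this prints, among other lines:

```
pearson: mean same-cell r = 0.277, other-cell r = 0.208
same vs other: Welch t = 23.45 (df = 34.13, p = 1.25e-22); KS D+ = 0.977
hallmark median r = 0.597 vs random 0.287; ANOVA F = 63.0 (p = 2.07e-71)
mrna: min NES = 0.78, 189/320 records significant at FDR < 0.2
mean delta across all (cell, hallmark): +0.548
bootstrap difference tests: 10/10 hallmark(s) with p < 0.05
fixed effect of delta on division rate: -3.452 (SE 0.209, p = 2.7e-44)
pooled delta-inhibition PCC = -0.023 (p = 3.59e-05; descriptive: ...)
```

Reading this: same-cell mRNA–protein correlation (0.28) clearly exceeds the
cross-cell background (0.21), and hallmark genes are far better coupled
(median 0.60) than a random gene set (0.29).  Every hallmark is positively
enriched on the mRNA side (min NES 0.78).  The mean enrichment delta is
positive — hallmarks are transcribed more than translated — and
significantly so for all ten hallmarks under the bootstrap null.  Division
rate falls with increasing delta (the generator's built-in trade-off), while
drug growth inhibition, generated independently, shows a near-zero
correlation (−0.02; its small p-value illustrates why the pooled cloud's
nominal n is an overstatement — see `docs/methods.md`).

The same pipeline runs from one config via the CLI, stage by stage or end to
end:

```sh
hallmarktasks run-all --outdir results/pipeline --seed 7
hallmarktasks enrich --mrna results/cohort/mrna.tsv \
    --protein results/cohort/protein.tsv --gmt results/cohort/hallmarks.gmt
```

To analyse real data, reshape it to the documented formats (abundance TSV
with a `gene_id` column, MSigDB-style GMT, growth TSV with a
`division_rate` column) and point a YAML config's `inputs:` block at the
files.

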