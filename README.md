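# vdindex

Stratification of vitamin D₃-supplemented individuals into **high, mid and
low responders** from paired PBMC transcriptomes and serum 25(OH)D₃
measurements.

## The problem

A single weight-adjusted vitamin D₃ bolus raises serum 25(OH)D₃ in
essentially everyone within 24 h, but the *transcriptomic* response of
circulating immune cells varies widely between individuals. The **vitamin D
response index** quantifies this: for each participant, plot

* *x* — the serum 25(OH)D₃ day-1 / day-0 ratio, against
* *y* — the mean |log₂FC| of vitamin-D target genes between day 1 and day 0,

draw the least-squares trendline constrained through the point (1, 0)
(no serum change ⇒ no expected response), and take the **signed orthogonal
distance** of each participant's point to that line:

```
m  =  Σᵢ (xᵢ − 1) yᵢ / Σᵢ (xᵢ − 1)²
dᵢ =  (yᵢ − m (xᵢ − 1)) / √(1 + m²)
```

Participants above the line (strong expression response relative to their
serum rise) are strong responders. Ranking the dᵢ in descending order and
clustering them with an exactly optimal one-dimensional k-means (k = 3,
dynamic programming — fully deterministic, no random initialization) yields
the high / mid / low stratification.

Upstream, the target genes come from a paired differential-expression
analysis of gene × sample counts: CPM normalization, an expression filter
(protein-coding, positioned genes with mean CPM > 10 at both timepoints),
TMM composition-bias correction, a moderated paired t-test with
empirical-Bayes variance shrinkage toward an abundance trend, a
fold-change-threshold (shifted-t) test against |log₂FC| > 0.25, and
Benjamini–Hochberg FDR. Downstream, two cohorts can be merged on shared
genes with per-gene mean-ratio harmonization and classified jointly.

A synthetic-cohort generator draws paired negative-binomial counts with a
trended dispersion, latent responder classes, and serum ratios negatively
coupled to each subject's effect size, providing ground truth for recovery
experiments.

## Worked example

```python
from vdindex import io, classify, pipeline, simulate

# headline serum statistics of the packaged 45-participant trial table
cohort = io.load_vitdpas_table1()
s = classify.serum_summary(cohort)
print(f"serum 25(OH)D3: mean d0 {s.mean_d0:.1f} ng/ml, mean d1 {s.mean_d1:.1f} ng/ml")
print(f"mean increase {s.mean_delta:.1f} ng/ml ({s.mean_pct_increase:.0f}%), "
      f"paired t p = {s.p_paired:.1e}")

# full pipeline on a synthetic cohort with known responder classes
counts, syn, ann, truth = simulate.simulate_cohort(simulate.SimulationConfig(seed=1))
res = pipeline.run_pipeline(counts, syn, ann, config=pipeline.RunConfig(seed=1))
d = res.report["de_summary"]
print(f"expressed genes: {d['n_expressed']}, significant (p<0.05): {d['n_sig_p05']} "
      f"({d['n_sig_p05_up']} up / {d['n_sig_p05_down']} down)")
print("class sizes:", res.report["classification"]["class_sizes"])
print("recovery concordance: %.3f" % simulate.truth_concordance(truth, res.index))
```

prints

```
serum 25(OH)D3: mean d0 26.5 ng/ml, mean d1 32.9 ng/ml
mean increase 6.4 ng/ml (29%), paired t p = 3.9e-21
expressed genes: 8474, significant (p<0.05): 827 (430 up / 397 down)
class sizes: {'high': 22, 'mid': 17, 'low': 6}
recovery concordance: 0.911
```

The serum block says the bolus raised vitamin D status by 6.4 ng/ml on
average — a 29 % mean per-participant increase, overwhelmingly significant
under a paired t-test. On the synthetic cohort, 827 of 8,474 expressed
genes respond at p < 0.05; clustering the response index recovers the
latent high/mid/low class of 91 % of participants.

The same steps are available from the shell via the `vdindex` console
script (`simulate`, `de`, `classify`, `merge`, `report` subcommands), e.g.

```
vdindex simulate --seed 1 --outdir sim/
vdindex de --counts sim/counts.tsv --samples sim/samples.tsv \
           --annotation sim/annotation.tsv --out de.tsv
vdindex report --participants sim/participants.tsv --outdir report/
```

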