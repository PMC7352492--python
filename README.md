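# nutnet

Dietary-pattern discovery and food co-consumption network analysis for
adolescent food-frequency-questionnaire (FFQ) cohorts.

## The problem

Cross-sectional school surveys of adolescent nutrition typically collect,
per subject, a semi-quantitative FFQ (how often each food item is eaten,
and the portion per occasion), anthropometric measurements, and a
self-perceived weight response ("How do you feel about your weight?").
Two questions drive the analysis this package implements:

1. **What dietary patterns exist?**  Item responses are converted to
   grams/day, aggregated into food groups, rescaled to each subject's
   *abundance of consumption* (the ecology-style fraction of total daily
   intake), and clustered with Ward's hierarchical method to find groups
   of adolescents with similar diet composition.
2. **Does weight misperception reshape *how* foods are eaten together?**
   Subjects are stratified by the divergence between measured and
   perceived weight (DMPW: Agreed / Underestimated / Overestimated, from
   an ordinal comparison of BMI-for-age status with collapsed
   self-perception), and within each stratum a signed Spearman
   correlation network over food groups is built and stabilized by
   bootstrap resampling.  Sparse networks with negative edges indicate
   *selective* eating — raising one food group while lowering another.

The package is aimed at nutrition epidemiologists who want this pipeline
as tested, reusable code, and it ships a synthetic-cohort generator that
plants known structure (pattern labels, DMPW labels, signed correlation
blocks) so every stage can be validated by parameter recovery.

## Methods at a glance

- **FFQ conversion** — daily grams = portion × frequency factor, with
  configurable per-category factors (defaults: never/rare → 0;
  1–3/month → 2/30.44; 1/week → 1/7; 2–4/week → 3/7; ≥4/week → 5.5/7).
- **Anthropometry** — BMI = (scale weight − 0.1 kg uniform)/height²;
  status bands on the BMI-for-age percentile: [0,3) underweight,
  [3,85) normal, [85,97) overweight, [97,100] obese; DMPW by ordinal
  comparison of measured level (thin/normal/fat, with overweight and
  obese merged into "fat") against perceived level.
- **Patterns** — abundance aᵢ𝓰 = intakeᵢ𝓰 / Σ𝓰 intakeᵢ𝓰; Ward linkage on
  Euclidean distances between abundance rows, cut at k = 4; per-group
  one-way ANOVA across patterns with Holm–Bonferroni adjustment.
- **Modelling** — baseline-category multinomial logit of pattern on DMPW
  adjusted for sex and status (pattern 2 and "Agreed" as references),
  with optional cluster-size-proportional sampling weights, plus the
  design effect Deff = 1 + (m̄ − 1)·ICC of the school-cluster sampling.
- **Networks** — per DMPW stratum: Spearman ρ matrices over B = 100
  bootstrap resamples; an edge survives if, in ≥ 50% of replicates, it
  simultaneously has Holm-adjusted p < 0.05, |ρ| > 0.5, and a consistent
  sign.  Density = L/(N(N−1)/2); per-replicate densities are compared
  between strata with Kruskal–Wallis + Dunn tests.

## Worked example

Generate a synthetic cohort with 300 subjects per DMPW stratum,
positive-only correlation structure planted in Agreed/Underestimated and
a sparser, partly negative structure in Overestimated, then recover the
networks:

```python
from nutnet import simulate, networks, anthropometry

cfg = simulate.network_recovery_config(n_per_group=300, seed=42)
cohort, truth = simulate.generate_cohort(cfg)
intakes = simulate.generate_ffq_intakes(cohort, cfg, truth)

print(anthropometry.dmpw_frequency_table(cohort).to_string(index=False))
for name in ("Agreed", "Underestimated", "Overestimated"):
    sub = intakes.loc[cohort["dmpw"] == name]
    ens = networks.bootstrap_ensemble(sub, n_boot=100, seed=1)
    net = networks.stable_edges(ens)
    neg = int((net.edges["sign"] < 0).sum())
    print(f"{name:15s} edges={net.n_edges:2d} negative={neg} density={net.density:.3f}")
```

prints

```
          dmpw  count  percent
        Agreed    300     33.3
Underestimated    300     33.3
 Overestimated    300     33.3
Agreed          edges=11 negative=0 density=0.121
Underestimated  edges= 7 negative=0 density=0.077
Overestimated   edges= 5 negative=3 density=0.055
```

All 11 planted Agreed edges and 7 Underestimated edges are recovered
with positive signs; the Overestimated stratum recovers its 5 planted
edges including the 3 negative ones (e.g. roots–oils, planted Spearman
−0.7, retained with median bootstrap ρ = −0.73 at persistence 1.00) and
has the lowest network density — the selective-consumption signature.

The same analysis runs from the shell:

```bash
nutnet simulate --out run/           # cohort + FFQ responses + planted truth
nutnet ffq --responses run/ffq_responses.tsv \
           --group-map run/item_group_map.tsv --out run/intakes.tsv
nutnet all --seed 42 --out run/      # full pipeline with summary.json
```

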