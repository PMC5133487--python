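# stagetrends

Tools for finding genes whose expression rises or falls along the ordered
stages of a progressive disease — e.g. healthy control → low-risk subtype →
high-risk subtype → acute disease — from a genes × samples expression matrix
and a per-sample stage annotation.

Standard two-group differential expression struggles with this setting:
patient heterogeneity within each stage hides changes that are only coherent
*across* the whole progression. `stagetrends` instead works in two steps:

1. **Trend screening with fuzzy Goodman–Kruskal gamma.** For each gene *g*
   and the ordinal stage variable *y*, the gamma rank correlation

   γ = (C − D) / (C + D)

   counts concordant (C) and discordant (D) sample pairs and is robust to
   the heavy ties an ordinal variable produces. Because expression values
   are noisy, strict ranking is softened: a pair of expression values is
   ordered only to the degree `min(1, max(0, (x_j − x_i)/r))`, with the tie
   tolerance *r* set to 10 % of the gene's interquartile range, and pair
   degrees of the two variables are combined with the `min` t-norm.
   Significance comes from stage-label permutations (1000 by default,
   two-sided, add-one estimator) with Benjamini–Hochberg FDR control;
   genes with |γ| > 0.50 and q < 0.05 are selected.

2. **Pattern discovery with a self-organizing map.** Selected genes are
   z-scored, oriented so every profile rises (a gene falling along the
   stages is sign-flipped), sorted by intensity, and clustered on a 3×3
   rectangular SOM. Each resulting pattern is annotated with its **δ/2
   point** — the interpolated stage at which the pattern's mean profile has
   completed half of its total change δ — classifying it as an *early*- or
   *late*-changing trend.

A staged RNA-seq simulator (`simulate_dataset`) generates count matrices
with ground-truth trend genes in four archetypes (up/down × early/late) for
validating the pipeline, and `evaluate_detection` scores any detected gene
set against that truth.

## Worked example

Simulate 300 genes (60 of them trend genes, 15 per archetype) over 6 stages
of 3 replicates, screen, cluster, and score against the truth:

```python
import numpy as np
from stagetrends import (GammaParams, SimConfig, evaluate_detection,
                         screen_genes, simulate_dataset,
                         standardize_and_orient, summarize_patterns, train_som)
from stagetrends.som import SOMTrainingParams

config = SimConfig(n_genes=300, trend_counts={a: 15 for a in
         ("up_early", "up_late", "down_early", "down_late")}, seed=7)
counts, design, truth = simulate_dataset(config)
expr = counts.log2_plus1()                       # counts -> log2(x+1)
table = screen_genes(expr, design, GammaParams(seed=7))
detected = table.loc[table.selected, "gene_id"].tolist()
print(f"selected {len(detected)} of {counts.n_genes} genes")

profiles = standardize_and_orient(expr, design, detected)
model = train_som(np.array([p.sorted_values for p in profiles]),
                  [p.gene_id for p in profiles], grid=(3, 3),
                  params=SOMTrainingParams(seed=7))
for s in summarize_patterns(model, profiles, design):
    if s.main:
        print(f"unit {s.unit}: {s.n_genes:3d} genes  delta={s.delta:.2f}  "
              f"half-change at stage {s.half_change_position:.2f} "
              f"({s.trend_class})  up/down={s.n_up}/{s.n_down}")
m = evaluate_detection(truth, detected, model.assignments)
print(f"precision={m['precision']:.3f} recall={m['recall']:.3f} FP={m['FP']}")
```

prints

```
selected 31 of 300 genes
unit 0:   5 genes  delta=2.21  half-change at stage 3.27 (early)  up/down=0/5
unit 2:   3 genes  delta=2.03  half-change at stage 2.67 (early)  up/down=3/0
unit 3:   5 genes  delta=2.37  half-change at stage 3.24 (early)  up/down=0/5
unit 5:   7 genes  delta=2.15  half-change at stage 2.79 (early)  up/down=7/0
unit 6:   2 genes  delta=1.91  half-change at stage 4.42 (late)  up/down=0/2
unit 8:   9 genes  delta=2.18  half-change at stage 3.50 (late)  up/down=9/0
precision=1.000 recall=0.517 FP=0
```

Every selected gene is a true injected trend gene (precision 1.0) and the
main patterns split cleanly into rising (up) and falling (down) groups with
early and late half-change points. Recall is limited by the simulator's
realistic noise: at a 4-fold total change with inter-patient-level
overdispersion and only 3 replicates per stage, roughly half of the injected
genes do not reach |γ| > 0.5 (see `docs/methods.md`).

The first rows of the gamma table look like:

```
gene_id     gamma          C          D   p_perm    q_fdr direction  selected
  G0001  0.069028 141.530868 123.253450 0.733267 0.929683        up     False
  G0002  0.739782 227.157201  33.975790 0.000999 0.027245        up      True
  G0003 -0.540140  59.392970 198.916023 0.006993 0.061703      down     False
```

G0002 rises monotonically along the stages (γ = 0.74, the smallest
attainable permutation p of 1/1001, q < 0.05 → selected); G0003 falls with
|γ| just above threshold but does not survive FDR control.

## Command line

```sh
stagetrends simulate --out sim/ --seed 7                 # counts, stages, truth
stagetrends run --expr sim/counts.tsv --stages sim/stages.tsv \
    --stage-order S1,S2,S3,S4,S5,S6 --out run/ --seed 7  # gamma + SOM outputs
stagetrends evaluate --truth sim/truth.tsv --gamma-table run/gamma.tsv \
    --membership run/membership.tsv --out metrics.json
```

`run` writes `gamma.tsv`, `membership.tsv`, `patterns.tsv`, `codebook.tsv`
and a `manifest.json` that records the fully resolved configuration; a YAML
`--config` can override any tunable (permutations, thresholds, grid, stage
merging such as collapsing disease subtypes into risk groups, …). Identical
inputs and `--seed` reproduce every output byte for byte.

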