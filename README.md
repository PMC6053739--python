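# stagepath

Stage-resolved co-expression and pathway-deviation analysis for
case/control expression cohorts, with a built-in synthetic-data
generator that makes every stage of the analysis verifiable end to end.

## The problem

Blood-based early diagnosis of lung adenocarcinoma (and staged disease
generally) is hard because single-gene markers are unstable across
samples. A more robust signal lives one level up: as disease
progresses, the *co-expression structure* among stage-specific genes
rewires, and the *functional level* of the pathways those genes regulate
drifts away from the healthy baseline. `stagepath` implements that
analysis chain for a genes × samples expression matrix whose samples are
labelled `control`, `early` (stage I) or `late` (stage II–IV):

1. **Normalization** — genes/samples with >10% missing values are
   dropped, gaps are mean-imputed, and every gene is z-scored against
   the control group, so controls are N(0, 1) per gene and case values
   read in control standard deviations.
2. **Stage-specific genes** — a coefficient-of-variation filter
   (CV = sd/mean over cancer samples, top 50% of |CV| kept) followed by
   a moderated two-sample t-test (empirical-Bayes variance shrinkage)
   per phase versus controls at P < 0.05 and |logFC| ≥ 1, giving the
   early-specific set Δ0, the late-specific set Δ1 and their
   intersection Δ2.
3. **Co-expression** — per-phase Pearson correlation of the
   stage-specific genes; pairs with r > 0.5 / r < −0.5 are classed
   positive/negative; pairs keeping the same sign in all phases are
   "stable pairs". Hierarchical clustering (1 − r distance, average
   linkage) orders genes and samples.
4. **Networks** — per-phase specific graphs over Δ0 ∪ Δ1 and a
   non-specific graph over Δ2, compared by average shortest path,
   degree distribution, closeness centrality and clustering
   coefficient. Gene importance is the sigmoid of the degree,
   w = 1/(1 + e^(−degree)) ∈ (0, 1); genes outside the network inherit
   the minimum in-network weight.
5. **Pathway deviation score** — for a pathway P with k differentially
   expressed members, each member's three-group ANOVA p-value becomes a
   weighted Z′ = w · Φ⁻¹(1 − p), and

       A(P) = max over 1 ≤ t ≤ k of (1/√t) · Σ of the t largest Z′

   A(P) grows with k, so it is standardized against a permutation null:
   random size-k gene sets drawn from the background pool give μ_k and
   σ_k, and A_corrected = (A − μ_k)/σ_k. Per-sample score profiles
   (same statistic on each sample's weighted expression) feed a
   pathway-level ANOVA screen across the three phases.
6. **Diagnostic model** — recursive feature elimination (linear-SVM
   weight ranking, RBF-SVM accuracy curve) over candidate genes, grid
   search over (C, γ), and stratified fivefold cross-validated ROC.

## Worked example

```python
import json
from stagepath import RunConfig, run_pipeline, synthetic

expr, meta, gmt, truth = synthetic.simulate_dataset(
    n_genes=1000, group_sizes=(81, 28, 53), n_pathways=50,
    pathway_size=20, n_deviated=5, seed=7)
raw, _ = synthetic.denormalize(expr, seed=8)      # raw intensity scale

cfg = RunConfig(n_perm=2000, seed=7, cv_quantile=1.0,
                label_scheme="control_vs_cancer")
summary = run_pipeline(raw, meta, gmt, cfg, raw_scale=True)
print(json.dumps(summary["stages"], indent=2, default=str))
```

The cohort mirrors an 81/28/53 control/early/late split with 100
early-related and 100 late-related planted genes (30 shared) and 5
deviated pathways among 50. The run prints, among other things:

```text
"stage_genes":  { "cv_kept": 1000, "delta0_total": 100, "delta0_up": 50,
                  "delta0_down": 50, "delta1_total": 100, "delta2_total": 30 }
"network":      { "nonspecific": { "n_nodes": 30, "n_edges": 270,
                  "avg_shortest_path": 1.379... } }
"pathways":     { "enriched": 5, "scored": 5, "anova_significant": 5 }
"classifier":   { "n_candidates": 30, "cv_accuracy": 1.0, "auroc": 1.0 }
```

Reading: all 100 + 100 planted phase genes and exactly the 30 planted
shared genes are recovered (`delta2_total`); the Δ2 genes form a dense
non-specific network (shared shifts induce strong correlation over all
162 samples); the 5 planted deviated pathways are exactly the enriched,
scored and ANOVA-significant ones; and the cross-validated SVM on Δ2
genes separates cases from controls perfectly at this effect size.

The same analysis is available from the shell:

```sh
stagepath simulate --n-genes 1000 --groups 81 28 53 --seed 7 --out-dir sim
stagepath run-all --expression sim/expression.tsv --metadata sim/metadata.tsv \
                  --gmt sim/pathways.gmt --seed 7 --out-dir results
```

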