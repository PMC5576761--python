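# screenrep

Cluster-aware empirical Bayes replicability analysis across studies.

Given an n-genes × m-studies matrix of p-values (or z-scores), `screenrep`
estimates, for every gene and a chosen k, the local Bayes false discovery
rate of the claim "this gene is non-null in at least k studies" — the
posterior probability of fewer than k non-null realizations. Genes with
fdr_k below a threshold (0.2 by default) are declared k-replicable.

Three run modes are provided:

| mode         | assumption                | algorithm |
|--------------|---------------------------|-----------|
| `screen`     | independent study clusters| cluster the studies from bootstrap-mean pairwise correlations (two-study EM → phi coefficient → thresholded graph → infomap), fit a configuration prior per cluster by EM, merge per-cluster non-null-count posteriors by dynamic programming |
| `screen-ind` | fully independent studies | exact O(nmk) count-indexed dynamic program |
| `repfdr-ub`  | one cluster of all studies| capacity-limited ("restricted") EM over configurations plus a provable fdr upper bound from the retained mass ξ and exclusion bound ε |

Per-study two-groups models are fitted with `normix` (EM mixture of a
half-normal null, scale ≥ 1, and a normal non-null, location > 0, on
absolute z-scores; the null can be pinned to the theoretical half-normal)
or a `locfdr`-style signed-z empirical null (central-region MLE → central
matching → theoretical fallback). Each study's non-null density is shrunk
by its estimated power (expected tdr under f1) before fdr computation.

Also included: Fisher meta-analysis + BH, per-study BH counting, the
expected-non-null-count (tdr-sum) statistic, simulation generators with
known ground truth (independent and block-correlated studies), and scoring
utilities (FDP, Jaccard, up/down/mixed direction calls, rank comparison).

## CLI

All matrices are TSV: header row of study ids, first column of gene ids.

```sh
# simulate a matrix with known truth
screen simulate --scenario clustered --r 0.8 --x 100 --seed 7 --out sim

# full pipeline: fdr_k per gene for k = 2..20
screen run --pvals sim.pvals.tsv --scale pvalue --k 2:20 \
    --mode screen --fdr-threshold 0.2 --n-configs 1024 \
    --edge-threshold 0.1 --bootstrap 100 --seed 7 \
    --out fdr.tsv --partition-out clusters.tsv

# independence-exact and upper-bound variants
screen run --pvals sim.pvals.tsv --k 2:5 --mode screen-ind --out ind.tsv
screen run --pvals sim.pvals.tsv --k 2:5 --mode repfdr-ub --n-configs 512 --out ub.tsv

# study clustering only, baselines, and scoring
screen cluster --pvals sim.pvals.tsv --bootstrap 100 --out clusters.tsv
screen fisher --pvals sim.pvals.tsv --out fisher.tsv
screen bh-count --pvals sim.pvals.tsv --k 3 --out bh.tsv
screen exp-count --pvals sim.pvals.tsv --k 3 --out exp.tsv
echo -e "g12\ng40" > picks.txt
screen evaluate --truth sim.truth.tsv --selected picks.txt --k 3
```

Defaults can also be given as a YAML key/value file via `--config`; command
line flags win.

## Library sketch

```python
import screenrep as sr

ds = sr.simulate_clustered(n=5000, M=4, cluster_size=10, r=0.8, seed=0)
results, info = sr.screen(ds.P, ks=[2, 3, 4], mode="screen", seed=0)
fdp, jaccard = sr.fdp_jaccard(results[4].selected, ds.H_true, k=4)
```

`sr.screen` returns one `FdrResult` per k (fdr values, bound flag,
selection calls) plus an info dict with the fitted models, the study
partition, per-cluster count posteriors and stage timings.
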