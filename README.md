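# knotpop

Population-genetic and integrative multivariate discrimination of the
three invasive knotweed taxa — *Reynoutria japonica*, *R. sachalinensis*,
and their hybrid *R. × bohemica* — from three evidence layers: dominant
molecular markers (SCoT/SRAP-style binary band matrices), leaf
morphometry, and rhizome metabolite profiles.

The package is aimed at plant population geneticists and pharmacognosists
who need to tell a pharmacopoeial species (*R. japonica*) apart from its
hybrid and the other parent when no single evidence layer is decisive.

## What it computes

For a samples × bands presence/absence matrix with presence frequency
*p* (and *q* = 1 − *p*) per band:

* **Marker informativeness** — PIC = 1 − (p² + q²), band informativeness
  I_b = 1 − 2|0.5 − p|, resolving power R_p = Σ I_b per primer, band
  counts and % polymorphism, with panel `Total`/`Mean` rows.
* **Diversity and differentiation** — N_a, N_e = 1/(p²+q²), Nei's
  H = 2pq, Shannon's I, NPL/PPL per population; Nei's H_T, H_S,
  G_ST = (H_T − H_S)/H_T and gene flow N_m = ((1/G_ST) − 1)/4.
* **AMOVA** — among/within-population variance components from squared
  Euclidean (mismatch-count) distances, Φ = σ²_among/(σ²_among+σ²_within),
  label-permutation p-value.
* **Clustering & ordination** — Dice ("Jaccard"-labelled) or true Jaccard
  band similarity; Ward / UPGMA dendrograms with Newick export and
  cophenetic access; PCA (SVD) for trait and metabolite tables; MCA of the
  binary indicator expansion; Kruskal–Wallis trait screening.
* **Integration** — Evanno ΔK = mean|L″(K)|/sd(L(K)) over replicate
  structure log-likelihoods; a lightweight Bernoulli-admixture EM
  (stand-in for Bayesian bar plots); Baker's gamma (Spearman correlation
  of fusion levels over all leaf pairs) between evidence-layer dendrograms.
* **Synthetic data** — a seeded generator for the whole design (two
  diverged parents + admixed hybrid, clonal duplicates, structural-zero
  metabolites, knee-shaped lnP(D) curves) with stored ground truth.

See `docs/methods.md` for formulas, conventions, and limitations.

## Worked example

```python
from knotpop import (default_config, simulate_band_matrix, primer_summary,
                     panel_summary, diversity_summary,
                     squared_euclidean_binary, permutation_test_phi,
                     pca, simulate_structure_likelihoods, evanno_delta_k)
from knotpop.datasets import quantified_compounds

cfg = default_config(seed=42)          # 5 RJ + 7 RB + 3 RS, 306 bands
bm, truth = simulate_band_matrix(cfg)

panel_summary(primer_summary(bm)).loc[["Total", "Mean"]]
#        total_bands  polymorphic_bands  pct_polymorphic  resolving_power  mean_pic
# Total        306.0            244.000              NaN          132.800       NaN
# Mean          17.0             13.556            0.797            7.378     0.286

ds = diversity_summary(bm)
round(ds.gst, 3), round(ds.nm, 3)
# (0.251, 0.744)        # moderate differentiation, ~0.7 migrants/generation

res, _ = permutation_test_phi(squared_euclidean_binary(bm),
                              bm.populations, n_perm=999, seed=42)
round(res.phi, 4), res.p_value
# (0.1091, 0.001)       # significant among-taxon structure

r = pca(quantified_compounds().data, center=True, scale=True)
print("PC1 %.1f%%  PC2 %.1f%%" % (100 * r.explained[0], 100 * r.explained[1]))
# PC1 64.9%  PC2 19.1%  # six quantified rhizome compounds, 15 accessions

evanno_delta_k(simulate_structure_likelihoods(2, seed=42)).best_k
# 2                     # two genetic groups: RS vs RJ+RB
```

The hybrid shows the highest diversity (H = 0.260 vs 0.213/0.171 in the
parents here), most variance lies within populations, and the
quantified-compound PCA puts almost two thirds of the variance on one
axis separating *R. sachalinensis* (piceid/resveratrol absent, vanicosides
high) from *R. japonica*.

A sub-command CLI mirrors the stages:

```sh
knotpop run-all config.yaml -o results/   # simulate: true in the config
```

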