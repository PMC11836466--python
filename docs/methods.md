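# Methods

## Scope and model of the data

`knotpop` analyses a three-layer evidence design used to discriminate the
invasive knotweed taxa *Reynoutria japonica* (RJ), *R. sachalinensis* (RS),
and their hybrid *R. × bohemica* (RB):

1. **Genetic layer** — a binary band matrix from dominant marker systems
   (SCoT and SRAP style): N accessions × L scored bands, each entry 1
   (band present), 0 (absent), or missing. Dominant markers cannot
   distinguish heterozygotes from dominant homozygotes, so every statistic
   here is a function of per-band presence frequencies.
2. **Morphological layer** — six continuous leaf characters (mm) per
   specimen: blade length/width, apex length/width, base width, petiolar
   sinus.
3. **Metabolite layer** — non-negative LC-MS feature intensities or
   quantified compound contents (mg/g dry extract) per specimen.

All layers share sample identity; `align_layers` reorders them onto the
lexicographically sorted intersection of sample ids and reports drops.
Missing band scores are retained as missing and excluded per band from
frequency denominators — never imputed as absence.

## Marker informativeness

For band presence frequency `p` (computed over non-missing entries):

* `PIC = 1 − (p² + q²)`, `q = 1 − p`; maximum 0.5 at `p = 0.5`.
* `Ib = 1 − 2|0.5 − p|`; resolving power `Rp = Σ Ib` per primer.
* A band is polymorphic iff `0 < p < 1` (strict rule, the default; the
  optional `p95` rule additionally requires `0.05 ≤ p ≤ 0.95`). The
  strict rule is the default because a panel in which one primer reaches
  100 % polymorphism is only possible under it.
* Mean PIC averages all of a primer's bands by default; a
  `pic_over="polymorphic"` mode is exposed because published tables do not
  always state the denominator.
* PIC is computed on the band-presence (phenotype) frequency directly; an
  `hwe` mode that infers allele frequencies via `q = √(1 − p_band)` exists
  for the diversity statistics, since both conventions circulate in the
  dominant-marker literature.

`panel_summary` appends `Total` (column sums of counts and Rp) and `Mean`
rows. Note that totals recomputed from per-primer values printed to two
decimals can differ from a source's printed total in the second decimal;
the package always reports exact column sums of its input.

## Diversity and differentiation

Treating each band as a biallelic locus with frequencies `(p, q)`:
`Na = #{alleles with frequency > 0}`, `Ne = 1/(p²+q²)`, `H = 2pq`,
`I = −p ln p − q ln q`. Per-population values average over loci
(complete-case per locus). Shannon's index is reported on **both** the
per-locus-mean scale (bounded by ln 2) and the sum-over-loci scale,
because published per-population values above ln 2 can only be sums and
the convention is frequently left unstated. Under strictly biallelic
presence/absence coding `Na ≤ 2` necessarily; published dominant-marker
tables sometimes print larger values produced by other allele-counting
conventions, which this package does not attempt to emulate.

Nei's decomposition: per locus, `HS` is the (by default unweighted) mean
of within-population `2pq` and `HT = 2 p̄ q̄` of the averaged allele
frequencies; both are averaged over loci and `GST = (HT − HS)/HT`
(defined as 0 when `HT = 0`). Population weighting is equal by default —
the motivating design has unequal sizes 5/7/3 and no stated convention —
with size weighting available. Gene flow `Nm = ((1/GST) − 1)/4`, infinite
(with a warning) at `GST ≤ 0`.

## AMOVA

Squared Euclidean distance between 0/1 profiles equals the band mismatch
count, so distances add across independent band sets and a combined-panel
AMOVA equals the AMOVA of summed per-system distance matrices. The
one-level decomposition uses the classical pairwise-distance sums
(`SS_total = (1/N)Σ_{i<j}d²`, `SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²`), df
`a−1 / N−a / N−1`, the unbalanced-design coefficient
`n0 = (N − Σn_g²/N)/(a−1)`, `σ²_among = max(0, (MS_among − MS_within)/n0)`
(clamped at zero, the standard convention), and
`Phi = σ²_among/(σ²_among + σ²_within)`. Significance: population labels
permuted across samples, `p = (1 + #{Phi* ≥ Phi})/(1 + n_perm)` with 999
permutations by default. Only the two-level design is implemented;
hierarchical regions are out of scope.

## Similarity, clustering, ordination

* The two-state similarity printed as "Jaccard" in parts of the
  dominant-marker literature, `2n_xy/(n_x+n_y)`, is algebraically the
  Dice/Sørensen coefficient; it is implemented verbatim as `dice_paper`
  and used as the default for the genetic dendrogram, with the true
  Jaccard `n_xy/(n_x+n_y−n_xy)` one flag away. Dice ≥ Jaccard always,
  with equality only for identical or disjoint profiles. Two all-zero
  profiles are defined as similarity 1 with a warning.
* Hierarchical clustering delegates to `scipy.cluster.hierarchy`:
  `ward` applies the Ward.D2-style Lance–Williams update directly to the
  given dissimilarities — an accepted approximation when the input
  (e.g. 1 − Dice) is not Euclidean — and `upgma` is average linkage,
  which reproduces ultrametric inputs exactly. Trees export to Newick
  with branch lengths from merge heights.
* Morphology clustering uses Euclidean distance on unstandardized traits
  by default (all six characters share mm units); a standardize flag
  exists for mixed-unit tables.
* PCA is an SVD of the centered (optionally unit-variance scaled) matrix;
  the sign convention makes each axis's largest-magnitude loading
  positive. The quantified-compound table is analysed centered and
  scaled; a `log10(x+1)` transform is available for raw intensity tables.
* MCA expands each band into present/absent indicator categories and runs
  correspondence analysis (SVD of standardized residuals) on the N × 2L
  indicator matrix. Total inertia of such a table is exactly
  `J/Q − 1 = 1`, which the tests verify to 1e−10. Constant bands would
  create zero-mass categories and are dropped with a warning. Axes are
  reported uncorrected by default; the Benzécri correction is optional.
* Kruskal–Wallis (tie-corrected, χ² reference on `groups − 1` df) screens
  each trait for between-taxon differences.

## Structure post-processing and concordance

* **Evanno ΔK**: per replicate, the absolute second difference
  `|L(K+1) − 2L(K) + L(K−1)|` is averaged over replicates and divided by
  the replicate standard deviation of `L(K)`; the interior K maximizing
  ΔK is reported, or none when ΔK is identically zero (a kneeless curve).
  ΔK is invariant to adding a constant to all log-likelihoods and scales
  as 1/σ when replicate scatter scales by σ.
* **Admixture EM**: a deliberately lightweight maximum-likelihood
  stand-in for Bayesian MCMC structure inference. Band presence is
  modelled as `x_ik ~ Bernoulli(Σ_c q_ic f_ck)` with per-sample
  memberships `q_i` on the simplex and per-cluster band frequencies
  `f_c`; EM alternates posterior ancestry assignment per (sample, band)
  with closed-form updates, from 10 random restarts (best likelihood
  kept, ties broken first-found). It ignores dominance and ploidy and
  approximates, not reproduces, a Bayesian bar plot. Label switching in
  recovery tests is resolved by exhaustive best matching of `F` profiles.
* **Baker's gamma**: for every leaf pair, the fusion level (merge index,
  not height) at which the pair first co-clusters is extracted from each
  tree; gamma is the Spearman correlation (average ranks on ties) of the
  two vectors. Using merge indices makes the statistic purely
  topological: trees with identical topology but different heights score
  1. The Pearson correlation of cophenetic heights is reported as a
  secondary statistic. An optional permutation p (shuffling one tree's
  leaf labels, 999 permutations, seeded) is off by default.

## Synthetic data generator

The generator emulates the study conditions so that every estimator has a
ground-truth test bed; its defaults are fixed, not tuned:

* **Design**: populations of 5 (RJ-like), 7 (hybrid), 3 (RS-like);
  two marker systems of nine primers × 17 bands each (306 bands, ~153 per
  system); six leaf traits; 117 metabolite features.
* **Bands**: independent Bernoulli draws given population frequencies
  (the same independence per-band statistics assume; no linkage).
  Parental frequencies follow a Balding–Nichols Beta model around a
  uniform ancestral frequency with divergence `F = 0.35`, giving the
  moderate differentiation regime the study reports.
* **Hybrid**: band frequencies are the admixture blend
  `α f_RJ + (1−α) f_RS` with `α = 0.55` — the source design describes the
  hybrid as admixed with a predominance of the *R. japonica* parent but
  gives no number, so a value slightly above one half encodes that
  predominance. A `mosaic` mode drawing a parental ancestry per band per
  individual is available; both have the same expected frequencies.
* **Clonality/noise**: with probability `clonal_duplicate_rate`, a sample
  copies an earlier row of its population and then applies per-cell
  `flip_noise` — emulating clonal near-duplicates; both default to 0.
* **Morphology**: multivariate normal per taxon, hybrid mean and
  covariance the α-blend of the parents, truncated at 0 (length traits);
  diagonal covariances with 12 % coefficients of variation. Apex length
  and width share one mean across taxa, so they carry no taxon signal —
  mirroring the study's finding that only those two characters are
  non-discriminating.
* **Metabolites**: log-normal intensities per taxon (log-sd 0.4), 15
  signature features raised and 15 lowered in the RS-like parent, and 3
  features structurally zero there (the piceid pattern — exactly 0 for
  every RS sample, while the hybrid inherits only zeros shared by both
  parents).
* **Structure likelihoods**: a piecewise-linear mean lnP(D) curve with a
  knee at the true K (rise 400 per K below, 20 above, replicate noise sd
  50) emulates the shape ΔK detects.

Every generator is a pure function of (config, seed). What the generator
does **not** emulate: linkage between bands, per-individual ancestry
mosaics beyond the optional mode, ploidy/dosage, backcrosses,
environmental trait plasticity, chromatographic peak-shape or
missing-at-acquisition artifacts in LC-MS tables. Tests passing on this
generator therefore demonstrate correctness of the estimators under the
stated model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* Frequencies at 0 or 1 yield `I = 0` via the `0·ln 0 = 0` convention.
* `GST` is defined 0 when `HT = 0`; `Nm` is flagged infinite at
  `GST ≤ 0`.
* Negative among-population variance components are clamped to zero with
  a warning (Phi then 0).
* Tie-breaking in agglomeration is deterministic (scipy's nearest-
  neighbor chain; verified against brute-force agglomeration that merges
  the lowest-index minimal pair on all small inputs).
* EM frequencies are clipped to (ε, 1−ε) to keep the likelihood finite;
  the trace is checked non-decreasing.
* Permutation p-values use the add-one rule, so `p ∈ (0, 1]` always.

## Problem sizes used in the checks

The bundled analyses are desk-scale by design: 15 accessions, ≈300 bands,
6 compounds. Simulation-backed checks use 2 000 samples per population
for frequency recovery, 500 null replicates (199 permutations each) for
the AMOVA type-I calibration, 20 seeds for ΔK recovery, and exhaustive
partition/agglomeration enumeration at N ≤ 6 for the oracle-equivalence
properties.

## Known limitations

* Diversity statistics assume biallelic dominant coding; published tables
  produced under other allele-counting conventions (e.g. `Na > 2`) are
  not reproducible from a 0/1 matrix and are not attempted.
* Ward on non-Euclidean dissimilarities is an approximation (shared with
  the common practice it mirrors).
* The admixture EM is a stand-in, not a reimplementation, of Bayesian
  structure inference; its memberships are maximum-likelihood point
  estimates without uncertainty.
* Pairwise-complete distances under missing data break the exact AMOVA
  SS decomposition and are gated behind an explicit option with a
  warning.
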