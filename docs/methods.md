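# Methods

This note documents the models, null distributions, parameter choices and
numerical conventions behind `dcnet`, and what the synthetic-data tests do
and do not establish about real data.

## Differential coexpression model

Given two single-condition expression matrices over a shared gene set (12
and 14 timepoints in the emulated glucose-shift design; equal grids are
also supported), every unordered gene pair gets within-condition Spearman
correlations r_a and r_b (average ranks for ties) and the aggregated score

    score = Δ · (1 + w·(|r_a| + |r_b|)/2),   Δ = r_b − r_a.

Positive scores mark pairs whose correlation is higher in condition b,
negative the converse; the magnitude term (weight `w`, default 1.0,
configurable) orders pairs sharing the same Δ by the strength of the
correlations involved.  The plain Δ is exported alongside the score so
users can rank on it alone.

**Permutation test.**  Significance of |score| is two-sided and empirical:
a single pool of `n_perm` column-label permutations is applied to all
pairs, and p = #{|score_perm| ≥ |score_obs|}/n_perm.  Two resampling
schemes are provided: `pooled` (default) reassigns the pooled sample
columns to conditions preserving the per-condition counts, appropriate for
independent series; `paired` swaps labels per shared timepoint and
requires equal grids, appropriate for paired designs.  The shared pool —
one set of reassignments reused for every pair — is what makes ~10⁵–10⁶
pairs tractable; per-pair pools would multiply cost by the pair count for
no change in the marginal null.  The estimator is count/n_perm (a
`plus_one` flag switches to (count+1)/(n_perm+1), which changes the
attainable minimum p).  A comparison tolerance of 1e-12 makes exactly tied
scores count as "≥", so a pair with score 0 gets p = 1 rather than a
float-noise-dependent value.

**Calling.**  Empirical p-values are Benjamini–Hochberg adjusted
(statsmodels) and pairs with adjusted p strictly below α = 10⁻⁴ become
DCELs (a flag thresholds the raw p instead).  Note the interaction between
`n_perm` and α: with BH over m pairs, only pairs with p = 0 can fall under
10⁻⁴ unless n_perm ≫ m/α, so the production setting is n_perm = 10⁵ and
desk-scale runs warn when α < 1/n_perm.  Constitutive links require
r > 0.95 strictly in both conditions.  Pairs involving a zero-variance
gene are dropped before scoring, with a logged count.

## Preprocessing

Fixed order: quantile normalisation → missing-fraction filter → KNN
imputation → probe collapse → variance filter.  Conventions:

* Quantile normalisation is rank-mean with the reference distribution
  interpolated onto a common quantile grid; ties receive the average
  reference value and missing entries stay missing.  Each condition's
  arrays form their own pool by default (the two conditions are separate
  series; `pool_conditions=True` merges them).  The transform is
  idempotent on complete matrices.
* Rows with more than 20% missing timepoints in *any one* condition are
  dropped.
* KNN imputation (k = 10): plain Euclidean distance over mutually
  non-missing columns, neighbour pool restricted to the same matrix,
  imputed value = unweighted mean of the k nearest rows observed at the
  target column.  Fewer than k candidates triggers a warning and uses all.
* Probes without a gene annotation are removed; multi-probe genes are
  averaged row-wise.
* The variance filter keeps a gene iff its sample SD is in the top 25% in
  condition a **or** condition b (drop only when low-variance in both);
  the cutoff is the SD of the ⌈0.25·n⌉-th ranked gene and ties at the cut
  are kept.

## Network topology

Edge signs are ignored for degree, clustering and path statistics (the
published summary tables treat the networks as unsigned simple graphs);
signs enter only the triad census and edge counts.  Path statistics are
defined on connected graphs; callers pass the largest component.

* **Power-law exponent.**  Discrete maximum-likelihood fit of
  P(k) ~ k^−γ with Hurwitz-zeta normalisation, γ searched in (1.01, 8);
  xmin is free by default, chosen by minimal Kolmogorov–Smirnov distance
  between the tail ECDF and the fitted model (the standard
  Clauset-style estimator).  Degrees are sorted before summation so the
  fit is exactly permutation-invariant.
* **Degree-preserving clustering null.**  Each sample rewires a copy of
  the graph with 10·E attempted double-edge swaps (degree sequence exact);
  the empirical p is the fraction of samples with C ≤ C_observed.  1,000
  samples are used in tests; 10⁵ is the documented production setting.
* **Data-randomisation triad null.**  Rebuilding a fully permutation-
  tested network inside every replicate is intractable, so each replicate
  shuffles the condition labels, recomputes all pair scores, and takes the
  top-|score| `observed_edge_count` pairs as the replicate network — a
  rank-matched stand-in preserving network size.  Its triads-per-edge
  proportion forms the null; the empirical p is the fraction of replicates
  at or below the observed proportion.
* **Triad census.**  Exact triangle enumeration classified by the number
  of positive edges; the fraction of odd-positive triads is the quantity
  predicted to be ~1 in single-condition coexpression networks by sign
  transitivity (undefined and reported as such on triangle-free graphs).

## GO semantics and functional clustering

Only the biological_process namespace is used; is_a links define the DAG
(part_of optional).  Annotations with evidence codes IEP and IGI are
excluded by default — both are inferred from exactly the kinds of data
(expression patterns, genetic interactions) the analysis interrogates, so
keeping them would be circular.  Term probability p(t) is the annotated-
gene frequency of t or any descendant, computed from the loaded corpus
itself after evidence filtering (no external reference corpus is assumed).
Term similarity is the relevance measure — Lin's ratio at the most
informative common ancestor weighted by (1 − p(MICA)) — so similarity
through the root is 0 and self-similarity of a term with probability p is
1 − p.  Gene similarity is the best-match average over the genes' direct
term sets (propagated sets are used for IC and enrichment, direct sets for
similarity, the standard funSim convention).  Enrichment is the upper-tail
hypergeometric test over terms with M ≥ 1 and k ≥ 1, BH-corrected within
one run.

Genes are clustered on their rows of the funSim matrix by average-linkage
agglomeration with distance 1 − Pearson correlation of profiles.  The
cluster count (or cut height) is a required user parameter — the original
analyses chose it by inspecting the heatmap, and no automatic selection is
attempted; the replication configurations use 7 and 9.  Constant profiles
(undefined correlation) become singleton clusters.  Link densities use the
pair-count normalisation D_ij = I_ij/(n_i·n_j) off-diagonal and
I_ii/C(n_i,2) on it — the only convention that makes D a density in
[0, 1]; singleton diagonals are reported as 0 and flagged.  Densities are
standardised against a label-shuffling null (cluster sizes preserved;
z = (D − μ)/ρ; z > 1.5 flags enriched cluster pairs, mirroring the
published cluster-interaction maps), and the same shuffle pool gives the
empirical p of the between/within link-count ratio.  Zero observed
within-cluster links make the ratio infinite; the test then falls back to
the between-link count and logs it.

## TF activation inference

The observed statistic per TF is the number of network edges with both
endpoints in the TF's target set.  The null replaces every network node
with a gene regulated by a similar number of TFs — matching pool = genes
with the same regulator count, widened ±1, ±2, … until it holds ≥ 50 genes
(the wording "same or a similar number" fixes no tolerance; adaptive
widening guarantees feasibility in sparse count bins) — without repetition
within a permutation, and a node may draw itself so the observed
configuration lies in the null's support.  Empirical p = fraction of
permutations with count ≥ observed; BH q is reported alongside, and the
activation call uses raw p < 0.05 by default (the published tables
threshold the p column; a flag switches the call to q).  Auxiliary
statistics: the common-TF index of a gene pair (mean of Jaccard and
overlap coefficients of the regulator sets; 0 with a flag when a gene has
no regulator) and the per-TF shift of target–target correlation
distributions between conditions, compared by two-sample
Kolmogorov–Smirnov (the original work reports only that the distributions
differ, without naming a test; KS is the assumption-light default).

## Synthetic data: what it emulates and what it does not

The generator produces two conditions with (optionally unequal) timepoint
counts, gene modules driven by a shared per-condition latent signal plus
iid Gaussian noise, a toy rooted ontology with annotations (including
IEP/IGI-tagged ones to exercise filtering), and a TF table with one
designated deactivated TF covering the differential-link endpoints.

* **Latent signal.**  Default is an iid Gaussian sequence rescaled to
  sample SD exactly `latent_amplitude`, so `latent_amplitude/noise_sd` is
  precisely the per-gene signal-to-noise ratio.  A shared-period sinusoid
  with random phase is available (`latent_kind="sine"`) for visually
  smooth trajectories, but sinusoids of one period are mutually correlated
  (cosine of the phase difference), which plants unlabelled cross-module
  structure; the white latent makes distinct modules exactly independent.
  Every statistic in the package is invariant to within-condition time
  ordering, so latent smoothness is irrelevant to what the tests measure.
* **Module types.**  (i) *Rewired* modules — coexpressed in both
  conditions with half the module sign-flipped in exactly one — are the
  calibrated differential condition: cross-half pairs flip correlation
  sign (|Δ| ≈ 2) and are detectable at the strict production threshold,
  while same-half pairs stay constitutive.  Their differential blocks are
  complete-bipartite, i.e. triangle-free — the constructive analogue of
  the sign-transitivity argument for tree-like differential networks.
  (ii) One-condition-only modules give every within-module pair a weaker
  |Δ| ≈ 1 contrast; with 12–14 samples per condition, the pooled
  permutation null's tail (moderately unbalanced splits compounded with
  noise fluctuation) reaches comparable scores, so such pairs are *not*
  reliably callable at adjusted p < 10⁻⁴ — they are generated for
  completeness and as triangle fuel in the shuffled-data null, not as the
  recovery benchmark.  (iii) Plain both-condition modules plant
  constitutive links.
* **Fidelity limits.**  No dye bias, spatial artifacts, heteroscedastic
  noise, probe-level effects or realistic module-size distributions; the
  toy ontology is far shallower than GO.  Passing tests therefore
  establish the *statistical machinery* (calibration of the permutation
  and randomisation nulls, recovery under the stated SNR, direction of
  the topology contrasts), not performance on any particular microarray
  platform.

## Problem sizes in the test and acceptance runs

Recovery and calibration run at 200 genes × 14+14 timepoints with 10,000
permutations (recovery) or 1,000–2,000 (calibration and network
construction); the clustering null uses 1,000 degree-preserving samples
and the triad null 200 shuffled-data replicates on a 70-gene fixture;
planted-TF recovery uses 20 generator seeds at 2,000 permutations.  These
sizes keep a full run in the low minutes while leaving every null
distribution well resolved relative to the thresholds tested; the
production defaults (10⁵ permutations everywhere) remain the configured
values for real-data runs.

## Known limitations

* The score's tie-break weight `w` has no published reference value; the
  default 1.0 reproduces the documented ordering of the worked example,
  and `w` is exposed precisely because the original functional form is
  not recoverable.
* The shared permutation pool makes per-pair p-values weakly dependent
  across pairs (they share the same extreme permutations); this is
  irrelevant to per-pair calibration but means joint error rates are
  controlled only through BH on the marginal p-values.
* The degree-matched TF null conditions on regulator counts only; TFs
  whose targets are structured in ways uncorrelated with regulator count
  (e.g. chromosomal clustering) are outside the null's reach.
* Average-linkage clustering of a similarity-profile correlation distance
  inherits the usual sensitivity of hierarchical clustering to the chosen
  cluster count; the package deliberately refuses to choose it.
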