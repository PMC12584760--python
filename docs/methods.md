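# Methods

`enteronet` implements the downstream statistical workflow used in
enterotype-centred livestock microbiome studies: discovery of discrete
community types from genus-level composition, comparison of diversity
and host phenotypes between them, differential-abundance testing,
co-occurrence network inference with random-matrix-theory (RMT)
thresholding and topological role assignment, and genus–phenotype
association. This note records the models, the defaults and why they
were chosen, and what the synthetic benchmark does and does not show.

## Enterotype model

Samples are compared on the **Jensen-Shannon distance**

d(p, q) = sqrt( ½·KL(p‖m) + ½·KL(q‖m) ),  m = (p+q)/2,

in natural log, a metric bounded by sqrt(ln 2) ≈ 0.8326. The literature
uses "divergence" and "distance" interchangeably; the square-root
(metric) form is what clustering and ordination require, so that is
what the package computes. Zeros are handled by adding a pseudocount
(default 1e-6) to every entry and renormalizing rows once before any
distance is computed; with pseudocount 0 the 0·log 0 = 0 convention
applies.

Clustering is classic **PAM** (k-medoids): greedy BUILD seeding
followed by steepest-descent SWAP accepting only strictly improving
exchanges, with all ties broken by lowest sample index. The procedure
is fully deterministic — no restarts, no seed. A consequence worth
knowing: on unstructured (uniform random) instances PAM can terminate
on a swap plateau that is not the global optimum; on data with genuine
cluster structure it recovers the exhaustive-search optimum, which the
test suite verifies by enumeration on small instances.

Model selection uses a **Calinski-Harabasz index computed from the
distance matrix via medoids**: W is the sum of squared sample-to-medoid
distances, B the size-weighted sum of squared medoid-to-overall-medoid
distances, CH = [B/(k−1)]/[W/(n−k)]. The Euclidean centroid form is
unavailable because Jensen-Shannon distances are not an inner-product
geometry; the medoid form is the natural analogue. k is scanned over
2..min(10, n−1) by default (CH is undefined at k=1); ties select the
smaller k.

**PCoA** is classical scaling: eigendecomposition of the double-centred
squared-distance matrix, axes scaled by the square roots of positive
eigenvalues. Negative eigenvalues (the distance is non-Euclidean) are
excluded from both the axes and the proportion-explained denominator.

## Diversity and differential statistics

Alpha diversity: Sobs, Shannon (nats; base configurable), Chao1 with
the `S + F1²/(2·F2)` form and the bias-corrected `S + F1(F1−1)/2`
fallback when no doubletons exist, and ACE with rare threshold 10 and
the Chao1 fallback at zero estimated coverage. Chao1 and ACE are
undefined on relative abundances, so the per-sample profile refuses to
compute them from fractions unless an explicit sequencing depth is
supplied for de-normalization — a deliberate guard against silently
wrong richness estimates. Beta diversity is Bray-Curtis with **ANOSIM**
(rank-based R, midranks for ties, permutation p with the plus-one rule
so p is never 0; the permutation seed is a required API argument).

Feature tables are tested per-feature with the **Wilcoxon rank-sum**
test (exact enumeration when the pooled sample is ≤12 without ties,
otherwise the tie- and continuity-corrected normal approximation) and
**Benjamini-Hochberg** FDR across features of one table. Phenotype
traits use **Welch t-tests** (pooled-variance Student variant by flag)
without multiplicity adjustment — the conventional treatment of a small
physiological trait panel — and report mean ± SE plus a "tendency"
flag for 0.05 < P < 0.10. Fat-corrected milk yield is the standard
0.4·M + 15·F combination of milk mass and fat mass.

Genus–phenotype association is a Spearman rho/p grid with pairwise
deletion of missing values and raw P < 0.05 significance flags by
default (BH adjustment available but off, matching the conventional
presentation of such heatmaps).

## Co-occurrence networks

Two presets share one engine:

* **Genus preset** — taxa filtered to mean relative abundance strictly
  >0.5 % and prevalence strictly >50 % of all samples, then all-pairs
  Spearman correlation within each enterotype's samples; edges kept at
  P < 0.05 with sign retained.
* **ASV preset** — taxa detected in ≥60 % of the cluster's samples
  (exclusion of anything under 60 %), Pearson similarity matrix, RMT
  threshold, fast-greedy (Clauset-Newman-Moore) modularity
  optimization, Zi/Pi node roles.

"Detected" means strictly positive abundance. The abundance filter uses
the mean across all samples of the analysed table; whether to compute
it before or after splitting by cluster is the caller's choice (the
pipeline computes it on all samples, then correlates within clusters).

### RMT threshold

For each candidate cutoff t (default 0.30–0.95 in steps of 0.01),
entries with |r| < t are zeroed and the eigenvalue spectrum of the
result is examined. Exact degeneracies are collapsed, the cumulative
spectral function is unfolded with a Gaussian-kernel empirical CDF
(Silverman bandwidth), and the nearest-neighbour spacing distribution
is tested by chi-square (Sturges binning, tail folded into the last
bin) against the Poisson law e^{−s} and the GOE Wigner surmise
(π/2)·s·e^{−πs²/4}. A noisy correlation matrix shows GOE level
repulsion; once thresholding has removed the noise edges the spectrum
of the decoupled signal blocks becomes Poisson. The chosen threshold is
the smallest t at which Poisson is not rejected (p > 0.05) and GOE
describes the spacings worse (rejected at 0.05, or simply a poorer fit
than Poisson). Two conventions make the scan robust on highly
structured matrices: a spectrum with fewer than 10 distinct spacings
after degeneracy collapse is classified Poisson-like outright (massive
exact degeneracy is the extreme opposite of level repulsion and occurs
exactly when the matrix has decomposed into disconnected rigid blocks),
and if no candidate qualifies the scan falls back to the maximum
candidate with an explicit warning flag. All internals (range, step,
bandwidth, binning, minimum spacing count, selection rule) are exposed
as parameters.

### Modules and roles

Modules come from CNM greedy modularity maximization (edgeless graphs
degenerate to singleton modules with Q = 0). Per node,
Zi = (κ − mean κ)/sd(κ) over its module with κ the within-module degree
(population SD; Zi = 0 when the SD is 0 or the module is a singleton)
and Pi = 1 − Σ_s (k_s/k)² over modules s (Pi = 0 for isolated nodes).
Roles use the standard thresholds with inclusive lower boundaries:
peripheral (Zi ≤ 2.5, Pi ≤ 0.62), connector (Zi ≤ 2.5, Pi > 0.62),
module hub (Zi > 2.5, Pi ≤ 0.62), network hub (Zi > 2.5, Pi > 0.62).

## Synthetic cohort generator

The generator plants known structure so that every stage can be scored
against ground truth without any sequencing data.

**Enterotype cohorts** are a Dirichlet mixture: 134 samples split
deterministically 43/91 (largest-remainder allocation, so tests can
assert exact counts), 80 genera, scalar base concentration 0.5 (a
sub-uniform Dirichlet produces the long-tailed, zero-rich genus
profiles typical of gut communities), and 5 disjoint driver genera per
enterotype whose concentration is multiplied by the driver effect
(default 10) in their own cluster. Phenotypes are Normal(mean[cluster],
sd); the default trait panel uses serum means observed in lactating
dairy goats (glucose 2.89 vs 2.65 mmol/L, albumin 24.0 vs 25.4 g/L,
total bile acid 13.9 vs 10.2 µmol/L; SDs back-computed from published
SEs) together with plausible milk-yield and fecal-VFA effects. Because
within-cluster heterogeneity of real cohorts is not published, the
effect sizes are calibration choices of this package, fixed once.

**Correlated-module tables** use a log-normal latent-factor model: each
module shares a standard-normal factor, members load
λ = sqrt(ρ/(1−ρ)) against unit residual noise (pairwise log-scale
correlation exactly ρ), and the designated hub loads 1.5× stronger.
Every taxon's total log-SD is rescaled to 0.8 — realistic dispersion;
without it the exponentiated tails destroy abundance-scale Pearson
correlation. Rows are closed to the simplex; the pre-closure log matrix
is kept in the ground truth because compositional closure provably
cancels a factor loading uniformly on all taxa, so planted-structure
checks that span the whole community must look at the pre-closure
correlations.

A multinomial resampling helper converts relative abundances to integer
counts at fixed depth (default 20 000 reads) for the richness
estimators.

All randomness in a call flows from one integer seed through a single
`numpy.random.Generator`; identical configuration gives bit-identical
tables.

### What the simulator does not emulate

Sequencing error, chimeras, count overdispersion beyond the Dirichlet,
taxonomic assignment uncertainty, phylogenetic structure, and the
unknown within-cluster heterogeneity of real cohorts. Passing recovery
tests therefore demonstrates correctness of the inference machinery
under its own assumptions, not field performance on real 16S data.

## Numerical conventions and edge cases

- All tie-breaks (PAM swaps, medoid selection, CH ties, nearest-medoid
  assignment) resolve to the lowest index / smallest k, making every
  clustering result order-stable and reproducible without seeds.
- CH returns +inf when the within-cluster dispersion is exactly 0.
- Wilcoxon on two identical groups, and Welch t on two equal-mean
  constant groups, return p = 1.
- Constant taxa: Spearman/Pearson correlations are undefined; the
  network code skips such pairs (Spearman) or records 0 (Pearson), each
  with a warning, and the association module returns NaN.
- Bray-Curtis between two all-zero samples is an error.
- BH q-values are clipped at 1 and mapped back to input order.
- An ANOSIM p-value can never be 0 (plus-one rule).

## Problem sizes used in the test suite

The suite runs the full recovery benchmark at the study scale (134
samples × 80 genera, 10 seeds), statistical calibration at 200–500
null replicates per test, oracle comparisons by exhaustive enumeration
at n ≤ 8, and network/RMT checks on 30–60 taxa with 120–300 samples.
These sizes give stable verdicts for every assertion while keeping the
whole suite fast.

## Known limitations

- The RMT selection rule is a heuristic; on matrices whose spectra are
  neither clearly GOE nor clearly Poisson the scan can fall back to the
  maximum candidate (flagged, never silent).
- Correlation-based co-occurrence on compositions carries the usual
  closure-induced negative bias (about −1/(T−1) between otherwise
  independent taxa); no SparCC-style correction is applied, mirroring
  the conventional workflow this package implements.
- PAM is exact only in the sense of its own local search; see above.
- Chao1/ACE assume counts are true read counts; resampled multinomial
  counts understate the rare tail of real libraries.
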