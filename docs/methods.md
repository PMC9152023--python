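# Methods

This note records the statistical model behind each stage, the conventions
adopted where the standard workflow leaves choices open, and what the
synthetic-data validation does and does not establish.

## Ingestion and matched representation

Raw quantification arrives as one row per (animal, region, bregma section)
with left/right hemisphere counts of c-fos+ nuclei, sampled between +2.80 and
−3.52 mm from bregma. Aggregation is a two-stage mean: hemispheres within a
section first (a lone hemisphere stands for the section if the other is
missing — discarding it would waste data without removing bias), then
sections within a region. Values are stored as reals, not integers, because
they are means.

Correlation analysis requires every retained animal to have a value for every
retained region ("matched representation"). How to reach that state when
cells are missing is under-determined, so the filter is a declared
convention, not a reconstruction: regions missing in more than half the
animals are dropped first (systematic absence), then a greedy alternating
deletion removes whichever animal or region has the most remaining holes
(ties favor dropping the animal, preserving regions). The result is complete,
deterministic, and maximal in the sense that re-adding any dropped row or
column would reintroduce a hole; it is not guaranteed to be the globally
largest complete submatrix (that problem is NP-hard).

## Regional activation screen

Per region, counts follow a fully crossed 2×2 between-subjects design
(sex × training). With unequal cell sizes (n = 3–5) the sums-of-squares type
matters; Type III with sum-to-zero coding is used because it is the
convention of the commercial packages such figures are produced with and is
well defined in the presence of the interaction. Since every term has one
degree of freedom, the Type III F equals the squared Wald t of the
corresponding coefficient in the full effect-coded OLS fit, which is how it
is computed (statsmodels OLS underneath); equality with
`anova_lm(..., typ=3)` and with an extra-sum-of-squares oracle is asserted in
tests. Regions with numerically zero residual variance are flagged degenerate
(NaN F/p) rather than raising.

Planned comparisons use Fisher's LSD: t = (x̄_a − x̄_b)/√(MSE(1/n_a + 1/n_b))
with the ANOVA's pooled MSE and error df. By default only the trained-male vs
trained-female contrast is run, and only where the interaction reaches α —
both configurable, since the gating convention is ambiguous in practice.
No multiple-testing correction is applied across regions by default
(region-wise α = 0.05 is the fidelity-first convention here);
Benjamini–Hochberg adjustment is available as an opt-in flag. ANOVA is run on
raw counts, not log counts, matching field practice; the calibration tests
show the F tests remain close to nominal under the generator's lognormal
noise at these sample sizes.

## Correlation networks

Within each group, Pearson r over animals for all region pairs; two-tailed
p from the exact t transform on n−2 df. Two-tailed is the right reading
because the implied critical values at α = 0.05 — r* = t*/√(t*² + n − 2) =
0.950 at n = 4 and 0.997 at n = 3 — are the two-tailed ones; positivity is
enforced at edge selection instead (edge iff r > 0 and p < threshold,
strictly). Zero-variance regions yield flagged-undefined (NaN) entries that
can never become edges. No adjustment across the ~6,000 pairs: at n = 3–4
any correction would eliminate essentially all edges, so the false-positive
burden is handled at the network level by the null models instead.

## Graph measures

Conventions, chosen once and used everywhere:

- **Active node**: degree ≥ 1. Isolated regions are excluded from centrality
  normalization, path-length averaging, ER matching and the hub denominator.
- **Betweenness** is normalized by (N−1)(N−2)/2 over active nodes
  ("fraction of shortest paths"). Hub identification is rank-based, so the
  constant is cosmetic.
- **Characteristic path length** averages over *reachable* pairs only —
  thresholded networks are routinely disconnected and an infinite-distance
  convention would make L undefined for every graph with two components.
- **Transitivity** = 3·triangles/connected triples; undefined (NaN) when no
  triples exist. **Assortativity** is the endpoint-degree correlation,
  undefined on degree-regular graphs.
- **Small-worldness** S = (T/⟨T_ER⟩)/(L/⟨L_ER⟩) with an ensemble of 100
  Erdős–Rényi G(n, m) graphs matched on active-node and edge counts; G(n, m)
  rather than G(n, p) because exact edge matching is tighter at small m.
  Seeded and therefore reproducible.

## Markov clustering

MCL is implemented directly (expansion power 2; inflation then column
renormalization; self-loop weight 1; prune entries < 1e−10; converged when
the largest elementwise change < 1e−8, hard stop at 200 iterations; attractor
rows read out clusters, overlaps resolved to the largest cluster, ties to the
lowest index). The inflation hyperparameter is tuned per graph over the grid
1.1–3.0 (step 0.1) by maximizing Newman–Girvan Q = Σ_c (e_cc − a_c²); the
modularity variant is a declared choice, as is the grid. Ties in Q resolve to
the smallest inflation (coarser partitions preferred).

## Null models and threshold sweep

Randomized controls preserve each node's degree exactly: 10·m attempted
double-edge swaps (Maslov–Sneppen convention; swaps creating self-loops or
duplicate edges are skipped, so unswappable graphs such as a triangle return
unchanged). Connectedness is not enforced — the data networks are themselves
disconnected. Ensemble comparisons report null mean/sd and the data value's
midpoint-rank empirical quantile (less + ½·equal)/n. The threshold sweep
rebuilds network + ensemble at 20 thresholds, p < 0.005 to p < 0.1 in steps
of 0.005; thresholds yielding empty networks produce NaN rows rather than
errors. Within an ensemble, small-worldness uses the same (smaller, default
20-graph) ER reference for data and replicates so the comparison is
like-for-like.

## Hubs

A hub ranks in the top 20% of active nodes for both degree and betweenness.
The cutoff index is ceil(0.2·N_active); boundary ties are included, with one
exception that keeps "top" meaningful: when the cutoff value equals the
sample minimum while larger values exist (typically betweenness 0 in sparse
graphs), bottom-tied nodes do not qualify. If every node is tied on a
measure, all qualify — a cycle graph is all-hubs by construction. Robustness
counts hub qualifications over the base network plus nine pruned networks
(p < 0.005…0.045, step 0.005; ten graphs per group); ranking ties share a
rank and the "most robust hub" is reported as a possibly-plural set.

## Synthetic cohorts

The generator emulates the study conditions: four groups (naive n = 4,
trained n = 3 per sex by default, matching a matched-representation cohort),
112 regions, and counts

count_ar = exp(μ_r + β_r·[trained] + σ_r·[female] + γ_r·[female×trained]
+ Σ_k L_rk f_ka + ε_ar),  f ~ N(0,1), ε ~ N(0, noise_sd).

The lognormal form keeps counts positive with right skew, and effects
multiplicative. Defaults: baseline μ = 4.0 (~55 counts); training effect 0.7
(log scale, ≈ 2× increase) in 93 of 112 regions; sex effects 0.35 in 5
regions and interactions 0.5 in 8, nested at the end of the training-
responsive range; noise_sd 0.3. The `with_blocks` design adds latent-factor
blocks: near-equal contiguous region blocks loading 0.5 on a private factor
(within-block log-scale correlation 0.8), one planted hub per group loading
0.4 on two adjacent factors so its edges bridge two blocks — mirroring the
observation that empirical hubs sit inside large clusters and border others.
Noise for the block design is 0.25, for a total log-sd ≈ 0.56 (count CV
≈ 0.5, typical of regional c-fos).

A property worth knowing: Pearson correlation is computed on raw counts (as
in the real analysis), and lognormal tails make the sample correlation
between *independent* blocks heavy-tailed — an animal with large scores on
two factors inflates every between-block pair at once. With strong loadings
this occasionally merges two planted blocks at any inflation; the default
loadings are mild enough to keep marginals realistic while leaving the
planted structure recoverable. Recovery tests therefore check the mean
adjusted Rand index over seeds, not every seed.

What passing tests show: the implementation is internally correct (oracle
equivalence), calibrated under the null, and able to recover planted
structure under realistic noise. What they do not show: robustness to
features real cohorts have and the generator lacks — section-level
variability, non-lognormal dispersion, unequal per-region baselines within a
block, registration artifacts, or damage-driven missingness patterns.

## Problem sizes used in validation

Oracle sweeps use 200 random graphs of ≤ 9 nodes (exhaustive path
enumeration is exact there). Null-model contracts use a 50-region cohort
with 1000 rewired replicates for the degree-sequence check and 100 per
threshold for the 20-point sweep. Recovery uses 48–49 regions × 50 animals ×
20 seeds; calibration uses 500 independent null regions × 4 seeds. These
sizes make the distributional claims stable without being wasteful.
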