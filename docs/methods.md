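# Methods

## Model and procedure

`dcmnet` tests, for every unordered pair of metabolites, whether the
Pearson correlation of their concentrations differs between two paired
compartments (plasma and joint fluid). The per-pair statistic is a weighted
difference of Fisher z-transformed correlations,

    r_diff(i,j) = sqrt((n_plasma − 3)/2) · z_plasma(i,j)
                − sqrt((n_JF − 3)/2) · z_JF(i,j),
    z = arctanh(r),

with the joint-fluid term subtracted from the plasma term, so a positive
value means stronger co-variation in plasma. The sqrt((n−3)/2) weights make
the statistic reduce exactly to the classical two-sample correlation z-test
`(z₁ − z₂)/sqrt(1/(n₁−3) + 1/(n₂−3))` when the two sample sizes are equal,
so its null distribution is approximately standard normal; this equivalence
is asserted to 1e−12 in the test suite, and an unweighted z-difference is
available (`weighted=False`) for sensitivity analysis only. |r| is clamped
to 1 − 1e−7 before the transform so degenerate, perfectly collinear columns
cannot produce infinities; the perturbation is far below sampling error for
any realistic n.

Significance is assessed by permutation rather than the normal
approximation. One shared set of B label shufflings is applied to all pairs
— the standard global-null construction, B× cheaper than per-pair shuffles
and exact for the familywise exchangeability null. Two schemes are offered:
**pooled** (default) reassigns all samples at random to two groups of the
original sizes; **paired** swaps the plasma/JF labels independently within
each subject and requires complete pairs. Two-sided p-values use the add-one
correction p = (1 + #{|r_diff_perm| ≥ |r_diff_obs|})/(B + 1), which is
strictly positive and gives valid type-I control; ties count as exceedances
(conservative). Analytic normal-approximation p-values exist only as a
cross-check (`analytic_pvalues`), never as the primary path.

Multiple testing across the m(m−1)/2 pairs uses Bonferroni by default
(threshold α/m_pairs; for 167 metabolites and α = 0.05 that is
0.05/13861 ≈ 3.6×10⁻⁶) or Benjamini–Hochberg. Because a permutation p-value
cannot fall below 1/(B+1), a Bonferroni threshold finer than the floor is
unreachable: the tool emits a warning in that case instead of silently
reporting zero discoveries. Raising B (the threshold above needs
B ≳ 2.8×10⁵) or using the analytic cross-check are the two remedies.

## Preprocessing

Wide-format delimited concentration tables are read with configurable
missing-value tokens (optionally treating 0 as below detection). Per sex
stratum, a metabolite is retained when detected in **strictly more than**
`min_detection` (default 0.8) of the stratum's samples — detection is
computed with plasma and JF pooled so both compartments keep one common
metabolite list, which the paired analysis requires; a per-compartment
variant (intersection of the two retained lists) is available. Remaining
missing values are imputed with half the metabolite's minimum observed value,
again pooled across compartments so both sides share one concentration
floor. Metabolites left with zero variance in either compartment are dropped
with a logged warning rather than aborting the stratum. At least 4 samples
per compartment are required (the n − 3 variance terms must be positive).

## Network construction and core metabolites

Edges are the pairs significant at the chosen tier (nominal permutation
p < α, or the corrected flags); nodes are the metabolites incident to at
least one edge, so isolated metabolites never enter the network and mean
degree is exactly 2|E|/|N|. Edge sign is the sign of r_diff. Centralities
treat every edge as unit length and ignore signs: degree; betweenness
normalized by (n−1)(n−2)/2; closeness in the within-component form scaled by
(component size − 1)/(n − 1) (the Wasserman–Faust convention, networkx
`wf_improved`), which matters whenever the network is disconnected. All
three are verified against exhaustive shortest-path enumeration on random
graphs of ≤ 7 nodes.

A node is a **core metabolite (hub)** when its degree reaches the
`degree_quantile` (default 0.9) of all node degrees and its betweenness or
closeness (configurable: or/and) reaches the `centrality_quantile` (default
0.9). Quantiles use the exclusive (Weibull) definition, position q·(n+1) in
the sorted sample: the common interpolated definition places the 90th
percentile of a star's degree sequence at the leaf value, so every leaf
would count as "high-degree", while the exclusive definition keeps the
cutoff in the distribution tail. Ties at the cutoff are included by default
(`ties="include"`), so a perfectly regular graph is all-hubs; `ties="strict"`
yields none there — both behaviours are legitimate readings of a
percentile rule, hence the switch. Networks export as GraphML (lossless
round-trip), SIF with `pos_dc`/`neg_dc` interaction types plus a node
attribute table (Cytoscape-ready), or a plain edge table; node and edge
order is lexicographic so outputs are diffable and byte-reproducible.

## Synthetic cohort generator

Because concentrations from the motivating study design are not publicly
available, the package ships a generator that emulates its structure: two
sex strata of `n_subjects` (default 50) subjects, each with one plasma and
one JF sample; a 186-metabolite panel (90 glycerophospholipids, 40
acylcarnitines, 21 amino acids, 19 biogenic amines, 15 sphingolipids, 1
hexose). Latent vectors are multivariate normal with a within-class
equicorrelation backbone (default r = 0.5), exponentiated to lognormal
concentrations with per-metabolite log-means drawn once (uniform on
log 0.5 – log 100, roughly µM scale) and log-SD 0.5 (≈ 50% CV, typical
biological variation for targeted metabolomics). The two compartments share
the backbone and differ exactly at the planted differential pairs (default:
10 disjoint cross-panel pairs at latent r 0.7 in plasma vs 0.1 in JF, a
Δr = 0.6 effect at the edge of reliable detectability at n = 50 per
compartment). Planted-pair members are detached from their class backbone,
which keeps both target matrices positive semi-definite by construction;
arbitrary user targets are repaired by eigenvalue-clipping nearest-PSD
projection and rejected if the projection moves any entry by more than 0.1.

Missingness is left-tail censoring: per metabolite and compartment block,
the lowest round(n·rate) values become missing (rate 0.05 by default),
mimicking below-LOD dropout; 19 metabolites are planted at rate 0.30 so they
fall below the 80% detection filter, leaving 167 retained — the panel
bookkeeping the pipeline tests rely on. Because censoring uses empirical
order statistics, realized missingness matches the requested rate exactly up
to rounding. One seed governs all randomness; global random state is never
touched, and equal specs give bit-identical cohorts.

What the generator does **not** emulate: instrument batch effects and drift,
the real study's covariance structure (unavailable), between-compartment
within-subject coupling (plasma and JF latent vectors are independent given
the targets), and assay-specific LOD values. Correlation targets live on the
latent Gaussian scale; observed-scale Pearson correlations of the lognormal
data are mildly attenuated (at log-SD 0.5, a latent 0.7 observes near
0.67), so recovery tests assert detection and rank behaviour, not exact r.
Passing tests therefore demonstrate the statistical machinery is correct and
calibrated under a realistic-but-idealized data-generating process; they do
not certify performance on any particular real cohort.

## Numerical and design choices

- Permutation count B defaults to 1000; the add-one floor is 1/1001.
- Type-I calibration is checked on 20 no-effect cohorts (m = 20 metabolites,
  50+50 samples, B = 500): the nominal significant fraction must be
  0.05 ± 0.02. Planted-effect recovery is checked at the default Δr = 0.6,
  n = 50+50: sensitivity ≥ 0.8 at p < 0.05 with background ≈ α. Problem
  sizes were chosen so the full suite and the acceptance script run in
  seconds to minutes on one CPU while keeping the Monte-Carlo error well
  inside the asserted tolerances.
- The convergence property of the generator is tested at n = 8000, where the
  0.05 tolerance on empirical-vs-target correlations is a ≈ 4.5σ bound (at
  n = 2000 it would be ≈ 2.2σ — a coin flip, not a test).
- Strata are processed independently, with per-stratum child seeds derived
  via `SeedSequence` from the run seed; one failed stratum writes a
  structured error file and the others continue.
- Empty significant sets build an empty network with a warning (not an
  error); empty networks export as valid empty documents.

## Known limitations

- Pearson-only in this version: no Spearman or partial correlations.
- The permutation null assumes exchangeability of samples across
  compartments under the null; strong compartment-specific variance
  differences would violate it (the paired scheme is more robust there).
- Hub detection is a percentile heuristic; the "high centrality" notion has
  no universal definition, and the quantiles are exposed precisely because
  reasonable choices differ.
- Bonferroni-tier networks are empty at the default B (see the floor warning
  above) unless B is raised substantially.
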