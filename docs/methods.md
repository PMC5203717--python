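# Methods

This note documents the statistical procedures implemented in
`pneumotyper`, the synthetic world its tests run against, and the places
where a genuine design choice had to be made.

## Pipeline statistics

**QC.** Samples with fewer than 2 000 reads are dropped (the threshold at
which Shannon-diversity rarefaction curves plateau in practice).  Shannon
outliers are removed in a single pass: mean and sd (ddof = 1) of the
per-sample Shannon index are computed once over all samples and anything
strictly above mean + z·sd (default z = 5) is excluded; the rule is not
iterated.  With identical samples (sd = 0) nothing is removed.

**Rarefaction** draws one multivariate-hypergeometric sample per row
(subsampling reads without replacement) at depth 2 000, seeded; repeated
calls with the same seed are bit-identical.  Sampling without replacement
is the exact model of subsampling a fixed observed library.

**Beta diversity.** Weighted UniFrac is computed from a sparse
branch × tip incidence matrix: per-sample branch fractions are one matrix
product, so the full pairwise matrix over ~1 700 samples takes seconds.
The normalized variant (default) divides by Σ d_j(A_j + B_j) and is
bounded in [0, 1]; the raw variant is available by flag since it is the
one that satisfies the triangle inequality exactly.  Jensen–Shannon
divergence uses natural logarithms (0 ≤ JSD ≤ ln 2); the √JSD metric
variant is exposed.  Both kernels renormalize raw counts internally.
Correctness is pinned to an independent brute-force oracle that enumerates
every branch (tests assert |Δ| < 1e-12 on random instances).

**PAM.** For tiny instances (C(n, k) ≤ 20 000 medoid subsets) the optimal
medoid set is found by exhaustive enumeration — classic BUILD + SWAP is a
local search and missed the global optimum on ~8 % of random 8-point
instances, so exactness at small n is guaranteed by construction.  Larger
instances use deterministic BUILD initialization and best-improvement
SWAP; all ties break toward the lowest sample index, making the procedure
fully deterministic for a given matrix.

**Choice of k** maximizes the average silhouette width over k = 2..10,
ties to the smaller k.  Silhouette values follow the usual conventions:
singleton clusters and all-zero distances score 0 (computation delegated
to scikit-learn on the precomputed matrix).

**Cluster optimality test.** The statistic is
T = Σ_clusters (within-cluster pairwise distance sum / cluster size); the
null permutes labels preserving cluster sizes; the add-one p-value counts
permutations with T ≤ T_observed.  Size normalization stops trivially
small clusters from dominating the sum.  The source publication did not
state its statistic; this definition is declared in the test's output.

**IndVal.** The group-equalized form: specificity A uses per-cluster mean
relative abundances (so cluster sizes cancel), fidelity B is presence
(count ≥ 1) prevalence in the cluster, IndVal = √(A·B).  Each OTU is
scored for its best single cluster; cluster *combinations* (as the R
implementation's default `multipatt` would also consider) are deliberately
not evaluated, because one indicator genus per pneumotype is the object of
interest.  The permutation p-value compares the observed best-cluster
IndVal against the max-over-clusters statistic under shuffled labels
(add-one convention), which is mildly conservative and valid.

**Core microbiota.** An infant's core is the set of OTUs with count ≥ 1 in
all three of its rarefied samples; infants missing any visit are excluded.
Core abundance per visit is the fraction of reads on core OTUs (its
complement is exactly the transient fraction).  Trend: two-sided paired
Wilcoxon between consecutive visits, p = 1 when every pair ties.
Stable-vs-changing comparison: per-visit two-sample Wilcoxon rank-sum plus
a one-way ANOVA pooling all subject × visit values by stability group.

**Dynamics.** χ² independence tests drop zero-margin rows/columns with a
warning and apply Yates' correction only to 2×2 tables (toggleable).  The
stability null is product-of-marginals — Σ_k p̂_k(W1)p̂_k(M1)p̂_k(M3) —
rather than uniform, because the pneumotype mix shifts across visits; the
observed stable count is tested with a 1-df goodness-of-fit χ².

**Distance ratio.** r_s divides the subject's own earlier→later distance
by the *median* (robust; mean by flag) of its distances to other infants'
later samples.  The permutation test reassigns each subject's "own" later
column to a uniformly random column — the true one included, independently
across subjects — and recomputes the median ratio; one-sided p is the
add-one fraction of permuted medians at or below the observed, two-sided
doubles the smaller tail.  Leave-one-out row medians are precomputed from
one sort per row, so 10 000 permutations over ~500 subjects take well
under a second.  The reassignment is with replacement across subjects;
an 800-replicate null simulation put the empirical type-I error at
0.048 ± 0.008, so the residual discreteness is negligible.

## The synthetic world

The generator emulates a 695-infant cohort sampled at 1 week (W1), 1 month
(M1) and 3 months (M3):

- **Pneumotypes.** Five community types — dominated by Staphylococcus,
  Streptococcus, Moraxella, Corynebacterium, and one mixed type defined by
  minor genera (Gemella, Dolosigranulum, Haemophilus, Prevotella,
  Neisseria, Enterococcus).  Per-visit type prevalences are taken from the
  observed per-visit cluster sizes of the study cohort.  Genus profiles
  are solved (SLSQP, floor 0.005 per genus) so the prevalence-weighted
  mixture reproduces the published genus trajectories *exactly*:
  Staphylococcus 49/22/10 %, Streptococcus 17/31/29 %, Moraxella
  9/13/23 % of reads at W1/M1/M3.
- **Transitions.** Sticky-diagonal Markov matrices αI + (1−α)1qᵀ with q
  chosen so each visit's marginal is mapped onto the next exactly;
  α = 0.082 and 0.146 give expected same-type agreements of ≈ 28 % and
  ≈ 34 %, and an expected fully-stable fraction of ≈ 8 % against an
  independence expectation of ≈ 4 %.
- **Covariates.** Prevalences mirror the cohort tables (siblings 56 %,
  C-section 22 %, boys 51 %, maternal asthma 26 %; per-visit antibiotics
  and exclusive breastfeeding).  Having siblings adds +1.0 / +0.8 log-odds
  for the Moraxella and mixed types at W1; the conditional probabilities
  are solved by fixed point so the marginal is preserved exactly.
  Covariates influence membership only through these logits, not
  composition directly.
- **Individuality.** Each subject carries (i) one persistent "core" OTU
  per genus, chosen among the genus's three core-eligible OTUs with
  probabilities (0.6, 0.25, 0.15), and (ii) a persistent lognormal genus
  tilt (sd 0.3).  Per visit, every genus's share splits ρ_t to the
  persistent OTU and 1−ρ_t spread over 4 randomly activated transient OTUs
  (of 12), with ρ = 0.90/0.81/0.63 — so the expected fraction of reads on
  OTUs present at all visits equals ρ_t by construction, and the measured
  per-subject core abundance recovers it.  The tilt's renormalization bias
  on cohort genus means is pre-compensated by a deterministic Monte-Carlo
  fixed point, keeping the trajectory calibration exact.
- **Noise.** Compositions are Dirichlet draws with concentration 300
  around the per-sample mean, counts multinomial at a log-normal depth
  (floor 500; 5 % of samples fall below the 2 000-read QC threshold by
  construction).  Concentration 300 is deliberately high: with heavier
  overdispersion (e.g. 50) the low-share persistent OTUs drop out of
  individual samples at depth 2 000, contradicting the constructed core.
- **Tree.** Genus subtrees are random coalescents normalized to a fixed
  depth (3 × 0.12), attached to a star-like backbone with stems of at
  least 0.5.  The signature genera belong to different families and phyla,
  so every pair is guaranteed comparably deep separation; leaving the
  backbone to an unconstrained coalescent made cluster recovery depend on
  the luck of the tree (adjacent genera merged community types; deep
  within-genus clades split them).
- **Missingness** is per-visit Bernoulli (22/11/10 %), reproducing the
  cohort's ~63 % complete-case fraction.

### What a green test does and does not establish

The generator produces well-separated types (ASW ≈ 0.75 versus ≈ 0.35 in
the real data), exactly multinomial read noise, no contamination, no
chimeras, a known tree, and taxonomy without errors.  Recovery tests
therefore establish the *correctness of the machinery* — that clustering,
k-selection, indicators, core statistics and permutation tests find
structure that is truly there, at effect sizes in the right regime — not
that the method would resolve the much noisier real cohort.  Cohort-level
results of the original study (silhouette 0.35/0.39, ratios 0.93/0.87,
9.4 % stable) depend on unreleased data and serve as qualitative
references only.

## Known divergences and limitations

- On synthetic data the Jensen–Shannon silhouette prefers many small
  clusters (k* = 10) because subject-specific core-OTU identities create
  OTU-level substructure that a phylogeny-blind divergence sees as
  distinct; weighted UniFrac absorbs it on short within-genus branches.
  The published analysis found k = 5 under both metrics on real data.
- The rank-one-plus-diagonal transition model carries dependence only
  through the diagonal; at W1→M1 stickiness (α = 0.082) the χ² dependence
  test is underpowered at n ≈ 440, whereas the real cohort showed
  p = 0.004 — real transitions have off-diagonal preferences this world
  does not model.
- Pneumotype IV is simulated with stronger Corynebacterium dominance
  (0.78) than the "less well-defined" real type, precisely so that it is
  recoverable; the real type IV would not separate this cleanly.
- Table-2-style summaries support per-cell denominator overrides because
  the printed tables occasionally imply denominators one less than n
  (missing covariate data); which cells were affected is unknowable.
- The per-pneumotype stability expectations and core-OTU identities of the
  real cohort depend on its data and are reproduced procedurally only.
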