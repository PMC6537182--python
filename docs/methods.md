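# Methods

This note documents the models implemented in `whogem`, the defaults
and why they were chosen, and what the synthetic-data tests do and do
not establish about real data.

## Admixture model

Dosage g_ij ∈ {0,1,2} at locus j of sample i is modelled as
Binomial(2, p_ij) with p_ij = Σ_k q_ik f_kj, where q_i lies on the
K-simplex and f_k ∈ [0,1]^M are ancestral allele frequencies.  Fitting
uses multiplicative EM updates for Q (and, in unsupervised mode, F),
which are monotone in the log-likelihood; the monotonicity is asserted
on every run.  We deliberately do not reproduce any particular external
optimizer (e.g. quasi-Newton block relaxation): the contract is
likelihood monotonicity and parameter recovery on data with known
truth, and externally produced `.Q` files are accepted everywhere
downstream.

- Frequency clipping: f ∈ [1e-6, 1−1e-6] (configurable) keeps the
  likelihood finite at fixed loci.
- Convergence: absolute log-likelihood improvement < 1e-7 or 2000
  iterations.  Cross-validation fits cap iterations at 200 with
  tolerance 1e-6; the masked-entry error is insensitive to the tail of
  the optimization and this keeps K scans affordable.
- Supervised mode estimates F from labelled samples as per-class
  observed frequencies with a ±0.5 pseudo-count, then fits each
  sample's q with F fixed.
- Unsupervised initialization: k-means on the top-10 PCA scores of
  mean-imputed dosages, with seeded multiplicative noise on Q.
  Components are canonicalized by descending total weight; cross-run
  comparisons use Hungarian matching on Q-column correlations.
- Missing dosages are skipped in the likelihood; for PCA/kinship/
  regression computations only, missing entries are mean-imputed.

**Model selection.**  The cross-validation criterion hides a seeded 10%
of non-missing entries per fold, fits on the rest, and scores the RMSE
of the predicted dosage 2·Σ_k q_ik f_kj on the hidden entries.  The
DAPC route clusters PCA scores by k-means and scores
BIC(K) = N·ln(WSS/N) + K·ln(N).  This BIC behaves as intended when the
retained dimensionality is comparable to the sample count (the regime
in which the DAPC methodology is used, e.g. 80 PCs from a few hundred
samples); with very few dimensions and many samples the K·ln(N) penalty
is weak relative to within-cluster variance reductions and the curve
can keep falling, which is a known property of this criterion, not a
defect of the scan.  `pipeline.determine_k` combines the two curves —
the one-standard-error band around each minimum spans the candidate K
range — and breaks the remaining near-ties with the geographic
parsimony rule (below).  The k-means row order is canonicalized
internally so the scan is exactly invariant to permuting input samples.

**Population statistics.**  Pairwise Fst between components uses Nei's
ratio of averages on ancestral frequencies: Fst = (mean H_T − mean H_S)
/ mean H_T with H_S the mean within-pair heterozygosity and H_T the
heterozygosity at the pair's mean frequency.  Fis per population is
1 − mean(Ho)/mean(He) over polymorphic loci.

## Geolocation (the provenance predictor)

Given a query admixture vector and a reference panel (either
accession-level units, or population-level units carrying mean
admixture vectors θ̄_m and geographic centroids — both run through the
same code path):

1. Δ_GEN(m): Euclidean distance to every unit; Δ_GEN^min the smallest.
2. Tie set: all units within relative tolerance 1e-9 of Δ_GEN^min
   (selfing species can produce exact admixture ties); the origin g₀ is
   the tie set's geographic centroid.  If Δ_GEN^min ≈ 0 the prediction
   is g₀ itself.
3. Radius r = a + b·Δ_GEN^min from the calibration line.  A fitted line
   with a negative intercept can give r < 0 at tiny genetic distances;
   r is clamped at 0 (the prediction collapses onto g₀).  Predictions
   with r beyond the calibration cutoff are flagged `extrapolated`.
4. Displacement D = Σ w_m (g_m − g₀) over the up-to-M nearest non-tie
   units (M = 10 by default, capped at the panel size; boundary ties are
   all retained), with weights w_m = Δ_GEN^min/Δ_GEN(m) ∈ (0, 1].
5. Predicted point: g₀ + min(1, r/‖D‖)·D.  Clipping (rather than always
   projecting onto the circle) preserves short, consistent
   displacements; projection is available by post-processing but the
   clip is the default and the invariant "never farther than r from g₀"
   is asserted on every call.

Two geographic metrics are supported and carried as a tag on the
calibration so they cannot be mixed: plain Euclidean distance on
(latitude, longitude) in degrees — appropriate at Mediterranean scale
and the metric in which the published calibration constants are
expressed — and great-circle km (haversine, R = 6371 km), in which
displacements are computed on a local tangent plane around g₀.  The
packaged constants (`PAPER_CALIBRATION`: a = 0.204, b = 4.973, cutoff
950 km) are tagged euclidean-degrees with a 111.32 km/degree reporting
factor; that unit reading is inferred from the magnitudes involved and
flagged as such in the docstring.

**Calibration.**  The Mantel statistic (Pearson correlation of
lower-triangle distances; one-sided permutation p with the +1
correction) is computed on the full matrices; pairs below the distance
cutoff are then fitted by OLS Geo = a + b·Gen, and the Pearson
correlation of the retained pairs is reported alongside.

**Leave-one-out validation.**  Each sample is removed; at population
level its population's mean admixture vector and centroid are
recomputed from the remaining members (θ̄^{−j} = Σ_{l≠j} θ_l/(n−1));
the sample is placed and its geographic error recorded.  Country
correctness uses the country label of the panel unit nearest (great
circle) to the predicted point — a deliberate proxy that avoids polygon
shapefiles; on synthetic maps, countries are defined as Voronoi cells
of the population centroids, which makes the proxy exact.  `select_k`
then picks the smallest K whose median error is within 5% of the best
and whose country accuracy is within 5% of the best.

## Trait models

LS means: y_ijk = μ + block_i + accession_j + ε fitted by OLS with
treatment contrasts; an accession's LS mean is its prediction averaged
over all blocks with equal weight.  Disconnected block/accession
designs are rejected with the components listed.  Ordinal 0–4 disease
scores are treated as numeric, matching field practice for symptom
scales.

Admixture regression: since Σ_k θ_k = 1, the full model is collinear;
the search space is every non-empty proper subset of the K components
(2^K − 2 candidates, exhaustive by default and cheap at K = 8, greedy
stepwise available).  Candidates are ranked by BIC — compared at 1e-6
precision so exactly aliased subsets (every (K−1)-subset spans the same
space) tie and fall through to the fewer-terms-then-lexicographic rule —
then backward-pruned until every retained term has p ≤ α (default 5%).

## Genomic-selection baselines

All five consume the same mean-imputed, column-centered marker matrix.

- RR-BLUP: variance ratio λ = σe²/σu² by maximum likelihood, profiled on
  the spectrum of WWᵀ; the search runs on a scale-free axis (relative
  to the mean eigenvalue) so rescaling the kernel cannot move the
  optimum against the search bounds.
- G-BLUP: BLUP on the VanRaden kinship WWᵀ/c, c = Σ 2p̂(1−p̂), using the
  same spectral ML routine — which makes the RR-BLUP/G-BLUP prediction
  identity hold to numerical precision, and the test suite asserts it
  at 1e-6.
- BayesB: Gibbs sampler with per-marker inclusion (prior exclusion
  π = 0.95), scaled-t effect prior (ν = 4.1; scale set so the expected
  genetic variance is half the phenotypic variance), defaults 5000
  iterations / 1000 burn-in, posterior-mean effects, fully seeded.
  These hyperparameters are package defaults, configurable, and no
  numeric concordance with any other BayesB implementation is claimed.
- RKHS: Gaussian kernel with the median-squared-distance bandwidth
  heuristic; ridge penalty by generalized cross-validation over a
  33-point log grid.
- LASSO: scikit-learn coordinate descent; penalty by internal seeded
  5-fold CV with the 1-SE rule.

Models serialize to versioned JSON (`format_version: 1`).

## Evaluation protocol

Folds are stratified by population: per round, each population's
members are shuffled and dealt round-robin from a seeded offset, so
fold counts per population differ by at most one.  Reliability is the
Pearson correlation between predicted and observed values per fold (one
value per fold; 250 values for 50×5).  Admixture proportions are
estimated once on all samples and reused across folds — mirroring how
such comparisons are run in practice; this leaks a small amount of
test-set information through the Q matrix and the comparison is
therefore mildly optimistic for the admixture model.  Methods are
compared with a tie-corrected Kruskal–Wallis omnibus test; pairwise
two-sided Mann–Whitney tests with Holm adjustment feed an
insert-and-absorb compact letter display (methods share a letter iff
their adjusted p exceeds α).

## Environment association

Pearson correlations between every component and every environmental
variable, Bonferroni-controlled over the full tested family (K ×
n_vars per call; the family size is recorded on the output).  RDA
variation partitioning regresses the centered admixture matrix on
centered predictors; the explained fraction is trace(ŶᵀŶ)/trace(YᵀY);
unique fractions residualize both sides on the conditioning set
(Frisch–Waugh), so a + b + c + residual = 1 holds exactly with raw
fractions — adjusted-R² values are attached as a secondary field since
ecological software commonly reports them.  Significance by
unrestricted row permutation of Y.  Admixture rows are used as-is
(compositional); log-ratio transforms are out of scope.

## Synthetic data

`make_landscape` places K centroids uniformly in the map box (minimum
separation 5% of the diagonal, bounded retries), scatters `n_per_pop`
samples Gaussian (s.d. `pop_spread` = 1°) around each, sets
q_ik ∝ exp(−d(x_i, c_k)/ρ) and adds Dirichlet(conc·q) noise.
Genotypes follow the Balding–Nichols model: p_j ~ U(0.05, 0.95),
f_kj ~ Beta(p(1−F)/F, (1−p)(1−F)/F), g ~ Binomial(2, Σ q f), with one
shared differentiation parameter F and independent loci (the pipeline
consumes LD-pruned SNPs).  Traits are y = β₀ + Σ β_k q_k + N(0, σ²).
Environment variables are affine-plus-quadratic functions of (lat, lon)
with noise; the last variable is pure noise, a null control for
correlation screens.  Defaults (K = 4, 50 samples/population, map
30–45°N × −10–25°E, ρ = 3°, Dirichlet concentration 100, F = 0.15,
1000 loci) sketch a Mediterranean-scale study with moderate
differentiation.  All randomness flows from one integer seed through
spawned generator streams.

What the generator does *not* emulate: linkage disequilibrium,
coalescent ancestry, selection, genotyping error, non-Voronoi political
borders, and real climate rasters.  Passing tests therefore establish
the correctness and internal consistency of the algorithms under the
stated generative assumptions, not field performance on real panels.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at sizes chosen to keep the default suite
fast on a single CPU while leaving each statistical question
well-posed: geolocation validation uses 200 samples × 2000 loci
(F = 0.2) over 10 seeds with the supervised EM capped at 600 iterations
(pilot runs showed recovery is unchanged versus the full cap);
K-recovery uses 160 samples × 800 loci over 12 seeds with 3 CV folds
and K ∈ 2..7; the admixture-versus-GS benchmark uses 152 samples × 300
loci with 3 rounds of 5-fold CV and shortened BayesB chains (800/150).
The acceptance script re-runs the same computations at the same or
slightly smaller seed counts.

## SNP filtering

Variant-level missingness (> 5%) and MAF (< 1%) filters precede
VIF-based LD pruning: sliding windows (300 variants, step 60) in which
the variant with the largest variance-inflation factor — the diagonal
of the inverse correlation matrix, computed on mean-imputed dosages —
is removed until all VIFs fall below the threshold (1.3).  Removals are
global, tied-worst sets drop the highest index (so exact duplicates keep
their first occurrence), and passes repeat until stable, which makes the
operation idempotent and guarantees the post-hoc bound on every window
of the survivors.  The exact recursion of other pruning tools is not
reproduced; the contract is the post-hoc VIF bound.  Note that the VIF
is a finite-sample quantity: when the window width approaches the
sample count, chance multicollinearity inflates every VIF, so windows
should be kept well below N.

## Known limitations

- Unsupervised EM can reach local optima at large K; the pipeline
  mitigates this with PCA/k-means initialization but does not multistart
  the full likelihood.
- Country assignment by nearest panel unit is a proxy; with few or
  unevenly placed reference units it can differ from polygon membership.
- The CV-error and BIC criteria are bands, not point decisions; on
  weakly structured data the parsimony rule dominates the choice of K.
- Q matrices are not re-estimated per CV fold (see Evaluation), a
  documented optimism for the admixture model's benchmark.
- Great-circle displacements use a local tangent plane; at continental
  scale (> ~2000 km radii) the linearization error becomes visible.
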