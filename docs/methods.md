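# Methods

## Model and estimation

The package treats a set of p observed variables (cognitive task scores,
regional cortical volumes, tract-wise fractional anisotropy, and age) as
jointly Gaussian. The object of inference is the Gaussian graphical model:
the matrix of partial correlations
w<sub>ij</sub> = −k<sub>ij</sub>/√(k<sub>ii</sub>k<sub>jj</sub>), where K is
the precision (inverse covariance) matrix. An absent edge (w = 0) means
conditional independence given all other variables.

Estimation proceeds in four stages.

**Pairwise-deletion correlations.** Each pairwise Pearson correlation is
computed over the subjects observed on both variables. This uses all
available data under nested missingness but does not guarantee a positive
semidefinite matrix. Preconditions enforced: every pair needs at least 10
complete observations (configurable), and zero-variance columns are an
error, not a silent NaN. The effective sample size used in the likelihood
defaults to the number of subjects with at least one observed cell;
the more conservative minimum pairwise count is available as an option.
Neither choice is canonical under pairwise deletion — the default reflects
that most cells come from the largest layer.

**PSD repair.** Indefinite matrices are repaired by clipping eigenvalues at
1e−8 and rescaling to unit diagonal. Already-PSD input is returned
unchanged; the repair magnitude is logged because a large repair signals
that pairwise deletion distorted the correlation structure.

**EBIC graphical lasso.** The graphical lasso (ℓ1-penalized Gaussian
maximum likelihood; the coordinate-descent solver from scikit-learn is used
as the inner solver) is run on a log-spaced path of 100 penalties from
λ_max = max|r<sub>ij</sub>| down to 0.01·λ_max. Each fit is scored with

  EBIC_γ = −2ℓ(K̂) + E·log(n) + 4·E·γ·log(p),  ℓ = (n/2)(log det K̂ − tr(S K̂)),

where E counts nonzero unique off-diagonal precision entries. γ defaults to
0.5, the standard density penalty in regularized network psychometrics; the
alternative reading of a fixed post-hoc edge threshold is available as an
off-by-default option (`post_threshold`). Penalties where the solver fails
to converge are skipped and recorded. Ties in EBIC go to the sparser model.
Entries below 1e−10 in magnitude are stored as literal zeros so sparsity
counts are well defined.

**Reporting conventions.** Age is included as a node in estimation (so all
edges are age-conditional) but excluded from edge summaries, centrality
tables and z-normalization. Edge summaries (mean, median, min, max) are
taken over the unique off-diagonal non-age entries with zeros included.
Age handling is configurable: `include_node` (default), `regress_out`
(residualize each variable on age beforehand), or `exclude`.

## Centrality

Strength is s<sub>i</sub> = Σ<sub>j</sub>|w<sub>ij</sub>| (age edges count
toward the sum). Bridge strength restricts the sum to neighbors in a
different pre-assigned community; the pre-assignment is the Walktrap
partition, not the layer labels, so "bridging" is defined against the
empirical community structure. For every node and any partition,
strength = bridge strength + within-community strength exactly. Z-scores use
the sample (n−1) SD over non-age nodes; the convention is not fixed by the
procedure's description, and with 10–30 nodes the choice moves z-scores by
under 5%. Central ⇔ z ≥ +1. Negative z-scores are computed but never
flagged or interpreted.

## Community detection

Walktrap builds a merge tree from short random-walk distances
(t = 4 steps, the algorithm's conventional default) with Ward-style
agglomeration; the python-igraph implementation supplies the merge tree.
Edge weights enter as absolute values — random walks need non-negative
weights — while every other module sees the signed matrix; the absolute-value
mapping is logged whenever negative edges are present. The dendrogram is cut
at the partition maximizing Newman's weighted modularity

  Q = (1/2m) Σ<sub>ij</sub> [a<sub>ij</sub> − d<sub>i</sub>d<sub>j</sub>/2m] δ(c<sub>i</sub>, c<sub>j</sub>),

recomputed here at every cut, so the reported Q always equals `modularity()`
on the returned assignment. Isolated nodes become singletons; an all-zero
network yields all singletons with Q defined as 0. Q ≥ 0.5 is labelled
strong, 0.3 ≤ Q < 0.5 moderate, otherwise weak; the 0.3 lower cut is this
package's choice of a conventional boundary, since only the 0.5 cut is
standard. Tie-breaking among merges follows the igraph implementation and
is deterministic given the input.

## Stability

The case-drop bootstrap drops ⌈f·n⌉ subjects without replacement for each
fraction f in {0.05, …, 0.75} (B = 1000 default replicates; at least 100),
re-runs the full estimation — and, for bridge strength, community
detection — on the subsample, and Spearman-correlates subsample with
full-sample centralities over non-age nodes (Pearson available). The CS
coefficient is the largest grid fraction with empirical
P(cor ≥ 0.7) ≥ 0.95; CS ≥ 0.5 is labelled stable, ≥ 0.25 moderate. The grid
tops out at 0.75 so a perfectly stable ordering reports CS = 0.75. Failed
replicates (estimation error, undefined correlation) count as
below-threshold rather than being dropped: failures can only lower CS.
Re-deriving the partition per resample propagates community-detection
uncertainty into bridge-strength stability rather than freezing it.

Edge-weight uncertainty uses the ordinary nonparametric bootstrap
(resampling subjects with replacement) with percentile 2.5/97.5% intervals.

Inside bootstrap loops the penalty path is shortened (25 points by default,
`bootstrap_path_size`) since path resolution contributes little to the
ordering of centralities but dominates runtime.

## Synthetic-data generator

The generator is the package's substitute for the non-shareable cohort
data. Each preset is an explicit, checked-in partial-correlation matrix
whose implied precision I − P is verified positive definite; the implied
unit-variance covariance is Σ = standardized (I − P)⁻¹. Sampling is
multivariate normal. The presets reproduce the published layer edge
summaries exactly at 2 decimals, with the named extreme edges planted
(reading–spelling 0.63; caudal-middle-frontal–frontal-pole −0.15; the FA
maximum 0.44 placed on the forceps-major–forceps-minor pair). Which node
pairs carry the remaining weights is *not* published information: the
fixtures distribute them by balancing row loads (which also keeps the
precision well conditioned), so node-level results (which specific nodes
come out central) are properties of the fixture, not recovered facts.
Cross-layer and age edges are likewise plausible calibration only (|p| ≤
0.15 cross-layer, mixed sign; small positive age edges).

Missingness is generated in two stages: whole-layer nesting first (every
diffusion subject also has grey-matter data, matching layer counts
805/246/165 at n = 805), then per-variable MCAR at the published task rates
(0.12%–9.94%). Only MCAR is implemented; the source material reports rates,
not mechanisms. The generator does not emulate non-Gaussian marginals,
floor/ceiling effects of raw task scores, site or scanner effects, or
age-dependent (MAR) missingness — so passing recovery tests demonstrates
estimator correctness under the stated model, not robustness to real-data
pathologies.

Outlier handling for sensitivity analyses masks cells beyond mean ± k·SD of
their column (k = 4 by default), computed on observed cells; zero-variance
columns are skipped with a notice.

## Numerical choices and degenerate inputs

- λ path: geometric, 100 points, min ratio 0.01; an all-zero off-diagonal
  correlation matrix short-circuits to the empty network.
- Exact zeros at |w| < 1e−10; PSD floor 1e−8; EBIC ties broken toward
  larger λ.
- Datasets require n ≥ 10; n < p warns rather than errors (the lasso still
  fits, the unregularized estimator will fail).
- Single-community partitions give all-zero bridge strength with a warning;
  fewer than 3 non-age nodes make z-scores undefined and error.
- All simulation, subsampling and resampling randomness flows through
  numpy Generators seeded explicitly; identical config + seed reproduces
  reports byte-identically.

## Problem sizes used in tests and drivers

Generator-fidelity and recovery tests use n up to 100,000 (31 variables at
most); plant-and-recovery of single edges uses 50–100 replicate cohorts at
the study's layer sizes (805/246/165). The analysis drivers bootstrap with
B = 200 replicates over the 15-point drop grid and use the unregularized
estimator inside stability loops; these sizes were chosen so each driver
completes in minutes on a single core while Monte-Carlo error stays a grid
step or less for CS and below 0.01 for mean recovered edges.

## Known limitations

- EBIC-glasso support recovery is not exact at large n: the single global
  penalty that preserves strong edges also admits numerically tiny spurious
  edges (|w| < 0.02 at n = 100,000). Support claims should therefore use a
  magnitude floor, as the tests do.
- Pairwise deletion with nested layers means different edges are estimated
  from very different sample sizes; the likelihood's single n_effective is
  an approximation, and no small-sample correction is applied.
- The CS coefficient inherits the grid's resolution (0.05) and its 0.75 cap.
- Walktrap on graphs with several disconnected components merges the
  components' subtrees in an implementation-defined order; partitions are
  still deterministic.
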