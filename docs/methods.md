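# Methods

`betaconn` implements a whole-brain network analysis of task fMRI at the
level of trial-wise activation estimates (beta series), together with a
synthetic cohort generator that plants the statistical structure the
analysis assumes. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic cohorts do and do
not show about real data.

## Analysis model

**Edges.** Functional connectivity between two regions is the Spearman
rank correlation of their beta series across trials, Fisher-z
transformed: `w_ij = atanh(spearman(b_i, b_j))`. Rank correlation makes
the edge invariant under any strictly monotone transform of a region's
response scale; the Fisher transform variance-stabilizes it.
Correlations of magnitude 1 (possible with few trials) are clipped to
`1 − 1e−12` so the transform stays finite. Constant beta series are an
error, reported with the offending node ids.

**Thresholding.** A weighted matrix is binarized at density `d%` by
keeping the `m = round(d/100 · n(n−1)/2)` strongest edges (round half
up; the convention is documented because the edge count rule is
otherwise ambiguous). "Strongest" means most positive signed weight by
default — the common choice for correlation networks, where negative
edges are not treated as strong connections — with an `absolute`
ranking available as a flag. Ties are broken by lexicographic `(i, j)`
order so the edge set is a deterministic function of the weights. Edge
sets are nested across densities by construction.

**Density range.** The analysis density range is chosen from
largest-connected-component (LCC) behaviour over all participant ×
condition networks: the lower bound is the sparsest candidate density
at which ≥ 90% of networks are fully connected, the upper bound the
sparsest at which all are. A repeated-measures permutation test on LCC
size at the lower bound checks that residual fragmentation does not
differ between conditions; it is reported as a check, not used as a
gate. On the default synthetic cohort the rule selects (16, 22).

**Graph measures.** All downstream measures operate on the binary
undirected network. Global: global efficiency
`E = mean over ordered pairs of 1/d(i,j)` (with `1/∞ = 0`) and the
unweighted mean clustering coefficient. Nodal: degree; clustering
`C_i = 2t_i / k_i(k_i−1)`; flow coefficient `f_i` = fraction of a
node's neighbor pairs with no direct edge between them (so their
shortest communication runs through the node — high values mark *local
bridges*); betweenness centrality over unordered pairs, unnormalized
(ranks are invariant to the ×2 convention — high values mark *global
bridges*); participation coefficient
`P_i = 1 − Σ_m (k_im/k_i)²` over the communities of the participant's
own consensus partition (high values mark *connectors*). Degenerate
degrees use fixed conventions (`C = f = 0` for `k < 2`, `P = 0` for
`k = 0`) so hub rankings stay total. The chosen flow-coefficient
formulation makes `f_i + C_i = 1` an exact identity for `k ≥ 2`, which
the test suite exploits as a cross-check between the two independently
coded measures.

**Communities.** Louvain modularity optimization (γ = 1) with
seed-driven randomized visitation is run as an ensemble (protocol: 1000
runs with seeds `seed+0 … seed+999`); the node-pair agreement matrix of
the ensemble is thresholded at τ = 0.5 and re-clustered by weighted
Louvain, iterating until every run returns the identical partition
(consensus partitioning). The agreement graph uses weighted modularity
with the agreement fractions as weights, as in the consensus-clustering
literature. An empty thresholded agreement matrix degenerates to the
all-singleton partition with a warning; non-convergence after a
configurable cap (default 50 cycles) is an error. Participant-level
consensus partitions are pooled by the same machinery into one
representative partition per condition. Similarity between partitions
is normalized mutual information, `2I/(H₁+H₂)`, with explicit
zero-entropy conventions (two identical trivial partitions → 1, a
single-community partition against anything else → 0).

**Sub-network labels.** Each community of a representative partition is
labeled by the reference sub-network assignment (e.g. a canonical
resting-state parcellation) with maximal Jaccard overlap; ties break by
overlap count then lexicographic label, no-overlap communities are
"unassigned", and the full overlap table is emitted for human review.
Automated labeling replaces visual inspection to keep the pipeline
deterministic and testable.

**Hubs and roles.** For each nodal measure, values are averaged across
participants and nodes ranked descending (exact ties keep node-id order
and are flagged). Hubs are the top 5%: rank ≤ `floor(0.05·n)`, i.e. 13
of 263. The target node is a *local bridge* iff hub by flow
coefficient, *global bridge* iff hub by betweenness, *connector* iff
hub by participation. A per-node paired permutation map (one-sided
sign-flip test of "comparison node lower than target", exhaustive for
≤ 12 participants, uncorrected) accompanies the ranks.

**Statistics.** The omnibus condition comparison is a repeated-measures
permutation test: statistic = between-condition sum of squares of
condition means after within-participant centering; the null permutes
condition labels independently within each participant; p-values use
the add-one convention `(1 + #{perm ≥ obs})/(1 + n_perm)`. This is a
deliberate exact/Monte-Carlo substitution for an asymptotic general
independence test — it tests the same within-participant
exchangeability null without asymptotic machinery. Post-hoc pairwise
comparisons sign-flip within-participant differences (exhaustive when
`2^n ≤ n_perm`, two-sided). Benjamini–Hochberg FDR corrects across the
density sweep. Brain–behavior association is a Pearson correlation with
the two-sided t-based p-value.

## Synthetic cohorts

The study's raw data are not public, so the generator emulates the
design: 24 participants, 263 ROIs (assembled by the same bookkeeping as
the reference atlas: 264 ROIs, minus one non-gray-matter thalamic ROI,
plus the target ROI, minus the one overlapping fusiform ROI), 80 trials
per condition, one passive baseline plus four active conditions (PN−,
PN+, CN−, CN+). Beta series are zero-mean multivariate Gaussian draws —
only rank correlations are analysed downstream, so mean activation
levels are irrelevant. Behavioral profiles (accuracy 96/92/88/63%, mean
RT 1296/1413/2389/2575 ms, between-participant SD 300 ms) follow the
published task performance.

**Default cohort (flat block model).** The correlation matrix has
within-module correlation ρ_in = 0.4 over four modules of 66/66/66/65
nodes and between-module correlation ρ_out = 0.05. The target node's
row is overwritten with `n_strong = 40` links of strength ρ_target
allocated across modules by the condition's role profile (largest
remainder). That patched matrix is far from positive semidefinite —
one variable cannot carry dozens of idiosyncratic above-background
correlations into strongly correlated blocks — and is repaired by
eigenvalue clipping at 0 followed by re-normalization to unit diagonal,
the simplest repair preserving structure. The repair necessarily
shrinks the planted row; the default cohort is therefore used where
that is irrelevant: community-count and partition recovery, hub-by-
participation recovery, and condition-dependent module membership with
strongly concentrated layouts.

**Role-dissociation cohort (factor model).** In a flat block graph the
flow coefficient and participation coefficient of a planted connector
are analytically coupled: if its neighbors retain within-module edges
at rate c, then `f ≈ (1−c) + c·P`, so a top-participation node is
automatically a top-flow node (and usually a top-betweenness node) —
connector-only nodes cannot exist in that world, though they do in real
cortex, where local neighborhood structure is heterogeneous. The
dissociation cohort therefore builds its correlation matrix as an
explicit factor model, positive semidefinite by construction: one
latent factor per module (factor correlations ρ_out/ρ_in reproduce the
flat block pattern for regular nodes) plus one global *bridge* factor
loaded by 6 designated nodes per module (`√(ρ_bridge − ρ_out)` with
ρ_bridge = 0.5), which gives those nodes elevated cross-module
correlations — an inter-module core mesh. The target's loadings derive
from the condition's role profile: the spread `1 − Σp²` sets its
bridge-factor loading (`0.8·(spread/0.75)^1.5`), the home-module excess
sets its home loading (`(p_home − ¼)/¾`). A connector-condition target
then connects evenly to the mesh: its neighbors are mutually connected
(low flow), the mesh provides abundant alternative inter-module routes
(low betweenness), and the even spread keeps participation at the top —
a connector and nothing else. Role profiles: baseline anchors the
target in module FPN (0.85 home), PN−/PN+ plant a VN-anchored connector
(0.55/0.15/0.15/0.15), CN− a SAN-anchored connector, CN+ a
VN-concentrated non-connector (0.70 home), reproducing the
condition-dependent membership and role switching the analysis is
designed to detect.

**Planted behavior.** A per-participant standard-normal latent scales
the target's cross-module connection strength in conditions with a
planted behavior correlation (default: r = −0.47 in CN+ only), and
reaction times are generated against that latent
(`RT = μ + σ(r·u + √(1−r²)ε)`). The correlation estimated from
*measured* participation is attenuated relative to the planted
population value, because the participation estimate carries sampling
noise — exactly the attenuation an empirical correlation exhibits. The
`generate_behavior` operation plants RT against supplied participation
values directly; re-estimating over many noise seeds recovers the
planted r in the mean (to within ±0.01 at 1000 seeds) and validates the
correlation stage itself.

**What the cohorts do not emulate.** No BOLD dynamics, no hemodynamic
response, no GLM estimation step, no motion or physiological noise, no
spatial autocorrelation between ROIs, no Go/NoGo trial labels (only the
80-trial count matters downstream), and no subject-level anatomy.
Passing recovery tests therefore shows that the pipeline detects the
targeted statistical structure at realistic sample sizes and noise
levels — not that such structure is detectable in any particular real
dataset.

## Numerical and scale choices

- All randomness flows from a single seed through SHA-salted,
  stage-named 31-bit streams (participant × stage × condition for the
  generator; stage names for the pipeline), so any subset of conditions
  reproduces the identical draws.
- Louvain uses the igraph multilevel implementation; the modularity of
  a returned assignment is always recomputed independently from the
  formula `q = (1/2m) Σ_ij [w_ij − γ k_i k_j/2m] δ(c_i,c_j)`.
- Validation experiments run the Louvain ensemble 100× rather than the
  protocol's 1000×: on these cohorts the ensemble is already unanimous
  at 100 runs, so the consensus fixed point is unchanged (the
  short-circuit when all ensemble partitions agree makes this exact,
  not approximate). Recovery experiments use study-sized cohorts (24 ×
  263 × 80) throughout; seed counts per experiment (20 for recovery
  rates, 1000 for behavior and calibration) were fixed at design time.
- The calibration experiment uses `n_perm = 199` so that
  `p ≤ 0.05` corresponds to exactly the 10 most extreme permutations of
  200 — the add-one estimator is then exactly calibrated at α = 0.05
  under a continuous null.
- Permutation comparisons use a `1e−12` tolerance when counting
  `perm ≥ obs` so ties at the observed statistic (exact replicas,
  sign-symmetric values) are counted conservatively.

## Known limitations

- The LCC-based density rule can fail on ensembles that never fully
  connect within the candidate range; the error carries the
  per-density connectivity table.
- Consensus partitioning on very flat agreement matrices (no planted
  structure, small τ) may cycle; the cycle cap turns this into a
  diagnosable error rather than a hang.
- The group representative partition of a strongly spread connector can
  isolate the target in its own singleton community when its home
  anchor is weak; the home-tilted profiles avoid this, and the
  labeling report flags it when it happens.
- Nodewise permutation maps are uncorrected by design (descriptive
  accompaniment to the rank plots); only the density sweep is
  FDR-corrected.
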