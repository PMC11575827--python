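# Methods

`fconntraj` models how resting-state functional connectivity (RSFC) and
graph efficiency develop across the perinatal window (roughly 25–55
post-conceptual weeks), with the birth transition near 40 weeks as the
event of interest. Because longitudinal fetal/infant fMRI data cannot be
redistributed, every stage is exercised against a synthetic cohort
generator with known ground truth; what the package establishes is that
the *methods* behave as claimed under realistic study conditions, not
that any particular empirical result holds in real data.

## The synthetic cohort

`synthetic.CohortSpec` defaults encode the study conditions: 140
subjects; session counts drawn from the observed distribution (108
subjects with one session, 21 with two, 10 with three, 1 with four —
184 sessions in expectation); a fetal age window of 25–39 weeks and an
infant window of 40–55 weeks; and five acquisition sequences (two fetal,
three infant) sampled proportionally to their observed scan counts.
Ages are drawn uniformly within each window — the study does not report
the within-window age density, so uniform is a stand-in, not a claim.
Multi-session subjects span birth with probability 0.6 (both within- and
cross-birth longitudinal pairs occur in the study; the exact mix is not
published). Parcel/network dimensions default to a desk-scale 40/4;
the full 195-parcel / 8-network configuration is available by config and
is used wherever only counting arithmetic matters (edge counts, pair
enumeration).

Edge-level ground truth comes in four trajectory families on the
Fisher-z scale:

- **sigmoid**: baseline + amplitude / (1 + exp(−steepness·(age − midpoint))),
  the "surge at birth" shape (amplitude 0.2–0.5 z, midpoint ≈ 40 wk,
  steepness 0.5–1.5 /wk in the default mixture);
- **linear up / down**: baseline + slope·(age − 25), |slope| 0.005–0.02 z/wk,
  referenced to the start of the study window;
- **flat**: baseline only.

Sessions receive a per-subject random intercept (SD 0.1 z), an additive
batch shift and a multiplicative batch variance scale keyed by sequence,
and Gaussian session noise (SD 0.1 z). These noise magnitudes put
single-edge age effects near the detection boundary at n ≈ 190 sessions,
which is the interesting regime for testing inference. The generator
does not attempt raw-image realism: no hemodynamics, no spatial
autocorrelation between edges, no maternal tissue or acquisition
artifacts. Consequently passing tests demonstrate statistical
correctness of the estimators under the declared generative model, and
nothing about preprocessing quality on real scans.

QC fixtures (`simulate_timeseries`) inject three kinds of known
positives at chosen frames: an intensity jump (drives DVARS), a
persistent translation step (drives framewise displacement at exactly
that frame), and an eroded brain mask (depresses the Dice overlap).

## Quality control

Framewise displacement is the sum of absolute frame-to-frame differences
of the three translations (mm) plus the three rotations converted to arc
length at a 50 mm head radius — with this convention the fetal threshold
of 1.5 mm corresponds to mean + 2 SD in the study data. DVARS is the
RMS over voxels of the temporal intensity difference, on raw intensity
units (the study's fetal threshold 132.69 implies an unnormalized
scale). Fetal censoring applies three sequential rules: mask Dice < 0.9,
FD above mean + 2 SD pooled over the supplied runs (fixed override
available), DVARS likewise. Infant censoring flags DVARS > 50 and
expands each flag one frame back and two frames forward, clipped at run
boundaries. Scans are excluded when fewer than 105 frames survive, or
when mean per-frame displacement exceeds 0.5 mm or the maximum exceeds
1 mm on retained frames. The exclusion thresholds' rotation units are
not published; rotations are converted to mm at the head radius so one
unit serves both rules, and this is a documented convention, not a
reproduction. Dice of two empty masks is defined as 1 (perfect agreement
about nothing) with a warning, since empty masks signal upstream failure.

## Connectivity matrices

Parcel time series are voxel means; censored frames are dropped, never
interpolated, before Pearson correlation (at least 3 retained frames and
nonzero variance per parcel required). Correlations are Fisher-z
transformed with |r| clipped at 1 − 1e−7 to keep degenerate synthetic
edges finite. The canonical edge order is the strict upper triangle,
row-major, so a P-parcel matrix yields P(P−1)/2 edges (18,915 at
P = 195) with an exact devectorization inverse. The group-mean map uses
a one-sample t test of z values against zero per edge.

## Longitudinal batch harmonization

Per edge, the model is y = β₀ + β₁·age + γ_batch + u_subject + ε with
Var(ε) = δ²_batch·σ². Fitting is REML on the homoscedastic
random-intercept model with batch fixed effects (reference coding,
re-centered so the batch-size-weighted mean of γ is zero). Additive
effects are batch means of conditional standardized residuals
(subject BLUPs removed). Multiplicative effects are estimated from
*marginal* batch variances: the marginal residual y − Xβ̂ has variance
σ²_u + δ²_b·σ², so subtracting the REML subject variance isolates the
batch scale. This choice matters because most subjects contribute a
single session, where conditional residuals mix subject and session
noise and would dilute a true δ² = 4 toward ≈ 2.5. Per-edge δ̂² values
are noisy (the subtraction can approach zero); they are floored at 1e−3
and intended to be read in aggregate across edges, which is also what
the empirical-Bayes step does.

With EB on (the default), additive effects shrink toward a normal prior
and multiplicative effects toward an inverse-gamma prior, hyperparameters
by method of moments across edges, solved by the classic iterative
conditional-posterior update (tolerance 1e−6, cap 100 iterations).
Adjustment standardizes the conditional residual, removes γ*, divides by
δ*, and restores the age effect and subject intercept. Application is
restricted to the design the model was fitted on; a single-batch table
yields an identity transform with a warning. The ComBat design uses a
linear age term: the final trajectory model is a spline, but a spline
design is not reproducible from the available description, so linear is
the default (a low-rank spline basis is available via `age_basis`).
Sequence is the batch; fetal/infant status enters only through age.

## Edge-wise age effects

Each edge is fitted with y = β₀ + β₁·age + u_subject by REML, using a
single vectorized solver (`_lmm.py`) that profiles the variance ratio
θ = σ²_u/σ² per edge: all REML quantities reduce to per-subject sums,
so a coarse log-grid scan plus golden-section refinement evaluates the
exact criterion for thousands of edges simultaneously. The solver is
validated against statsmodels MixedLM.

The Wald statistic β̂₁/SE is referred, by default, to a t distribution
with n_subjects − 2 degrees of freedom. The large-sample normal
reference is available (`df_method="normal"`), but at study size
(~190 sessions, 140 subjects, mostly single-session) REML noise in the
SE makes its extreme tails anti-conservative — in a complete-null
simulation the realized tail mass at p < 1e−4 is about 2.2× nominal,
enough to break FDR control across 1000 edges; the subject-level t
reference restores control while remaining slightly conservative at
moderate thresholds. Edges with singular fits (zero residual variance)
are excluded from FDR with a warning. Benjamini–Hochberg is applied
across edges at q = 0.05; significant edges are classified by slope
sign.

Growth series average the z values of significant edges: globally by
sign, and per network pair (K(K+1)/2 unordered pairs including
within-network; 36 pairs for 8 networks) regardless of sign, with empty
pairs reported as missing. Diagnostics: a rank-based comparison of
parcel-distance distributions between positive and negative edge sets,
and the QC-FC distance statistic — per-edge correlation of edge values
with session mean FD, correlated against edge Euclidean distance —
which should be negligible (within ±0.2) when motion does not drive the
results.

## Growth trajectories

The trajectory model is y ~ 1 + s(age) + (1 | subject): a cubic
B-spline smooth (basis dimension 10, knots at age quantiles, exact
integrated-squared-second-derivative penalty assembled by two-point
Gauss–Legendre per knot span) plus a subject random intercept. The
penalty's null space (constant + linear) becomes the fixed part; the
wiggly part is rescaled into an i.i.d. random-effect block, so the
smoothing parameter λ = σ²/σ²_smooth and the subject variance are both
REML-estimated (Nelder–Mead over the two log variance ratios, three
starts). λ can be fixed, which at λ → ∞ reproduces the mixed-model
straight-line fit to ~1e−4.

Curves, pointwise empirical-Bayes 95% bands (fitted ± 1.96·SE from the
joint coefficient posterior; smoothing-parameter uncertainty and
simultaneous coverage are out of scope) and analytic first derivatives
are evaluated on a 0.2-week grid over the data range. The rate-of-change
peak is the grid age maximizing |derivative| (ties → youngest age;
all-zero derivative → undefined). The original analysis used thin-plate
smooths with package defaults; this implementation is an equivalence
class of that model, verified by parameter recovery (sigmoid midpoint
recovered to ≈1 week at study noise), not a numerical clone.

## Graph efficiency

Matrices are binarized by keeping the top 15% (ceil of proportion ×
edge count, so 2,838 of 18,915 at P = 195) of signed z values over
unique pairs, ties broken by canonical edge order; whether negative
correlations could enter the retained set in the original toolbox is
unstated, and signed descending order is the documented choice here.
Distances are unweighted hop counts; unreachable pairs contribute 0 via
the 1/∞ convention, and nodes are never dropped. Node-wise global
efficiency is the mean inverse distance to all other nodes; local
efficiency is the mean global efficiency of the subgraph induced by a
node's neighbors (degree < 2 ⇒ 0). Both are verified exhaustively
against a brute-force Floyd–Warshall oracle on all graphs of ≤5 nodes
and on seeded 10-node random graphs, and cross-checked against
networkx. Efficiency series re-enter the same age-effect and trajectory
machinery with nodes in place of edges.

## Pipeline

`run_pipeline` executes simulate/ingest → QC → connectome → harmonize →
age effects → trajectories → graph → within-period (fetal-only /
infant-only) follow-ups, from a validated YAML config (defaults: FDR
q = 0.05, Dice ≥ 0.9, infant DVARS 50, top proportion 0.15, minimum 105
frames). All randomness derives from the single config seed; rerunning
an identical config is byte-identical, and the manifest records row
counts and SHA-256 hashes of every output.

## Problem sizes and numerical choices

Simulation-based checks use the full study-size cohort (140 subjects,
~190 sessions): the null FDR check runs 200 replicates of 1000 flat
edges; harmonization recovery 50 replicates of 50 edges; trajectory
recovery 20 replicates. Aggregates over replicates (means/medians) are
compared against truth because single-replicate estimates carry design
noise comparable to the tolerances themselves (e.g., the linear-rate
sampling SE is ≈8% of the slope). Edge-level pipelines default to 40
parcels (780 edges), the package's desk-scale configuration.

Known limitations: edges are simulated and fitted independently
(no spatial correlation, so FDR behavior under realistic edge
dependence is untested); harmonization application is row-linked to its
fitted design; the GAMM fits one series at a time and is not vectorized
across edges; and confidence bands are pointwise only.
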