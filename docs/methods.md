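# Methods

This note documents the modeling choices behind `cytobool`: what each
stage assumes, which parameters matter, what the synthetic-data generator
does and does not emulate, and where the design was genuinely open.

## Model and assumptions

The pipeline treats each stimulated macrophage culture as a synchronous
Boolean network over the measured cytokines: every protein is either
active (1) or inactive (0) relative to its own activation threshold, all
proteins update simultaneously on a fixed simulation interval, and the
regulatory structure is constant over the 24-h response.  Three standing
assumptions follow: functional changes are slower than the simulation
interval; response cycles are longer than that interval; and rules do not
rewire mid-experiment.  The simulation interval is 13.5 min — 40 samples
over the first 9 h, where activation dynamics concentrate, plus 10 samples
to 24 h, 50 grid points in all.  Fifty samples support rules of at most
5 parents (2⁵ = 32 < 50); the pipeline caps rule size accordingly, keeping
the strongest LP contributions.

## Stage-by-stage choices

### Spline enrichment

The fit minimizes `p Σ aᵢ(xᵢ − s(tᵢ))² + (1 − p) ∫ (s″)²`.  The smoothing
parameter `p` is not dictated by the procedure; the default selects the
equivalent roughness penalty by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`, with `λ = (1 − p)/p` mapping
the two parameterizations), overridable per run.  Error weights `aᵢ`
default to 1.  `p = 1` interpolates; `p = 0` degenerates to the
straight-line least-squares fit, realized exactly.  Fitted values are
clamped at zero — negative expression is physically meaningless — and the
curvature term is integrated exactly (s″ of a cubic spline is piecewise
linear), which is what lets the test suite verify optimality by coefficient
perturbation.

Two endpoint conventions exist for the dense grid segment: 40 intervals of
exactly 13.5 min covering [0, 9) (default, honoring the printed interval),
or 40 points inclusive of both 0 and 9 h (spacing ≈ 13.85 min).  Both are
implemented; `ResampleGrid.standard(convention=...)` switches.

The control screen applies a two-sample Kolmogorov–Smirnov test to the 50
fitted values of stimulus vs. control (keep at p < 0.01).  Fitted curves
are autocorrelated, so KS independence assumptions do not hold; the test
is implemented exactly as specified but its p-values should be read as a
screening heuristic.  Profiles are labeled promotion / inhibition / bell
by the final-to-initial ratio (> 2, < ½, otherwise); a zero initial value
is replaced by the 1e-6 detection floor so the ratio is defined.

### Binarization

The L1 objective makes optimal centroids cluster medians; the cascade
starts from 8 quantile-seeded clusters, merges the two closest centroids,
and re-runs Lloyd iterations at each k down to 2.  At the final stage the
exact optimal contiguous split — cheap to enumerate in one dimension — is
tried as an extra seed, so the final 2-clustering is globally optimal
under the L1 objective (the cascade alone can stall in a local optimum on
adversarial inputs).  The printed threshold rule, "the average of the mean
distance from each cluster", is ambiguous; the default reading is the
midpoint of the two final centroids (equivalently the average of the two
cluster means), which matches the single threshold line in the published
binarization figures; the literal mean-within-cluster-distance reading is
available via `ClusterConfig(threshold_rule="mean_distance")`, and an
L2/mean-centroid variant via `metric="l2"`.  Ties at the threshold go to
0 (strictly-above rule).  The sensitivity band is δ ± mean absolute fit
error; a profile with more than 5% of grid points inside the band is
flagged as potentially falsely binarized.

### LP structure inference

As printed, the inactive-sample constraint duplicates the active one
(`… ≥ 0 + ζ`), which would leave the slack variables and the
"down-regulating" role of the constraint meaningless.  The implemented
reading applies it to samples with `x_{i,m} < δᵢ` and bounds the predictor
*above* by ζ ≥ 0.  Absolute weights are linearized by the standard
positive/negative split.  The `x_j` in the objective term `|w_{j,i}| x_j`
varies by sample; the implementation uses the sample mean `x̄_j`, the same
quantity the 70% contribution pruning uses (maximum or final-value
variants would be trivial switches but are not needed by any result).
Υ = 100 weights the bias down (bias is cheap, links are expensive), which
is what drives sparsity toward genuine parents.  λ is selected per child
by 5-fold cross-validated prediction error over an 8-point log grid capped
at L·σ² (L the inactive-sample count, σ² the pooled parent variance); a
zero-variance cap falls back to λ = 1.  The fold assignment derives from
the run seed.  By default the LP explains the child at grid step k+1 from
parents at step k (`lag = 1`), consistent with the synchronous update the
Boolean stage assumes; `lag = 0` gives the same-sample variant.

The 70% pruning fraction is a study constant, not an optimizer: the
pipeline exposes it as a parameter and the link-count/weight-sum sweep is
a reporting diagnostic only.  Proteins failing the control screen and
orphan nodes are excluded.

### Boolean rule determination

Truth-table rows never observed stay don't-care; conflicting observations
resolve by majority with the conflict count retained (ties to 0, matching
the constant-0 rule for fully undetermined tables).  Minimization is
Quine–McCluskey via `sympy.SOPform` with don't-cares used freely; term
order is fixed lexicographically so output is reproducible.  Consistency
is checked two ways: predictive agreement on the observed transitions
(escalation threshold 0.85) and sign agreement — a promotion-weighted
parent must enter the rule positively unate, an inhibition-weighted one
negatively; non-unate dependence always escalates.  Escalation pools the
per-replicate transitions (196 rows), which can fill rows the
replicate-averaged course never visited; for children pinned at logic
high, self-maintenance `x' = x` is admitted and preferred at equal
agreement.

### Semi-tensor-product dynamics

States are delta-indexed: `index = 1 + value of the complemented bit
string`, first-listed protein most significant (all-ones ↦ 1, all-zeros ↦
2ⁿ).  This convention was cross-checked against every printed state row of
the three published course tables.  The transition structure is stored as
a successor array; the dense logical matrix and the fully algebraic STP
construction (per-node structure matrices lifted by Kronecker projectors
and fused with Khatri–Rao products) are built on demand and agree exactly
with per-state evaluation — the test suite asserts this on random
networks.  Attractor enumeration is iterative coloring, linear in the
2ⁿ states, with an 11-node cap (2¹¹ states) matching what a workstation
handles comfortably.

### Core reduction

Stripping childless nodes iteratively and clamping parentless inputs are
dynamics-exact operations: the reduced network's trajectory is the
projection of the full one, and removed nodes are reconstructed
step-for-step from their recorded rules in dependency order.  Collapsing a
single-in/single-out transduction node composes its relay function (and
negation parity) into its child but *shortens the path by one synchronous
step*; each removed relay records the number of original steps its
composed rule spans, and reconstruction honors that span.  Fixed points
are invariant under the collapse (timing is irrelevant at equilibrium),
which is what the published attractor statements rest on; transient timing
of a collapsed core is advanced relative to the full network, so the exact
trajectory-reconstruction guarantee is stated for the stripped (uncollapsed)
stage.  Nodes whose single parent equals their single child (2-cycles) are
never collapsed — this is what preserves the published MCP-5/SCF
mutual-inhibition loop — and stripping never removes a node on a directed
cycle.

Applied to the published IL-10 (M2c) parent lists, strip-then-collapse
reproduces the printed 5-node core exactly (MCP-3 is the one collapsed
relay).  The printed M1 and M2a core memberships are *not* derivable from
their printed function tables by any purely topological rule (the M1 table
lacks an edge its network figure evidently has; the M2a collapse removes
nodes of in-degree 2), so those cores ship as explicit fixtures with their
printed node lists, and the M1 core — whose printed rules happen to be
closed over the core nodes — reproduces its printed trajectory and both
printed stable states.

## The synthetic generator

Real panel data behind the published networks is not deposited, so
validation uses generated panels with known ground truth.  The generator
simulates a Boolean network on the 50-point grid and renders each node's
state through one of three archetypal shape kernels — promotion
`c·t/(1+t)`, inhibition `c/(1+t) + bias`, bell `c·exp(−(t−center)²/2w²)`
— with the kernel clock restarting at every Boolean switch (the archetypes
are single-transition shapes), multiplicative log-normal replicate noise,
and a detection floor.  Defaults mirror the study design: 7 measurement
times (0, 0.5, 1, 3, 6, 12, 24 h), 4 replicates, control plus stimulus
groups, σ = 0.15 log-normal scatter and a 0.01 floor — moderate assay
noise consistent with the high fit quality the study reports.  The control
group is rendered from a *held* all-low state (noise only); stimulated
groups start from configurable initial states (default all-high).  The
default low/high kernels are separated plateaus (5–25 vs. 300–500
expression units); overlapping ranges are flagged as a warning because
they make binarization unidentifiable.

What the generator does not emulate: receptor signaling, mRNA dynamics,
protein half-lives, or any mechanistic macrophage biology.  It realizes
exactly the statistical structure the pipeline assumes — Boolean dynamics
rendered through monotone state-dependent levels plus noise.  Passing
recovery tests therefore demonstrates the *pipeline's* correctness under
its own assumptions, not the biological fidelity of those assumptions.
Note also that the 7-point default design cannot resolve dynamics that
switch on the 13.5-min grid; exact round-trip and recovery tests sample
the panel on the simulation grid itself, while the 7-point design is
exercised for layout, screening and noise behavior.

## Numerical and degenerate-case conventions

* Zero/flat profiles: threshold replaced by the 1e-6 detection floor;
  all-don't-care truth tables become constant 0; shape ratios use the
  floor for zero initial values.
* K-means with fewer distinct values than clusters collapses duplicates
  and proceeds.
* LP solutions zero out weights below 1e-9; the LP is always feasible
  (slacks and a free non-negative bias), and an infeasible solver return
  raises rather than silently relaxing.
* KS on identical series short-circuits to D = 0 (drop).
* All randomness (noise, CV folds, generator rules) flows from explicit
  integer seeds; equal seeds give bit-identical panels and artifacts.

## Problem sizes

Exhaustive oracles run where exhaustion is cheap: all 2ᵖ rows for rules of
≤ 5 parents, all contiguous splits for 1-D clustering, all 2ⁿ states for
networks of ≤ 11 nodes, LP cross-checks at ≤ 6 candidate parents, and
synthetic recovery at 3–6 node networks with 50-grid sampling and 4
replicates.  These sizes match the published study's own scales (5–7 node
cores, 2⁵–2⁷ state spaces) and keep the full test suite a matter of
seconds on one CPU.

## Known limitations

* The KS screen drops genuinely responsive proteins whose activity is a
  brief transient — the distribution of fitted values then resembles the
  control's.  This mirrors the specified procedure.
* Rules that are not linearly separable (e.g. XOR-like, which the
  published M1 IL-2 rule is) cannot be found by the LP structure stage,
  only by the logic stage if the LP happens to propose the right parents.
* Collapse-based cores distort transient timing (documented above); use
  `collapse=False` where step-exact reconstruction matters.
* Inferred rules are only determined on visited parent states; don't-care
  rows are resolved by minimality, not by evidence.
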