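# Methods

This note records the models, estimators and numerical choices behind
`cardsflux`, in the order the pipeline uses them, together with the design
decisions that were genuinely open and the limitations a user should know
about.

## Dihedral discretization and disorder

Backbone φ/ψ dihedrals take two structural states — cis (|angle| < 90°) and
trans — and side-chain χ dihedrals take the three staggered rotamers with
half-open 120° sectors on the angle mod 360°: gauche+ = [0°, 120°),
trans = [120°, 240°), gauche− = [240°, 360°). The 120° boundary belongs to
the sector on its right (half-open rule); the backbone cut at ±90° is the
symmetric choice between the two named states. Angles are degrees in
[−180°, 180°), IUPAC sign convention; a torsion of exactly 180° is stored
as −180°. Residues that lack a given χ simply contribute no dihedral — no
imputation.

A residue's conformational disorder is the summed Shannon entropy (bits) of
its dihedrals' rotamer occupancies, normalized by the summed channel
capacities (log2 of the alphabet size), giving a value in [0, 1]: 0 for a
residue frozen in one rotamer combination, 1 for uniform occupancy of every
well. Entropy differences between two ensembles (e.g. before/after a
rate-limiting step) are reported per residue and are antisymmetric by
construction.

## Dynamical states

Each dihedral's structural-state series is run-length encoded into
segments between transitions. The segment durations are split at their
median; the mean duration above the median is the *ordered* timescale, the
mean at or below it the *disordered* timescale. Each segment is then
assigned to whichever timescale its duration is closer to in log space
(ties → disordered), and frames inherit their segment's label. Dihedrals
with fewer than two transitions are all-ordered; if the median split leaves
no upper group (all segments equally short, e.g. strict alternation), all
segments are disordered. This two-step rule (distribution estimation, then
per-segment assignment) is deterministic and parameter-free; it is a
concrete instantiation of the ordered/disordered idea and should not be
assumed numerically identical to other implementations of the same idea.

## Mutual-information channels

All information measures use base-2 logarithms. The MI estimator is the
plug-in estimate on the joint counts table, with empty cells contributing
zero; no bias correction is applied — bootstrap spreads convey uncertainty
instead, and all significance decisions are made against empirical nulls
(below) rather than against the estimator's absolute scale. Each of the
four channels (structure/dynamics × structure/dynamics) is normalized by
its channel capacity log2(min |X|, |Y|); the mixed channels Ī_sd(X,Y) and
Ī_ds(X,Y) are stored separately (Ī_sd(X,Y) = Ī_ds(Y,X)), and the holistic
communication I_H is their four-way sum, symmetric and in [0, 4].
Intra-residue pairs and the diagonal are excluded from every residue-level
score to avoid trivial self-correlation; residue aggregation uses sums (not
means) of dihedral-pair terms, so residues with more dihedrals can
accumulate larger scores — a documented convention that affects ranking
only through dihedral counts.

## Target communication, null model and network tracing

A residue's communication to a target site is the sum of I_H over all
dihedral pairs linking it to the target's dihedrals; uncertainty comes from
10 bootstrap resamples of the frames (with replacement, dynamical labels
resampled jointly with structural ones).

Significance is judged against a *circular-shift null*: rolling the target
site's series by 1/4, 1/2 and 3/4 of the trajectory destroys any real
cross-correlation while preserving each dihedral's occupancies and
autocorrelation — and it is the autocorrelation (persistent rotamer wells,
long ordered/disordered episodes) that sets the finite-sample floor of the
plug-in MI, at roughly the asymptotic bias times the autocorrelation time.
A candidate is significant when its score exceeds twice its worst shifted
score.

The iterative trace ("score everything against the current target, recruit
the strongest group, make it the new target") defines its frontier as the
*most strongly communicating group*: the top significant scorer plus any
candidate within two combined bootstrap spreads of it. An absolute
noise-floor threshold alone cannot work here: communication is transitive
(if A drives B and B drives C, then A and C correlate), so on any real
pathway several residues sit far above the noise floor and the frontier
must be the statistically strongest group, not everything significant.
The trace stops when the sink site is recruited, the frontier is empty, or
an iteration cap (50) is hit.

## Markov state models

k-centers clustering is the greedy farthest-point algorithm seeded at frame
0 (deterministic), stopping when every frame is within the cutoff of a
center; centers are actual frames. The k-medoids refinement proposes one
random member per cluster per sweep and accepts only objective-decreasing
swaps (mean frame-to-medoid distance), so the objective is non-increasing.
Ligand poses can be clustered the same way and combined with protein states
into product states indexed over observed pairs only; states whose mean
residence time falls below a residence-time parameter can be merged into
their most-connected neighbor — a deliberate simplification of residence-
time-aware partitioning algorithms, not a reimplementation of one.

Transition counts use a sliding window at lag τ within each trajectory,
never across trajectory boundaries. The default estimator symmetrizes the
counts, (C + Cᵀ)/2, then row-normalizes — this enforces detailed balance
exactly (π ∝ symmetrized row sums), which keeps committors and reactive
fluxes well defined; a 'raw' row-normalized estimator with π from the
leading left eigenvector is available for diagnostics. Estimation is
restricted to the largest strongly connected component of the count graph;
dropped states are reported in a warning. Implied timescales
t_i(τ) = −τ/ln λ_i(τ) flag complex or non-positive eigenvalues as
undefined (NaN) and unit eigenvalues as infinite.

## Transition path theory and the rate-limiting step

Forward committors solve q⁺ = T q⁺ on intermediates with q⁺ = 0 on the
bound set A and 1 on the unbound set B (dense linear solve, residual
checked at 1e-10). The reactive flux from i to j is
f_ij = π_i q⁻_i T_ij q⁺_j (zero on the diagonal); the net flux is its
positive antisymmetric part and is divergence-free at intermediates for
detailed-balance models, which is the conservation law the tests assert.

Pathways are extracted by the standard bottleneck decomposition: find the
widest (maximum-bottleneck) A→B path — binary search over the distinct edge
capacities with reachability testing — record it, subtract its capacity
from its edges, repeat. Path ties are broken by fewest hops, then
lexicographic state order. Path capacity uses the *gross* directional flux
f_ij by default rather than the net flux: on a single release path the net
flux is the same constant on every edge (a divergence-free 1-D current),
so only the gross flux, which adds the recrossing traffic, can distinguish
where the current is throttled.

The bottleneck of a path is its minimum-flux step, with one refinement: the
first edge (out of A) and last edge (into B) are excluded when the path has
interior steps, because their backward reactive flux vanishes identically
(q⁺ = 0 on A, q⁻ = 0 on B), making their gross flux exactly the path's net
current regardless of where the kinetic bottleneck lies — they always tie
the minimum and carry no information. On ties among considered edges the
first is returned. The consensus rate-limiting step across the k highest-
flux paths is the most frequent per-path bottleneck, frequency ties going
to the edge with the smallest flux. Two macrostate presets are exposed:
transition-path endpoints (bound = ligand–site distance ≤ 6 Å AND ligand
RMSD < 0.5 Å; unbound = distance > 55 Å) and a single-threshold 8 Å
bound/released ensemble split — they serve different roles (TPT endpoints
vs. comparing ensembles on either side of a step).

## Metadynamics and free-energy reconstruction

The integrator is overdamped Langevin (Euler–Maruyama) with friction γ = 1
and abstract time units; temperature enters as k_B T in kJ/mol. Gaussians
of fixed height (default 1.5 kJ/mol — non-well-tempered) are deposited at
the walker's CV position every `stride` steps. One-dimensional runs use a
compiled fast path: the potential gradient and the accumulated bias force
are tabulated on a grid of spacing σ/5 and linearly interpolated, an
O((spacing/σ)²) ≈ 0.5% approximation of a Gaussian's shape that makes
10⁸-step runs take seconds. Escaping the potential's rectangular domain
truncates the run with a warning; optional one-sided harmonic walls can
confine the walker (they act on the dynamics only, never on the recorded
bias).

F(S) = −V_G(S) anchored to min F = 0 is the basic estimate. Because a
constant-height bias never converges pointwise — the well-to-well bias
difference oscillates with amplitude ~h·k_BT^(1/2)-scale and a correlation
time of ~10² deposits — `fes_estimate` optionally averages −V_G over the
last fraction of deposits (computed in closed form from per-Gaussian
weights). The double-well benchmark uses: barrier 25 kJ/mol = 10 k_BT at
k_BT = 2.494 kJ/mol, tilt 2.5 (well ΔF ≈ 5 kJ/mol), Gaussian width 0.2 CV
units (~1/10 of the inter-well distance), deposition every 4 time units
(stride 8000 at dt = 5·10⁻⁴, chosen so deposits are roughly diffusion-
decorrelated), 1.6·10⁸ steps (20 000 deposits — ending before the bias
floods the confining quartic walls), and averaging over the last 90% of
deposits. Under these conditions the recovered well free-energy difference
is within 0.5 kJ/mol of the analytic value across seeds, and the barrier
within a few percent. The run length and width are convergence parameters
of the estimator, not physical claims; shorter runs give proportionally
larger (√-law) errors.

## String method and seeding

The minimum free-energy path is found with the zero-temperature string
method on the gridded surface: a straight start→end string of n nodes,
interior nodes descending the multilinearly interpolated gradient
(central-difference gradients on the grid), endpoints anchored,
reparameterized to equal arc length every iteration, converged when the
maximum node displacement falls below the tolerance (default 1e-4 CV
units). The step size defaults to 0.1 × grid spacing / max |∇F|. This is a
deliberate simplification of finite-temperature string formalisms: it
yields the zero-temperature MFEP, which coincides with the finite-
temperature path only when the CV-space metric is approximately constant
along the path. Seeding picks, for each of n equally spaced arc-length
points, the trajectory frame with the nearest CV value; frames farther than
a caller-supplied cutoff (typically one grid spacing) are skipped with a
warning.

## Synthetic generators: what they emulate, and what they do not

`gen_coupled_rotamers` produces side-chain-like dihedrals hopping among
wells at +60°/180°/−60° with wrapped-Gaussian noise σ = 15° — the
gauche+/trans/gauche− convention — with per-frame well persistence 0.9 and
a uniform stationary distribution. A planted edge makes the target
residue's dihedrals copy the source's already-updated state with
probability ε (edges applied in listed order, so chains propagate within a
frame): ε = 0 is exactly independent, ε = 1 maximally informative. This
captures the statistical structure CARDS consumes (rotamer occupancies,
ordered/disordered kinetics, directed coupling) but none of the physics of
real allostery — no energetics, no backbone/side-chain asymmetry, no
through-space contact structure. Passing recovery tests therefore
demonstrates correctness of the inference machinery, not its power on real
ensembles.

`gen_unbinding_chain` builds the exact tridiagonal transition matrix of a
linear bound → intermediates → unbound chain (self-loops absorb the
remainder) and samples trajectories from it; a designed bottleneck edge is
validated to carry strictly the smallest rate. `gen_particle_trajectory`
is the same Langevin integrator without bias. Time units everywhere are
frames/abstract; no attempt is made to emulate nanosecond timescales or
real release kinetics.

## Problem sizes used in the validation suite

Network recovery uses 10 residues × 2 dihedrals × 10⁵ frames × 10
replicates (planted chain at ε = 0.7); bottleneck recovery uses 7-state
chains sampled for 10⁶ steps × 10 replicates; flux conservation uses 100
random reversible 50-state models; widest-path enumeration uses 100 random
graphs of ≤ 8 states against exhaustive simple-path search; the
metadynamics benchmark runs three seeds of the double well above. These
sizes keep the full suite under a few minutes on one CPU while leaving the
statistical margins (e.g. recovery 10/10, ΔF error ≤ 0.5 kJ/mol) wide.

## Known limitations

* The plug-in MI floor depends on autocorrelation; the circular-shift null
  handles significance, but absolute I_H values between datasets with
  different kinetics are not directly comparable.
* The ordered/disordered parsing rule is one concrete instantiation of a
  two-timescale idea; alternatives (e.g. fitting a two-component duration
  mixture) would label borderline segments differently.
* The frontier rule recruits one statistically tied group per iteration;
  genuinely parallel pathways of different strength are recruited in
  successive iterations rather than simultaneously.
* The symmetrized-count MSM estimator is biased for strongly irreversible
  processes; it is the standard price for exact detailed balance.
* Constant-height metadynamics has a non-vanishing stationary error;
  tail averaging controls it but the √-law convergence is slow.
* The zero-temperature string ignores the metric tensor of the CV map;
  paths on strongly curved CV spaces should be treated as qualitative.
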