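# Methods

This note records the models implemented, the parameter choices that
matter, the numerical conventions, and what the synthetic fixtures do and
do not establish.

## Zonal schooling model

Agents are point particles in 2-D with constant individual speed.  Speeds
are drawn once at initialisation as `speed * (1 + σ z_i)`, z_i standard
normal (σ is per-agent variability, not per-step noise), and never change.
Headings are unit vectors updated each step by a zonal steering rule with
three concentric shells around each agent:

- repulsion, `dist < r_r`: steer along `−Σ r̂_ij` (away from everyone in
  the shell).  This zone has absolute priority — when it is non-empty the
  outer shells are ignored.
- orientation, `r_r ≤ dist < r_o`: the normalised mean heading of the
  shell's occupants.
- attraction, `r_o ≤ dist < r_a`: the normalised mean unit vector towards
  the shell's occupants.

When both outer shells are occupied their two unit responses are averaged
with weight 1/2; a degenerate (zero) resultant, or an empty neighbourhood,
leaves the heading unchanged.  Coincident agents are treated as repulsion
along a random direction drawn from the run's generator, so runs remain
seed-reproducible.  The heading may rotate by at most β per step; larger
disagreements are clipped to a rotation by exactly β towards the desired
direction.  Positions then advance by `|v_i| d_i dt`.

In a bounded arena (circle of radius 25 m) an agent whose provisional step
would exit has its desired direction replaced by the unit vector towards
the origin before the turn limit; after the move, positions are radially
projected onto the disc, so containment is exact.  This is the minimal
rule consistent with wall collisions producing transient re-orientations.

### Parameters and regimes

Defaults: N = 64, speed 4 m/s, σ = 0.05, dt = 0.01 s, arena radius 25 m,
r_a = 20 m, and orientation radius r_o ∈ {2, 10, 13} m for the swarm,
torus and parallel regimes.  Initial positions are uniform in angle with
radii uniform in [6, 16] m; initial headings are the counter-clockwise
tangent (perpendicular to the position vector), which seeds the coherent
rotation from which the torus develops.  Analysis windows start at 10 s
for the torus (analysed right after its transient) and 30 s for swarm and
parallel (which take longer to develop), with 40 s runs.

Two constants are not fixed by the published protocol and were chosen
here so that the three regimes actually emerge from r_o alone:

- `r_r = 2.0 m`.  With a 1 m personal space the attraction-driven mill at
  r_o = 2 is a stable attractor (angular momentum ≈ 0.9) and no swarm
  forms; the larger repulsion zone breaks that mill while leaving the
  r_o = 10 torus intact.
- `β = 0.012 rad/step` (1.2 rad/s at dt = 0.01 s, the same order as the
  40°/s turning rate of the classic zonal model).  Much larger values make
  alignment effectively instantaneous and every orientation radius above a
  few metres polarises; much smaller values leave the parallel state
  unreachable within the protocol duration.

With these values, 5-seed means under the protocol windows are:
angular momentum 0.78 (torus) vs 0.08–0.12 elsewhere; polarization 0.65
(parallel) vs 0.11–0.15 elsewhere.  Both constants are exposed in
`SchoolingParams` for substitution.

`TrajectoryEnsemble.velocities` stores forward differences of positions,
so the positions/velocities pair is exactly self-consistent (the boundary
projection makes the heading-based velocity only approximate at wall
contacts).

## Observables

For swarms the decomposition input is the nearest-sorted distance series:
per frame, each agent's distances to the other N−1 agents sorted
ascending, rows concatenated in agent order (p = N(N−1)).  Within-row
sorting removes neighbour identity and makes the series far smoother than
the fixed-pair ordering; relabelling agents permutes whole rows, which
leaves the decomposition spectrum unchanged.  Fixed-order upper-triangle
distances (p = N(N−1)/2) and stacked Cartesian coordinates (p = 2N) are
provided for comparison.

For 5-on-5 game segments the canonical observable is the per-frame sorted
5×5 attacker–defender distance matrix: column 1 is the ball-handler, the
remaining columns are attackers by decreasing nearest-defender
separation (ties broken by attacker index), and each column lists that
attacker's defender distances nearest-first.  The input variants are
(i)–(iv) the first one to four *critical distances* — ball-mark and
ball-help (the handler's first and second defender distances), pass-mark
and pass-help (the largest and second-largest nearest-defender distance
among off-ball attackers) — (v)–(vii) the top-left 3×3 / 4×4 / full 5×5
block of the sorted matrix, (viii) the 25 unsorted pair distances and
(ix) the 20 raw coordinates.  Attack segments run from the first frame
with all five attackers in the attacking half to exactly 1 s (25 frames)
before the shot.

## Dynamic mode decomposition

Plain DMD follows the projected (SVD) algorithm; the default rank is the
numerical rank of the singular spectrum at a relative threshold of 1e−10.
Frequency and growth are separated through the principal branch of the
complex logarithm, `f = Im ln λ/(2πΔt)` and `g = Re ln λ/Δt`; λ = 0 modes
are reported as fully decayed (g = −∞) and their mode vectors are kept
without the λ⁻¹ scaling (which is undefined there).  Spectral amplitude
is `|ψ_j|·‖φ_j‖`, which is invariant to the arbitrary scaling split
between mode and coefficient (`|ψ_j|` alone is available by option).
Spatial band-power maps average `|ψ_j|²|φ_j|²` over the modes in a
frequency band — the bare `|φ_j|²` average is convention-dependent and is
kept only as an option.  Conjugate pairs are merged (f ≥ 0 reported).

Kernel DMD eigendecomposes the centred Gram matrix `H G_yy H`
(H = I − 1/n over the n = τ−1 snapshots) with the symmetric solver, drops
components below 1e−12 of the leading eigenvalue, and forms
`F̂ = S̄^{−1/2} B̄* (H G_yy' H) B̄ S̄^{−1/2}`; both Gram matrices are centred
with the same H.  Eigenvalues below 1e−12 of the spectral radius are
discarded; eigenvectors are unit-normalised with their largest entry
rotated to be real-positive so complex scaling is reproducible.  The
Gaussian bandwidth defaults to the median pairwise snapshot distance.
Data-space pre-images of kernel modes are not computed; the linear-kernel
path (where feature space equals data space and the decomposition matches
plain DMD exactly) and a one-step spectral prediction error in the
principal-component coordinates serve as the reconstruction checks.

## Koopman spectral kernels

A fitted segment's Koopman modes `φ̄_j = U v_j` span a subspace of the
RKHS (U = kernel-PCA directions, v_j the F̂ eigenvectors).  All inner
products between two segments' modes reduce to Gram-block algebra; the
cross block routes through the centred Gram of the two snapshot series
connected head to tail (centred at the joint length, upper-right block
cut out).  The mode Gram blocks enter the standard generalized
eigenproblem for principal angles; eigenvalues come in ± pairs whose
magnitudes are the cosines, of which the top min(r_i, r_j) are kept,
clipped to [0, 1].  The scalar kernel is their product (the determinant /
Binet–Cauchy form; a sum option exists), and distances follow
d(i,j) = k(i,i) + k(j,j) − 2k(i,j), clipped at zero against rounding.

Two conventions deserve note.  First, the mode Gram blocks are computed in
Hermitian form `V* (·) V`; a one-sided `V⁻¹ (·) V` form would make the
diagonal blocks exactly the identity (kernel-PCA directions are
orthonormal) and destroy the Gram semantics the principal-angle problem
needs.  Second, because the whitened problem only sees the *span* of the
modes, the kernel compares the visited regions of feature space weighted
by their principal directions — eigenvalue phases as such are invisible.
Discriminative power therefore requires the class signal to shape the
visited geometry of the observables, which informs the design of the
synthetic game generator below.  When a segment set is processed
together, one shared Gaussian bandwidth (median pairwise distance of the
pooled snapshots) keeps every fit in a single RKHS; per-pair bandwidths
would compare subspaces of different spaces.

Model order for the game pipeline is fixed at rank 10 — two to three
spectral components per observable channel for the 4-channel
critical-distance input — and exposed everywhere as a parameter.

## Dynamic structure factors

Currents `j_L(q,t) = Σ_i (v_i·q̂) e^{iq·r_i}` (and transverse analogue)
are Fourier-transformed in time per wavenumber and direction;
`S = |Δt Σ_t j e^{iωt}|² / (2πNT)` so that `Σ_ω S Δω` equals the
time-averaged `|j|²/N` (discrete Parseval; asserted in tests at 5%).  The
full ω grid (negative and positive) is kept; no taper is applied by
default because peak *positions* are the quantity of interest (a Hann
option exists).  Directions are averaged over n_angles = 16 equally
spaced unit vectors by default and trials arithmetically.  Mean group
drift is not subtracted.  The dispersion slope is the least-squares fit
of the ω > 0 peak ridge through the origin; ties in the argmax break
towards the smallest |ω|, so a featureless spectrum reports a peak at
zero.  For the ballistic oracle the current of a uniformly translating
cloud is a superposition of plane waves at ω = q·v, so the ridge along
q ∥ v has slope exactly the speed; direction-averaged grids bias the
apparent peak below q·v on coarse angle grids (the ±φ degeneracy near the
band edge), hence the oracle is evaluated along the motion.

## Embedding and classification

Classical (Torgerson) MDS double-centres −D²/2 and keeps the top
nonnegative eigenpairs; exact Euclidean inputs are reproduced to 1e−8.
Classification is Gaussian naive Bayes (variance floor 1e−9) on feature
vectors formed from each segment's kernel-similarity row restricted to
the training-fold columns (distance rows are available by option), with
stratified, seed-fixed 5-fold cross-validation; the summary statistic is
the median of the five fold error rates, and confusion counts are pooled
across folds.

## Synthetic fixtures and what they establish

- `linear_fixture`: y_{t+1} = A y_t (+ optional noise); spectrum of A is
  the stored ground truth.  Establishes exactness of the decompositions on
  their ideal model class.
- `koopman_oscillator_fixture`: x1 ← λx1, x2 ← μx2 + c x1²; Koopman
  eigenvalues {λ, μ, λ²} are recovered by any kernel whose feature space
  contains quadratics.  This is a documented stand-in for a nonlinear
  demonstration system whose exact definition is not public; it is chosen
  for its closed-form Koopman spectrum, not for physical realism.
- `ballistic_fixture`: uniform translation; dispersion slope equals the
  speed.
- `game_segment_generator`: two-class 5-on-5 segments at 25 fps, 3–8 s,
  balanced labels.  Attackers drift slowly around a pentagon formation on
  a half court; each defender marks one attacker at a stereotyped
  baseline distance (2.0 ± 0.2 m).  Score segments superpose a slowly
  growing 0.5 Hz oscillation (amplitude 0.5 m, growth 0.1 /s) on the
  marking distances — defenders progressively losing their marks — while
  no-score segments carry only 0.15 m, 3 Hz tracking jitter;
  `class_effect` scales both signatures and 0 makes the classes
  statistically identical.  The baseline is kept tight deliberately: the
  spectral kernel compares visited observable geometry, so a label signal
  buried under large per-segment baseline scatter is unrecoverable by
  construction (and by any observer).

Passing tests on these fixtures show that each analysis recovers declared
ground truth under its stated assumptions.  They do not show robustness
to tracking noise, missing agents, identity switches, or the
non-stationary tactics of real game data, none of which the generators
emulate; nor does the schooling model include sensory noise, a blind
angle, body size or 3-D motion.

## Known limitations

- The regime constants (r_r, β) were set so the published three-regime
  phenomenology emerges; other combinations move the regime boundaries,
  and the torus is init-sensitive (mixed initial handedness destroys it).
- Under this parameterisation the torus and parallel sorted-distance
  spectra have statistically indistinguishable 0.5–1.5 Hz band amplitude,
  and all regimes (torus included) show *elevated* rather than depressed
  band power in the nearest-neighbour entries — strong ~1 Hz
  approach–retreat dynamics inside the 2 m repulsion shell dominate that
  band.  The overall swarm > parallel > torus strength ordering does hold
  on 5-seed means.
- The spectral kernel ignores eigenvalue phases (see above); inputs must
  encode class structure geometrically.
- Distance matrices use raw Euclidean distances; no spatiotemporal
  correction of marking distances is applied.
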