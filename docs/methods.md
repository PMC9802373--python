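# Methods

`plectonemics` measures the size and dynamics of topological domains in
supercoiled DNA from extension fluctuations. It has four scientific layers
— analytical elasticity, a twistable wormlike-chain Monte Carlo,
synthetic-trace generation, and the fluctuation-analysis pipeline — plus a
thin text-file/CLI interface. This note records the models, the defaults
and why, the numerical choices, and the limits of what the tests show.

## Analytical elasticity (`plectonemics.theory`)

A stretched, overwound DNA of contour length L is described by free
energies per unit length (units pN; k_BT = 4.114 pN·nm at 298 K):

- stretched phase: S(σ; f) = −g(f) + ½ k_BT c_s(f) ω0² σ², with
  g(f) = f − √(k_BT f/A) the high-force wormlike-chain free energy gain
  and c_s(f) = C[1 − (C/4A)√(k_BT/(A f))] the force-renormalized
  (Moroz–Nelson) twist persistence length;
- plectonemic phase: P(σ) = ½ k_BT P ω0² σ², with constant torsional
  stiffness P.

Here σ = ΔLk/Lk0 is the supercoiling density and ω0 = 2π/(10.5·0.34 nm)
the intrinsic twist density. Beyond the buckling density σ_s the
equilibrium free energy is the common tangent between the branches —
linear in σ — and the molecule is a mixture of stretched DNA at σ_s and
plectoneme at σ_p. Because both branches are quadratic the tangency
conditions have a closed-form solution,

    σ_p = √(2 g / (c̃_p (1 − c̃_p/c̃_s))),   σ_s = (c̃_p/c̃_s) σ_p,

with c̃ = k_BT c ω0²; the solver still runs a Newton refinement of the
tangency residuals from this starting point (and falls back to a grid
search) so that non-quadratic phase models can be dropped in later.

Mean extension and variance follow by force differentiation:
⟨z⟩/L = −dF/df and ⟨Δz²⟩/L = −k_BT d²F/df² = k_BT d(⟨z⟩/L)/df. On the
coexistence branch ⟨z⟩/L = Γ(f)(σ_p − σ) with
Γ = (−∂S/∂f at σ_s)/(σ_p − σ_s); by the envelope theorem this makes the
branch exactly linear and continuous at σ_s. The variance grows linearly
in σ and reaches κ = k_BT Γ ∂σ_p/∂f at σ = σ_p — the constant that
converts a variance drop into looped contour length. Force derivatives of
Γ and σ_p are taken by central differences with one Richardson step
(step 10⁻³·f); the fluctuation–response identity holds to better than
10⁻³ relative on a (σ, f) grid, checked against an independent
second-difference of F.

Defaults: A = 40 nm, C = 100 nm, P = 20 nm, 10.5 bp/turn, 0.34 nm/bp,
T = 298 K. All overridable. Underwound DNA (σ < 0) and the fully
plectonemic branch (σ > σ_p) are refused rather than extrapolated: the
model contains no torque-induced melting, and magnetic-tweezers data
cannot probe σ > σ_p anyway.

Known limitation: the two-phase model with these standard forms
overestimates the magnitude of the postbuckling slopes (at 0.5 pN it gives
≈66 nm/turn against ≈53 from simulation and experiment). Only the force
*scalings* of the four rotation-curve coefficients (f^(−3/2), f^(−5/2)
prebuckling; f^(−1/2), f^(−3/2) postbuckling) are treated as quantitative
predictions of the theory layer; absolute postbuckling slopes come from
the Monte Carlo layer.

## Monte Carlo (`plectonemics.chain`, `plectonemics.mc`)

The chain is N beads with exact bond length a, clamped terminal tangents
(phantom ẑ segments at both ends entering the bending energy), energy

    E/k_BT = (A/a) Σ (1 − cos θ_i) + (2π²C/L)(ΔLk − Wr)² − f·z/k_BT,

and a hard-core excluded diameter d_ex between beads of contour
separation > 1. Twist is implicit: the molecule's twist is ΔLk − Wr,
partitioned uniformly along the contour. Writhe is the exact pairwise
Gauss sum over non-adjacent segment pairs (each pair's solid angle
evaluated as two spherical triangles by the van Oosterom–Strackee
formula, equivalent to the Klenin–Langowski pairwise result), under the
open-chain convention with axis-directed termini. During a move only the
pair terms involving moved segments are recomputed (rigid-rotation
invariance cancels the rest); the tracked writhe equals a from-scratch
recomputation to 10⁻⁸ after 10⁵ moves.

Moves: sub-chain crankshafts (rotation about the chord joining the block
ends) and end pivots about a random axis through the pivot bead, chosen
with state-independent probabilities; rotation angles are uniform on
±θ_max with θ_max scaled as 2θ/√(block) for blocks larger than 4 beads so
acceptance stays roughly uniform across scales. Topology is preserved by
(i) rejecting any configuration with bead overlaps, checked along the
swept rotation in ≤10° increments, and (ii) rejecting any single move
with |ΔWr| > 0.5 as a strand-passage sentinel (a passage changes Wr
by ≈ ±2). Sampling uses a fixed stride; errors are block averaged, and a
drifting half-trace mean raises a non-equilibration warning.

Bridged simulations mimic a two-site DNA-bridging protein: the six beads
i−1…i+1, j−1…j+1 form a rigid cluster whose relative pose is preserved
exactly, because the only moves allowed to touch it are large crankshafts
that rotate the whole cluster (and everything between the chosen pivots)
rigidly; all other moves must leave it untouched. Bridge candidates are
bead pairs closer than 8 nm, both in the plectonemic phase, with
antiparallel tangents (dot < −0.5, the operational reading of "opposite
superhelical strands"). The loop's linking difference is the writhe of
the chord-closed loop subchain plus its uniform-twist share
(ΔLk − Wr)·ΔL/L; the complement is assigned the remainder, so the
partition conserves ΔLk by construction.

Plectoneme detection labels a bead plectonemic when another bead at
contour separation > 4A lies within 10 nm, followed by a 5-bead majority
vote; each bead carries contour weight L/N so L_s + L_p = L exactly.

Numerical defaults and why:

- a = 2.5 nm (≈ 16 beads per bending persistence length) is the library
  default. Coarser discretizations make plectoneme end loops too cheap
  (the discrete bending energy (A/a)(1 − cos θ) under-penalizes sharp
  bends), which tightens plectonemes and flattens the ⟨z⟩-vs-ΔLk slope;
  the headline slope computation therefore uses the 2.5 nm default.
- d_ex = 4 nm approximates the electrostatic effective diameter at
  ≈150 mM monovalent salt.
- Desk-scale schedules (10⁵–10⁶ steps per point) are used in tests and
  the reproduction script — far below publication-scale runs. At low
  force (0.5 pN) the slowest modes are plectoneme nucleation, growth and
  morphology changes: independent runs of a few 10⁶ steps can settle on
  distinct long-lived branches (same writhe stored in more or less
  compact plectonemes) whose mean extensions differ by tens of nm.
  Three mitigations are built in: (i) postbuckling starts can be seeded
  with a constructed interwound plectoneme
  (`chain.plectoneme_conformation`, used automatically well past
  buckling), which places the chain in the developed-plectoneme basin
  instead of waiting for nucleation; (ii) ΔLk ladders can anneal, reusing
  the previous point's conformation; (iii) the headline slope protocol
  measures every point twice — relaxing from a straight (over-extended)
  chain and from a seeded plectoneme (under-extended) — and fits the
  bracket midpoints, so the leading initialization bias cancels and the
  bracket spread enters the reported uncertainty. Block-averaged SEs and
  a half-trace drift diagnostic flag residual non-equilibration.
- For a 2 kbp molecule the buckling transition is strongly rounded by
  finite size (the shoulder extends to σ ≈ 0.04 at 0.5 pN), so per-turn
  slopes of ⟨z⟩ versus ΔLk are quoted on the asymptotic linear branch
  (σ ≈ 0.042–0.060). Desk-scale slope estimates at 0.5 pN sit near
  40 nm/turn with branch-dominated uncertainties of order 10 nm/turn,
  below the ≈53 nm/turn that publication-scale simulations of this model
  class reach at these conditions; the gap and its diagnosis (verified
  sampler, metastable morphology branches at desk scale) are part of
  this package's documented scope.

## Synthetic traces (`plectonemics.synth`)

Bead-tracking traces are Ornstein–Uhlenbeck: exact AR(1) discretization,
stationary from the first sample, with variance ⟨Δz²⟩ and correlation
time τ_c tied to the friction by τ_c = γ⟨Δz²⟩/k_BT. Protein-bridging
dynamics are a continuous-time Markov chain over loop linking-number
states ΔΔLk: leave events at rate 1/τ_p, destination drawn from the
equilibrium occupancies p_i (Gaussian in ΔΔLk with variance ΔL/(4π²P)),
self-transitions allowed — so the observed dwell time in state i is
τ_p/(1 − p_i). State k sits at extension −spacing·k relative to the
central state. Defaults mirror the loop-kinetics observations this
package is built around: spacing 48 nm/turn, τ_p = 65 s, ΔL = 254 nm,
P = 20 nm, 1 kHz acquisition.

Not modelled: camera blur/aliasing (τ_c > 1 ms at 1 kHz sampling makes it
negligible), instrument drift, state-dependent noise variance (predicted
changes are below experimental resolution). Passing the recovery tests
therefore shows the pipeline is correct for the assumed statistical
structure, not that it is robust to drift or blur.

## Analysis pipeline (`plectonemics.analysis`)

- Windowed statistics: non-overlapping 1 s windows; per-window mean
  subtraction removes drift slower than the window; pooled variance is
  the mean of window variances with an SE from their scatter.
- Correlation time: FFT autocorrelation integrated (trapezoid) to its
  first non-positive lag; a correlation that has not crossed zero within
  a quarter of the trace raises rather than returning a number.
- Rotation-curve fit: even quadratic (prebuckling) plus straight line
  (postbuckling). The buckling density is located from the variance
  column when present — the variance *jumps* at buckling, which
  localizes the transition to within a grid spacing, far better than the
  kink in ⟨z⟩ — otherwise from a two-regime split scan of the fitted
  observable. Branch coefficients are then fitted on the two sides
  separately, so noiseless inputs are recovered exactly.
- Calibration: σ_p is the zero-extension intercept of the weighted linear
  postbuckling ⟨z⟩ fit (window starting 0.005 above the detected
  buckling density); κ is the linear ⟨Δz²⟩ fit evaluated at σ_p divided
  by L. Covariances propagate into σ_p and κ errors; extrapolating σ_p
  beyond twice the fitted range flags the calibration unreliable.
- Domain size: ΔL = Δ⟨Δz²⟩/κ with propagated SE; a non-positive drop
  returns ΔL = 0 with a no-bridging diagnostic.
- State segmentation: 10 s sliding average, histogram peaks constrained
  to a common spacing (iteratively refined integer-rank regression),
  sticky nearest-level assignment with 0.25·spacing hysteresis. Fewer
  than two resolvable peaks is a valid single-state result.
- Plectoneme stiffness: P = ΔL/(4π²⟨(ΔΔLk)²⟩) with ⟨(ΔΔLk)²⟩ the squared
  width of a free-center Gaussian fitted to the occupancies; a
  direct-variance estimator on raw loop-ΔLk samples is provided for
  cross-checks.
- Dwell times: censored first/last dwells dropped; dwells shorter than
  the filter window excluded, and — because the exponential is
  memoryless — the cutoff is subtracted before the maximum-likelihood
  mean and the Lilliefors exponentiality test, which removes the
  left-truncation bias (≈ +(1 − p_i)·10 s otherwise). τ_p = (1 − p_i)τ_i
  per state, summarized as mean ± SD over the three most-populated
  states.

The sliding filter also merges sub-window excursions, which inflates
apparent dwells by a few percent when neighbouring states live ≳10× the
window; this residual bias is visible in the recovery tests and is the
main reason the τ_p tolerance is 10% rather than statistical.

## Degenerate inputs and tie-breaks

Zero or negative forces, non-positive elastic constants, σ < 0, σ > σ_p,
non-uniform trace sampling, non-finite samples, windows shorter than 10
samples, and bridges without interior neighbours all raise immediately.
A degenerate double tangent (c_s(f) ≤ P) raises `NoCoexistenceError`
rather than clamping. Exactly straight chains are handled in the writhe
sum by returning zero for degenerate (collinear) segment pairs.

## What the tests do and do not show

Unit and property tests pin the algebra (exact inversions, conservation
laws, symmetry, seeded determinism) and the statistical estimators on
data generated by the package's own models. Monte Carlo observables are
verified against analytical limits (stretched-WLC extension,
fluctuation–response) and internal oracles (quadrature writhe, proximity
clustering); postbuckling observables at 0.5 pN carry the largest
uncertainty because desk-scale runs sit at the edge of the plectoneme
equilibration time, which is reported through block SEs and drift flags.
Agreement on synthetic data does not demonstrate robustness to features
real traces have and the generators omit (drift, blur, heterogeneous
noise).
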