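# Methods

`modflex` models how cytosine modifications (5-mC, 5-hmC, 5-fC, 5-caC) at CpG
steps change the mechanics of double-stranded DNA and of nucleosomes, at three
levels: local structural fluctuations of the double helix, loop-closure
(cyclization) behaviour of ~90-bp fragments, and the force response of
nucleosomal DNA observed by smFRET.  Because the primary data behind such
studies — cluster-scale MD trajectories and single-molecule recordings — are
not available at desk scale, the package pairs every analysis with a synthetic
generator that reproduces the relevant *statistical* structure of those data,
so each pipeline can be validated closed-loop: generate with known truth,
analyse, check recovery.

## Rigid base-pair description (`modflex.geometry`)

Duplex DNA is described by the standard twelve rigid-body parameters: six
inter-base-pair step parameters (shift, slide, rise in Å; tilt, roll, twist in
degrees) and six intra-base-pair parameters (shear, stretch, stagger; buckle,
propeller, opening).  The implementation uses the mid-frame (CEHS-style)
decomposition — the convention of the widely used 3DNA analysis tool — rather
than a helical-axis scheme: the rotation between consecutive base-pair frames
is factored as

    A = Rz(Ω/2 − φ) · Ry(Γ) · Rz(Ω/2 + φ)

with twist Ω about the mid-frame z-axis and a bend Γ about a hinge in the
mid-frame xy-plane at phase φ, giving roll = Γ·cos φ and tilt = Γ·sin φ;
translations are expressed in the mid frame.  The same decomposition between
the reference-strand base frame and the y/z-flipped complementary frame
yields the intra-base-pair parameters (buckle ↔ x-rotation, propeller ↔
y-rotation, opening ↔ z-rotation).

Numerical choices:

* Phase recovery uses φ = Ω/2 − atan2(A₁₂, A₀₂) with Ω already wrapped into
  (−180°, 180°]; recovering φ from the half-difference of the two atan2
  angles alone is ambiguous mod 180° and can land on the (−Γ, φ+180°) branch.
* `rebuild_frames` is the exact algebraic inverse of `step_params`; round
  trips hold to < 1e-8 (the test suite also checks equivalence < 1e-6 with an
  independent hinge-construction oracle built on scipy rotations).
* Frame orthonormality is enforced at 1e-6 on input and preserved to 1e-9.
* Base frames are fitted by Kabsch superposition of ring atoms only (C1′ and
  all exocyclic substituents excluded), so modified and unmodified cytosines
  yield directly comparable frames and parameter statistics reflect
  base/backbone motion, not substituent placement.  Fewer than three matched
  ring atoms, or a (near-)collinear matched set, is an error.
* Standard-frame base geometries are embedded in `modflex.basegeom` (v1,
  frozen).  Because every geometric test is a round trip or an oracle
  comparison, the analysis depends only on these being rigid, non-collinear
  templates.

## Synthetic conformational ensembles (`modflex.ensemble`)

The generator emulates one statistical fact about MD ensembles of B-DNA: the
instantaneous distributions of all twelve parameters are Gaussian per
position.  Each (position, parameter) series is sampled i.i.d. Gaussian with

    mean(pos) = baseline_mean + Σ_steps kernel(d) · Δmean(mod)
    sd(pos)   = baseline_sd   + Σ_steps kernel(d) · Δsd(mod)

where d is the signed bp distance from the centre of an annotated CpG step
and the kernel decays linearly from 1 at d = 0 to 0 at |d| = 3 — a
modification touches up to ~6 neighbouring base pairs.  Base-pair positions
map to integer d by rounding toward zero, so both central pairs of a step
share the d = 0 bin; step positions use plain integer offsets.  Negative
computed sds (possible only through effects) are floored at 1e-6 with a
warning; a zero baseline sd stays exactly zero so degenerate generators are
deterministic.

Defaults.  Baseline B-DNA: twist 36°, rise 3.38 Å, all other means 0; sds
4–5° for angles and 0.3–0.7 Å for translations — typical B-DNA simulation
values, exposed in `DEFAULT_BASELINE`.  Frame interval 4.8 ps.  Modification
effects are a *synthetic calibration*, not measured values: a single Δsd
scale per modification (5-fC +1.0°, 5-hmC +0.10°, 5-caC +0.07°, 5-mC −0.8°
at the CpG centre for angular parameters; translations get 0.06 Å per unit),
chosen to reproduce the qualitative flexibility ordering
fC > hmC ≳ caC ≈ C > mC with the two largest effects well resolved and the
middle conditions deliberately near-tied.  Consequences of that choice are
discussed under "ranking" below.

Frames are i.i.d. by default — real MD is autocorrelated; an AR(1) mode with
configurable correlation time exists specifically so block averaging has
something to correct for.  Parameters are independent across positions and
parameter types, which real DNA's elastic couplings (e.g. twist–roll) are
not; passing tests therefore validate the *pipeline*, not force-field
physics.

`realize_coordinates` turns a full 12-parameter ensemble into 3-D
coordinates (chain the base-pair frames from step parameters, split each
into two base frames via the intra-bp parameters, place standard base
atoms), and `extract_parameters` inverts it; the in-memory round trip is
exact to ~1e-9 (the biotite `AtomArrayStack` carries float32, ~1e-4 after
conversion, and the PDB format itself carries 1e-3 Å).

## Fluctuation statistics (`modflex.fluctuations`)

The "Gaussian fit" of a parameter series is computed as sample moments —
the maximum-likelihood Gaussian fit, bin-free and unbiased.  Standard errors
come from block averaging: the series is cut into fixed-length blocks
(default 20 ns) and the spread of per-block statistics over √M complete
blocks is the standard error; with fewer than two complete blocks the
operation errors rather than silently shrinking blocks.  For i.i.d. frames
the block SE converges to sd/√n; for correlated series it is the honest,
larger value.  Differences (modified − unmodified) carry quadrature-combined
SEs; Δ profiles pool the four CpG steps per distance bin; the per-parameter
scalar summary averages Δsd over a 3-bp window centred at the CpG step.
Analyses of the synthetic i.i.d. ensembles in the tests use 1–5 ns blocks
(the 24-ns span of a 5,000-frame ensemble holds only one 20-ns block; for
i.i.d. data the block length does not bias the SE).

Ranking orders conditions by the window-averaged Δsd; adjacent conditions
closer than `tie_threshold` (default 1.0) propagated SEs are rendered "≳".
With the default calibration the 5-hmC / 5-caC / unmodified trio is
near-tied by construction: their internal order legitimately permutes
between seeds, while 5-fC is always first and 5-mC always last.  No
multiplicity correction is applied — the profiles are descriptive summaries,
not hypothesis tests.

## Cyclization kinetics (`modflex.looping`)

Looping is a reversible two-state process; after a salt jump all molecules
start unlooped and the expected looped fraction follows
f(t) = f_eq(1 − e^(−t/τ)) with f_eq = k_loop/(k_loop+k_unloop) and apparent
looping time τ = 1/(k_loop+k_unloop).  The simulator propagates each
molecule with the exact two-state transition probabilities between sample
times (no discretization error); molecules are independent and
photobleaching-free by default (a dropout rate exists to stress fits).  The
default time grid is dense-early/log-spaced, mimicking a salt-jump
experiment.

The fit is unweighted least squares of the exponential, plateau floated by
default (a fixed-plateau mode exists).  Because the same molecules are
followed through time, fractions at successive time points are strongly
correlated and the naive least-squares covariance understates the τ
uncertainty severely (empirically ~40% CI coverage where 95% is nominal).
`fit_looping` therefore defaults to a parametric bootstrap: re-simulate
populations at the fitted rates, refit, and report the spread.  This
restores calibrated CIs (≥ 90% coverage of a generative threefold ratio in
the acceptance suite).

## Loop-closure propensity (`modflex.closure`)

A Monte-Carlo embodiment of the mechanism linking fluctuations to looping:
larger roll/tilt fluctuation amplitudes make a ~90-bp chain reach closed
configurations more often.  Step parameters are drawn independently Gaussian
per step, the frame chain is folded (vectorized pairwise composition of
rigid transforms; cross-checked against the scalar geometry), and a sample
counts as closed when end distance < r_c, terminal z-axes within θ_c, and
optionally accumulated twist within φ_c of a full number of turns.
Propensities carry exact Clopper–Pearson binomial CIs.

Results are comparative, never absolute J-factors.  At the package default
capture (r_c = 50 Å, θ_c = 60°) closure of a 90-step chain at realistic
stiffness (bend sd 4–6° per step ⇒ persistence length ≈ 90–200 bp) is so
rare that 10⁶ samples contain zero events; the monotonicity experiment in
the acceptance suite therefore uses a loose capture (r_c = 120 Å,
θ_c = 120°) that scores conformations *bent toward closure*, where the
4° → 6° contrast is resolvable with ~30× separated CIs at 10⁶ samples.
Importance sampling or half-chain convolution, which would make tight-capture
estimates feasible, is a documented extension point.

## Force spectroscopy (`modflex.smfret`)

FRET efficiency is ratiometric, E = IA/(IA + γ·ID), with detection
correction γ = 1 by default.  Histogram peaks are Gaussian fits to binned
counts (sum of Gaussians for multi-component fits), reporting the dominant
peak with its fit SE.

Stretching traces (FRET vs monotonically increasing force; only the stretch
segment is analysed) fall into three exhaustive behaviours: a sudden drop at
high force (~15 pN), a gradual decline before that final drop, or a major
drop already at low force (~5 pN).  The classifier is this package's
operationalization: find the largest windowed FRET decrease along the force
axis (2-pN window); below the low/high boundary (8 pN, midway between the
two landmarks) → low-force class; otherwise a pre-drop fitted slope below
−0.006 E/pN → gradual class, else high-force class.  Drops smaller than
0.15 E are unclassifiable (error, not a silent default).  Classification is
differential, hence invariant to constant FRET offsets.  The trace simulator
generates sigmoidal drops (width 0.8 pN) between plateaus at E 0.8/0.1 with
per-point Gaussian noise (default sd 0.05, 20-ms dwell), and the closed loop
simulate → classify recovers ≥ 95% of labels at default noise.  Class
percentages are rounded half-away-from-zero at one decimal (a zero-decimal
option matches coarser reporting styles).

## Problem sizes in the test and acceptance suites

Chosen once for desk-scale runtime: coordinate-level ensemble recovery uses
a 21-bp duplex with two modified CpG steps at 5,000 frames; array-level
profile/ranking experiments use the full 70-bp construct at 5,000 frames ×
100 replicates; looping-fit coverage uses 100 seeds × 500 molecules with
150-sample bootstraps; closure monotonicity uses 10⁶ samples per condition;
trace classification pools 600 traces over 20 seeds.

## Known limitations

* The generator shares none of MD's physics: no sequence dependence of the
  baseline, no elastic couplings between parameters, no autocorrelation by
  default, and modification effect sizes are calibrated, not measured.
* The closure model ignores intra-bp degrees of freedom, excluded volume,
  electrostatics and kinking; twist-register phasing is off by default.
* The trace classifier's thresholds (8 pN boundary, slope and drop cutoffs)
  are package choices exposed as arguments; real instrument noise is neither
  white nor force-independent.
* Modified bases reuse the cytosine ring geometry in coordinate realization;
  substituent atoms are placeholders and never enter frame fitting.
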