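# Methods

## Scope and reduction

The package models the F<sub>o</sub> motor (a-subunit + c₁₀-ring) as a rigid
rotor with a single angular degree of freedom coupled to the protonation
state of 12 sites: the ten ring carboxylates (labelled a–j, 36° apart) and
the two stator relays.  The full-resolution antecedent of this kind of model
is a Cα protein representation with an implicit membrane; here everything
the implemented observables live on — ring angle, protonation occupancy,
transfer events — is retained, and the protein degrees of freedom that only
renormalize time scales and local geometry are replaced by a small set of
effective parameters.  Consequences of the reduction:

* absolute durations and velocities are reported in MD steps/frames and are
  not comparable to wall-clock or to full-structure simulations; only
  ratios, orderings and coupling stoichiometries are meaningful;
* the stator is frozen: aR176 at 0° (the x-axis), the matrix relay aE162 at
  −36°, the IMS relay aE223 at +36°, with an a-facing window of ±72°
  (about four of the ten subunits face the a-subunit at any time).

## Geometry of proton transfer

Hop attempt weights use the distance between the donor and acceptor beads.
The carriers sit on a circle of radius `c_radius = 1.2 nm` and the stator
beads at `a_radius = 2.0 nm`, so the aligned site–relay distance is the
0.8 nm contact distance of the glutamate carrier (f(r) ≤ 1 everywhere).
These radii are *effective hop-geometry* radii, not the physical ring
radius: in the real complex the long tilted stator helices track the ring
over several subunits, so the donor–acceptor distance grows much more
slowly with angular offset than two concentric circles of crystallographic
radius would suggest.  The effective radii reproduce that flat profile
(site–relay distance at one subunit offset: 1.15 nm instead of 1.95 nm at
crystallographic radii).  This matters scientifically: with the flat
profile an aspartate carrier (A = 9 nm⁻¹) is transfer-competent over a
±15–20° window, which is what allows two *adjacent* mutated subunits to
interleave their uptake attempts (duration sharing) instead of paying them
strictly serially.  With crystallographic radii the model deadlocks: a
deprotonated mutant site pushed past the relay can neither advance nor be
serviced, and the separation trend of the double mutants inverts.

## Energy terms and units

Internal energy unit kT = 1 (T = 298 K; kT/e = 25.693 mV).

* **Coulomb**: Debye–Hückel screened pairwise term
  `B·q_i·q_j·e^{−d/λ_D}/d` with B = 2 kT·nm, λ_D = 1 nm, distance floor
  0.3 nm.  Charged beads: deprotonated carboxylates (−1), aR176 (+1).
* **Membrane penalty**: ε_mem = 8 kT per deprotonated c-site outside the
  a-facing window — large enough to forbid deprotonated membrane entry in
  practice while keeping the Monte Carlo ergodic.  The window edge is
  smoothed over 2° (logistic) so the torque exists everywhere.
* **Protonation**: each occupied site contributes
  `−ln10·kT·pKa_i + U(s_i)` where `U(s) = (1−s)·eΔψ` is the electrostatic
  energy of a proton at depth fraction s across the membrane (s = 0 at the
  IMS, 1 at the matrix).  The c-ring sits at s = 0.5; the relays at 0.25
  (aE223) and 0.75 (aE162), splitting each half-channel evenly — the true
  potential profile is unknown, and these fractions only repartition the
  fixed total driving energy `ln10·ΔpH + eΔψ = 8.14 kT` per proton.
* **Background** `V_non-es`: a smooth periodic stand-in for the
  non-electrostatic protein energy, identically zero by default.

### Site parameters

| carrier | A (1/nm) | r₀ (nm) | pKa |
|---|---|---|---|
| Glu (wild type) | 2.5 | 0.8 | 8.0 |
| Asp (E→D)       | 9.0 | 0.6 | 7.0 |

Sensitivity variants (Asp with A = 2.5, or pKa = 7.8) are plain overrides.

### Relay pKa values (a declared assumption)

No experimental pKa is available for the relays.  The defaults are
pKa(aE223) = 8.5 and pKa(aE162) = 7.0, chosen on two modelling grounds:

* the IMS relay must *hold* its proton tightly enough that the final
  handover to the ring carboxylate is mildly endergonic (≈ +0.5 kT for Glu
  after the Coulomb contribution).  This makes proton uptake
  acceptance-limited — several Metropolis trials fail before one succeeds —
  which is what gives stage 3 (the uptake wait) a nonzero duration in the
  wild type and amplifies it by ln10·ΔpKa ≈ 2.3 kT for the lower-pKa
  aspartate mutant.  With a low relay pKa, uptake is so strongly downhill
  that every first trial succeeds and the mutant signature collapses into
  stage 2;
* the matrix relay must never trap protons: at pKa 7.0 carrier→relay
  release is moderately uphill (≈ 0.43 acceptance, so proton release takes
  a few Metropolis trials and stage 1 has nonzero duration) and
  relay→matrix discharge is immediate, with negligible matrix-side
  back-flow.  Raising it speeds release but was found to erase the
  duration-sharing signal of adjacent double mutants, so 7.0 stands.

Both are configurable (`relay_pKa_ims`, `relay_pKa_matrix`).

### The arginine gate

`h(R176)` is hard (0/1): release only on the matrix side of aR176, uptake
only on the IMS side, and — new relative to a pure side-of-axis rule — a
dead zone of ±4.5° around the arginine itself where both are blocked,
representing the exclusion of transferable protons from the immediate
vicinity of the positive charge.  Without the dead zone a site wobbling
across 0° can release at −ε and re-protonate at +ε, translocating protons
without rotation; this leak inflates the coupling ratio by ~0.3–0.5
protons/turn at desk scale.  A logistic soft gate is available
(`gate_width_deg`).

### Orientation factor

g(θ) is a Gaussian in the angle between the carrier's outward radial
direction and the carrier→relay direction, with θ₀ = 0 and σ = 30°.  The
antecedent structure-derived parameters are unpublished; the peak at perfect
alignment is the natural choice and σ = 30° keeps off-aligned leak hops
strongly suppressed (g ≈ 0.07 at the gate) without killing the aligned
attempt rate.

## Monte-Carlo scheme

One sweep per round attempts every admissible channel once, in a fresh
random order.  `w` is the attempt probability and the Metropolis rule
`min(1, e^{−ΔV/kT})` the acceptance; `w` is evaluated identically for the
forward and reverse hop of a pair (distance and sidechain orientation do
not depend on who holds the proton), and reservoir exchanges (constant
attempt weight 1) carry the bulk chemical potential
`−ln10·kT·pH_r + U(s_r)`, so the chain satisfies detailed balance and the
*only* source of directed motion is the proton motive force.  The
equilibrium null test (pH 7/7, Δψ = 0 → no net rotation) checks exactly
this.  Protons are created/destroyed only at reservoir channels; direct
c↔c hops do not exist (no pathway is described for them).

## Dynamics and run profiles

The ring angle follows overdamped Euler–Maruyama:
`φ' = φ + (D/kT)·τ·dt + sqrt(2·D·dt)·ζ` with analytic torque
τ = −∂V/∂φ (implemented twice: a Python reference and a numba kernel,
cross-checked bit-for-bit in the tests).

* **Default profile**: 6000 rounds × 10⁵ MD steps (6×10⁸ steps, 60 000
  frames), D_rot·dt = 6×10⁻⁹ rad²/step.  A wild-type run completes of order
  one to a few net turns.
* **Desk profile** (`SimConfig.desk()`): 1000 rounds × 10⁴ MD steps with dt
  rescaled ×240, i.e. ~10° RMS angular diffusion per round
  (the default profile diffuses ~2° per round).  A wild-type
  run completes ~5–7 net turns in a few seconds on one core; ensembles of
  ten replicates of all seven strains run in minutes.  All shipped tests
  and the acceptance script use this profile; the trade-off of the larger
  per-round diffusion is a slightly noisier coupling ratio per run
  (counting statistics of ~10 turns/run), handled by averaging ensembles.

Initial state: φ = 0, every c-site protonated except those strictly between
the two relays, the IMS relay loaded, the matrix relay empty.  After a few
rounds the pipeline of deprotonated sites reaches its steady pattern;
observables use whole runs, and the initialization is configurable.

## Trajectory observables

* **Velocity** (last-return convention): cumulative angle at the last
  crossing of a *nonzero* whole multiple of 360°, divided by that time;
  crossings are interpolated linearly between frames.  Runs that never
  complete a turn yield an undefined estimate and are excluded (and
  counted) in ensemble summaries.  Returns to 0° do not count as
  crossings — otherwise any diffusive excursion at the start would define
  a zero velocity.
* **Proton flux**: gross IMS-entry and matrix-delivery counts from the
  event log; the net count subtracts matrix back-flow.  Coupling =
  net matrix protons (up to the last return) / net turns.
* **Stage durations**, per subunit and transport cycle: stage 1 = first
  release trial → release success; stage 2 = release success → first uptake
  trial; stage 3 = first uptake trial → uptake success; resting is the
  remainder.  "Arrival at the uptake angle" is operationalized as the first
  uptake trial — the first MC attempt admissible under the gate — keeping
  all boundaries event-defined.  Cycles truncated at the end of a run are
  dropped and counted; rare back-flow hops abort the cycle in progress.
* **Duration sharing**: |intersection of two subunits' stage-3 interval
  sets| / min(total stage-3 time of each) — symmetric, scale-free, 1 for
  identical waits, 0 for disjoint or absent ones.

## Biochemical pipeline

Implements the reduction arithmetic of the assays exactly as printed:
synthesis slope = least-squares slope over 50 s after the NADH addition
minus the slope over 90 s before; ATP calibration = mean of four step
heights (5-s window means around each addition, 20-s spacing) per ATP
amount, SD over the four; specific activity = slope / calibration /
protein mass with first-order independent error propagation
(`s = |a/b|·sqrt((s_a/a)² + (s_b/b)²)`); expression normalization by LDAO
ATPase activity rescaled to the mean of the e/ef/eg/eh references; ACMA
quench = 100·(F_postFCCP − F_3min)/F_postFCCP; DCCD-sensitive fraction =
1 − (+DCCD)/(−DCCD).  Inference from summaries: pooled-variance two-sample
Student's t (df = n₁+n₂−2, two-sided — sidedness is not stated in the
source tables, and two-sided reproduces them), and OLS of activity on
mutation separation.  The printed "±" values are treated as standard
deviations: recomputing the pairwise p-values from (mean, SD, n) matches
the printed table to a few percent, which SEs would not.

## Synthetic data

Generators are seeded and deterministic.  Activity replicates are Gaussian
around the published per-mutant mean/SD with the published n (lognormal
optional); luminescence traces are piecewise linear (baseline slope,
NADH-triggered synthesis slope, synthesis stopped by the uncoupler before
four calibration steps at 20-s intervals) plus white noise; ACMA traces
quench exponentially after ATP and recover after FCCP.  What the generators
do *not* emulate: instrument artifacts (photobleaching, mixing dead time),
non-Gaussian replicate scatter, and correlated baseline drift — so passing
recovery tests shows the reduction arithmetic is unbiased under the stated
noise model, not that it is robust to every real-world pathology.

## Numerical choices

* Angles degrees external / radians internal; energies kT; mV→kT via
  25.693 mV at 298 K.
* Metropolis on total-energy differences computed by full re-evaluation
  (12 sites, 13 beads — cheap and bug-resistant).
* Torque is analytic; the membrane edge uses a clipped logistic so energy
  and force stay consistent; the Coulomb distance floor makes the energy
  finite for any geometry (the floored region contributes zero force).
* Replicate seeds derive from the base seed via `numpy` SeedSequence
  spawning; identical config + seed ⇒ bit-identical trajectories.

## Known limitations

* One rigid rotational coordinate: no elastic coupling between subunits,
  no stator compliance, no F₁ or b-subunit load.  Absolute stage durations
  are therefore only qualitatively comparable to full-structure results.
* The time base (MD step ↔ seconds) is undefined; no attempt is made to
  match physical rotation rates.
* The leak/slip balance of the coupling ratio depends on the gate dead
  zone and the desk-profile dt; at the shipped defaults the wild-type
  ensemble mean is 10 ± 0.5 protons/turn, but individual runs scatter by
  ±1 proton/turn from turn-counting statistics.
* ATP chemistry, lipid composition and hydrolysis-driven (clockwise)
  operation are out of scope; reversing the driving via configuration
  (pH/Δψ signs) is possible but untested against data.
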