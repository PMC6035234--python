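# Methods

## Model

The system is a stoichiometric binary mixture of hard uniaxial ellipsoids:
N_A bifunctional A particles (semiaxes 2σ, 2σ, 10σ; mass 3.4 m; bonding
sites at the two tips of the major axis) and N_B = 0.4 N_A pentafunctional
B particles (σ, σ, 5σ; mass m; two sites near each tip plus one on the
equator), with f_A N_A = f_B N_B.  All sites lie exactly on the hard-core
surface.  A free A site and a free B site interact through a square well of
depth u₀ = 0.1 k_BT and range δ = 0.2σ guarded by a repulsive entry barrier
ΔU at r = δ; bonds form on crossing into r < δ and are made irreversible by
an infinite exit wall.  Each site holds at most one bond, and only A–B
bonds exist.  Autocatalysis: ΔU(p) = ΔU₀ − β⁻¹ln(1 + ξp), refreshed from
the instantaneous extent of reaction p = bonds/(f_A N_A) every 0.05 reduced
time units and floored at zero (a negative entry barrier is undefined in
the model; the floor only matters deep in strongly autocatalytic runs).

Units: lengths in σ, energies in k_BT, masses in m; the public time axis is
the reduced unit √(10 m σ²/k_BT).  Internally the code uses natural units
(σ = m = k_BT = 1), a factor √10 in time.

### B-site placement

Only "two near each tip and one on the equator" is specified by the model
family; the exact tip angles are not.  The two end sites are placed in the
x–z body plane at a parametric angle of ±30° from the major axis, the
equatorial site at (σ, 0, 0).  This keeps all five sites on the surface and
mutually farther apart than δ, enforcing single-bond-per-patch geometry and
mimicking the two primary-amine hydrogens plus one secondary site.  The
emergent chemical prefactor is very sensitive to this choice (below).

## Dynamics

The integrator is a hybrid event scheme rather than a strict event-driven
queue: torque-free rigid-body flight is exact (symmetric-top closed form;
positions linear), and constraint crossings are detected on a sub-step grid
of 0.05 natural time units (≈0.016 reduced) — fine enough that a site
moving at thermal speed cannot tunnel through the δ = 0.2σ shell.  At each
sub-step endpoint the engine looks for (i) hard-core contacts via the
Perram–Wertheim contact function, (ii) free-A–B site pairs entering the
shell, (iii) bonded pairs reaching the confinement wall; each crossing is
bisected in time to ~1e-14 and queued.  Events are processed in time order;
because free flight is per-body independent, resolving an event patches
only the two bodies involved (per-body local times) and re-scans only their
neighbor pairs, so the cost is O(detection + events).  Candidate pairs come
from per-block neighbor lists built with a spherocylinder prescreen (a
prolate ellipsoid with semiaxes (b, b, c) fits in the spherocylinder of
radius b and half-length c − b) with a 4σ skin.

Collisions are resolved by elastic impulses along the contact normal
(energy, linear and angular momentum conserved to machine precision in NVE
segments).  Barrier events in the default *energetic* mode compare the
radial relative kinetic energy of the two site material points against ΔU;
on crossing, the radial velocity is remapped for a net potential change
−u₀ and the bond registered.  Pairs failing the barrier are reflected
elastically — they rattle and retry, which is the microscopic mechanism of
the barrier effect.  A *stochastic* mode (crossing probability e^(−βΔU),
velocities untouched) is retained for cheap attempt-statistics checks; both
modes give geometric attempt counts with mean e^(βΔU).

Grazing crossings that enter and leave a shell within one sub-step are
knowingly missed (transit times are ~2–3 sub-steps for non-grazing
encounters); corrective branches handle the rare pair found on the wrong
side of a constraint at a sub-step start.  A bonded pair that slips through
its wall tangentially (near-zero radial speed) is reflected back at the
first sub-step start at which it separates; until then it may sit a few
tenths of σ outside, which softens the effective well edge slightly.  A
watchdog aborts on deep hard-core penetration (F < 0.5) or a gross
bond-wall excursion (> δ + 1σ).

Temperature is held at k_BT = 1 by rescaling linear and angular velocities
jointly by one factor every 0.1 reduced units (the rotational share can be
excluded via a switch).  Each replica starts from a random sequential
insertion packing (with a push-apart relaxation fallback) equilibrated
bond-free for 1 reduced unit.  Seeds: one master seed spawns independent
replica streams; all randomness flows through `numpy.random.Generator`.

### Box-size constraint

The minimum-image convention requires every pair-contact distance to fit in
half the box.  An A–A tip-tip contact spans 20σ, so at φ = 0.30 the
smallest valid mixture is (N_A, N_B) ≈ (110, 44); `random_packing` raises
on anything smaller.  Test and acceptance runs use (120, 48); the published
scale is (1200, 480).

## Emergent rate scale of this realization

The chemical prefactor k_c is an entropic quantity: it counts how often two
surface-bound sites align within δ.  In this implementation the measured
barrier-free rate is k_c ≈ 3×10⁻⁴ (reduced units), an order of magnitude
below the ≈4.6×10⁻³ of the original event-driven realization of the same
model family.  Diagnostics show the site-encounter rate at generous ranges
(r < 0.8σ) matches the ideal kinetic flux, with the suppression appearing
progressively as r → δ — i.e. it is genuine orientational shadowing of
surface-embedded sites, controlled by the unspecified details of site
exposure (tip angles, effective site protrusion) rather than an integration
artifact.  All *structural* results (cluster statistics, gel point,
barrier-independence) and all *functional* results (second-order kinetics,
geometric attempt statistics, the (1 + ξp) acceptance growth, the form of
the barrier corrections) are insensitive to this scale; absolute fitted
constants (k_c, k_d) are not, and comparisons against published absolute
values are expected to fail at the 10% level.  The acceptance suite reports
them anyway rather than recalibrating the geometry toward a target.

## Observables

Clusters are connected components of the particle–bond graph (union-find);
a cluster is called percolating when its unwrapped extent exceeds the box
edge in any dimension.  Cluster-size histograms are reported as raw counts
(normalization documented in file headers).  Diffusion at fixed p uses the
frozen-bond protocol: clone the state, replace the finite entry barrier by
an infinite wall for all unbonded pairs, evolve, and read
D = lim ⟨Δr²⟩/6t from unwrapped coordinates over the trailing half of the
horizon, requiring the local log-log slope to be within 0.25 of 1 (the
sub-diffusive transient must be over; shorter horizons raise a window
error).  S(q) is computed on the box-commensurate grid q = 2πn/L and
shell-averaged.

## Mean-field framework and fitting

`meanfield` implements the barrier-effect rate constants, their
autocatalytic forms (algebraically identical to substituting ΔU(p), which
the suite verifies to 1e-12), the D(p) power law D₀[(p₀ − p)/p₀]^γ, the
Kamal rate, and stiff-capable forward integration of
dp/dt = k_overall(1 − p)² (LSODA, rtol 1e-10), with the barrier floor and
the arrest point p₀ treated as absorbing conditions with warnings.

Estimators fit dp/dt by default (the quantity the framework predicts and
the literature plots), computed from p(t) with a local-polynomial
derivative (window 7, order 2; edge windows are dropped as biased); a
p(t)-space option integrates the model instead and fits the conversion
directly, which removes the small bias the derivative estimator carries at
low signal-to-noise and is what the calibration suite exercises.  Weights
are 1/SEM²; covariances are scaled by the reduced χ², keeping quoted
uncertainties calibrated when the error model is known only up to a
constant.  The staged protocol is: barrier-free
curve → (k_c, k_d); per-barrier curves → (n, k₀) with (k_c, k_d) frozen;
laws across barriers → (n₀, n∞, b) by weighted regression; autocatalytic
prediction with zero free parameters.  If the diffusive channel never
limits the rate (constant D, k_d D ≫ k_c) the (k_c, k_d) split is a flat
ridge; the fit detects the degeneracy, reports the single-constant chemical
fit and flags k_d unidentifiable.  The seven-parameter epoxy fit
(ΔU_c, ΔU_a, A, B, n∞, k_d, λ; n₀ fixed at 2) runs a bounded trust-region
solver from 8 perturbed starts (mildly multimodal surface); τ(p) is
interpolated monotone-cubically in ln τ.

## Synthetic isotherm generator

Published epoxy cure datasets are not redistributable, so recovery and
calibration tests use a generator that emulates their structure: four
temperatures (330–360 K by default), the full chemical model with
ΔU_c = 9.6×10⁻²⁰ J, ΔU_a = 9.1×10⁻²⁰ J, n∞ = 1.38, λ = 0.45 (values in
the range reported for DGEBA–amine systems), prefactors chosen so cure
takes tens of minutes, a Vogel-type relaxation time
τ(p, T) = τ∞ e^(ΔU_τ/k_BT) e^(cp/(p_v − p)) spanning decades, and additive
Gaussian noise on p (σ = 0.002 by default; a multiplicative option exists
because the noise model of real datasets is not published).  Noisy
conversions are monotonized by cumulative maximum, as cure data are
reported.  What passing recovery tests shows is that the estimators are
calibrated *for this noise model*; real data add baseline drift,
temperature lag and τ-measurement error that the generator does not
emulate.

## Problem sizes used by the test suite

Analytic and statistical checks run at 10⁴–10⁵ samples.  The
simulation-based acceptance tests share one battery: (120, 48) particles,
barrier heights βΔU ∈ {0, 0.5, 1} (one to two replicas each, 450–700
reduced time units, reaching p ≈ 0.1–0.2) plus one autocatalytic run
(ΔU₀ = 1, ξ = 30), with matched-p states kept at p ≈ 0.075 and frozen-bond
diffusion horizons of 20–60 reduced units.  These sizes are the package's
default desk scale; the published scale (1680 particles, 40 replicas,
p → 0.9, βΔU up to 4) is reachable with the same code but needs orders of
magnitude more CPU time.  Consequences: the barrier-law fits sample only
βΔU ≤ 1, the D(p) grid spans p ≤ 0.15 (so γ and p₀ of the arrest law are
essentially unconstrained), k_d is unidentifiable in the chemically
controlled window, and the (n, k₀) corrections — designed to describe the
full conversion range — saturate at their bounds when asked to represent
the strong chemical-regime enhancement this realization shows at small p.
The zero-free-parameter autocatalytic closure therefore misses by a few
percent at desk scale.  The corresponding acceptance comparisons are
reported honestly rather than silenced.

## Known limitations

- Emergent k_c (and everything downstream of its absolute scale) differs
  from the original realization; see above.
- Endpoint-based crossing detection misses sub-sub-step grazing encounters;
  this slightly depresses the encounter rate but leaves its statistics
  geometric.
- Bonds are strictly irreversible; reversible (finite exit barrier)
  variants are out of scope.
- The sink model is a minimal radiation-boundary sphere with a configurable
  growth law R(p) ∝ mass^(1/d_f), d_f = 2.5; its numbers are qualitative
  and internal to the package.
- The event tie-break is array order (lowest index first); distinct seeds
  give fully independent, reproducible trajectories.
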