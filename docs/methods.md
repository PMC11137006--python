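# Methods

`cartsim` simulates the response of a heterogeneous tumour-derived
organoid to chimeric antigen receptor (CAR) T-cell therapy with a
multiscale agent-based model: off-lattice centre-based cell mechanics, a
reaction–diffusion chemical microenvironment on a voxel mesh, a
stochastic four-phase cell cycle modulated by per-cell oncoprotein
expression and local oxygen, and self-propelled CAR T-cell agents that
chemotax toward an immunostimulatory factor, adhere to targets, attempt
kills, and exhaust stochastically.

## Model

### Microenvironment

Two substrates diffuse, decay, and exchange with cells on a Cartesian
mesh of cubic voxels (edge Δx = 20 µm):

| substrate | D (µm²/min) | λ (1/min) | role |
|---|---|---|---|
| oxygen (mmHg) | 1×10⁵ | 0.1 | gates proliferation and necrosis |
| immunostimulatory factor (a.u.) | 1×10³ | 0.016 | chemoattractant for CAR T-cells |

The solver is a locally-one-dimensional (LOD) implicit splitting: one
implicit decay substep 1/(1+λΔt) followed by three implicit tridiagonal
sweeps (Thomas algorithm) along x, y, z with zero-flux faces. The scheme
is unconditionally stable, conserves mass exactly at λ = 0 (the sweep
matrices are symmetric with unit row sums), and is globally first-order
in time; the test suite pins its closed forms (pure decay, single-voxel
secretion–decay fixed point) and compares it against a fine-step
explicit-Euler oracle.

Cells exchange with their containing voxel only (nearest-voxel lumping;
the 20 µm voxel is about one cell diameter). Per agent the update is the
rate-limited implicit rule c ← (c + Δt·ρ·S·c\*)/(1 + Δt·ρ·(S+U)) with ρ
the cell-to-voxel volume ratio; secretion pushes toward the saturation
value c\*, uptake is a proportional sink, and positivity holds for any
Δt. Cancer cells take up oxygen at 10/min and secrete the factor at
10/min toward saturation 1; CAR T-cells take up oxygen at 1/min; dead
cells exchange nothing. Within each diffusion substep the exchange is
applied in two half-steps around the diffusion sweep (Strang
arrangement): in organoid voxels the summed uptake rate is O(10/min), and
the symmetric splitting removes the leading O(Δt·U) splitting bias that a
plain sequential arrangement shows there.

Oxygen enters through a shell of Dirichlet nodes on the domain boundary,
clamped at 38 mmHg (physioxia) after every step — a configurable
stand-in, since the physical oxygen source of the modelled co-culture is
not part of the model. The factor's absolute scale is arbitrary; only
its gradient direction is consumed (by chemotaxis), which is why its
units are immaterial.

### Cell mechanics

Cells are overdamped spheres (default R_cell = 8.4 µm; the drag
coefficient is absorbed into the force constants, so "forces" are
velocities in µm/min). For centre separation d, with contact distance
R_a+R_b and maximum adhesion distance R_A = 1.25·(R_a+R_b):

- repulsion (elastic resistance to deformation), d < R_a+R_b:
  C_ccr·(1 − d/(R_a+R_b))², with C_ccr = 10.0ν for cancer cells and
  5.0ν for CAR T-cells (ν = 1 µm/min; pair values combine by geometric
  mean);
- adhesion, d < R_A: −C_cca·(1 − d/R_A)², C_cca = 0.4ν.

Positions advance by forward Euler at Δt_mech; the contact stiffness
bounds the stable step at ≈3 min, far above both the reference step
(0.1 min) and the desk step (0.5 min). Neighbour search uses a
linked-cell list on a 30 µm mechanics grid refreshed every t_v = 20
mechanics steps; a verified property is that a stale list still answers
exactly while no agent moves more than one mechanics voxel between
refreshes. Positions are clamped to the domain faces and clamp events
are counted.

### Heterogeneity and the cell cycle

Each cancer cell draws an oncoprotein expression o once at
initialisation from N(1.0, 0.25) truncated to [0, 2] by resampling (no
atoms at the bounds). o is inherited exactly at division; clonal
dominance of high-o cells is an emergent consequence of selection, not
of mutation. For reporting, o is binned into Type 1 [1.5, 2.0] … Type 4
[0.0, 0.5).

The cycle is G1→S→G2→M→division with phase means 20.4, 13.6, 3.0 and
1.6 h (38.6 h total). Phase exits are memoryless with per-step
probability Δt_cycle/T_phase (a deterministic fixed-duration mode exists
behind a flag). Only the G1 exit rate is scaled, by o·f(O2), where
f ramps linearly from 0 at 5 mmHg to 1 at 10 mmHg — so o = 0 or hypoxia
arrests the cycle, and the expected cycle time is T_G1/(o·f) + 18.2 h.
A cell held by an attached CAR T-cell freezes its cycle entirely.
Division halves the volume between two daughters offset ±R_cell/2 along
an isotropic random axis.

Death: below 5 mmHg a cell turns necrotic with rate 1/τ_nec
(τ_nec = 6 h); CAR T kills trigger apoptosis. Corpses stop cycling and
secreting, shrink exponentially toward zero volume (implicit relaxation;
apoptotic rate 0.01/min, necrotic 0.002/min), and leave the mechanics
population below 5 % of the reference volume while remaining in the
cumulative dead count. The oxygen thresholds and τ_nec are stand-in
defaults of this model family, exposed in the config.

### CAR T-cells

Unattached CAR T-cells migrate with speed v_mot = 2 µm/min along
(b·d + (1−b)·d_r)/‖·‖, where d is the unit vector up the local factor
gradient (previous d is kept where the gradient vanishes), d_r a random
unit direction redrawn with probability Δt_mech/t_per (t_per = 10 min),
and b = 0.5 the migration bias; b = 1 gives deterministic gradient
climbing, b = 0 a Brownian-like walk. The default d_r sampling follows
the spherical-angle recipe [sin φ cos θ, sin φ sin θ, cos φ] with
θ ~ U[0, π], φ ~ U[0, 2π], which is deliberately *not* area-uniform on
the sphere (it overweights the ±z poles); an area-uniform alternative is
available via `uniform_sphere_directions`, and both are covered by
tests. The migration velocity is added to the interaction velocity.

A live, recognisable cancer cell within R_LA = 18 µm can be bound with
probability r_a·Δt per step (r_a = 0.2/min; nearest candidate, ties to
the lowest index). In antigen-specific mode, recognisable means
o ≥ 0.5, and the per-step kill probability while attached is
r_K·Δt·o (r_K = 0.06/min) — immunogenicity proportional to antigen
burden. In multi-antigen (syn-Notch-like) mode every cancer cell is a
target with o-independent kill probability r_K·Δt. On a kill the target
enters apoptosis, the kill is attributed to that T-cell, and the T-cell
detaches; otherwise it stays attached until the attachment clock passes
t_a = 60 min and detaches without killing. While attached, the T-cell's
motility is off and the target's cycle is frozen; interaction forces
still apply. Several T-cells may bind one target; a T-cell holds one
adhesion. A T-cell whose target died detaches immediately and may
re-engage the same cell later (memoryless).

Each administered T-cell draws a lifespan once from N(10 d, 5 d)
truncated to positive values by resampling (truncated mean ≈ 10.28 d);
past its lifespan it is exhausted and removed from the simulation. In
long-term-persistence mode the lifespan is infinite. Doses are specified
as (day, ratio) pairs: the first dose administers round(ratio × live
cancer count) T-cells, later doses reuse that absolute count; agents are
placed uniformly at random in the domain outside the organoid's bounding
sphere inflated by one cell diameter, so they approach through the
exposed surface with no preferred direction.

### Time hierarchy and reproducibility

Per cycle step (Δt_cycle = 6 min): dosing checks, phase
transitions/divisions, necrosis, volume relaxation, corpse removal,
metrics. Per mechanics step within it (Δt_mech): forces, T-cell
decisions, position update. Per diffusion step within that (Δt_diff):
decay+LOD diffusion with exchange and Dirichlet re-clamping. Metrics are
recorded at the first cycle boundary at or past each multiple of
t_save = 1400 min (1400 is not a multiple of 6; the actual record time
is stored).

One master seed spawns independent streams (numpy `SeedSequence`) for
initial sampling, dose placement/lifespans, cycle decisions, and the
fused mechanics/immune kernel (numba's own deterministic stream). Runs
are single-threaded and bitwise reproducible for a fixed (config, seed).

## Performance scheme and desk scale

The inner loops (pair forces over the linked-cell list, T-cell
decisions, the diffusion subcycle) are numba kernels; readable
numpy/Python reference implementations of the same operations live in
`mechanics.py`, `microenvironment.py`, `immune.py` and are cross-checked
against the kernels in the test suite (exact for forces and diffusion,
statistical for the stochastic decisions).

The reference study conditions (3963 cells, 1000³ µm, 30 days, Δt_mech
= 0.1 min, Δt_diff = 0.01 min) are the config defaults but amount to a
multi-hour single-core computation. The `desk_config` preset used by
the test suite and the acceptance script scales the conditions down:

- **Δt_mech = 0.5 min.** The overdamped contact dynamics are stable to
  ≈3 min, and every per-step event probability stays ≪ 1
  (adhesion 0.1, kill ≤ 0.06, direction redraw 0.05).
- **Quasi-steady field subcycle.** Δt_diff stays at the accurate
  0.01 min, but the subcycle advances the fields for only a fraction
  (default 0.1) of each mechanics step. Both substrates are
  relaxation-type with no conserved accumulation — oxygen equilibrates
  in under a minute, the factor within ~1/λ ≈ 62 min — while their
  sources move on hour scales, so the shortened subcycle tracks the
  full hierarchy. A dedicated test verifies this against the reference
  hierarchy: oxygen agrees to better than 1 % of physioxia, and the
  factor's gradient directions (the only feature chemotaxis consumes)
  are aligned. Coarsening Δt_diff instead is *not* safe: the
  diffusion↔uptake splitting error is O(Δt·U) with summed uptake
  ~10/min in organoid voxels, which visibly biases the oxygen hole.
- **Problem sizes.** The headline desk studies are: untreated controls
  with 500-cell organoids in a 300³ µm domain for 5–6 days (untreated
  organoids grow near-exponentially with doubling ≈1.45 d, so longer
  desk controls become large); and a day-1 single-dose scan with
  500-cell organoids in a 500³ µm domain — the same organoid-to-domain
  proportion as the reference geometry — for 12 days at ratios
  0.25/1.0/2.0, with 2–3 replicates per condition. Replicate counts are
  chosen to keep the default suite fast; the underlying biology
  (the model's rate parameters, organoid construction, dosing protocol) is
  never rescaled.

## What the desk studies do and do not show

The untreated-control study demonstrates selection: high-o cells cycle
faster, so the population mean o drifts upward from 1.0
(≈ +0.013/day at desk scale) — the same mechanism that takes the
full-scale 30-day control from 1.00 to ≈1.3. The dose-scan reproduces
the dose-response structure of the therapy: dead-cells-per-CAR-T falls
monotonically with dose and drops below 1 at ratio 2.0 (the free-CAR-T
regime), survivors are oncoprotein-depleted, and Type 4 cells are never
killed in antigen-specific mode.

One full-scale feature compresses at desk scale: because a desk organoid
is only a few cell layers deep, any dose ≥ 0.25 can strip it to its
unrecognisable (Type 4) core before exhaustion, so the *pre-exhaustion
tumour minimum* saturates near that floor and separates between doses
far less than at full scale (a few cells on means, versus the clearly
separated troughs of full-scale runs). Resolving it also needs a save
cadence finer than the full-scale default: a desk trough is sharp, and
the 1400-min cadence can miss it entirely, which is why the dose-scan
study records every 6 h. The dead-per-CAR-T ordering, by contrast,
stays sharp at any cadence.

The synthetic initial conditions emulate a freshly seeded spherical
organoid: a jittered FCC packing at contact spacing trimmed to the exact
cell count, independent truncated-normal oncoprotein draws, and cycle
phases assigned with probability proportional to phase duration. Real
organoids have irregular shapes, extracellular matrix, and niches none
of which are modelled; passing tests show the *model's* mechanisms —
selection, shielding, dose saturation — not agreement with any
particular biological dataset.

## Numerical choices and degenerate inputs

- Exchange and decay are implicit, hence positivity-preserving for any
  step; concentrations are checked finite each cycle step and the run
  aborts naming substrate and voxel otherwise.
- Coincident cell centres (measure-zero; possible only through extreme
  initial conditions) get a repulsive kick along a seeded random axis
  and are counted.
- Ties in nearest-target selection break toward the lowest agent index.
- o = 2.0 is assigned to Type 1 (the printed bins are half-open;
  the upper endpoint is measure-zero).
- Division axes are area-uniform; the *printed* non-uniform angle
  recipe is reserved for the migration direction where it is part of
  the described behaviour.
- A dose scheduled at or after the end of the run is rejected at
  configuration time, as are clock hierarchies violating
  Δt_diff ≤ Δt_mech ≤ Δt_cycle.
- `growth_rate` is a least-squares fit of ln(count) over a trailing
  window (default 5 days) in units of 1/day; a zero count in the window
  makes it NaN with a warning.

## Known limitations

- No vasculature: the Dirichlet-node mechanism exists, but the only
  built-in source is the boundary shell.
- No T-cell proliferation, recruitment, cytokine signalling or
  immunosuppressive stroma; exhaustion is a clock, not a state.
- The solver's global first-order time accuracy means the oxygen
  profile carries an O(Δt_diff) bias even at the reference step; all
  comparisons in the tests are against the scheme's own closed forms,
  fine-step oracles, or the reference hierarchy.
- Single-threaded by design (determinism over speed); full-scale runs
  are possible but slow.
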