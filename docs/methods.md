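# Methods

`sparclet` is a desk-scale inverse-planning engine for spot-scanning
proton therapy that jointly optimizes physical dose and dose-averaged
linear energy transfer (LET_d), for both fixed-beam IMPT and
continuous-rotation arc (SPArc) delivery. This note records the models,
the assumptions behind them, the tunable parameters, and the design
choices that were genuinely open.

## The planning model

Per-voxel dose and LET_d are linear-algebraic functions of the spot
monitor units (MU) `w`:

    dose_i = sum_j D_ij w_j
    letd_i = sum_j L_ij D_ij w_j / sum_j D_ij w_j        (0 where dose_i = 0)

where `D_ij` (Gy/MU) and `L_ij` (keV/µm) are the unit-weight dose and
LET of spot `j` at voxel `i`, stored as matched sparse matrices. The
objective is a voxel-count-normalized quadratic with one-sided
(Heaviside, `H(x)=1` iff `x>0`) gating:

    Obj(w) = Σ_targets  p/N Σ_i (dose_i − D0)²
           + Σ_OARs     p/N Σ_i H(dose_i − D0)(dose_i − D0)²
           + Σ_t,LET    p/N Σ_i H(L0 − letd_i)(letd_i − L0)²
           + Σ_oar,LET  p/N Σ_i H(letd_i − L0)(letd_i − L0)²

Target-LET terms use an intentionally unattainable goal (8 keV/µm by
default) so they act as maximizers; OAR-LET terms cap at a low goal
(1.5 keV/µm). Dose-volume terms are supported through the standard
per-evaluation voxel-selection reformulation: among voxels above the
dose level, the allowed volume fraction keeps the hottest voxels and the
excess voxels closest to the level are penalized quadratically.

Gradients are exact. Dose terms are linear in `w`; LET terms use the
full quotient rule `∂letd_i/∂w_j = D_ij (L_ij − letd_i) / dose_i`, with
the Heaviside gates (and the dose-volume voxel selection) frozen at the
evaluation point. LET terms are evaluated only on voxels with strictly
positive dose, where the ratio is defined. The ratio makes the problem
nonconvex; we accept local minima and rely on deterministic
initialization for reproducibility. The solver is scipy's L-BFGS-B
(bound-constrained, relative tolerance 1e-6, 200 iterations per round by
default).

Every fresh optimization runs in two stages: the dose-only problem
first, then the full objective warm-started from the dose solution.
This mirrors how LET objectives are added to an already-acceptable dose
plan in practice, and it substantially stabilizes the nonconvex LET
stage — with cold starts, different beam configurations land in
different local minima and beam-count comparisons become noisy.

After the deliverable step, plans are renormalized: all weights are
scaled so the target D95 equals the prescription. Scaling is exact for
this purpose because dose is linear in `w` while every `letd_i` is
invariant under uniform scaling — so coverage is matched across compared
plans without touching LET distributions. Nonzero weights are floored
at the minimum MU afterwards (the floor only touches spots already at
the threshold).

## The analytic beam model

A closed-form pencil-beam engine stands in for Monte Carlo transport.
It is built from the proton range-energy power law `R = α E^p`
(α = 0.0022 cm/MeV^p, p = 1.77), giving the stopping power at residual
range r:

    S(r) = (1/(αp)) (r/α)^(1/p − 1)      [MeV/cm]

- **Depth-dose**: the ensemble average of `S` over Gaussian range
  straggling (σ_R = 0.012·R^0.935 cm, plus a 0.08 cm beam-line energy
  spread in quadrature), times an exponential nuclear fluence loss
  (µ = 0.01/cm). This yields a single-peaked Bragg curve with the peak
  at the predicted range, peak-to-entrance ratios of 4.8–5.5 across
  70–230 MeV, and an 80–20 distal falloff of ~2.6 mm at 160 MeV.
- **Depth-LET_d**: the dose-weighted mean stopping power of the same
  ensemble, `⟨S²⟩/⟨S⟩` (converted to keV/µm). Anchor points emerge
  without tuning: entrance LET_d at 160 MeV is 0.52 keV/µm (the water
  stopping power at 160 MeV), the curve is monotone non-decreasing
  through the distal falloff with its maximum past the dose peak, and
  the mid-plateau LET_d of an energy-stacked uniform SOBP (distal range
  16 cm, modulation 6 cm) is 2.2 keV/µm, inside the published 2–3
  keV/µm band. The `S(r)` singularity is clipped at r = 0.015 cm
  (≈3 MeV), where the power law physically breaks down.
- **Lateral model**: one Gaussian per spot with
  σ(w)² = σ_air² + (0.294·w^0.896 cm→mm)², σ_air = 3 mm. No nuclear
  halo: the halo affects absolute dose tails, not the optimization
  mechanics studied here.
- **MU calibration**: 1 MU is defined so a 160 MeV pristine peak
  integrates to 30 Gy·mm² over the lateral plane, which puts optimized
  spot weights in the clinical few-MU regime where the 0.02 MU
  deliverable threshold is active.

Secondary-particle transport is not modeled; its LET contribution is
folded into the effective depth curves. This is a fidelity limit: the
engine preserves the *structure* of the optimization problem (Bragg
geometry, LET-depth correlation, lateral coupling), not voxel-level
agreement with any Monte Carlo code.

WEPL through the phantom uses an exact Siddon-style voxel traversal for
point queries, and a beam-frame resampling grid (1 mm depth steps, 2 mm
lateral, trilinear interpolation) for bulk influence assembly. Beams
are parallel (no source divergence). Influence matrices drop entries
below 1e-4 of each column's maximum and truncate the lateral Gaussian at
3σ; both bounds perturb optimized doses well below 1%.

## Arc sequencing

Arc plans follow a coarse-to-fine schedule (20° → 10° → 5° → 2.5° by
default, binary halving). Control points sit at the centers of equal
angular cells, so cell-halving refinements never leave the arc span.
At each refinement a control point splits into children at ±quarter
spacing; its energy layers, ranked by total MU, are dealt alternately to
the children (disjoint and exhaustive), spots carried verbatim as warm
starts — total MU is conserved exactly, including the single-layer case,
which duplicates the layer into both children at half weight. Each
round re-assembles influence at the new angles and re-optimizes. At the
final sampling, layers per control point are reduced to a configured
maximum (default 1: arc deliverability) keeping the heaviest layers
(ties to the lower energy), re-optimized, then made deliverable: weights
below 0.02 MU are removed and the survivors re-optimized with the bound
active. The ordering — refine, re-optimize, then reduce at the end — is
one of several defensible interleavings; it was chosen because weight
information (which drives both the partition and the reduction) is most
reliable immediately after an optimization round.

The fixed-beam path shares everything except sequencing: one control
point per beam, full layer sets, no reduction. The LET-free comparator
zeroes the LET penalties over an identical spot set, so its plans differ
only in weights.

## Delivery time

A static beam takes `n_spots·t_spot + (n_layers−1)·t_layer + MU·rate`;
defaults are 2 ms spot switching, 0.6 s layer switching, zero per-MU
beam-on time (no dose-rate parameter is modeled) and zero inter-field
setup. Arc delivery models continuous rotation (1 rpm default) that
slows only when delivery is the bottleneck: each inter-control-point
interval contributes `max(travel time, delivery time)`, including travel
from the arc start to the first control point and from the last to the
arc stop. A trivially light full arc therefore takes exactly one
rotation, and arc time is bounded below by span/speed. Whether a real
gantry dwells or modulates speed is machine-specific; the max
composition covers both limits without claiming either.

## Synthetic phantoms and what they do (not) show

Three deterministic scenarios emulate common clinical situations on
water-cylinder bodies (air 0.001 RSP) with 4 mm isotropic grids:

- **prostate-like** (full arc, 78 Gy / 39 fx): central 14 mm-radius
  spherical target, two 10 mm OARs at ±45° posterior, 28 mm off-center.
- **liver-like** (partial arc 160°→40° IEC 61217, 75 Gy / 25 fx):
  16 mm CTV with a 10 mm GTV boost core, lateralized 40 mm to the
  patient's right, inside a normal-organ shell; the partial arc spans
  the directions that face the target through the least tissue.
- **brain-like** (full arc, 54 Gy / 30 fx): central 14 mm target
  flanked by four 6 mm OARs on the ±x/±y axes at 24 mm.

The packaged objective sets are the study conditions: uniform target
dose at prescription (p=100), OAR dose caps (p=20), a whole-body dose
cap at prescription (p=10, hot-spot control), target LET_d maximization
(goal 8 keV/µm, p=60), and for the brain scenario OAR LET_d caps
(1.5 keV/µm, p=30). The prostate OAR cap is 60 Gy: the OARs abut the
target, and a tighter cap turns into an *entrance* block whose severity
depends on how close the discrete beam set comes to the two OAR axes —
a lattice artifact that can invert beam-count comparisons for reasons
unrelated to LET physics. At 60 Gy the cap still enforces high-dose
sparing (OAR mean doses 33–44 Gy against a 78 Gy prescription).

These phantoms are piecewise-constant, convex, and symmetric; real
anatomy is none of those. Passing the directional experiments shows
that the optimizer exploits arc freedom the way the planning model
predicts — more beam directions let dose be delivered via high-LET
distal spots, monotonically in beam number, maximally for the arc, and
boost-volume LET escalates as the volume shrinks — not that any specific
clinical magnitude would be reproduced on patient CTs.

## Experiment problem sizes

The comparison experiments (beam-number sweep, boost-volume sweep, liver
and brain head-to-heads) run at deliberately modest sizes chosen once
for single-CPU desk-scale runs: 6 mm spot lattices, arcs refined to 5°
sampling with 150 optimizer iterations per round, fixed-beam plans at
200 iterations, and the boost-volume sweep on a single fixed 15° arc
geometry whose influence is computed once and re-optimized per boost
volume (the arc trajectory, spot set, and dose objectives are identical
across the sweep by construction). Single-plan workflows default to the
finer 2.5°/5 mm settings.

## Numerical choices and edge cases

- Zero-dose voxels have LET_d = 0 by convention; evaluation restricts
  LET reporting (LVHs, mean LET_d) to voxels receiving ≥1% of
  prescription so the convention cannot distort statistics.
- Histograms are cumulative volume-receiving-≥x curves; DVH bins 0.1 Gy,
  LVH bins 0.05 keV/µm.
- Mean LET_d over an ROI is the plain voxel average of `letd_i` over
  reported voxels (no second dose-weighting); with the reporting
  threshold this matches how LET summaries are commonly quoted, and the
  choice is flagged here because conventions differ.
- ROI erosion works on the metric distance transform with a
  quarter-voxel threshold correction (voxel-center distances
  overestimate surface distances by 0 to half a voxel depending on
  direction).
- Heaviside gates use strict inequality; equality contributes nothing.
- Degenerate inputs fail loudly: empty targets, rays missing the grid,
  energies off the machine span, non-deliverable plans, all-spot removal.

## Known limitations

- No robust (scenario-based) optimization; nominal geometry only.
- Constant RBE 1.1 is metadata; no variable-RBE biological model.
- No nuclear halo, no spot-size energy dependence beyond the σ model,
  no patient CT ingestion (synthetic phantoms only).
- The LET objective is nonconvex: solutions are stationary points, and
  comparisons across configurations reflect the deterministic two-stage
  protocol, not certified global optima.
- Multi-room beam switching and energy-switching direction asymmetry are
  not modeled.
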