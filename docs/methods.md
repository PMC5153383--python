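# Methods

This note documents the models implemented in `ablate90`, the numerical
choices behind them, what the synthetic phantoms do and do not emulate, and
the known limitations.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Absorbed-dose model

⁹⁰Y microspheres are a permanent implant with purely physical decay, so the
committed absorbed dose per voxel follows the local deposition method
(LDM): all beta energy from the activity trapped in a voxel is absorbed in
that voxel,

    D [Gy] = C · A [GBq] / m [kg],       C = 49.67 Gy·kg/GBq.

`C` follows from the mean beta energy per decay integrated over complete
decay (E_mean·T½/ln 2 per unit mass); it is configuration, along with the
tissue density used for voxel mass (1060 kg/m³) and the half-life
(64.05 h).  The delivered-dose fraction at time t is `1 − exp(−ln2·t/T½)`;
at two weeks this evaluates to ≈ 97.4%, a figure commonly quoted as 97.5% —
we do not force agreement beyond 0.2 percentage points.

Dose–volume metrics use the descending-sort rank convention: `Dxx` is the
dose of the voxel at rank ⌈xx%·N⌉, with no interpolation; this is
deterministic and exactly testable against a brute-force oracle.  `V100`
counts voxels **strictly above** 100 Gy.  `Davg`/`Dmax` are the mask mean
and maximum.  Cumulative DVHs use ≥-dose binning with a configurable bin
width; the DVH-read V100 and the metric V100 agree to within one bin.

Eligibility for adjuvant ablation is `D70 < 100 Gy` for resin microspheres
and `D70 < 150 Gy` for glass, with strict inequality at the limit.

## Thermal ablation model

A water-cooled, 17-gauge (0.7365 mm radius), 30-mm active-tip monopolar
electrode heats tissue by the quasi-static Joule source.  Because the
electrical conductivity σ is taken constant per tissue type, the potential
field shape is fixed: `∇·(σ∇V) = 0` is solved once per run with V = 1 on
the active tip and V = 0 on the domain boundary (standing in for the
dispersive ground pad), and the controller scales it to U(t) volts, giving
q = U²·σ|∇V|².  The insulated shaft carries σ = 0 and no source.

Temperature obeys the Pennes bioheat equation

    ρc ∂T/∂t = ∇·(k∇T) + w_b c_b (T_a − T) + q,

with T_a = 37 °C arterial blood, the domain boundary held at 37 °C, and
the active tip surface held at the coolant temperature (default 25 °C;
water-cooled electrodes are typically run near room temperature).  The
metabolic term is zero: the only volumetric source is the RF deposition.

Damage kinetics are first-order Arrhenius integrals computed in log space
(`exp(ln A − Ea/(R·T))`, since A = 2.984×10⁸⁰ 1/s and 1.98×10¹⁰⁶ 1/s
overflow naive evaluation):

* cell death: A = 2.984×10⁸⁰ 1/s, Ea = 5.06×10⁵ J/mol; the kill boundary
  is Ω ≥ 6.9, i.e. surviving fraction exp(−6.9) ≈ 0.001;
* vascular coagulation: A = 1.98×10¹⁰⁶ 1/s, Ea = 6.67×10⁵ J/mol; the
  occluded-flow fraction C_f = 1 − exp(−Ω_vasc) feeds back on perfusion as
  w_b = w_b,nc·(1 − C_f), computed as w_b,nc·exp(−Ω_vasc).

Both integrals use the trapezoid rule on the solver's time samples.  The
threshold comparison is inclusive (Ω ≥ 6.9).

Tissue presets (central literature values):

| preset          | σ (S/m) | ρ (kg/m³) | c (J/kg/°C) | k (W/m/°C) | w_b,nc (1/s) |
|-----------------|---------|-----------|-------------|------------|--------------|
| normal_liver    | 0.260   | 1060      | 3540        | 0.52       | 0.0180       |
| cirrhotic_liver | 0.260   | 1040      | 3540        | 0.52       | 0.0115       |
| hcc             | 0.504   | 1060      | 3540        | 0.52       | 0.0155       |

Blood specific heat is 3617 J/kg/°C.  HCC patients use the `hcc` preset;
metastatic/cholangiocarcinoma cases use `normal_liver`.  The cirrhotic
preset exists for the oven-effect comparison: lower baseline perfusion
removes less heat, so the kill volume is larger.

### Discretization

Uniform-spacing Cartesian finite differences with the 7-point stencil
replace a body-fitted tetrahedral mesh; graded spacing was considered and
dropped in favour of uniform refinement for convergence checks.  Each time
step (default 0.5 s) splits into

1. an **exact pointwise integration** of the perfusion/source ODE,
   written in the cancellation-free form
   `T ← T + (T_a − T)·φ + (q/ρc)·ψ` with `φ = 1 − e^{−r·dt}`, `ψ = φ/r`
   (→ dt as r → 0).  The naive "relax toward T_eq = T_a + q/hs" form loses
   all precision once coagulation drives w_b to denormal values — this is
   a genuine failure mode, not a theoretical one;
2. an **implicit (unconditionally stable) diffusion solve** by matrix-free
   conjugate gradients.  The system `(ρc/dt)I − ∇·k∇` has condition number
   ≈ 1 + 12·k·dt/(ρc·h²) (< 2 for the default step), so warm-started CG
   converges in a handful of iterations; a numba-compiled stencil is used
   when available, with a pure-numpy fallback.

**Sub-voxel electrode coupling.**  The electrode radius (0.74 mm) is below
the grid spacings used (1–3 mm).  A single pinned cell column behaves like
a line source of equivalent radius ≈ 0.2·h (the classic well-model
result), which makes the delivered power — and hence the lesion size —
grid-dependent.  We therefore scale the four lateral faces of every
active-tip cell, in both the electrical and the thermal operator, by

    β = (π/2) / ln(h / r_w),

which restores the analytic near-field resistance from the physical radius
r_w to the first node ring.  With this coupling the unit-drive conductance
agrees within ~3% between 1, 2, and 3 mm grids, and the 600 s kill volume
changes by ≤ 10% under spacing halving (2 mm → 1 mm), versus ~30% without
it.  The correction applies when h > r_w; on finer grids the radius is
rasterized geometrically.  Faces at the tip ends are left unscaled (end
effects are a residual discretization error).

**Controller.**  The applied voltage targets `temp_cap − 0.5 °C` (default
cap 105 °C) at the hottest tissue node.  Because that node lags the power
by a few local thermal time constants, the controller throttles on a short
linear extrapolation of the hottest-node temperature (default 8 steps
ahead) rather than its instantaneous value; below the set point the ramp
is bounded at +4%/step, above it the cut is super-linear
(ratio^1.5, floored at 0.5).  A run aborts if any tissue node exceeds the
cap by more than 0.5 °C.  Initial voltage 30 V, ceiling 200 V.

**Grid/geometry conventions.**  The simulation grid is centered on the
active-tip midpoint with odd shapes, so an axis-aligned electrode passes
through voxel centers and the discretization is symmetric under quarter
rotations about the electrode axis.  Kill masks are rebinned onto the dose
grid by fractional occupancy: a coarse voxel is killed when it is fully
covered by fine voxels and ≥ 50% of them are above threshold (both the
value threshold and the occupancy are exposed).  The rebinning is monotone
in the occupancy threshold.

**Problem sizes.**  The package's reference scenario runs the 600 s
ablation on a cropped 80×80×120 mm analysis domain — the electrode's
far field in a larger liver block is isothermal at 37 °C and is
represented by the Dirichlet boundary — at 2 mm spacing, with a 1 mm
uniform refinement for the convergence check; the cohort pipeline uses
2.5 mm / 2 s per-site simulations on the same domain.  These sizes are the
package's default analysis fidelity; all of them are configuration.

## Planning rules

Cold regions are connected components of `{tumor ∧ dose < level}` (default
level 100 Gy) whose minimum bounding-box edge is ≥ 20 mm — the operational
reading of "areas of decreased uptake > 2 cm"; the size rule is exposed.
Plan validation reports, per placement: fraction of the predicted zone
outside the tumor, fraction over the target isodose (a soft warning —
plans should ablate under-dosed tumor "when possible"), minimum
surface-to-surface Euclidean distance to the gastrointestinal mask (hard
failure below 10 mm), and any overlap with spare organs (hard failure).
Distances use a sampled Euclidean distance transform and match a
brute-force all-pairs oracle on small masks.

`auto_plan` is a deterministic greedy heuristic, *not* a reproduction of
manual clinical planning: it takes the largest unserved cold region,
places the electrode through its centroid along the first of six axis
directions whose longest admissible duration (600, 480, 360, 240, 120 s)
passes validation, marks the zone served, and repeats up to four times.
Plans can always be supplied as JSON instead.

## Pipeline conventions

Pre- and post-ablation metrics come from the *same* dose map; the post
mask is `tumor ∧ ¬(∪ zones)` with overlapping zones counted once, and
volume bookkeeping is exact in voxel counts.  When a dose level is given
(`restrict_ablation_below_gy`), zones are clipped to voxels under that
level before subtraction — the mask-level operationalization of planning
that confines ablation to under-dosed tumor; with it, the hottest voxel is
never removed and ΔDmax ≡ 0.  Percent volume change uses the
post-ablation denominator, `100·(pre − post)/post`, because that
convention reproduces every printed cell of the bundled reference cohort;
report rounding is half-up to one decimal (banker's rounding would flip
exact .x5 ties such as 14.35).  The reference cohort's published summary
volume statistics do not recompute from its own per-tumor rows under any
convention we tried; the package reports its own reproducible summaries
(sum of site counts, mean pre−post difference) instead.

## Statistics

All tests are two-sided at α = 0.05.  The KS normality screen applies the
Lilliefors correction by default because the null parameters are estimated
from the sample (the uncorrected test is anticonservative); the
uncorrected variant is available for comparison.  The paired t test is on
differences with n−1 df.  Spearman uses mid-rank tie correction with the
t-approximation p-value; an exact full-permutation p-value is available
for n ≤ 8 (full enumeration beyond that is impractical).  Simple linear
regression is tested against the constant model with
F = (n−2)·R²/(1−R²) on (1, n−2) df; a regression follow-up is gated on
|ρ| > 0.5 (strict).

## Synthetic phantoms

No patient ⁹⁰Y PET/CT volumes are publicly deposited, so the analysis is
exercised on seeded phantoms built to the study population's premises:

* lumpy ellipsoidal tumors; the target volume is hit exactly in voxel
  count by thresholding a noise-modulated radial field at the matching
  quantile;
* rim-dominant uptake (microspheres arrive through the arterial rim):
  an exponentiated Gaussian random field (σ = 0.5 log-units, ~8 mm
  correlation) times a rim weight `0.35 + 1.3(1 − depth)²`, with the
  deepest ~40% of the volume (the hypo-perfused core) further depressed by
  a factor partially coupled to `cold_uptake_fraction`;
* one or two embedded cold spheres (> 2 cm, default 25 mm, uptake ×0.15)
  placed fully inside the tumor — the visually distinct ablation targets;
* a surrounding liver ellipsoid receiving most of the infused activity
  (the tumor's share, not the infusion, sets the tumor mean dose), and
  simple organ-at-risk geometry (GI tube, gallbladder ellipsoid, capsule
  shell);
* the activity map is renormalized to the infused activity exactly.

`calibrate_to_eligibility` bisects the cold/core uptake factor until
D70 sits just below the device limit (target 95% of the limit, ≤ 50
iterations), returning already-eligible cases unchanged; the case's mean
dose must lie in the admissible 67.3–210.2 Gy pre-ablation range or the
case is rejected with diagnostics.  The core coupling exists precisely so
this lever is effective: the cold spheres alone occupy well under 30% of
the volume and cannot move the 30th dose percentile.

`make_cohort` draws volumes and activities uniformly from the published
treatment ranges (42.5–374.6 cm³, 0.62–4.13 GBq), flags ~70% of cases HCC,
~20% glass, and sets the liver background share so the tumor mean dose
lands at a drawn target; for resin cases the target is capped at 140 Gy
because D70 sits near 0.6–0.65 of the mean dose under the default texture
and the resin inclusion rule is unreachable above that.  Cold-region
layouts that cannot fit a small tumor fall back toward one region at the
2 cm floor.

**What passing phantom tests does and does not show.**  The phantoms share
the analysis-relevant *structure* of real data — eligibility, cold
sub-regions, rim-weighted heterogeneity, realistic volumes and mean doses
— but not PET physics (no noise, no point-spread blurring, no
reconstruction artifacts), no respiratory motion, and no real anatomy.
Results on phantoms therefore validate the computational chain and its
qualitative behaviour (every dose metric improves when ablation is
confined to under-dosed tumor; Dmax is invariant when the hottest voxel
is spared; the benefit shrinks with tumor volume), not patient-level
effect sizes.  The phantom cohort is also somewhat more heterogeneous
than the published one (D70/Davg ≈ 0.4–0.6 versus ≈ 0.64), so absolute
metric deltas on phantoms run larger than the published means.

## Numerical details and edge cases

* CG tolerance 1e-8 (relative); Dirichlet handled by folding boundary
  values into the right-hand side, keeping the free-node operator SPD.
* The potential solve clips V to [0, 1]; the discrete maximum principle
  holds up to solver tolerance.
* Zero-duration ablations return 37 °C everywhere and empty masks.
* Insulating (σ = 0) voxels are pinned to 0 V to keep the system
  non-singular; no current crosses their faces.
* Empty masks are rejected by metric computations ("no voxels in mask");
  zero-variance samples are rejected by the statistics.
* C_f < 1 holds mathematically but saturates to 1.0 in floating point
  when Ω_vasc exceeds ~745 (exp underflow); fields are validated as
  C_f ≤ 1 with strict inequality at moderate heating.
* NIfTI affines must be axis-aligned with positive scales; anything
  oblique is rejected with the offending axes named, never resampled.
* Mask binarization threshold for float volumes is > 0.5.

## Known limitations

* No tissue vaporization, impedance roll-off, or temperature-dependent
  electrical/thermal properties — kill volumes at full 600 s runs are
  accordingly on the generous side of in vivo experience.
* Single straight monopolar electrode only; no multi-tine or bipolar
  geometry.
* The ground pad is idealized as the whole domain boundary.
* The electrode face coupling assumes h > r_w and a mostly axis-aligned
  electrode; oblique electrodes fall back to scaling all tissue faces.
* `auto_plan` explores only six axis directions and a fixed duration
  ladder; it makes no claim to reproduce manually selected clinical
  plans or per-patient site counts.
* Voxel-exact tumor volume control means mask volumes inherit the voxel
  quantization of the grid (≤ one voxel, well inside the 5% construction
  tolerance used in tests).
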