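"""Water-cooled RF ablation on a Cartesian grid: quasi-static Joule heating,
Pennes bioheat time stepping, perfusion coagulation, and a temperature-cap
feedback controller.

Model
-----
The electric potential obeys the quasi-static equation ∇·(σ∇V) = 0 with
V = 1 (unit drive) on the active electrode tip and V = 0 on the domain
boundary, which stands in for the dispersive ground pad.  Because σ is
temperature-independent, the field *shape* is fixed: the potential is solved
once per run and scaled by the controller's applied voltage U(t), so the
volumetric heat source is q(t) = U(t)²·σ|∇V|².

Temperature follows the Pennes bioheat equation

    ρc ∂T/∂t = ∇·(k∇T) + w_b·c_b·(T_a − T) + q,

with the blood perfusion rate coagulating during heating: w_b =
w_b,nc·(1 − C_f), where C_f = 1 − exp(−Ω_vascular) accumulates with the
vascular Arrhenius kinetics.  Cell death accumulates in parallel with the
cell-death kinetics; the ablation (kill) boundary is Ω ≥ 6.9.

Numerics
--------
Uniform-spacing finite differences (7-point stencil); each time step splits
into an exact pointwise perfusion/source update followed by an implicit
(unconditionally stable) diffusion solve by matrix-free conjugate gradients.
The array boundary is pinned at 37 °C and the active tip surface at the
coolant temperature.  The controller rescales U every step toward the set
point ``temp_cap − controller_band`` at the hottest tissue node, with a
bounded per-step ramp; exceeding the cap by more than 0.5 °C aborts the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import arrhenius
from .grids import LabelMask, ScalarMap, VoxelGrid, rebin_fine_to_coarse

__all__ = [
    "TissueProperties",
    "TISSUE_PRESETS",
    "ElectrodeSpec",
    "SimulationConfig",
    "AblationResult",
    "solve_potential",
    "power_density",
    "step_bioheat",
    "simulate_ablation",
    "ablation_zone_on_grid",
    "electrode_masks",
    "make_simulation_grid",
    "reference_scenario",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class TissueProperties:
    """Electrothermal tissue constants (central literature values).

    sigma : electrical conductivity, S/m
    density : kg/m³
    specific_heat : J/kg/°C
    thermal_conductivity : W/m/°C
    w_b_nc : baseline (non-coagulated) blood perfusion, m³/m³/s
    blood_specific_heat : J/kg/°C
    arterial_temp : °C
    """

    sigma: float
    density: float
    specific_heat: float
    thermal_conductivity: float
    w_b_nc: float
    blood_specific_heat: float = 3617.0
    arterial_temp: float = 37.0

    def __post_init__(self) -> None:
        for name in ("sigma", "density", "specific_heat", "thermal_conductivity",
                     "w_b_nc", "blood_specific_heat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def rho_c(self) -> float:
        return self.density * self.specific_heat


TISSUE_PRESETS: dict[str, TissueProperties] = {
    "normal_liver": TissueProperties(
        sigma=0.260, density=1060.0, specific_heat=3540.0,
        thermal_conductivity=0.52, w_b_nc=0.0180),
    "cirrhotic_liver": TissueProperties(
        sigma=0.260, density=1040.0, specific_heat=3540.0,
        thermal_conductivity=0.52, w_b_nc=0.0115),
    "hcc": TissueProperties(
        sigma=0.504, density=1060.0, specific_heat=3540.0,
        thermal_conductivity=0.52, w_b_nc=0.0155),
}


@dataclass(frozen=True)
class ElectrodeSpec:
    """Straight water-cooled RF electrode (17-gauge, 30 mm active tip).

    ``tip_position`` is the distal end of the active tip in world mm;
    ``direction`` points from the shaft toward the tip and is normalized.
    """

    tip_position: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    active_length: float = 30.0
    radius: float = 0.7365  # 17 gauge -> 1.473 mm OD
    insulated_shaft: bool = True
    coolant_temp: float = 25.0

    def __post_init__(self) -> None:
        if self.active_length <= 0:
            raise ValueError("active_length must be > 0")
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ValueError("direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / n))
        object.__setattr__(self, "tip_position", tuple(float(x) for x in self.tip_position))


@dataclass(frozen=True)
class SimulationConfig:
    """Discretization, duration, and controller settings for one ablation."""

    domain_size: tuple[float, float, float] = (200.0, 200.0, 200.0)  # mm
    grid_spacing: float = 1.0  # mm, uniform
    time_step: float = 0.5  # s
    duration: float = 600.0  # s
    max_duration: float = 600.0  # s, per-site ceiling
    temp_cap: float = 105.0  # °C, hottest-tissue-node ceiling
    boundary_temp: float = 37.0  # °C
    controller_band: float = 0.5  # °C below the cap the controller targets
    initial_volts: float = 30.0
    max_volts: float = 200.0
    max_ramp: float = 1.04  # per-step multiplicative voltage bound
    snapshot_interval: float = 60.0  # s between stored kill-mask snapshots
    controller_lookahead: float = 8.0  # steps of linear temperature extrapolation
    cg_tol: float = 1e-8
    coagulation_feedback: bool = True  # Eq-style w_b = w_b_nc (1 - C_f) update

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.duration > self.max_duration:
            raise ValueError(
                f"duration {self.duration} s exceeds the per-site maximum "
                f"{self.max_duration} s")
        if self.temp_cap <= self.boundary_temp:
            raise ValueError("temp_cap must exceed boundary_temp")
        if self.time_step <= 0 or self.grid_spacing <= 0:
            raise ValueError("time_step and grid_spacing must be > 0")


@dataclass
class AblationResult:
    """Outputs of one simulated ablation on the fine simulation grid."""

    grid: VoxelGrid
    final_temperature: ScalarMap
    omega_map: ScalarMap  # cell-death Ω
    coagulation_map: ScalarMap  # C_f ∈ [0, 1)
    kill_mask_fine: LabelMask  # Ω >= 6.9
    applied_voltage_trace: np.ndarray  # (n_steps, 2): time s, volts
    kill_volume_trace: np.ndarray  # (n_steps, 2): time s, cm³
    peak_tissue_temp: float  # max over the whole run, °C
    kill_snapshots: list[tuple[float, np.ndarray]] = field(default_factory=list)

    @property
    def kill_volume_cm3(self) -> float:
        return self.kill_mask_fine.volume_cm3

    def kill_mask_at(self, duration_s: float) -> LabelMask:
        """Kill mask at the last stored snapshot time <= ``duration_s``.

        Ω is non-decreasing in time, so this is the exact kill mask of a
        shorter run with the same controller trajectory.
        """
        best = np.zeros(self.grid.shape, dtype=bool)
        for t, m in self.kill_snapshots:
            if t <= duration_s + 1e-9:
                best = m
        return LabelMask(self.grid, best)


# ---------------------------------------------------------------------------
# Discrete operators

try:  # numba fast path for the constant-coefficient 7-point stencil
    import numba

    @numba.njit(cache=False, fastmath=True)
    def _axpy_stencil_const(x, a, c, hx2, hy2, hz2, out):  # pragma: no cover
        nx, ny, nz = x.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    v = x[i, j, k]
                    lap = 0.0
                    if i > 0:
                        lap += (x[i - 1, j, k] - v) / hx2
                    if i < nx - 1:
                        lap += (x[i + 1, j, k] - v) / hx2
                    if j > 0:
                        lap += (x[i, j - 1, k] - v) / hy2
                    if j < ny - 1:
                        lap += (x[i, j + 1, k] - v) / hy2
                    if k > 0:
                        lap += (x[i, j, k - 1] - v) / hz2
                    if k < nz - 1:
                        lap += (x[i, j, k + 1] - v) / hz2
                    out[i, j, k] = a * v - c * lap

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _face_coef(c: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean face coefficient along ``axis`` (zero-safe)."""
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    a = c[tuple(sl_lo)]
    b = c[tuple(sl_hi)]
    s = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    return f


def _divgrad(x: np.ndarray, coef, spacing_m: tuple[float, float, float]) -> np.ndarray:
    """∇·(coef ∇x) with zero-flux treatment at the array edge.

    ``coef`` is a scalar or a per-voxel array (faces use harmonic means).
    Edge behaviour is irrelevant in practice because the outermost layer is
    always a Dirichlet boundary.
    """
    out = np.zeros_like(x)
    is_scalar = np.isscalar(coef)
    for ax in range(3):
        h2 = spacing_m[ax] ** 2
        d = np.diff(x, axis=ax)
        cf = coef if is_scalar else _face_coef(coef, ax)
        flux = cf * d / h2
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        out[tuple(sl_lo)] += flux
        out[tuple(sl_hi)] -= flux
    return out


def _apply_face_extras(x, out, extras, coef_scalar, spacing_m):
    """Add the flux of extra face conductance to an operator output.

    ``extras`` is a list of (axis, lo_cells (N,3), extra_scale (N,)); each
    face between lo and lo+1 along ``axis`` carries the additional
    coefficient extra_scale·coef_scalar.  Used for the sub-voxel electrode
    coupling; out is modified in place for the operator a·x − ∇·(c∇x).
    """
    for ax, lo, scale in extras:
        hi = lo.copy()
        hi[:, ax] += 1
        li = (lo[:, 0], lo[:, 1], lo[:, 2])
        hi_i = (hi[:, 0], hi[:, 1], hi[:, 2])
        f = (scale * coef_scalar / spacing_m[ax] ** 2) * (x[hi_i] - x[li])
        np.subtract.at(out, li, f)
        np.add.at(out, hi_i, f)
    return out


def _make_operator(a: float, coef, spacing_m, face_extras=None, extra_coef=None):
    """Return apply(x) = a·x − ∇·(coef ∇x) (+ extra electrode-face fluxes),
    using numba for the constant-coefficient bulk stencil when possible."""
    if extra_coef is None and np.isscalar(coef):
        extra_coef = float(coef)
    if _HAVE_NUMBA and np.isscalar(coef):
        hx2, hy2, hz2 = (s * s for s in spacing_m)
        c = float(coef)

        def apply(x, _buf=[None]):
            if _buf[0] is None or _buf[0].shape != x.shape:
                _buf[0] = np.empty_like(x)
            _axpy_stencil_const(x, a, c, hx2, hy2, hz2, _buf[0])
            out = _buf[0].copy()
            if face_extras:
                _apply_face_extras(x, out, face_extras, extra_coef, spacing_m)
            return out

        return apply

    def apply_np(x):
        out = a * x - _divgrad(x, coef, spacing_m)
        if face_extras:
            _apply_face_extras(x, out, face_extras, extra_coef, spacing_m)
        return out

    return apply_np


def _cg_dirichlet(apply_A, rhs, fixed_mask, fixed_values, x0=None,
                  tol=1e-8, maxiter=20000):
    """Solve A x = rhs with x = fixed_values on fixed_mask by CG on the free
    nodes (A must be SPD on the free set)."""
    free = ~fixed_mask
    g = np.where(fixed_mask, fixed_values, 0.0)
    b = (rhs - apply_A(g)) * free
    x = np.where(free, x0, 0.0) if x0 is not None else np.zeros_like(b)
    r = (b - apply_A(x) * free) * free
    bnorm = float(np.sqrt(np.vdot(b, b).real))
    if bnorm == 0.0:
        return g
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    for _ in range(maxiter):
        if math.sqrt(rs) <= tol * bnorm:
            break
        Ap = apply_A(p) * free
        alpha = rs / float(np.vdot(p, Ap).real)
        x += alpha * p
        r -= alpha * Ap
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
    else:
        raise RuntimeError(
            f"conjugate gradients failed to converge (residual "
            f"{math.sqrt(rs) / bnorm:.2e} after {maxiter} iterations)")
    return x + g


# ---------------------------------------------------------------------------
# Geometry helpers


def make_simulation_grid(electrode: ElectrodeSpec, config: SimulationConfig) -> VoxelGrid:
    """Uniform grid centered on the electrode's active-tip midpoint.

    Shapes are forced odd so that an axis-aligned electrode passes through
    voxel centers, keeping the discretization rotationally symmetric.
    """
    h = config.grid_spacing
    tip = np.asarray(electrode.tip_position)
    mid = tip - 0.5 * electrode.active_length * np.asarray(electrode.direction)
    shape = tuple(2 * max(1, int(round(d / (2 * h)))) + 1 for d in config.domain_size)
    origin = tuple(mid[i] - (shape[i] - 1) / 2 * h for i in range(3))
    return VoxelGrid(shape, (h, h, h), origin)


def _segment_distance(grid: VoxelGrid, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance (mm) from every voxel center to the segment p0–p1."""
    X, Y, Z = grid.center_coords()
    d = p1 - p0
    L2 = float(d @ d)
    px, py, pz = X - p0[0], Y - p0[1], Z - p0[2]
    if L2 == 0:
        return np.sqrt(px ** 2 + py ** 2 + pz ** 2)
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
    return np.sqrt((px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2)


def _segment_cells(grid: VoxelGrid, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Boolean mask of the cells traversed by the segment p0–p1 (dense
    sampling at h/5 steps, clipped to the grid)."""
    h = min(grid.spacing)
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, int(math.ceil(length / (0.2 * h))) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = p0[None, :] + t * (p1 - p0)[None, :]
    idx = np.round((pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    mask = np.zeros(grid.shape, dtype=bool)
    if ok.any():
        sel = idx[ok]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


def electrode_masks(grid: VoxelGrid, electrode: ElectrodeSpec) -> tuple[np.ndarray, np.ndarray]:
    """(active_tip, insulated_shaft) voxel masks.

    The active tip is the column of cells traversed by the tip segment plus
    any cell centers inside the physical radius; the sub-voxel radius itself
    enters through the well-model face coupling (see
    :func:`electrode_face_boosts`).
    """
    h = max(grid.spacing)
    tip = np.asarray(electrode.tip_position)
    direction = np.asarray(electrode.direction)
    base = tip - electrode.active_length * direction

    lo, hi = grid.bounds()
    if np.any(tip <= lo + h) or np.any(tip >= hi - h) or np.any(base <= lo + h) or np.any(base >= hi - h):
        raise ValueError(
            f"electrode active tip (tip {tuple(tip)}, base {tuple(np.round(base, 3))} mm) "
            f"is not inside the simulation domain [{lo}, {hi}] mm")

    active = _segment_cells(grid, base, tip) | (
        _segment_distance(grid, base, tip) <= electrode.radius)
    if not active.any():
        raise ValueError("electrode rasterization produced no active-tip voxels")

    shaft = np.zeros(grid.shape, dtype=bool)
    if electrode.insulated_shaft:
        far = base - direction * float(np.linalg.norm(hi - lo))
        shaft = (_segment_cells(grid, far, base)
                 | (_segment_distance(grid, far, base) <= electrode.radius)) & ~active
    return active, shaft


def electrode_face_boosts(
    grid: VoxelGrid, electrode: ElectrodeSpec, active: np.ndarray
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Sub-voxel electrode coupling: extra conductance on the lateral faces
    between active-tip cells and tissue.

    A single pinned cell column behaves like a line source of equivalent
    radius ≈ 0.2·h (the classic well-model result), which under-represents
    an electrode of physical radius r_w when r_w > 0.2·h and makes delivered
    power grid-dependent.  Scaling the four lateral faces of each pinned
    cell by β = (π/2)/ln(h/r_w) restores the analytic near-field resistance
    from r_w to the first ring, so the effective radius becomes r_w on every
    grid with h > r_w.  Returns face extras as (axis, lo_cells, extra_scale)
    in units of the bulk coefficient; empty when the radius is resolved.
    """
    h = max(grid.spacing)
    if h <= 1.05 * electrode.radius:
        return []
    beta = (math.pi / 2.0) / math.log(h / electrode.radius)
    extra = beta - 1.0
    if extra <= 0:
        return []
    direction = np.abs(np.asarray(electrode.direction))
    lateral_axes = [ax for ax in range(3) if direction[ax] < 0.9]
    if len(lateral_axes) < 2:  # oblique: treat all axes as lateral
        lateral_axes = [0, 1, 2]
    out = []
    cells = np.argwhere(active)
    for ax in lateral_axes:
        for sign in (-1, +1):
            nb = cells.copy()
            nb[:, ax] += sign
            inb = (nb[:, ax] >= 0) & (nb[:, ax] < grid.shape[ax])
            sel = cells[inb]
            nbs = nb[inb]
            tissue = ~active[nbs[:, 0], nbs[:, 1], nbs[:, 2]]
            sel = sel[tissue]
            if len(sel) == 0:
                continue
            lo = np.minimum(sel, sel + np.eye(3, dtype=int)[ax][None, :] * sign)
            out.append((ax, lo, np.full(len(lo), extra)))
    return out


def _boundary_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


# ---------------------------------------------------------------------------
# Field solvers


def solve_potential(
    grid: VoxelGrid,
    sigma_field: ScalarMap | float,
    electrode: ElectrodeSpec | np.ndarray,
    ground_mask: np.ndarray | None = None,
    tol: float = 1e-8,
    face_extras: list | None = None,
    bulk_sigma: float | None = None,
) -> ScalarMap:
    """Unit-drive quasi-static potential: ∇·(σ∇V) = 0, V = 1 on the active
    tip, V = 0 on the ground (domain boundary unless ``ground_mask`` given).

    ``electrode`` may be an :class:`ElectrodeSpec` or a precomputed boolean
    source mask.  Returns V ∈ [0, 1] (dimensionless unit drive).
    """
    if isinstance(electrode, ElectrodeSpec):
        source, shaft = electrode_masks(grid, electrode)
        sigma = sigma_field.values.copy() if isinstance(sigma_field, ScalarMap) \
            else np.full(grid.shape, float(sigma_field))
        sigma[shaft] = 0.0
    else:
        source = np.asarray(electrode, dtype=bool)
        sigma = sigma_field.values if isinstance(sigma_field, ScalarMap) \
            else np.full(grid.shape, float(sigma_field))
    if not source.any():
        raise ValueError("empty electrode source mask")
    ground = _boundary_mask(grid.shape) if ground_mask is None else np.asarray(ground_mask, bool)
    if (source & ground).any():
        raise ValueError("electrode source overlaps the ground region")
    # Zero-conductivity voxels (insulated shaft) carry no current and would
    # make the system singular; pin them at 0 V — no flux crosses their faces.
    insulating = (np.asarray(sigma) == 0) & ~source & ~ground

    spacing_m = tuple(s * 1e-3 for s in grid.spacing)
    sigma_coef = float(sigma.flat[0]) if np.ptp(sigma) == 0 else sigma
    if bulk_sigma is None:
        bulk_sigma = float(np.max(sigma))
    apply_A = _make_operator(0.0, sigma_coef, spacing_m,
                             face_extras=face_extras, extra_coef=bulk_sigma)

    def neg_A(x):
        return -apply_A(x)

    fixed = source | ground | insulating
    values = np.where(source, 1.0, 0.0)
    V = _cg_dirichlet(neg_A, np.zeros(grid.shape), fixed, values, tol=tol)
    # Discrete maximum principle holds up to solver tolerance.
    V = np.clip(V, 0.0, 1.0)
    return ScalarMap(grid, V, units="V (unit drive)")


def power_density(
    potential: ScalarMap,
    sigma_field: ScalarMap | float | np.ndarray,
    applied_volts: float,
    face_extras: list | None = None,
    bulk_sigma: float | None = None,
) -> ScalarMap:
    """Joule heat source q = σ|∇(U·V)|² in W/m³, face-based so that the total
    dissipated power equals the discrete dissipation exactly (including any
    electrode well-coupling faces)."""
    grid = potential.grid
    sigma = sigma_field.values if isinstance(sigma_field, ScalarMap) else sigma_field
    spacing_m = tuple(s * 1e-3 for s in grid.spacing)
    q = np.zeros(grid.shape)
    for ax in range(3):
        d = np.diff(potential.values, axis=ax) / spacing_m[ax]
        cf = sigma if np.isscalar(sigma) else _face_coef(np.asarray(sigma), ax)
        p = cf * d * d  # W/m³ attributed to the face
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        q[tuple(sl_lo)] += 0.5 * p
        q[tuple(sl_hi)] += 0.5 * p
    if face_extras:
        if bulk_sigma is None:
            bulk_sigma = float(np.max(sigma)) if not np.isscalar(sigma) else float(sigma)
        V = potential.values
        for ax, lo, scale in face_extras:
            hi = lo.copy()
            hi[:, ax] += 1
            li = (lo[:, 0], lo[:, 1], lo[:, 2])
            hi_i = (hi[:, 0], hi[:, 1], hi[:, 2])
            dV = (V[hi_i] - V[li]) / spacing_m[ax]
            p = scale * bulk_sigma * dV * dV
            np.add.at(q, li, 0.5 * p)
            np.add.at(q, hi_i, 0.5 * p)
    return ScalarMap(grid, q * applied_volts ** 2, units="W/m^3")


def step_bioheat(
    temperature: ScalarMap,
    q: ScalarMap | np.ndarray | float,
    props: TissueProperties,
    w_b: np.ndarray | float,
    dt: float,
    fixed_mask: np.ndarray | None = None,
    fixed_values: np.ndarray | float | None = None,
    conduction: bool = True,
    tol: float = 1e-8,
    face_extras: list | None = None,
) -> ScalarMap:
    """One Pennes bioheat step: exact pointwise perfusion/source update, then
    an implicit (unconditionally stable) diffusion solve.

    ``fixed_mask``/``fixed_values`` pin Dirichlet nodes (domain boundary at
    37 °C, active tip at the coolant temperature).  Pass ``conduction=False``
    (or a zero thermal conductivity) to disable diffusion.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    T = temperature.values
    qv = q.values if isinstance(q, ScalarMap) else np.asarray(q, dtype=float)
    rho_c = props.rho_c
    hs = np.asarray(w_b, dtype=float) * props.blood_specific_heat  # W/m³/K
    # Pointwise ODE ρc dT/dt = hs (T_a − T) + q, integrated exactly in the
    # cancellation-free form T + (T_a − T)·φ + (q/ρc)·ψ with φ = 1 − e^{−r·dt}
    # and ψ = φ/r (→ dt as r → 0); the naive T_eq form loses all precision
    # when the perfusion has coagulated to a denormal rate.
    r = hs / rho_c
    phi = -np.expm1(-r * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(r > 0, phi / np.where(r > 0, r, 1.0), dt)
    T1 = T + (props.arterial_temp - T) * phi + (qv / rho_c) * psi
    if not np.all(np.isfinite(T1)):
        raise RuntimeError("bioheat step produced non-finite temperatures")

    k = props.thermal_conductivity if conduction else 0.0
    if k > 0:
        spacing_m = tuple(s * 1e-3 for s in temperature.grid.spacing)
        a = rho_c / dt
        apply_A = _make_operator(a, k, spacing_m, face_extras=face_extras,
                                 extra_coef=k)
        if fixed_mask is None:
            fixed_mask = np.zeros(T.shape, dtype=bool)
            fixed_values = 0.0
        fv = np.broadcast_to(np.asarray(fixed_values, dtype=float), T.shape)
        T1 = _cg_dirichlet(apply_A, a * T1, fixed_mask, fv, x0=T1, tol=tol)
    elif fixed_mask is not None:
        fv = np.broadcast_to(np.asarray(fixed_values, dtype=float), T.shape)
        T1 = np.where(fixed_mask, fv, T1)
    if not np.all(np.isfinite(T1)):
        raise RuntimeError("bioheat step produced non-finite temperatures")
    return ScalarMap(temperature.grid, T1, units="degC")


# ---------------------------------------------------------------------------
# Full ablation simulation


def _controller_scale(t_max: float, t_prev: float, config: SimulationConfig) -> float:
    """Predictive voltage rescaling toward the set point.

    The hottest node lags the applied power by a few thermal time constants,
    so the controller throttles on a short linear extrapolation of its
    temperature rather than on the instantaneous value; above the set point
    the cut is super-linear so overshoot is pulled back within a few steps.
    """
    target = config.temp_cap - config.controller_band
    t_ref = config.boundary_temp
    rise = max(t_max - t_prev, 0.0)
    t_pred = t_max + config.controller_lookahead * rise
    ratio = max(target - t_ref, 0.0) / max(t_pred - t_ref, 1e-6)
    if ratio >= 1.0:
        scale = min(math.sqrt(ratio), config.max_ramp)
    else:
        scale = max(ratio ** 1.5, 0.5)
    return float(scale)


def simulate_ablation(
    electrode: ElectrodeSpec,
    tissue: TissueProperties | str = "hcc",
    config: SimulationConfig = SimulationConfig(),
) -> AblationResult:
    """Simulate one water-cooled RF ablation and return temperature, damage,
    coagulation, and kill-mask fields on the fine grid."""
    props = TISSUE_PRESETS[tissue] if isinstance(tissue, str) else tissue
    grid = make_simulation_grid(electrode, config)
    active, shaft = electrode_masks(grid, electrode)
    boundary = _boundary_mask(grid.shape)

    sigma = np.full(grid.shape, props.sigma)
    sigma[shaft] = 0.0

    T0 = np.full(grid.shape, config.boundary_temp)
    n_steps = int(round(config.duration / config.time_step))
    if n_steps == 0:
        zeros = np.zeros(grid.shape)
        return AblationResult(
            grid=grid,
            final_temperature=ScalarMap(grid, T0, "degC"),
            omega_map=ScalarMap(grid, zeros, "Omega"),
            coagulation_map=ScalarMap(grid, zeros.copy(), "C_f"),
            kill_mask_fine=LabelMask(grid, zeros > 1),
            applied_voltage_trace=np.zeros((0, 2)),
            kill_volume_trace=np.zeros((0, 2)),
            peak_tissue_temp=config.boundary_temp,
        )

    extras = electrode_face_boosts(grid, electrode, active)
    V_unit = solve_potential(grid, ScalarMap(grid, sigma, "S/m"), active,
                             ground_mask=boundary, tol=config.cg_tol,
                             face_extras=extras, bulk_sigma=props.sigma)
    q_unit = power_density(V_unit, sigma, 1.0, face_extras=extras,
                           bulk_sigma=props.sigma).values

    fixed = boundary | active
    fixed_values = np.where(active, electrode.coolant_temp, config.boundary_temp)
    tissue_nodes = ~fixed

    T = ScalarMap(grid, T0, "degC")
    omega_cell = np.zeros(grid.shape)
    omega_vasc = np.zeros(grid.shape)
    rate_cell = arrhenius.damage_rate(arrhenius.celsius_to_kelvin(T.values), arrhenius.CELL_DEATH)
    rate_vasc = arrhenius.damage_rate(arrhenius.celsius_to_kelvin(T.values), arrhenius.VASCULAR)
    w_b = np.full(grid.shape, props.w_b_nc)

    U = config.initial_volts
    dt = config.time_step
    volt_trace = np.zeros((n_steps, 2))
    kill_trace = np.zeros((n_steps, 2))
    snapshots: list[tuple[float, np.ndarray]] = []
    next_snap = config.snapshot_interval
    peak = config.boundary_temp
    t_prev = config.boundary_temp
    abort_temp = config.temp_cap + 0.5

    for step in range(n_steps):
        t_now = (step + 1) * dt
        q = U * U * q_unit
        T = step_bioheat(T, q, props, w_b, dt, fixed_mask=fixed,
                         fixed_values=fixed_values, tol=config.cg_tol,
                         face_extras=extras)
        t_kelvin = arrhenius.celsius_to_kelvin(T.values)
        new_rate_cell = arrhenius.damage_rate(t_kelvin, arrhenius.CELL_DEATH)
        new_rate_vasc = arrhenius.damage_rate(t_kelvin, arrhenius.VASCULAR)
        omega_cell += 0.5 * dt * (rate_cell + new_rate_cell)
        omega_vasc += 0.5 * dt * (rate_vasc + new_rate_vasc)
        rate_cell, rate_vasc = new_rate_cell, new_rate_vasc
        if config.coagulation_feedback:
            w_b = props.w_b_nc * np.exp(-omega_vasc)  # w_b_nc (1 − C_f)

        t_max = float(T.values[tissue_nodes].max())
        peak = max(peak, t_max)
        if t_max > abort_temp:
            raise RuntimeError(
                f"feedback controller failed: hottest tissue node {t_max:.2f} °C "
                f"exceeds the {config.temp_cap} °C cap by more than 0.5 °C at "
                f"t = {t_now:.1f} s (applied {U:.1f} V)")

        volt_trace[step] = (t_now, U)
        kill = omega_cell >= arrhenius.KILL_THRESHOLD_OMEGA
        kill_trace[step] = (t_now, np.count_nonzero(kill) * grid.voxel_volume_mm3 / 1000.0)
        if t_now + 1e-9 >= next_snap:
            snapshots.append((t_now, kill.copy()))
            next_snap += config.snapshot_interval

        U = min(U * _controller_scale(t_max, t_prev, config), config.max_volts)
        t_prev = t_max

    if not snapshots or snapshots[-1][0] < config.duration - 1e-9:
        snapshots.append((config.duration, (omega_cell >= arrhenius.KILL_THRESHOLD_OMEGA).copy()))

    c_f = -np.expm1(-omega_vasc)
    return AblationResult(
        grid=grid,
        final_temperature=T,
        omega_map=ScalarMap(grid, omega_cell, "Omega"),
        coagulation_map=ScalarMap(grid, c_f, "C_f"),
        kill_mask_fine=LabelMask(grid, omega_cell >= arrhenius.KILL_THRESHOLD_OMEGA),
        applied_voltage_trace=volt_trace,
        kill_volume_trace=kill_trace,
        peak_tissue_temp=peak,
        kill_snapshots=snapshots,
    )


def ablation_zone_on_grid(
    result: AblationResult,
    dose_grid: VoxelGrid,
    occupancy: float = 0.5,
    duration_s: float | None = None,
) -> LabelMask:
    """Rebin the fine kill mask (Ω >= 6.9) onto the coarse dose grid.

    ``duration_s`` selects an earlier stored snapshot (shorter ablation).
    """
    mask = result.kill_mask_fine if duration_s is None else result.kill_mask_at(duration_s)
    field_ = ScalarMap(result.grid, mask.values.astype(float), "kill")
    return rebin_fine_to_coarse(field_, dose_grid, value_threshold=0.5, occupancy=occupancy)


def reference_scenario(
    spacing_mm: float = 2.0,
    duration_s: float = 600.0,
    tissue: str = "hcc",
    time_step_s: float = 0.5,
) -> tuple[ElectrodeSpec, TissueProperties, SimulationConfig]:
    """The package's reference single-electrode scenario: a 600 s ablation
    with the cooled 30 mm tip along +z in uniform tissue, on a cropped
    80×80×120 mm analysis domain (the far field of a larger liver block is
    isothermal at 37 °C and is represented by the Dirichlet boundary)."""
    electrode = ElectrodeSpec(tip_position=(0.0, 0.0, 15.0), direction=(0.0, 0.0, 1.0))
    config = SimulationConfig(
        domain_size=(80.0, 80.0, 120.0),
        grid_spacing=spacing_mm,
        time_step=time_step_s,
        duration=duration_s,
    )
    return electrode, TISSUE_PRESETS[tissue], config
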