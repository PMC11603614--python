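"""Analytic toy systems with quadrature-exact free energies.

These stand in for the MD engine: model potentials (a 1-D double well and a
3-D binding pocket with a slow orthogonal "hydration" coordinate), a
funnel-shaped restraint, synthetic solvent tracers, and an overdamped
Langevin integrator.  Every potential is cheap enough that reference free
energies can be computed by direct Boltzmann quadrature, which is what the
sampling machinery is validated against.

Units: kJ/mol, nm, ps, K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate

from .collective_variables import SystemCV
from .units import DEFAULT_TEMPERATURE, KB


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ToyPotential:
    """An analytic potential: energy/force callables on flat coordinates.

    ``force_fn`` must be the negative gradient of ``energy_fn``; this is
    checked by finite differences in the test suite.
    """

    dimensionality: int
    energy_fn: Callable[[np.ndarray], float]
    force_fn: Callable[[np.ndarray], np.ndarray]
    descriptor: str


@dataclass
class FunnelGeometry:
    """Cone-plus-cylinder restraint region.

    The allowed region is ``rho <= R(z)`` with ``R(z) = cylinder_radius`` for
    ``z >= cone_to_cylinder_z`` and linearly widening (half angle
    ``cone_half_angle``) for smaller ``z``.  ``dual=True`` makes the allowed
    region the union of the funnel and its mirror image through the origin
    plane (two symmetric funnels).
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    cylinder_radius: float = 0.2
    cone_half_angle: float = 0.7
    cone_to_cylinder_z: float = 0.4
    wall_spring_constant: float = 5000.0
    dual: bool = False

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError(f"funnel axis must be a unit vector (norm={n})")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be > 0")
        if self.wall_spring_constant < 0:
            raise ValueError("wall_spring_constant must be >= 0")

    def allowed_radius(self, z: float | np.ndarray) -> float | np.ndarray:
        """Wall radius R(z) of a single (non-mirrored) funnel."""
        zcc = self.cone_to_cylinder_z
        slope = np.tan(self.cone_half_angle)
        return np.where(
            np.asarray(z) >= zcc,
            self.cylinder_radius,
            self.cylinder_radius + (zcc - np.asarray(z)) * slope,
        )


@dataclass
class SimulationState:
    """Coordinates + step counter + reproducible RNG for overdamped dynamics.

    ``prev_noise`` carries the previous step's Gaussian draw for the
    BAOAB-limit update (None before the first step).
    """

    coordinates: np.ndarray
    step: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )
    prev_noise: np.ndarray | None = None

    @classmethod
    def from_seed(cls, coordinates: np.ndarray, seed: int) -> "SimulationState":
        return cls(np.array(coordinates, dtype=float), 0, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# model potentials
# ---------------------------------------------------------------------------

def double_well_1d(x, barrier_height: float, minima_sep: float):
    """Symmetric quartic double well.

    Minima of depth 0 at ``x = +-minima_sep/2``; barrier ``barrier_height``
    at ``x = 0``.
    """
    if barrier_height <= 0 or minima_sep <= 0:
        raise ValueError("barrier_height and minima_sep must be > 0")
    a = minima_sep / 2.0
    u = (np.asarray(x, dtype=float) / a) ** 2 - 1.0
    return barrier_height * u * u


def double_well_1d_force(x, barrier_height: float, minima_sep: float):
    a = minima_sep / 2.0
    x = np.asarray(x, dtype=float)
    return -4.0 * barrier_height * x * ((x / a) ** 2 - 1.0) / a**2


def toy_binding_potential(
    r,
    well_depth: float,
    well_width: float,
    solvent_coupling: float = 0.0,
    w: float = -1.0,
    hydration_barrier: float = 27.0,
    dry_spring: float = 4.0,
):
    """Toy host-guest pocket: Gaussian well at the origin, flat far field.

    With ``solvent_coupling = c > 0`` the energy also depends on a scalar
    solvent-occupancy coordinate ``w``: the pocket depth is gated
    (fully attractive at ``w = -1``, "dry"; scaled by ``1 - c`` at
    ``w = +1``, "wet").  ``w`` lives in an asymmetric double well
    ``hydration_barrier*(w^2-1)^2 + dry_spring/2*(w+1)^2``: the dry state
    dominates the equilibrium, while the wet state is a long-lived kinetic
    trap — the slow orthogonal degree of freedom that main-CV biasing
    cannot cross.
    """
    if well_depth <= 0:
        raise ValueError("well_depth must be > 0")
    r = np.asarray(r, dtype=float)
    r2 = np.sum(r * r, axis=-1)
    pocket = -well_depth * np.exp(-r2 / (2.0 * well_width**2))
    if solvent_coupling == 0.0:
        return pocket
    gate = 1.0 - solvent_coupling * (1.0 + w) / 2.0
    return (
        gate * pocket
        + 0.5 * dry_spring * (w + 1.0) ** 2
        + hydration_barrier * (w**2 - 1.0) ** 2
    )


def funnel_restraint_energy(r, geom: FunnelGeometry) -> float:
    """Half-harmonic wall outside the funnel region; exactly 0 inside."""
    e, _ = _funnel_energy_force(np.asarray(r, dtype=float), geom)
    return e


def funnel_restraint_force(r, geom: FunnelGeometry) -> np.ndarray:
    _, f = _funnel_energy_force(np.asarray(r, dtype=float), geom)
    return f


def _single_funnel_energy_force(rel: np.ndarray, geom: FunnelGeometry):
    z = float(np.dot(rel, geom.axis))
    rho_vec = rel - z * geom.axis
    rho = float(np.linalg.norm(rho_vec))
    wall = float(geom.allowed_radius(z))
    d = rho - wall
    if d <= 0.0:
        return 0.0, np.zeros(3)
    k = geom.wall_spring_constant
    energy = 0.5 * k * d * d
    rho_hat = rho_vec / rho if rho > 0 else np.zeros(3)
    grad = rho_hat.copy()
    if z < geom.cone_to_cylinder_z:
        # wall radius shrinks with z at rate tan(alpha): d = rho - R(z)
        grad += np.tan(geom.cone_half_angle) * geom.axis
    return energy, -k * d * grad


def _funnel_energy_force(r: np.ndarray, geom: FunnelGeometry):
    rel = r - geom.origin
    e1, f1 = _single_funnel_energy_force(rel, geom)
    if not geom.dual:
        return e1, f1
    # mirrored funnel: reflect the axial component through the origin plane
    z = np.dot(rel, geom.axis)
    rel_m = rel - 2.0 * z * geom.axis
    e2, f2 = _single_funnel_energy_force(rel_m, geom)
    if e1 <= e2:
        return e1, f1
    # chain rule through the reflection: mirror the axial force component back
    zf = np.dot(f2, geom.axis)
    return e2, f2 - 2.0 * zf * geom.axis


# ---------------------------------------------------------------------------
# integrator & solvent
# ---------------------------------------------------------------------------

def langevin_step(
    state: SimulationState,
    total_force: np.ndarray,
    dt: float,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 1.0,
) -> SimulationState:
    """One overdamped Langevin update (BAOAB limit), in place.

    dx = F*dt/friction + sqrt(2*kB*T*dt/friction) * (xi_n + xi_{n-1})/2,
    xi ~ N(0,1).  The averaged-noise (Leimkuhler-Matthews) form has O(dt^2)
    configurational sampling bias versus O(dt) for plain Euler-Maruyama.
    Deterministic for a fixed RNG state.
    """
    if dt <= 0 or temperature < 0 or friction <= 0:
        raise ValueError("dt > 0, temperature >= 0, friction > 0 required")
    f = np.asarray(total_force, dtype=float)
    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(~np.isfinite(f))[0])
        raise FloatingPointError(
            f"non-finite force on coordinate {bad} at step {state.step}"
        )
    noise = state.rng.standard_normal(state.coordinates.shape)
    if state.prev_noise is None:
        state.prev_noise = state.rng.standard_normal(state.coordinates.shape)
    state.coordinates = (
        state.coordinates
        + f * dt / friction
        + np.sqrt(2.0 * KB * temperature * dt / friction)
        * 0.5 * (noise + state.prev_noise)
    )
    state.prev_noise = noise
    state.step += 1
    return state


def generate_solvent_shell(n_solvent: int, box, seed: int) -> np.ndarray:
    """Uniform pseudo-random "water oxygen" tracer positions in a box."""
    if n_solvent < 0:
        raise ValueError("n_solvent must be >= 0")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n_solvent, 3)) * box


# ---------------------------------------------------------------------------
# runnable systems (what the ladder consumes)
# ---------------------------------------------------------------------------

class DoubleWellSystem:
    """1-D double well; CV label "x" is the coordinate itself."""

    def __init__(self, barrier_height: float = 37.0, minima_sep: float = 2.0):
        self.barrier_height = barrier_height
        self.minima_sep = minima_sep
        self.ndof = 1
        # overdamped stability: dt << 2*friction/max curvature
        self.recommended_dt = 0.001
        self.x0 = np.array([-minima_sep / 2.0])
        self.cv_labels = {
            "x": SystemCV(lambda x: float(x[0]), lambda x: np.array([1.0]))
        }
        self.potential = ToyPotential(
            1,
            lambda x: float(double_well_1d(x[0], barrier_height, minima_sep)),
            lambda x: np.atleast_1d(
                double_well_1d_force(x[0], barrier_height, minima_sep)
            ),
            "double_well_1d",
        )

    def energy(self, x: np.ndarray) -> float:
        return self.potential.energy_fn(x)

    def force(self, x: np.ndarray) -> np.ndarray:
        return self.potential.force_fn(x)

    def energy_and_force(self, x: np.ndarray):
        return self.energy(x), self.force(x)

    def free_energy_profile(self, grid: np.ndarray, temperature: float) -> np.ndarray:
        """Exact F(x) on the grid: just the potential (1 dof), min-shifted."""
        f = double_well_1d(grid, self.barrier_height, self.minima_sep)
        return f - f.min()

    def well_probability_ratio(self, temperature: float) -> float:
        """Quadrature Boltzmann weight ratio right/left (=1 by symmetry)."""
        beta = 1.0 / (KB * temperature)
        lo, hi = -self.minima_sep, self.minima_sep

        def boltz(x):
            return np.exp(-beta * double_well_1d(x, self.barrier_height, self.minima_sep))

        right, _ = integrate.quad(boltz, 0.0, hi)
        left, _ = integrate.quad(boltz, lo, 0.0)
        return right / left


class ToyBindingSystem:
    """Toy ligand (x, y, z) + slow hydration coordinate w inside a funnel.

    Coordinates are flattened to ``[x, y, z, w]``.  Soft harmonic caps keep
    ``z`` within ``z_range`` so the unbound cylinder has finite extent.  CV
    labels: ``z`` (funnel-axis projection), ``w`` (solvent occupancy).
    """

    def __init__(
        self,
        well_depth: float = 20.0,
        well_width: float = 0.15,
        solvent_coupling: float = 0.8,
        hydration_barrier: float = 27.0,
        dry_spring: float = 4.0,
        funnel: FunnelGeometry | None = None,
        z_range: tuple[float, float] = (-0.35, 1.0),
        cap_spring: float = 4000.0,
    ):
        self.well_depth = well_depth
        self.well_width = well_width
        self.solvent_coupling = solvent_coupling
        self.hydration_barrier = hydration_barrier
        self.dry_spring = dry_spring
        self.funnel = funnel or FunnelGeometry(
            cylinder_radius=0.25,
            cone_half_angle=0.6,
            cone_to_cylinder_z=0.3,
            wall_spring_constant=4000.0,
        )
        self.z_range = z_range
        self.cap_spring = cap_spring
        self.ndof = 4
        # wall stiffness bounds the stable step: k*dt/friction <= ~0.8
        self.recommended_dt = 2e-4
        # start bound, in the metastable "wet" trap
        self.x0 = np.array([0.0, 0.0, 0.0, 0.95])
        ez = np.array([0.0, 0.0, 1.0, 0.0])
        ew = np.array([0.0, 0.0, 0.0, 1.0])
        self.cv_labels = {
            "z": SystemCV(lambda x: float(x[2]), lambda x, g=ez: g),
            "w": SystemCV(lambda x: float(x[3]), lambda x, g=ew: g),
        }

    # -- energies -----------------------------------------------------------

    def _gate(self, w):
        return 1.0 - self.solvent_coupling * (1.0 + w) / 2.0

    def energy(self, x: np.ndarray) -> float:
        r, w = x[:3], x[3]
        e = float(
            toy_binding_potential(
                r,
                self.well_depth,
                self.well_width,
                self.solvent_coupling,
                w,
                self.hydration_barrier,
                self.dry_spring,
            )
        )
        e += funnel_restraint_energy(r, self.funnel)
        zlo, zhi = self.z_range
        z = r[2]
        if z < zlo:
            e += 0.5 * self.cap_spring * (z - zlo) ** 2
        elif z > zhi:
            e += 0.5 * self.cap_spring * (z - zhi) ** 2
        return e

    def force(self, x: np.ndarray) -> np.ndarray:
        return self.energy_and_force(x)[1]

    def energy_and_force(self, x: np.ndarray):
        """Single-pass energy + force (the runner's hot path)."""
        r, w = x[:3], x[3]
        ww2 = self.well_width**2
        r2 = float(r @ r)
        g = np.exp(-r2 / (2.0 * ww2))
        gate = self._gate(w)
        pocket = -self.well_depth * g
        w2m1 = w * w - 1.0
        wp1 = w + 1.0
        e = (
            gate * pocket
            + 0.5 * self.dry_spring * wp1 * wp1
            + self.hydration_barrier * w2m1 * w2m1
        )
        f = np.empty(4)
        f[:3] = (gate * pocket / ww2) * r
        # -d/dw: pocket gate derivative + tilted double well
        f[3] = (self.solvent_coupling / 2.0) * pocket
        f[3] += -self.dry_spring * wp1
        f[3] += -4.0 * self.hydration_barrier * w * w2m1
        ef, ff = _funnel_energy_force(r, self.funnel)
        e += ef
        f[:3] += ff
        zlo, zhi = self.z_range
        z = r[2]
        if z < zlo:
            e += 0.5 * self.cap_spring * (z - zlo) ** 2
            f[2] += -self.cap_spring * (z - zlo)
        elif z > zhi:
            e += 0.5 * self.cap_spring * (z - zhi) ** 2
            f[2] += -self.cap_spring * (z - zhi)
        return float(e), f

    # -- quadrature oracles -------------------------------------------------

    def _hydration_partition(self, beta: float) -> float:
        """Far-field partition function of w (tilted double well)."""
        w = np.linspace(-4.0, 4.0, 2001)
        vw = (
            0.5 * self.dry_spring * (w + 1.0) ** 2
            + self.hydration_barrier * (w**2 - 1.0) ** 2
        )
        return float(np.trapezoid(np.exp(-beta * vw), w))

    def profile_quadrature(
        self, z_grid: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
    ) -> np.ndarray:
        """Exact G(z) = -kBT ln Int dx dy dw exp(-beta*V), no min shift.

        Includes the funnel restraint, so the z -> large plateau encodes the
        pi*Rcyl^2 cylinder cross-section exactly.
        """
        beta = 1.0 / (KB * temperature)
        wgrid = np.linspace(-4.0, 4.0, 401)
        vw = (
            0.5 * self.dry_spring * (wgrid + 1.0) ** 2
            + self.hydration_barrier * (wgrid**2 - 1.0) ** 2
        )
        # soft-wall penetration scale; the rho grid must resolve it
        delta = np.sqrt(1.0 / (beta * max(self.funnel.wall_spring_constant, 1.0)))
        out = np.empty(len(z_grid))
        for i, z in enumerate(z_grid):
            wall = float(self.funnel.allowed_radius(z))
            if self.funnel.dual:
                wall = max(wall, float(self.funnel.allowed_radius(-z)))
            # radial xy quadrature (integrand is axisymmetric about the z axis)
            rho = np.unique(
                np.concatenate(
                    [
                        np.linspace(0.0, wall, 601),
                        wall + np.linspace(0.0, 8.0 * delta, 241),
                    ]
                )
            )
            r2 = rho**2 + z**2
            g = np.exp(-r2 / (2.0 * self.well_width**2))
            d = np.clip(rho - wall, 0.0, None)
            vf = 0.5 * self.funnel.wall_spring_constant * d * d
            # (rho, w) grid: V = gate(w)*pocket + w double well + funnel
            pocket = -self.well_depth * g[None, :]
            vtot = (
                self._gate(wgrid)[:, None] * pocket
                + vw[:, None]
                + vf[None, :]
            )
            integ = np.exp(-beta * vtot) * (2.0 * np.pi * rho)[None, :]
            val = np.trapezoid(np.trapezoid(integ, rho, axis=1), wgrid)
            out[i] = -KB * temperature * np.log(val)
        return out

    def binding_dg_quadrature(
        self,
        bound_window: tuple[float, float],
        temperature: float = DEFAULT_TEMPERATURE,
        c0_per_nm3: float | None = None,
    ) -> float:
        """Standard-state binding free energy by direct 4-D Boltzmann quadrature.

        dG = -kBT ln[ C0 * Int_bound d3r dw exp(-beta V) / z_w ]  (kJ/mol),
        with z_w the per-volume hydration partition function of the far field.
        """
        from .units import C0_PER_NM3

        beta = 1.0 / (KB * temperature)
        c0 = C0_PER_NM3 if c0_per_nm3 is None else c0_per_nm3
        zlo, zhi = bound_window
        zgrid = np.linspace(zlo, zhi, 241)
        g = self.profile_quadrature(zgrid, temperature)  # -kBT ln of 3-D density
        zw = self._hydration_partition(beta)
        vol_integral = float(np.trapezoid(np.exp(-beta * g), zgrid)) / zw
        return -KB * temperature * np.log(c0 * vol_integral)
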