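"""Replica-0 post-processing: reweighted G(z) profiles, funnel-corrected
standard-state binding free energies, dual-funnel combination and block
errors.

The binding free energy applies the funnel volume correction

    dG_B = -kB*T * ln[ C0 * pi * Rcyl^2 * Int_bound exp(-(G(z)-G_U)/kB*T) dz ]

with C0 the standard concentration, Rcyl the funnel cylinder radius, G(z)
the free energy along the funnel axis and G_U its unbound-plateau reference.
Internal energies are kJ/mol; `BindingFreeEnergy` reports kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .units import C0_PER_NM3, KB, kjmol_to_kcalmol


class AnalysisError(RuntimeError):
    pass


@dataclass
class ColvarTrajectory:
    """Time series of CV values and bias energies (PLUMED COLVAR content)."""

    time: np.ndarray
    cv_values: dict[str, np.ndarray]
    bias_energies: dict[str, np.ndarray] = field(default_factory=dict)
    potential_energy: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.time)
        for name, arr in {**self.cv_values, **self.bias_energies}.items():
            if len(arr) != n:
                raise ValueError(f"series {name!r} length {len(arr)} != {n}")
        if self.potential_energy is not None and len(self.potential_energy) != n:
            raise ValueError("potential_energy length mismatch")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def total_bias(self) -> np.ndarray:
        if "total_bias" in self.bias_energies:
            return self.bias_energies["total_bias"]
        if not self.bias_energies:
            return np.zeros(len(self.time))
        return np.sum(list(self.bias_energies.values()), axis=0)

    def slice(self, i0: int, i1: int) -> "ColvarTrajectory":
        return ColvarTrajectory(
            self.time[i0:i1],
            {k: v[i0:i1] for k, v in self.cv_values.items()},
            {k: v[i0:i1] for k, v in self.bias_energies.items()},
            None if self.potential_energy is None else self.potential_energy[i0:i1],
            dict(self.metadata),
        )


@dataclass
class FreeEnergyProfile:
    """G(z) on a grid with an unbound reference G_U (kJ/mol, gauge: G_U)."""

    z_grid: np.ndarray  # bin centers
    G: np.ndarray       # kJ/mol; NaN on unsampled bins
    G_U: float
    temperature: float
    funnel_side: str = "single"  # above | below | single

    def __post_init__(self) -> None:
        if len(self.z_grid) != len(self.G):
            raise ValueError("z_grid / G length mismatch")
        if self.funnel_side not in ("above", "below", "single"):
            raise ValueError(f"bad funnel_side {self.funnel_side!r}")


@dataclass
class BindingFreeEnergy:
    """Block-averaged dG_B in kcal/mol."""

    value: float
    per_block: np.ndarray
    std: float
    sides_used: str = "both"  # both | above_only | below_only

    def __post_init__(self) -> None:
        self.per_block = np.asarray(self.per_block, dtype=float)
        if self.sides_used not in ("both", "above_only", "below_only"):
            raise ValueError(f"bad sides_used {self.sides_used!r}")


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------

def reweighted_profile(
    traj: ColvarTrajectory,
    z_label: str,
    grid: np.ndarray,
    temperature: float,
    discard_fraction: float = 0.2,
    plateau_window: tuple[float, float] | None = None,
    funnel_side: str = "single",
) -> FreeEnergyProfile:
    """Standard reweighting of a replica-0 trajectory onto a z grid.

    ``grid`` are bin *edges*.  Each post-discard frame is weighted by
    ``exp(+V_total/(kB*T))``; ``G = -kB*T*ln(weighted histogram)`` (min-bias
    gauge handled by G_U).  ``G_U`` is the mean of G over the plateau window
    (defaults to the outer 20% of the grid).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise AnalysisError("discard_fraction must be in [0, 1)")
    n = len(traj)
    i0 = int(np.floor(discard_fraction * n))
    if i0 >= n:
        raise AnalysisError("no frames left after discard")
    z = np.asarray(traj.cv_values[z_label][i0:], dtype=float)
    if z.size == 0:
        raise AnalysisError("no frames left after discard")
    kbt = KB * temperature
    logw = traj.total_bias[i0:] / kbt
    logw = logw - logw.max()  # gauge-invariant; prevents overflow
    w = np.exp(logw)

    grid = np.asarray(grid, dtype=float)
    hist, edges = np.histogram(z, bins=grid, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        G = -kbt * np.log(hist / w.sum())
    G[hist <= 0] = np.nan

    if plateau_window is None:
        span = grid[-1] - grid[0]
        plateau_window = (grid[-1] - 0.2 * span, grid[-1])
    lo, hi = plateau_window
    sel = (centers >= lo) & (centers <= hi) & np.isfinite(G)
    if not np.any(sel):
        raise AnalysisError(
            f"unbound plateau window [{lo}, {hi}] has no sampled bins"
        )
    g_u = float(np.mean(G[sel]))
    return FreeEnergyProfile(centers, G, g_u, temperature, funnel_side)


def binding_free_energy(
    profile: FreeEnergyProfile,
    bound_window: tuple[float, float],
    geom,
    c0_per_nm3: float = C0_PER_NM3,
    out_units: str = "kJ/mol",
) -> float:
    """Funnel-corrected standard-state binding free energy from G(z).

    dG_B = -kB*T*ln[ C0*pi*Rcyl^2 * sum_bound exp(-(G-G_U)/kB*T) * dz ].
    """
    if not np.isfinite(profile.G_U):
        raise AnalysisError("profile G_U is undefined")
    lo, hi = bound_window
    z = profile.z_grid
    half = 0.5 * float(np.mean(np.diff(z))) if len(z) > 1 else 0.0
    if lo < z[0] - half - 1e-12 or hi > z[-1] + half + 1e-12:
        raise AnalysisError("bound window outside the profile grid")
    sel = (z >= lo) & (z <= hi)
    g = profile.G[sel]
    if not np.any(np.isfinite(g)):
        raise AnalysisError("bound window has no sampled bins")
    kbt = KB * profile.temperature
    dz = float(np.mean(np.diff(z)))
    integral = np.nansum(np.exp(-(g - profile.G_U) / kbt)) * dz
    rcyl = geom.cylinder_radius
    dg = -kbt * np.log(c0_per_nm3 * np.pi * rcyl**2 * integral)
    if out_units == "kJ/mol":
        return float(dg)
    if out_units == "kcal/mol":
        return float(kjmol_to_kcalmol(dg))
    raise ValueError(f"unknown units {out_units!r}")


# ---------------------------------------------------------------------------
# block machinery
# ---------------------------------------------------------------------------

def block_error(
    traj: ColvarTrajectory,
    estimator: Callable[[ColvarTrajectory], float],
    n_blocks: int = 3,
    discard_fraction: float = 0.0,
    sides_used: str = "both",
) -> BindingFreeEnergy:
    """Contiguous-block error: per-block dG, mean, sample (n-1) std.

    ``estimator`` maps a trajectory block to a dG value (kcal/mol).
    """
    if n_blocks < 2:
        raise AnalysisError("need n_blocks >= 2")
    n = len(traj)
    i0 = int(np.floor(discard_fraction * n))
    m = n - i0
    if m < n_blocks:
        raise AnalysisError(f"{m} frames cannot fill {n_blocks} blocks")
    size = m // n_blocks
    vals = []
    for b in range(n_blocks):
        j0 = i0 + b * size
        j1 = i0 + (b + 1) * size if b < n_blocks - 1 else n
        vals.append(float(estimator(traj.slice(j0, j1))))
    vals = np.array(vals)
    return BindingFreeEnergy(
        float(vals.mean()), vals, float(vals.std(ddof=1)), sides_used
    )


def blocks_from_runs(
    runs: Sequence[ColvarTrajectory],
    estimator: Callable[[ColvarTrajectory], float],
    sides_used: str = "both",
) -> BindingFreeEnergy:
    """Triplicate-run mode: each independent run is one block."""
    if len(runs) < 2:
        raise AnalysisError("need at least 2 runs")
    vals = np.array([float(estimator(r)) for r in runs])
    return BindingFreeEnergy(
        float(vals.mean()), vals, float(vals.std(ddof=1)), sides_used
    )


def is_side_sampled(
    traj: ColvarTrajectory,
    z_label: str,
    unbound_window: tuple[float, float],
    discard_fraction: float = 0.0,
    min_fraction: float = 0.01,
) -> bool:
    """Undersampling rule: a funnel side counts as sampled when at least
    ``min_fraction`` of post-discard frames fall in its unbound window."""
    n = len(traj)
    i0 = int(np.floor(discard_fraction * n))
    z = np.asarray(traj.cv_values[z_label][i0:])
    if z.size == 0:
        return False
    lo, hi = unbound_window
    return float(np.mean((z >= lo) & (z <= hi))) >= min_fraction


def dual_funnel_combine(
    above: BindingFreeEnergy | None,
    below: BindingFreeEnergy | None,
    sampling_ok: tuple[bool, bool] = (True, True),
) -> BindingFreeEnergy:
    """Combine the two unbound-side estimates of a dual-funnel setup.

    Both sides sampled: per-block values are averaged pairwise first, then
    block statistics are taken.  Only one side sampled: pass-through with
    ``sides_used`` recorded.
    """
    ok_above, ok_below = sampling_ok
    if not ok_above and not ok_below:
        raise AnalysisError("neither funnel side is sampled")
    if ok_above and not ok_below:
        return BindingFreeEnergy(above.value, above.per_block, above.std, "above_only")
    if ok_below and not ok_above:
        return BindingFreeEnergy(below.value, below.per_block, below.std, "below_only")
    if len(above.per_block) != len(below.per_block):
        raise AnalysisError("side block counts differ")
    per_block = 0.5 * (above.per_block + below.per_block)
    return BindingFreeEnergy(
        float(per_block.mean()),
        per_block,
        float(per_block.std(ddof=1)),
        "both",
    )
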