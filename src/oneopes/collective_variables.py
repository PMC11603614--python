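"""Collective variables: funnel-axis projection, orientation cosine,
water-coordination numbers with a rational switching function, and torsions.

The coordination switching function follows the PLUMED RATIONAL dialect:
``s_raw(r) = (1-(r/r0)^n)/(1-(r/r0)^m)``, stretched and shifted so that
``s(0) = 1`` and ``s(d_max) = 0`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass
class SystemCV:
    """A runnable CV: value + gradient on a system's flat coordinate vector.

    Toy systems expose their biasable degrees of freedom this way so the
    ladder runner can apply chain-rule bias forces without numerical
    differentiation.
    """

    fn: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    periodic: bool = False
    period: float = 2.0 * np.pi


@dataclass
class CoordinationParams:
    """Parameters of the rational switching coordination number.

    Defaults carry the published values verbatim (r0 = 2.5 A, d_max = 0.8 A,
    r_nl = 1.5 A, neighbor-list stride 20; WL exponents n=6/m=10).  As printed
    these lengths are mutually inconsistent (d_max < r0 makes the CV vanish,
    r_nl < d_max truncates it), which is why every field is overridable in
    both value and unit — consistent setups should pass e.g. nm-scaled
    values.  Nothing is silently corrected.
    """

    r0: float = 0.25
    d_max: float = 0.08
    r_nl: float = 0.15
    n: int = 6
    m: int = 10
    nl_update_stride: int = 20

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.d_max <= 0:
            raise ValueError("r0 and d_max must be > 0")
        if self.n >= self.m:
            raise ValueError("need n < m for the rational switching function")
        if self.nl_update_stride < 1:
            raise ValueError("nl_update_stride must be >= 1")

    @classmethod
    def water_ligand(cls, **kw) -> "CoordinationParams":
        return cls(n=6, m=10, **kw)

    @classmethod
    def water_host(cls, **kw) -> "CoordinationParams":
        return cls(n=2, m=6, **kw)


@dataclass
class CVSpec:
    """Declarative CV definition used by ladder assembly and file emission."""

    kind: str  # z_projection | cos_orientation | coordination_WL | coordination_WH | torsion
    atom_selector: tuple = ()
    params: CoordinationParams | None = None
    label: str = ""

    _KINDS = (
        "z_projection",
        "cos_orientation",
        "coordination_WL",
        "coordination_WH",
        "torsion",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "torsion" and len(self.atom_selector) != 4:
            raise ValueError("torsion selector needs exactly 4 atoms")

    @property
    def periodic(self) -> bool:
        return self.kind == "torsion"


# ---------------------------------------------------------------------------
# switching function
# ---------------------------------------------------------------------------

def rational_switch(r, p: CoordinationParams):
    """Stretched-and-shifted PLUMED RATIONAL switching function.

    Exactly 1 at r=0, exactly 0 for r >= d_max; C1-continuous in between
    (the raw rational and its derivative are finite everywhere, including
    the removable singularity at r = r0).
    """
    r = np.asarray(r, dtype=float)
    s_dmax = _raw_rational(np.asarray(p.d_max), p.r0, p.n, p.m)
    stretch = 1.0 / (1.0 - s_dmax)
    raw = _raw_rational(np.clip(r, 0.0, p.d_max), p.r0, p.n, p.m)
    return np.where(r >= p.d_max, 0.0, (raw - s_dmax) * stretch)


def _raw_rational(r, r0: float, n: int, m: int):
    x = np.asarray(r, dtype=float) / r0
    xn = x**n
    xm = x**m
    # removable singularity at x == 1: limit is n/m (L'Hopital)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - xn) / (1.0 - xm)
    return np.where(np.isclose(x, 1.0, atol=1e-12), n / m, s)


# ---------------------------------------------------------------------------
# CV evaluations
# ---------------------------------------------------------------------------

def cv_z_projection(coords, ligand_indices, geom) -> float:
    """Signed projection of the ligand centroid onto the funnel axis.

    Toy particles are unit mass, so the centroid is the unweighted mean;
    emitted PLUMED files use mass-weighted COM instead.
    """
    idx = np.asarray(ligand_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("ligand_indices must be non-empty")
    com = np.mean(np.asarray(coords, dtype=float)[idx], axis=0)
    return float(np.dot(com - geom.origin, geom.axis))


def cv_cos_orientation(coords, axis_pair, geom) -> float:
    """Cosine of the angle between a two-atom ligand axis and the funnel axis."""
    i, j = axis_pair
    if i == j:
        raise ValueError("axis_pair atoms must be distinct")
    coords = np.asarray(coords, dtype=float)
    v = coords[j] - coords[i]
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("axis_pair atoms are coincident")
    return float(np.dot(v / n, geom.axis))


class NeighborList:
    """Verlet-style list for the coordination CV; rebuilt every
    ``nl_update_stride`` evaluations (or on demand)."""

    def __init__(self, params: CoordinationParams):
        self.params = params
        self._members: np.ndarray | None = None
        self._age = 0

    def members(self, center: np.ndarray, solvent: np.ndarray) -> np.ndarray:
        if (
            self._members is None
            or self._age % self.params.nl_update_stride == 0
        ):
            d = np.linalg.norm(solvent - center, axis=1)
            self._members = np.flatnonzero(d <= self.params.r_nl)
        self._age += 1
        return self._members


def coordination_number(
    center,
    solvent,
    p: CoordinationParams,
    neighbor_list: NeighborList | None = None,
) -> float:
    """Sum of switching-function terms over solvent (water-oxygen) sites.

    Brute force over all pairs unless a NeighborList is supplied.
    """
    solvent = np.asarray(solvent, dtype=float)
    if solvent.size == 0:
        return 0.0
    center = np.asarray(center, dtype=float)
    if neighbor_list is not None:
        solvent = solvent[neighbor_list.members(center, solvent)]
        if solvent.size == 0:
            return 0.0
    r = np.linalg.norm(solvent - center, axis=1)
    return float(np.sum(rational_switch(r, p)))


def torsion_angle(coords, four_atoms) -> float:
    """Dihedral angle in (-pi, pi] via the standard two-plane atan2 form."""
    a, b, c, d = (np.asarray(coords, dtype=float)[i] for i in four_atoms)
    if len(set(four_atoms)) != 4:
        raise ValueError("torsion needs four distinct atoms")
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear atom triple in torsion definition")
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    angle = float(np.arctan2(y, x))
    if angle <= -np.pi:
        angle += 2 * np.pi
    return angle
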