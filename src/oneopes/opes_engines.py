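"""Adaptive-bias engines: OPES Explore and OPES MultiThermal.

Conventions (held fixed; the oracle tests in the suite depend on them):

OPES Explore
    The target of sampling is the well-tempered distribution
    ``p_tg(s) ~ [P(s)]^(1/gamma)`` with bias factor ``gamma = DeltaE/(kB*T)``.
    ``p_tg`` is estimated on the fly as an (unweighted) kernel-density
    estimate over the biased samples themselves — the defining choice of the
    Explore variant — and the bias at step n is

        V_n(s) = (gamma - 1) * kB*T * ln( (1-eps) * min(p_n(s)/Z_n, 1) + eps )

    with ``eps = exp[-DeltaE / ((gamma-1)*kB*T)]`` and ``Z_n`` the running
    maximum of the density estimate.  At the self-consistent fixed point
    ``p_n -> p_tg`` this gives ``V = -(1 - 1/gamma) * F(s)`` (up to a
    constant), i.e. sampling of the well-tempered distribution, and the
    clipped form makes the BARRIER contract exact:
    ``max V - min V <= DeltaE`` algebraically, at all times.

OPES MultiThermal
    Expanded temperature ensemble on the potential energy U:

        V(U) = -(1/beta0) * ln[ (1/N) * sum_l exp(-(beta_l - beta0)*U + f_l) ]

    with inverse temperatures ``beta_l`` on a geometric grid between T_min
    and T_max, and dimensionless offsets
    ``f_l = -ln < exp(-(beta_l-beta0)*U) >_beta0`` (gauge ``f_0 = 0``)
    estimated by reweighted running averages over the simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .units import KB

TWO_PI = 2.0 * np.pi


@dataclass
class OPESKernel:
    """One deposited Gaussian: center in CV space, per-dimension widths."""

    center: np.ndarray
    widths: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if np.any(self.widths <= 0) or self.weight <= 0:
            raise ValueError("kernel widths and weight must be > 0")


class OPESExploreState:
    """State of one OPES Explore bias instance (exact KDE bookkeeping).

    Parameters
    ----------
    sigma : per-CV kernel width (from an unbiased pre-run).
    barrier : the BARRIER DeltaE (kJ/mol), caps the bias range.
    temperature : thermostat temperature (K).
    pace : deposition stride in integration steps.
    gamma : bias factor; defaults to DeltaE/(kB*T).
    periodic : per-CV periodicity flags (wrapped kernels, minimum image).
    adaptive_sigma : optional shrinking-width rule
        ``sigma_k = sigma * max(1, k)^(-1/(d+4))`` (off by default).
    """

    def __init__(
        self,
        sigma,
        barrier: float,
        temperature: float,
        pace: int,
        gamma: float | None = None,
        periodic=None,
        periods=None,
        adaptive_sigma: bool = False,
        label: str = "opes",
    ):
        self.sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        self.ndim = self.sigma.size
        self.barrier = float(barrier)
        self.temperature = float(temperature)
        self.pace = int(pace)
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        kbt = KB * temperature
        self.null = self.barrier == 0.0  # explicit null bias (no deposition)
        if self.null:
            self.gamma = float("inf")
            self.prefactor = 0.0
            self.epsilon = 1.0
        else:
            self.gamma = barrier / kbt if gamma is None else float(gamma)
            if self.gamma <= 1.0:
                raise ValueError(
                    f"bias factor gamma={self.gamma:.3f} must exceed 1 "
                    f"(barrier {barrier} kJ/mol vs kBT {kbt:.3f})"
                )
            self.prefactor = (self.gamma - 1.0) * kbt
            self.epsilon = float(np.exp(-self.barrier / self.prefactor))
        self.periodic = np.zeros(self.ndim, dtype=bool) if periodic is None else np.atleast_1d(periodic).astype(bool)
        self.periods = np.full(self.ndim, TWO_PI) if periods is None else np.atleast_1d(np.asarray(periods, dtype=float))
        self.adaptive_sigma = bool(adaptive_sigma)
        self.label = label
        self.centers = np.empty((0, self.ndim))
        self.widths = np.empty((0, self.ndim))
        self.Z = 1.0
        self.deposit_count = 0
        # running KDE values at every kernel center (incremental Z bookkeeping)
        self._dens_at_centers = np.empty(0)
        # hot-path caches (valid while sigma is fixed per kernel)
        self._any_periodic = bool(np.any(self.periodic))
        self._inv2 = np.empty((0, self.ndim))
        self._norm = np.empty(0)

    # -- kernel bookkeeping -------------------------------------------------

    @property
    def kernels(self) -> list[OPESKernel]:
        return [
            OPESKernel(c.copy(), w.copy())
            for c, w in zip(self.centers, self.widths)
        ]

    def _delta(self, s: np.ndarray) -> np.ndarray:
        """(K, D) displacements with minimum image on periodic dims."""
        d = s[None, :] - self.centers
        for k in np.flatnonzero(self.periodic):
            p = self.periods[k]
            d[:, k] -= p * np.round(d[:, k] / p)
        return d

    def _density(self, s: np.ndarray):
        """KDE value and gradient at s (mean of normalized Gaussians)."""
        if self.deposit_count == 0:
            return 0.0, np.zeros(self.ndim)
        d = np.atleast_1d(np.asarray(s, dtype=float))[None, :] - self.centers
        if self._any_periodic:
            for k in np.flatnonzero(self.periodic):
                p = self.periods[k]
                d[:, k] -= p * np.round(d[:, k] / p)
        dinv = d * self._inv2
        expo = -0.5 * (d * dinv).sum(axis=1)
        vals = np.exp(expo) / self._norm
        p = vals.sum() / self.deposit_count
        grad = -(vals @ dinv) / self.deposit_count
        return float(p), grad

    def deposit(self, s_now, step: int | None = None) -> "OPESExploreState":
        """Append a kernel at s_now and refresh the normalization Z.

        When ``step`` is given, deposition only happens at multiples of
        ``pace`` (call-every-step usage); with ``step=None`` it is forced.
        """
        s_now = np.atleast_1d(np.asarray(s_now, dtype=float))
        if not np.all(np.isfinite(s_now)):
            raise FloatingPointError(
                f"non-finite CV value {s_now} at step {step} ({self.label})"
            )
        if self.null:
            return self
        if step is not None and step % self.pace != 0:
            return self
        width = self.sigma
        if self.adaptive_sigma:
            shrink = max(1, self.deposit_count) ** (-1.0 / (self.ndim + 4))
            width = np.maximum(self.sigma * shrink, self.sigma * 0.1)
        # incremental update of the KDE values at all centers:
        # new mean = (n*old + G_new(c_i)) / (n+1), plus the value at s_now.

        n_old = self.deposit_count
        if n_old > 0:
            d = self.centers - s_now[None, :]
            for k in np.flatnonzero(self.periodic):
                p = self.periods[k]
                d[:, k] -= p * np.round(d[:, k] / p)
            inv2 = 1.0 / width**2
            g_new_at_old = np.exp(-0.5 * np.sum(d * d * inv2[None, :], axis=1))
            g_new_at_old /= np.prod(width * np.sqrt(TWO_PI))
            p_at_new, _ = self._density(s_now)  # mean over the n_old old kernels
        self.centers = np.vstack([self.centers, s_now[None, :]])
        self.widths = np.vstack([self.widths, width[None, :]])
        self._inv2 = np.vstack([self._inv2, (1.0 / width**2)[None, :]])
        self._norm = np.append(self._norm, np.prod(width * np.sqrt(TWO_PI)))
        self.deposit_count += 1
        self_term = 1.0 / np.prod(width * np.sqrt(TWO_PI))
        if n_old == 0:
            self._dens_at_centers = np.array([self_term])
        else:
            updated = (n_old * self._dens_at_centers + g_new_at_old) / (n_old + 1)
            at_new = (n_old * p_at_new + self_term) / (n_old + 1)
            self._dens_at_centers = np.append(updated, at_new)
        self.Z = float(self._dens_at_centers.max())
        return self

    # -- bias ---------------------------------------------------------------

    def bias(self, s) -> float:
        return self.bias_and_grad(s)[0]

    def bias_and_grad(self, s):
        """V(s) and dV/ds.  Empty state => identically zero bias."""
        if self.deposit_count == 0:
            return 0.0, np.zeros(self.ndim)
        p, dp = self._density(s)
        x = p / self.Z
        if x >= 1.0:
            x, dx = 1.0, np.zeros(self.ndim)
        else:
            dx = dp / self.Z
        inner = (1.0 - self.epsilon) * x + self.epsilon
        v = self.prefactor * np.log(inner)
        dv = self.prefactor * (1.0 - self.epsilon) * dx / inner
        return float(v), dv

    def bias_range(self, grid) -> float:
        """max-min of V over a grid of CV points (BARRIER contract audit)."""
        vals = np.array([self.bias(np.atleast_1d(g)) for g in np.atleast_1d(grid)])
        return float(vals.max() - vals.min())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "oneopes-explore-state-v1",
            "label": self.label,
            "sigma": self.sigma.tolist(),
            "barrier": self.barrier,
            "temperature": self.temperature,
            "pace": self.pace,
            "gamma": self.gamma,
            "periodic": self.periodic.tolist(),
            "periods": self.periods.tolist(),
            "Z": self.Z,
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OPESExploreState":
        st = cls(
            d["sigma"], d["barrier"], d["temperature"], d["pace"],
            gamma=d["gamma"], periodic=d["periodic"], periods=d["periods"],
            label=d["label"],
        )
        st.centers = np.asarray(d["centers"], dtype=float).reshape(-1, st.ndim)
        st.widths = np.asarray(d["widths"], dtype=float).reshape(-1, st.ndim)
        st._inv2 = 1.0 / st.widths**2
        st._norm = np.prod(st.widths * np.sqrt(TWO_PI), axis=1)
        st.deposit_count = len(st.centers)
        if st.deposit_count:
            st._dens_at_centers = np.array(
                [st._density(c)[0] for c in st.centers]
            )
        st.Z = float(d["Z"])
        return st

    def kernels_table(self) -> str:
        """PLUMED KERNELS-style dump of the deposited Gaussians."""
        cols = (
            [f"center_{i}" for i in range(self.ndim)]
            + [f"sigma_{i}" for i in range(self.ndim)]
        )
        lines = ["#! FIELDS kernel_id " + " ".join(cols)]
        for k, (c, w) in enumerate(zip(self.centers, self.widths)):
            vals = " ".join(f"{v:.10g}" for v in np.concatenate([c, w]))
            lines.append(f"{k} {vals}")
        return "\n".join(lines) + "\n"


def multithermal_temperature_grid(t_min: float, t_max: float, n_temps: int) -> np.ndarray:
    """Geometric temperature ladder between t_min and t_max (inclusive)."""
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    if t_max == t_min or n_temps == 1:
        return np.array([t_min])
    return np.geomspace(t_min, t_max, n_temps)


class MultiThermalState:
    """Expanded-temperature-ensemble bias on the potential energy."""

    def __init__(
        self,
        t_min: float,
        t_max: float,
        pace: int = 100,
        n_temps: int = 8,
    ):
        self.t_min = float(t_min)
        self.t_max = float(t_max)
        self.pace = int(pace)
        self.temperatures = multithermal_temperature_grid(t_min, t_max, n_temps)
        self.n_temps = len(self.temperatures)
        self.betas = 1.0 / (KB * self.temperatures)
        self.beta0 = self.betas[0]
        self.f = np.zeros(self.n_temps)  # gauge: f[0] = 0
        # streaming accumulators: logS_l = log sum_t w_t exp(-(b_l-b0) u_t)
        self._logS = np.full(self.n_temps, -np.inf)
        self._logSw = -np.inf
        self._u_min = np.inf
        self._u_max = -np.inf
        self._n_samples = 0
        self._warned_degenerate = False

    @property
    def deltaf_estimates(self) -> np.ndarray:
        """Per-temperature free-energy offsets kB*T_l*f_l (kJ/mol), gauge 0 at T_min."""
        return KB * self.temperatures * self.f

    def update(self, u_now: float, step: int, log_weight: float = 0.0) -> "MultiThermalState":
        """Accumulate one (U, log-weight) sample; refresh offsets at ``pace``.

        ``log_weight`` is beta0 * V_total at the sampled frame so that the
        offset estimates are reweighted expectations in the T_min ensemble.
        Accumulation is streaming (O(n_temps) per call, O(1) memory).
        """
        u_now = float(u_now)
        contrib = float(log_weight) - (self.betas - self.beta0) * u_now
        self._logS = np.logaddexp(self._logS, contrib)
        self._logSw = np.logaddexp(self._logSw, float(log_weight))
        self._u_min = min(self._u_min, u_now)
        self._u_max = max(self._u_max, u_now)
        self._n_samples += 1
        if step % self.pace == 0 and self._n_samples > 1:
            self.refresh()
        return self

    def refresh(self) -> None:
        if self._u_max == self._u_min:
            if not self._warned_degenerate and self._n_samples > 1:
                warnings.warn(
                    "constant potential energy: MultiThermal bias stays 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                self._warned_degenerate = True
            self.f = (self.betas - self.beta0) * self._u_max
            self.f -= self.f[0]
            return
        f = -(self._logS - self._logSw)
        self.f = f - f[0]

    @staticmethod
    def offsets_from_samples(u: np.ndarray, logw: np.ndarray, betas: np.ndarray) -> np.ndarray:
        """f_l = -ln( sum_t w_t exp(-(beta_l-beta0) u_t) / sum_t w_t ).

        Pure function (logsumexp-stable); the closed-form oracle tests call
        it directly with quadrature-weighted samples.
        """
        beta0 = betas[0]
        denom = logsumexp(logw)
        f = np.array(
            [
                -(logsumexp(logw - (b - beta0) * u) - denom)
                for b in betas
            ]
        )
        return f - f[0]

    def bias(self, u: float) -> float:
        return self.bias_and_dvdu(u)[0]

    def bias_and_dvdu(self, u: float):
        """V(U) and dV/dU for the current offsets."""
        if self.n_temps == 1:
            return 0.0, 0.0
        expo = -(self.betas - self.beta0) * u + self.f
        m = expo.max()
        w = np.exp(expo - m)
        sw = w.sum()
        v = -(m + np.log(sw / self.n_temps)) / self.beta0
        dvdu = float(np.sum(w * (self.betas - self.beta0)) / sw / self.beta0)
        return float(v), dvdu


def total_bias(replica_spec, explore_states, mt_state, cv_values: dict, u: float | None) -> float:
    """Sum of all active bias energies for one replica.

    ``explore_states`` is the ordered list [main, aux_1, ..., aux_k]; each
    state's CVs are looked up by label in ``cv_values``.  Raises on a
    roster/state mismatch.
    """
    rosters = [list(replica_spec.main_cvs)] + [list(r) for r in replica_spec.aux_biases]
    if len(explore_states) != len(rosters):
        raise ValueError(
            f"replica {replica_spec.index}: {len(explore_states)} bias states "
            f"for {len(rosters)} rosters"
        )
    v = 0.0
    for st, roster in zip(explore_states, rosters):
        if st.ndim != len(roster):
            raise ValueError(f"bias {st.label}: dimension != roster {roster}")
        try:
            s = np.array([cv_values[lbl] for lbl in roster])
        except KeyError as e:
            raise ValueError(f"CV value missing for label {e.args[0]}") from None
        v += st.bias(s)
    if mt_state is not None:
        if replica_spec.multithermal_tmax is None:
            raise ValueError(f"replica {replica_spec.index} has no MultiThermal slot")
        if u is None:
            raise ValueError("potential energy required for MultiThermal bias")
        v += mt_state.bias(u)
    elif replica_spec.multithermal_tmax is not None:
        raise ValueError(f"replica {replica_spec.index}: missing MultiThermal state")
    return float(v)


@dataclass
class BiasSettings:
    """BARRIER/PACE roster for a ladder; defaults are the published protocol."""

    main_barrier: float = 100.0
    main_pace: int = 10000
    aux_barrier: float = 3.0
    aux_pace: int = 20000
    mt_pace: int = 100
    n_temps: int = 8

    @classmethod
    def toy_preset(cls, steps: int, main_barrier: float = 50.0, aux_barrier: float = 3.0) -> "BiasSettings":
        """Desk-scale preset: paces shrink proportionally to run length.

        The published paces (10000/20000/100 steps) assume multi-ns runs;
        toy runs of ~1e4-1e5 steps keep the same ordering main:aux = 1:2
        but deposit often enough to converge.
        """
        # kernel budget ~1000: dense enough for smooth late-stage bias
        # evolution, cheap enough that per-step KDE evaluation stays O(1000)
        main_pace = max(10, steps // 1000)
        return cls(
            main_barrier=main_barrier,
            main_pace=main_pace,
            aux_pace=main_pace,
            aux_barrier=aux_barrier,
            mt_pace=max(5, steps // 2000),
        )
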