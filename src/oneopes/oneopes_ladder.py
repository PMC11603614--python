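"""The 8-replica OneOPES scheme: ladder assembly, Metropolis bias
exchanges, and a sequential runner over the toy Langevin systems.

Replica 0 is the convergence replica (main OPES Explore bias only, on the
main CVs); replicas 1-7 stack an increasing number of weak auxiliary
OPES Explore biases (hydration CVs, plus torsions when present) and, on
replicas 4-7, an OPES MultiThermal bias with increasing T_max.  All
replicas share the thermostat temperature; exchanges swap configurations
between neighbors while bias potentials stay attached to their slot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .free_energy_analysis import ColvarTrajectory
from .opes_engines import (
    BiasSettings,
    MultiThermalState,
    OPESExploreState,
)
from .units import DEFAULT_TEMPERATURE, KB

DEFAULT_AUX_CV_ORDER = ("WL4", "WH1", "WL1", "WH3", "WH8", "WH5", "WH10")
DEFAULT_TMAX_LIST = (310.0, 330.0, 350.0, 370.0)
DEFAULT_EXCHANGE_STRIDE = 1000


@dataclass
class ReplicaSpec:
    """Which CVs and which biases one replica carries."""

    index: int
    main_cvs: tuple[str, ...] = ("z", "COS")
    aux_biases: tuple[tuple[str, ...], ...] = ()
    multithermal_tmax: float | None = None

    def __post_init__(self) -> None:
        self.main_cvs = tuple(self.main_cvs)
        self.aux_biases = tuple(tuple(r) for r in self.aux_biases)
        if self.index == 0:
            if self.aux_biases:
                raise ValueError("replica 0 must carry no auxiliary biases")
            if self.multithermal_tmax is not None:
                raise ValueError("replica 0 must carry no MultiThermal bias")
        if self.multithermal_tmax is not None and self.index < 4:
            raise ValueError("MultiThermal biases live on replicas 4 and up")


@dataclass
class LadderConfig:
    replicas: tuple[ReplicaSpec, ...]
    exchange_stride: int = DEFAULT_EXCHANGE_STRIDE
    seed: int = 0
    steps: int = 10000
    thermostat_temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.replicas = tuple(self.replicas)
        if self.exchange_stride < 1:
            raise ValueError("exchange_stride must be >= 1")
        counts = [len(r.aux_biases) for r in self.replicas]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("aux bias count must be non-decreasing in replica index")
        for k, r in enumerate(self.replicas):
            if r.index != k:
                raise ValueError("replica indices must be 0..n-1 in order")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def cv_labels(self) -> list[str]:
        """All CV labels referenced anywhere in the ladder, in first-use order."""
        seen: dict[str, None] = {}
        for r in self.replicas:
            for lbl in r.main_cvs:
                seen.setdefault(lbl, None)
            for roster in r.aux_biases:
                for lbl in roster:
                    seen.setdefault(lbl, None)
        return list(seen)


def _torsion_part(torsions: tuple[str, ...], bias_index: int) -> tuple[str, ...]:
    """Torsion membership of aux bias ``bias_index`` (1-based).

    Up to two torsions: all of them in every roster.  Three: cycle pairs so
    each roster holds 3 CVs and every unordered pair occurs across 1..7.
    """
    if len(torsions) <= 2:
        return tuple(torsions)
    j = bias_index
    return (torsions[j % 3], torsions[(j + 1) % 3])


def build_default_ladder(
    aux_cv_order: tuple[str, ...] = DEFAULT_AUX_CV_ORDER,
    torsions: tuple[str, ...] = (),
    tmax_list: tuple[float, ...] = DEFAULT_TMAX_LIST,
    exchange_stride: int = DEFAULT_EXCHANGE_STRIDE,
    steps: int = 10000,
    seed: int = 0,
    thermostat_temperature: float = DEFAULT_TEMPERATURE,
) -> LadderConfig:
    """The published 8-replica scheme: replica k carries aux biases 1..k on
    the hydration CVs WL4, WH1, WL1, WH3, WH8, WH5, WH10 (plus torsions),
    and replicas 4-7 carry MultiThermal up to 310/330/350/370 K."""
    if len(torsions) > 3:
        raise ValueError("at most 3 torsional CVs are supported")
    if len(aux_cv_order) != 7:
        raise ValueError("need exactly 7 auxiliary hydration CVs")
    if len(tmax_list) != 4:
        raise ValueError("need exactly 4 MultiThermal T_max values")
    replicas = [ReplicaSpec(0)]
    for k in range(1, 8):
        rosters = tuple(
            (aux_cv_order[j - 1],) + _torsion_part(tuple(torsions), j)
            for j in range(1, k + 1)
        )
        tmax = tmax_list[k - 4] if k >= 4 else None
        replicas.append(
            ReplicaSpec(k, aux_biases=rosters, multithermal_tmax=tmax)
        )
    return LadderConfig(
        tuple(replicas),
        exchange_stride=exchange_stride,
        steps=steps,
        seed=seed,
        thermostat_temperature=thermostat_temperature,
    )


def build_toy_ladder(
    main_cvs: tuple[str, ...],
    aux_cv: str | None,
    n_replicas: int = 8,
    tmax_list: tuple[float, ...] = DEFAULT_TMAX_LIST,
    exchange_stride: int = 200,
    steps: int = 20000,
    seed: int = 0,
    thermostat_temperature: float = DEFAULT_TEMPERATURE,
) -> LadderConfig:
    """Desk-scale ladder over a toy system's CV labels.

    Keeps the scheme's shape — convergence replica 0, replica k stacking k
    weak auxiliary biases (all on the toy's single hidden CV, mirroring the
    k-bias stacking of the full scheme), MultiThermal on replicas 4+.
    """
    replicas = [ReplicaSpec(0, main_cvs=main_cvs)]
    for k in range(1, n_replicas):
        aux = ((aux_cv,),) * k if aux_cv is not None else ()
        tmax = tmax_list[min(k - 4, len(tmax_list) - 1)] if k >= 4 else None
        replicas.append(
            ReplicaSpec(k, main_cvs=main_cvs, aux_biases=aux, multithermal_tmax=tmax)
        )
    return LadderConfig(
        tuple(replicas),
        exchange_stride=exchange_stride,
        steps=steps,
        seed=seed,
        thermostat_temperature=thermostat_temperature,
    )


# ---------------------------------------------------------------------------
# exchanges
# ---------------------------------------------------------------------------

def attempt_exchange(i, j, configs, bias_of, beta, rng):
    """Metropolis swap of configurations between replicas i and j.

    ``bias_of(r, x)`` evaluates replica r's total bias on configuration x.
    Accept with probability
    ``min(1, exp(beta*[(V_i(x_i)+V_j(x_j)) - (V_i(x_j)+V_j(x_i))]))``.
    Bias states never swap.  Returns (accepted, configs).
    """
    xi, xj = configs[i], configs[j]
    delta = beta * (
        (bias_of(i, xi) + bias_of(j, xj)) - (bias_of(i, xj) + bias_of(j, xi))
    )
    accepted = delta >= 0 or rng.random() < np.exp(delta)
    if accepted:
        configs[i], configs[j] = xj, xi
    return accepted, configs


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

@dataclass
class ExchangeEvent:
    step: int
    i: int
    j: int
    accepted: bool


@dataclass
class OneOPESRun:
    trajectories: list[ColvarTrajectory]
    exchange_log: list[ExchangeEvent]
    explore_states: list[list[OPESExploreState]]
    mt_states: list[MultiThermalState | None]


class _ReplicaEngine:
    """Per-slot bias machinery bound to a toy system's CVs."""

    def __init__(self, spec, system, sigma, settings, temperature):
        self.spec = spec
        self.system = system
        self.cvs = {}
        for lbl in set(spec.main_cvs) | {l for r in spec.aux_biases for l in r}:
            try:
                self.cvs[lbl] = system.cv_labels[lbl]
            except KeyError:
                raise ValueError(
                    f"replica {spec.index}: CV label {lbl!r} not resolvable "
                    f"on system (has {sorted(system.cv_labels)})"
                ) from None
        self.explore: list[OPESExploreState] = []
        rosters = [tuple(spec.main_cvs)] + [tuple(r) for r in spec.aux_biases]
        for bi, roster in enumerate(rosters):
            barrier = settings.main_barrier if bi == 0 else settings.aux_barrier
            pace = settings.main_pace if bi == 0 else settings.aux_pace
            name = "main" if bi == 0 else f"aux{bi}"
            self.explore.append(
                OPESExploreState(
                    sigma=[sigma[l] for l in roster],
                    barrier=barrier,
                    temperature=temperature,
                    pace=pace,
                    periodic=[self.cvs[l].periodic for l in roster],
                    periods=[self.cvs[l].period for l in roster],
                    label=f"r{spec.index}.{name}",
                )
            )
        self.rosters = rosters
        self.mt: MultiThermalState | None = None
        if spec.multithermal_tmax is not None:
            self.mt = MultiThermalState(
                temperature, spec.multithermal_tmax,
                pace=settings.mt_pace, n_temps=settings.n_temps,
            )

    def cv_values(self, x) -> dict[str, float]:
        return {lbl: cv.fn(x) for lbl, cv in self.cvs.items()}

    def bias_terms(self, x, cvs: dict, u=None, f_phys=None):
        """Per-bias energies and the summed bias force vector.

        ``cvs`` holds precomputed CV values; ``f_phys`` (physical force) is
        needed for the MultiThermal chain rule dV/dx = (dV/dU)(-F).
        """
        f = np.zeros_like(x)
        energies = {}
        for st, roster in zip(self.explore, self.rosters):
            s = np.array([cvs[l] for l in roster])
            v, dvds = st.bias_and_grad(s)
            energies[st.label.split(".", 1)[1]] = v
            for d, lbl in enumerate(roster):
                if dvds[d] != 0.0:
                    f -= dvds[d] * self.cvs[lbl].grad(x)
        if self.mt is not None:
            if u is None:
                u = self.system.energy(x)
            if f_phys is None:
                f_phys = self.system.force(x)
            v, dvdu = self.mt.bias_and_dvdu(u)
            energies["multithermal"] = v
            f += dvdu * f_phys
        return energies, f

    def total_bias_value(self, x) -> float:
        u = self.system.energy(x) if self.mt is not None else None
        energies, _ = self.bias_terms(x, self.cv_values(x), u)
        return float(sum(energies.values()))

    def deposit(self, cvs: dict, step):
        for st, roster in zip(self.explore, self.rosters):
            if step % st.pace == 0:
                st.deposit(np.array([cvs[l] for l in roster]))

    def mt_update(self, u, v_total, kbt, step):
        if self.mt is not None:
            self.mt.update(u, step, log_weight=v_total / kbt)


def run_oneopes(
    system,
    ladder: LadderConfig,
    settings: BiasSettings | None = None,
    sigma: dict[str, float] | None = None,
    dt: float = 0.002,
    friction: float = 1.0,
    record_stride: int = 10,
    sigma_estimate_steps: int = 2000,
) -> OneOPESRun:
    """Run the full scheme on a toy system; returns per-replica COLVAR-style
    trajectories plus the exchange log and final bias states.

    Missing ``sigma`` values are estimated from a short unbiased pre-run at
    the thermostat temperature (the toy analogue of extracting CV standard
    deviations from a short plain-MD segment).
    """
    settings = settings or BiasSettings.toy_preset(ladder.steps)
    temperature = ladder.thermostat_temperature
    kbt = KB * temperature
    labels = ladder.cv_labels()
    for lbl in labels:
        if lbl not in system.cv_labels:
            raise ValueError(
                f"CV label {lbl!r} not resolvable on system "
                f"(has {sorted(system.cv_labels)})"
            )

    master = np.random.default_rng(ladder.seed)
    child_seeds = master.integers(0, 2**63 - 1, size=ladder.n_replicas + 2)
    if sigma is None or any(l not in sigma for l in labels):
        est = _unbiased_sigma(
            system, temperature, dt, friction,
            sigma_estimate_steps, int(child_seeds[-2]),
        )
        sigma = {**est, **(sigma or {})}

    engines = [
        _ReplicaEngine(spec, system, sigma, settings, temperature)
        for spec in ladder.replicas
    ]
    rngs = [np.random.default_rng(int(s)) for s in child_seeds[:-2]]
    ex_rng = np.random.default_rng(int(child_seeds[-1]))
    configs = [np.array(system.x0, dtype=float) for _ in ladder.replicas]

    rec: list[dict[str, list]] = [
        {
            "time": [], "U": [], "total_bias": [],
            **{f"cv:{l}": [] for l in labels},
            **{f"bias:{name}": [] for name in _bias_names(engines[r])},
        }
        for r in range(ladder.n_replicas)
    ]
    exchange_log: list[ExchangeEvent] = []
    sqrt_noise = np.sqrt(2.0 * kbt * dt / friction)
    prev_noise = [rngs[r].standard_normal(configs[r].shape) for r in range(ladder.n_replicas)]
    sweep = 0

    have_ef = hasattr(system, "energy_and_force")
    for step in range(1, ladder.steps + 1):
        record = step % record_stride == 0
        for r, eng in enumerate(engines):
            x = configs[r]
            # pre-move accounting: evaluate everything at the current frame,
            # update biases from it, then advance
            need_u = eng.mt is not None or record
            if need_u and have_ef:
                u, f_phys = system.energy_and_force(x)
            else:
                u = system.energy(x) if need_u else None
                f_phys = system.force(x)
            cvs = {lbl: cv.fn(x) for lbl, cv in eng.cvs.items()}
            energies, fbias = eng.bias_terms(x, cvs, u, f_phys)
            if record:
                row = rec[r]
                row["time"].append(step * dt)
                row["U"].append(u)
                row["total_bias"].append(float(sum(energies.values())))
                for l in labels:
                    row[f"cv:{l}"].append(
                        cvs[l] if l in cvs else system.cv_labels[l].fn(x)
                    )
                for name, v in energies.items():
                    row[f"bias:{name}"].append(v)
            eng.deposit(cvs, step)
            if eng.mt is not None:
                eng.mt_update(u, float(sum(energies.values())), kbt, step)
            f = f_phys + fbias
            if not np.all(np.isfinite(f)):
                bad = int(np.flatnonzero(~np.isfinite(f))[0])
                raise FloatingPointError(
                    f"non-finite force on coordinate {bad} of replica {r} at step {step}"
                )
            noise = rngs[r].standard_normal(x.shape)
            configs[r] = x + f * dt / friction + sqrt_noise * 0.5 * (noise + prev_noise[r])
            prev_noise[r] = noise
        if step % ladder.exchange_stride == 0 and ladder.n_replicas > 1:
            start = sweep % 2
            sweep += 1
            for i in range(start, ladder.n_replicas - 1, 2):
                accepted, configs = attempt_exchange(
                    i, i + 1, configs,
                    lambda rr, xx: engines[rr].total_bias_value(xx),
                    1.0 / kbt, ex_rng,
                )
                exchange_log.append(ExchangeEvent(step, i, i + 1, accepted))

    trajectories = []
    for r, row in enumerate(rec):
        bias_cols = {
            name.split("bias:", 1)[1]: np.array(vals)
            for name, vals in row.items()
            if name.startswith("bias:")
        }
        bias_cols["total_bias"] = np.array(row["total_bias"])
        trajectories.append(
            ColvarTrajectory(
                np.array(row["time"]),
                {l: np.array(row[f"cv:{l}"]) for l in labels},
                bias_cols,
                np.array(row["U"]),
                metadata={
                    "replica": r,
                    "seed": ladder.seed,
                    "dt": dt,
                    "record_stride": record_stride,
                    "columns": ["time"] + labels + list(bias_cols) + ["U"],
                },
            )
        )
    return OneOPESRun(trajectories, exchange_log, [e.explore for e in engines],
                      [e.mt for e in engines])


def _bias_names(engine: _ReplicaEngine) -> list[str]:
    names = [st.label.split(".", 1)[1] for st in engine.explore]
    if engine.mt is not None:
        names.append("multithermal")
    return names


def _unbiased_sigma(system, temperature, dt, friction, steps, seed):
    """Short unbiased run -> per-CV standard deviation (SIGMA source)."""
    rng = np.random.default_rng(seed)
    x = np.array(system.x0, dtype=float)
    kbt = KB * temperature
    sqrt_noise = np.sqrt(2.0 * kbt * dt / friction)
    samples = {l: [] for l in system.cv_labels}
    prev = rng.standard_normal(x.shape)
    for step in range(steps):
        f = system.force(x)
        noise = rng.standard_normal(x.shape)
        x = x + f * dt / friction + sqrt_noise * 0.5 * (noise + prev)
        prev = noise
        if step % 5 == 0:
            for l, cv in system.cv_labels.items():
                samples[l].append(cv.fn(x))
    out = {}
    for l, vals in samples.items():
        s = float(np.std(vals))
        out[l] = s if s > 1e-8 else 0.1
    return out
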