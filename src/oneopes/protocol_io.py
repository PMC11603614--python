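"""File formats and protocol emission.

COLVAR dialect: whitespace-separated columns headed by ``#! FIELDS ...``,
as written by PLUMED.  Protocol emission writes one directory per replica,
each with a PLUMED-dialect input realizing that replica's bias roster
(main OPES Explore on z/COS, stacked weak MultiCV biases, MultiThermal on
the top replicas), plus a GROMACS .mdp template and a run script carrying
the replica-exchange stride.  Emission is byte-deterministic; provenance
lives in a YAML sidecar, never inside the protocol files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .collective_variables import CoordinationParams, CVSpec
from .free_energy_analysis import ColvarTrajectory
from .oneopes_ladder import LadderConfig, ReplicaSpec, build_default_ladder
from .toy_systems import FunnelGeometry

FLOAT_FMT = "%.10g"


class ColvarFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# COLVAR I/O
# ---------------------------------------------------------------------------

def read_colvar(path) -> ColvarTrajectory:
    """Parse a PLUMED-dialect COLVAR file.

    Column classification: ``time`` is the time stamp, names containing
    ``.bias`` or named ``total_bias`` are bias energies, ``U``/``ene`` is
    the potential energy, everything else is a CV.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#! FIELDS"):
            raise ColvarFormatError(f"{path}: missing '#! FIELDS' header")
        names = header.split()[2:]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(names):
                raise ColvarFormatError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {len(names)})"
                )
            rows.append([float(p) for p in parts])
    data = np.array(rows, dtype=float).reshape(-1, len(names))
    cols = dict(zip(names, data.T))
    time = cols.pop("time", np.arange(len(data), dtype=float))
    bias = {}
    cvs = {}
    pot = None
    for name, arr in cols.items():
        if name in ("U", "ene"):
            pot = arr
        elif ".bias" in name or name == "total_bias":
            bias[name] = arr
        else:
            cvs[name] = arr
    return ColvarTrajectory(
        time, cvs, bias, pot, metadata={"columns": names, "path": str(path)}
    )


def write_colvar(traj: ColvarTrajectory, path) -> None:
    """Deterministic COLVAR writer (fixed %.10g precision, stable order)."""
    path = Path(path)
    names = ["time"]
    series = [traj.time]
    order = traj.metadata.get("columns")
    cols: dict[str, np.ndarray] = {}
    cols.update(traj.cv_values)
    cols.update(traj.bias_energies)
    if traj.potential_energy is not None:
        cols["U"] = traj.potential_energy
    if order:
        keys = [c for c in order if c in cols] + [c for c in cols if c not in order]
    else:
        keys = list(cols)
    for k in keys:
        names.append(k)
        series.append(cols[k])
    data = np.column_stack(series) if series[0].size else np.empty((0, len(names)))
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        np.savetxt(fh, data, fmt=FLOAT_FMT)


def compute_sigma_from_unbiased(
    traj: ColvarTrajectory,
    cv_labels,
    periodic: set[str] | None = None,
) -> dict[str, float]:
    """Per-CV standard deviation from an unbiased trajectory (SIGMA source).

    Periodic CVs (torsions) use the circular standard deviation
    ``sqrt(-2 ln R)``, which is immune to branch-cut inflation.
    """
    bias = traj.total_bias
    if bias.size and np.any(np.abs(bias) > 1e-9):
        raise ValueError("trajectory is biased; SIGMA needs an unbiased run")
    periodic = periodic or set()
    out = {}
    for lbl in cv_labels:
        x = np.asarray(traj.cv_values[lbl], dtype=float)
        if lbl in periodic:
            r = np.hypot(np.mean(np.sin(x)), np.mean(np.cos(x)))
            s = math.sqrt(max(0.0, -2.0 * math.log(min(r, 1.0)))) if r > 0 else float("inf")
        else:
            s = float(np.std(x, ddof=1))
        if not np.isfinite(s) or s <= 1e-12:
            raise ValueError(f"CV {lbl!r} is constant; SIGMA would be degenerate")
        out[lbl] = s
    return out


# ---------------------------------------------------------------------------
# protocol config
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


@dataclass
class ProtocolConfig:
    """Everything needed to emit the per-replica PLUMED input tree."""

    ladder: LadderConfig
    cv_specs: list[CVSpec]
    funnel: FunnelGeometry
    main_barrier: float = 100.0
    main_pace: int = 10000
    multicv_barrier: float = 3.0
    multicv_pace: int = 20000
    multithermal_pace: int = 100
    sigma: dict[str, float] = field(default_factory=dict)
    ligand_atoms: tuple[int, ...] = (1,)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.main_barrier <= 0 or self.multicv_barrier <= 0:
            raise ValueError("barriers must be > 0")
        for name in ("main_pace", "multicv_pace", "multithermal_pace"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def exchange_stride(self) -> int:
        return self.ladder.exchange_stride

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "ladder": {
                "exchange_stride": self.ladder.exchange_stride,
                "seed": self.ladder.seed,
                "steps": self.ladder.steps,
                "thermostat_temperature": self.ladder.thermostat_temperature,
                "replicas": [
                    {
                        "index": r.index,
                        "main_cvs": list(r.main_cvs),
                        "aux_biases": [list(a) for a in r.aux_biases],
                        "multithermal_tmax": r.multithermal_tmax,
                    }
                    for r in self.ladder.replicas
                ],
            },
            "cv_specs": [
                {
                    "kind": c.kind,
                    "atom_selector": list(c.atom_selector),
                    "label": c.label,
                    "params": None
                    if c.params is None
                    else {
                        "r0": c.params.r0, "d_max": c.params.d_max,
                        "r_nl": c.params.r_nl, "n": c.params.n,
                        "m": c.params.m,
                        "nl_update_stride": c.params.nl_update_stride,
                    },
                }
                for c in self.cv_specs
            ],
            "funnel": {
                "origin": self.funnel.origin.tolist(),
                "axis": self.funnel.axis.tolist(),
                "cylinder_radius": self.funnel.cylinder_radius,
                "cone_half_angle": self.funnel.cone_half_angle,
                "cone_to_cylinder_z": self.funnel.cone_to_cylinder_z,
                "wall_spring_constant": self.funnel.wall_spring_constant,
                "dual": self.funnel.dual,
            },
            "biases": {
                "main_barrier": self.main_barrier,
                "main_pace": self.main_pace,
                "multicv_barrier": self.multicv_barrier,
                "multicv_pace": self.multicv_pace,
                "multithermal_pace": self.multithermal_pace,
            },
            "sigma": dict(self.sigma),
            "ligand_atoms": list(self.ligand_atoms),
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {d.get('schema_version')!r}")
        lad = d["ladder"]
        replicas = tuple(
            ReplicaSpec(
                r["index"],
                main_cvs=tuple(r["main_cvs"]),
                aux_biases=tuple(tuple(a) for a in r["aux_biases"]),
                multithermal_tmax=r["multithermal_tmax"],
            )
            for r in lad["replicas"]
        )
        ladder = LadderConfig(
            replicas,
            exchange_stride=lad["exchange_stride"],
            seed=lad["seed"],
            steps=lad["steps"],
            thermostat_temperature=lad["thermostat_temperature"],
        )
        cv_specs = [
            CVSpec(
                c["kind"],
                tuple(c["atom_selector"]),
                None if c["params"] is None else CoordinationParams(**c["params"]),
                c["label"],
            )
            for c in d["cv_specs"]
        ]
        f = d["funnel"]
        funnel = FunnelGeometry(
            np.array(f["origin"]), np.array(f["axis"]),
            f["cylinder_radius"], f["cone_half_angle"],
            f["cone_to_cylinder_z"], f["wall_spring_constant"], f["dual"],
        )
        b = d["biases"]
        return cls(
            ladder, cv_specs, funnel,
            main_barrier=b["main_barrier"], main_pace=b["main_pace"],
            multicv_barrier=b["multicv_barrier"], multicv_pace=b["multicv_pace"],
            multithermal_pace=b["multithermal_pace"],
            sigma=dict(d["sigma"]),
            ligand_atoms=tuple(d["ligand_atoms"]),
        )

    @classmethod
    def from_yaml(cls, source) -> "ProtocolConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))


def default_protocol_config(
    torsion_atoms: tuple[tuple[int, int, int, int], ...] = (),
    **ladder_kw,
) -> ProtocolConfig:
    """Published default: 8 replicas, Table-1 rosters, a single funnel and
    example CV selections on a small index set."""
    torsion_labels = tuple(f"T{i+1}" for i in range(len(torsion_atoms)))
    ladder = build_default_ladder(torsions=torsion_labels, **ladder_kw)
    wl = CoordinationParams.water_ligand()
    wh = CoordinationParams.water_host()
    cv_specs = [
        CVSpec("z_projection", (1, 2, 3), None, "z"),
        CVSpec("cos_orientation", (1, 3), None, "COS"),
        CVSpec("coordination_WL", (4,), wl, "WL4"),
        CVSpec("coordination_WH", (101,), wh, "WH1"),
        CVSpec("coordination_WL", (1,), wl, "WL1"),
        CVSpec("coordination_WH", (103,), wh, "WH3"),
        CVSpec("coordination_WH", (108,), wh, "WH8"),
        CVSpec("coordination_WH", (105,), wh, "WH5"),
        CVSpec("coordination_WH", (110,), wh, "WH10"),
    ]
    for lbl, atoms in zip(torsion_labels, torsion_atoms):
        cv_specs.append(CVSpec("torsion", tuple(atoms), None, lbl))
    sigma = {"z": 0.05, "COS": 0.05}
    sigma.update({lbl: 0.1 for lbl in torsion_labels})
    return ProtocolConfig(
        ladder, cv_specs,
        FunnelGeometry(cylinder_radius=0.2, cone_half_angle=0.55,
                       cone_to_cylinder_z=1.0, wall_spring_constant=10000.0),
        sigma=sigma,
    )


# ---------------------------------------------------------------------------
# PLUMED emission
# ---------------------------------------------------------------------------

_HEADER = """\
# PLUMED input for replica {index} of the OneOPES ladder.
# Funnel restraint composition: the ligand COM is projected on the funnel
# axis (fps.z) and radially (fps.rho); a half-harmonic UPPER_WALLS on
# rho - R(z) confines the guest to the cone+cylinder volume.  R(z) equals
# RCYL for z >= ZCC and widens with slope tan(ALPHA) below ZCC.
"""


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _cv_block(spec: CVSpec, ligand_atoms) -> str:
    if spec.kind == "z_projection":
        atoms = ",".join(str(a) for a in spec.atom_selector)
        return (
            f"lig: COM ATOMS={atoms}\n"
            f"fps: FUNNEL_PS LIGAND=lig REFERENCE=funnel_ref.pdb\n"
            f"{spec.label}: COMBINE ARG=fps.lp PERIODIC=NO"
        )
    if spec.kind == "cos_orientation":
        a, b = spec.atom_selector
        return (
            f"lax: DISTANCE ATOMS={a},{b} COMPONENTS\n"
            f"lnorm: DISTANCE ATOMS={a},{b}\n"
            f"{spec.label}: CUSTOM ARG=lax.z,lnorm FUNC=x/y PERIODIC=NO"
        )
    if spec.kind in ("coordination_WL", "coordination_WH"):
        p = spec.params
        center = ",".join(str(a) for a in spec.atom_selector)
        return (
            f"{spec.label}: COORDINATION GROUPA={center} GROUPB=@water-oxygens "
            f"SWITCH={{RATIONAL R_0={_fmt(p.r0)} D_MAX={_fmt(p.d_max)} "
            f"NN={p.n} MM={p.m}}} "
            f"NLIST NL_CUTOFF={_fmt(p.r_nl)} NL_STRIDE={p.nl_update_stride}"
        )
    if spec.kind == "torsion":
        atoms = ",".join(str(a) for a in spec.atom_selector)
        return f"{spec.label}: TORSION ATOMS={atoms}"
    raise ValueError(f"cannot emit CV kind {spec.kind!r}")


def _funnel_block(f: FunnelGeometry, tag: str, mirror: bool) -> str:
    sign = "-" if mirror else ""
    return (
        f"{tag}_rz: CUSTOM ARG=fps.z FUNC={sign}x PERIODIC=NO\n"
        f"{tag}_wall: CUSTOM ARG=fps.rho,{tag}_rz "
        f"FUNC=x-(step({_fmt(f.cone_to_cylinder_z)}-y)*"
        f"({_fmt(np.tan(f.cone_half_angle))}*({_fmt(f.cone_to_cylinder_z)}-y))"
        f"+{_fmt(f.cylinder_radius)}) PERIODIC=NO\n"
        f"UPPER_WALLS ARG={tag}_wall AT=0.0 KAPPA={_fmt(f.wall_spring_constant)} "
        f"LABEL={tag}_restraint"
    )


def emit_plumed_protocol(config: ProtocolConfig, out_dir) -> Path:
    """Write one subdirectory per replica with its PLUMED-dialect input.

    Refuses to emit when SIGMA is missing for a main CV or the funnel
    geometry is absent.  Output is byte-deterministic.
    """
    if config.funnel is None:
        raise ValueError("funnel geometry required for emission")
    specs = {c.label: c for c in config.cv_specs}
    main_labels = config.ladder.replicas[0].main_cvs
    for lbl in main_labels:
        if lbl not in config.sigma:
            raise ValueError(f"SIGMA missing for main CV {lbl!r}; refusing to emit")
        if lbl not in specs:
            raise ValueError(f"no CVSpec for main CV {lbl!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for rep in config.ladder.replicas:
        rep_dir = out / f"replica_{rep.index}"
        rep_dir.mkdir(exist_ok=True)
        lines = [_HEADER.format(index=rep.index)]
        emitted: set[str] = set()

        def emit_cv(lbl: str) -> None:
            if lbl in emitted:
                return
            if lbl not in specs:
                raise ValueError(f"no CVSpec for CV label {lbl!r}")
            lines.append(_cv_block(specs[lbl], config.ligand_atoms))
            emitted.add(lbl)

        for lbl in main_labels:
            emit_cv(lbl)
        for roster in rep.aux_biases:
            for lbl in roster:
                emit_cv(lbl)

        lines.append(_funnel_block(config.funnel, "funnel", mirror=False))
        if config.funnel.dual:
            lines.append(_funnel_block(config.funnel, "funnel2", mirror=True))

        sigmas = ",".join(_fmt(config.sigma[l]) for l in main_labels)
        lines.append(
            f"opes_main: OPES_METAD_EXPLORE ARG={','.join(main_labels)} "
            f"BARRIER={_fmt(config.main_barrier)} PACE={config.main_pace} "
            f"SIGMA={sigmas}"
        )
        for bi, roster in enumerate(rep.aux_biases, start=1):
            sig = ",".join(
                _fmt(config.sigma.get(l, 0.1)) for l in roster
            )
            lines.append(
                f"opes_multicv_{bi}: OPES_METAD_EXPLORE ARG={','.join(roster)} "
                f"BARRIER={_fmt(config.multicv_barrier)} "
                f"PACE={config.multicv_pace} SIGMA={sig}"
            )
        if rep.multithermal_tmax is not None:
            tmin = config.ladder.thermostat_temperature
            lines.append(
                "ene: ENERGY\n"
                f"ecv_mt: ECV_MULTITHERMAL ARG=ene "
                f"TEMP_MIN={_fmt(tmin)} TEMP_MAX={_fmt(rep.multithermal_tmax)}\n"
                f"opes_multithermal: OPES_EXPANDED ARG=ecv_mt.ene "
                f"PACE={config.multithermal_pace}"
            )
        printables = ",".join(list(main_labels) + sorted(emitted - set(main_labels)))
        lines.append(f"PRINT ARG={printables},*.bias STRIDE=500 FILE=COLVAR")
        (rep_dir / "plumed.dat").write_text("\n".join(lines) + "\n")
        (rep_dir / "gromacs.mdp.template").write_text(_mdp_template(config))

    n = config.ladder.n_replicas
    (out / "run.sh").write_text(
        "#!/bin/sh\n"
        "# Hamiltonian replica exchange across the ladder; exchanges every\n"
        f"# {config.exchange_stride} integration steps.\n"
        f"mpirun -np {n} gmx_mpi mdrun -multidir "
        + " ".join(f"replica_{k}" for k in range(n))
        + f" -plumed plumed.dat -replex {config.exchange_stride} -hrex\n"
    )
    config.to_yaml(out / "protocol.yaml")
    return out


def _mdp_template(config: ProtocolConfig) -> str:
    t = config.ladder.thermostat_temperature
    return (
        "; GROMACS template (running the MD engine is out of scope here)\n"
        "integrator               = md       ; leap-frog\n"
        "dt                       = 0.002    ; 2 fs\n"
        "constraints              = h-bonds  ; LINCS on hydrogen stretches\n"
        "coulombtype              = PME\n"
        "rvdw                     = 1.0\n"
        "tcoupl                   = V-rescale\n"
        f"ref_t                    = {t:g}\n"
        "pcoupl                   = C-rescale\n"
        "ref_p                    = 1.0\n"
    )
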