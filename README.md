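# oneopes

A desk-scale implementation of the OneOPES multi-replica enhanced-sampling
scheme and its absolute-binding-free-energy post-processing:

- **OPES Explore** bias engines (kernel-density target estimate, BARRIER-capped
  bias, wrapped kernels for periodic CVs) and **OPES MultiThermal**
  expanded-temperature biases on the potential energy.
- The **8-replica ladder**: a convergence replica carrying only the main bias
  on (z, COS), exploration replicas stacking weak MultiCV biases on hydration
  CVs and torsions, MultiThermal on the top four replicas, and Metropolis
  configuration exchanges between neighbors.
- **Collective variables**: funnel-axis projection, orientation cosine,
  rational-switching water-coordination numbers (with neighbor list), and
  torsions.
- **Toy systems** (1-D double well; 3-D binding pocket with a slow orthogonal
  hydration coordinate inside a funnel restraint) integrated with overdamped
  (BAOAB-limit) Langevin dynamics, where reference free energies are exact by
  Boltzmann quadrature.
- **Free-energy analysis**: COLVAR reweighting to G(z), the funnel-corrected
  standard-state binding free energy
  `dG = -kBT ln[C0 pi Rcyl^2 Int_bound exp(-(G-G_U)/kBT) dz]`,
  dual-funnel combination with the undersampled-side rule, and 3-block error
  estimation.
- **Benchmark metrics**: Kendall tau-b, linear-fit R^2/slope, MAE/ME/RMSE,
  with a vectorized percentile bootstrap (resample systems, optional Gaussian
  noise from per-system uncertainties).
- **Protocol emission**: byte-deterministic per-replica PLUMED-dialect input
  trees (plus a GROMACS .mdp template and replica-exchange run script) from a
  YAML protocol config.

Internal units are kJ/mol, nm, ps, K; binding free energies are reported in
kcal/mol at the interface boundaries.

## CLI

```sh
oneopes simulate-toy --system binding --steps 20000 --seed 1 --out run/
oneopes analyze run/COLVAR.0 --blocks 3 --out dg.json
oneopes metrics affinities.csv --n-iter 100000 --out metrics.json
oneopes emit-protocol --out protocol/           # published 8-replica default
oneopes emit-protocol --config my_protocol.yaml --out protocol/
```

`affinities.csv` columns: `id,predicted[,uncertainty],experimental`
(kcal/mol).

## Layout

```
src/oneopes/
  toy_systems.py          analytic potentials, funnel, Langevin, solvent
  collective_variables.py z / COS / coordination / torsion CVs
  opes_engines.py         OPES Explore + MultiThermal bias states
  oneopes_ladder.py       ladder assembly, exchanges, runner
  free_energy_analysis.py reweighting, dG_B, blocks, dual funnel
  benchmark_metrics.py    tau/R2/slope/MAE/ME/RMSE + bootstrap
  protocol_io.py          COLVAR I/O, YAML config, PLUMED emission
  cli.py                  command-line interface
```
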