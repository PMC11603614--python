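#!/bin/sh
# Hamiltonian replica exchange across the ladder; exchanges every
# 1000 integration steps.
mpirun -np 8 gmx_mpi mdrun -multidir replica_0 replica_1 replica_2 replica_3 replica_4 replica_5 replica_6 replica_7 -plumed plumed.dat -replex 1000 -hrex
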