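# PLUMED input for replica 0 of the OneOPES ladder.
# Funnel restraint composition: the ligand COM is projected on the funnel
# axis (fps.z) and radially (fps.rho); a half-harmonic UPPER_WALLS on
# rho - R(z) confines the guest to the cone+cylinder volume.  R(z) equals
# RCYL for z >= ZCC and widens with slope tan(ALPHA) below ZCC.

lig: COM ATOMS=1,2,3
fps: FUNNEL_PS LIGAND=lig REFERENCE=funnel_ref.pdb
z: COMBINE ARG=fps.lp PERIODIC=NO
lax: DISTANCE ATOMS=1,3 COMPONENTS
lnorm: DISTANCE ATOMS=1,3
COS: CUSTOM ARG=lax.z,lnorm FUNC=x/y PERIODIC=NO
funnel_rz: CUSTOM ARG=fps.z FUNC=x PERIODIC=NO
funnel_wall: CUSTOM ARG=fps.rho,funnel_rz FUNC=x-(step(1-y)*(0.6131052133*(1-y))+0.2) PERIODIC=NO
UPPER_WALLS ARG=funnel_wall AT=0.0 KAPPA=10000 LABEL=funnel_restraint
opes_main: OPES_METAD_EXPLORE ARG=z,COS BARRIER=100 PACE=10000 SIGMA=0.05,0.05
PRINT ARG=z,COS,*.bias STRIDE=500 FILE=COLVAR
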