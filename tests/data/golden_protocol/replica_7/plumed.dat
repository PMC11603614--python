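# PLUMED input for replica 7 of the OneOPES ladder.
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
WL4: COORDINATION GROUPA=4 GROUPB=@water-oxygens SWITCH={RATIONAL R_0=0.25 D_MAX=0.08 NN=6 MM=10} NLIST NL_CUTOFF=0.15 NL_STRIDE=20
WH1: COORDINATION GROUPA=101 GROUPB=@water-oxygens SWITCH={RATIONAL R_0=0.25 D_MAX=0.08 NN=2 MM=6} NLIST NL_CUTOFF=0.15 NL_STRIDE=20
WL1: COORDINATION GROUPA=1 GROUPB=@water-oxygens SWITCH={RATIONAL R_0=0.25 D_MAX=0.08 NN=6 MM=10} NLIST NL_CUTOFF=0.15 NL_STRIDE=20
WH3: COORDINATION GROUPA=103 GROUPB=@water-oxygens SWITCH={RATIONAL R_0=0.25 D_MAX=0.08 NN=2 MM=6} NLIST NL_CUTOFF=0.15 NL_STRIDE=20
WH8: COORDINATION GROUPA=108 GROUPB=@water-oxygens SWITCH={RATIONAL R_0=0.25 D_MAX=0.08 NN=2 MM=6} NLIST NL_CUTOFF=0.15 NL_STRIDE=20
WH5: COORDINATION GROUPA=105 GROUPB=@water-oxygens SWITCH={RATIONAL R_0=0.25 D_MAX=0.08 NN=2 MM=6} NLIST NL_CUTOFF=0.15 NL_STRIDE=20
WH10: COORDINATION GROUPA=110 GROUPB=@water-oxygens SWITCH={RATIONAL R_0=0.25 D_MAX=0.08 NN=2 MM=6} NLIST NL_CUTOFF=0.15 NL_STRIDE=20
funnel_rz: CUSTOM ARG=fps.z FUNC=x PERIODIC=NO
funnel_wall: CUSTOM ARG=fps.rho,funnel_rz FUNC=x-(step(1-y)*(0.6131052133*(1-y))+0.2) PERIODIC=NO
UPPER_WALLS ARG=funnel_wall AT=0.0 KAPPA=10000 LABEL=funnel_restraint
opes_main: OPES_METAD_EXPLORE ARG=z,COS BARRIER=100 PACE=10000 SIGMA=0.05,0.05
opes_multicv_1: OPES_METAD_EXPLORE ARG=WL4 BARRIER=3 PACE=20000 SIGMA=0.1
opes_multicv_2: OPES_METAD_EXPLORE ARG=WH1 BARRIER=3 PACE=20000 SIGMA=0.1
opes_multicv_3: OPES_METAD_EXPLORE ARG=WL1 BARRIER=3 PACE=20000 SIGMA=0.1
opes_multicv_4: OPES_METAD_EXPLORE ARG=WH3 BARRIER=3 PACE=20000 SIGMA=0.1
opes_multicv_5: OPES_METAD_EXPLORE ARG=WH8 BARRIER=3 PACE=20000 SIGMA=0.1
opes_multicv_6: OPES_METAD_EXPLORE ARG=WH5 BARRIER=3 PACE=20000 SIGMA=0.1
opes_multicv_7: OPES_METAD_EXPLORE ARG=WH10 BARRIER=3 PACE=20000 SIGMA=0.1
ene: ENERGY
ecv_mt: ECV_MULTITHERMAL ARG=ene TEMP_MIN=298 TEMP_MAX=370
opes_multithermal: OPES_EXPANDED ARG=ecv_mt.ene PACE=100
PRINT ARG=z,COS,WH1,WH10,WH3,WH5,WH8,WL1,WL4,*.bias STRIDE=500 FILE=COLVAR
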