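# Published per-residue MM-GBSA decomposition (kcal/mol) of chiglitazar
# binding to the PPARgamma ligand-binding domain.
residue	kcal_per_mol
ILE_262	-2.7
ILE_281	-1.1
PHE_282	-1.2
GLY_284	-2.6
CYS_285	-5.6
GLN_286	-3.8
PHE_287	-3.2
ARG_288	-5.1
SER_289	-1.9
HIS_323	-2.6
ILE_326	-4.3
TYR_327	-4.7
MET_329	-1.1
LEU_330	-4.3
LEU_333	-2.4
ILE_341	-9.6
SER_342	-4.3
GLU_343	-1.0
MET_348	-1.9
PHE_363	-1.0
LYS_367	-1.2
LEU_465	-1.7
LEU_469	-2.1
TYR_473	-1.1
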