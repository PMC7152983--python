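# Published per-residue MM-GBSA decomposition (kcal/mol) of chiglitazar
# binding to the PPARalpha ligand-binding domain.
residue	kcal_per_mol
ILE_241	-1.2
LEU_254	-1.5
VAL_255	-2.9
LEU_258	-2.9
PHE_273	-1.0
CYS_275	-2.6
CYS_276	-6.7
GLN_277	-1.4
THR_279	-4.7
SER_280	-3.2
THR_283	-3.0
ILE_317	-2.9
PHE_318	-1.8
LEU_321	-5.0
MET_330	-1.8
VAL_332	-8.7
ALA_333	-4.2
TYR_334	-3.6
ILE_339	-1.2
ILE_354	-1.5
MET_355	-1.8
LYS_358	-3.6
HIS_440	-1.6
VAL_444	-1.0
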