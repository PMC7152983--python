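# Published per-residue MM-GBSA decomposition (kcal/mol) of chiglitazar
# binding to the PPARbeta/delta ligand-binding domain.
residue	kcal_per_mol
VAL_245	-1.0
PHE_246	-2.4
ARG_248	-5.3
CYS_249	-4.9
GLN_250	-1.9
THR_252	-4.2
ILE_290	-1.6
PHE_291	-1.9
LEU_294	-4.7
ILE_297	-2.6
VAL_298	-1.4
LEU_303	-4.2
VAL_305	-7.8
ALA_306	-2.3
ILE_327	-1.6
LYS_331	-9.3
MET_416	-3.1
ILE_420	-1.2
LEU_429	-1.2
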