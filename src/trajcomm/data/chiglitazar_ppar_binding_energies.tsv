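# Published MM-GBSA binding-energy summaries (kcal/mol) for chiglitazar bound
# to the PPARalpha, PPARbeta/delta and PPARgamma ligand-binding domains.
# Means +/- SD over the analyzed trajectory window.
system	de_mean	de_sd	dvdw_mean	dvdw_sd	dlipo_mean	dlipo_sd	dgbele_mean	dgbele_sd
alpha	-138.0	7.3	-82.9	3.8	-67.5	3.0	12.4	4.8
beta	-135.9	5.3	-76.4	2.9	-71.9	2.4	12.4	2.3
gamma	-144.6	5.6	-87.9	3.0	-71.3	2.2	14.6	3.5
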