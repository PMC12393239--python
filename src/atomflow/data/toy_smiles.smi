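CC(=O)Nc1ccccc1 acetanilide
CC(=O)Nc1ccc(O)cc1 paracetamol
c1ccccc1 benzene
Oc1ccccc1 phenol
Cc1ccccc1 toluene
c1ccncc1 pyridine
c1cnc[nH]1 imidazole
c1ccoc1 furan
c1ccsc1 thiophene
c1cc[nH]c1 pyrrole
Nc1ccccc1 aniline
OC(=O)c1ccccc1 benzoic_acid
CCOC(C)=O ethyl_acetate
CC(N)=O acetamide
NCC(O)=O glycine
CC(N)C(O)=O alanine
CC(C)O isopropanol
CC(C)=O acetone
CC(O)=O acetic_acid
Fc1ccccc1 fluorobenzene
Clc1ccccc1 chlorobenzene
NC(=O)c1ccccc1 benzamide
COc1ccccc1 anisole
C=Cc1ccccc1 styrene
C1COCCN1 morpholine
C1CCNCC1 piperidine
C1CCCCC1 cyclohexane
C1CCOC1 tetrahydrofuran
c1cncnc1 pyrimidine
CN1CCCC1 n_methylpyrrolidine
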