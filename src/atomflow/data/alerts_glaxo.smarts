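# Glaxo Wellcome hard-filter collection (curated subset of the public
# Hann et al. reactive/unsuitable functional group set).
[Br,Cl,I][CX4;CH,CH2] reactive_alkyl_halide
[C,c](=O)[Cl,Br,I] acid_halide
[CX3H1](=O)[#6] carbonyl_aldehyde
C1OC1 epoxide
C1NC1 aziridine
O=CC=O glyoxal_dicarbonyl
[SX2][SX2] disulfide
[SX2][CX2]#[NX1] thiocyanate
S(=O)(=O)O[#6] sulfonate_ester
[#6][NX2]=[OX1] nitroso
[OX2][OX2H] hydroperoxide
O=C1CCN1 beta_lactam
[NX4+] quaternary_ammonium
[PX4] pentavalent_phosphorus
C=C[SX4](=O)(=O) vinyl_sulfone
[CX3](=O)[OX2][CX3](=O) acid_anhydride
[#16X2H0][#16X2H0] polysulfide
[NX3](=O)=O charged_free_nitro
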