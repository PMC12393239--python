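# Dundee structural-alert collection (curated subset of the public
# Brenk et al. filter set; SMARTS verified against RDKit).
[C,c](=O)[F,Cl,Br,I] acyl_halide
N=[N+]=[N-] azide
C1[O,N,S]C1 three_membered_heterocycle
[OX2][OX2] peroxide
N=C=O isocyanate
N=C=S isothiocyanate
S(=O)(=O)[F,Cl,Br,I] sulfonyl_halide
[N+](=O)[O-] nitro_group
C(=O)C(=O) alpha_diketone
C=[N+]=[N-] diazo
[N;R0]=[N;R0] acyclic_azo
[SX2H] thiol
C(=O)OC(=O) anhydride
[CX3H1](=O) aldehyde
[NX3;R0][NX3;R0] hydrazine
[CX3]=[SX1] thiocarbonyl
[NX3][OX2H1] hydroxylamine
[CX4;!$(C(F)(F)F)][Cl,Br,I] alkyl_halide
[CX3]=[CX3][CX3]=[OX1] michael_acceptor
[CX3;R0]=[NX2;R0] acyclic_imine
O=c1ccc2ccccc2o1 coumarin
[cX3][OX2][CX3](=O)[#6] phenol_ester
[CX3]=[NX2][OX2H1] oxime
[NX4+] quaternary_nitrogen
[N,O,S;R0][CH2;R0][N,O,S;R0] heteroatoms_separated_by_carbon
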