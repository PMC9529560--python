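# Starter reactive-functional-group substructure list (SMARTS  name), user-replaceable.
[CX3H1]=O  aldehyde
C(=O)[F,Cl,Br,I]  acyl_halide
C(=O)OC(=O)  anhydride
C1OC1  epoxide
C1NC1  aziridine
N=C=O  isocyanate
N=C=S  isothiocyanate
[CX4][F,Cl,Br,I]  alkyl_halide
[CX3]=[CX3][CX3]=O  michael_acceptor_enone
S(=O)(=O)[F,Cl,Br]  sulfonyl_halide
C(=O)OO  peroxyester
OO  peroxide
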