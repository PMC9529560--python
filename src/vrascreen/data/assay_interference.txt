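# Starter assay-interference substructure list (SMARTS  name), user-replaceable.
c1cc(O)c(O)cc1O  pyrogallol
c1cc(O)c(O)cc1  catechol
O=C1C=CC(=O)C=C1  para_quinone
O=C1C(=O)c2ccccc21  ortho_quinone_fused
S=C1SC(=O)N1  rhodanine_core
[N;!$(N-C=O)]=[N+]=[N-]  azide
N=Nc1ccccc1  azo_aryl
[OX2H][NX2]=C  oxime
C(=S)N  thioamide
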