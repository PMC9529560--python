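code,name,smiles,group_label,kind,pka
A,alanine,N[C@@H](C)C(=O)O,backbone_carboxyl,acid,2.34
A,alanine,N[C@@H](C)C(=O)O,backbone_amine,base,9.69
R,arginine,N[C@@H](CCCNC(=N)N)C(=O)O,backbone_carboxyl,acid,2.17
R,arginine,N[C@@H](CCCNC(=N)N)C(=O)O,backbone_amine,base,9.04
R,arginine,N[C@@H](CCCNC(=N)N)C(=O)O,side_guanidine,base,12.48
N,asparagine,N[C@@H](CC(N)=O)C(=O)O,backbone_carboxyl,acid,2.02
N,asparagine,N[C@@H](CC(N)=O)C(=O)O,backbone_amine,base,8.80
D,aspartic acid,N[C@@H](CC(=O)O)C(=O)O,backbone_carboxyl,acid,1.88
D,aspartic acid,N[C@@H](CC(=O)O)C(=O)O,backbone_amine,base,9.60
D,aspartic acid,N[C@@H](CC(=O)O)C(=O)O,side_carboxyl,acid,3.65
C,cysteine,N[C@@H](CS)C(=O)O,backbone_carboxyl,acid,1.96
C,cysteine,N[C@@H](CS)C(=O)O,backbone_amine,base,10.28
C,cysteine,N[C@@H](CS)C(=O)O,side_thiol,acid,8.18
E,glutamic acid,N[C@@H](CCC(=O)O)C(=O)O,backbone_carboxyl,acid,2.19
E,glutamic acid,N[C@@H](CCC(=O)O)C(=O)O,backbone_amine,base,9.67
E,glutamic acid,N[C@@H](CCC(=O)O)C(=O)O,side_carboxyl,acid,4.25
Q,glutamine,N[C@@H](CCC(N)=O)C(=O)O,backbone_carboxyl,acid,2.17
Q,glutamine,N[C@@H](CCC(N)=O)C(=O)O,backbone_amine,base,9.13
G,glycine,NCC(=O)O,backbone_carboxyl,acid,2.34
G,glycine,NCC(=O)O,backbone_amine,base,9.60
H,histidine,N[C@@H](Cc1c[nH]cn1)C(=O)O,backbone_carboxyl,acid,1.82
H,histidine,N[C@@H](Cc1c[nH]cn1)C(=O)O,backbone_amine,base,9.17
H,histidine,N[C@@H](Cc1c[nH]cn1)C(=O)O,side_imidazole,base,6.00
I,isoleucine,N[C@@H]([C@@H](C)CC)C(=O)O,backbone_carboxyl,acid,2.36
I,isoleucine,N[C@@H]([C@@H](C)CC)C(=O)O,backbone_amine,base,9.68
L,leucine,N[C@@H](CC(C)C)C(=O)O,backbone_carboxyl,acid,2.36
L,leucine,N[C@@H](CC(C)C)C(=O)O,backbone_amine,base,9.60
K,lysine,N[C@@H](CCCCN)C(=O)O,backbone_carboxyl,acid,2.18
K,lysine,N[C@@H](CCCCN)C(=O)O,backbone_amine,base,8.95
K,lysine,N[C@@H](CCCCN)C(=O)O,side_amine,base,10.53
M,methionine,N[C@@H](CCSC)C(=O)O,backbone_carboxyl,acid,2.28
M,methionine,N[C@@H](CCSC)C(=O)O,backbone_amine,base,9.21
F,phenylalanine,N[C@@H](Cc1ccccc1)C(=O)O,backbone_carboxyl,acid,1.83
F,phenylalanine,N[C@@H](Cc1ccccc1)C(=O)O,backbone_amine,base,9.13
P,proline,N1CCC[C@H]1C(=O)O,backbone_carboxyl,acid,1.99
P,proline,N1CCC[C@H]1C(=O)O,backbone_amine,base,10.96
S,serine,N[C@@H](CO)C(=O)O,backbone_carboxyl,acid,2.21
S,serine,N[C@@H](CO)C(=O)O,backbone_amine,base,9.15
T,threonine,N[C@@H]([C@@H](C)O)C(=O)O,backbone_carboxyl,acid,2.11
T,threonine,N[C@@H]([C@@H](C)O)C(=O)O,backbone_amine,base,9.62
W,tryptophan,N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O,backbone_carboxyl,acid,2.38
W,tryptophan,N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O,backbone_amine,base,9.39
Y,tyrosine,N[C@@H](Cc1ccc(O)cc1)C(=O)O,backbone_carboxyl,acid,2.20
Y,tyrosine,N[C@@H](Cc1ccc(O)cc1)C(=O)O,backbone_amine,base,9.11
Y,tyrosine,N[C@@H](Cc1ccc(O)cc1)C(=O)O,side_phenol,acid,10.07
V,valine,N[C@@H](C(C)C)C(=O)O,backbone_carboxyl,acid,2.32
V,valine,N[C@@H](C(C)C)C(=O)O,backbone_amine,base,9.62
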