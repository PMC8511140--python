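O	water
CO	methanol
CCO	ethanol
CCCO	1-propanol
CC(C)O	2-propanol
CCCCO	1-butanol
CC(C)=O	acetone
CCC(C)=O	butanone
CC#N	acetonitrile
ClC(Cl)Cl	chloroform
ClCCl	dichloromethane
ClC(Cl)(Cl)Cl	tetrachloromethane
CCOCC	diethyl-ether
C1CCOC1	tetrahydrofuran
C1COCCO1	1,4-dioxane
CN(C)C=O	N,N-dimethylformamide
CN(C)C(C)=O	N,N-dimethylacetamide
CS(C)=O	dimethylsulfoxide
CCOC(C)=O	ethyl-acetate
COC(C)=O	methyl-acetate
Cc1ccccc1	toluene
c1ccccc1	benzene
c1ccncc1	pyridine
CCCCCC	n-hexane
CCCCC	n-pentane
CCCCCCC	n-heptane
C1CCCCC1	cyclohexane
OCCO	ethylene-glycol
C[N+](=O)[O-]	nitromethane
OC=O	formic-acid
CC(O)=O	acetic-acid
CN1CCCC1=O	N-methyl-2-pyrrolidone
COCCOC	1,2-dimethoxyethane
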