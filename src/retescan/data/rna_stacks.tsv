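# Nearest-neighbor RNA:RNA helix parameters, delta-G at 37 C (kcal/mol).
# Watson-Crick stacks: Xia et al. 1998; GU wobble stacks: Mathews et al. 1999.
# Step notation XY/ZW: top strand 5'-XY-3' over bottom strand 3'-ZW-5',
# i.e. base pairs X:Z then Y:W. Symmetric entries are derived by the loader.
step	kcal_per_mol
AA/UU	-0.93
AU/UA	-1.10
UA/AU	-1.33
AC/UG	-2.24
AG/UC	-2.08
CA/GU	-2.11
GA/CU	-2.35
CG/GC	-2.36
CC/GG	-3.26
GC/CG	-3.42
AG/UU	-0.55
AU/UG	-1.36
CG/GU	-1.41
CU/GG	-2.11
GG/CU	-1.53
GU/CG	-2.51
UG/AU	-1.00
UU/AG	-1.27
GG/UU	-0.50
GU/UG	1.29
UG/GU	0.30
init	4.09
terminal_au	0.45
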