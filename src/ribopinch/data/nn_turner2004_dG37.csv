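# Nearest-neighbor RNA free-energy parameters, dG37 (kcal/mol)
# Provenance: Turner 2004 parameter set (ViennaRNA 2.7 reference energies);
# Watson-Crick stacks agree with Xia et al. 1998 to rounding (0.1 kcal/mol).
# step notation: top(5'->3')/bottom(5'->3'), antiparallel alignment.
kind,key,dG37_kcal
init,,4.10
terminal_au,,0.50
hairpin_loop,3,5.40
hairpin_loop,4,5.60
hairpin_loop,5,5.70
hairpin_loop,6,5.40
hairpin_loop,7,6.00
hairpin_loop,8,5.50
hairpin_loop,9,6.40
stack,AA/UU,-0.90
stack,AC/GU,-2.20
stack,AG/CU,-2.10
stack,AG/UU,-0.60
stack,AU/AU,-1.10
stack,AU/GU,-1.40
stack,CA/UG,-2.10
stack,CC/GG,-3.30
stack,CG/CG,-2.40
stack,CG/UG,-1.40
stack,CU/AG,-2.10
stack,CU/GG,-2.10
stack,GA/UC,-2.40
stack,GA/UU,-1.30
stack,GC/GC,-3.40
stack,GC/GU,-2.50
stack,GG/CC,-3.30
stack,GG/CU,-2.10
stack,GG/UC,-1.50
stack,GG/UU,-0.50
stack,GU/AC,-2.20
stack,GU/AU,-1.40
stack,GU/GC,-2.50
stack,GU/GU,1.30
stack,UA/UA,-1.30
stack,UA/UG,-1.00
stack,UC/GA,-2.40
stack,UC/GG,-1.50
stack,UG/CA,-2.10
stack,UG/CG,-1.40
stack,UG/UA,-1.00
stack,UG/UG,0.30
stack,UU/AA,-0.90
stack,UU/AG,-0.60
stack,UU/GA,-1.30
stack,UU/GG,-0.50
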