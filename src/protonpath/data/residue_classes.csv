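# Residue polarity classes for channel-lining analysis.  "titratable"
# takes precedence over "polar" for residues that are both (Asp, Glu,
# Lys, Arg, His, Cys, Tyr); these are the residues removed from the
# obstacle set when the gate-free channel radius profile is evaluated.
residue_name,cls
ALA,nonpolar
VAL,nonpolar
LEU,nonpolar
ILE,nonpolar
PRO,nonpolar
PHE,nonpolar
MET,nonpolar
TRP,nonpolar
GLY,nonpolar
SER,polar
THR,polar
ASN,polar
GLN,polar
ASP,titratable
GLU,titratable
LYS,titratable
ARG,titratable
HIS,titratable
HSD,titratable
HSE,titratable
HSP,titratable
CYS,titratable
TYR,titratable
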