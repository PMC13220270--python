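# Element van der Waals radii (Å), Bondi (1964) set; fallback used when an
# atom is not listed in a user-supplied charge/radius table.
element,vdw_radius
H,1.20
C,1.70
N,1.55
O,1.52
F,1.47
P,1.80
S,1.80
CL,1.75
BR,1.85
I,1.98
NA,2.27
K,2.75
MG,1.73
CA,2.31
FE,2.00
ZN,1.39
MN,2.00
CU,1.40
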