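# Most-abundant-isotope masses (Da), IUPAC/CODATA values.
# element	mass
H	1.0078250319
C	12.0000000000
N	14.0030740052
O	15.9949146221
F	18.9984031630
Na	22.9897692820
Mg	23.9850416980
Si	27.9769265350
P	30.9737619984
S	31.9720711744
Cl	34.9688527100
K	38.9637064864
Ca	39.9625909100
Fe	55.9349363300
Zn	63.9291420100
Br	78.9183376000
I	126.9044719000
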