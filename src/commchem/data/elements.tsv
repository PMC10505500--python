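# Standard average (not monoisotopic) atomic masses, g/mol.
element	mass
C	12.011
H	1.008
N	14.007
O	15.999
S	32.06
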