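# Ionization constants for polypeptide terminal groups (one amino and one
# carboxyl terminus per chain). Generic N-terminal pK, not residue-specific.
group	pk	pk_class
Nterm	7.5	base
Cterm	3.55	acid
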