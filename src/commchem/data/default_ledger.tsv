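# Default manual-mapping ledger: reconciles classifier taxon names with
# reference-database taxon names when automatic rank+name matching fails.
# Rules are applied in file order; the first rule whose source matches wins.
# Supply your own ledger at run time to extend or replace these.
source_rank	source_name	target_rank	target_name	note
genus	Escherichia/Shigella	genus	Escherichia	RDP pools the two genera; reference databases keep them separate
genus	Clostridium sensu stricto	genus	Clostridium	RDP qualifier absent from reference names
genus	Marinimicrobia_genera_incertae_sedis	phylum	Marinimicrobia	unplaced genus mapped to its phylum-level reference
class	Cyanobacteria	phylum	Cyanobacteria	RDP places Cyanobacteria at class rank
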