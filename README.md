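# commchem

Chemical metrics of **community reference proteomes** from 16S rRNA
amplicon data.

Microbial community composition can be re-expressed in chemical terms:
combine the taxonomic classification of each sample (who is there, and in
what abundance) with precomputed amino-acid compositions of per-taxon
reference proteomes, and you obtain an abundance-weighted *community
reference proteome* — the expected composition of one protein drawn from
the community's genomes. Chemical metrics of that composition track
genomic adaptation to the environment: the carbon oxidation state of
proteins tends to be higher in communities from oxidizing settings, and
the stoichiometric hydration state responds to factors such as salinity.
`commchem` is for microbial ecologists and geobiologists who want those
variables from standard amplicon-pipeline outputs without touching genome
databases at analysis time.

## The metrics

For a composition C_c H_h N_n O_o S_s with formal charge Z and `n`
residues:

- **Zc** = (Z − h + 3n + 2o + 2s) / c — average carbon oxidation state;
- **nO2, nH2O** — per-residue O2 and H2O coefficients of the unique
  decomposition in the QEC basis (glutamine, glutamic acid, cysteine,
  H2O, O2): the stoichiometric oxidation and hydration state;
- elemental ratios **H/C, N/C, O/C, S/C**;
- **length** (residues/chain) and **MW** (mean residue mass, g/mol);
- **GRAVY** (Kyte–Doolittle hydropathy mean) and **pI** (isoelectric
  point, ProtParam-style charge model).

See `docs/methods.md` for conventions (terminal water, pK set,
aggregation rules) and numerical details.

## Inputs

1. RDP Classifier hierarchical count files (cumulative counts per taxon
   node, one column per sample);
2. generic OTU/ASV count + taxonomy tables (TSV/CSV, one rank per column,
   empty = unassigned) as exported from DADA2/QIIME-style pipelines;
3. protein FASTA files plus GTDB-style taxonomy strings
   (`d__...;p__...;...;s__...`) for *building* per-taxon reference
   databases;
4. the package's per-taxon reference proteome TSV (rank, name, n_genomes,
   n_proteins, Ala..Val).

Classified reads are reduced to lowest-level counts (each read counted
once, at its deepest rank from genus up to phylum), nonprokaryotic
lineages (Chloroplast, Mitochondria, Eukaryota) are filtered, and taxa
are matched to the reference database by exact rank + name with an
auditable manual-mapping ledger for the stragglers. Unmapped reads are
never redistributed; their percentages are reported.

## Worked example

Generate a synthetic dataset with known ground truth (12 genera in 3
phyla, 4 samples of 1000 reads, 5% of reads assigned to a genus that is
absent from the reference database), then compute metrics:

```sh
commchem simulate --seed 6 --unmapped-fraction 0.05 -o demo
commchem metrics --rdp demo/rdp.tsv --refdb demo/refdb.tsv -o demo/metrics.tsv
```

The log reports the mapping audit:

```
read 16 lowest-level taxa from demo/rdp.tsv (4 samples); dropped 0.0 domain-level and 0.0 filtered reads
unmapped: (genus) Unmappedium — 5.00% of reads
overall unmapped: 5.00% of reads
wrote metrics for 4 samples to demo/metrics.tsv
```

and `demo/metrics.tsv` holds the three default metrics per sample:

```
sample	Zc	nO2	nH2O
sample1	-0.11535981520275489	-0.7299261861393158	-1.1957811248016912
sample2	-0.08867639898243897	-0.6824012276541617	-1.2088826052597366
sample3	-0.11707599812575353	-0.709174346383085	-1.0935984212023826
sample4	-0.13421582118078637	-0.7769889143438322	-1.242321496409585
```

Zc near −0.1 means the average protein carbon is slightly reduced;
sample2's higher Zc marks the most oxidized community proteome of the
four, and nH2O (waters released per residue when the composition is
formed from the basis species) varies independently of it. Plot facets or
metric pairs with:

```sh
commchem plot --metrics-table demo/metrics.tsv --metrics Zc,nH2O --x sample -o facets.png
commchem plot --metrics-table demo/metrics.tsv --pair Zc nH2O -o pair.svg
```

The same works from OTU/taxonomy tables (`--otu`/`--tax`), and
`commchem build-refdb` turns protein FASTAs + taxonomy strings into a
reference TSV. Every command is a thin wrapper over library functions
(`commchem.read_rdp_hierarchy`, `map_taxa`, `get_metrics`, ...) that can
be used directly from Python.

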