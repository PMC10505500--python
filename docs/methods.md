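# Methods

## What the package computes

`commchem` turns taxonomic classifications of 16S rRNA amplicon data into
*community reference proteomes* and characterizes them with chemical
metrics. The community reference proteome of a sample is the
abundance-weighted mean of the per-taxon reference amino-acid compositions
of the taxa detected in it:

    aa_community = Σ_t w_t · aa_t / Σ_t w_t

where `w_t` are the mapped lowest-level read counts and `aa_t` is the mean
composition of one protein from taxon *t*'s reference genomes. This is an
*inferred* proteome: it describes the genomes present, not protein
expression, and metrics derived from it are indicators of genomic — not
transcriptional — adaptation.

## Chemical metrics

All metrics operate on an amino-acid composition (fractional counts
allowed, plus a number of polypeptide chains) and are intensive: scaling
counts and chains together changes nothing, so the same code serves single
proteins and community means.

**Carbon oxidation state.** For an elemental composition C_c H_h N_n O_o
S_s with formal charge Z,

    Zc = (Z − h + 3n + 2o + 2s) / c .

Zc is invariant to adding or removing whole waters, so the terminal-water
convention cannot affect it (asserted exactly in the tests).

**Stoichiometric oxidation and hydration state.** Any CHNOS composition has
a unique decomposition in a basis of five species; the default "QEC" basis
is glutamine (C5H10N2O3), glutamic acid (C5H9NO4), cysteine (C3H7NO2S),
H2O and O2. The five basis coefficients solve the 5×5 element-balance
system (one `numpy.linalg.solve` call; the basis matrix is checked for
nonsingularity at construction). `nH2O` and `nO2` are the water and
dioxygen coefficients per residue. Worked example, frozen into the tests:
the glycine residue C2H3NO decomposes as 0.6 Gln − 0.2 Glu − 0.6 H2O +
0.3 O2, so nH2O = −0.6 and nO2 = 0.3.

**Elemental ratios, length, MW.** H/C, N/C, O/C, S/C come from the same
elemental composition; `length` is residues per chain; `MW` is the mean
residue mass from standard average (not monoisotopic) atomic masses
(Gly residue 57.052 g/mol).

**GRAVY and pI.** GRAVY is the count-weighted mean of the published
20-value Kyte–Doolittle hydropathy scale. The isoelectric point uses a
Bjellqvist-style pK set (C-terminus 3.55, Asp 4.05, Glu 4.45, His 5.98,
N-terminus 7.5 generic, Cys 9.0, Tyr 10.0, Lys 10.0, Arg 12.0) with net
charge

    Q(pH) = Σ_basic n_i / (1 + 10^(pH − pK_i)) − Σ_acidic n_i / (1 + 10^(pK_i − pH)) ,

which is strictly decreasing in pH, so the root on [0, 14] is unique.

All constants live in plain-text TSVs under `src/commchem/data/` and can
be audited or swapped without code changes.

## Conventions and tunable parameters

- **Terminal water** (`include_terminal_water`, default off): elemental
  ratios, nH2O and MW use residue formulas (free amino acid minus H2O) by
  default, matching the per-residue framing of the metrics; the flag adds
  one H2O per chain for intact-polypeptide formulas. nH2O shifts by exactly
  one water per residue-normalizing unit; Zc and nO2 are unaffected.
- **Termini in pI** (`chains`): a community composition has no defined
  first residue, so the generic N-terminal pK is used and `chains` sets how
  many termini pairs the charge model sees. With fractional community
  compositions (chains = 1 per mean protein) termini are included by
  default; set `chains=0` to model side chains only.
- **pI bisection** converges the pH bracket below 1e−7 (under 30
  iterations, hard cap 100). Only the *sign* of Q is consulted, so pI is
  exactly invariant under count scaling; an absolute charge threshold
  would not be, since Q scales with the counts. For length-100
  compositions the residual |Q| at the returned pH is far below 1e−4. A
  composition whose charge does not change sign on [0, 14] returns the
  nearer boundary.
- **Nonstandard residues** (B, Z, X, U, ...) are rejected with the
  offending code named, never silently dropped: reference compositions are
  curated, and silent drops would bias every metric.
- **Lowest retained rank** (`lowest_rank`, default genus; `keep_species`
  flag): cumulative hierarchy counts are decomposed so each read is counted
  once at its deepest retained rank; ranks below the cutoff are collapsed
  upward (a species' reads stay in its genus), not discarded.
- **Filter terms** (default Chloroplast, Mitochondria, Eukaryota): exact,
  case-sensitive lineage-name matches; rows whose lineage contains a term
  are removed entirely and tallied, extensible per call.
- **Mapping** is exact on (rank, name) after whitespace trimming. The
  manual-mapping ledger (TSV: source_rank, source_name, target_rank,
  target_name, note) is the only escape hatch; rules are applied only when
  the automatic match fails, first matching rule wins, and run-time rules
  override the packaged defaults. A rule may change rank (e.g. an unplaced
  genus mapped to a family-level reference). Unmapped rows are excluded
  from aggregation — never redistributed — and count-weighted unmapped
  percentages (overall, per sample, per taxon) make the loss visible.
- **Reference aggregation** (`weight_by_proteins`, default off): a taxon's
  composition is the unweighted mean of its member genomes' per-genome mean
  compositions, so heavily sequenced lineages do not dominate; the flag
  switches to protein-count weighting (total residues over total
  proteins). Reference entries are stored per protein (chains = 1), which
  keeps community length and MW interpretable as per-protein expectations.

## Synthetic fixtures

The generators in `commchem.simulate` emulate the four input kinds
(reference TSV, RDP hierarchical file, OTU + taxonomy tables, protein
FASTA via the builder tests) with ground truth computed *by construction*:
expected lowest-level counts, unmapped percentages and per-sample Zc, nO2,
nH2O are produced by straight-line array arithmetic
(`simulate.independent_metrics`) that shares only the constants TSVs with
the main chemistry code. Genus compositions are Dirichlet(1)-random over
the 20 amino acids at mean length 300 (SD 30), spanning a realistic
community Zc range (about −0.3 to 0) without encoding any real taxon;
abundances are log-normal; default fixtures use 1000 reads per sample
across 3 phyla × 4 genera, allocating 10% of mapped reads at phylum level
and configurable unmapped/filtered slices by largest-remainder rounding.

What the fixtures deliberately do not model: sequencing or classifier
error (a fixture read's taxon is exact), chimeras, rank inconsistencies
between classifier and reference taxonomies, or realistic amino-acid
covariance structure. Passing the fixture suite therefore demonstrates
that parsing, decomposition, mapping, aggregation and the metric algebra
are correct — not that real classifier output maps completely; on real
data the unmapped report and the ledger are the tools for that gap.

## Numerical choices and degenerate inputs

- Counts are floats throughout; rarefied or otherwise fractional tables
  are first-class.
- Cumulative-count violations (children exceeding a parent) raise a
  `MalformedHierarchyError` naming the node; residual negatives within
  1e−9 are clipped to zero.
- A sample with no mapped, nonzero counts is omitted from the metrics
  table with a warning rather than aborting the run; asking for its
  composition directly raises `EmptyCommunityError`.
- Element-balance reconstruction of the basis projection is exact to
  better than 1e−9 (asserted over random compositions).
- Plot helpers render with the Agg backend and return figures whose point
  coordinates equal the metrics table to 1e−12; no silent transformation.

## Known limitations

- Reference databases must be built (or supplied) locally; nothing is
  downloaded, and the packaged default ledger is a small starter set, not
  a complete classifier-to-reference reconciliation.
- Thermodynamic stability modeling is out of scope: the package stops at
  compositional metrics.
- The pI model ignores charged-residue interactions and N-terminal residue
  identity (generic N-terminus pK only).
- Only the fixed RDP hierarchical dialect described above is parsed;
  other classifier export flavors should go through the OTU/taxonomy-table
  route.
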