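# Methods

`legfam` re-implements, as a tested library, the workflow of a genome-wide
gene-family survey: identify every AP2/ERF-superfamily and HSP90 gene in a
set of annotated proteomes, classify them to subfamily and phylogenetic
subgroup, characterise their gene structure, duplication history and
cross-species orthology, and profile their expression.  Because the real
survey inputs are multi-hundred-megabase genome assemblies, the package
ships a synthetic-genome generator that emulates those inputs at desk
scale with a machine-readable truth table, so every stage can be scored
against planted ground truth.

## Domain detection

Domains (AP2, B3, HATPase_c, HSP90) are found with an ungapped per-column
log-odds profile (PSSM) slid along the protein.  The score of residue *a*
at column *c* is `log2((n_a + k*q_a) / (n + k) / q_a)` with pseudocount
weight `k = 1` and Robinson–Robinson background frequencies `q`; columns
with more than 50% gaps in the seed alignment are dropped; `X` scores 0.
Windows at or above the profile threshold are reported; overlapping
same-domain windows resolve to the highest score, ties to the leftmost.

Ungapped scanning is a deliberate simplification: the pipeline needs
presence/absence, coordinates and the residues at canonical domain
positions, not remote-homology sensitivity.  Gapped sensitivity is
available through the optional `hmmscan` backend (profile HMMs built from
the same seed alignments) and a BLASTP mining backend at e ≤ 1e-5; both
return the same unified hit records and agree with the internal scanner on
the bundled fixtures.

Thresholds are calibrated per profile as the score exceeded by fewer than
0.1% of 10^5 random background windows, floored at 10 bits so the
threshold stays positive for informative profiles (the raw 99.9% quantile
of background scores is deeply negative, and 10 bits still corresponds to
a vanishing false-discovery rate).  Calibration is deterministic per
domain name.

**Seed alignments.** The bundled seed alignments are *synthetic* stand-ins
for the curated domain families they emulate (filenames carry
`.synthetic.`).  Each is a consensus plus seven variants in which every
column also carries one designated alternative residue in two of eight
rows.  That construction gives every column a well-supported second
residue, so a genuinely divergent family member — the "soloist" case —
can score positively against the profile while sharing under 30% identity
with the consensus.  The AP2 consensus is laid out on the canonical
58-position frame of the AP2 DNA-binding domain: position 14 (A in ERF,
V in DREB), position 19 (D/E), the WLG element at 27–29 and the RAYD
element at 39–42.

## Classification decision tree

* ≥1 AP2 domain → AP2/ERF superfamily; HATPase_c + HSP90 domains → HSP90
  family; both (pathological) → AP2/ERF with a warning flag.
* AP2 + B3 → RAV; two AP2 domains → AP2 subfamily; one AP2 domain with
  best identity < 30% against the bundled ERF reference set → soloist;
  otherwise the ERF subfamily sensu lato.
* ERF vs DREB by the residues at canonical positions 14 and 19 of the
  AP2 domain: V14 → DREB irrespective of position 19 (position-14
  primacy, reflecting its dominant role in DNA-binding specificity to the
  DRE element); A14 → ERF, flagged when position 19 is not D; anything
  else → unresolved (and flagged when the positions cannot be mapped).
  Keeping A14/non-D19 in ERF keeps the tree total; the flag preserves
  auditability.
* The soloist cutoff (30% identity over the domain) is a package choice —
  the criterion in the literature is only "low homology"; it is
  configurable (`soloist_identity_cutoff`).
* CRF signatures for ERF/DREB proteins: the core ATDxSS searched
  N-terminal of the AP2 domain, and SP[T/V]SVL searched in the C-terminal
  third of the protein.  "C-terminal third" is a package decision; the
  literature does not delimit the region.
* WLG/YLG and RAYD/RAHD are exact-string states within the domain; the
  EAR repression motif is scanned as either published form ([L/D]xLxL or
  DLNxxP) and flagged as heuristic, since the motif is named but not
  defined as a regular expression in the surveys that report it.

Physico-chemical properties use bundled tables: average residue masses
(ExPASy) plus one water for MW, and the EMBOSS pKa set with bisection on
the net-charge curve (tolerance 0.01 pH) for pI.

### Table-style tallies

`tally` reproduces the summary-table arithmetic of family surveys: DREB
total = ΣA1..A6, ERF-subfamily total = DREB + ΣB1..B6, family total =
ERF-subfamily + AP2 + ANT + RAV + soloist, percentage of genome genes and
genes per Mb to two decimals.  These identities are exercised against the
printed five-legume counts in the acceptance suite.

## Phylogeny

Distances are p-distances with pairwise deletion (gap-containing sites
excluded per pair).  Trees are Saitou–Nei neighbour joining; negative
branch lengths are clamped to zero with the deficit moved to the sister
branch, preserving the joined pair's path length.  Ties in the
Q-criterion are broken first by smaller pairwise distance — so identical
taxa agglomerate before being attached to other clusters, which matters
on noise-free fixtures where whole subgroups are sequence-identical —
then by taxon name.  Bootstrap resamples alignment columns with
replacement and reports, per original internal split, the percentage of
replicate trees containing it (default 5000 replicates to mirror survey
practice; tests and examples use 100, a scale choice, not an algorithmic
one).

Subgroup assignment is clade-based: a query takes the label of a
monophyletic group (either side of an internal edge at support ≥ 50%)
containing it and references of exactly one subgroup; among qualifying
clades, the one whose in-clade reference is nearest to the query by path
length wins, then the smallest.  The distance preference resolves the
arbitrary local branching order among sequence-identical taxa.  Reference
taxa for A1–A6, B1–B6, AP2 and ANT are constructed in
`legfam.references` from the bundled AP2 consensus (subgroup-specific
substitutions at positions away from the conserved landmarks; the ANT
reference carries the WLG→YLG conversion observed in the AP2 subfamily).
Single-AP2-domain genes that land in the AP2/ANT reference clade are
re-labelled AP2/ANT by the pipeline, overriding the domain-count call —
the same correction surveys apply when single-domain genes cluster with
AP2 sequences.

## Gene structure

Intron count is exon count − 1 on the coding exons of the longest-CDS
isoform (UTR introns are not counted; the phase definition references
codons, so CDS-only counting is the consistent choice).  The phase of
intron *i* is the number of coding nucleotides 5′ of it modulo 3 (0 after
a complete codon, 1 after one nucleotide, 2 after two), traversed in
transcription order so plus- and minus-strand genes behave identically.
Paralog structure comparison is by intron-count equality, with the phase
string reported as auxiliary evidence.

## Duplication and orthology

Pairwise alignment is Smith–Waterman (BLOSUM62, gap open 11 / extend 1)
with identity measured over aligned non-gap columns, and e-values from
the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the documented gapped
BLOSUM62 constants (λ = 0.267, K = 0.041), so expectation values are
reproducible without a database.

Duplication events are unordered pairs at identity ≥ 80% and e ≤ 1e-10,
classed tandem when on one chromosome within 5 Mb (start-to-start) and
segmental otherwise, including cross-chromosome pairs.  One filter is
added beyond the survey thresholds: the alignment must cover ≥ 70% of the
longer protein.  Without it, any two family members sharing a
near-identical 58-residue DNA-binding domain satisfy both thresholds
through a domain-only local alignment, and "duplication" would collapse
into "family membership"; the coverage requirement restricts the call to
whole-gene duplications, which is what the planted-pair truth (and the
survey's sparse duplication counts) describe.

Orthologs are best bidirectional hits: a cross-species pair is emitted
iff each protein is the other's highest-scoring hit at e ≤ 1e-10, ties
broken by lower e-value then subject id.  The pair set is symmetric under
argument swap.  When only part of a proteome has true orthologs, BBH can
pair ortholog-less co-family members across species (they are genuinely
each other's closest relatives in that case); the exact-recovery checks
therefore plant orthologs for every gene.

## Expression

FPKM[g,s] = counts[g,s] / (length_kb[g] · mapped[s]/10^6).  Heatmap
preparation is log10(FPKM + 1) — the +1 offset is the package's choice
for zeros — ordered by average-linkage hierarchical clustering (Euclidean
by default; correlation available).  The 2^−ΔΔCt calculator averages
replicate Ct values on the Ct scale, takes ΔCt = Ct_target −
Ct_endogenous, references the calibrator condition, and returns 2^−ΔΔCt
per gene and condition.

## The synthetic-genome generator

The generator's defaults are the study conditions it emulates: five
species (species 1 plays the chickpea-like reference), 160 genes per
species mixed pro rata to the chickpea family table (76 ERF, 43 DREB,
14 AP2, 10 ANT, 2 RAV, 2 soloist, 5 HSP90, 8 background), eight
chromosomes of 60 Mb (desk-scale stand-ins for ~50–90 Mb pseudomolecules),
subgroup sampling weighted by the chickpea subgroup counts, intron-count
distributions following the published per-subfamily tallies (e.g. 53/79
ERFs intronless, 41/43 DREBs intronless, AP2 genes 6–11 introns), an 80%
E19 majority among DREBs, CRFs planted in 10% of ERF genes with 37.5% of
those carrying the C-terminal motif, two tandem plus eleven segmental
duplication events in the reference species, and a 65% ortholog fraction
(about 100 of 147 chickpea family genes have orthologs in each relative).
Copies diverge at 5% per site with the label-defining residues
(positions 14/19 of planted AP2 domains) exempt, so the planted truth
label remains the truth of the copy.

Proteins are assembled from the archetype domain sequences of
`legfam.references` plus random background flanks; genes are placed on
chromosomes without overlap by rejection sampling (a capacity error is
raised when they cannot fit); intron positions are uniform over the CDS
with recorded phases; strands are random, with minus-strand models
emitted in transcription order.  Expression counts are negative-binomial
around block-structured means (stress-responsive block = DREB + HSP90
genes, induced `fold_separation`-fold in stressed samples while the other
block is repressed; dispersion 0.05, base-abundance log-sd 0.4,
fold separation 8); dispersion 0 returns the exact means as a noise-free
limit.  Ct tables are constructed so 2^−ΔΔCt inverts them exactly at zero
noise.  All randomness flows from one integer seed through a single PCG64
stream; a fixed seed reproduces FASTA/GFF3/truth files byte for byte.

What the generator does *not* emulate: real codon usage and nucleotide
sequence (genes exist only as coordinates plus protein sequence),
alignment gaps within domains (planted domains are ungapped), selection,
UTRs and alternative splicing, read-level RNA-seq, and realistic
inter-gene homology gradients (non-homologous flanks are random, so
background discrimination is easier than in real proteomes).  Passing
recovery tests therefore demonstrates internal correctness of each stage
and of the pipeline's plumbing — not detection performance on real
genomes, where domain divergence, fragmented gene models and assembly
artefacts dominate.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (GFF3 convention),
  including on proteins.
* Profile threshold floor 10 bits; calibration 10^5 windows, 99.9%
  quantile, deterministic per domain name.
* pI bisection tolerance 0.01 pH on [0, 14].
* NJ tie-breaks: smaller distance, then lexicographic representative
  names; bootstrap replicates that lose all comparable sites for some
  pair are skipped (counted against support).
* The longest-CDS isoform represents multi-mRNA genes; the surveys do not
  state isoform handling.
* `threads` is accepted for interface parity and does not affect results;
  computations are single-threaded.
* Problem sizes in tests and the acceptance script (50–500 genes, 10
  seeds, 100 bootstrap replicates) were chosen as the smallest fixtures
  that exercise every planted signal category with comfortable
  statistical margins.

## Known limitations

* The ungapped scanner will miss domains with internal indels relative to
  the profile; use the `hmmscan` backend for gapped sensitivity.
* E-values rely on fixed Karlin–Altschul constants rather than
  sequence-composition-corrected estimates; rankings (and hence BBH) are
  unaffected, absolute e-values near a cutoff may differ from BLAST's.
* Clade-based subgroup assignment needs the reference taxa in the tree
  and degrades to None (flagged) for queries on poorly supported edges.
* The EAR motif scan is pattern-based and over-calls on random sequence;
  it is reported with a heuristic flag and never drives classification.
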