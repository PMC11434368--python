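# Methods

## Scope and model

`hemenet` reimplements, at desk scale, a comparative-genomics workflow for
assessing extracellular electron transfer (EET) potential across bacterial
families such as the iron reducers *Geobacteraceae* and *Shewanellaceae* and
the sulfate reducers *Desulfovibrionaceae*. The workflow treats a genome as
a bag of proteins plus a handful of per-genome covariates, and asks five
questions:

1. How many c-type cytochromes does each genome encode, and of what kind?
   The operational proxy is the covalent heme-attachment motif CXXCH (and
   the rarer CXXXCH); a protein with ≥ 3 motifs is a multi-heme cytochrome,
   the class most strongly associated with EET.
2. Which genomes carry orthologs of known EET genes (outer-membrane
   cytochromes, porin–cytochrome conduits, Cbc complexes, CymA, PpcA,
   riboflavin biosynthesis), and in how many copies?
3. How do the putatively extracellular multi-heme cytochromes relate to one
   another across families? (A protein sequence similarity network with
   community detection.)
4. How mobile are these genomes (prophages, CRISPR arrays, integrons, IS
   elements, ICEs)?
5. Which of these traits separate the families in a low-dimensional
   projection? (A PCA over 13 per-genome variables.)

External detection tools (CheckM, OrthoFinder, PSORTb, PHASTER,
CRISPRCasFinder, ISFinder, IntegronFinder, CONJScan) are *not* run;
their outputs are consumed as normalized TSV tables. The only
sequence-level computation done in-package is exact pairwise local
alignment, motif scanning, and a self-contained orthology clusterer used
when no orthogroup table is supplied.

## Heme motif scanning

A window matches CXXCH when positions (0, 3, 4) are literally C, C, H, and
CXXXCH when positions (0, 4, 5) are; wildcard positions accept any residue
*including* the unknown X, while anchors must be literal, because the two
cysteines and the histidine define the heme ligation chemistry and an
ambiguous residue cannot be asserted to provide it.

Two policies are offered. `nonoverlap_greedy` (default) walks left to
right, tries CXXCH before CXXXCH at each position, and consumes matched
windows so no residue serves two motifs — the behaviour of a global regex
alternation in a scripted scanner. `all_matches` enumerates every
satisfying window, overlaps allowed, for sensitivity analysis. Counting
semantics downstream: a protein is mono/bi/multi-heme by its total motif
count (1 / 2 / ≥ 3), and the motif-type categories (CXXCH-only,
CXXXCH-only, both) are mutually exclusive per protein.

## Orthogroups

Orthogroup tables follow the OrthoFinder `Orthogroups.tsv` dialect. The
fallback clusterer aligns all cross-genome protein pairs (Smith–Waterman,
below), takes each protein's best hit per other genome among alignments
with ≥ 30% identity and ≥ 70% coverage, and unions proteins with their best
hits; connected components are orthogroups. Reciprocal best hits are a
subset of these links. Pure RBH components were rejected during design:
paralogous extra copies lose every reciprocal race to a sibling copy and
either drop out or form small mutual-best satellite islands, which breaks
copy-number accounting; best-hit linkage keeps a gene family's copies in
one component while cross-family merges remain impossible whenever
between-family similarity sits below the identity/coverage bar. Proteins
with no qualifying hit stay unassigned; no singleton orthogroups are
created. A raw-score floor (default 60) prunes candidate pairs before
traceback: optimal local scores of unrelated 150–450 aa proteins were
measured at ≤ 65, while any alignment that can reach 30% identity over
≥ 70% of the shorter sequence scores in the hundreds.

Sharing statistics: *universal* orthogroups span every genome;
*species-specific* ones span exactly one; *family-exclusive* ones draw
members from exactly one family over ≥ 2 genomes (the ≥ 2 keeps
species-specific orthogroups out of the exclusive counts; configurable);
pairwise counts cover orthogroups spanning exactly two families. Marker
profiling maps each EET marker to the orthogroup containing its reference
sequence (by membership, else by best qualifying alignment), and the
genome × marker matrix stores membership counts — copy numbers — whose
boolean view (≥ 1) is presence.

## Similarity network

Sequences enter the network if their orthogroup contains at least one
multi-heme protein predicted extracellular or outer-membrane; whole
orthogroups ride along deliberately, so near relatives that missed the
localization filter are still visible in the graph.

All pairs are aligned with exact Smith–Waterman (affine gaps, BLOSUM62,
BLAST-style gap open 11 / extend 1, i.e. a gap of length L costs 11 + L).
This replaces BLASTP's seeded heuristic with the statistic BLASTP
approximates; it is quadratic but adequate below a few thousand sequences.
The implementation delegates the DP to Biopython's `PairwiseAligner`
(open_gap_score −12, extend −1 reproduces the BLAST convention); the test
suite holds it to an independent quadratic Gotoh DP written from the
recurrences. Identity is identical columns over alignment columns (gap
columns count in the denominator); coverage is alignment columns over the
shorter sequence length by default (query-based and mutual variants are
provided). E-values use Karlin–Altschul statistics, bitscore
`(λS − ln K)/ln 2` with the published gapped BLOSUM62/11-1 constants
λ = 0.267, K = 0.041, search space m·n with no length adjustment — a
documented simplification adequate for thresholding at 1e−40.

An edge is kept iff E ≤ 1e−40, identity ≥ 0.30 and coverage ≥ 0.70, one
edge per pair (alignment scores are symmetric, so one orientation
suffices). Edge weight is the bitscore rather than −log E, which saturates
once E underflows below ~1e−308.

## Community detection

Weighted Louvain, resolution γ = 1 by default, implemented in-package so
that (i) the node-visit order is an explicit seeded shuffle, (ii) the
modularity after every aggregation pass is exposed — the algorithm accepts
only strictly positive gains, so this trajectory must be non-decreasing and
the tests assert it — and (iii) the partition is byte-reproducible from one
seed. Modularity is Q = Σ_c [W_c/m − γ(K_c/2m)²]. Isolated nodes are
singleton communities; an edgeless or empty graph has Q = 0 by definition.
Singletons count toward the total community number, and the ≥ 2-node count
is reported separately. Tie-handling: a node moves only on a strict gain
(> 1e−12) over staying, which makes the partition deterministic given the
seed. Layout is out of scope; the GraphML export carries community and
family attributes for external tools.

## Mobilome

Normalized element tables are aggregated per genome: prophage regions by
completeness category (intact / questionable / incomplete), CRISPR arrays,
integron elements by kind (complete / In0 / CALIN), IS blastn hits filtered
to alignment length strictly > 700 bp and E ≤ 1e−6, and ICEs counted as
*distinct conjugation-system types* per genome. Prophage density is
prophages per Mbp; by default all completeness categories count, with an
intact-only knob, since the source statistic does not specify. Family and
subclade summaries report mean counts per strain, prevalence (fraction of
strains with ≥ 1) and mean density.

## Feature table and PCA

Thirteen variables per genome, in fixed order: genome size (Mbp), GC (%),
prophages, total cytochromes per Mbp, complete integrons, CRISPR arrays, IS
count, ICE types, and copy numbers for PpcA, OmpJ, Cbc (summed over
cytochrome-bc-complex markers), CymA and Rib (summed over
riboflavin-biosynthesis markers). "Total cytochromes per Mbp" counts
proteins with ≥ 1 heme motif per Mbp (all motif-bearing proteins by
default; a multi-heme-only switch exists) — the only cytochrome census the
pipeline computes, stated as an interpretation.

PCA defaults to the correlation matrix: the variables mix Mbp, percent and
counts, so unstandardized PCA would be dominated by scale. Columns are
z-scored (ddof 1, constant columns dropped with a warning) and the
correlation matrix eigendecomposed; loadings are oriented so each
component's largest-magnitude entry is positive; percent variance is
100·λ_k/Σλ. `standardize=False` preserves covariance PCA. Scores
reconstruct the standardized table exactly when all components are kept,
and the implementation is cross-checked against scikit-learn's PCA in the
tests.

## Quality control and genome statistics

Genomes are kept iff completeness > 98 and contamination < 5, both strict
as written. Genome length counts all bases including N over all contigs;
GC is (G+C)/(A+C+G+T) with ambiguous bases excluded from the denominator
(undefined, hence an error, when no unambiguous base exists).

## Synthetic study generator

The generator emits a complete toy study with known ground truth. Each
*gene family* has a random ancestor protein of 150–450 aa; per-genome
copies substitute a fraction (1 − t)/2 of positions uniformly (t = target
pairwise identity, default 0.85), so two copies meet the target in
expectation, while different families are unrelated random sequences whose
best local alignments cannot pass the 30%/70% clustering bar. The
substitution model is uniform over non-identical residues — deliberately
non-phylogenetic, sufficient for identity-threshold behaviour.

Heme motifs are planted at family-level slots (non-overlapping, ≥ 6 residue
gaps, wildcards never C or H); per protein, a Poisson draw (rate 1.0
background, 5.0 for the five designated cytochrome families) decides how
many slots are written. Accidental motifs arising from the random
background are scrubbed by mutating an anchor residue outside every planted
slot — the slot geometry guarantees such an anchor exists — so the realized
census equals the planted one; it is nevertheless re-verified by an
internal brute-force scan before being recorded as truth, and the truth
records realized, not intended, counts. Cytochrome-family proteins get
extracellular/outer-membrane localization labels (making their orthogroups
the expected network communities); background proteins draw from the
remaining categories, with ~10% of rows withheld to exercise the
missing-localization path.

Gene families follow fixed presence archetypes so the sharing statistics
have nontrivial truth: universal single-copy, universal multi-copy (1–3
copies per genome), the cytochrome families, family-exclusive, two-family
and genome-specific families, plus per-genome orphan genes that belong to
no orthogroup (the analogue of a real run's unassigned fraction). Marker
genes are attached to specific families — ompJ/omcA/mtrA/cbcA/cbcB on the
cytochrome families, ppcA/cymA/ribB/ribE on multi-copy universal families
so their copy-number columns vary — with external reference sequences
(mutated ancestors) exercising the alignment-fallback mapping path.
Mobilome tables are Poisson draws per element with IS hits straddling the
length/E-value filters, and the truth stores post-filter counts. Nucleotide
genomes are GC/length-controlled filler only (no stage maps proteins to
coordinates). All output is a deterministic function of the config seed.

Default sizes — 3 families × 4 genomes, 30 gene families, 3 orphans per
genome (~440 proteins), 1.5 Mbp genomes — are the package's chosen
desk-scale study: large enough that every statistic has nontrivial truth,
small enough that the quadratic all-vs-all alignment steps complete in
minutes on one core. What passing on this study shows: exact bookkeeping,
filter and threshold semantics, and recoverability under clean separation
(within-family identity far above, between-family far below, the
thresholds). What it does not show: behaviour on real proteomes with domain
shuffling, indels, promiscuous homology near the 30% identity boundary, or
realistic paralogy depth — there the clustering and network structure are
approximations whose quality this package does not certify.

## Pipeline determinism

All randomness flows from one config seed; each stage derives its own
stream seed by hashing the stage name (CRC32, masked below 2³¹), so adding
or reordering stages does not shift another stage's draws. The manifest
records per-stage parameters and sha256 digests of every output; two runs
with identical inputs and seed produce identical manifests, and the test
suite asserts this at the byte level.

## Known limitations

- E-values ignore length-adjusted effective search space; absolute values
  are slightly conservative, the 1e−40 threshold behaviour is unaffected.
- The co-optimal alignment reported for identity/coverage is the aligner's
  first traceback; other co-optimal tracebacks could differ in identity by
  a column or two near ties (scores are exact regardless).
- The orthology fallback is single-linkage-flavoured best-hit clustering,
  not OrthoFinder; on real data it will over-merge promiscuous families.
- Louvain is the only community algorithm offered (by design), and small
  modularity plateaus can admit multiple optimal partitions; the seed fixes
  the one reported.
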