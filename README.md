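# hemenet

Comparative genomics of extracellular electron transfer (EET) potential.

Some bacteria respire by moving electrons across the cell envelope onto
external acceptors — Fe(III) minerals, electrodes, other cells. The
molecular signature of this lifestyle is an arsenal of multi-heme c-type
cytochromes: proteins carrying three or more covalent heme-attachment
motifs (CXXCH, occasionally CXXXCH), many of them displayed on or outside
the outer membrane. `hemenet` is a desk-scale pipeline for profiling that
signature across bacterial families — iron reducers like *Geobacteraceae*
and *Shewanellaceae*, sulfate reducers like *Desulfovibrionaceae* — from
proteome FASTA files and the tabular outputs of standard detection tools.

It computes, per genome and per family:

- a **heme-motif census**: CXXCH/CXXXCH hits per protein, mono/bi/multi-heme
  classes (1 / 2 / ≥ 3 motifs), motif-type and subcellular-localization
  breakdowns;
- **orthogroup statistics** (OrthoFinder `Orthogroups.tsv` dialect, or a
  built-in best-hit clusterer): universal / species-specific /
  family-exclusive orthogroup counts, the single-copy core, and a
  genome × marker **copy-number matrix** for a database of known EET genes
  (OmcA, MtrA, OmpJ, Cbc complexes, CymA, PpcA, riboflavin biosynthesis, …);
- a **sequence similarity network** of extracellular multi-heme
  cytochromes: exact Smith–Waterman all-vs-all (BLOSUM62, affine gaps
  11/1), edges kept at E ≤ 10⁻⁴⁰, identity ≥ 30%, coverage ≥ 70%, with
  weighted **Louvain** communities (resolution γ = 1) maximizing
  Q = Σ_c [W_c/m − γ(K_c/2m)²];
- a **mobilome census** from normalized prophage / CRISPR / integron / IS /
  ICE tables (IS hits filtered to length > 700 bp and E ≤ 10⁻⁶), with
  prevalence and per-Mbp prophage density;
- a **13-variable correlation-matrix PCA** (genome size, GC%, mobilome
  counts, total cytochromes per Mbp, and EET-marker copy numbers).

A seeded synthetic-study generator (`hemenet.synthetic`) emits a complete
toy dataset with planted ground truth — gene families with controlled
identity, planted heme motifs, marker copy numbers, localization labels,
mobilome counts — so the entire pipeline is testable offline; see
`docs/methods.md` for the model and its limits.

## Worked example

Generate a synthetic study and run every stage:

```sh
hemenet simulate --seed 1 -o study/
hemenet all --study study/ --seed 1 -o results/
```

The run prints the stage list and writes, among others,
`results/ssn_summary.json`:

```json
{
  "modularity": 0.7566933678908853,
  "n_communities": 5,
  "n_communities_ge2": 5,
  "n_edges": 1317,
  "n_nodes": 117
}
```

117 sequences entered the network (all members of the five orthogroups that
contain at least one extracellular/outer-membrane multi-heme cytochrome),
and Louvain at γ = 1 resolves them into 5 communities — exactly the five
planted cytochrome gene families, at modularity Q ≈ 0.76. The heme census
(`results/heme_family_summary.tsv`) reports for this study a mean of
24.75 heme-motif-bearing proteins per genome, and
`results/pca_variance.tsv` shows PC1+PC2 carrying ≈ 47% of the variance of
the 13-variable feature table. Per-stage outputs (annotation tables, the
marker copy matrix, mobilome profiles, GraphML network, PCA loadings and
scores) land in the same directory, together with `manifest.json` holding
sha256 digests of every file — two runs with the same seed produce
identical manifests.

Library use mirrors the CLI:

```python
from hemenet import scan_heme_motifs

hits = scan_heme_motifs("CAACHCAAACH")
# [MotifHit(protein_id='', start=0, pattern='CXXCH'),
#  MotifHit(protein_id='', start=5, pattern='CXXXCH')]
```

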