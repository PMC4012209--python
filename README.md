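# caslink

Gene-neighborhood and CRISPR-Cas association analysis for prokaryotic
genomes, with a synthetic-genome simulator that plants the ground truth
every stage is validated against.

## The problem

Many genes inside CRISPR-Cas loci are not themselves *cas* genes.  Two
widespread examples are the CARF domain (CRISPR-associated Rossmann
fold, a predicted ligand sensor, frequently fused to a winged
helix-turn-helix and to C-terminal "effector" nucleases such as HEPN or
PIN) and the WYL domain (an Sm-like β-barrel, also a predicted ligand
sensor, often encoded next to CARF genes).  Characterizing such
families is a comparative-genomics exercise: collect the genes within a
window of *k* genes on either side of every query gene, cluster the
neighbor proteins into families, annotate the clusters from domain
hits, and count how often each neighbor family — and each CRISPR-Cas
system type — co-occurs with the query family.

`caslink` implements that pipeline as a reusable, tested library and
CLI for anyone doing gene-context analysis of defense systems:

* **annotation I/O** — GenBank flat files and NCBI PTT + protein FASTA
  parsed into a uniform per-replicon gene table (1-based inclusive
  coordinates), with a completeness filter that discards partial,
  pseudo and sequence-less records;
* **pairwise similarity** — Smith–Waterman local alignment under
  BLOSUM62 with affine gaps (NCBI convention: a gap of length *k* costs
  11 + *k*), raw scores converted to bits via the Karlin–Altschul
  formula *bits* = (λ·S − ln K)/ln 2 with λ = 0.267, K = 0.041;
* **clustering** — BLASTCLUST-semantics single linkage: two proteins
  are linked iff the optimal local alignment covers ≥ 0.8 of **both**
  sequences and its score density (bit score / alignment columns) is
  ≥ 0.8 bits per column; clusters are connected components, the longest
  member represents each cluster;
* **neighborhoods** — window extraction (truncated at linear ends,
  wrapped on circular replicons), pooled neighbor clustering, cluster
  annotation by majority domain hit (e ≤ 0.01), the window-level
  co-occurrence histogram, and reverse *cas*-linkage reported as
  "total (linked)";
* **CRISPR-Cas association** — *cas* loci called as gapped-maximal runs
  of cas-annotated genes, typed by signature families (cas3 → I,
  cas9 → II, cas10 + csm2/cmr5 → III-A/III-B), per-family type
  association tables, genome-level type co-occurrence (type III
  standing alone vs co-occurring with I/II) and the cas1/cas10
  presence summary;
* **domain architectures** — greedy overlap resolution of hit tables,
  classification of CARF proteins as effector-bearing vs
  regulatory-only, and a scanner for the CARF ligand-binding motif
  [DN]X[ST]XXX[RK];
* **representative selection** — one genome per genus (largest genome,
  with model-organism overrides such as *Bacillus subtilis* 168);
* **synthetic data** — a deterministic generator that emits genome
  collections (GenBank *and* PTT+FASTA), domain-hit tables, taxa tables
  and machine-readable ground truth: protein families at controlled
  identity, CRISPR-Cas loci built from type templates, and CARF/WYL
  genes planted near (or away from) loci at configured probabilities.

## Worked example

```bash
caslink demo --seed 1 --out demo_out
```

simulates a 9-genome collection (6 genera, one CARF and one WYL gene
per genome, CRISPR-Cas loci instantiated from I/II/III-A/III-B
templates) and runs the full analysis on the emitted files.  It prints:

```
caslink run report
===================
n_genomes                    9
n_replicons                  9
n_genes                      788
n_complete_proteins          749
n_removed_incomplete         39
n_query_genes                9
n_windows                    9
n_pooled_proteins            174
n_clusters                   142
n_loci                       17
n_representative_genomes     6
reverse cas linkage CARF     9 (8)
reverse cas linkage WYL      9 (6)
genomes with query family    6 (lacking cas1/cas10: 0)
parameters: {"annotation_format": "genbank", "evalue_cutoff": 0.01, ...}
```

Reading it: 788 genes were parsed, 39 incomplete records discarded; 9
CARF query genes produced 9 windows of ≤ 21 genes; the 174 pooled
neighbor proteins collapsed into 142 single-linkage clusters (planted
families merge, unique backgrounds stay singletons); 17 cas loci were
called and typed.  "9 (8)" is the reverse-linkage convention: of 9 CARF
genes, 8 have at least one *cas* gene within the window.  The
genome-level summaries are computed on the 6 genus representatives.

`demo_out/analysis/` holds the per-stage TSVs.  The co-occurrence
histogram (`cooccurrence.tsv`) shows WYL next to CARF in 8 of 9
windows, with *cas* families as the other frequent neighbors; the
association table (`association.tsv`) gives, per query family, the
gene counts near loci of each type:

```
family  total  near_cas  I  II  III-A  III-B  ...
CARF    9      8         2  1   3      2
WYL     9      6         0  0   2      4
```

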