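# Methods

## Scope and data model

`caslink` analyzes annotated prokaryotic genomes; it never touches
nucleotide sequence beyond coordinates.  All coordinates are 1-based
inclusive (the PTT "Location" convention), on both input formats, so no
conversion happens anywhere inside the package.  A genome is a set of
replicons; a replicon is an ordered gene table whose index (rank by
start coordinate) is the unit of all neighborhood distances.  Genes
spanning the origin of a circular replicon keep their annotated
coordinates (end < start) behind an explicit `wraps_origin` flag and
are ranked by start like any other gene.

Incomplete records — partial locations, pseudogenes, or CDS without a
usable protein — are discarded before any similarity computation, but
by default they still occupy window *positions* (a pseudogene between
two genes keeps them two index steps apart).  They never count as cas
genes and never enter clustering pools.

## Alignment and the linked relation

The similarity primitive is optimal Smith–Waterman local alignment
under BLOSUM62 with affine gaps.  Gap costs follow the NCBI convention
(`gap_open` 11, `gap_extend` 1; a gap of length k costs 11 + k).  Raw
scores S become bits via the Karlin–Altschul formula
(λ·S − ln K)/ln 2 with the standard gapped BLOSUM62/(11,1) constants
λ = 0.267, K = 0.041; all four are configurable, and the substitution
matrix may be a built-in name or an NCBI-format matrix file.

Two proteins are **linked** when one optimal local alignment
simultaneously satisfies

* length coverage ≥ 0.8 on **each** sequence (aligned span on that
  sequence divided by its full length — the symmetric, stricter reading
  of a mutual-coverage filter; a shorter-sequence-only mode is a flag),
* score density ≥ 0.8 bits per alignment column, where the column count
  **includes gap columns** (the literal reading of "bit score divided
  by alignment length").

Clusters are connected components of the linked relation over all
pairs (single linkage); there is no heuristic prefiltering by word
hits, so results do not depend on seeding parameters.  The
representative of a cluster is its longest member, ties broken by
smallest id; partitions are provably independent of input order, and a
configurable `max_pairs` cap turns accidental quadratic blow-ups into
an immediate error.

Two implementation notes.  First, the all-pairs loop computes a
score-only Smith–Waterman (a numba kernel, verified equal to
Biopython's aligner) and skips the traceback alignment when the raw
score is below the level any linked pair must reach — a pair with
coverage ≥ 0.8 on the longer sequence L aligns ≥ 0.8·L columns at
≥ 0.8 bits each, so raw < raw(0.64·L bits) proves "not linked".  The
prescreen uses the same scoring and therefore cannot change the
partition, only skip work.  Second, when co-optimal alignments exist,
coverage and density are measured on the single alignment produced by
the deterministic traceback order of the dynamic program; this is the
one place where the decision could in principle depend on tie-breaking,
and the oracle tests exercise it only through score equality plus
partition equality.

When no residue pair scores positive, the local alignment is empty:
raw score 0, zero columns, zero coverage — never a link.

## Neighborhoods and co-occurrence

The neighborhood of a query gene is the window of `window_k` genes on
either side (default 10, valid 1–25; screening analyses conventionally
use 5–10).  Windows truncate at linear replicon ends and wrap without
duplication on circular replicons; they never span replicons.  The
reported parameter echo in every run report states the window used.

Neighbor proteins pooled across all query windows (each protein once;
query genes excluded, so a query never counts as its own neighbor) are
clustered, and each cluster is annotated with the most frequent domain
family among its members' hits at e ≤ 0.01, ties broken by best
e-value.  Two summaries follow:

* the **co-occurrence histogram**: per family, the number of query
  windows containing ≥ 1 member of it — window-level presence, not gene
  counts, so one window with three WYL genes counts once;
* the **reverse linkage**: for any family of query genes, the number of
  windows containing ≥ 1 neighbor annotated with a *cas* family,
  reported as "total (linked)".

## CRISPR-Cas loci, types, and genome-level summaries

A locus is a maximal run of cas-annotated genes merged across gaps of
at most `locus_max_gap` = 2 intervening non-cas genes; locus boundaries
are not standardized in the literature, so the tolerance is a
first-class configuration knob, and the signature table (family → role)
is an external two-column TSV.  Typing: cas3 ⇒ I, cas9 ⇒ II, cas10 ⇒
III, resolved III-A by csm2 or III-B by cmr5 (cas10 alone ⇒
III-unspecified); cas1/cas2/cas4 mark adaptation and are never
signatures; conflicting signatures report all matching types and flag
the locus composite.

A query gene is *near cas* when its window overlaps a called locus
span on the same replicon — one proximity definition across the whole
pipeline.  It is attributed to the type of the nearest overlapping
locus by gene-index distance; when two loci of different types tie,
both types are counted (the tie does not inflate the near-cas count).
Genome-level summaries partition genomes into {III co-occurring with
I/II, III sole, I only, II only, none} — a genome with I and II but no
III is folded into "I only" to keep the partition disjoint —
cross-tabulated with whether the genome carries an effector-bearing
CARF protein, plus the count of query-family genomes lacking both cas1
and cas10.  These statistics are computed on the genus-representative
set: per genus the largest genome wins (ties to smallest id), except
genera with named model-organism overrides.

## Domain architectures

Hit tables (protein, family, residue interval, e-value, score) are
resolved greedily by ascending e-value (ties: higher score, smaller
start, family name); a hit survives if it overlaps every kept hit by at
most 30% of the shorter interval.  Manual curation of overlapping
assignments cannot be encoded, so the tolerant-greedy rule is explicit
and both the cutoff and tolerance are parameters.  A CARF protein is
*effector-bearing* iff an effector-family domain (HEPN, PIN, RelE,
REase, HD, Ada, HNH, Csx15 by default) starts strictly C-terminal of a
CARF interval; otherwise it is regulatory-only.  Degraded domains count
only if the hit table labels them.  The ligand-binding motif
[DN]X[ST]XXX[RK] is scanned as a 7-position class pattern returning all
1-based match starts.

## The synthetic generator

The generator emulates the *inputs* of the analysis, not evolution:

* **Background genes** are unique uniform-random proteins (default
  100–400 aa), so any non-planted cluster of size > 1 is an error —
  measured background identity between such sequences is ~5–10%, far
  below the linked thresholds.
* **Families** derive from one random seed sequence per family by
  substituting round((1 − w)·L) positions, replacement uniform over the
  other 19 residues (no indels unless `indel_rate` > 0).  Each member
  is exactly w identical to the seed; two members agree at a position
  iff both kept it or both mutated to the same residue, so pairwise
  identity concentrates near w² + (1 − w²)/19 (0.585 at the default
  w = 0.75) — comfortably above linkage at these lengths, and
  comfortably below it across families.
* **Loci** are contiguous instantiations of type templates
  (I: cas3-cas1-cas2-cas4; II: cas9-cas1-cas2; III-A:
  cas10-csm2-csx19-cas1-cas2; III-B: cas10-cmr5-cas2), placed with at
  least 3 background genes between loci so distinct templates can never
  merge under the default gap tolerance.
* **Planting**: each genome carries one CARF gene — within `window_k`
  of a locus with probability `carf_near_cas_prob`, else at a position
  with no cas gene within the window — and one WYL gene, inside the
  CARF window with probability `wyl_near_carf_prob`.  A configured
  fraction of genomes is generated entirely cas-free.  CARF proteins
  receive CARF + wHTH hits, plus a HEPN hit (C-terminal) with
  probability `carf_effector_prob`.  Partial flags fall on background
  genes only, at `partial_fraction`.
* Per-genome layouts that cannot satisfy the placement constraints are
  re-drawn deterministically (up to 50 draws); a replicon genuinely too
  small for its templates is a configuration error.

Everything derives from one integer seed through a seed tree (one
stream per family, one for layout), so a fixed config reproduces the
output byte for byte — including GenBank files, whose LOCUS date is
pinned and whose sequence is an all-N placeholder of the annotated
length.  Ground truth (gene table with planted families and flags,
locus spans and types, association events, taxa, realized identities)
is emitted as TSVs and is re-derivable by parsing the emitted files.

What passing on this generator does **not** show: robustness to indels
and domain shuffling (substitution-only model), to annotation noise
(hit tables are exact for planted proteins), to paralog-rich background
families, to operon strandedness, or to the profile-search stage that
produces real hit tables — those searches are upstream inputs, not
part of this package.

## Validation scenario sizes

The recovery checks run at sizes chosen for exactness on one CPU:
alignment oracle on 200 random pairs of ≤ 8 residues (exhaustive
enumeration of monotone matchings); clustering oracle on 50 instances
of ≤ 25 sequences (30–80 aa, mixed families and singletons); planted
dereplication on 10 families × 20 members at w = 0.75, length 200, plus
30 background singletons; neighborhood recovery on 200 single-query
genomes of 22–30 genes with window k = 5 and 80–150 aa backgrounds
(~1800-protein pool, ~1.6 M pairs); typing/association on the default
collection (~9 genomes, ~17 loci); presence summary on 40 genomes with
10% generated cas-free.  The planted probabilities under test
(wyl_near_carf_prob 0.8, carf_near_cas_prob ∈ {0, 1}) are the study
conditions themselves.

## Known limitations

* Exact all-pairs clustering is O(n²) alignments; desk-scale only
  (thousands of proteins, not the ~10⁶ of a full RefSeq screen).
* PTT carries no partial/pseudo fields; the writer adds a sidecar
  `Flags` column and the reader accepts it, but third-party PTT files
  parse with `is_partial = False`.
* Subtype resolution stops at {I, II, III-A, III-B}; repeat arrays are
  not detected (annotation-level analysis only).
* Co-optimal alignment ties are resolved by traceback order; linkage
  decisions within a hair of a threshold can in principle depend on
  that order.
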