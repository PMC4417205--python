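# Methods

This note records the models, conventions and numerical choices behind
`nbskit`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the bundled simulator does and does not
emulate.

## Coordinates and data model

All genomic intervals are 0-based half-open internally; GFF3's 1-based
inclusive coordinates are converted only at the I/O boundary, and protein
coordinates in domain hits stay 1-based inclusive as reported by
hmmscan/Pfam. One representative isoform is kept per gene — the mRNA with
the longest summed CDS, ties broken lexicographically by mRNA id; public
annotation projects rarely state which isoform their summaries used, so
this convention is ours and is applied uniformly. Strand is stored but
never used to reverse-complement: CDS and protein FASTA inputs are assumed
strand-resolved, as emitted by every mainstream annotation pipeline.

## Identification and classification

A gene is an NBS candidate when it has ≥ 1 NB-ARC (PF00931) domain hit
with E ≤ 10⁻⁴; the comparison is inclusive at the cutoff. Candidate
redundancy ("two gene models, one locus") is resolved by collapsing
candidates on one scaffold whose intervals overlap by **more than 50% of
the shorter interval** (transitively), keeping the longest CDS. The 50%
figure is a design choice; it only matters for annotation bundles that
contain overlapping alternative models.

Coiled-coils are scored with the classic sliding-window heptad method:
per-residue, per-heptad-position propensities (the MTK reference set),
window 28, unweighted; the window score is the geometric mean of the
propensities over the best of the 7 frames, a residue takes the maximum
over covering windows, and raw scores are converted to probabilities with
the two-Gaussian model (coiled-coil mean 1.63, sd 0.24; globular mean
0.77, sd 0.20; prior ratio 30) kept in a config block, not inline. A gene
"has CC" when the probability reaches 0.9 anywhere in the first 200
residues. Zero-propensity residues (e.g. proline at most positions) are
handled with a large finite log-penalty so scores underflow cleanly.

Class assignment: TIR hit ⇒ TIR class; else CC ⇒ non-TIR; else the gene
takes the majority class of the smallest enclosing clade of the NBS-domain
tree containing ≥ 3 classified leaves (ties and missing context fall back
to non-TIR, flagged "unresolved"). Subtypes TN/TNL, CN/CNL, XN/XNL follow
from the TIR/CC/neither decision plus LRR presence; X-type genes can
therefore sit in either class, which is how mixed subtype tables for TIR
and non-TIR groups arise.

## Families

Pairwise similarity is computed on CDS nucleotides with a global aligner
(match 1, mismatch 0, gap open −2, extend −0.5, free end gaps). Identity =
matches / alignment columns between the first and last aligned column;
coverage = doubly-aligned length / shorter sequence length. Families are
single-linkage components with edges at identity > 0.60 AND coverage >
0.60, both strict. Choices the thresholds' source leaves open — nucleotide
vs protein level, coverage denominator, linkage — are fixed here as:
nucleotide (so clustering and the 80%-similarity clade rule share
machinery), shorter sequence, single linkage.

For tractability, equal-length pairs whose ungapped identity falls outside
a guard band (0.15 below to 0.10 above the identity threshold) are decided
without the full alignment; the band was calibrated against the observed
worst-case effect of gapped realignment (≈ 0.12) so the decision matches
the full computation. Borderline pairs are always aligned.

## Divergence and Ka/Ks

Nucleotide divergence per pair is the observed difference proportion p
over comparable columns (gap/ambiguity columns excluded) with the
Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p); p ≥ 0.75 is reported NA
rather than extrapolated. Ka/Ks uses Nei–Gojobori (1986) with the
MEGA-style stop-codon convention: per codon position, the synonymous
fraction is computed over non-stop single-base changes (renormalised
denominator); codon pairs differing at k positions average Sd/Nd over all
k! pathways, pathways through stops are excluded, and a pair whose
pathways are all excluded is skipped entirely (sites and differences).
S and N are averaged over the two sequences across the codon pairs
actually compared. dS and dN get the same JC correction; Ka/Ks is NA when
dS = 0 or either correction is undefined. Family summaries average over
all unordered member pairs of families with ≥ 3 members, excluding NA
pairs and reporting their count — "average nucleotide divergence" is the
plain all-pairs mean and is labelled as such.

Alignments are an input throughout: the package never aligns multiple
sequences (the simulator's output is indel-free and therefore
self-aligning; real data should be aligned externally, e.g. with a
codon-aware aligner, before the evolution and phylogeny stages).

## Duplication mapping

Tandem: same family, same scaffold, consecutive start-to-start distance ≤
window (50 or 100 kb), chained transitively, arrays of ≥ 2 emitted, plus
the per-species percentage of NBS genes in arrays. Start-to-start distance
is our reading of "within X kb"; it makes chains independent of gene
lengths.

Segmental: for every same-species, same-family NBS pair not sharing a
tandem array (and with disjoint windows), the two 31-gene windows (anchor
+ 15 flanking genes each side, truncated at scaffold edges and flagged)
are compared; window genes are matched one-to-one greedily by descending
protein global-alignment identity, a pair counting as homologous at
identity ≥ 0.5 and coverage ≥ 0.5 — a configurable stand-in for a BLAST
E < 10⁻¹⁰ cutoff, since no external BLAST is run. A block needs **more
than five** matched pairs (≥ 6). Blocks sharing > 50% of their genes with
a stronger block are collapsed, which handles nearby anchors describing
the same physical event.

## Phylogeny and expansion clades

Trees are built from NB-ARC domain nucleotides only (the LRR region is too
variable to align reliably), extracted from the CDS by the protein-span →
codon-span mapping. Distances are Kimura two-parameter,
d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q), NA when a log argument is ≤ 0.
Neighbor joining is the standard Saitou–Nei agglomeration; tie-breaks on
the Q criterion take the lowest index pair over sorted labels, and a
negative branch length is clamped to zero with the deficit moved to its
sister so the joined pair's path length is preserved. The point tree on
the full alignment must have a complete distance matrix (NA is an error
telling the user to filter); bootstrap replicates resample columns with
replacement, each replicate's RNG stream derived from (seed, replicate
index) for bit-reproducibility, and an internal edge's support is the
percentage of *tree-yielding* replicates containing the same bipartition —
replicates whose resample saturates a distance produce no tree and are
excluded from the denominator (the count of valid replicates is recorded
on the tree).

Species-specific clades are evaluated on both sides of every internal
edge (the tree is unrooted): one species only, more than two members,
subtending support > 50, and minimum pairwise **ungapped** identity > 0.80
on the domain alignment (the similarity denominator is columns where both
sequences have a base). Nested qualifying sets collapse to the maximal
one.

## The simulator

`simulate_repertoire` evolves an ancestral repertoire down a
user-supplied species tree (default: three species, ((A:0.04,B:0.04):0.03,
C:0.07), in substitutions per site). Per branch, every gene's CDS evolves
by accept/reject single-base codon proposals — synonymous accepted,
nonsynonymous accepted with probability equal to the family's target
dN/dS, stop-creating proposals rejected — with the accepted count drawn
Poisson(branch length × CDS length). Genes are lost with probability
1 − exp(−loss·t) and duplicated Poisson(dup·t) times; copies are placed in
tandem (2–8 kb downstream) with probability 0.6, else on a fresh scaffold.
Terminal branches additionally receive planted expansions (2 per species,
3–5 copies, the signature of a species-specific clade) and segmental
events (2 per species) that copy an NBS gene together with its 15-gene
flanking windows onto a new scaffold with light divergence (0.02).
Optional per-branch WGD duplicates every scaffold.

Defaults were chosen once to represent a plausible desk-scale version of a
multi-rosid survey: 30 ancestral genes (~120–140 NBS genes across three
species), 300-codon genes, family dN/dS cycling through {0.2, 0.5, 1.0},
duplication rate 3 and loss rate 0.8 per gene per unit branch length.
Every NB-ARC domain descends from one shared ancestral domain (each
founding family diverged 0.42 from it) so domain distances are defined
repertoire-wide, as for real NBS genes, while family-private termini keep
inter-family CDS identity far below the 60% clustering threshold; the
within-family divergence implied by the tree depth (≈ 0.14 pairwise) sits
far above it. TIR/non-TIR truth classes receive exon counts with means
6.2 and 2.9 to mirror the observed intron-richness contrast, CC-type
genes carry an N-terminal leucine-zipper heptad block that the coils
scorer detects, and 5% of duplicates lose their TIR annotation to
exercise tree-context classification.

What the simulator does **not** emulate: indels (alignments are exact by
construction, so alignment error never reaches the estimators), intron
sequence evolution, base-composition bias, recombination/gene conversion,
and annotation noise (missing or chimeric gene models). Passing recovery
tests therefore demonstrates correctness of the estimators and detectors
given correct alignments and annotations — not robustness to real-world
annotation artifacts.

## Determinism and problem sizes

Every stochastic step flows from one integer seed (numpy PCG64;
per-replicate streams derived by counter), and reruns are byte-identical
across all pipeline artifacts except the wall-clock log. Shipped
configurations use desk-scale sizes chosen as the package's own test
conditions: ~130 NBS genes across three species, 200 bootstrap replicates
in the automated runs (1000 remains the CLI default for real analyses),
dN/dS recovery at 300 codons × 50 replicates.

## Known limitations

- The report's percentage column follows the half-up two-decimal rounding
  of the published survey tables it mirrors; a handful of that survey's
  printed percentages are inconsistent with their own counts and are
  recomputed here, not reproduced.
- Site-model likelihood tests for positive selection (PAML M7/M8) are out
  of scope; the family report carries the Ka/Ks column only, and an
  externally produced codeml summary can be joined by family id.
- X-type class assignment depends on tree context; on simulated data a few
  deep, isolated X genes (2–3%) take the wrong class when their nearest
  classified clade is mixed.
- Segmental detection follows the windowed-synteny definition (31-gene
  windows, > 5 homologous pairs); genome-wide collinearity chains are not
  attempted, so blocks larger than the window are reported piecewise.
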