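# nbskit

Comparative analysis of plant **NBS-LRR resistance-gene (R-gene) repertoires**
across related genomes: identification of NBS-encoding genes from standard
annotation bundles, TIR/non-TIR architecture classification, gene-family
clustering, divergence and selection statistics, tandem/segmental duplication
mapping, and mining of species-specific expansion clades from bootstrapped
NBS-domain phylogenies.

## Who this is for

Plant comparative genomicists studying the evolution of the largest class of
disease-resistance genes. Given per-species GFF3 gene models, CDS/protein
FASTA and a protein-domain hit table (hmmscan-style), the pipeline answers:
how many NBS genes does each genome encode, of which architectures, organised
into which families, duplicated by which mechanism, and which lineages have
expanded the repertoire since speciation?

## The method

1. **Identification.** Candidates are proteins with an NB-ARC (Pfam PF00931)
   hit at E ≤ 10⁻⁴. Redundant models whose loci overlap by more than half of
   the shorter interval are collapsed (longest CDS kept).
2. **Classification.** TIR domain present → TIR class; otherwise a
   Lupas-style sliding-window coiled-coil score (window 28, probability ≥ 0.9
   within the first 200 residues) marks CC-type genes; genes with neither
   signal (X type) take the majority class of their neighbourhood in the
   NBS-domain tree. LRR presence splits each into TN/TNL, CN/CNL, XN/XNL.
3. **Families.** Single-linkage clusters with an edge when CDS identity
   > 60% **and** coverage (of the shorter sequence) > 60%, from global
   alignment with free end gaps.
4. **Divergence and selection.** Per family (≥ 3 members), all-pairs
   Jukes–Cantor-corrected nucleotide divergence
   `d = −(3/4)·ln(1 − (4/3)p)` and Ka/Ks by the Nei–Gojobori (1986)
   pathway method: fractional synonymous site counts per codon, all
   mutational pathways averaged for multi-position codon differences,
   pathways through stops excluded, JC correction applied to pS and pN.
5. **Duplication mapping.** Tandem arrays chain same-family genes whose
   start coordinates lie within 50 kb (or 100 kb) on one scaffold.
   Segmental blocks pair two NBS anchors whose 31-gene windows (15 flanking
   genes each side) share more than five one-to-one homologous gene pairs.
6. **Phylogeny and expansion clades.** NBS (NB-ARC) domain sequences,
   Kimura two-parameter distances, Saitou–Nei neighbor joining, bootstrap
   supports from column resampling. Species-specific clades: > 2 members,
   one species, minimum pairwise nucleotide similarity > 80%, support > 50.

A truth-tracked simulator (`nbskit.simulate`) generates multi-species
repertoires — birth/death of genes along a species tree, codon evolution
with controlled dN/dS, planted tandem arrays, segmental events and
terminal-branch expansions — so every stage is testable without downloading
genomes.

## Worked example

```bash
nbskit simulate --seed 5 --out sim            # 3 species, ~135 NBS genes, truth tables
nbskit run-all --simdir sim --seed 5 --reps 100 --out run
```

which finishes with

```
done: {'nbs_genes': 134, 'families': 30, 'clades': 8, 'segmental_blocks': 6}
```

`run/table1.tsv` holds the per-genome repertoire summary (percentage =
NBS genes / all annotated genes, rounded half-up):

```
species  total_genes  nbs_genes  percentage
A        1156         46         3.98%
B        1155         45         3.90%
```

and `run/clades.tsv` the recent lineage-specific expansions, e.g.

```
clade_id  species  n  min_similarity  support  members
clade001  A        4  0.9812          100.0    A_g01025,A_g01094,A_g01095,A_g01096
clade002  A        3  0.9833          100.0    A_g00063,A_g01056,A_g01057
```

— four apple-style paralogs at 98% nucleotide similarity on a fully
supported branch, i.e. a duplication burst after the last speciation.
Other artifacts: `nbs_genes.tsv` (classification), `families.tsv`,
`evolution.tsv` (avg divergence, avg Ka/Ks per family), `tandem_50kb.tsv` /
`tandem_100kb.tsv` / `tandem_percent.tsv`, `segmental.tsv`, `tree.nwk`
(supports as internal labels), `table2.tsv` (subtype counts) and
`run_meta.json` (thresholds, seed, counts).

The same stages are importable (`nbskit.identify`, `nbskit.families`,
`nbskit.evolution`, `nbskit.duplication`, `nbskit.phylogeny`,
`nbskit.pipeline`) and runnable one at a time (`nbskit identify`,
`cluster`, `evolve`, `dups`, `phylo`, `clades`, `report`).

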