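"""Tandem-array chaining and segmental-duplication block detection.

Tandem duplicates are same-family genes on one scaffold chained while
consecutive start coordinates fall within a physical window (50 or 100 kb).
Segmental duplications are evidenced by two windows of up to 31 genes (an
NBS anchor plus 15 flanking genes each side) sharing more than five
one-to-one homologous gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

from .families import GeneFamily, pairwise_identity_coverage
from .genome_io import GenomeAnnotation
from .identify import NBSGene


@dataclass
class TandemArray:
    family_id: str
    species: str
    scaffold: str
    members: list[str]  # gene ids ordered by start coordinate
    window_kb: int

    @property
    def size(self) -> int:
        return len(self.members)


def tandem_arrays(
    families: Sequence[GeneFamily], window_kb: int = 50
) -> list[TandemArray]:
    """Maximal chains of same-family genes within ``window_kb`` of each other.

    Distance is measured between start coordinates of consecutive family
    members on a scaffold and chaining is transitive; chains of length >= 2
    are emitted.
    """
    window = window_kb * 1000
    arrays: list[TandemArray] = []
    for fam in families:
        groups: dict[tuple[str, str], list[NBSGene]] = {}
        for g in fam.members:
            groups.setdefault((g.species, g.gene.scaffold), []).append(g)
        for (species, scaffold), genes in sorted(groups.items()):
            genes.sort(key=lambda g: (g.gene.start, g.gene_id))
            chain = [genes[0]]
            for prev, cur in zip(genes, genes[1:]):
                if cur.gene.start - prev.gene.start <= window:
                    chain.append(cur)
                else:
                    if len(chain) >= 2:
                        arrays.append(
                            TandemArray(fam.family_id, species, scaffold,
                                        [g.gene_id for g in chain], window_kb)
                        )
                    chain = [cur]
            if len(chain) >= 2:
                arrays.append(
                    TandemArray(fam.family_id, species, scaffold,
                                [g.gene_id for g in chain], window_kb)
                )
    arrays.sort(key=lambda a: (a.species, a.scaffold, a.members[0]))
    return arrays


def tandem_percentages(
    arrays: Iterable[TandemArray], genes: Sequence[NBSGene]
) -> dict[str, float]:
    """Per-species percentage of NBS genes sitting in a tandem array."""
    tandem_ids: dict[str, set[str]] = {}
    for arr in arrays:
        tandem_ids.setdefault(arr.species, set()).update(arr.members)
    totals: dict[str, int] = {}
    for g in genes:
        totals[g.species] = totals.get(g.species, 0) + 1
    return {
        sp: 100.0 * len(tandem_ids.get(sp, set())) / n for sp, n in sorted(totals.items())
    }


# ---------------------------------------------------------------------------
# Segmental blocks
# ---------------------------------------------------------------------------

@dataclass
class SegmentalBlock:
    anchor_a: str
    anchor_b: str
    species: str
    window_a: list[str]
    window_b: list[str]
    syntenic_pairs: list[tuple[str, str]]
    n_pairs: int = 0
    truncated: bool = False  # a window hit a scaffold edge

    def __post_init__(self) -> None:
        self.n_pairs = len(self.syntenic_pairs)

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.window_a) | frozenset(self.window_b)


def default_homology(
    a: str, b: str, min_identity: float = 0.5, min_coverage: float = 0.5
) -> float | None:
    """Protein global-alignment homology score; None below thresholds.

    Stands in for a BLAST E-value cutoff: a pair counts as homologous when
    global identity and coverage both reach 0.5, and pairs are ranked by
    identity for the one-to-one greedy matching.
    """
    if not a or not b:
        return None
    ident, cov = pairwise_identity_coverage(a, b)
    return ident if (ident >= min_identity and cov >= min_coverage) else None


def segmental_blocks(
    annotations: Mapping[str, GenomeAnnotation],
    nbs_genes: Sequence[NBSGene],
    families: Sequence[GeneFamily],
    tandem: Sequence[TandemArray] = (),
    homology: Callable[[str, str], float | None] = default_homology,
    flank: int = 15,
    min_pairs: int = 6,
    max_block_overlap: float = 0.5,
) -> list[SegmentalBlock]:
    """Detect duplicated blocks around pairs of same-family NBS anchors.

    For every unordered same-species, same-family pair of NBS genes that do
    not share a tandem array, the two (anchor + ``flank`` each side)
    windows are compared; window genes are matched one-to-one greedily by
    descending homology score and a block is emitted when the number of
    matched pairs reaches ``min_pairs`` ("more than five").  Blocks sharing
    more than ``max_block_overlap`` of their genes with a stronger block
    are dropped.
    """
    in_same_tandem: set[frozenset] = set()
    for arr in tandem:
        for a, b in combinations(arr.members, 2):
            in_same_tandem.add(frozenset((a, b)))

    blocks: list[SegmentalBlock] = []
    for fam in families:
        by_species: dict[str, list[NBSGene]] = {}
        for g in fam.members:
            by_species.setdefault(g.species, []).append(g)
        for species, genes in sorted(by_species.items()):
            ann = annotations[species]
            for ga, gb in combinations(sorted(genes, key=lambda g: g.gene_id), 2):
                if frozenset((ga.gene_id, gb.gene_id)) in in_same_tandem:
                    continue
                win_a = ann.neighbors(ga.gene_id, flank)
                win_b = ann.neighbors(gb.gene_id, flank)
                if set(win_a) & set(win_b):
                    continue  # overlapping windows cannot be two blocks
                pairs = _greedy_match(win_a, win_b, ann, homology)
                if len(pairs) >= min_pairs:
                    truncated = (
                        len(win_a) < 2 * flank + 1 or len(win_b) < 2 * flank + 1
                    )
                    blocks.append(
                        SegmentalBlock(
                            anchor_a=ga.gene_id,
                            anchor_b=gb.gene_id,
                            species=species,
                            window_a=win_a,
                            window_b=win_b,
                            syntenic_pairs=pairs,
                            truncated=truncated,
                        )
                    )

    # deduplicate near-identical blocks (nearby anchors share flanks)
    blocks.sort(key=lambda b: (-b.n_pairs, b.anchor_a, b.anchor_b))
    kept: list[SegmentalBlock] = []
    for blk in blocks:
        redundant = False
        for other in kept:
            inter = len(blk.gene_set & other.gene_set)
            if inter > max_block_overlap * min(len(blk.gene_set), len(other.gene_set)):
                redundant = True
                break
        if not redundant:
            kept.append(blk)
    kept.sort(key=lambda b: (b.species, b.anchor_a, b.anchor_b))
    return kept


def _greedy_match(
    win_a: Sequence[str],
    win_b: Sequence[str],
    ann: GenomeAnnotation,
    homology: Callable[[str, str], float | None],
) -> list[tuple[str, str]]:
    scored: list[tuple[float, str, str]] = []
    for ga in win_a:
        pa = ann.genes[ga].protein
        for gb in win_b:
            score = homology(pa, ann.genes[gb].protein)
            if score is not None:
                scored.append((score, ga, gb))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for score, ga, gb in scored:
        if ga in used_a or gb in used_b:
            continue
        used_a.add(ga)
        used_b.add(gb)
        pairs.append((ga, gb))
    pairs.sort()
    return pairs
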