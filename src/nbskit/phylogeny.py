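"""NBS-domain phylogenetics: K2P distances, neighbor-joining, bootstrap,
and species-specific expansion-clade mining.

Trees are held as :class:`skbio.TreeNode` objects rooted at a trifurcation
(the usual unrooted-NJ representation); every internal non-root node then
corresponds to exactly one internal edge / leaf bipartition.  Bootstrap
supports are percentages of replicate trees containing the same bipartition
and are attached to internal nodes as ``node.support``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

PURINES = frozenset("AG")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NBS-domain trimming
# ---------------------------------------------------------------------------

def cds_subsequence(cds: str, p_start: int, p_end: int) -> str:
    """CDS substring encoding protein residues p_start..p_end (1-based incl.)."""
    lo, hi = (p_start - 1) * 3, p_end * 3
    if not (0 <= lo < hi <= len(cds)):
        raise PhylogenyError(
            f"protein span ({p_start},{p_end}) maps outside CDS of length {len(cds)}"
        )
    return cds[lo:hi]


def extract_nbs_domain(nbs_gene) -> str:
    """Nucleotides of the NB-ARC (NBS) domain of a classified gene.

    The variable LRR region is deliberately excluded from tree building;
    only the domain span reported by the NB-ARC hit is used.
    """
    p_start, p_end = nbs_gene.nbarc_span
    return cds_subsequence(nbs_gene.gene.cds, p_start, p_end)


# ---------------------------------------------------------------------------
# Kimura two-parameter distance
# ---------------------------------------------------------------------------

def k2p_distance(aligned_a: str, aligned_b: str) -> float | None:
    """K2P distance; columns with gaps/ambiguity excluded; None if undefined.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P, Q the transition and
    transversion proportions.  Raises on zero comparable columns.
    """
    if len(aligned_a) != len(aligned_b):
        raise PhylogenyError("aligned sequences differ in length")
    compared = ts = tv = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _BASE_CODE or y not in _BASE_CODE:
            continue
        compared += 1
        if x != y:
            if (x in PURINES) == (y in PURINES):
                ts += 1
            else:
                tv += 1
    if compared == 0:
        raise PhylogenyError("no comparable columns")
    P, Q = ts / compared, tv / compared
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, NaN where undefined

    def has_na(self) -> bool:
        return bool(np.isnan(self.matrix).any())


def _encode(alignment: Mapping[str, str], labels: Sequence[str]) -> np.ndarray:
    lengths = {len(alignment[l]) for l in labels}
    if len(lengths) != 1:
        raise PhylogenyError("alignment rows differ in length")
    (L,) = lengths
    X = np.full((len(labels), L), -1, dtype=np.int8)
    for i, l in enumerate(labels):
        row = alignment[l].upper()
        for j, ch in enumerate(row):
            X[i, j] = _BASE_CODE.get(ch, -1)
    return X


def k2p_matrix(alignment: Mapping[str, str], labels: Sequence[str] | None = None) -> DistanceMatrix:
    """All-pairs K2P distances from an aligned set of equal-length sequences."""
    if labels is None:
        labels = sorted(alignment)
    X = _encode(alignment, labels)
    return _k2p_matrix_encoded(X, list(labels))


def _k2p_matrix_encoded(X: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = X.shape[0]
    purine = (X == 0) | (X == 2)
    valid = X >= 0
    D = np.zeros((n, n))
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        compared = v.sum(axis=1).astype(float)
        diff = (X[i] != X[i + 1 :]) & v
        ts = (diff & (purine[i] == purine[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(compared > 0, ts / compared, np.nan)
            Q = np.where(compared > 0, tv / compared, np.nan)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                np.nan,
            )
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Neighbor-joining (Saitou & Nei)
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """An (unrooted) NJ tree rooted at a trifurcation for storage."""

    root: TreeNode
    labels: list[str] = field(default_factory=list)

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions, keyed by the child-side leaf set."""
        out: dict[frozenset, TreeNode] = {}
        for node in self.root.traverse(include_self=False):
            if node.is_tip():
                continue
            out[frozenset(t.name for t in node.tips())] = node
        return out

    def write(self, path) -> None:
        # skbio's writer emits each internal node's ``support`` as its label
        self.root.write(str(path), format="newick")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch so the joined pair's summed length is preserved.
    Ties in the Q criterion break on the smallest (i, j) index pair, which
    makes the result independent of input label order once labels are
    sorted by the caller.
    """
    if dm.has_na():
        raise PhylogenyError(
            "distance matrix contains NA entries; filter saturated columns "
            "or drop the offending sequences before tree building"
        )
    n = len(dm.labels)
    if n < 3:
        raise PhylogenyError("need at least 3 labels for NJ")

    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> lowest flat index (deterministic)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        parent = TreeNode()
        na, nb = nodes[i], nodes[j]
        na.length, nb.length = li, lj
        parent.extend([na, nb])
        nodes[i] = parent
        # distances from the new node
        for ak in active:
            if ak in (i, j):
                continue
            D[i, ak] = D[ak, i] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        active.remove(j)

    # final trifurcation
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.append(nodes[idx])
    return PhyloTree(root=root, labels=list(dm.labels))


def load_tree(path) -> PhyloTree:
    """Read a Newick tree whose internal node labels are bootstrap supports."""
    root = TreeNode.read(str(path), format="newick", convert_underscores=False)
    for node in root.traverse(include_self=False):
        if not node.is_tip() and node.name not in (None, ""):
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return PhyloTree(root=root, labels=sorted(t.name for t in root.tips()))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(
    alignment: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports.

    Columns are resampled with replacement per replicate; each replicate's
    RNG stream is derived from ``(seed, replicate_index)`` so runs are
    bit-reproducible regardless of execution order.  Support of an internal
    edge = percentage of replicate trees containing the same bipartition.
    With ``n_reps=0`` the point tree is returned without supports.
    """
    if labels is None:
        labels = sorted(alignment)
    labels = list(labels)
    X = _encode(alignment, labels)
    tree = nj_tree(_k2p_matrix_encoded(X, labels))
    if n_reps <= 0:
        return tree

    biparts = tree.bipartitions()
    counts = {bp: 0 for bp in biparts}
    L = X.shape[1]
    full = frozenset(labels)
    n_valid = 0
    for rep in range(n_reps):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, rep])))
        cols = rng.integers(0, L, size=L)
        dm = _k2p_matrix_encoded(X[:, cols], labels)
        if dm.has_na():
            # a resample saturated some distance: no tree from this replicate
            continue
        n_valid += 1
        rep_biparts = set(nj_tree(dm).bipartitions())
        rep_canon = {bp for bp in rep_biparts} | {full - bp for bp in rep_biparts}
        for bp in counts:
            if bp in rep_canon:
                counts[bp] += 1
    # support is the percentage over replicates that yielded a tree
    for bp, node in biparts.items():
        node.support = 100.0 * counts[bp] / n_valid if n_valid else 0.0
    tree.n_bootstrap_valid = n_valid
    tree.n_bootstrap_requested = n_reps
    return tree


# ---------------------------------------------------------------------------
# Tree-context class assignment and clade mining
# ---------------------------------------------------------------------------

def tree_class_assignment(
    tree: PhyloTree,
    classified: Mapping[str, str],
    min_classified: int = 3,
) -> dict[str, str]:
    """Assign TIR / nonTIR to unclassified leaves from their tree context.

    Walks from each unclassified leaf toward the root until the enclosing
    clade holds >= ``min_classified`` classified leaves, then takes the
    majority class; ties (or no such clade) fall back to nonTIR.
    """
    out: dict[str, str] = {}
    for leaf in tree.root.tips():
        if leaf.name in classified:
            continue
        node = leaf
        assigned = None
        while node.parent is not None:
            node = node.parent
            votes = [classified[t.name] for t in node.tips() if t.name in classified]
            if len(votes) >= min_classified:
                tir = sum(1 for v in votes if v == "TIR")
                assigned = "TIR" if tir * 2 > len(votes) else "nonTIR"
                break
        out[leaf.name] = assigned if assigned is not None else "nonTIR"
    return out


@dataclass
class SpeciesClade:
    clade_id: str
    species: str
    members: frozenset
    size: int
    min_pairwise_similarity: float
    support: float


def ungapped_identity(aligned_a: str, aligned_b: str) -> float:
    """Matches / columns where both sequences have a base (gaps excluded)."""
    compared = matches = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in _BASE_CODE and y in _BASE_CODE:
            compared += 1
            if x == y:
                matches += 1
    if compared == 0:
        raise PhylogenyError("no comparable columns")
    return matches / compared


def species_specific_clades(
    tree: PhyloTree,
    alignment: Mapping[str, str],
    species_of: Callable[[str], str] | None = None,
    min_size: int = 3,
    min_similarity: float = 0.80,
    min_support: float = 50.0,
) -> list[SpeciesClade]:
    """Mine well-supported single-species expansion clades.

    Both sides of every internal edge are candidate clades (the tree is
    unrooted).  A clade qualifies when all leaves are one species, it has
    more than two members, the subtending edge's bootstrap support exceeds
    ``min_support`` and the minimum pairwise ungapped identity exceeds
    ``min_similarity``.  Nested qualifying clades collapse to the maximal
    one.
    """
    if species_of is None:
        species_of = lambda label: label.split("|", 1)[0]
    full = frozenset(t.name for t in tree.root.tips())
    candidates: dict[frozenset, tuple[float, float]] = {}
    for bp, node in tree.bipartitions().items():
        support = getattr(node, "support", None)
        if support is None or support <= min_support:
            continue
        for side in (bp, full - bp):
            if len(side) < min_size:
                continue
            if len({species_of(l) for l in side}) != 1:
                continue
            min_sim = min(
                ungapped_identity(alignment[a], alignment[b])
                for a, b in combinations(sorted(side), 2)
            )
            if min_sim > min_similarity:
                prev = candidates.get(side)
                if prev is None or support > prev[0]:
                    candidates[side] = (support, min_sim)

    # keep maximal sets only
    keep = [
        (side, sup, sim)
        for side, (sup, sim) in candidates.items()
        if not any(side < other for other in candidates)
    ]
    keep.sort(key=lambda t: (species_of(min(t[0])), -len(t[0]), sorted(t[0])))
    clades = []
    for k, (side, sup, sim) in enumerate(keep, 1):
        clades.append(
            SpeciesClade(
                clade_id=f"clade{k:03d}",
                species=species_of(next(iter(side))),
                members=side,
                size=len(side),
                min_pairwise_similarity=sim,
                support=sup,
            )
        )
    return clades
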