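"""Independent brute-force oracles used only by the tests.

Deliberately written with different machinery from the package (Biopython
translation, direct enumeration, explicit products, exhaustive topology
search) so that agreement is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import networkx as nx
import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# Nei–Gojobori by direct enumeration
# ---------------------------------------------------------------------------

def syn_sites_oracle(codon: str) -> float:
    """Fractional synonymous sites of one codon by enumerating all changes."""
    total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) == "*":
                continue
            nonstop += 1
            if _aa(mut) == _aa(codon):
                syn += 1
        if nonstop:
            total += syn / nonstop
    return total


def _pathway_diffs(c1: str, c2: str):
    if c1 == c2:
        return 0.0, 0.0
    pos = [i for i in range(3) if c1[i] != c2[i]]
    syn_counts, nonsyn_counts = [], []
    for order in permutations(pos):
        cur = c1
        s = n = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _aa(nxt) == "*":
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if not blocked:
            syn_counts.append(s)
            nonsyn_counts.append(n)
    if not syn_counts:
        return None
    return (
        sum(syn_counts) / len(syn_counts),
        sum(nonsyn_counts) / len(nonsyn_counts),
    )


def ng86_oracle(a: str, b: str):
    """(S, N, Sd, Nd, dS, dN, ratio) for an aligned in-frame CDS pair."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if any(x not in BASES for x in c1 + c2):
            continue
        if _aa(c1) == "*" or _aa(c2) == "*":
            continue
        diffs = _pathway_diffs(c1, c2)
        if diffs is None:
            continue
        S += (syn_sites_oracle(c1) + syn_sites_oracle(c2)) / 2
        N += (3 - syn_sites_oracle(c1) + 3 - syn_sites_oracle(c2)) / 2
        Sd += diffs[0]
        Nd += diffs[1]
    ps, pn = Sd / S, Nd / N

    def jc(p):
        if p >= 0.75:
            return None
        return -3.0 / 4.0 * math.log(1.0 - 4.0 * p / 3.0)

    dS, dN = jc(ps), jc(pn)
    ratio = None if (dS in (None, 0.0) or dN is None) else dN / dS
    return S, N, Sd, Nd, dS, dN, ratio


# ---------------------------------------------------------------------------
# Coiled-coil window scoring, the slow way
# ---------------------------------------------------------------------------

def coils_prob_oracle(protein: str, propensities, gaussians, ratio, window=28):
    """Per-residue probabilities via explicit window/frame products."""
    L = len(protein)
    if L < window:
        return [0.0] * L
    score = [0.0] * L
    for w in range(L - window + 1):
        for frame in range(7):
            prod = 1.0
            for i in range(w, w + window):
                row = propensities.get(protein[i])
                prod *= 1.0 if row is None else row[(i - w + frame) % 7]
            s = prod ** (1.0 / window)
            for i in range(w, w + window):
                score[i] = max(score[i], s)
    g = gaussians[window]
    out = []
    for s in score:
        fcc = math.exp(-((s - g["mean_cc"]) ** 2) / (2 * g["sd_cc"] ** 2)) / g["sd_cc"]
        fg = math.exp(-((s - g["mean_g"]) ** 2) / (2 * g["sd_g"] ** 2)) / g["sd_g"]
        out.append(fcc / (fcc + ratio * fg))
    return out


# ---------------------------------------------------------------------------
# Exhaustive least-squares tree fitting
# ---------------------------------------------------------------------------

def all_unrooted_topologies(labels):
    """Yield edge lists (u, v) of every unrooted binary topology."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    counter = [0]

    def new_internal():
        counter[0] += 1
        return f"#{counter[0]}"

    base_internal = new_internal()
    base = [(base_internal, labels[0]), (base_internal, labels[1]), (base_internal, labels[2])]

    def insert(edges, leaf):
        for k in range(len(edges)):
            u, v = edges[k]
            mid = new_internal()
            yield edges[:k] + edges[k + 1 :] + [(u, mid), (mid, v), (mid, leaf)]

    trees = [base]
    for leaf in labels[3:]:
        trees = [t2 for t in trees for t2 in insert(t, leaf)]
    return trees


def ls_fit(edges, labels, dm: np.ndarray):
    """Least-squares branch lengths and SSE for one topology."""
    G = nx.Graph(edges)
    pairs = list(combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    eidx = {frozenset(e): k for k, e in enumerate(edges)}
    for r, (i, j) in enumerate(pairs):
        path = nx.shortest_path(G, labels[i], labels[j])
        for u, v in zip(path, path[1:]):
            A[r, eidx[frozenset((u, v))]] = 1.0
        d[r] = dm[i, j]
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    sse = float(((A @ x - d) ** 2).sum())
    return x, sse


def ls_best_bipartitions(labels, dm: np.ndarray):
    """Bipartition set of the least-squares-best topology."""
    best = None
    for edges in all_unrooted_topologies(labels):
        _, sse = ls_fit(edges, labels, dm)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, edges)
    _, edges = best
    G = nx.Graph(edges)
    leafset = set(labels)
    biparts = set()
    for u, v in edges:
        H = G.copy()
        H.remove_edge(u, v)
        side = frozenset(n for n in nx.node_connected_component(H, u) if n in leafset)
        if 1 < len(side) < len(labels) - 1:
            biparts.add(min(side, frozenset(leafset - side), key=sorted))
    return biparts, best[0]


def tree_bipartition_set(tree, labels):
    """Canonical internal bipartitions of a package PhyloTree."""
    full = frozenset(labels)
    out = set()
    for bp in tree.bipartitions():
        if 1 < len(bp) < len(full) - 1:
            out.add(min(bp, full - bp, key=sorted))
    return out
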