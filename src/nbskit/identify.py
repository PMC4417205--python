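"""NBS-gene identification and domain-architecture classification.

Candidates are proteins with an NB-ARC (Pfam PF00931) domain hit at or
below an E-value cutoff (default 1e-4).  Redundant gene models at the same
locus are collapsed, N-terminal coiled-coils are scored with a Lupas-style
sliding-window method, and each confirmed gene is assigned a class
(TIR / non-TIR) and a subtype (TN, TNL, CN, CNL, XN, XNL): TIR or CC (or
neither, X) at the N-terminus, with or without C-terminal LRRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import LRR, NB_ARC, TIR, DomainHit, GeneModel

# ---------------------------------------------------------------------------
# Coiled-coil scoring configuration
#
# Per-residue propensities by heptad position a..g from the original
# coiled-coil prediction method (MTK: myosin / tropomyosin / keratin
# reference set), window 28, unweighted.  The probability converting a raw
# window score x uses the two published Gaussian populations
# (coiled-coil vs globular) and their 1:30 prior ratio:
#     P(cc | x) = f_cc(x) / (f_cc(x) + RATIO_G_CC * f_g(x))
# ---------------------------------------------------------------------------

COILS_MTK_PROPENSITIES: dict[str, tuple[float, ...]] = {
    #      a      b      c      d      e      f      g
    "L": (3.167, 0.297, 0.398, 3.902, 0.585, 0.501, 0.483),
    "I": (2.597, 0.098, 0.345, 0.894, 0.514, 0.471, 0.431),
    "V": (1.665, 0.403, 0.386, 0.949, 0.211, 0.342, 0.360),
    "M": (2.240, 0.370, 0.480, 1.409, 0.541, 0.772, 0.663),
    "F": (0.531, 0.076, 0.403, 0.662, 0.189, 0.106, 0.013),
    "Y": (1.417, 0.090, 0.122, 1.659, 0.190, 0.130, 0.155),
    "G": (0.045, 0.275, 0.578, 0.216, 0.211, 0.426, 0.156),
    "A": (1.297, 1.551, 1.084, 2.612, 0.377, 1.248, 0.877),
    "K": (1.375, 2.639, 1.763, 0.191, 1.815, 1.961, 2.795),
    "R": (0.659, 1.163, 1.210, 0.031, 1.358, 1.937, 1.798),
    "H": (0.347, 0.275, 0.679, 0.395, 0.294, 0.579, 0.213),
    "N": (0.835, 1.475, 1.534, 0.039, 1.722, 2.456, 2.280),
    "D": (0.030, 2.352, 2.268, 0.237, 2.787, 1.748, 2.079),
    "Q": (1.804, 1.416, 1.937, 0.064, 1.222, 1.938, 1.677),
    "E": (3.130, 2.447, 1.711, 0.286, 4.971, 0.987, 1.798),
    "S": (0.382, 0.583, 1.052, 0.419, 0.525, 0.916, 0.628),
    "T": (0.169, 0.702, 0.955, 0.654, 0.791, 0.843, 0.647),
    "C": (0.824, 0.022, 0.308, 0.152, 0.180, 0.156, 0.044),
    "W": (0.240, 0.000, 0.000, 0.456, 0.019, 0.000, 0.000),
    "P": (0.000, 0.008, 0.000, 0.013, 0.000, 0.000, 0.000),
}

COILS_GAUSSIANS = {
    # window 28, unweighted scoring
    28: {"mean_cc": 1.63, "sd_cc": 0.24, "mean_g": 0.77, "sd_g": 0.20},
}
COILS_RATIO_G_CC = 30.0  # prior ratio of globular to coiled-coil residues
NEUTRAL_PROPENSITY = 1.0  # unknown residues neither help nor hurt


@dataclass
class CoilsProfile:
    """Per-residue coiled-coil probability of one protein."""

    probabilities: np.ndarray
    max_prob_first200: float
    window: int = 28

    def has_cc(self, threshold: float = 0.9) -> bool:
        return self.max_prob_first200 >= threshold


def coils_score(protein: str, window: int = 28) -> CoilsProfile:
    """Sliding-window heptad score converted to a per-residue probability.

    For every window and each of the 7 heptad frames the raw score is the
    geometric mean of the per-residue, per-heptad-position propensities; a
    residue's score is the maximum over all windows/frames covering it.
    Raw scores become probabilities through the two-Gaussian model above.
    Proteins shorter than the window get an all-zero profile.
    """
    if not protein:
        raise ValueError("empty protein")
    if window not in COILS_GAUSSIANS:
        raise ValueError(f"no Gaussian parameters for window {window}")
    L = len(protein)
    if L < window:
        return CoilsProfile(np.zeros(L), 0.0, window)

    protein = protein.upper()
    # log-propensity per residue for each of the 7 global frames; zero
    # propensities (coil breakers) get a large finite penalty so window
    # scores underflow to ~0 without producing inf-inf artifacts
    ZERO_LOG = -700.0
    logp = np.empty((7, L))
    for i, aa in enumerate(protein):
        row = COILS_MTK_PROPENSITIES.get(aa)
        for f in range(7):
            v = NEUTRAL_PROPENSITY if row is None else row[(i + f) % 7]
            logp[f, i] = ZERO_LOG if v == 0.0 else math.log(v)

    n_win = L - window + 1
    # rolling sum of logs per frame -> geometric-mean window scores
    cs = np.concatenate([np.zeros((7, 1)), np.cumsum(logp, axis=1)], axis=1)
    win_log = (cs[:, window:] - cs[:, :-window]) / window  # may be -inf
    win_score = np.exp(win_log.max(axis=0))  # best frame per window start

    score = np.zeros(L)
    for w in range(n_win):
        s = win_score[w]
        seg = score[w : w + window]
        np.maximum(seg, s, out=seg)

    g = COILS_GAUSSIANS[window]
    fcc = np.exp(-0.5 * ((score - g["mean_cc"]) / g["sd_cc"]) ** 2) / g["sd_cc"]
    fg = np.exp(-0.5 * ((score - g["mean_g"]) / g["sd_g"]) ** 2) / g["sd_g"]
    prob = fcc / (fcc + COILS_RATIO_G_CC * fg)
    return CoilsProfile(prob, float(prob[: min(200, L)].max()), window)


def coils_probability(raw_score: float, window: int = 28) -> float:
    """The two-Gaussian probability for a single raw window score."""
    g = COILS_GAUSSIANS[window]
    fcc = math.exp(-0.5 * ((raw_score - g["mean_cc"]) / g["sd_cc"]) ** 2) / g["sd_cc"]
    fg = math.exp(-0.5 * ((raw_score - g["mean_g"]) / g["sd_g"]) ** 2) / g["sd_g"]
    return fcc / (fcc + COILS_RATIO_G_CC * fg)


# ---------------------------------------------------------------------------
# Candidate selection and locus deduplication
# ---------------------------------------------------------------------------

def select_candidates(hits: Iterable[DomainHit], e_cutoff: float = 1e-4) -> set[str]:
    """Gene ids with at least one NB-ARC hit at E <= cutoff (inclusive)."""
    return {h.gene_id for h in hits if h.domain == NB_ARC and h.e_value <= e_cutoff}


def deduplicate_by_locus(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse candidates occupying the same locus.

    Two candidates are the same locus when, on the same scaffold, their
    genomic intervals overlap by more than 50% of the shorter interval;
    overlap clusters are merged transitively and one survivor is kept per
    cluster (longest CDS, ties broken by lexicographic gene id).
    """
    parent = {g.gene_id: g.gene_id for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for glist in by_scaffold.values():
        glist.sort(key=lambda g: (g.start, g.gene_id))
        for i, a in enumerate(glist):
            for b in glist[i + 1 :]:
                if b.start >= a.end:
                    break
                overlap = min(a.end, b.end) - max(a.start, b.start)
                if overlap > 0.5 * min(a.length, b.length):
                    ra, rb = find(a.gene_id), find(b.gene_id)
                    if ra != rb:
                        parent[rb] = ra

    clusters: dict[str, list[GeneModel]] = {}
    for g in genes:
        clusters.setdefault(find(g.gene_id), []).append(g)
    survivors = [
        min(members, key=lambda g: (-len(g.cds), g.gene_id))
        for members in clusters.values()
    ]
    survivors.sort(key=lambda g: g.gene_id)
    return survivors


# ---------------------------------------------------------------------------
# Class / subtype assignment
# ---------------------------------------------------------------------------

KLASS_TIR = "TIR"
KLASS_NONTIR = "nonTIR"
SUBTYPES = ("TN", "TNL", "CN", "CNL", "XN", "XNL")


@dataclass
class NBSGene:
    """A confirmed NBS-encoding gene with architecture classification."""

    gene: GeneModel
    nbarc_span: tuple[int, int]
    has_tir: bool
    has_lrr: bool
    has_cc: bool
    klass: str
    subtype: str
    exon_count: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = _expected_subtype(self.has_tir, self.has_cc, self.has_lrr)
        if self.subtype != expected:
            raise ValueError(
                f"{self.gene.gene_id}: subtype {self.subtype} inconsistent with "
                f"flags (expected {expected})"
            )
        if self.has_tir and self.klass != KLASS_TIR:
            raise ValueError(f"{self.gene.gene_id}: TIR domain but class {self.klass}")
        if self.has_cc and not self.has_tir and self.klass != KLASS_NONTIR:
            raise ValueError(f"{self.gene.gene_id}: CC without TIR but class {self.klass}")

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def species(self) -> str:
        return self.gene.species


def _expected_subtype(has_tir: bool, has_cc: bool, has_lrr: bool) -> str:
    if has_tir:
        stem = "TN"
    elif has_cc:
        stem = "CN"
    else:
        stem = "XN"
    return stem + ("L" if has_lrr else "")


def assign_class_subtype(
    candidate: GeneModel,
    hits: Iterable[DomainHit],
    coils: CoilsProfile,
    tree_context: Mapping[str, str] | None = None,
    e_cutoff: float = 1e-4,
    coils_threshold: float = 0.9,
) -> NBSGene:
    """Build the classified :class:`NBSGene` for one candidate.

    Class is TIR whenever a TIR domain is present; a coiled-coil without
    TIR gives nonTIR; X-type genes (neither) take the class of their tree
    neighbourhood (``tree_context``, a gene_id -> class mapping computed
    from the NBS-domain tree) and fall back to nonTIR with an "unresolved"
    flag when no context is available.
    """
    mine = [h for h in hits if h.gene_id == candidate.gene_id and h.e_value <= e_cutoff]
    nbarc = [h for h in mine if h.domain == NB_ARC]
    if not nbarc:
        raise ValueError(f"{candidate.gene_id}: no NB-ARC hit at E <= {e_cutoff:g}")
    best = min(nbarc, key=lambda h: (h.e_value, h.p_start))
    has_tir = any(h.domain == TIR for h in mine)
    has_lrr = any(h.domain == LRR for h in mine)
    has_cc = (not has_tir) and coils.has_cc(coils_threshold)

    flags: list[str] = []
    if has_tir:
        klass = KLASS_TIR
    elif has_cc:
        klass = KLASS_NONTIR
    elif tree_context is not None and candidate.gene_id in tree_context:
        klass = tree_context[candidate.gene_id]
    else:
        klass = KLASS_NONTIR
        flags.append("unresolved_class")

    return NBSGene(
        gene=candidate,
        nbarc_span=(best.p_start, best.p_end),
        has_tir=has_tir,
        has_lrr=has_lrr,
        has_cc=has_cc,
        klass=klass,
        subtype=_expected_subtype(has_tir, has_cc, has_lrr),
        exon_count=candidate.exon_count,
        flags=flags,
    )


def exon_stats(genes: Iterable[NBSGene]) -> dict[str, float | None]:
    """Mean exon count per class; empty classes report None (NA)."""
    counts: dict[str, list[int]] = {KLASS_TIR: [], KLASS_NONTIR: []}
    for g in genes:
        counts.setdefault(g.klass, []).append(g.exon_count)
    return {
        k: (sum(v) / len(v) if v else None) for k, v in counts.items()
    }
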