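"""Pairwise divergence and Ka/Ks estimation.

Nucleotide divergence is the observed proportion of differences with the
Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - (4/3)·p).  Ka/Ks uses
the Nei–Gojobori (1986) evolutionary-pathway method: fractional synonymous
site counts per codon, all mutational pathways averaged for codons differing
at more than one position, pathways through stop codons excluded, and the
same Jukes–Cantor correction applied separately to the synonymous and
nonsynonymous proportions.  Undefined quantities (saturated distances,
dN/dS with dS = 0) are reported as None, never silently zero-filled.

Alignments are an input here: sequences must arrive aligned and in frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Sequence

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def _is_clean_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon) and codon not in STOP_CODONS


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Jukes–Cantor corrected nucleotide distance
# ---------------------------------------------------------------------------

def jc_distance(aligned_a: str, aligned_b: str) -> tuple[float, float | None]:
    """(p-distance, JC-corrected distance) over comparable columns.

    Columns with a gap or non-ACGT symbol in either sequence are excluded.
    Returns jc = None when p >= 0.75 (correction undefined).  Raises
    :class:`AlignmentError` on length mismatch or zero comparable columns.
    """
    if len(aligned_a) != len(aligned_b):
        raise AlignmentError("aligned sequences differ in length")
    compared = diffs = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in BASES and y in BASES:
            compared += 1
            if x != y:
                diffs += 1
    if compared == 0:
        raise AlignmentError("no comparable columns")
    p = diffs / compared
    return p, jukes_cantor(p)


def jukes_cantor(p: float) -> float | None:
    """JC correction of a difference proportion; None at/beyond saturation."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    At each position the synonymous fraction is the number of synonymous
    single-base changes divided by the number of changes that do not create
    a stop codon (the denominator is renormalised when stop-adjacent
    changes are excluded).  s + n = 3 unless a position has all three
    changes leading to stops (cannot happen in the standard code).
    """
    codon = codon.upper()
    if not _is_clean_codon(codon):
        raise ValueError(f"ng86_sites: not a clean sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            nonstop += 1
            if CODON_TABLE[mutant] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions; pathways whose
    intermediate codons are stops are excluded.  Returns None when every
    pathway is excluded.
    """
    if c1 == c2:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    total_s = total_n = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        path_s = path_n = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                path_s += 1.0
            else:
                path_n += 1.0
            cur = nxt
        if ok:
            total_s += path_s
            total_n += path_n
            n_paths += 1
    if n_paths == 0:
        return None
    return total_s / n_paths, total_n / n_paths


@dataclass
class PairwiseEvolution:
    """Everything the Nei–Gojobori comparison of one aligned CDS pair yields."""

    p_dist: float
    jc_dist: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    dS: float | None
    dN: float | None
    ka_ks: float | None
    n_codons: int  # codon pairs actually compared


def ng86_pair(aligned_cds_a: str, aligned_cds_b: str) -> PairwiseEvolution:
    """Nei–Gojobori Ka/Ks with Jukes–Cantor correction for one aligned pair.

    Codon pairs containing a gap, an ambiguous base or a stop codon in
    either sequence are skipped, as are pairs whose mutational pathways all
    pass through stops.  Site counts S and N are the average of the two
    sequences over the codon pairs actually compared.
    """
    a = aligned_cds_a.upper()
    b = aligned_cds_b.upper()
    if len(a) != len(b):
        raise AlignmentError("aligned sequences differ in length")
    if len(a) % 3 != 0:
        raise AlignmentError("aligned length not a multiple of 3")

    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if not (_is_clean_codon(c1) and _is_clean_codon(c2)):
            continue
        diffs = _codon_pair_diffs(c1, c2)
        if diffs is None:
            continue
        s1, n1 = ng86_sites(c1)
        s2, n2 = ng86_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        n_codons += 1

    if n_codons == 0:
        raise AlignmentError("no comparable codons")

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(ps)
    dN = jukes_cantor(pn)
    if dS is None or dN is None or dS == 0.0:
        ka_ks = None
    else:
        ka_ks = dN / dS

    p_dist, jc = jc_distance(a, b)
    return PairwiseEvolution(
        p_dist=p_dist, jc_dist=jc, S=S, N=N, Sd=Sd, Nd=Nd,
        ps=ps, pn=pn, dS=dS, dN=dN, ka_ks=ka_ks, n_codons=n_codons,
    )


# ---------------------------------------------------------------------------
# Family-level summaries
# ---------------------------------------------------------------------------

@dataclass
class FamilyEvolution:
    family_id: str
    avg_divergence: float | None
    avg_ka_ks: float | None
    n_pairs: int
    n_na_divergence: int
    n_na_ka_ks: int


def family_evolution(
    family_id: str,
    member_ids: Sequence[str],
    alignment: dict[str, str],
    min_members: int = 3,
) -> FamilyEvolution:
    """All-unordered-pairs mean JC divergence and Ka/Ks for one family.

    Families with fewer than ``min_members`` members are refused (the
    divergence/selection survey excludes them).  Pairs with undefined values
    are dropped from the relevant mean and counted.
    """
    if len(member_ids) < min_members:
        raise ValueError(
            f"family {family_id}: {len(member_ids)} members "
            f"(need >= {min_members} for evolutionary statistics)"
        )
    missing = [m for m in member_ids if m not in alignment]
    if missing:
        raise KeyError(f"family {family_id}: members missing from alignment: {missing}")

    divs: list[float] = []
    ratios: list[float] = []
    n_pairs = n_na_div = n_na_kaks = 0
    for ga, gb in combinations(sorted(member_ids), 2):
        n_pairs += 1
        pe = ng86_pair(alignment[ga], alignment[gb])
        if pe.jc_dist is None:
            n_na_div += 1
        else:
            divs.append(pe.jc_dist)
        if pe.ka_ks is None:
            n_na_kaks += 1
        else:
            ratios.append(pe.ka_ks)
    return FamilyEvolution(
        family_id=family_id,
        avg_divergence=sum(divs) / len(divs) if divs else None,
        avg_ka_ks=sum(ratios) / len(ratios) if ratios else None,
        n_pairs=n_pairs,
        n_na_divergence=n_na_div,
        n_na_ka_ks=n_na_kaks,
    )
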