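"""Synthetic multi-species NBS repertoires with known truth.

The generator evolves an ancestral set of NBS genes down a user-supplied
species tree: per-branch codon substitution with an accept/reject scheme
enforcing a per-family target dN/dS, Poisson gene duplications (tandem
copies placed within the tandem window on the same scaffold, dispersed
copies on fresh scaffolds), gene losses, optional whole-genome
duplication, planted segmental-duplication events that copy an NBS gene
together with its 15-gene flanking windows, and planted terminal-branch
expansions that create species-specific clades.  Each NBS gene lives on a
scaffold padded with unrelated single-exon "filler" genes so that flanking
-gene windows and physical tandem distances are meaningful.

Sequences evolve without indels, so the emitted CDS of one family are
mutually aligned as-is and the NB-ARC domain occupies the same protein
span in every gene; the bundles are therefore self-aligning and no
external aligner is needed to run the full pipeline on them.

Everything is driven by one integer seed; identical seeds give
byte-identical bundles.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from skbio import TreeNode

from .evolution import BASES, CODON_TABLE, STOP_CODONS
from .genome_io import (
    LRR,
    NB_ARC,
    TIR,
    DomainHit,
    GeneModel,
    GenomeAnnotation,
    write_domain_table,
    write_fasta,
    write_gff3,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)

# Fixed protein architecture (1-based residue spans on the 300-aa protein).
TIR_SPAN = (1, 80)
CC_SPAN = (5, 60)  # heptad repeat region of CC-type genes
NBARC_SPAN = (91, 250)
LRR_SPAN = (260, 300)
HEPTAD = "LEALEGK"  # canonical leucine-zipper repeat unit

ARCHITECTURES = ("TNL", "TN", "CNL", "CN", "XNL", "XN")


@dataclass
class SimConfig:
    """All knobs of the simulator; the defaults define the study conditions."""

    species_newick: str = "((A:0.04,B:0.04):0.03,C:0.07);"
    seed: int = 0
    n_ancestral_genes: int = 30
    n_codons: int = 300
    # divergence of each founding family's NB-ARC domain from the shared
    # ancestral domain (the domain is homologous across the whole
    # repertoire, as in real NBS genes, while the termini are family-private)
    ancestral_domain_divergence: float = 0.42
    arch_weights: tuple[float, ...] = (0.25, 0.10, 0.25, 0.10, 0.15, 0.15)  # per ARCHITECTURES
    family_dnds: tuple[float, ...] = (0.2, 0.5, 1.0)  # cycled over ancestral families
    dup_rate: float = 3.0  # duplications / gene / unit branch length
    loss_rate: float = 0.8
    tandem_fraction: float = 0.6
    arch_loss_prob: float = 0.05  # TIR-domain loss on duplication (creates X genes)
    wgd_branches: tuple[str, ...] = ()
    segmental_events_per_species: int = 2
    expansions_per_species: int = 2
    expansion_size_range: tuple[int, int] = (3, 5)  # final clade size incl. parent
    expansion_copy_divergence: float = 0.005
    segmental_block_divergence: float = 0.02
    flank_genes: int = 15
    filler_codons: int = 150
    intergenic_bp: tuple[int, int] = (8000, 12000)
    tandem_gap_bp: tuple[int, int] = (2000, 8000)
    intron_bp: int = 200
    tir_exon_mean: float = 6.2
    nontir_exon_mean: float = 2.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.tandem_fraction <= 1.0):
            raise ValueError("tandem_fraction must be in [0, 1]")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if any(d <= 0 for d in self.family_dnds):
            raise ValueError("dN/dS targets must be > 0")


# ---------------------------------------------------------------------------
# Codon-level mutation with dN/dS control
# ---------------------------------------------------------------------------

def mutate_cds(cds: str, branch_length: float, dnds_target: float, seed) -> str:
    """Evolve a CDS by accept/reject single-base codon changes.

    Synonymous proposals are always accepted, nonsynonymous ones with
    probability ``dnds_target`` (capped at 1), proposals creating stop
    codons are rejected.  The number of accepted substitutions is
    Poisson(branch_length * len(cds)).  ``seed`` may be an integer or a
    numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(cds)
    if L % 3:
        raise ValueError("CDS length must be a multiple of 3")
    n_target = int(rng.poisson(branch_length * L))
    if n_target == 0:
        return cds
    seq = list(cds)
    accepted = 0
    attempts = 0
    max_attempts = 200 * n_target + 1000
    omega = min(dnds_target, 1.0)
    while accepted < n_target and attempts < max_attempts:
        # proposals are drawn in batches but applied strictly in order
        k = min(max(4 * (n_target - accepted), 16), max_attempts - attempts)
        positions = rng.integers(L, size=k)
        bases = rng.integers(4, size=k)
        unif = rng.random(size=k)
        for pos, bi, u in zip(positions, bases, unif):
            attempts += 1
            pos = int(pos)
            old = seq[pos]
            new = BASES[bi]
            if new == old:
                continue
            c0 = pos - pos % 3
            codon = "".join(seq[c0 : c0 + 3])
            mutant = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_TABLE[codon] != CODON_TABLE[mutant] and u >= omega:
                continue
            seq[pos] = new
            accepted += 1
            if accepted >= n_target:
                break
    return "".join(seq)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    picks = rng.random(size=len(protein))
    return "".join(
        _CODONS_FOR[aa][int(p * len(_CODONS_FOR[aa]))]
        for aa, p in zip(protein, picks)
    )


def _ancestral_protein(arch: str, n_aa: int, rng: np.random.Generator) -> str:
    prot = list(_random_protein(rng, n_aa))
    if arch.startswith("C"):
        lo, hi = CC_SPAN
        block = (HEPTAD * math.ceil((hi - lo + 1) / len(HEPTAD)))[: hi - lo + 1]
        prot[lo - 1 : hi] = block
    return "".join(prot)


# ---------------------------------------------------------------------------
# Evolving genome state
# ---------------------------------------------------------------------------

@dataclass
class SimGene:
    uid: str
    kind: str  # "nbs" | "filler"
    cds: str
    family: str | None = None
    arch: str | None = None  # current domain architecture
    klass: str | None = None  # truth class (from the founding family)
    dnds: float = 1.0
    tandem_child: bool = False
    cluster: str | None = None  # terminal-branch duplication cluster


@dataclass
class Scaffold:
    units: list[SimGene]


@dataclass
class TruthTables:
    families: dict[str, str] = field(default_factory=dict)  # gene id -> family
    klass: dict[str, str] = field(default_factory=dict)
    arch: dict[str, str] = field(default_factory=dict)
    family_dnds: dict[str, float] = field(default_factory=dict)
    tandem_arrays: dict[int, list[list[str]]] = field(default_factory=dict)  # window -> arrays
    segmental_blocks: list[dict] = field(default_factory=list)
    expansion_clades: list[dict] = field(default_factory=list)
    species_totals: dict[str, dict] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "truth_genes.tsv", "w") as fh:
            fh.write("gene_id\tfamily\tklass\tarch\n")
            for gid in sorted(self.families):
                fh.write(
                    f"{gid}\t{self.families[gid]}\t{self.klass[gid]}\t{self.arch[gid]}\n"
                )
        payload = {
            "family_dnds": self.family_dnds,
            "tandem_arrays": {str(k): v for k, v in self.tandem_arrays.items()},
            "segmental_blocks": self.segmental_blocks,
            "expansion_clades": self.expansion_clades,
            "species_totals": self.species_totals,
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SpeciesBundle:
    species: str
    annotation: GenomeAnnotation
    cds: dict[str, str]
    protein: dict[str, str]
    domain_hits: list[DomainHit]

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff": str(outdir / f"{self.species}.gff3"),
            "cds": str(outdir / f"{self.species}.cds.fasta"),
            "protein": str(outdir / f"{self.species}.protein.fasta"),
            "domains": str(outdir / f"{self.species}.domains.tsv"),
        }
        write_gff3(self.annotation, paths["gff"])
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.protein, paths["protein"])
        write_domain_table(self.domain_hits, paths["domains"])
        return paths


class _Simulator:
    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.uid_counter = 0
        self.truth = TruthTables()
        self.bundles: dict[str, SpeciesBundle] = {}
        self.cluster_counter = 0

    def new_uid(self) -> str:
        self.uid_counter += 1
        return f"g{self.uid_counter:05d}"

    # -- ancestral state ----------------------------------------------------

    def ancestral_state(self) -> list[Scaffold]:
        cfg, rng = self.cfg, self.rng
        weights = np.asarray(cfg.arch_weights, dtype=float)
        weights = weights / weights.sum()
        # one homologous NB-ARC domain underlies every family
        dom_lo, dom_hi = (NBARC_SPAN[0] - 1) * 3, NBARC_SPAN[1] * 3
        shared_domain = _reverse_translate(
            _random_protein(rng, NBARC_SPAN[1] - NBARC_SPAN[0] + 1), rng
        )
        scaffolds = []
        for k in range(cfg.n_ancestral_genes):
            fam = f"anc{k + 1:03d}"
            arch = ARCHITECTURES[int(rng.choice(len(ARCHITECTURES), p=weights))]
            klass = "TIR" if arch.startswith("T") else "nonTIR"
            dnds = cfg.family_dnds[k % len(cfg.family_dnds)]
            self.truth.family_dnds[fam] = dnds
            prot = _ancestral_protein(arch, cfg.n_codons, rng)
            cds = _reverse_translate(prot, rng)
            fam_domain = mutate_cds(
                shared_domain, cfg.ancestral_domain_divergence, 1.0, rng
            )
            cds = cds[:dom_lo] + fam_domain + cds[dom_hi:]
            gene = SimGene(
                uid=self.new_uid(), kind="nbs", cds=cds,
                family=fam, arch=arch, klass=klass, dnds=dnds,
            )
            units = (
                [self._new_filler() for _ in range(cfg.flank_genes)]
                + [gene]
                + [self._new_filler() for _ in range(cfg.flank_genes)]
            )
            scaffolds.append(Scaffold(units))
        return scaffolds

    def _new_filler(self) -> SimGene:
        prot = _random_protein(self.rng, self.cfg.filler_codons)
        return SimGene(uid=self.new_uid(), kind="filler",
                       cds=_reverse_translate(prot, self.rng))

    # -- branch evolution ---------------------------------------------------

    def evolve_branch(
        self, scaffolds: list[Scaffold], branch_length: float, terminal: str | None
    ) -> list[Scaffold]:
        cfg, rng = self.cfg, self.rng
        # substitutions
        for scaf in scaffolds:
            for g in scaf.units:
                omega = g.dnds if g.kind == "nbs" else 1.0
                g.cds = mutate_cds(g.cds, branch_length, omega, rng)
        # losses
        p_loss = -math.expm1(-cfg.loss_rate * branch_length)
        for scaf in scaffolds:
            scaf.units = [
                g
                for g in scaf.units
                if g.kind != "nbs" or rng.random() >= p_loss
            ]
        # duplications
        new_scaffolds: list[Scaffold] = []
        for scaf in scaffolds:
            i = 0
            while i < len(scaf.units):
                g = scaf.units[i]
                if g.kind == "nbs":
                    for _ in range(int(rng.poisson(cfg.dup_rate * branch_length))):
                        copy = self._copy_gene(g, rng)
                        # the copy has existed for part of the branch
                        age = float(rng.random()) * branch_length
                        copy.cds = mutate_cds(copy.cds, age, copy.dnds, rng)
                        if terminal is not None:
                            self._tag_cluster(g, copy, terminal)
                        if rng.random() < cfg.tandem_fraction:
                            copy.tandem_child = True
                            scaf.units.insert(i + 1, copy)
                        else:
                            new_scaffolds.append(self._dispersed_scaffold(copy))
                i += 1
        scaffolds.extend(new_scaffolds)
        return scaffolds

    def _copy_gene(self, g: SimGene, rng: np.random.Generator) -> SimGene:
        copy = replace(g, uid=self.new_uid(), tandem_child=False)
        if copy.arch and copy.arch.startswith("T") and rng.random() < self.cfg.arch_loss_prob:
            copy.arch = "X" + copy.arch[1:]  # TIR domain lost; class kept by descent
        return copy

    def _dispersed_scaffold(self, gene: SimGene) -> Scaffold:
        n = self.cfg.flank_genes
        return Scaffold(
            [self._new_filler() for _ in range(n)]
            + [gene]
            + [self._new_filler() for _ in range(n)]
        )

    def _tag_cluster(self, parent: SimGene, copy: SimGene, species: str) -> None:
        if parent.cluster is None:
            self.cluster_counter += 1
            parent.cluster = f"{species}_x{self.cluster_counter:03d}"
        copy.cluster = parent.cluster

    def apply_wgd(self, scaffolds: list[Scaffold]) -> list[Scaffold]:
        copies = []
        for scaf in scaffolds:
            copies.append(
                Scaffold([replace(g, uid=self.new_uid()) for g in scaf.units])
            )
        return scaffolds + copies

    # -- planted terminal-branch events ------------------------------------

    def plant_expansions(self, scaffolds: list[Scaffold], species: str) -> None:
        cfg, rng = self.cfg, self.rng
        candidates = [
            (si, ui)
            for si, scaf in enumerate(scaffolds)
            for ui, g in enumerate(scaf.units)
            if g.kind == "nbs" and g.cluster is None
        ]
        for _ in range(cfg.expansions_per_species):
            if not candidates:
                break
            pick = int(rng.integers(len(candidates)))
            si, ui = candidates.pop(pick)
            parent = scaffolds[si].units[ui]
            size = int(rng.integers(cfg.expansion_size_range[0], cfg.expansion_size_range[1] + 1))
            self._tag_cluster(parent, parent, species)  # opens the cluster
            insert_at = ui
            for _ in range(size - 1):
                copy = self._copy_gene(parent, rng)
                copy.cds = mutate_cds(copy.cds, cfg.expansion_copy_divergence, parent.dnds, rng)
                copy.cluster = parent.cluster
                copy.tandem_child = True
                insert_at += 1
                scaffolds[si].units.insert(insert_at, copy)
            # candidate indices after the insertion point are now stale
            candidates = [
                (s, u)
                for s, u in candidates
                if s != si or u <= ui
            ]

    def plant_segmental(self, scaffolds: list[Scaffold], species: str) -> None:
        cfg, rng = self.cfg, self.rng
        anchors = [
            (si, ui)
            for si, scaf in enumerate(scaffolds)
            for ui, g in enumerate(scaf.units)
            if g.kind == "nbs" and g.cluster is None
        ]
        for _ in range(cfg.segmental_events_per_species):
            if not anchors:
                break
            pick = int(rng.integers(len(anchors)))
            si, ui = anchors.pop(pick)
            scaf = scaffolds[si]
            lo, hi = max(0, ui - cfg.flank_genes), min(len(scaf.units), ui + cfg.flank_genes + 1)
            window = scaf.units[lo:hi]
            copies = []
            anchor_copy_uid = None
            for g in window:
                c = replace(g, uid=self.new_uid(), tandem_child=False, cluster=None)
                c.cds = mutate_cds(c.cds, cfg.segmental_block_divergence,
                                   c.dnds if c.kind == "nbs" else 1.0, rng)
                if g.uid == scaf.units[ui].uid:
                    anchor_copy_uid = c.uid
                copies.append(c)
            scaffolds.append(Scaffold(copies))
            self.truth.segmental_blocks.append(
                {
                    "species": species,
                    "anchor_a": f"{species}_{scaf.units[ui].uid}",
                    "anchor_b": f"{species}_{anchor_copy_uid}",
                    "genes": [f"{species}_{g.uid}" for g in window]
                    + [f"{species}_{c.uid}" for c in copies],
                }
            )

    # -- emission -----------------------------------------------------------

    def emit_species(self, species: str, scaffolds: list[Scaffold]) -> SpeciesBundle:
        cfg, rng = self.cfg, self.rng
        genes: list[GeneModel] = []
        cds_map: dict[str, str] = {}
        prot_map: dict[str, str] = {}
        hits: list[DomainHit] = []
        n_nbs = 0
        for s_idx, scaf in enumerate(scaffolds, 1):
            scaffold_name = f"{species}_scf{s_idx:03d}"
            cursor = 0
            for g in scaf.units:
                gid = f"{species}_{g.uid}"
                gap = (
                    int(rng.integers(*cfg.tandem_gap_bp))
                    if g.tandem_child
                    else int(rng.integers(*cfg.intergenic_bp))
                )
                start = cursor + gap
                if g.kind == "nbs":
                    n_nbs += 1
                    mean = cfg.tir_exon_mean if g.klass == "TIR" else cfg.nontir_exon_mean
                    n_exons = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
                else:
                    n_exons = 1
                exons, end = _exon_layout(start, len(g.cds), n_exons, cfg.intron_bp, rng)
                protein = _translate(g.cds)
                genes.append(
                    GeneModel(
                        gene_id=gid, species=species, scaffold=scaffold_name,
                        start=start, end=end,
                        strand="+" if rng.random() < 0.5 else "-",
                        exons=exons, cds=g.cds, protein=protein,
                    )
                )
                cds_map[gid] = g.cds
                prot_map[gid] = protein
                if g.kind == "nbs":
                    hits.extend(self._domain_rows(gid, g, rng))
                    self.truth.families[gid] = g.family
                    self.truth.klass[gid] = g.klass
                    self.truth.arch[gid] = g.arch
                cursor = end
        ann = GenomeAnnotation(species, genes)
        ann.attach_sequences(cds_map, prot_map)
        self.truth.species_totals[species] = {
            "total_genes": len(genes),
            "nbs_genes": n_nbs,
        }
        self._record_tandem_truth(species, scaffolds, ann)
        self._record_expansion_truth(species, scaffolds)
        return SpeciesBundle(species, ann, cds_map, prot_map, hits)

    def _domain_rows(self, gid: str, g: SimGene, rng) -> list[DomainHit]:
        def e() -> float:
            return float(10.0 ** -rng.uniform(10, 40))

        rows = [DomainHit(gid, NB_ARC, e(), *NBARC_SPAN)]
        if g.arch.startswith("T"):
            rows.append(DomainHit(gid, TIR, e(), *TIR_SPAN))
        if g.arch.endswith("L"):
            rows.append(DomainHit(gid, LRR, e(), *LRR_SPAN))
        return rows

    def _record_tandem_truth(
        self, species: str, scaffolds: list[Scaffold], ann: GenomeAnnotation
    ) -> None:
        for window_kb in (50, 100):
            arrays = self.truth.tandem_arrays.setdefault(window_kb, [])
            for scaf in scaffolds:
                nbs = [g for g in scaf.units if g.kind == "nbs"]
                by_fam: dict[str, list[SimGene]] = {}
                for g in nbs:
                    by_fam.setdefault(g.family, []).append(g)
                for fam in sorted(by_fam):
                    members = by_fam[fam]
                    ids = [f"{species}_{g.uid}" for g in members]
                    ids.sort(key=lambda gid: ann.genes[gid].start)
                    chain = [ids[0]]
                    for prev, cur in zip(ids, ids[1:]):
                        if (
                            ann.genes[cur].start - ann.genes[prev].start
                            <= window_kb * 1000
                        ):
                            chain.append(cur)
                        else:
                            if len(chain) >= 2:
                                arrays.append(chain)
                            chain = [cur]
                    if len(chain) >= 2:
                        arrays.append(chain)

    def _record_expansion_truth(self, species: str, scaffolds: list[Scaffold]) -> None:
        clusters: dict[str, list[str]] = {}
        for scaf in scaffolds:
            for g in scaf.units:
                if g.kind == "nbs" and g.cluster:
                    clusters.setdefault(g.cluster, []).append(f"{species}_{g.uid}")
        for cid in sorted(clusters):
            members = clusters[cid]
            if len(members) >= 3:
                self.truth.expansion_clades.append(
                    {"cluster": cid, "species": species, "members": sorted(members)}
                )

    # -- driver --------------------------------------------------------------

    def run(self) -> tuple[dict[str, SpeciesBundle], TruthTables]:
        tree = TreeNode.read(io.StringIO(self.cfg.species_newick), format="newick")
        state = self.ancestral_state()
        self._descend(tree, state, is_root=True)
        return self.bundles, self.truth

    def _descend(self, node: TreeNode, state: list[Scaffold], is_root: bool = False) -> None:
        if not is_root:
            bl = float(node.length or 0.0)
            terminal = node.name if node.is_tip() else None
            state = self.evolve_branch(state, bl, terminal)
            name = node.name or ""
            if name in self.cfg.wgd_branches:
                state = self.apply_wgd(state)
            if node.is_tip():
                self.plant_expansions(state, node.name)
                self.plant_segmental(state, node.name)
                self.bundles[node.name] = self.emit_species(node.name, state)
                return
        for child in node.children:
            self._descend(child, _clone_state(state))


def _clone_state(state: list[Scaffold]) -> list[Scaffold]:
    return [Scaffold([replace(g) for g in scaf.units]) for scaf in state]


def _translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def _exon_layout(
    start: int, cds_len: int, n_exons: int, intron_bp: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], int]:
    """Split a CDS into n exon intervals separated by fixed-size introns."""
    n_exons = max(1, min(n_exons, cds_len))
    cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0] + [int(c) for c in cuts] + [cds_len]
    exons = []
    pos = start
    for a, b in zip(bounds, bounds[1:]):
        exons.append((pos, pos + (b - a)))
        pos += (b - a) + intron_bp
    end = exons[-1][1]
    return exons, end


def simulate_repertoire(cfg: SimConfig) -> tuple[dict[str, SpeciesBundle], TruthTables]:
    """Generate per-species annotation bundles and the matching truth tables."""
    return _Simulator(cfg).run()


def write_bundles(
    bundles: Mapping[str, SpeciesBundle], truth: TruthTables, outdir: str | Path
) -> dict[str, dict[str, str]]:
    outdir = Path(outdir)
    manifest = {}
    for sp in sorted(bundles):
        paths = bundles[sp].write(outdir / sp)
        # store paths relative to the bundle root so the directory is portable
        manifest[sp] = {
            k: str(Path(v).relative_to(outdir)) for k, v in paths.items()
        }
    truth.write(outdir / "truth")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
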