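"""End-to-end orchestration and survey-style report tables.

``run_all`` drives the stages in method order — identify → classify →
cluster → evolution → duplications → phylogeny → clades → reports — on a
set of per-species annotation bundles, writing one TSV artifact per stage
plus a Newick tree and a reproducibility record (thresholds, seed,
version, per-stage counts).  All randomness flows from the single seed in
the run configuration, so a rerun with the same inputs and seed reproduces
every artifact byte for byte (the free-text log with wall-clock timings is
the one deliberately non-deterministic file).

The module also bundles the published repertoire-survey count tables
(per-genome NBS totals and TIR/non-TIR subtype counts) used to exercise
the report shapes against real numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import duplication, families, genome_io, identify, phylogeny
from .evolution import family_evolution
from .genome_io import GenomeAnnotation, write_tsv

logger = logging.getLogger("nbskit")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def percentage_str(nbs: int, total: int) -> str:
    """Share of NBS genes as a half-up-rounded two-decimal percentage."""
    if total <= 0:
        raise ValueError("total gene count must be positive")
    if nbs < 0:
        raise ValueError("NBS count must be >= 0")
    pct = Decimal(nbs) / Decimal(total) * 100
    return f"{pct.quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"


def report_table1(counts: Iterable[tuple[str, int, int]]) -> pd.DataFrame:
    """Per-species totals: (species, total genes, NBS genes) -> report rows."""
    rows = [
        {
            "species": sp,
            "total_genes": total,
            "nbs_genes": nbs,
            "percentage": percentage_str(nbs, total),
        }
        for sp, total, nbs in counts
    ]
    return pd.DataFrame(rows, columns=["species", "total_genes", "nbs_genes", "percentage"])


def report_table2(genes: Sequence[identify.NBSGene]) -> pd.DataFrame:
    """Long-format subtype counts by (species, class, subtype)."""
    rows = []
    for g in genes:
        rows.append({"species": g.species, "klass": g.klass, "subtype": g.subtype})
    if not rows:
        return pd.DataFrame(columns=["species", "klass", "subtype", "count"])
    df = (
        pd.DataFrame(rows)
        .value_counts(["species", "klass", "subtype"])
        .reset_index(name="count")
        .sort_values(["species", "klass", "subtype"])
        .reset_index(drop=True)
    )
    return df


def subtype_summary(counts: pd.DataFrame) -> dict:
    """Grand sums and the TNL/TIR ratio from a long-format subtype table.

    Sums are always recomputed from the per-species cells, never taken
    from any pre-printed total row.
    """
    if counts.empty:
        return {
            "tir_total": 0, "nontir_total": 0,
            "subtype_totals": {}, "tnl_tir_ratio": None,
        }
    tir = counts[counts.klass == "TIR"]
    nontir = counts[counts.klass == "nonTIR"]
    tir_total = int(tir["count"].sum())
    tnl_total = int(tir[tir.subtype == "TNL"]["count"].sum())
    by_subtype = {
        (k, s): int(v)
        for (k, s), v in counts.groupby(["klass", "subtype"])["count"].sum().items()
    }
    return {
        "tir_total": tir_total,
        "nontir_total": int(nontir["count"].sum()),
        "subtype_totals": by_subtype,
        "tnl_total": tnl_total,
        "tnl_tir_ratio": (tnl_total / tir_total) if tir_total else None,
    }


def published_genome_counts() -> pd.DataFrame:
    """Bundled published survey: per-genome gene totals and NBS counts."""
    with resources.files("nbskit.data").joinpath("published_genome_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_subtype_counts() -> pd.DataFrame:
    """Bundled published survey: TIR/non-TIR subtype counts per genome."""
    with resources.files("nbskit.data").joinpath("published_subtype_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class SpeciesInput:
    species: str
    gff: str
    cds: str
    protein: str
    domains: str


@dataclass
class RunConfig:
    species_inputs: list[SpeciesInput]
    outdir: str
    seed: int = 0
    e_cutoff: float = 1e-4
    coils_threshold: float = 0.9
    min_identity: float = 0.60
    min_coverage: float = 0.60
    min_family_size_evolution: int = 3
    tandem_windows_kb: tuple[int, ...] = (50, 100)
    segmental_flank: int = 15
    segmental_min_pairs: int = 6
    bootstrap_reps: int = 1000
    clade_min_size: int = 3
    clade_min_similarity: float = 0.80
    clade_min_support: float = 50.0
    domain_alignment: str | None = None  # aligned FASTA overriding self-alignment
    species_order: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = [SpeciesInput(**s) for s in raw.pop("species")]
        for key in ("tandem_windows_kb",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(species_inputs=inputs, **raw)

    def validate(self) -> None:
        for si in self.species_inputs:
            for p in (si.gff, si.cds, si.protein, si.domains):
                if not Path(p).exists():
                    raise FileNotFoundError(f"{si.species}: missing input {p}")
        if not (0 < self.coils_threshold <= 1):
            raise ValueError("coils_threshold must be in (0, 1]")
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must be in [0, 1]")


def config_from_simdir(simdir: str | Path, outdir: str | Path, **overrides) -> RunConfig:
    """Build a run configuration from a simulator output directory."""
    simdir = Path(simdir)
    with open(simdir / "manifest.json") as fh:
        manifest = json.load(fh)
    inputs = [
        SpeciesInput(
            species=sp,
            **{k: str(simdir / paths[k]) for k in ("gff", "cds", "protein", "domains")},
        )
        for sp, paths in sorted(manifest.items())
    ]
    return RunConfig(species_inputs=inputs, outdir=str(outdir), **overrides)


def load_nbs_genes_tsv(
    path: str | Path,
    cds: Mapping[str, str] | None = None,
    protein: Mapping[str, str] | None = None,
) -> list[identify.NBSGene]:
    """Rebuild classified NBS genes from a ``nbs_genes.tsv`` artifact.

    Exon structure is not stored in the artifact, so the rebuilt gene
    models carry the exon count but no exon intervals.
    """
    df = pd.read_csv(path, sep="\t")
    genes = []
    for row in df.itertuples():
        gm = genome_io.GeneModel(
            gene_id=row.gene_id, species=row.species, scaffold=row.scaffold,
            start=int(row.start), end=int(row.end), strand="+",
            cds=(cds or {}).get(row.gene_id, ""),
            protein=(protein or {}).get(row.gene_id, ""),
        )
        genes.append(
            identify.NBSGene(
                gene=gm, nbarc_span=(int(row.nbarc_start), int(row.nbarc_end)),
                has_tir=bool(row.has_tir), has_lrr=bool(row.has_lrr),
                has_cc=bool(row.has_cc), klass=row.klass, subtype=row.subtype,
                exon_count=int(row.exons),
            )
        )
    return genes


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunResult:
    annotations: dict[str, GenomeAnnotation]
    nbs_genes: list[identify.NBSGene]
    families: list
    family_evolution: list
    tandem: dict[int, list]
    tandem_percent: dict[int, dict[str, float]]
    segmental: list
    tree: phylogeny.PhyloTree | None
    clades: list
    table1: pd.DataFrame
    table2: pd.DataFrame
    counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# The pipeline driver
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> RunResult:
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()

    def done(name, **counts_):
        timings[name] = time.time() - timings[name]
        logger.info("stage %s done in %.2fs %s", name, timings[name], counts_)

    # ---- load ------------------------------------------------------------
    stage("load")
    annotations: dict[str, GenomeAnnotation] = {}
    hits_by_species: dict[str, list] = {}
    try:
        for si in cfg.species_inputs:
            ann = genome_io.read_gff3(si.gff, si.species)
            ann.attach_sequences(
                genome_io.read_fasta(si.cds), genome_io.read_fasta(si.protein)
            )
            annotations[si.species] = ann
            hits_by_species[si.species] = genome_io.read_domain_table(si.domains)
    except Exception as exc:
        raise StageError("load", exc) from exc
    done("load", species=len(annotations))

    # ---- identify + provisional classification ---------------------------
    stage("identify")
    try:
        nbs_genes: list[identify.NBSGene] = []
        for sp in sorted(annotations):
            ann, hits = annotations[sp], hits_by_species[sp]
            keep = identify.select_candidates(hits, cfg.e_cutoff)
            candidates = [ann.genes[g] for g in sorted(keep) if g in ann.genes]
            candidates = identify.deduplicate_by_locus(candidates)
            by_gene: dict[str, list] = {}
            for h in hits:
                by_gene.setdefault(h.gene_id, []).append(h)
            for cand in candidates:
                coils = identify.coils_score(cand.protein) if cand.protein else None
                if coils is None:
                    continue
                nbs_genes.append(
                    identify.assign_class_subtype(
                        cand, by_gene.get(cand.gene_id, []), coils,
                        tree_context=None, e_cutoff=cfg.e_cutoff,
                        coils_threshold=cfg.coils_threshold,
                    )
                )
        nbs_genes.sort(key=lambda g: g.gene_id)
    except Exception as exc:
        raise StageError("identify", exc) from exc
    done("identify", nbs_genes=len(nbs_genes))

    # ---- NBS-domain alignment + tree -------------------------------------
    stage("phylogeny")
    tree = None
    domain_aln: dict[str, str] = {}
    try:
        if cfg.domain_alignment:
            domain_aln = genome_io.read_fasta(cfg.domain_alignment)
            domain_aln = {g.gene_id: domain_aln[g.gene_id] for g in nbs_genes}
        else:
            domain_aln = {g.gene_id: phylogeny.extract_nbs_domain(g) for g in nbs_genes}
            if len({len(s) for s in domain_aln.values()}) > 1:
                raise ValueError(
                    "extracted NBS domains differ in length; supply an aligned "
                    "FASTA via domain_alignment"
                )
        if len(domain_aln) >= 3:
            tree = phylogeny.bootstrap(
                domain_aln, n_reps=cfg.bootstrap_reps, seed=cfg.seed
            )
            # resolve X-type genes from their tree neighbourhood
            classified = {
                g.gene_id: g.klass for g in nbs_genes if g.has_tir or g.has_cc
            }
            ctx = phylogeny.tree_class_assignment(tree, classified)
            for g in nbs_genes:
                if not g.has_tir and not g.has_cc and g.gene_id in ctx:
                    g.klass = ctx[g.gene_id]
                    if "unresolved_class" in g.flags:
                        g.flags.remove("unresolved_class")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("phylogeny", exc) from exc
    done("phylogeny", leaves=len(domain_aln))

    # ---- families ---------------------------------------------------------
    stage("cluster")
    try:
        fams = families.cluster_families(
            nbs_genes,
            min_identity=cfg.min_identity,
            min_coverage=cfg.min_coverage,
            species_order=cfg.species_order or sorted(annotations),
        )
        type_rows = families.family_stats(fams, cfg.min_family_size_evolution)
    except Exception as exc:
        raise StageError("cluster", exc) from exc
    done("cluster", families=len(fams))

    # ---- evolution ---------------------------------------------------------
    stage("evolution")
    fam_evo = []
    try:
        for fam in fams:
            if fam.size < cfg.min_family_size_evolution:
                continue
            seqs = {g.gene_id: g.gene.cds for g in fam.members}
            if len({len(s) for s in seqs.values()}) > 1:
                logger.warning(
                    "family %s: members differ in CDS length; supply aligned "
                    "sequences to include it", fam.family_id,
                )
                continue
            fam_evo.append(
                family_evolution(
                    fam.family_id, list(seqs), seqs, cfg.min_family_size_evolution
                )
            )
    except Exception as exc:
        raise StageError("evolution", exc) from exc
    done("evolution", families_analyzed=len(fam_evo))

    # ---- duplications -------------------------------------------------------
    stage("duplication")
    try:
        tandem: dict[int, list] = {}
        tandem_pct: dict[int, dict[str, float]] = {}
        for w in cfg.tandem_windows_kb:
            tandem[w] = duplication.tandem_arrays(fams, window_kb=w)
            tandem_pct[w] = duplication.tandem_percentages(tandem[w], nbs_genes)
        seg = duplication.segmental_blocks(
            annotations, nbs_genes, fams,
            tandem=tandem.get(min(cfg.tandem_windows_kb), []),
            flank=cfg.segmental_flank, min_pairs=cfg.segmental_min_pairs,
        )
    except Exception as exc:
        raise StageError("duplication", exc) from exc
    done("duplication", segmental_blocks=len(seg))

    # ---- clades -------------------------------------------------------------
    stage("clades")
    clades = []
    try:
        if tree is not None:
            species_of = {g.gene_id: g.species for g in nbs_genes}
            clades = phylogeny.species_specific_clades(
                tree, domain_aln,
                species_of=lambda l: species_of[l],
                min_size=cfg.clade_min_size,
                min_similarity=cfg.clade_min_similarity,
                min_support=cfg.clade_min_support,
            )
    except Exception as exc:
        raise StageError("clades", exc) from exc
    done("clades", clades=len(clades))

    # ---- reports -------------------------------------------------------------
    stage("report")
    try:
        per_species_nbs: dict[str, int] = {sp: 0 for sp in annotations}
        for g in nbs_genes:
            per_species_nbs[g.species] += 1
        table1 = report_table1(
            (sp, len(annotations[sp]), per_species_nbs[sp]) for sp in sorted(annotations)
        )
        table2 = report_table2(nbs_genes)
        _write_artifacts(
            out, nbs_genes, fams, type_rows, fam_evo, tandem, tandem_pct, seg,
            tree, clades, table1, table2, cfg,
        )
    except Exception as exc:
        raise StageError("report", exc) from exc
    done("report")
    with open(out / "run.log", "w") as fh:
        for name, dt in timings.items():
            fh.write(f"{name}\t{dt:.3f}s\n")

    return RunResult(
        annotations=annotations, nbs_genes=nbs_genes, families=fams,
        family_evolution=fam_evo, tandem=tandem, tandem_percent=tandem_pct,
        segmental=seg, tree=tree, clades=clades, table1=table1, table2=table2,
        counts={
            "nbs_genes": len(nbs_genes),
            "families": len(fams),
            "clades": len(clades),
            "segmental_blocks": len(seg),
        },
    )


def _na(v):
    return "NA" if v is None else (f"{v:.6g}" if isinstance(v, float) else v)


def _write_artifacts(
    out: Path, nbs_genes, fams, type_rows, fam_evo, tandem, tandem_pct, seg,
    tree, clades, table1, table2, cfg,
) -> None:
    write_tsv(
        [
            {
                "gene_id": g.gene_id, "species": g.species,
                "scaffold": g.gene.scaffold, "start": g.gene.start,
                "end": g.gene.end, "klass": g.klass, "subtype": g.subtype,
                "has_tir": g.has_tir, "has_lrr": g.has_lrr, "has_cc": g.has_cc,
                "nbarc_start": g.nbarc_span[0], "nbarc_end": g.nbarc_span[1],
                "exons": g.exon_count, "flags": ";".join(g.flags),
            }
            for g in nbs_genes
        ],
        out / "nbs_genes.tsv",
    )
    write_tsv(
        [
            {
                "family_id": f.family_id, "size": f.size,
                "composition": f.composition_label,
                "species_specific": f.is_species_specific,
                "members": ",".join(f.member_ids),
            }
            for f in fams
        ],
        out / "families.tsv",
    )
    write_tsv(type_rows, out / "family_types.tsv")
    write_tsv(
        [
            {
                "family_id": e.family_id,
                "avg_divergence": _na(e.avg_divergence),
                "avg_ka_ks": _na(e.avg_ka_ks),
                "n_pairs": e.n_pairs,
                "n_na_divergence": e.n_na_divergence,
                "n_na_ka_ks": e.n_na_ka_ks,
            }
            for e in fam_evo
        ],
        out / "evolution.tsv",
    )
    for w, arrays in tandem.items():
        write_tsv(
            [
                {
                    "family_id": a.family_id, "species": a.species,
                    "scaffold": a.scaffold, "size": a.size,
                    "members": ",".join(a.members),
                }
                for a in arrays
            ],
            out / f"tandem_{w}kb.tsv",
        )
    write_tsv(
        [
            {"window_kb": w, "species": sp, "tandem_percent": f"{pct:.2f}"}
            for w, d in sorted(tandem_pct.items())
            for sp, pct in sorted(d.items())
        ],
        out / "tandem_percent.tsv",
    )
    write_tsv(
        [
            {
                "species": b.species, "anchor_a": b.anchor_a, "anchor_b": b.anchor_b,
                "n_pairs": b.n_pairs, "truncated": b.truncated,
                "pairs": ",".join(f"{x}:{y}" for x, y in b.syntenic_pairs),
            }
            for b in seg
        ],
        out / "segmental.tsv",
    )
    if tree is not None:
        tree.write(out / "tree.nwk")
    write_tsv(
        [
            {
                "clade_id": c.clade_id, "species": c.species, "n": c.size,
                "min_similarity": f"{c.min_pairwise_similarity:.4f}",
                "support": f"{c.support:.1f}",
                "members": ",".join(sorted(c.members)),
            }
            for c in clades
        ],
        out / "clades.tsv",
    )
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    table2.to_csv(out / "table2.tsv", sep="\t", index=False)

    meta = {
        "seed": cfg.seed,
        "thresholds": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("species_inputs", "outdir")
        },
        "counts": {
            "nbs_genes": len(nbs_genes),
            "families": len(fams),
            "families_analyzed": len(fam_evo),
            "segmental_blocks": len(seg),
            "clades": len(clades),
        },
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=list)
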