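"""Data model and readers/writers for the formats the pipeline touches.

Internally every interval is 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at the I/O boundary and nowhere else.  Protein
coordinates inside :class:`DomainHit` stay 1-based inclusive because that is
how hmmscan and Pfam report them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

# Canonical domain names.  Anything else is kept verbatim ("other" domains).
NB_ARC = "NB-ARC"
TIR = "TIR"
LRR = "LRR"

_DOMAIN_ALIASES = {
    "NB-ARC": NB_ARC,
    "NBARC": NB_ARC,
    "NB_ARC": NB_ARC,
    "PF00931": NB_ARC,
    "TIR": TIR,
    "PF01582": TIR,
}


def canonical_domain(name: str) -> str:
    """Map a raw domain label to NB-ARC / TIR / LRR, else keep it as-is.

    LRR comes in many Pfam flavours (LRR_1 .. LRR_8, LRR_NT ...); any label
    starting with "LRR" counts as an LRR hit.
    """
    key = name.strip()
    if key.upper().startswith("LRR"):
        return LRR
    return _DOMAIN_ALIASES.get(key.upper().replace("-", "_"), _DOMAIN_ALIASES.get(key, key))


class GenomeIOError(ValueError):
    """Malformed input file (message carries file/line context)."""


@dataclass
class GeneModel:
    """One annotated protein-coding gene (representative isoform only)."""

    gene_id: str
    species: str
    scaffold: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: str = ""
    protein: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id}: strand must be + or -")
        self._check_exons()

    def _check_exons(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise GenomeIOError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span"
                )
            if prev_end is not None and s < prev_end:
                raise GenomeIOError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exons) if self.exons else 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_cds(self) -> list[str]:
        """Check frame and CDS↔protein agreement; returns (and records) flags."""
        problems: list[str] = []
        if self.cds:
            if len(self.cds) % 3 != 0:
                problems.append("cds_frame")
            elif self.protein:
                translated = str(Seq(self.cds).translate())
                if translated.endswith("*"):
                    translated = translated[:-1]
                if translated != self.protein.rstrip("*"):
                    problems.append("cds_protein_mismatch")
        for p in problems:
            if p not in self.flags:
                self.flags.append(p)
        return problems


@dataclass(frozen=True)
class DomainHit:
    """A protein-domain match (1-based inclusive protein coordinates)."""

    gene_id: str
    domain: str
    e_value: float
    p_start: int
    p_end: int

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise GenomeIOError(f"domain hit {self.gene_id}: e_value must be > 0")
        if not (1 <= self.p_start <= self.p_end):
            raise GenomeIOError(
                f"domain hit {self.gene_id}: bad protein span "
                f"({self.p_start}, {self.p_end})"
            )


class GenomeAnnotation:
    """All gene models of one species plus a per-scaffold ordinal index.

    The ordinal index (rank of each gene along its scaffold by start
    coordinate) is what duplication analysis uses to cut "N flanking genes"
    windows.
    """

    def __init__(self, species: str, genes: Iterable[GeneModel]):
        self.species = species
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise GenomeIOError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        self._build_index()

    def _build_index(self) -> None:
        by_scaffold: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            by_scaffold.setdefault(g.scaffold, []).append(g)
        self.scaffold_order: dict[str, list[str]] = {}
        self.rank: dict[str, int] = {}
        for scaf, glist in by_scaffold.items():
            glist.sort(key=lambda g: (g.start, g.gene_id))
            self.scaffold_order[scaf] = [g.gene_id for g in glist]
            for i, g in enumerate(glist):
                self.rank[g.gene_id] = i

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def neighbors(self, gene_id: str, flank: int) -> list[str]:
        """The window of up to ``2*flank + 1`` gene ids centred on a gene."""
        g = self.genes[gene_id]
        order = self.scaffold_order[g.scaffold]
        i = self.rank[gene_id]
        return order[max(0, i - flank) : i + flank + 1]

    def attach_sequences(
        self,
        cds: Mapping[str, str] | None = None,
        protein: Mapping[str, str] | None = None,
        validate: bool = True,
    ) -> None:
        for g in self.genes.values():
            if cds is not None and g.gene_id in cds:
                g.cds = cds[g.gene_id]
            if protein is not None and g.gene_id in protein:
                g.protein = protein[g.gene_id]
            if validate:
                g.validate_cds()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA → {id: sequence}.  Duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise GenomeIOError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | Path, species: str) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    One representative mRNA is kept per gene: the one with the longest summed
    CDS, ties broken lexicographically by mRNA id.  1-based inclusive GFF
    coordinates become 0-based half-open.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GenomeIOError(f"{path}: GFF3 parse failed: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            def cds_len(m) -> int:
                return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

            rep = min(mrnas, key=lambda m: (-cds_len(m), m.id))
            exon_feats = list(db.children(rep, featuretype="exon"))
            if not exon_feats:
                exon_feats = list(db.children(rep, featuretype="CDS"))
        else:
            exon_feats = list(db.children(gene, featuretype="exon")) or list(
                db.children(gene, featuretype="CDS")
            )
        exons = sorted((f.start - 1, f.end) for f in exon_feats)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                species=species,
                scaffold=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
            )
        )
    return GenomeAnnotation(species, genes)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Emit gene/mRNA/exon features (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf in sorted(annotation.scaffold_order):
            for gid in annotation.scaffold_order[scaf]:
                g = annotation.genes[gid]
                base = f"{g.scaffold}\tnbskit\t"
                tail = f"\t.\t{g.strand}\t."
                fh.write(
                    base + f"gene\t{g.start + 1}\t{g.end}" + tail + f"\tID={gid}\n"
                )
                mid = f"{gid}.m1"
                fh.write(
                    base
                    + f"mRNA\t{g.start + 1}\t{g.end}"
                    + tail
                    + f"\tID={mid};Parent={gid}\n"
                )
                for k, (s, e) in enumerate(g.exons or [(g.start, g.end)], 1):
                    fh.write(
                        base + f"exon\t{s + 1}\t{e}" + tail + f"\tID={mid}.e{k};Parent={mid}\n"
                    )
                    fh.write(
                        base + f"CDS\t{s + 1}\t{e}" + tail + f"\tID={mid}.c{k};Parent={mid}\n"
                    )


def read_domain_table(path: str | Path, dialect: str = "tsv") -> list[DomainHit]:
    """Read domain hits.

    ``dialect="tsv"`` expects a header line with columns
    gene_id, domain, e_value, p_start, p_end.  ``dialect="domtblout"``
    accepts raw ``hmmscan --domtblout`` output (target = domain model,
    query = protein; per-domain independent E-value and alignment
    coordinates are used).
    """
    hits: list[DomainHit] = []
    if dialect == "domtblout":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 22:
                    raise GenomeIOError(f"{path}:{lineno}: short domtblout row")
                hits.append(
                    DomainHit(
                        gene_id=parts[3],
                        domain=canonical_domain(parts[0]),
                        e_value=float(parts[12]),
                        p_start=int(parts[17]),
                        p_end=int(parts[18]),
                    )
                )
        return hits

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        want = ["gene_id", "domain", "e_value", "p_start", "p_end"]
        try:
            idx = [header.index(w) for w in want]
        except ValueError as exc:
            raise GenomeIOError(f"{path}: missing column: {exc}") from exc
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                raise GenomeIOError(f"{path}:{lineno}: expected {len(header)} columns")
            try:
                hits.append(
                    DomainHit(
                        gene_id=parts[idx[0]],
                        domain=canonical_domain(parts[idx[1]]),
                        e_value=float(parts[idx[2]]),
                        p_start=int(parts[idx[3]]),
                        p_end=int(parts[idx[4]]),
                    )
                )
            except (ValueError, GenomeIOError) as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdomain\te_value\tp_start\tp_end\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.domain}\t{h.e_value:g}\t{h.p_start}\t{h.p_end}\n")


# ---------------------------------------------------------------------------
# Generic tabular / tree output
# ---------------------------------------------------------------------------

def write_tsv(records: Sequence[Mapping | object], path: str | Path, columns=None) -> None:
    """Write dataclasses or mappings as a TSV with a header row."""
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(row.get(c, "")) for c in columns) + "\n")


def _cell(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (list, tuple, set, frozenset)):
        return ",".join(str(x) for x in sorted(v, key=str))
    return str(v)


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (skbio TreeNode or an object exposing one) to Newick."""
    node = getattr(tree, "root", tree)
    node.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick", convert_underscores=False)
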