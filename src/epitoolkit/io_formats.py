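"""Readers and writers for the standard formats the pipeline consumes.

All coordinates are 1-based inclusive, exactly as in GFF3 and BLAST tabular
output; nothing here converts to half-open coordinates. Every writer emits
LF line endings and a deterministic field order, and every reader parses the
writer's output back to an equal value.

Supported dialects:

* FASTA (id = header token before first whitespace, sequences uppercased)
* GFF3 with gene/mRNA/CDS features linked by ID/Parent
* InterProScan-style TSV (protein id col 1, accession col 5, start/stop
  cols 7-8, e-value col 9, ``-`` meaning "no e-value")
* OrthoFinder ``Orthogroups.tsv`` (classic, not the hierarchical N0.tsv)
* BLAST tabular ``-outfmt 6`` (12 columns)
* newick via :mod:`dendropy`
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "DomainAnnotation",
    "Orthogroup",
    "BlastHit",
    "read_fasta",
    "write_fasta",
    "read_gff_genes",
    "write_gff_genes",
    "read_domain_table",
    "write_domain_table",
    "read_orthogroups",
    "write_orthogroups",
    "read_blast_tab",
    "write_blast_tab",
    "read_newick",
    "write_newick",
]

# IUPAC nucleotide alphabet incl. ambiguity codes and gap-free U (RNA).
_NT_CHARS = set("ACGTUNRYSWKMBDHV")
_PFAM_RE = re.compile(r"^PF\d{5}$")


@dataclass(frozen=True)
class SequenceRecord:
    """A named biosequence; ``moltype`` is ``"nt"`` or ``"aa"``."""

    id: str
    seq: str
    moltype: str = "nt"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"moltype must be 'nt' or 'aa', got {self.moltype!r}")


def guess_moltype(seq: str) -> str:
    letters = set(seq.upper()) - {"-", "*"}
    return "nt" if letters <= _NT_CHARS else "aa"


@dataclass
class GeneModel:
    """A gene with 1-based inclusive coordinates and sorted CDS intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    product_protein_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        self.cds_intervals = sorted(self.cds_intervals)
        prev_end = 0
        for s, e in self.cds_intervals:
            if s > e:
                raise ValueError(f"{self.gene_id}: CDS interval {s}-{e} inverted")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: CDS {s}-{e} outside gene span")
            prev_end = e

    @property
    def cds_span(self) -> tuple[int, int]:
        if not self.cds_intervals:
            raise ValueError(f"{self.gene_id} has no CDS")
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class DomainAnnotation:
    """One (protein, domain, interval, e-value) evidence record.

    ``evalue`` is ``None`` when the annotation source reported none
    (the InterProScan ``-`` sentinel).
    """

    protein_id: str
    domain_acc: str
    start: int
    end: int
    evalue: Optional[float]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}/{self.domain_acc}: start > end")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"{self.protein_id}/{self.domain_acc}: negative e-value")


@dataclass
class Orthogroup:
    og_id: str
    members: dict[str, list[str]]
    tree: Optional[dendropy.Tree] = None

    def all_members(self) -> set[str]:
        return {p for plist in self.members.values() for p in plist}

    def __post_init__(self) -> None:
        if self.tree is not None:
            leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
            missing = leaves - self.all_members()
            if missing:
                raise ValueError(
                    f"{self.og_id}: tree leaves not among members: {sorted(missing)}"
                )


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")
        if self.qstart > self.qend:
            raise ValueError("qstart must not exceed qend")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, moltype: Optional[str] = None) -> list[SequenceRecord]:
    """Read FASTA; ids are header tokens before the first whitespace."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq, moltype or guess_moltype(seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into :class:`GeneModel` records.

    CDS features are attached to genes through their Parent chain (either
    directly or via an mRNA). A CDS whose Parent is unknown, or a gene with
    strand ``.``, is an error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known_ids = {f.id for f in db.all_features()}
    gene_of_feature: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    order: list[str] = []

    for g in db.features_of_type("gene", order_by="start"):
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id}: strand {g.strand!r} not allowed")
        gene_of_feature[g.id] = g.id
        genes[g.id] = GeneModel(g.id, g.seqid, g.start, g.end, g.strand)
        order.append(g.id)

    for m in db.features_of_type("mRNA"):
        for parent in m.attributes.get("Parent", []):
            if parent in genes:
                gene_of_feature[m.id] = parent
                genes[parent].product_protein_ids.append(m.id)

    cds_by_gene: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genes}
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent", [])
        if not parents:
            raise ValueError(f"CDS at {c.seqid}:{c.start}-{c.end} has no Parent")
        for parent in parents:
            if parent not in known_ids or parent not in gene_of_feature:
                raise ValueError(
                    f"CDS at {c.seqid}:{c.start}-{c.end} has unknown Parent {parent!r}"
                )
            cds_by_gene[gene_of_feature[parent]].append((c.start, c.end))

    out = []
    for gid in order:
        g = genes[gid]
        out.append(
            GeneModel(
                g.gene_id, g.chrom, g.start, g.end, g.strand,
                sorted(cds_by_gene[gid]), g.product_protein_ids,
            )
        )
    return out


def write_gff_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/CDS rows; one mRNA per gene carrying all CDS parts."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tepitoolkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = g.product_protein_ids[0] if g.product_protein_ids else f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tepitoolkit\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for s, e in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\tepitoolkit\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# InterProScan-style domain table


def read_domain_table(
    path: str | Path, accession_filter: Optional[str] = r"^PF\d{5}$"
) -> list[DomainAnnotation]:
    """Read an InterProScan-style TSV.

    Columns used: 1 protein id, 5 signature accession, 7 start, 8 stop,
    9 e-value (``-`` means "no e-value"). Extra columns are ignored. By
    default only Pfam accessions (``PF#####``) are kept; pass
    ``accession_filter=None`` to keep everything.
    """
    pattern = re.compile(accession_filter) if accession_filter else None
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 9 tab-separated columns, got {len(cols)}"
                )
            acc = cols[4]
            if pattern is not None and not pattern.match(acc):
                continue
            evalue = None if cols[8] == "-" else float(cols[8])
            out.append(DomainAnnotation(cols[0], acc, int(cols[6]), int(cols[7]), evalue))
    return out


def write_domain_table(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    """Write the 9-column InterProScan-style dialect read_domain_table expects."""
    with open(path, "w", newline="\n") as fh:
        for d in domains:
            ev = "-" if d.evalue is None else format(d.evalue, ".3g")
            fh.write(
                f"{d.protein_id}\tmd5\t0\tPfam\t{d.domain_acc}\tdesc\t"
                f"{d.start}\t{d.end}\t{ev}\n"
            )


# ---------------------------------------------------------------------------
# OrthoFinder Orthogroups.tsv


def read_orthogroups(path: str | Path) -> list[Orthogroup]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        species = header[1:]
        ogs: list[Orthogroup] = []
        owner: dict[str, str] = {}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            og_id = cols[0]
            members: dict[str, list[str]] = {}
            for sp, cell in zip(species, cols[1:]):
                ids = [p for p in cell.split(", ") if p] if cell else []
                members[sp] = ids
                for pid in ids:
                    if pid in owner:
                        raise ValueError(
                            f"protein {pid!r} appears in both {owner[pid]} and {og_id}"
                        )
                    owner[pid] = og_id
            for sp in species:
                members.setdefault(sp, [])
            ogs.append(Orthogroup(og_id, members))
    return ogs


def write_orthogroups(ogs: Sequence[Orthogroup], path: str | Path) -> None:
    species = sorted({sp for og in ogs for sp in og.members})
    with open(path, "w", newline="\n") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for og in ogs:
            cells = [", ".join(og.members.get(sp, [])) for sp in species]
            fh.write(og.og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BLAST outfmt 6


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            c = line.split("\t")
            if len(c) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(c)}")
            try:
                evalue = float(c[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric e-value {c[10]!r}") from exc
            hits.append(
                BlastHit(
                    c[0], c[1], float(c[2]), int(c[3]), int(c[4]), int(c[5]),
                    int(c[6]), int(c[7]), int(c[8]), int(c[9]), evalue, float(c[11]),
                )
            )
    return hits


def write_blast_tab(hits: Sequence[BlastHit], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, format(h.pct_identity, ".3f"),
                        str(h.aln_len), str(h.mismatches), str(h.gapopens),
                        str(h.qstart), str(h.qend), str(h.sstart), str(h.send),
                        format(h.evalue, ".3g"), format(h.bitscore, ".1f"),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# newick


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a newick tree from a path or a newick string."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in newick input")
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def newick_leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}
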