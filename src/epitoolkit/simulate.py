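"""Seeded generators for every input the pipeline consumes, with planted truth.

Each generator is a pure function of its configuration and seed: identical
calls produce identical outputs. Scenarios return in-memory records (the same
types the readers produce) plus a truth table sufficient to decide every
downstream recovery property; ``write()`` serializes the standard-format
files and a ``truth.json`` next to them.

The generators emulate the *shapes* of real comparative-genomic inputs —
domain-annotated proteomes, orthogroup tables consistent with a species tree,
tandem histone clusters with 3' stem-loops, a conserved gene neighborhood
with a planted deletion or pseudogenization — not realistic molecular
evolution. Background protein sequences are i.i.d. uniform over the 20 amino
acids: the classifiers act on evidence channels, not sequence content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .datasets import DEFAULT_SPECIES_TREE, load_default_taxonomy
from .histones import DEFAULT_STEMLOOP_CONSENSUS, detect_stemloop, revcomp
from .io_formats import (
    BlastHit,
    DomainAnnotation,
    GeneModel,
    Orthogroup,
    SequenceRecord,
    read_newick,
    write_blast_tab,
    write_domain_table,
    write_fasta,
    write_gff_genes,
    write_orthogroups,
)
from .toolkit import ReferenceSets

__all__ = [
    "plant_epigenetic_toolkit",
    "simulate_gene_families",
    "synthesize_histone_region",
    "synthesize_loss_scenario",
    "synthesize_evalue_set",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
# sense codons only (no TAA/TAG/TGA)
_CODONS = [
    a + b + c
    for a in _NT for b in _NT for c in _NT
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# one representative codon per amino acid for reverse translation
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NT), size=n))


def _loguniform(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    """10**U(lo_exp, hi_exp)."""
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def _dump_truth(truth: dict, out_dir: Path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.generic):
            return o.item()
        raise TypeError(type(o))

    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, default=default))


# ---------------------------------------------------------------------------
# toolkit scenario


@dataclass
class ToolkitScenario:
    proteome: list[SequenceRecord]
    domains: list[DomainAnnotation]
    orthogroups: list[Orthogroup]
    refs: ReferenceSets
    gene_map: dict[str, str]
    species: str
    model_species: str
    taxonomy: dict
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteome, out / "proteome.faa")
        write_domain_table(self.domains, out / "domains.tsv")
        write_orthogroups(self.orthogroups, out / "orthogroups.tsv")
        trees = out / "trees"
        trees.mkdir(exist_ok=True)
        for og in self.orthogroups:
            if og.tree is not None:
                (trees / f"{og.og_id}.nwk").write_text(og.tree.as_string(schema="newick"))
        with open(out / "refs.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "epi_domains": sorted(self.refs.epi_domains),
                    "epi_specific_domains": sorted(self.refs.epi_specific_domains or []),
                    "epi_proteins": {
                        sp: sorted(ids) for sp, ids in self.refs.epi_proteins.items()
                    },
                },
                fh,
            )
        with open(out / "taxonomy.yaml", "w") as fh:
            yaml.safe_dump(self.taxonomy, fh)
        with open(out / "gene_map.tsv", "w", newline="\n") as fh:
            for pid, gid in sorted(self.gene_map.items()):
                fh.write(f"{pid}\t{gid}\n")
        _dump_truth(self.truth, out)


def plant_epigenetic_toolkit(
    n_background: int = 100,
    family_spec: Optional[dict[str, int]] = None,
    seed: int = 0,
    decoy_fraction: float = 0.1,
    isoform_fraction: float = 0.2,
    species: str = "target",
    model_species: str = "human",
) -> ToolkitScenario:
    """Proteome with planted epigenetic families, decoys, and isoforms.

    ``family_spec`` maps "FAMILY/Subfamily" labels from the default taxonomy
    to planted copy numbers. Planted proteins carry the subfamily's reference
    domain accession and sit in orthogroups seeded with a model-species
    reference protein. Decoys carry near-miss (non-reference) accessions;
    background proteins carry unrelated accessions or none.
    """
    family_spec = family_spec or {"HMT/SET": 5, "HAT/GNAT": 3}
    rng = np.random.default_rng(seed)
    taxonomy = load_default_taxonomy()
    acc_of_subfam = {
        f"{v['family']}/{v['subfamily']}": acc for acc, v in taxonomy["domain_map"].items()
    }
    epi_domains = set(taxonomy["domain_map"])

    proteome: list[SequenceRecord] = []
    domains: list[DomainAnnotation] = []
    ogs: list[Orthogroup] = []
    gene_map: dict[str, str] = {}
    ref_proteins: set[str] = set()
    planted_genes: set[str] = set()
    planted_families: dict[str, tuple[str, str]] = {}
    reference_map: dict[str, dict[str, str]] = {}

    serial = 0
    for label, count in family_spec.items():
        if label not in acc_of_subfam:
            raise ValueError(f"unknown family/subfamily {label!r}")
        fam, subfam = label.split("/", 1)
        acc = acc_of_subfam[label]
        for i in range(count):
            serial += 1
            gid = f"tg{serial:03d}"
            planted_genes.add(gid)
            planted_families[gid] = (fam, subfam)
            ref_id = f"{model_species}|{fam.replace('/', '_')}_{subfam.replace(' ', '_')}_{i}"
            ref_proteins.add(ref_id)
            reference_map[ref_id] = {"family": fam, "subfamily": subfam}
            n_iso = 2 if rng.random() < isoform_fraction else 1
            pids = [f"{gid}.p{k+1}" for k in range(n_iso)]
            length = int(rng.integers(200, 400))
            base_seq = _rand_aa(rng, length)
            for pid in pids:
                gene_map[pid] = gid
                proteome.append(SequenceRecord(pid, base_seq, "aa"))
                start = int(rng.integers(1, 40))
                domains.append(
                    DomainAnnotation(pid, acc, start, start + 100,
                                     _loguniform(rng, -50, -20))
                )
            og_id = f"OG{serial:07d}"
            members = {model_species: [ref_id], species: pids}
            newick = "(" + ",".join([f"'{ref_id}':1.0"] + [f"'{p}':0.1" for p in pids]) + ");"
            ogs.append(Orthogroup(og_id, members, dendropy.Tree.get(data=newick, schema="newick")))

    n_decoys = max(1, round(decoy_fraction * n_background))
    decoy_genes: set[str] = set()
    for i in range(n_decoys):
        gid = f"dc{i:03d}"
        pid = f"{gid}.p1"
        decoy_genes.add(gid)
        gene_map[pid] = gid
        proteome.append(SequenceRecord(pid, _rand_aa(rng, int(rng.integers(150, 300))), "aa"))
        domains.append(
            DomainAnnotation(pid, f"PF999{i % 100:02d}", 5, 90, _loguniform(rng, -30, -10))
        )

    bg_acc_pool = [f"PF7{i:04d}" for i in range(40)]
    for i in range(n_background):
        gid = f"bg{i:03d}"
        pid = f"{gid}.p1"
        gene_map[pid] = gid
        proteome.append(SequenceRecord(pid, _rand_aa(rng, int(rng.integers(150, 400))), "aa"))
        if rng.random() < 0.7:
            for acc in rng.choice(bg_acc_pool, size=int(rng.integers(1, 3)), replace=False):
                s = int(rng.integers(1, 60))
                domains.append(DomainAnnotation(pid, str(acc), s, s + 60,
                                                _loguniform(rng, -40, -5)))
        # single-species orthogroup, no reference member
        ogs.append(Orthogroup(f"OGB{i:06d}", {species: [pid], model_species: []}))

    refs = ReferenceSets(epi_domains, {model_species: ref_proteins})
    taxonomy_with_refs = dict(taxonomy)
    taxonomy_with_refs["reference_map"] = reference_map
    truth = {
        "planted_toolkit_genes": planted_genes,
        "planted_families": {g: list(v) for g, v in planted_families.items()},
        "decoy_genes": decoy_genes,
        "seed": seed,
    }
    return ToolkitScenario(
        proteome, domains, ogs, refs, gene_map, species, model_species,
        taxonomy_with_refs, truth,
    )


# ---------------------------------------------------------------------------
# gene-family / orthogroup simulation


@dataclass
class FamilyScenario:
    orthogroups: list[Orthogroup]
    species_tree: dendropy.Tree
    model_species: str
    reference_proteins: set[str]
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_orthogroups(self.orthogroups, out / "orthogroups.tsv")
        trees = out / "trees"
        trees.mkdir(exist_ok=True)
        for og in self.orthogroups:
            if og.tree is not None:
                (trees / f"{og.og_id}.nwk").write_text(
                    og.tree.as_string(schema="newick")
                )
        _dump_truth(self.truth, out)


class _GeneNode:
    __slots__ = ("children", "label", "length")

    def __init__(self, length: float = 0.0):
        self.children: list[_GeneNode] = []
        self.label: Optional[str] = None
        self.length = length

    def newick(self) -> str:
        if self.label is not None:
            return f"'{self.label}':{self.length}"
        return "(" + ",".join(c.newick() for c in self.children) + f"):{self.length}"


def simulate_gene_families(
    species_tree: str | dendropy.Tree | None = None,
    birth_rate: float = 0.1,
    loss_rate: float = 0.05,
    n_families: int = 20,
    seed: int = 0,
    model_species: Optional[str] = None,
    n_reference_families: Optional[int] = None,
) -> FamilyScenario:
    """Gene families evolving by duplication/loss down a species tree.

    Each family starts as one gene at the root; along every branch each gene
    copy duplicates Poisson(birth_rate x length) times and survives with
    probability exp(-loss_rate x length). Descendants of one root gene form
    one orthogroup, and the simulated genealogy is the orthogroup's gene
    tree. The model species' member of the first ``n_reference_families``
    families is planted as a reference epigenetic protein.
    """
    if birth_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    if species_tree is None:
        species_tree = DEFAULT_SPECIES_TREE
    tree = read_newick(species_tree) if not isinstance(species_tree, dendropy.Tree) else species_tree
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    model_species = model_species or species[0]
    n_ref = n_families if n_reference_families is None else n_reference_families
    rng = np.random.default_rng(seed)

    ogs: list[Orthogroup] = []
    events: list[dict] = []
    reference_proteins: set[str] = set()
    for fam in range(n_families):
        counter: dict[str, int] = {}
        members: dict[str, list[str]] = {sp: [] for sp in species}

        def descend(sp_node, gene: _GeneNode) -> bool:
            """Populate gene subtree below sp_node; return True if any leaf survives."""
            if sp_node.is_leaf():
                sp = sp_node.taxon.label
                counter[sp] = counter.get(sp, 0) + 1
                gene.label = f"{sp}|f{fam}g{counter[sp]}"
                members[sp].append(gene.label)
                return True
            ok = False
            for child in sp_node.child_nodes():
                L = child.edge.length if child.edge.length is not None else 1.0
                n_copies = 1 + int(rng.poisson(birth_rate * L))
                if n_copies > 1:
                    events.append(
                        {"family": fam, "event": "duplication", "n": n_copies - 1}
                    )
                kept: list[_GeneNode] = []
                for _ in range(n_copies):
                    if rng.random() >= np.exp(-loss_rate * L):
                        events.append({"family": fam, "event": "loss"})
                        continue
                    sub = _GeneNode(L)
                    if descend(child, sub):
                        kept.append(sub)
                if kept:
                    if len(kept) == 1:
                        gene.children.append(kept[0])
                    else:
                        stub = _GeneNode(0.0)
                        stub.children = kept
                        gene.children.append(stub)
                    ok = True
            return ok

        root = _GeneNode()
        if not descend(tree.seed_node, root):
            ogs.append(Orthogroup(f"FOG{fam:05d}", {sp: [] for sp in species}))
            continue
        # collapse unary chains for a clean newick
        total = sum(len(v) for v in members.values())
        gtree = None
        if total >= 2:
            gtree = dendropy.Tree.get(data=root.newick() + ";", schema="newick")
        ogs.append(Orthogroup(f"FOG{fam:05d}", dict(members), gtree))
        if fam < n_ref and members[model_species]:
            reference_proteins.add(members[model_species][0])

    truth = {
        "membership": {og.og_id: {sp: ids for sp, ids in og.members.items()} for og in ogs},
        "events": events,
        "reference_proteins": reference_proteins,
        "model_species": model_species,
        "seed": seed,
    }
    return FamilyScenario(ogs, tree, model_species, reference_proteins, truth)


# ---------------------------------------------------------------------------
# histone region


@dataclass
class HistoneScenario:
    genome: SequenceRecord
    genes: list[GeneModel]
    class_hits: list[BlastHit]
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], out / "genome.fa")
        write_gff_genes(self.genes, out / "genes.gff3")
        write_blast_tab(self.class_hits, out / "class_hits.tsv")
        _dump_truth(self.truth, out)


PPA_QUARTET = [("H2A", "+"), ("H2B", "+"), ("H3", "+"), ("H4", "+")]
CEL_QUARTET = [("H2A", "-"), ("H2B", "+"), ("H4", "-"), ("H3", "+")]


def synthesize_histone_region(
    quartet_spec: Sequence[tuple[str, str]] = tuple(PPA_QUARTET),
    n_repeats: int = 4,
    n_clusters: int = 1,
    spacing_bp: int = 2000,
    cluster_gap_bp: int = 50_000,
    hairpin_consensus: str = DEFAULT_STEMLOOP_CONSENSUS,
    hairpin_offset: int = 12,
    n_variants: int = 2,
    cds_len: int = 312,
    seed: int = 0,
) -> HistoneScenario:
    """Tandem histone clusters with planted 3' stem-loops and planted truth.

    Quartet units of the given class order and strand pattern repeat
    ``n_repeats`` times per cluster; canonical genes carry the stem-loop
    ``hairpin_offset`` nt downstream of the stop codon (strand-aware),
    variants sit far outside clusters with no hairpin. The per-class hit
    table gives canonical copies the class-maximum bitscore and variants a
    diverged score.
    """
    rng = np.random.default_rng(seed)

    # canonical CDS per class: identical within a class, ending in TAA
    n_codons = cds_len // 3
    canonical_cds = {
        cls: "".join(rng.choice(_CODONS, size=n_codons - 1)) + "TAA"
        for cls in ("H2A", "H2B", "H3", "H4")
    }

    region_genes: list[tuple[str, str, str, bool]] = []  # (gene_id, class, strand, canonical)
    truth_genes: dict[str, dict] = {}
    genes: list[GeneModel] = []
    chrom = "chrSim"
    pos = 1001  # leave room for minus-strand upstream hairpins
    serial = 0
    cluster_spans: list[tuple[int, int]] = []
    placements: list[tuple[int, str, str, str, bool, int]] = []
    # first lay out coordinates, then build the sequence
    for c in range(n_clusters):
        cstart = pos
        for r in range(n_repeats):
            for cls, strand in quartet_spec:
                serial += 1
                gid = f"hg{serial:03d}"
                placements.append((pos, gid, cls, strand, True, c))
                pos += cds_len + spacing_bp
        cluster_spans.append((cstart, pos - spacing_bp))
        pos += cluster_gap_bp
    pos += 100_000  # variants live far from any cluster
    core = ("H2A", "H2B", "H3", "H4")
    for v in range(n_variants):
        serial += 1
        gid = f"hv{serial:03d}"
        cls = core[v % 4]
        strand = "+" if v % 2 == 0 else "-"
        placements.append((pos, gid, cls, strand, False, -1))
        pos += cds_len + 30_000

    genome_len = pos + 1000
    genome = bytearray(_rand_nt(rng, genome_len).encode())

    def _write(idx0: int, s: str) -> None:
        genome[idx0 : idx0 + len(s)] = s.encode()

    hits: list[BlastHit] = []
    for start, gid, cls, strand, canonical, cluster_idx in placements:
        end = start + cds_len - 1
        cds = canonical_cds[cls]
        if not canonical:
            # diverge ~20% of codons (sense codons only), keep terminal TAA
            codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
            for i in range(len(codons)):
                if rng.random() < 0.2:
                    codons[i] = str(rng.choice(_CODONS))
            cds = "".join(codons) + "TAA"
        _write(start - 1, cds if strand == "+" else revcomp(cds))
        if canonical:
            if strand == "+":
                _write(end + hairpin_offset, hairpin_consensus)
            else:
                # window offset o maps to genome[(start-1) - 1 - o]; motif at
                # window[offset:offset+16] == genome[start-1-offset-16 : start-1-offset], revcomp'd
                _write(start - 1 - hairpin_offset - len(hairpin_consensus),
                       revcomp(hairpin_consensus))
        genes.append(GeneModel(gid, chrom, start, end, strand, [(start, end)], [f"{gid}.t1"]))
        bits = 200.0 if canonical else float(rng.uniform(120, 160))
        hits.append(
            BlastHit(cls, gid, 100.0 if canonical else 80.0, n_codons, 0, 0,
                     1, n_codons, start, end, 1e-60, bits)
        )
        truth_genes[gid] = {
            "class": cls, "strand": strand,
            "status": "canonical" if canonical else "variant",
            "rd": canonical, "cluster": cluster_idx,
            "hairpin_offset": hairpin_offset if canonical else None,
        }

    genome_seq = genome.decode()
    # scrub chance stem-loops downstream of variant stops so the planted truth
    # (variants are replication-independent) holds exactly
    for start, gid, cls, strand, canonical, _ in placements:
        if canonical:
            continue
        end = start + cds_len - 1
        for _attempt in range(50):
            if strand == "+":
                win = genome_seq[end : end + 100]
            else:
                win = revcomp(genome_seq[max(0, start - 101) : start - 1])
            if detect_stemloop(win, consensus=hairpin_consensus) is None:
                break
            if strand == "+":
                genome[end : end + 100] = _rand_nt(rng, 100).encode()
            else:
                genome[start - 101 : start - 1] = _rand_nt(rng, 100).encode()
            genome_seq = genome.decode()

    truth = {
        "genes": truth_genes,
        "quartet_spec": [list(q) for q in quartet_spec],
        "n_clusters": n_clusters,
        "n_repeats": n_repeats,
        "cluster_spans": cluster_spans,
        "seed": seed,
    }
    return HistoneScenario(SequenceRecord(chrom, genome_seq, "nt"), genes, hits, truth)


# ---------------------------------------------------------------------------
# loss scenario


@dataclass
class LossScenario:
    species_tree: dendropy.Tree
    genes_by_species: dict[str, list[GeneModel]]
    og_of: dict[str, str]                    # gene id -> orthogroup label
    locus_seqs: dict[str, Optional[SequenceRecord]]
    reference_protein: SequenceRecord
    evidence: dict[str, dict[str, object]]   # species -> channel -> value
    expression: list[dict]
    repeats: list[tuple[str, int, int, str]]
    focal_og: str
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "species_tree.nwk").write_text(
            self.species_tree.as_string(schema="newick")
        )
        for sp, genes in self.genes_by_species.items():
            write_gff_genes(genes, out / f"{sp}.gff3")
        loci = [s for s in self.locus_seqs.values() if s is not None]
        write_fasta(loci, out / "loci.fna")
        write_fasta([self.reference_protein], out / "reference_protein.faa")
        with open(out / "evidence.tsv", "w", newline="\n") as fh:
            fh.write("species\tchannel\tvalue\n")
            for sp, ev in self.evidence.items():
                for ch, val in ev.items():
                    fh.write(f"{sp}\t{ch}\t{val}\n")
        with open(out / "counts.tsv", "w", newline="\n") as fh:
            fh.write("gene_id\ttotal_reads\tgene_length_bp\ttotal_mapped_reads\n")
            for row in self.expression:
                fh.write(
                    f"{row['gene_id']}\t{row['total_reads']}\t"
                    f"{row['gene_length_bp']}\t{row['total_mapped_reads']}\n"
                )
        with open(out / "repeats.tsv", "w", newline="\n") as fh:
            fh.write("chrom\tstart\tend\tlabel\n")
            for rc, rs, re_, lbl in self.repeats:
                fh.write(f"{rc}\t{rs}\t{re_}\t{lbl}\n")
        with open(out / "og_of.tsv", "w", newline="\n") as fh:
            for gid, og in sorted(self.og_of.items()):
                fh.write(f"{gid}\t{og}\n")
        _dump_truth(self.truth, out)


def _clade_leafsets(tree: dendropy.Tree) -> dict[frozenset[str], object]:
    out = {}
    for node in tree.preorder_node_iter():
        out[frozenset(lf.taxon.label for lf in node.leaf_iter())] = node
    return out


def synthesize_loss_scenario(
    species_tree: str | dendropy.Tree | None = None,
    lost_clade: Sequence[str] = ("P_pacificus", "P_exspectatus", "P_arcanus"),
    mode: str = "deletion",
    seed: int = 0,
    n_neighbors: int = 12,
    planted_stops: int = 4,
    truncation_fraction: float = 0.3,
    ref_len_aa: int = 180,
) -> LossScenario:
    """A conserved multi-species neighborhood with a planted gene loss.

    Every species carries the same ordered orthologous neighborhood; in the
    species of ``lost_clade`` (which must form a clade of the tree) the focal
    gene is deleted (flanks drawn together) or pseudogenized (planted
    in-frame stops; in clades of >1 species the last species is truncated
    instead, mirroring a sister-pair stop/truncation split). Search-channel
    e-values come from a strong-hit band for functional species and a noise
    band otherwise; every existing locus — pseudogenes included — gets
    nonzero expression.
    """
    if mode not in ("deletion", "pseudogenization"):
        raise ValueError(f"unknown mode {mode!r}")
    if species_tree is None:
        species_tree = DEFAULT_SPECIES_TREE
    tree = read_newick(species_tree) if not isinstance(species_tree, dendropy.Tree) else species_tree
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    lost = frozenset(lost_clade)
    if lost and lost not in _clade_leafsets(tree):
        raise ValueError(f"{sorted(lost)} is not a clade of the species tree")
    rng = np.random.default_rng(seed)

    focal_og = "OG_FOCAL"
    neighbor_ogs = [f"OG_NB{i:02d}" for i in range(n_neighbors)]
    mid = n_neighbors // 2
    og_order = neighbor_ogs[:mid] + [focal_og] + neighbor_ogs[mid:]
    og_strand = {og: ("+" if rng.random() < 0.5 else "-") for og in og_order}

    ref_aa = _rand_aa(rng, ref_len_aa)
    functional_cds = "".join(_CODON_OF[a] for a in ref_aa) + "TAA"

    pseudo_kind: dict[str, str] = {}
    ordered_lost = [sp for sp in leaves if sp in lost]
    if mode == "pseudogenization":
        for i, sp in enumerate(ordered_lost):
            pseudo_kind[sp] = (
                "truncated" if (len(ordered_lost) > 1 and i == len(ordered_lost) - 1)
                else "stop_disrupted"
            )

    genes_by_species: dict[str, list[GeneModel]] = {}
    og_of: dict[str, str] = {}
    locus_seqs: dict[str, Optional[SequenceRecord]] = {}
    evidence: dict[str, dict[str, object]] = {}
    expression: list[dict] = []
    gene_len = 1500

    for sp in leaves:
        affected = sp in lost
        pos = 80_000  # clear of the contig edge for a 60-70 kb flank
        genes: list[GeneModel] = []
        for j, og in enumerate(og_order):
            if og == focal_og and affected and mode == "deletion":
                continue  # flanks drawn together
            gid = f"{sp}_g{j:02d}"
            length = gene_len if og == focal_og else int(rng.integers(900, 2400))
            start, end = pos, pos + length - 1
            genes.append(GeneModel(gid, f"{sp}_chr1", start, end, og_strand[og],
                                   [(start, end)], [f"{gid}.t1"]))
            og_of[gid] = og
            pos = end + int(rng.integers(3000, 6000))
        genes_by_species[sp] = genes

        if affected and mode == "deletion":
            locus_seqs[sp] = None
        elif affected:  # pseudogenization
            if pseudo_kind[sp] == "stop_disrupted":
                codons = [functional_cds[i : i + 3] for i in range(0, len(functional_cds) - 3, 3)]
                idx = rng.choice(np.arange(10, len(codons) - 10), size=planted_stops, replace=False)
                for i in sorted(int(x) for x in idx):
                    codons[i] = "TAA"
                seq = "".join(codons) + "TAA"
            else:
                keep = int(len(ref_aa) * truncation_fraction)
                seq = "".join(_CODON_OF[a] for a in ref_aa[:keep]) + "TAA"
            locus_seqs[sp] = SequenceRecord(f"{sp}_focal_locus", seq, "nt")
        else:
            locus_seqs[sp] = SequenceRecord(f"{sp}_focal_locus", functional_cds, "nt")

        if not affected:
            ev = {
                "blastp": _loguniform(rng, -120, -40),
                "orthofinder": True,
                "tblastn_tx": _loguniform(rng, -120, -40),
                "tblastn_genome": _loguniform(rng, -80, -20),
                "rnaseq_locus": True,
            }
        elif mode == "deletion":
            ev = {
                "blastp": _loguniform(rng, -8, -1),
                "orthofinder": False,
                "tblastn_tx": _loguniform(rng, -4, -1),
                "tblastn_genome": _loguniform(rng, -3, -1),
                "rnaseq_locus": False,
            }
        else:
            ev = {
                "blastp": _loguniform(rng, -8, -1),
                "orthofinder": False,
                "tblastn_tx": _loguniform(rng, -60, -35),
                "tblastn_genome": _loguniform(rng, -60, -20),
                "rnaseq_locus": True,  # pseudogenes still show expression
            }
        evidence[sp] = ev

        if locus_seqs[sp] is not None:
            expression.append(
                {"gene_id": f"{sp}_focal", "total_reads": int(rng.poisson(200)) + 1,
                 "gene_length_bp": gene_len, "total_mapped_reads": 1_000_000}
            )

    # repeats: planted away from every focal window ("no transposon signature")
    repeats = [(f"{leaves[0]}_chr1", 1, 500, "helitron_like"),
               (f"{leaves[0]}_chr1", 2_000_000, 2_001_000, "mariner_like")]

    truth = {
        "mode": mode,
        "lost_clade": lost,
        "loss_branch_leafset": lost,
        "pseudo_kind": pseudo_kind,
        "planted_stops": planted_stops if mode == "pseudogenization" else 0,
        "truncation_fraction": truncation_fraction,
        "focal_og": focal_og,
        "seed": seed,
    }
    return LossScenario(
        tree, genes_by_species, og_of, locus_seqs,
        SequenceRecord("reference_protein", ref_aa, "aa"),
        evidence, expression, repeats, focal_og, truth,
    )


# ---------------------------------------------------------------------------
# e-value sets


def synthesize_evalue_set(
    n_true: int = 40,
    n_noise: int = 40,
    mode_gap_log10: float = 20.0,
    seed: int = 0,
) -> tuple[list[float], tuple[float, float]]:
    """Bimodal top-hit e-values: a strong band and a noise band.

    True hits are log-uniform in [1e-120, 1e-40]; noise occupies
    [10**-(40 - mode_gap_log10), 1e-1], i.e. the two modes are separated by
    at least ``mode_gap_log10`` log10 units. A non-positive gap means no
    bimodality at all and is emitted as a smooth geometric ladder spanning
    both bands (truth interval None). Returns the e-values (shuffled) and
    the truth interval the plateau threshold should land in.
    """
    if n_true < 1 or n_noise < 1:
        raise ValueError("need at least one value per mode")
    rng = np.random.default_rng(seed)
    if mode_gap_log10 <= 0:
        exps = np.linspace(-120.0, -1.0, n_true + n_noise)
        values = 10.0 ** exps
        rng.shuffle(values)
        return values.tolist(), None
    true = 10.0 ** rng.uniform(-120, -40, size=n_true)
    noise_hi_exp = min(-1.0, -(40.0 - mode_gap_log10))
    noise = 10.0 ** rng.uniform(noise_hi_exp, -1.0, size=n_noise)
    values = np.concatenate([true, noise])
    rng.shuffle(values)
    interval = (1e-40, 10.0 ** noise_hi_exp)
    return values.tolist(), interval
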