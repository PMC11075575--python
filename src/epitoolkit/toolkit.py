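"""Evidence-merged epigenetic-gene inventory construction.

Two evidence streams identify candidate epigenetic proteins in a target
species: (i) carrying at least one reference epigenetic-associated protein
domain, and (ii) membership in an orthogroup that contains at least one
known epigenetic protein from a model species. Orthology-derived candidates
pass quality control (outlier-domain screening, tree-placement flags, a
"close relative" exemption), the two streams are merged, isoforms are
collapsed to genes, and each gene receives a family/subfamily label from its
domain composition (orthology provenance as fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .io_formats import DomainAnnotation, Orthogroup

__all__ = [
    "ReferenceSets",
    "CandidateProtein",
    "FamilyAssignment",
    "QCConfig",
    "TreePlacementFlag",
    "GeneInventoryRecord",
    "select_by_domain",
    "select_by_orthology",
    "find_outlier_domains",
    "flag_tree_placement",
    "qc_filter",
    "collapse_to_genes",
    "assign_family",
    "tabulate_counts",
]

DISCARD_REASONS = (
    "bad_tree_placement",
    "outlier_domain_no_epi_function",
    "no_domains_no_epi_ortholog",
    "kinase_no_adjacent_reference",
)


@dataclass
class ReferenceSets:
    """User-supplied reference epigenetic domains and proteins.

    ``epi_specific_domains`` marks the subset of domains found exclusively in
    epigenetic-function proteins (the QC exemption); by default every
    reference domain is treated as specific.
    """

    epi_domains: set[str]
    epi_proteins: dict[str, set[str]]
    epi_specific_domains: Optional[set[str]] = None

    def __post_init__(self) -> None:
        if self.epi_specific_domains is None:
            self.epi_specific_domains = set(self.epi_domains)
        if not self.epi_specific_domains <= self.epi_domains:
            raise ValueError("epi_specific_domains must be a subset of epi_domains")
        if any(not k for k in self.epi_proteins):
            raise ValueError("species keys must be non-empty")

    def all_reference_proteins(self) -> set[str]:
        return {p for ids in self.epi_proteins.values() for p in ids}


@dataclass
class CandidateProtein:
    protein_id: str
    gene_id: str
    species: str
    evidence: set[str]
    og_id: Optional[str] = None
    discard_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.discard_reason is None and not self.evidence:
            raise ValueError(f"{self.protein_id}: retained candidate needs evidence")
        if ("orthology" in self.evidence) != (self.og_id is not None):
            raise ValueError(f"{self.protein_id}: og_id set iff orthology evidence")


@dataclass(frozen=True)
class FamilyAssignment:
    family: str
    subfamily: str


@dataclass
class QCConfig:
    predicted_epi_function: set[str] = field(default_factory=set)
    kinase_domain_accs: set[str] = field(default_factory=lambda: {"PF00069"})
    closely_related_clade_factor: int = 2


@dataclass
class TreePlacementFlag:
    status: str                      # ok | flagged | not_evaluable
    triplet: Optional[tuple[str, str, str]] = None
    gene_resolution: Optional[frozenset[str]] = None
    species_resolution: Optional[frozenset[str]] = None
    note: str = ""


@dataclass
class GeneInventoryRecord:
    gene_id: str
    species: str
    protein_ids: list[str]
    evidence: set[str]
    og_ids: set[str]
    sequence_duplicate: bool = False
    assignment: Optional[FamilyAssignment] = None


# ---------------------------------------------------------------------------
# selection


def select_by_domain(
    domains: Sequence[DomainAnnotation], refs: ReferenceSets
) -> set[str]:
    """Proteins carrying at least one reference epigenetic domain."""
    if not refs.epi_domains:
        raise ValueError("refs.epi_domains is empty (misconfigured reference set)")
    return {d.protein_id for d in domains if d.domain_acc in refs.epi_domains}


def select_by_orthology(
    ogs: Sequence[Orthogroup], refs: ReferenceSets, target_species: str
) -> dict[str, str]:
    """Target-species proteins in orthogroups seeded by a reference protein.

    Returns a mapping protein id -> orthogroup id (provenance) for every
    target-species member of any orthogroup containing one or more reference
    epigenetic proteins from any model species.
    """
    ref_ids = refs.all_reference_proteins()
    found_species = False
    out: dict[str, str] = {}
    for og in ogs:
        members = og.members.get(target_species, [])
        if target_species in og.members:
            found_species = True
        if not members:
            continue
        if ref_ids & og.all_members():
            for pid in members:
                out[pid] = og.og_id
    if not found_species:
        raise ValueError(f"species {target_species!r} absent from all orthogroups")
    return out


def find_outlier_domains(
    og: Orthogroup,
    domains_by_protein: Mapping[str, Sequence[DomainAnnotation]],
    focal: str,
) -> set[str]:
    """Domain accessions on the focal protein absent from every other member."""
    members = og.all_members()
    if focal not in members:
        raise ValueError(f"{focal!r} is not a member of {og.og_id}")
    focal_accs = {d.domain_acc for d in domains_by_protein.get(focal, [])}
    other_accs = {
        d.domain_acc
        for pid in members
        if pid != focal
        for d in domains_by_protein.get(pid, [])
    }
    return focal_accs - other_accs


# ---------------------------------------------------------------------------
# tree-based QC


def _patristic(tree: dendropy.Tree):
    return tree.phylogenetic_distance_matrix()


def _leaf(tree: dendropy.Tree, label: str):
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == label:
            return lf
    return None


def closely_related(
    og: Orthogroup,
    focal: str,
    trusted_ids: set[str],
    target_species: str,
    clade_factor: int = 2,
) -> bool:
    """The reproducible surrogate for a visual "close relative" check.

    True when the focal leaf's nearest neighbor by patristic distance, within
    the smallest clade of at most ``clade_factor`` x (number of target-species
    members) leaves containing the focal leaf, is a reference or
    already-retained epigenetic protein.
    """
    if og.tree is None:
        return False
    node = _leaf(og.tree, focal)
    if node is None:
        return False
    n_target = max(1, len(og.members.get(target_species, [])))
    limit = clade_factor * n_target
    clade = node
    while clade.parent_node is not None:
        parent = clade.parent_node
        if len(parent.leaf_nodes()) > max(limit, 2):
            break
        clade = parent
    labels = {lf.taxon.label for lf in clade.leaf_iter()} - {focal}
    if not labels:
        return False
    pdm = _patristic(og.tree)
    taxa = {t.label: t for t in og.tree.taxon_namespace}
    has_lengths = all(
        e.length is not None for e in og.tree.preorder_edge_iter() if e.head_node.parent_node
    )
    if has_lengths:
        nearest = min(labels, key=lambda l: pdm.patristic_distance(taxa[focal], taxa[l]))
    else:
        nearest = min(labels, key=lambda l: pdm.path_edge_count(taxa[focal], taxa[l]))
    return nearest in trusted_ids


def flag_tree_placement(
    og: Orthogroup,
    focal: str,
    species_tree: dendropy.Tree,
    species_of: Mapping[str, str],
) -> TreePlacementFlag:
    """Flag (never auto-discard) phylogenetically suspect placements.

    Takes the three non-target leaves nearest to the focal leaf (patristic
    distance) with three distinct species, resolves their triplet in the gene
    tree and in the species tree, and flags the candidate when the two
    resolutions disagree. Emits the triplet and both resolutions for manual
    review. Returns ``not_evaluable`` when no gene tree or no usable triplet
    exists — never a silent pass.
    """
    if og.tree is None:
        return TreePlacementFlag("not_evaluable", note="orthogroup has no gene tree")
    node = _leaf(og.tree, focal)
    if node is None:
        return TreePlacementFlag("not_evaluable", note=f"{focal} not in gene tree")
    focal_species = species_of.get(focal)
    sp_taxa = {t.label: t for t in species_tree.taxon_namespace}
    if focal_species not in sp_taxa:
        return TreePlacementFlag(
            "not_evaluable", note=f"species {focal_species!r} not in species tree"
        )
    pdm = _patristic(og.tree)
    taxa = {t.label: t for t in og.tree.taxon_namespace}
    has_lengths = all(
        e.length is not None for e in og.tree.preorder_edge_iter() if e.head_node.parent_node
    )

    def _dist(l: str) -> float:
        if has_lengths:
            return pdm.patristic_distance(taxa[focal], taxa[l])
        return pdm.path_edge_count(taxa[focal], taxa[l])

    others = sorted(
        (
            l for l in taxa
            if l != focal and species_of.get(l) not in (None, focal_species)
            and species_of[l] in sp_taxa
        ),
        key=_dist,
    )
    triplet: list[str] = []
    species_seen: set[str] = set()
    for l in others:
        sp = species_of[l]
        if sp not in species_seen:
            triplet.append(l)
            species_seen.add(sp)
        if len(triplet) == 3:
            break
    if len(triplet) < 3:
        return TreePlacementFlag("not_evaluable", note="fewer than 3 distinct non-target species")

    # gene-tree side: which triplet leaves sit in the smallest clade
    # containing the focal leaf and at least one triplet leaf
    triplet_set = set(triplet)
    clade = node
    sisters: set[str] = set()
    while clade.parent_node is not None:
        clade = clade.parent_node
        sisters = {lf.taxon.label for lf in clade.leaf_iter()} & triplet_set
        if sisters:
            break
    if not sisters:
        return TreePlacementFlag("not_evaluable", tuple(triplet), note="no sister found")
    gene_res = frozenset(sisters)
    gene_sister_species = {species_of[l] for l in sisters}

    # species-tree side: which of the three species are nearest the focal
    # species (topological distance)
    sp_pdm = species_tree.phylogenetic_distance_matrix()
    dists = {
        species_of[l]: sp_pdm.path_edge_count(sp_taxa[focal_species], sp_taxa[species_of[l]])
        for l in triplet
    }
    dmin = min(dists.values())
    expected = frozenset(sp for sp, d in dists.items() if d == dmin)
    status = "ok" if gene_sister_species & expected else "flagged"
    return TreePlacementFlag(status, tuple(triplet), gene_res, expected)


# ---------------------------------------------------------------------------
# QC filter


def qc_filter(
    candidates: Sequence[CandidateProtein],
    domains_by_protein: Mapping[str, Sequence[DomainAnnotation]],
    ogs_by_id: Mapping[str, Orthogroup],
    refs: ReferenceSets,
    config: QCConfig | None = None,
    target_species: Optional[str] = None,
) -> tuple[list[CandidateProtein], list[CandidateProtein]]:
    """Conjunctive QC discard rules over orthology-derived candidates.

    A candidate with outlier domains is discarded only if it (a) carries no
    epigenetic-specific domain, (b) has no externally supplied predicted
    epigenetic function, and (c) is not closely related to a reference or
    retained epigenetic protein in its orthogroup tree. A candidate with zero
    predicted domains is discarded unless it is a close ortholog of such a
    protein. Kinase-domain candidates additionally require the close
    relationship. Every discard carries a reason code.
    """
    config = config or QCConfig()
    trusted = refs.all_reference_proteins() | {
        c.protein_id for c in candidates
    }  # provisional: peers count as potential close relatives on the first pass
    retained: list[CandidateProtein] = []
    discards: list[CandidateProtein] = []

    for cand in candidates:
        doms = list(domains_by_protein.get(cand.protein_id, []))
        accs = {d.domain_acc for d in doms}
        has_specific = bool(accs & refs.epi_specific_domains)
        predicted = cand.protein_id in config.predicted_epi_function
        og = ogs_by_id.get(cand.og_id) if cand.og_id else None
        species = target_species or cand.species

        def _close() -> bool:
            if og is None:
                return False
            return closely_related(
                og, cand.protein_id, trusted - {cand.protein_id}, species,
                config.closely_related_clade_factor,
            )

        reason = None
        if not doms:
            if not (has_specific or predicted or _close()):
                reason = "no_domains_no_epi_ortholog"
        else:
            outliers = (
                find_outlier_domains(og, domains_by_protein, cand.protein_id)
                if og is not None
                else set()
            )
            if outliers and not (has_specific or predicted or _close()):
                reason = "outlier_domain_no_epi_function"
            elif (
                accs & config.kinase_domain_accs
                and not (accs & refs.epi_specific_domains - config.kinase_domain_accs)
                and not (predicted or _close())
            ):
                reason = "kinase_no_adjacent_reference"

        if reason is None:
            retained.append(cand)
        else:
            discards.append(
                CandidateProtein(
                    cand.protein_id, cand.gene_id, cand.species,
                    set(cand.evidence), cand.og_id, discard_reason=reason,
                )
            )
    # discarded peers are no longer trusted close relatives; re-check retained
    discarded_ids = {c.protein_id for c in discards}
    if discarded_ids:
        trusted -= discarded_ids
    return retained, discards


# ---------------------------------------------------------------------------
# gene collapse and family assignment


def collapse_to_genes(
    retained: Sequence[CandidateProtein],
    gene_map: Mapping[str, str],
    seqs: Optional[Mapping[str, str]] = None,
) -> list[GeneInventoryRecord]:
    """One inventory record per gene, evidence unioned over isoforms.

    Distinct genes encoding identical protein sequences stay distinct (each
    counted) and are flagged as sequence duplicates.
    """
    unmapped = [c.protein_id for c in retained if c.protein_id not in gene_map]
    if unmapped:
        raise ValueError(f"proteins with no gene mapping: {sorted(unmapped)}")
    by_gene: dict[str, GeneInventoryRecord] = {}
    for c in retained:
        gid = gene_map[c.protein_id]
        rec = by_gene.get(gid)
        if rec is None:
            rec = GeneInventoryRecord(gid, c.species, [], set(), set())
            by_gene[gid] = rec
        rec.protein_ids.append(c.protein_id)
        rec.evidence |= c.evidence
        if c.og_id:
            rec.og_ids.add(c.og_id)
    records = list(by_gene.values())
    if seqs is not None:
        sig_to_genes: dict[frozenset[str], list[GeneInventoryRecord]] = {}
        for rec in records:
            sig = frozenset(seqs[p] for p in rec.protein_ids if p in seqs)
            if sig:
                sig_to_genes.setdefault(sig, []).append(rec)
        for group in sig_to_genes.values():
            if len(group) > 1:
                for rec in group:
                    rec.sequence_duplicate = True
    return sorted(records, key=lambda r: r.gene_id)


def assign_family(
    record: GeneInventoryRecord,
    domains_by_protein: Mapping[str, Sequence[DomainAnnotation]],
    taxonomy: Mapping,
    og_reference_members: Optional[Mapping[str, Sequence[str]]] = None,
) -> FamilyAssignment:
    """Family/subfamily from domain composition, orthology as fallback.

    Among the gene's domains with a taxonomy mapping, the lowest-e-value
    domain decides (ties across subfamilies resolved the same way; a missing
    e-value ranks last). If no domain maps, the reference member of the
    gene's orthogroup decides via the taxonomy's reference map. Unresolvable
    genes fall to OTHER / "Misc.".
    """
    domain_map: Mapping[str, Mapping[str, str]] = taxonomy.get("domain_map", {})
    reference_map: Mapping[str, Mapping[str, str]] = taxonomy.get("reference_map", {})
    mapped: list[tuple[float, str]] = []
    for pid in record.protein_ids:
        for d in domains_by_protein.get(pid, []):
            if d.domain_acc in domain_map:
                ev = d.evalue if d.evalue is not None else float("inf")
                mapped.append((ev, d.domain_acc))
    if mapped:
        mapped.sort()
        entry = domain_map[mapped[0][1]]
        return FamilyAssignment(entry["family"], entry["subfamily"])
    if og_reference_members:
        for og_id in sorted(record.og_ids):
            for ref_pid in og_reference_members.get(og_id, []):
                if ref_pid in reference_map:
                    entry = reference_map[ref_pid]
                    return FamilyAssignment(entry["family"], entry["subfamily"])
    return FamilyAssignment("OTHER", "Misc.")


def tabulate_counts(data) -> dict:
    """Family x subfamily x species gene counts with margins.

    ``data`` is either a mapping species -> list of family-assigned
    :class:`GeneInventoryRecord`, or an already-tabulated DataFrame with
    ``family``/``subfamily`` columns followed by one count column per
    species. Returns the counts table, per-family sums, and grand totals.
    """
    if isinstance(data, pd.DataFrame):
        counts = data.copy()
    else:
        rows = []
        for species, records in data.items():
            for rec in records:
                if rec.assignment is None:
                    raise ValueError(f"{rec.gene_id}: inventory not family-assigned")
                rows.append(
                    {"family": rec.assignment.family,
                     "subfamily": rec.assignment.subfamily,
                     "species": species}
                )
        if rows:
            counts = (
                pd.DataFrame(rows)
                .groupby(["family", "subfamily", "species"])
                .size()
                .unstack("species", fill_value=0)
                .reset_index()
            )
            counts.columns.name = None
        else:
            counts = pd.DataFrame(columns=["family", "subfamily"])
    species_cols = [c for c in counts.columns if c not in ("family", "subfamily")]
    family_totals = (
        counts.groupby("family", sort=False)[species_cols].sum()
        if len(counts)
        else pd.DataFrame(columns=species_cols)
    )
    grand_totals = {sp: int(counts[sp].sum()) for sp in species_cols}
    return {
        "counts": counts,
        "family_totals": family_totals,
        "grand_totals": grand_totals,
    }
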