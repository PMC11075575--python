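"""Stage orchestration: evidence merging, histone architecture, loss
inference, and the end-to-end run with config validation and a manifest.

These functions are the programmatic pipeline surface; the command-line
interface in :mod:`epitoolkit.cli` is a thin wrapper around them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from . import count_stats, histones, loss as loss_mod, toolkit as tk
from .datasets import DEFAULT_SPECIES_TREE
from .io_formats import (
    DomainAnnotation,
    GeneModel,
    Orthogroup,
    SequenceRecord,
    read_newick,
)

logger = logging.getLogger("epitoolkit")

__all__ = [
    "run_toolkit_inventory",
    "analyze_histone_region",
    "infer_loss",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# toolkit stage


def run_toolkit_inventory(
    domains: Sequence[DomainAnnotation],
    orthogroups: Sequence[Orthogroup],
    refs: tk.ReferenceSets,
    gene_map: Mapping[str, str],
    species: str,
    taxonomy: Mapping,
    seqs: Optional[Mapping[str, str]] = None,
    species_tree: Optional[dendropy.Tree] = None,
    species_of: Optional[Mapping[str, str]] = None,
    qc: Optional[tk.QCConfig] = None,
) -> dict:
    """Domain + orthology selection, QC, gene collapse, family assignment.

    Returns the gene-level inventory with family assignments, the discard
    ledger, tree-placement review flags, and the family/subfamily count
    table.
    """
    dom_sel = tk.select_by_domain(domains, refs)
    orth_sel = tk.select_by_orthology(orthogroups, refs, species)
    domains_by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        domains_by_protein.setdefault(d.protein_id, []).append(d)

    candidates = []
    for pid in sorted(dom_sel | set(orth_sel)):
        evidence = set()
        if pid in dom_sel:
            evidence.add("domain")
        og_id = orth_sel.get(pid)
        if og_id is not None:
            evidence.add("orthology")
        candidates.append(
            tk.CandidateProtein(pid, gene_map.get(pid, pid), species, evidence, og_id)
        )
    logger.info("selected %d candidate proteins (%d by domain, %d by orthology)",
                len(candidates), len(dom_sel), len(orth_sel))

    ogs_by_id = {og.og_id: og for og in orthogroups}
    retained, discards = tk.qc_filter(
        candidates, domains_by_protein, ogs_by_id, refs, qc, species
    )
    for d in discards:
        logger.info("discarded %s (%s)", d.protein_id, d.discard_reason)

    flags = {}
    if species_tree is not None and species_of is not None:
        for cand in retained:
            og = ogs_by_id.get(cand.og_id) if cand.og_id else None
            if og is not None and og.tree is not None:
                flag = tk.flag_tree_placement(og, cand.protein_id, species_tree, species_of)
                if flag.status == "flagged":
                    flags[cand.protein_id] = flag

    records = tk.collapse_to_genes(retained, gene_map, seqs)
    ref_ids = refs.all_reference_proteins()
    og_reference_members = {
        og.og_id: sorted(ref_ids & og.all_members()) for og in orthogroups
    }
    for rec in records:
        rec.assignment = tk.assign_family(
            rec, domains_by_protein, taxonomy, og_reference_members
        )
    table = tk.tabulate_counts({species: records})
    return {
        "inventory": records,
        "discards": discards,
        "flags": flags,
        "counts": table,
    }


# ---------------------------------------------------------------------------
# histone stage


def analyze_histone_region(
    genome: SequenceRecord,
    genes: Sequence[GeneModel],
    class_hits: Mapping[str, Sequence],
    max_gap: int = 10_000,
    **stemloop_kwargs,
) -> dict:
    """Canonical/variant labels, RD calls, clusters, and quartet grammar."""
    labeled = histones.assign_canonical(genes, dict(class_hits))
    for hg in labeled:
        rd, hit = histones.call_replication_dependent(hg.gene, genome, **stemloop_kwargs)
        hg.rd, hg.hairpin = rd, hit
    histones.find_clusters(labeled, max_gap=max_gap)
    clusters: dict[str, list] = {}
    for hg in labeled:
        if hg.cluster_id:
            clusters.setdefault(hg.cluster_id, []).append(hg)
    quartets = {
        cid: histones.classify_quartets(members) for cid, members in sorted(clusters.items())
    }
    return {"histones": labeled, "clusters": clusters, "quartets": quartets}


# ---------------------------------------------------------------------------
# loss stage


def infer_loss(
    species_tree: dendropy.Tree,
    evidence: Mapping[str, Mapping[str, object]],
    locus_seqs: Mapping[str, Optional[SequenceRecord]],
    reference_protein: SequenceRecord,
    genes_by_species: Mapping[str, Sequence[GeneModel]],
    og_of: Mapping[str, str],
    focal_og: str,
    cfg: Optional[loss_mod.LossConfig] = None,
    repeats: Sequence[tuple[str, int, int, str]] = (),
) -> dict:
    """Presence calls, pseudogene features, synteny, and Dollo placement."""
    cfg = cfg or loss_mod.LossConfig()
    calls: dict[str, loss_mod.PresenceCall] = {}
    for sp, ev in evidence.items():
        seq = locus_seqs.get(sp)
        features = (
            loss_mod.detect_pseudogene_features(seq.seq, reference_protein.seq, cfg)
            if seq is not None
            else None
        )
        calls[sp] = loss_mod.call_presence(sp, ev, cfg, features)

    verdicts = {
        sp: ("functional" if c.verdict == "present" else "lost") for sp, c in calls.items()
    }
    branches = loss_mod.place_loss_dollo(verdicts, species_tree)

    blocks = []
    for sp, genes in genes_by_species.items():
        anchor = next((g.gene_id for g in genes if og_of.get(g.gene_id) == focal_og), None)
        neighbor_ogs = None
        if anchor is None:
            labels = [og_of.get(g.gene_id, "unassigned") for g in sorted(genes, key=lambda g: g.start)]
            # bracket the focal slot with the labels around the largest gap;
            # with a conserved neighborhood any adjacent pair near the middle works
            mid = len(labels) // 2
            neighbor_ogs = (labels[mid - 1], labels[mid])
        blocks.append(
            loss_mod.extract_synteny_window(
                list(genes), og_of, sp,
                anchor_gene=anchor, anchor_og=focal_og if anchor else None,
                neighbor_ogs=neighbor_ogs, cfg=cfg,
            )
        )
    synteny = loss_mod.synteny_conservation(
        blocks, focal_og, verdict_of={sp: c.verdict for sp, c in calls.items()}
    )
    repeat_overlaps = {}
    for b in blocks:
        if b.genes:
            chrom = genes_by_species[b.species][0].chrom
            span = (chrom, b.genes[0][2], b.genes[-1][3])
            repeat_overlaps[b.species] = loss_mod.detect_repeat_overlap(span, repeats)
    return {
        "calls": calls,
        "verdicts": verdicts,
        "loss_branches": branches,
        "synteny": synteny,
        "blocks": blocks,
        "repeat_overlaps": repeat_overlaps,
    }


# ---------------------------------------------------------------------------
# full run


_KNOWN_TOP = {"stages", "seed", "out_dir", "toolkit", "compare_counts", "histones", "loss"}
_KNOWN_STAGE_KEYS = {
    "toolkit": {"workspace", "species"},
    "compare_counts": {"counts", "reps", "species_a", "species_b"},
    "histones": {"workspace", "max_gap"},
    "loss": {"workspace"},
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order and write reports.

    ``config`` keys: ``stages`` (subset of toolkit, compare_counts, histones,
    loss), ``seed``, and one block per stage pointing at a workspace
    directory in the formats the ``simulate`` commands emit. Unknown keys are
    an error before any stage runs. Writes per-stage TSVs, a JSON summary,
    and a manifest of input checksums and parameters.
    """
    unknown = set(config) - _KNOWN_TOP
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for stage, block in config.items():
        if stage in _KNOWN_STAGE_KEYS and isinstance(block, dict):
            bad = set(block) - _KNOWN_STAGE_KEYS[stage]
            if bad:
                raise ValueError(f"unknown config key(s) in {stage!r}: {sorted(bad)}")
    stages = config.get("stages", [])
    seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": list(stages), "inputs": {}}
    summary: dict = {}

    # inputs must exist before any stage runs
    for stage in stages:
        block = config.get(stage, {})
        ws = block.get("workspace") or block.get("counts")
        if ws and not Path(ws).exists():
            raise FileNotFoundError(f"{stage}: input {ws} does not exist")

    for stage in stages:
        if stage == "toolkit":
            summary["toolkit"] = _toolkit_stage(config["toolkit"], out, manifest)
        elif stage == "compare_counts":
            summary["compare_counts"] = _counts_stage(config["compare_counts"], out, manifest, seed)
        elif stage == "histones":
            summary["histones"] = _histones_stage(config["histones"], out, manifest)
        elif stage == "loss":
            summary["loss"] = _loss_stage(config["loss"], out, manifest)
        else:
            raise ValueError(f"unknown stage {stage!r}")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _record_inputs(manifest: dict, paths: Sequence[Path]) -> None:
    for p in paths:
        if p.is_file():
            manifest["inputs"][str(p)] = _sha256(p)


def _toolkit_stage(block: dict, out: Path, manifest: dict) -> dict:
    import yaml

    from .io_formats import read_domain_table, read_fasta, read_orthogroups

    ws = Path(block["workspace"])
    species = block.get("species", "target")
    _record_inputs(manifest, sorted(ws.glob("*.*")))
    domains = read_domain_table(ws / "domains.tsv")
    ogs = read_orthogroups(ws / "orthogroups.tsv")
    trees_dir = ws / "trees"
    if trees_dir.is_dir():
        by_id = {og.og_id: og for og in ogs}
        for t in sorted(trees_dir.glob("*.nwk")):
            if t.stem in by_id:
                by_id[t.stem].tree = read_newick(t)
    refs_raw = yaml.safe_load((ws / "refs.yaml").read_text())
    refs = tk.ReferenceSets(
        set(refs_raw["epi_domains"]),
        {sp: set(ids) for sp, ids in refs_raw["epi_proteins"].items()},
        set(refs_raw.get("epi_specific_domains") or []) or None,
    )
    taxonomy = yaml.safe_load((ws / "taxonomy.yaml").read_text())
    gene_map = dict(
        line.split("\t") for line in (ws / "gene_map.tsv").read_text().splitlines() if line
    )
    seqs = {r.id: r.seq for r in read_fasta(ws / "proteome.faa", moltype="aa")}
    result = run_toolkit_inventory(
        domains, ogs, refs, gene_map, species, taxonomy, seqs=seqs
    )
    rows = [
        {
            "gene_id": r.gene_id,
            "species": r.species,
            "evidence": ",".join(sorted(r.evidence)),
            "family": r.assignment.family,
            "subfamily": r.assignment.subfamily,
            "og_ids": ",".join(sorted(r.og_ids)),
            "sequence_duplicate": r.sequence_duplicate,
        }
        for r in result["inventory"]
    ]
    pd.DataFrame(rows).to_csv(out / "inventory.tsv", sep="\t", index=False)
    result["counts"]["counts"].to_csv(out / "counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"protein_id": d.protein_id, "reason": d.discard_reason}
            for d in result["discards"]
        ]
    ).to_csv(out / "discards.tsv", sep="\t", index=False)
    return {
        "n_genes": len(result["inventory"]),
        "n_discards": len(result["discards"]),
        "grand_totals": result["counts"]["grand_totals"],
    }


def _counts_stage(block: dict, out: Path, manifest: dict, seed: int) -> dict:
    counts_path = Path(block["counts"])
    _record_inputs(manifest, [counts_path])
    counts = pd.read_csv(counts_path, sep="\t")
    report = count_stats.compare_family_counts(
        counts,
        species_a=block.get("species_a"),
        species_b=block.get("species_b"),
        reps=int(block.get("reps", 20000)),
        seed=seed,
    )
    report["per_family"].to_csv(out / "family_pvalues.tsv", sep="\t", index=False)
    return {
        "global_mc_p": report["global_mc_p"],
        "totals": report["totals"],
        "min_family_p": float(report["per_family"]["p"].min()),
    }


def _histones_stage(block: dict, out: Path, manifest: dict) -> dict:
    from .io_formats import read_blast_tab, read_fasta, read_gff_genes

    ws = Path(block["workspace"])
    _record_inputs(manifest, sorted(ws.glob("*.*")))
    genome = read_fasta(ws / "genome.fa", moltype="nt")[0]
    genes = read_gff_genes(ws / "genes.gff3")
    hits = read_blast_tab(ws / "class_hits.tsv")
    hits_by_class: dict[str, list] = {}
    for h in hits:
        hits_by_class.setdefault(h.query_id, []).append(h)
    result = analyze_histone_region(
        genome, genes, hits_by_class, max_gap=int(block.get("max_gap", 10_000))
    )
    rows = [
        {
            "gene_id": hg.gene.gene_id, "class": hg.histone_class, "status": hg.status,
            "rd": hg.rd, "cluster": hg.cluster_id or "",
            "strand": hg.gene.strand, "start": hg.gene.start,
        }
        for hg in result["histones"]
    ]
    pd.DataFrame(rows).to_csv(out / "histones.tsv", sep="\t", index=False)
    qrows = []
    for cid, reports in result["quartets"].items():
        for q in reports:
            qrows.append(
                {
                    "cluster": cid,
                    "order": ",".join(q.unit_order),
                    "strands": ",".join(q.unit_strands),
                    "duets": ";".join(f"{p}:{o}" for p, o in q.duets),
                    "irregular": q.irregular,
                }
            )
    pd.DataFrame(qrows).to_csv(out / "quartets.tsv", sep="\t", index=False)
    return {
        "n_histones": len(result["histones"]),
        "n_clusters": len(result["clusters"]),
        "n_quartets": sum(
            sum(not q.irregular for q in reps) for reps in result["quartets"].values()
        ),
    }


def _loss_stage(block: dict, out: Path, manifest: dict) -> dict:
    from .io_formats import read_fasta, read_gff_genes

    ws = Path(block["workspace"])
    _record_inputs(manifest, sorted(ws.glob("*.*")))
    tree_path = ws / "species_tree.nwk"
    tree = read_newick(tree_path if tree_path.exists() else DEFAULT_SPECIES_TREE)
    evidence: dict[str, dict[str, object]] = {}
    for line in (ws / "evidence.tsv").read_text().splitlines()[1:]:
        sp, ch, val = line.split("\t")
        if val in ("True", "False"):
            parsed: object = val == "True"
        else:
            try:
                parsed = float(val)
            except ValueError:
                parsed = val
        evidence.setdefault(sp, {})[ch] = parsed
    loci = {r.id.rsplit("_focal_locus", 1)[0]: r for r in read_fasta(ws / "loci.fna", moltype="nt")}
    reference = read_fasta(ws / "reference_protein.faa", moltype="aa")[0]
    og_of = dict(
        line.split("\t") for line in (ws / "og_of.tsv").read_text().splitlines() if line
    )
    genes_by_species = {
        gff.stem: read_gff_genes(gff) for gff in sorted(ws.glob("*.gff3"))
    }
    locus_seqs = {sp: loci.get(sp) for sp in genes_by_species}
    repeats = []
    rep_path = ws / "repeats.tsv"
    if rep_path.exists():
        for line in rep_path.read_text().splitlines()[1:]:
            rc, rs, re_, lbl = line.split("\t")
            repeats.append((rc, int(rs), int(re_), lbl))
    result = infer_loss(
        tree, evidence, locus_seqs, reference, genes_by_species, og_of,
        focal_og="OG_FOCAL", repeats=repeats,
    )
    rows = [
        {
            "species": sp,
            **{ch: c.evidence.get(ch, "not_evaluated") for ch in loss_mod.EVIDENCE_CHANNELS},
            "verdict": c.verdict,
        }
        for sp, c in result["calls"].items()
    ]
    pd.DataFrame(rows).to_csv(out / "presence_matrix.tsv", sep="\t", index=False)
    with open(out / "loss_branches.txt", "w", newline="\n") as fh:
        for br in result["loss_branches"]:
            fh.write(",".join(sorted(br)) + "\n")
    return {
        "verdicts": result["verdicts"],
        "loss_branches": [sorted(b) for b in result["loss_branches"]],
    }
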