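"""Gene presence/absence, pseudogenization, synteny, and Dollo loss placement.

This is the machinery used to establish a gene-family loss on a phylogeny
from layered homology evidence: per-species search channels (protein BLAST,
orthology clustering, transcriptome and genome TBLASTN, locus-level RNA-seq
support) are thresholded into hit/no-hit calls; loci that still exist are
screened for disabling features (in-frame stop codons, open-reading-frame
truncation); conserved gene neighborhoods establish that an absence is a
true locus deletion rather than an assembly artifact; and the resulting
functional/lost leaf states are placed on the species tree under Dollo
parsimony (one ancestral gain, irreversible losses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import GeneModel

__all__ = [
    "LossConfig",
    "PresenceCall",
    "SyntenyBlock",
    "PseudogeneFeatures",
    "ExpressionRecord",
    "pick_evalue_threshold",
    "detect_pseudogene_features",
    "call_presence",
    "extract_synteny_window",
    "synteny_conservation",
    "place_loss_dollo",
    "compute_fpkm",
    "detect_repeat_overlap",
]

EVIDENCE_CHANNELS = ("blastp", "orthofinder", "tblastn_tx", "tblastn_genome", "rnaseq_locus")


@dataclass
class LossConfig:
    """Thresholds for the presence/absence analysis.

    ``evalue_protein_tx`` applies to proteome and transcriptome searches,
    ``evalue_genome`` to whole-genome searches (which yield fewer, weaker
    hits), and ``evalue_relaxed`` is the exploratory ceiling used when a
    family cannot be found at all. The synteny half-window ``flank_bp``
    defaults to 60 kb (legal profile 50-70 kb).
    """

    evalue_protein_tx: float = 1e-29
    evalue_genome: float = 1e-5
    evalue_relaxed: float = 1e-1
    flank_bp: int = 60_000
    max_internal_stops: int = 0
    min_length_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.evalue_protein_tx <= self.evalue_genome <= self.evalue_relaxed:
            raise ValueError("thresholds must satisfy protein/tx <= genome <= relaxed")
        if not 50_000 <= self.flank_bp <= 70_000:
            raise ValueError("flank_bp outside the 50,000-70,000 bp profile")


@dataclass
class PresenceCall:
    species: str
    evidence: dict[str, str]           # channel -> hit | no_hit | not_evaluated
    verdict: str                       # present | pseudogene | absent
    best_evalues: dict[str, float] = field(default_factory=dict)
    features: Optional["PseudogeneFeatures"] = None


@dataclass
class SyntenyBlock:
    species: str
    genes: list[tuple[str, str, int, int, str]]  # (gene_id, og_id, start, end, strand)
    anchor_og: str
    anchor_pos: int
    truncated: bool = False

    def labels(self) -> list[tuple[str, str]]:
        return [(og, strand) for (_, og, _, _, strand) in self.genes]


@dataclass
class PseudogeneFeatures:
    internal_stops: int
    length_fraction: float
    classification: str                # intact | truncated | stop_disrupted | both
    frame: int = 0                     # 0,1,2 (+) or -1,-2,-3 (reverse)


@dataclass
class ExpressionRecord:
    gene_id: str
    total_reads_per_gene: int
    gene_length_bp: int
    total_mapped_reads: int

    @property
    def fpkm(self) -> float:
        return compute_fpkm(self.total_reads_per_gene, self.gene_length_bp, self.total_mapped_reads)


# ---------------------------------------------------------------------------
# e-value threshold choice


def pick_evalue_threshold(
    evalues: Sequence[float],
    default: float = 1e-29,
    min_gap_log10: float = 2.0,
) -> tuple[float, dict]:
    """Choose a significance threshold at the plateau edge of top-hit e-values.

    Sorts -log10(e) descending and finds the largest successive gap: a clear
    bimodal split between a strong-hit mode and a noise mode. The threshold
    is the geometric midpoint of the two e-values flanking the gap. If the
    largest gap is below ``min_gap_log10`` units, the configured default is
    returned with a "no clear plateau" warning in the diagnostics.
    """
    if len(evalues) < 5:
        raise ValueError("need at least 5 top-hit e-values")
    logs = np.sort(-np.log10(np.maximum(np.asarray(evalues, dtype=float), 1e-300)))[::-1]
    gaps = logs[:-1] - logs[1:]
    k = int(np.argmax(gaps))
    diag = {"sorted_neg_log10": logs, "gaps": gaps, "largest_gap": float(gaps[k])}
    if gaps[k] < min_gap_log10:
        diag["warning"] = "no clear plateau; returning default threshold"
        return default, diag
    mid = (logs[k] + logs[k + 1]) / 2.0
    return float(10.0 ** (-mid)), diag


# ---------------------------------------------------------------------------
# pseudogene features


_ALIGNER = None


def _protein_aligner() -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        aln = PairwiseAligner()
        aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aln.open_gap_score = -11
        aln.extend_gap_score = -1
        aln.mode = "local"
        _ALIGNER = aln
    return _ALIGNER


def _translate_frame(seq: str, frame: int) -> str:
    """frame 0,1,2 translate forward; -1,-2,-3 translate the reverse complement."""
    if frame >= 0:
        sub = seq[frame:]
    else:
        sub = str(Seq(seq).reverse_complement())[-frame - 1 :]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate()) if sub else ""


def detect_pseudogene_features(
    locus_seq: str,
    reference_protein: str,
    cfg: LossConfig | None = None,
    search_reverse: bool = True,
) -> PseudogeneFeatures:
    """Screen a putative locus sequence for disabling mutations.

    Translates the locus in all forward (and optionally reverse) frames,
    picks the frame whose translation aligns best to the reference protein
    (ties broken toward fewer internal stops, conservative against false
    pseudogene calls), then counts stop codons strictly inside the aligned
    span and measures aligned coverage of the reference. Classification:
    ``stop_disrupted`` if internal stops exceed ``max_internal_stops``,
    ``truncated`` if coverage < ``min_length_fraction``, ``both`` or
    ``intact`` accordingly.
    """
    cfg = cfg or LossConfig()
    if len(locus_seq) < 30:
        raise ValueError("locus sequence shorter than 30 nt")
    locus_seq = locus_seq.upper()
    aligner = _protein_aligner()
    frames = [0, 1, 2] + ([-1, -2, -3] if search_reverse else [])
    best = None  # (score, -stops, frame, alignment, translation)
    for frame in frames:
        prot = _translate_frame(locus_seq, frame)
        if not prot:
            continue
        aln = aligner.align(prot, reference_protein)
        if len(aln) == 0:
            continue
        top = aln[0]
        qs, qe = top.aligned[0][0][0], top.aligned[0][-1][1]
        stops = prot[qs:qe].count("*")
        # drop a trailing terminator just past the aligned span from the count
        key = (top.score, -stops)
        if best is None or key > best[0]:
            best = (key, frame, top, prot, (qs, qe), stops)
    if best is None:
        raise ValueError("no frame of the locus aligns to the reference protein")
    _, frame, top, prot, (qs, qe), stops = best
    ref_cov = sum(e - s for s, e in top.aligned[1])
    length_fraction = ref_cov / len(reference_protein)
    stop_disrupted = stops > cfg.max_internal_stops
    truncated = length_fraction < cfg.min_length_fraction
    if stop_disrupted and truncated:
        cls = "both"
    elif stop_disrupted:
        cls = "stop_disrupted"
    elif truncated:
        cls = "truncated"
    else:
        cls = "intact"
    return PseudogeneFeatures(stops, length_fraction, cls, frame)


# ---------------------------------------------------------------------------
# presence calls


def call_presence(
    species: str,
    evidence: Mapping[str, object],
    cfg: LossConfig | None = None,
    locus_features: Optional[PseudogeneFeatures] = None,
) -> PresenceCall:
    """Threshold an evidence bundle into present / pseudogene / absent.

    ``evidence`` maps channel names to a best e-value (BLAST channels), a
    boolean (orthofinder / rnaseq_locus), or the string ``"not_evaluated"``.
    Protein and transcriptome channels use ``evalue_protein_tx``; the genome
    channel uses ``evalue_genome``. The verdict is ``present`` when any
    channel hits and the locus (when sequence-level features are available)
    is intact; ``pseudogene`` when the locus exists but carries disabling
    features; ``absent`` otherwise. RNA-seq support never overrides
    sequence-level pseudogene features (pseudogenes can still be expressed).
    """
    cfg = cfg or LossConfig()
    calls: dict[str, str] = {}
    best_evalues: dict[str, float] = {}
    for ch in EVIDENCE_CHANNELS:
        val = evidence.get(ch, "not_evaluated")
        if val == "not_evaluated" or val is None:
            calls[ch] = "not_evaluated"
        elif isinstance(val, bool):
            calls[ch] = "hit" if val else "no_hit"
        else:
            e = float(val)
            best_evalues[ch] = e
            thr = cfg.evalue_genome if ch == "tblastn_genome" else cfg.evalue_protein_tx
            calls[ch] = "hit" if e <= thr else "no_hit"
    if all(v == "not_evaluated" for v in calls.values()):
        raise ValueError(f"{species}: all evidence channels not_evaluated")
    any_hit = any(v == "hit" for v in calls.values())
    if locus_features is not None and locus_features.classification != "intact":
        verdict = "pseudogene"
    elif any_hit:
        verdict = "present"
    else:
        verdict = "absent"
    return PresenceCall(species, calls, verdict, best_evalues, locus_features)


# ---------------------------------------------------------------------------
# synteny


def extract_synteny_window(
    genes: Sequence[GeneModel],
    og_of: Mapping[str, str],
    species: str,
    anchor_gene: Optional[str] = None,
    anchor_og: Optional[str] = None,
    neighbor_ogs: Optional[tuple[str, str]] = None,
    cfg: LossConfig | None = None,
    chrom_length: Optional[int] = None,
) -> SyntenyBlock:
    """All genes overlapping ``[anchor_mid - flank, anchor_mid + flank]``.

    The anchor is located directly by gene id, by orthogroup label, or — for
    species where the anchor gene is gone — as the midpoint between two
    flanking orthogroup labels. Windows clipped at a contig edge are marked
    truncated with a warning.
    """
    cfg = cfg or LossConfig()
    by_id = {g.gene_id: g for g in genes}
    anchor_label = anchor_og or (og_of.get(anchor_gene, "unassigned") if anchor_gene else None)

    mid: Optional[int] = None
    if anchor_gene and anchor_gene in by_id:
        mid = by_id[anchor_gene].midpoint
    elif anchor_og is not None:
        carriers = [g for g in genes if og_of.get(g.gene_id) == anchor_og]
        if carriers:
            mid = carriers[0].midpoint
    if mid is None and neighbor_ogs is not None:
        left = [g for g in genes if og_of.get(g.gene_id) == neighbor_ogs[0]]
        right = [g for g in genes if og_of.get(g.gene_id) == neighbor_ogs[1]]
        if left and right:
            mid = (left[0].midpoint + right[0].midpoint) // 2
            anchor_label = anchor_label or "unassigned"
    if mid is None:
        raise ValueError(f"{species}: anchor not locatable directly or via neighbors")

    lo, hi = mid - cfg.flank_bp, mid + cfg.flank_bp
    truncated = lo < 1 or (chrom_length is not None and hi > chrom_length)
    if truncated:
        warnings.warn(f"{species}: synteny window clipped at contig edge")
    selected = sorted(
        (g for g in genes if g.end >= lo and g.start <= hi), key=lambda g: g.start
    )
    return SyntenyBlock(
        species,
        [(g.gene_id, og_of.get(g.gene_id, "unassigned"), g.start, g.end, g.strand)
         for g in selected],
        anchor_og=anchor_label or "unassigned",
        anchor_pos=mid,
        truncated=truncated,
    )


def _lcs(a: Sequence, b: Sequence) -> int:
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            dp[i][j] = dp[i - 1][j - 1] + 1 if a[i - 1] == b[j - 1] else max(
                dp[i - 1][j], dp[i][j - 1]
            )
    return dp[-1][-1]


def _flip(labels: list[tuple[str, str]]) -> list[tuple[str, str]]:
    flip = {"+": "-", "-": "+"}
    return [(og, flip[s]) for og, s in reversed(labels)]


def synteny_conservation(
    blocks: Sequence[SyntenyBlock],
    focal_og: str,
    verdict_of: Optional[Mapping[str, str]] = None,
    conserved_score: float = 0.5,
) -> dict:
    """Pairwise neighborhood-order conservation plus focal-locus status.

    Each pair of species is scored |strand-aware LCS of orthogroup label
    sequences| / min(block lengths), allowing whole-block reversal (the
    reversed, strand-flipped sequence is also tried). Reports, per species,
    whether the focal orthogroup is intact / pseudogene / missing inside an
    otherwise conserved neighborhood (mean pairwise score >= threshold).
    """
    if len(blocks) < 2:
        raise ValueError("need at least two synteny blocks")
    scores: dict[tuple[str, str], float] = {}
    for i, bi in enumerate(blocks):
        for bj in blocks[i + 1 :]:
            la, lb = bi.labels(), bj.labels()
            shared = {og for og, _ in la} & {og for og, _ in lb}
            if not shared:
                warnings.warn(f"{bi.species}/{bj.species}: no shared orthogroup labels")
                score = 0.0
            else:
                score = max(_lcs(la, lb), _lcs(la, _flip(lb))) / min(len(la), len(lb))
            scores[(bi.species, bj.species)] = score
    status = {}
    for b in blocks:
        ogs = {og for og, _ in b.labels()}
        others = [s for pair, s in scores.items() if b.species in pair]
        mean_score = float(np.mean(others)) if others else 0.0
        if focal_og in ogs:
            state = (verdict_of or {}).get(b.species, "present")
            focal = "pseudogene" if state == "pseudogene" else "intact"
        else:
            focal = "missing"
        status[b.species] = {
            "focal": focal,
            "flanks_conserved": mean_score >= conserved_score,
            "mean_pairwise_score": mean_score,
        }
    return {"pairwise_scores": scores, "focal_status": status}


# ---------------------------------------------------------------------------
# Dollo loss placement


def place_loss_dollo(
    verdicts: Mapping[str, str], species_tree: dendropy.Tree
) -> list[frozenset[str]]:
    """Minimal irreversible-loss branches explaining a functional/lost pattern.

    Under the Dollo model (single ancestral gain at the root, losses cannot
    revert) the unique minimal solution is the set of maximal all-lost
    clades: branches whose subtree leaves are all lost but whose parent's
    subtree is not. Each loss branch is returned as the frozenset of leaf
    labels below it. Pseudogenes should be passed as ``lost`` (functional
    loss) by the caller.
    """
    leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    if not leaves:
        raise ValueError("empty species tree")
    missing = leaves - set(verdicts)
    if missing:
        raise ValueError(f"no verdict for leaves: {sorted(missing)}")
    for sp, v in verdicts.items():
        if v not in ("functional", "lost"):
            raise ValueError(f"{sp}: verdict must be 'functional' or 'lost', got {v!r}")

    all_lost: dict[int, bool] = {}
    leafset: dict[int, frozenset[str]] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            all_lost[id(node)] = verdicts[lbl] == "lost"
            leafset[id(node)] = frozenset([lbl])
        else:
            kids = node.child_nodes()
            all_lost[id(node)] = all(all_lost[id(c)] for c in kids)
            leafset[id(node)] = frozenset().union(*(leafset[id(c)] for c in kids))

    losses: list[frozenset[str]] = []
    for node in species_tree.preorder_node_iter():
        parent = node.parent_node
        if all_lost[id(node)] and (parent is None or not all_lost[id(parent)]):
            losses.append(leafset[id(node)])
    return sorted(losses, key=lambda s: (len(s), sorted(s)))


# ---------------------------------------------------------------------------
# expression and repeats


def compute_fpkm(
    total_reads_per_gene: float, gene_length_bp: int, total_mapped_reads: int
) -> float:
    """Fragments per kilobase of transcript per million mapped reads:
    reads / (length_bp * mapped_reads / 1e9)."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return total_reads_per_gene / (gene_length_bp * total_mapped_reads / 1e9)


def detect_repeat_overlap(
    window: tuple[str, int, int],
    repeats: Iterable[tuple[str, int, int, str]],
) -> list[tuple[str, int, int, str]]:
    """Repeats intersecting a (chrom, start, end) window, 1-based inclusive.

    ``repeats`` rows are (chrom, start, end, label). An empty result is the
    meaningful "no transposon signature at this locus" outcome.
    """
    chrom, lo, hi = window
    tree = IntervalTree()
    rows = list(repeats)
    for i, (rc, rs, re_, _) in enumerate(rows):
        if rc == chrom:
            tree[rs : re_ + 1] = i    # half-open tree over inclusive coords
    return [rows[iv.data] for iv in sorted(tree.overlap(lo, hi + 1))]
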