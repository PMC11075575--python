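"""Histone gene architecture: canonical/variant assignment, replication-
dependent stem-loop detection, tandem cluster finding, and quartet/duet
order-and-orientation grammar.

Canonical metazoan replication-dependent histone mRNAs end in a conserved
~16-nt stem-loop (6-bp stem, 4-nt loop) instead of a poly(A) tail; scanning
the 100 nt immediately 3' of the stop codon for that element separates
replication-dependent (canonical) from replication-independent (variant)
copies. Within tandem clusters the four core histones form "quartet" units
whose adjacent complementary pairs (H2A-H2B and H3-H4, the "duets") are
classified by strand: same strand = head-to-tail; divergent (5' ends facing)
= head-to-head; convergent (3' ends facing) = tail-to-tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import BlastHit, GeneModel, SequenceRecord

__all__ = [
    "HistoneGene",
    "HairpinHit",
    "QuartetReport",
    "DEFAULT_STEMLOOP_CONSENSUS",
    "assign_canonical",
    "detect_stemloop",
    "call_replication_dependent",
    "find_clusters",
    "classify_quartets",
    "hairpin_logo_matrix",
]

CORE_CLASSES = ("H2A", "H2B", "H3", "H4")
HISTONE_CLASSES = ("H1",) + CORE_CLASSES

#: 16-nt metazoan histone downstream stem-loop: 6-bp stem, 4-nt loop.
DEFAULT_STEMLOOP_CONSENSUS = "GGCTCTTTTCAGAGCC"
DEFAULT_STEM_LEN = 6
DEFAULT_LOOP_LEN = 4

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HairpinHit:
    offset: int          # 0-based offset into the scanned window
    stem_len: int
    loop_len: int
    loop_seq: str
    score: float


@dataclass
class HistoneGene:
    gene: GeneModel
    histone_class: str
    status: str = "variant"            # canonical | variant
    rd: bool = False
    hairpin: Optional[HairpinHit] = None
    cluster_id: Optional[str] = None
    best_bitscore: Optional[float] = None

    def __post_init__(self) -> None:
        if self.histone_class not in HISTONE_CLASSES:
            raise ValueError(f"unknown histone class {self.histone_class!r}")
        if self.rd and self.hairpin is None:
            raise ValueError(f"{self.gene.gene_id}: rd=True requires a hairpin hit")


@dataclass
class QuartetReport:
    unit_order: list[str]
    unit_strands: list[str]
    duets: list[tuple[str, str]] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    irregular: bool = False


# ---------------------------------------------------------------------------
# canonical vs variant


def assign_canonical(
    genes: Sequence[GeneModel],
    hits_by_class: dict[str, Sequence[BlastHit]],
    rel_tol: float = 0.01,
    preassigned_class: Optional[dict[str, str]] = None,
) -> list[HistoneGene]:
    """Label histone genes canonical or variant from per-class similarity hits.

    For every histone class, all genes whose best bitscore against that
    class's reference query lies within ``rel_tol`` of the class maximum are
    canonical (canonical copies are near-identical, so ties at the top are
    expected); every other hit gene is a variant of that class. A gene within
    tolerance of the maximum of two classes is ambiguous and raises unless
    its class is preassigned.
    """
    best: dict[str, dict[str, float]] = {}  # class -> gene -> best bitscore
    for cls, hits in hits_by_class.items():
        if cls not in HISTONE_CLASSES:
            raise ValueError(f"unknown histone class {cls!r}")
        per_gene: dict[str, float] = {}
        for h in hits:
            per_gene[h.subject_id] = max(per_gene.get(h.subject_id, -np.inf), h.bitscore)
        best[cls] = per_gene

    class_max = {cls: max(pg.values()) for cls, pg in best.items() if pg}
    gene_index = {g.gene_id: g for g in genes}
    out: list[HistoneGene] = []
    for gid, gene in gene_index.items():
        candidates = {cls: pg[gid] for cls, pg in best.items() if gid in pg}
        if not candidates:
            continue
        if preassigned_class and gid in preassigned_class:
            cls = preassigned_class[gid]
        else:
            top = [
                c for c, s in candidates.items()
                if s >= class_max[c] * (1.0 - rel_tol)
            ]
            if len(top) > 1:
                raise ValueError(
                    f"{gid}: within canonical tolerance of classes {sorted(top)}; "
                    "pre-assign its class to disambiguate"
                )
            cls = top[0] if top else max(candidates, key=candidates.get)
        score = candidates[cls]
        status = "canonical" if score >= class_max[cls] * (1.0 - rel_tol) else "variant"
        out.append(HistoneGene(gene, cls, status=status, best_bitscore=score))
    out.sort(key=lambda hg: (hg.gene.chrom, hg.gene.start))
    return out


# ---------------------------------------------------------------------------
# stem-loop detection


def _consensus_score(window: str, offset: int, consensus: str) -> float:
    """Fraction of consensus positions matched (IUPAC-aware)."""
    matched = 0
    for i, c in enumerate(consensus):
        if window[offset + i] in _IUPAC.get(c, c):
            matched += 1
    return matched / len(consensus)


def _inverted_repeat_scan(window: str, min_stem: int = 5, loop_range=(3, 6)) -> Optional[HairpinHit]:
    """Generic fallback: inverted repeat with >=min_stem bp allowing one
    mismatch or G.T wobble, loop 3-6 nt. Returns the best-scoring hit."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    best: Optional[HairpinHit] = None
    n = len(window)
    for stem in range(min_stem, 9):
        for loop in range(loop_range[0], loop_range[1] + 1):
            span = 2 * stem + loop
            for off in range(0, n - span + 1):
                left = window[off : off + stem]
                right = window[off + stem + loop : off + span]
                bad = sum(
                    (l, r) not in pairs for l, r in zip(left, reversed(right))
                )
                if bad <= 1:
                    score = (stem - bad) / stem * 0.9  # below any strong consensus hit
                    if best is None or score > best.score:
                        best = HairpinHit(
                            off, stem, loop, window[off + stem : off + stem + loop], score
                        )
    return best


def detect_stemloop(
    window: str,
    consensus: str = DEFAULT_STEMLOOP_CONSENSUS,
    stem_len: int = DEFAULT_STEM_LEN,
    loop_len: int = DEFAULT_LOOP_LEN,
    min_score: float = 0.8,
    fallback_inverted_repeat: bool = False,
) -> Optional[HairpinHit]:
    """Scan a <=100-nt window for the histone downstream stem-loop.

    Pass 1 slides the consensus motif over the window and scores the
    IUPAC-aware match fraction; a hit requires ``score >= min_score``. Pass 2
    (disabled by default) falls back to a generic inverted-repeat scan.
    Returns the highest-scoring hit or None.
    """
    if len(window) > 100:
        raise ValueError("window longer than 100 nt; pre-slice the 3' region")
    window = window.upper()
    best: Optional[HairpinHit] = None
    span = len(consensus)
    for off in range(0, len(window) - span + 1):
        score = _consensus_score(window, off, consensus)
        if score >= min_score and (best is None or score > best.score):
            loop = window[off + stem_len : off + stem_len + loop_len]
            best = HairpinHit(off, stem_len, loop_len, loop, score)
    if best is None and fallback_inverted_repeat:
        best = _inverted_repeat_scan(window)
    return best


def extract_downstream_window(
    gene: GeneModel, genome: SequenceRecord, length: int = 100
) -> str:
    """The ``length`` nt immediately 3' of the stop codon, strand-aware.

    Minus-strand genes take the bases with genomic coordinates immediately
    below the CDS start, reverse-complemented. Truncated windows (contig end)
    are returned with a warning.
    """
    seq = genome.seq
    lo, hi = gene.cds_span
    if gene.strand == "+":
        start0 = hi              # 0-based index just past the stop codon
        end0 = min(len(seq), hi + length)
        win = seq[start0:end0]
    else:
        end0 = lo - 1            # 0-based exclusive end (base before CDS start)
        start0 = max(0, end0 - length)
        win = revcomp(seq[start0:end0])
    if len(win) < length:
        warnings.warn(
            f"{gene.gene_id}: 3' window truncated to {len(win)} nt at contig edge"
        )
    return win


def call_replication_dependent(
    gene: GeneModel, genome: SequenceRecord, **stemloop_kwargs
) -> tuple[bool, Optional[HairpinHit]]:
    """True iff the stem-loop is found within 100 nt 3' of the stop codon."""
    window = extract_downstream_window(gene, genome)
    hit = detect_stemloop(window, **stemloop_kwargs)
    return hit is not None, hit


# ---------------------------------------------------------------------------
# clusters and quartets


def find_clusters(
    histones: Sequence[HistoneGene],
    max_gap: int = 10_000,
    min_cluster_size: int = 4,
) -> list[HistoneGene]:
    """Single-linkage chaining of histone genes along each chromosome.

    Consecutive genes <= ``max_gap`` apart (end-to-start distance) join one
    chain; chains with >= ``min_cluster_size`` genes get a cluster id
    ``<chrom>:<k>``, smaller chains stay unclustered (orphans/singletons).
    """
    by_chrom: dict[str, list[HistoneGene]] = {}
    for hg in histones:
        by_chrom.setdefault(hg.gene.chrom, []).append(hg)
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda hg: hg.gene.start)
        chains: list[list[HistoneGene]] = [[genes[0]]] if genes else []
        for hg in genes[1:]:
            if hg.gene.start - chains[-1][-1].gene.end <= max_gap:
                chains[-1].append(hg)
            else:
                chains.append([hg])
        k = 0
        for chain in chains:
            if len(chain) >= min_cluster_size:
                k += 1
                for hg in chain:
                    hg.cluster_id = f"{chrom}:{k}"
            else:
                for hg in chain:
                    hg.cluster_id = None
    return list(histones)


def _duet_orientation(left: HistoneGene, right: HistoneGene) -> str:
    """Orientation of two position-adjacent genes (left.start <= right.start)."""
    s1, s2 = left.gene.strand, right.gene.strand
    if s1 == s2:
        return "head-to-tail"
    if s1 == "-" and s2 == "+":
        return "head-to-head"   # divergent: 5' ends face each other
    return "tail-to-tail"       # convergent: 3' ends face each other


def classify_quartets(cluster: Sequence[HistoneGene]) -> list[QuartetReport]:
    """Partition a cluster into quartets of the four core histones.

    Scans consecutive windows of four genes; windows containing one each of
    H2A, H2B, H3, H4 become quartets with class order, strand vector, and
    duet orientations for the adjacent complementary pairs. Windows missing
    a class are reported irregular rather than forced; H1 genes are skipped.
    """
    genes = sorted(
        (hg for hg in cluster if hg.histone_class in CORE_CLASSES),
        key=lambda hg: hg.gene.start,
    )
    reports: list[QuartetReport] = []
    i = 0
    while i + 4 <= len(genes):
        window = genes[i : i + 4]
        classes = [hg.histone_class for hg in window]
        if set(classes) == set(CORE_CLASSES):
            duets: list[tuple[str, str]] = []
            for a, b in zip(window, window[1:]):
                pair = {a.histone_class, b.histone_class}
                if pair == {"H2A", "H2B"}:
                    duets.append(("H2A-H2B", _duet_orientation(a, b)))
                elif pair == {"H3", "H4"}:
                    duets.append(("H3-H4", _duet_orientation(a, b)))
            for name in ("H2A-H2B", "H3-H4"):
                if all(d[0] != name for d in duets):
                    duets.append((name, "n/a"))
            reports.append(
                QuartetReport(
                    unit_order=classes,
                    unit_strands=[hg.gene.strand for hg in window],
                    duets=sorted(duets),
                    gene_ids=[hg.gene.gene_id for hg in window],
                )
            )
            i += 4
        else:
            reports.append(
                QuartetReport(
                    unit_order=[window[0].histone_class],
                    unit_strands=[window[0].gene.strand],
                    gene_ids=[window[0].gene.gene_id],
                    irregular=True,
                )
            )
            i += 1
    # trailing genes that cannot fill a window
    for hg in genes[i:]:
        reports.append(
            QuartetReport(
                unit_order=[hg.histone_class],
                unit_strands=[hg.gene.strand],
                gene_ids=[hg.gene.gene_id],
                irregular=True,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# logo matrix


def hairpin_logo_matrix(windows: Sequence[str]) -> np.ndarray:
    """Position frequency matrix (4 x L over A,C,G,T) of aligned windows.

    IUPAC ambiguity codes contribute fractionally to their compatible bases.
    Columns sum to 1.
    """
    if not windows:
        raise ValueError("no windows given")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise ValueError("windows must all have equal length")
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.zeros((4, L))
    for w in windows:
        for j, ch in enumerate(w.upper()):
            bases = _IUPAC.get(ch)
            if bases is None:
                raise ValueError(f"non-nucleotide character {ch!r}")
            frac = 1.0 / len(bases)
            for b in bases:
                mat[idx[b], j] += frac
    return mat / len(windows)
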