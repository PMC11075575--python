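# Methods

This note documents the models, decision rules, defaults, and numerical
choices behind each stage, and what the synthetic-data generators do and do
not emulate.

## Inventory construction

**Model.** A protein is a candidate epigenetic protein if it carries at least
one domain from a user-supplied reference set of epigenetic-associated
domains, or belongs to an orthogroup containing at least one reference
epigenetic protein from a model species. The two streams are merged at the
gene level (evidence unioned over isoforms); distinct genes encoding
identical proteins each count, flagged as sequence duplicates.

**Quality control.** Orthology clustering over-merges: large orthogroups pick
up proteins with unrelated functions. Three conjunctive discard rules operate
on orthology-derived candidates, each exemption sufficient to retain:

* *Outlier domains* — a candidate carrying a domain found on no other member
  of its orthogroup is discarded only if it (a) has no epigenetic-specific
  domain, (b) has no externally supplied "predicted epigenetic function"
  annotation (an optional per-protein boolean input, default false — not a
  live database query), and (c) is not closely related to a reference or
  retained epigenetic protein.
* *Zero domains* — discarded unless closely related to such a protein.
* *Kinases* — histone-kinase candidates (by domain) are kept only with the
  close relationship, because kinase orthogroups are dominated by
  non-chromatin kinases.

"Closely related" is a reproducible surrogate for a visual gene-tree check:
inside the smallest clade of at most 2 × (number of target-species members)
leaves containing the focal leaf, the focal leaf's nearest neighbor by
patristic distance (edge count when branch lengths are absent) must be a
reference or already-retained epigenetic protein. Suspicious *tree
placements* are flagged for review, never auto-discarded: the three nearest
non-target leaves of distinct species form a triplet; if the species that the
gene tree makes the focal gene's sister is not among the species nearest the
focal species in the species tree, the candidate is flagged with the triplet
and both resolutions attached. Each discard carries a reason code
(`outlier_domain_no_epi_function`, `no_domains_no_epi_ortholog`,
`bad_tree_placement` reserved for user-confirmed flags,
`kinase_no_adjacent_reference`).

Monotonicity caveat: adding an epigenetic-specific domain to a protein can
never cause a discard, but adding a *non-reference* domain can create a new
outlier and flip a retained protein to discarded — that is the intended
semantics of the outlier rule, and the property suite tests the guaranteed
direction only.

**Family assignment.** A shipped taxonomy maps one representative Pfam-style
accession to each of the 37 subfamilies in the nine-family scheme (HAT, HDAC,
HMT, HDMT, HISTONE, DNA_METH, NCRNA, REMODELER, OTHER). Domain evidence takes
precedence, ties resolved by lowest domain e-value (a missing e-value ranks
last); a gene with no mapped domain inherits the label of its orthogroup's
reference member; anything else is OTHER/"Misc.". Real analyses should
override the default map — several subfamilies share Pfam clans and a single
accession cannot always separate them.

## Count statistics

The two-sided Fisher exact p is defined as the sum of hypergeometric point
probabilities not exceeding the observed table's probability (relative tie
tolerance 1e-7 so floating-point ties count as ties), computed by direct
enumeration over the support; this matches the conventional two-sided
definition. The r×2 Monte Carlo test samples fixed-margin tables with
Patefield's algorithm and reports p̂ = (1 + hits)/(reps + 1) — never exactly
zero — with a binomial standard error; the default 20,000 replicates put the
SE near 0.003 at p ≈ 0.2 and far lower in the tails. Bonferroni (min(1, m·p))
is the only multiplicity correction offered.

The packaged two-species count table (37 subfamily rows; totals 291 and 265)
is the worked-example fixture; its histone-vs-rest 2×2 test gives p = 0.0037
(0.004 at three decimals), the only family significant after Bonferroni.

## Histone architecture

* **Canonical vs variant:** per histone class, canonical = best bitscore
  within 1% (relative) of the class maximum. Canonical copies are
  near-identical, so ties at the top are expected and an exact-tie rule would
  be fragile to alignment arithmetic. A gene within tolerance of two class
  maxima is an error unless its class is pre-assigned.
* **Stem-loop:** default consensus `GGCTCTTTTCAGAGCC` (16 nt, 6-bp stem,
  4-nt loop); a hit requires an IUPAC-aware match fraction ≥ 0.8 somewhere in
  the 100-nt window 3′ of the stop codon. At that threshold the false-positive
  rate on uniform random 100-mers is below 1%. A generic inverted-repeat
  fallback (stem ≥ 5 bp allowing one mismatch/G·U, loop 3–6 nt) exists but is
  off by default: the consensus scan is reproducible, the fallback is
  permissive. Minus-strand windows are the 100 bases with genomic coordinates
  immediately below the CDS start, reverse-complemented. Windows truncated by
  a contig edge are scanned as-is with a warning.
* **Clusters:** single-linkage chaining with a 10-kb maximum gap; chains of
  ≥ 4 genes are clusters, smaller chains orphans. 10 kb separates tandem
  arrays (intra-cluster spacing is a few kb) from inter-cluster distances
  (tens of kb to Mb).
* **Quartets/duets:** consecutive windows of four genes containing one each
  of H2A/H2B/H3/H4; windows missing a class are reported irregular, never
  forced. Duets are classified only on position-adjacent complementary pairs:
  same strand → head-to-tail; (−,+) in position order → head-to-head
  (divergent 5′ ends); (+,−) → tail-to-tail. These labels are invariant under
  reverse-complementing the whole region (order reverses, strands flip, both
  diagnostic patterns map to themselves), which the property suite checks on
  random clusters. H1 is inventoried but excluded from quartet grammar.

## Gene-loss inference

* **Thresholds:** protein/transcriptome searches 1e-29, genome searches 1e-5
  (genome TBLASTN yields fewer, weaker hits), exploratory ceiling 1e-1. The
  plateau finder sorts −log10(e) descending and takes the largest successive
  gap; below 2 log-units it declares "no clear plateau" and returns the
  configured default. E-values ≤ 0 are floored at 1e-300.
* **Pseudogene screening:** the locus is translated in all six frames; the
  frame with the best local alignment (BLOSUM62, gap open −11 / extend −1) to
  the reference protein wins, ties broken toward fewer internal stops —
  conservative against false pseudogene calls. Internal stops are counted
  strictly inside the aligned span; coverage is the aligned fraction of the
  reference. Defaults: any internal stop disrupts; coverage < 0.5 is
  truncated.
* **Presence calls:** present requires a passing hit and an intact locus
  where locus sequence exists; a locus with disrupting features is a
  pseudogene regardless of expression (pseudogenes are often still
  transcribed, so RNA-seq support never overrides sequence-level features);
  absent otherwise. All-channels-unevaluated is an error, never a silent
  absent.
* **Synteny:** windows of ± flank_bp (default 60,000; profile 50,000–70,000)
  around the anchor midpoint; an absent anchor is located as the midpoint
  between two flanking orthogroup labels. Pairwise conservation is the
  strand-aware longest common subsequence of orthogroup-label sequences,
  allowing whole-block reversal, normalized by the shorter block; a
  neighborhood is "conserved" at mean score ≥ 0.5. Repeat-interval overlap
  with the window is reported so that an empty result documents "no
  transposon signature".
* **Dollo placement:** one ancestral gain, irreversible losses. The unique
  minimal loss set is the set of maximal all-lost clades, computed in one
  postorder pass; pseudogene counts as functional loss (raw calls are kept so
  users can rerun with pseudogene = functional). Equivalence with brute-force
  minimal-set search is tested exhaustively on all 256 patterns of an 8-leaf
  ladder.
* Coordinates are 1-based inclusive throughout; window midpoints round down.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (configuration, seed). Defaults define the
study conditions used by the tests and the acceptance script:

* toolkit scenario — 100 background proteins, 8 planted toolkit genes
  (5 SET-domain methyltransferases, 3 GNAT acetyltransferases), 10% decoys
  carrying near-miss accessions, 20% of genes with two isoforms;
* gene families — duplication/loss as Poisson(rate × branch length) down an
  8-species ladder mirroring the *Pristionchus* phylogeny;
* histone regions — quartets of 312-nt single-CDS genes at 2-kb spacing,
  stem-loop planted 12 nt after the stop (strand-aware), variants 20%
  diverged and placed far outside clusters (their downstream windows are
  scrubbed of chance motif matches so the planted truth is exact);
* loss scenarios — a 13-gene conserved neighborhood per species; hit-band
  e-values log-uniform in [1e-120, 1e-40] and noise in [1e-8, 1e-1],
  bracketing the 1e-29 default threshold; pseudogenization plants 4 in-frame
  stops (the last species of a multi-species clade is truncated to 30%
  instead, mirroring a sister-pair stop/truncation split); every existing
  locus, pseudogenes included, gets nonzero expression.

Background protein sequences are i.i.d. uniform over 20 amino acids and
nucleotide backgrounds are uniform: the classifiers act on evidence channels
(domains, orthogroups, e-values, motifs), not on sequence realism. No codon
model, indel process, read-level noise, assembly gaps, or annotation error is
simulated. Passing recovery tests therefore demonstrates that the decision
rules implement their contracts exactly on clean signals; they do not
estimate error rates on real genomes, where annotation quality and divergence
dominate.

## Problem sizes

The test suite and acceptance script run at desk scale: exhaustive Fisher
agreement over all 2×2 tables with N ≤ 40 plus a 2,000-table seeded sample
in the acceptance script; 50 Monte Carlo agreement checks at 20,000
replicates; all 256 Dollo patterns on 8 leaves; 200 seeded loss scenarios per
mode; 4-repeat histone clusters. These sizes make every check exact or
tightly bounded while keeping the full suite under a couple of minutes.

## Known limitations

* The default taxonomy's one-accession-per-subfamily map is a usable default,
  not a curated classification.
* The quartet partitioner is greedy (left to right); pathological interleaved
  clusters could be partitioned differently by an exhaustive tiling.
* The stem-loop detector's consensus and threshold are configuration, not
  learned; organisms with diverged downstream elements need their own
  consensus.
* Synteny scoring uses orthogroup labels only; it does not penalize local
  inversions below the whole-block level.
* The tree-placement flag is a coarse triplet heuristic intended to queue
  candidates for manual review, not a reconciliation method.
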