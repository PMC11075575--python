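"""Threshold choice, pseudogene screening, presence calls, synteny, Dollo
placement, FPKM, and repeat overlap."""

import itertools

import numpy as np
import pytest

from epitoolkit.io_formats import GeneModel, SequenceRecord, read_newick
from epitoolkit.loss import (
    LossConfig,
    call_presence,
    compute_fpkm,
    detect_pseudogene_features,
    detect_repeat_overlap,
    extract_synteny_window,
    pick_evalue_threshold,
    place_loss_dollo,
    synteny_conservation,
)


class TestEvalueThreshold:
    def test_bimodal_set_threshold_in_gap(self):
        from epitoolkit.simulate import synthesize_evalue_set

        values, interval = synthesize_evalue_set(40, 40, mode_gap_log10=20, seed=5)
        thr, diag = pick_evalue_threshold(values)
        assert interval[0] <= thr <= interval[1]
        assert "warning" not in diag

    def test_smooth_ladder_falls_back_to_default(self):
        values = [10.0 ** (-x) for x in np.linspace(1, 120, 100)]
        thr, diag = pick_evalue_threshold(values, default=1e-29)
        assert thr == 1e-29
        assert "warning" in diag

    def test_zero_evalues_floored(self):
        values = [0.0, 0.0, 1e-300, 1e-3, 1e-2, 1e-1]
        thr, diag = pick_evalue_threshold(values)
        assert np.isfinite(diag["sorted_neg_log10"]).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            pick_evalue_threshold([1e-5] * 4)

    def test_default_config_thresholds(self):
        cfg = LossConfig()
        assert cfg.evalue_protein_tx == 1e-29
        assert cfg.evalue_genome == 1e-5
        assert cfg.evalue_relaxed == 1e-1
        with pytest.raises(ValueError):
            LossConfig(evalue_protein_tx=1e-2, evalue_genome=1e-5)
        with pytest.raises(ValueError):
            LossConfig(flank_bp=10_000)


class TestPseudogeneFeatures:
    ref = "MKVADQRLTEWSGHNPYFICEKMKVADQRLTEWSGHNPYFICEK" * 3  # 132 aa

    def _cds(self, aa):
        from epitoolkit.simulate import _CODON_OF

        return "".join(_CODON_OF[a] for a in aa) + "TAA"

    def test_clean_cds_intact(self):
        f = detect_pseudogene_features(self._cds(self.ref), self.ref)
        assert f.classification == "intact"
        assert f.internal_stops == 0
        assert f.length_fraction == pytest.approx(1.0, abs=0.02)

    def test_planted_stops_counted(self):
        cds = self._cds(self.ref)
        codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        for i in (20, 45, 70, 100):
            codons[i] = "TAA"
        f = detect_pseudogene_features("".join(codons) + "TAA", self.ref)
        assert f.classification == "stop_disrupted"
        assert f.internal_stops == 4

    def test_truncation_detected(self):
        keep = int(len(self.ref) * 0.3)
        f = detect_pseudogene_features(self._cds(self.ref[:keep]), self.ref)
        assert f.classification == "truncated"
        assert f.length_fraction == pytest.approx(0.3, abs=0.05)

    def test_reverse_strand_frame_found(self):
        from epitoolkit.histones import revcomp

        f = detect_pseudogene_features(revcomp(self._cds(self.ref)), self.ref)
        assert f.classification == "intact"
        assert f.frame < 0

    def test_short_locus_rejected(self):
        with pytest.raises(ValueError, match="30"):
            detect_pseudogene_features("ATGAAA", self.ref)


class TestPresenceCalls:
    def test_strong_hit_intact_locus_present(self):
        call = call_presence("sp", {"blastp": 1e-60, "orthofinder": True})
        assert call.verdict == "present"
        assert call.evidence["blastp"] == "hit"
        assert call.evidence["rnaseq_locus"] == "not_evaluated"

    def test_no_hits_anywhere_absent(self):
        call = call_presence(
            "sp",
            {"blastp": 1e-2, "orthofinder": False, "tblastn_tx": 1e-1,
             "tblastn_genome": 1e-1, "rnaseq_locus": False},
        )
        assert call.verdict == "absent"

    def test_disrupted_locus_pseudogene_despite_expression(self):
        from epitoolkit.loss import PseudogeneFeatures

        features = PseudogeneFeatures(4, 0.9, "stop_disrupted")
        call = call_presence(
            "sp", {"tblastn_genome": 1e-20, "rnaseq_locus": True},
            locus_features=features,
        )
        assert call.verdict == "pseudogene"

    def test_channel_specific_thresholds(self):
        # 1e-10 passes the genome threshold (1e-5... no: fails) but not protein
        call = call_presence("sp", {"blastp": 1e-10, "tblastn_genome": 1e-10})
        assert call.evidence["blastp"] == "no_hit"       # > 1e-29
        assert call.evidence["tblastn_genome"] == "hit"  # <= 1e-5

    def test_all_not_evaluated_rejected(self):
        with pytest.raises(ValueError, match="not_evaluated"):
            call_presence("sp", {})

    def test_verdict_monotone_in_threshold(self):
        # more stringent threshold can flip present -> absent, never back
        ev = {"blastp": 1e-20}
        lax = call_presence("sp", ev, LossConfig(evalue_protein_tx=1e-10))
        strict = call_presence("sp", ev, LossConfig(evalue_protein_tx=1e-30))
        assert lax.verdict == "present" and strict.verdict == "absent"


class TestSyntenyWindow:
    def _genes(self, positions, chrom="c1"):
        return [
            GeneModel(f"g{i}", chrom, p, p + 999, "+", [(p, p + 999)])
            for i, p in enumerate(positions)
        ]

    def test_window_gene_count_arithmetic(self):
        # anchor mid ~100.5 kb, flank 60 kb, genes every 10 kb -> 13 genes inside
        genes = self._genes([100_000 + 10_000 * i for i in range(-9, 10)])
        og_of = {g.gene_id: f"OG{i}" for i, g in enumerate(genes)}
        anchor = genes[9].gene_id
        block = extract_synteny_window(
            genes, og_of, "sp", anchor_gene=anchor, cfg=LossConfig(flank_bp=60_000)
        )
        assert len(block.genes) == 13

    def test_anchor_located_via_neighbor_orthogroups(self):
        genes = self._genes([200_000, 210_000, 230_000, 240_000])
        og_of = {"g0": "L", "g1": "A", "g2": "B", "g3": "R"}
        block = extract_synteny_window(
            genes, og_of, "sp", neighbor_ogs=("A", "B"), cfg=LossConfig(flank_bp=60_000)
        )
        assert block.anchor_pos == (210_499 + 230_499) // 2
        assert len(block.genes) == 4

    def test_clipped_window_warns(self):
        genes = self._genes([5_000, 15_000])
        og_of = {"g0": "A", "g1": "B"}
        with pytest.warns(UserWarning, match="clipped"):
            block = extract_synteny_window(genes, og_of, "sp", anchor_gene="g0")
        assert block.truncated

    def test_unlocatable_anchor_rejected(self):
        genes = self._genes([5_000])
        with pytest.raises(ValueError, match="anchor"):
            extract_synteny_window(genes, {}, "sp", anchor_gene="nope")


class TestSyntenyConservation:
    def _block(self, sp, labels, start=1000):
        genes = []
        pos = start
        for i, (og, strand) in enumerate(labels):
            genes.append((f"{sp}_g{i}", og, pos, pos + 999, strand))
            pos += 5000
        from epitoolkit.loss import SyntenyBlock

        return SyntenyBlock(sp, genes, anchor_og="F", anchor_pos=start)

    def test_identical_blocks_score_one(self):
        labels = [("A", "+"), ("F", "+"), ("B", "-")]
        out = synteny_conservation([self._block("s1", labels), self._block("s2", labels)], "F")
        assert list(out["pairwise_scores"].values()) == [1.0]

    def test_whole_block_reversal_scores_one(self):
        labels = [("A", "+"), ("F", "+"), ("B", "-")]
        flipped = [("B", "+"), ("F", "-"), ("A", "-")]
        out = synteny_conservation([self._block("s1", labels), self._block("s2", flipped)], "F")
        assert list(out["pairwise_scores"].values()) == [1.0]

    def test_no_shared_labels_scores_zero_with_warning(self):
        b1 = self._block("s1", [("A", "+"), ("B", "+")])
        b2 = self._block("s2", [("X", "+"), ("Y", "+")])
        with pytest.warns(UserWarning, match="shared"):
            out = synteny_conservation([b1, b2], "F")
        assert list(out["pairwise_scores"].values()) == [0.0]

    def test_missing_focal_with_conserved_flanks(self):
        full = [("A", "+"), ("F", "+"), ("B", "-"), ("C", "+")]
        without = [("A", "+"), ("B", "-"), ("C", "+")]
        out = synteny_conservation(
            [self._block("s1", full), self._block("s2", without)], "F"
        )
        assert out["focal_status"]["s2"]["focal"] == "missing"
        assert out["focal_status"]["s2"]["flanks_conserved"]


def _bruteforce_dollo(tree, lost, leaves):
    """Minimal set of clade leafsets unioning exactly to the lost set."""
    clades = []
    for n in tree.preorder_node_iter():
        clades.append(frozenset(lf.taxon.label for lf in n.leaf_iter()))
    best = None
    for r in range(0, len(clades) + 1):
        for combo in itertools.combinations(clades, r):
            union = frozenset().union(*combo) if combo else frozenset()
            if union == lost:
                best = set(combo)
                break
        if best is not None:
            break
    return best


class TestDollo:
    def test_paper_shaped_pattern_single_stem_loss(self):
        tree = read_newick(
            "(((((((pacificus,exspectatus),arcanus),maxplancki),japonicus),"
            "mayeri),entomophagus),fissidentatus);"
        )
        verdicts = {
            lf.taxon.label: "lost" if lf.taxon.label in
            {"pacificus", "exspectatus", "arcanus"} else "functional"
            for lf in tree.leaf_node_iter()
        }
        branches = place_loss_dollo(verdicts, tree)
        assert branches == [frozenset({"pacificus", "exspectatus", "arcanus"})]

    def test_no_losses_empty_set(self, ladder8):
        verdicts = {l: "functional" for l in "ABCDEFGH"}
        assert place_loss_dollo(verdicts, ladder8) == []

    def test_all_patterns_match_bruteforce_on_ladder(self, ladder8):
        leaves = list("ABCDEFGH")
        for bits in range(256):
            lost = frozenset(l for i, l in enumerate(leaves) if bits >> i & 1)
            verdicts = {l: "lost" if l in lost else "functional" for l in leaves}
            got = set(place_loss_dollo(verdicts, ladder8))
            expected = _bruteforce_dollo(ladder8, lost, leaves)
            assert got == expected, f"pattern {sorted(lost)}"

    def test_missing_verdict_rejected(self, ladder8):
        with pytest.raises(ValueError, match="verdict"):
            place_loss_dollo({"A": "lost"}, ladder8)


class TestFpkmAndRepeats:
    def test_printed_formula_hand_value(self):
        assert compute_fpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_reads_zero_fpkm(self):
        assert compute_fpkm(0, 1000, 1_000_000) == 0.0

    def test_doubling_library_halves_fpkm(self):
        assert compute_fpkm(7, 800, 2_000_000) == pytest.approx(
            compute_fpkm(7, 800, 1_000_000) / 2
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_fpkm(1, 0, 100)
        with pytest.raises(ValueError):
            compute_fpkm(1, 100, 0)

    def test_repeat_overlap_boundaries(self):
        window = ("c1", 1000, 2000)
        inside = ("c1", 1200, 1300, "rep1")
        abutting = ("c1", 900, 999, "rep2")          # end = window start - 1
        other_chrom = ("c2", 1200, 1300, "rep3")
        assert detect_repeat_overlap(window, [inside, abutting, other_chrom]) == [inside]

    def test_repeat_overlap_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        repeats = [
            ("c1", int(s), int(s + rng.integers(10, 500)), f"r{i}")
            for i, s in enumerate(rng.integers(1, 50_000, size=200))
        ]
        for _ in range(20):
            lo = int(rng.integers(1, 49_000))
            hi = lo + int(rng.integers(100, 5_000))
            got = detect_repeat_overlap(("c1", lo, hi), repeats)
            expected = [r for r in repeats if r[1] <= hi and r[2] >= lo]
            assert sorted(got) == sorted(expected)
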