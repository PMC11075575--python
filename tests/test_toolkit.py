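"""Evidence selection, QC rules, gene collapse, family assignment, counts."""

import numpy as np
import pytest

from epitoolkit.datasets import load_default_taxonomy
from epitoolkit.io_formats import DomainAnnotation, Orthogroup, read_newick
from epitoolkit.toolkit import (
    CandidateProtein,
    GeneInventoryRecord,
    QCConfig,
    ReferenceSets,
    assign_family,
    collapse_to_genes,
    find_outlier_domains,
    flag_tree_placement,
    qc_filter,
    select_by_domain,
    select_by_orthology,
    tabulate_counts,
)


def _dom(pid, acc, ev=1e-20, start=1, end=100):
    return DomainAnnotation(pid, acc, start, end, ev)


@pytest.fixture
def refs():
    return ReferenceSets(
        epi_domains={"PF00856", "PF00583", "PF00069"},
        epi_proteins={"human": {"EZH2", "GCN5", "AURKB"}},
        epi_specific_domains={"PF00856", "PF00583", "PF00069"},
    )


class TestSelection:
    def test_select_by_domain(self, refs):
        doms = [_dom("p1", "PF00856"), _dom("p2", "PF99999")]
        assert select_by_domain(doms, refs) == {"p1"}

    def test_empty_reference_domains_rejected(self):
        refs = ReferenceSets(set(), {"human": {"EZH2"}}, set())
        with pytest.raises(ValueError, match="empty"):
            select_by_domain([_dom("p1", "PF00856")], refs)

    def test_select_by_orthology(self, refs):
        ogs = [
            Orthogroup("OG1", {"human": ["EZH2"], "target": ["pX"]}),
            Orthogroup("OG2", {"human": ["OTHER"], "target": ["pY"]}),
        ]
        assert select_by_orthology(ogs, refs, "target") == {"pX": "OG1"}

    def test_missing_species_rejected(self, refs):
        ogs = [Orthogroup("OG1", {"human": ["EZH2"]})]
        with pytest.raises(ValueError, match="absent"):
            select_by_orthology(ogs, refs, "target")

    def test_planted_families_selected_via_reference_seeds(self):
        from epitoolkit.simulate import simulate_gene_families

        sc = simulate_gene_families(birth_rate=0.2, loss_rate=0.1, n_families=10,
                                    seed=4, n_reference_families=5)
        refs = ReferenceSets({"PF00856"}, {sc.model_species: sc.reference_proteins})
        target = sorted(sc.orthogroups[0].members)[-1]
        selected = select_by_orthology(sc.orthogroups, refs, target)
        expected = {
            pid: og.og_id
            for og in sc.orthogroups
            if sc.reference_proteins & og.all_members()
            for pid in og.members.get(target, [])
        }
        assert selected == expected


class TestOutlierDomains:
    def test_unique_domain_is_outlier(self):
        og = Orthogroup("OG", {"s1": ["a"], "s2": ["b", "c"]})
        doms = {"a": [_dom("a", "A"), _dom("a", "B")],
                "b": [_dom("b", "A")], "c": [_dom("c", "A")]}
        assert find_outlier_domains(og, doms, "a") == {"B"}

    def test_shared_domains_no_outlier(self):
        og = Orthogroup("OG", {"s1": ["a"], "s2": ["b"]})
        doms = {"a": [_dom("a", "A")], "b": [_dom("b", "A")]}
        assert find_outlier_domains(og, doms, "a") == set()

    def test_focal_not_member_rejected(self):
        og = Orthogroup("OG", {"s1": ["a"]})
        with pytest.raises(ValueError, match="member"):
            find_outlier_domains(og, {}, "zz")

    def test_matches_bruteforce_on_random_orthogroups(self):
        rng = np.random.default_rng(11)
        pool = [f"D{i}" for i in range(12)]
        for _ in range(100):
            n = int(rng.integers(2, 21))
            members = [f"p{i}" for i in range(n)]
            og = Orthogroup("OG", {"s": members})
            doms = {
                m: [_dom(m, a) for a in rng.choice(pool, size=rng.integers(0, 5), replace=False)]
                for m in members
            }
            focal = members[int(rng.integers(n))]
            got = find_outlier_domains(og, doms, focal)
            # brute force: set difference against the union over the others
            union_others = set()
            for m in members:
                if m != focal:
                    union_others |= {d.domain_acc for d in doms[m]}
            expected = {d.domain_acc for d in doms[focal]} - union_others
            assert got == expected


class TestTreePlacement:
    sp_tree = read_newick("(((human,mouse),target),(yeast,pombe));")
    species_of = {"h1": "human", "m1": "mouse", "t1": "target",
                  "y1": "yeast", "p1": "pombe"}

    def _og(self, newick):
        return Orthogroup(
            "OG",
            {"human": ["h1"], "mouse": ["m1"], "target": ["t1"],
             "yeast": ["y1"], "pombe": ["p1"]},
            read_newick(newick),
        )

    def test_congruent_tree_not_flagged(self):
        flag = flag_tree_placement(
            self._og("((h1,(m1,t1)),(y1,p1));"), "t1", self.sp_tree, self.species_of
        )
        assert flag.status == "ok"

    def test_target_inside_fungal_clade_flagged(self):
        flag = flag_tree_placement(
            self._og("((h1,m1),(y1,(p1,t1)));"), "t1", self.sp_tree, self.species_of
        )
        assert flag.status == "flagged"
        assert flag.triplet is not None and flag.species_resolution is not None

    def test_missing_tree_is_not_evaluable(self):
        og = Orthogroup("OG", {"target": ["t1"], "human": ["h1"]})
        flag = flag_tree_placement(og, "t1", self.sp_tree, self.species_of)
        assert flag.status == "not_evaluable"


class TestQCFilter:
    def _og_with_tree(self, members, newick):
        return Orthogroup("OG", members, read_newick(newick))

    def test_outlier_with_epi_specific_domain_retained(self, refs):
        og = Orthogroup("OG", {"target": ["p1"], "human": ["EZH2"]})
        cand = CandidateProtein("p1", "g1", "target", {"orthology"}, "OG")
        doms = {"p1": [_dom("p1", "PF00856"), _dom("p1", "PFX")], "EZH2": []}
        retained, discards = qc_filter([cand], doms, {"OG": og}, refs,
                                       target_species="target")
        assert [c.protein_id for c in retained] == ["p1"]

    def test_zero_domain_with_reference_sister_retained(self, refs):
        og = self._og_with_tree(
            {"target": ["p1"], "human": ["EZH2"]}, "('EZH2':1,'p1':0.2);"
        )
        cand = CandidateProtein("p1", "g1", "target", {"orthology"}, "OG")
        retained, discards = qc_filter([cand], {}, {"OG": og}, refs,
                                       target_species="target")
        assert [c.protein_id for c in retained] == ["p1"]

    def test_zero_domain_in_reference_free_subtree_discarded(self, refs):
        og = self._og_with_tree(
            {"target": ["p1"], "other": ["q1", "q2"]},
            "(('q1':0.1,'p1':0.1):1,'q2':1);",
        )
        cand = CandidateProtein("p1", "g1", "target", {"orthology"}, "OG")
        retained, discards = qc_filter([cand], {}, {"OG": og}, refs,
                                       target_species="target")
        assert retained == []
        assert discards[0].discard_reason == "no_domains_no_epi_ortholog"

    def test_outlier_without_exemptions_discarded(self, refs):
        og = self._og_with_tree(
            {"target": ["p1"], "other": ["q1", "q2"]},
            "(('q1':0.1,'p1':0.1):1,'q2':1);",
        )
        cand = CandidateProtein("p1", "g1", "target", {"orthology"}, "OG")
        doms = {"p1": [_dom("p1", "PFWEIRD")], "q1": [_dom("q1", "PFA")],
                "q2": [_dom("q2", "PFA")]}
        retained, discards = qc_filter([cand], doms, {"OG": og}, refs,
                                       target_species="target")
        assert discards and discards[0].discard_reason == "outlier_domain_no_epi_function"

    def test_predicted_function_annotation_exempts(self, refs):
        og = self._og_with_tree(
            {"target": ["p1"], "other": ["q1", "q2"]},
            "(('q1':0.1,'p1':0.1):1,'q2':1);",
        )
        cand = CandidateProtein("p1", "g1", "target", {"orthology"}, "OG")
        doms = {"p1": [_dom("p1", "PFWEIRD")]}
        retained, _ = qc_filter(
            [cand], doms, {"OG": og}, refs,
            config=QCConfig(predicted_epi_function={"p1"}), target_species="target",
        )
        assert [c.protein_id for c in retained] == ["p1"]

    def test_kinase_requires_adjacent_reference(self, refs):
        # kinase domain, tree sister is the reference histone kinase -> kept
        og1 = self._og_with_tree(
            {"target": ["p1"], "human": ["AURKB"]}, "('AURKB':0.2,'p1':0.2);"
        )
        cand1 = CandidateProtein("p1", "g1", "target", {"orthology"}, "OG")
        doms = {"p1": [_dom("p1", "PF00069")]}
        retained, _ = qc_filter([cand1], doms, {"OG": og1}, refs,
                                target_species="target")
        assert [c.protein_id for c in retained] == ["p1"]
        # same domain, no reference nearby -> discarded with the kinase reason
        og2 = self._og_with_tree(
            {"target": ["p2"], "other": ["q1", "q2"]},
            "(('q1':0.1,'p2':0.1):1,'q2':1);",
        )
        cand2 = CandidateProtein("p2", "g2", "target", {"orthology"}, "OG")
        doms2 = {"p2": [_dom("p2", "PF00069")]}
        _, discards = qc_filter([cand2], doms2, {"OG": og2}, refs,
                                target_species="target")
        assert discards[0].discard_reason == "kinase_no_adjacent_reference"

    def test_adding_epi_specific_domain_never_causes_discard(self, refs):
        # monotonicity in the direction the QC rules guarantee
        og = self._og_with_tree(
            {"target": ["p1"], "other": ["q1", "q2"]},
            "(('q1':0.1,'p1':0.1):1,'q2':1);",
        )
        cand = CandidateProtein("p1", "g1", "target", {"orthology"}, "OG")
        base = {"p1": [_dom("p1", "PFA")], "q1": [_dom("q1", "PFA")],
                "q2": [_dom("q2", "PFA")]}
        retained0, _ = qc_filter([cand], base, {"OG": og}, refs,
                                 target_species="target")
        assert retained0
        richer = {**base, "p1": base["p1"] + [_dom("p1", "PF00856")]}
        retained1, _ = qc_filter([cand], richer, {"OG": og}, refs,
                                 target_species="target")
        assert [c.protein_id for c in retained1] == [c.protein_id for c in retained0]


class TestCollapseAndAssign:
    def test_isoform_evidence_unioned(self):
        cands = [
            CandidateProtein("g1.p1", "g1", "t", {"domain"}),
            CandidateProtein("g1.p2", "g1", "t", {"orthology"}, "OG1"),
        ]
        (rec,) = collapse_to_genes(cands, {"g1.p1": "g1", "g1.p2": "g1"})
        assert rec.evidence == {"domain", "orthology"}
        assert rec.og_ids == {"OG1"}

    def test_identical_proteins_stay_distinct_genes(self):
        cands = [
            CandidateProtein("a.p", "a", "t", {"domain"}),
            CandidateProtein("b.p", "b", "t", {"domain"}),
        ]
        seqs = {"a.p": "MKV", "b.p": "MKV"}
        recs = collapse_to_genes(cands, {"a.p": "a", "b.p": "b"}, seqs)
        assert len(recs) == 2
        assert all(r.sequence_duplicate for r in recs)

    def test_unmapped_protein_rejected(self):
        cands = [CandidateProtein("x.p", "x", "t", {"domain"})]
        with pytest.raises(ValueError, match="x.p"):
            collapse_to_genes(cands, {})

    def test_generator_gene_counts_recovered(self):
        from epitoolkit.simulate import plant_epigenetic_toolkit

        sc = plant_epigenetic_toolkit(n_background=30, seed=21, isoform_fraction=0.5)
        cands = [
            CandidateProtein(pid, sc.gene_map[pid], "target", {"domain"})
            for pid in sc.gene_map
            if pid.startswith("tg")
        ]
        recs = collapse_to_genes(cands, sc.gene_map)
        assert {r.gene_id for r in recs} == sc.truth["planted_toolkit_genes"]

    def test_assign_family_domain_precedence_and_fallback(self):
        taxonomy = load_default_taxonomy()
        taxonomy["reference_map"] = {"AGO_ref": {"family": "NCRNA", "subfamily": "Argonautes"}}
        rec = GeneInventoryRecord("g1", "t", ["g1.p1"], {"domain"}, set())
        doms = {"g1.p1": [_dom("g1.p1", "PF00856", 1e-40)]}
        a = assign_family(rec, doms, taxonomy)
        assert (a.family, a.subfamily) == ("HMT", "SET")

        rec2 = GeneInventoryRecord("g2", "t", ["g2.p1"], {"orthology"}, {"OG9"})
        a2 = assign_family(rec2, {}, taxonomy, {"OG9": ["AGO_ref"]})
        assert (a2.family, a2.subfamily) == ("NCRNA", "Argonautes")

        rec3 = GeneInventoryRecord("g3", "t", ["g3.p1"], {"orthology"}, {"OGX"})
        a3 = assign_family(rec3, {}, taxonomy, {})
        assert (a3.family, a3.subfamily) == ("OTHER", "Misc.")

    def test_assign_family_tie_broken_by_lowest_evalue(self):
        taxonomy = load_default_taxonomy()
        rec = GeneInventoryRecord("g1", "t", ["p"], {"domain"}, set())
        doms = {"p": [_dom("p", "PF00385", 1e-10), _dom("p", "PF00176", 1e-30)]}
        a = assign_family(rec, doms, taxonomy)
        assert a.subfamily == "SWI/SNF"       # PF00176 has the lower e-value


class TestTabulate:
    def test_published_totals(self, table1):
        out = tabulate_counts(table1)
        assert out["grand_totals"] == {"P_pacificus": 291, "C_elegans": 265}
        assert int(out["family_totals"].loc["HISTONE", "P_pacificus"]) == 61
        assert int(out["family_totals"].loc["HISTONE", "C_elegans"]) == 85

    def test_empty_inventory_all_zero(self):
        out = tabulate_counts({"sp": []})
        assert out["grand_totals"] == {}
        assert len(out["counts"]) == 0

    def test_generator_truth_counts(self):
        from epitoolkit.pipeline import run_toolkit_inventory
        from epitoolkit.simulate import plant_epigenetic_toolkit

        sc = plant_epigenetic_toolkit(
            n_background=40, family_spec={"HMT/SET": 4, "NCRNA/Argonautes": 2}, seed=8
        )
        res = run_toolkit_inventory(
            sc.domains, sc.orthogroups, sc.refs, sc.gene_map, sc.species, sc.taxonomy
        )
        counts = res["counts"]["counts"].set_index("subfamily")["target"]
        assert counts.to_dict() == {"SET": 4, "Argonautes": 2}
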