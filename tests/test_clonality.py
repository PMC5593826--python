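"""Trunk/branch/private classification, tree reconstruction, verdicts."""

import numpy as np
import pandas as pd
import pytest

from mtlineage.clonality import (
    ClonalityError,
    build_clonal_tree,
    classify_trunk_branch_private,
    clonal_verdict,
    to_newick,
    venn_summary,
)
from mtlineage.simulate import SimConfig, patient_05_like, simulate_patient


def call_row(lesion, position, vaf, ref="A", alt="G", plasmy="heteroplasmic",
             known=False, patient="P1"):
    return dict(patient=patient, lesion=lesion, position=position, ref=ref, alt=alt,
                var_type="SNV", label=f"{ref}{position}{alt}", vaf=vaf, depth=1000,
                fwd_alt=int(500 * vaf), rev_alt=int(500 * vaf), strand_balance=0.5,
                plasmy=plasmy, known_polymorphism=known, flags="")


def truth_as_calls(truth, known_positions=()):
    """Present simulator truth rows as PASS calls."""
    df = truth.rename(columns={"true_vaf": "vaf"}).copy()
    df["plasmy"] = np.where(df["vaf"] >= 0.95, "homoplasmic", "heteroplasmic")
    df["known_polymorphism"] = df["origin"].eq("germline") | df["position"].isin(known_positions)
    df["flags"] = ""
    return df


class TestClassification:
    def test_variant_in_all_lesions_is_trunk(self):
        rows = [call_row(f"TN{i}", 650, 0.4) for i in range(1, 5)]
        a = classify_trunk_branch_private(pd.DataFrame(rows), [f"TN{i}" for i in range(1, 5)])
        assert a.somatic["category"].tolist() == ["trunk"]

    def test_subset_is_branch_like_case_06(self):
        # a T650C-style variant carried by lesions 3 and 4 of four
        rows = [call_row("TN3", 650, 0.3, ref="T", alt="C"),
                call_row("TN4", 650, 0.35, ref="T", alt="C")]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2", "TN3", "TN4"])
        assert a.somatic["category"].tolist() == ["branch"]
        assert a.somatic["carriers"].iloc[0] == frozenset({"TN3", "TN4"})

    def test_single_lesion_variant_is_private_like_case_03(self):
        rows = [call_row("TN1", 66, 0.2, ref="G", alt="")]
        rows[0]["var_type"] = "deletion"
        rows[0]["label"] = "66 del-G"
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        assert a.somatic["category"].tolist() == ["private"]

    def test_presence_threshold_governs_carriers(self):
        rows = [call_row("TN1", 650, 0.4), call_row("TN2", 650, 0.03)]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        assert a.somatic["category"].tolist() == ["private"]

    def test_known_homoplasmic_everywhere_is_polymorphism(self):
        rows = [call_row(l, 263, 0.99, plasmy="homoplasmic", known=True)
                for l in ("TN1", "TN2")]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        assert len(a.somatic) == 0
        assert len(a.polymorphisms) == 1

    def test_single_lesion_patient_rejected(self):
        with pytest.raises(ClonalityError, match="one lesion"):
            classify_trunk_branch_private(pd.DataFrame([call_row("TN1", 650, 0.4)]), ["TN1"])

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property(self, reference, default_panel, seed):
        """|trunk| + |branch| + |private| == number of somatic variants."""
        cfg = SimConfig(n_germline=3, n_trunk=2, n_branch=2, n_private=3,
                        deamination_rate=0.0, seed=seed)
        rng = np.random.default_rng(seed)
        _, truth = simulate_patient(cfg, default_panel, reference, "P1", rng,
                                    n_lesions=int(rng.integers(2, 6)))
        calls = truth_as_calls(truth)
        lesions = sorted(truth["lesion"].unique())
        a = classify_trunk_branch_private(calls, lesions)
        counts = a.category_counts()
        n_somatic = truth[truth["origin"] != "germline"]["label"].nunique()
        assert sum(counts.values()) == len(a.somatic) == n_somatic


class TestTree:
    def test_05_like_subclone_reconstruction(self, reference):
        tree_true, truth = patient_05_like(reference)
        a = classify_trunk_branch_private(truth_as_calls(truth), ["TN1", "TN2", "TN3"])
        tree, conflicts = build_clonal_tree(a)
        assert conflicts == []
        # TN2 and TN3 are sister subclones under a shared internal node
        assert tree.clade(tree.parent["TN2"]) == frozenset({"TN2", "TN3"})
        assert tree.parent["TN2"] == tree.parent["TN3"]
        assert tree.parent[tree.parent["TN2"]] == tree.root
        assert tree.clades() == tree_true.clades()

    def test_non_laminar_sets_reported_as_conflict(self):
        rows = [call_row("TN1", 100, 0.3), call_row("TN2", 100, 0.3),
                call_row("TN2", 200, 0.3), call_row("TN3", 200, 0.3)]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2", "TN3"])
        tree, conflicts = build_clonal_tree(a)
        assert len(conflicts) == 1
        assert {frozenset({"TN1", "TN2"}), frozenset({"TN2", "TN3"})} == set(conflicts[0])
        kept = tree.clades()
        assert len(kept & set(conflicts[0])) == 1  # exactly one of the pair kept

    def test_private_only_star_tree(self):
        rows = [call_row("TN1", 100, 0.3), call_row("TN2", 200, 0.3),
                call_row("TN3", 300, 0.3)]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2", "TN3"])
        tree, conflicts = build_clonal_tree(a)
        assert conflicts == []
        assert all(tree.parent[l] == tree.root for l in ("TN1", "TN2", "TN3"))

    def test_no_somatic_variants_no_tree(self):
        rows = [call_row(l, 263, 0.99, plasmy="homoplasmic", known=True)
                for l in ("TN1", "TN2")]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        tree, conflicts = build_clonal_tree(a)
        assert tree is None and conflicts == []

    @pytest.mark.parametrize("seed", range(50))
    def test_topology_recovery_on_noise_free_simulations(self, reference, default_panel, seed):
        """With >=2 variants per edge and no noise, the reconstructed clades
        equal the simulated ones exactly."""
        rng = np.random.default_rng(seed)
        n_lesions = int(rng.integers(3, 6))
        cfg = SimConfig(n_germline=2, n_trunk=2, n_branch=4, n_private=2 * n_lesions,
                        deamination_rate=0.0, sequencing_error_rate=0.0,
                        somatic_homoplasmic_fraction=0.0, seed=seed)
        tree_true, truth = simulate_patient(cfg, default_panel, reference, "P1", rng,
                                            n_lesions=n_lesions)
        # every leaf edge needs >= 1 variant for its clade to be observable;
        # n_private = 2 * n_lesions round-robins 2 per leaf
        a = classify_trunk_branch_private(truth_as_calls(truth),
                                          sorted(truth["lesion"].unique()))
        tree, conflicts = build_clonal_tree(a)
        assert conflicts == []
        assert tree.clades() == tree_true.clades()

    def test_newick_is_parseable_with_lesion_leaves(self, reference):
        import dendropy

        _, truth = patient_05_like(reference)
        a = classify_trunk_branch_private(truth_as_calls(truth), ["TN1", "TN2", "TN3"])
        tree, _ = build_clonal_tree(a)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = {l.taxon.label for l in parsed.leaf_node_iter()}
        assert leaves == {"TN1", "TN2", "TN3"}


class TestVerdict:
    def test_only_homoplasmic_polymorphisms_untrackable(self):
        rows = [call_row(l, p, 0.99, plasmy="homoplasmic", known=True)
                for l in ("TN1", "TN2") for p in (263, 750, 1438)]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        v = clonal_verdict(a)
        assert v.verdict == "untrackable"
        assert v.n_polymorphisms == 3

    def test_trunk_variant_proves_monoclonal(self):
        rows = [call_row("TN1", 650, 0.4), call_row("TN2", 650, 0.5)]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        assert clonal_verdict(a).verdict == "monoclonal"

    def test_disjoint_somatic_sets_independent(self):
        rows = [call_row("TN1", 100, 0.3), call_row("TN1", 150, 0.4),
                call_row("TN2", 200, 0.3)]
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        assert clonal_verdict(a).verdict == "independent"

    def test_adding_trunk_variant_keeps_monoclonal(self):
        """Monotonicity: extra trunk evidence never demotes the verdict."""
        rows = [call_row("TN1", 100, 0.3), call_row("TN2", 200, 0.3)]
        base = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        assert clonal_verdict(base).verdict == "independent"
        more = rows + [call_row("TN1", 650, 0.4), call_row("TN2", 650, 0.5)]
        a = classify_trunk_branch_private(pd.DataFrame(more), ["TN1", "TN2"])
        assert clonal_verdict(a).verdict == "monoclonal"

    @pytest.mark.parametrize("seed", range(10))
    def test_single_tree_simulations_never_independent(self, reference, default_panel, seed):
        cfg = SimConfig(n_germline=2, n_trunk=1, n_branch=1, n_private=1,
                        deamination_rate=0.0, seed=seed)
        rng = np.random.default_rng(seed)
        _, truth = simulate_patient(cfg, default_panel, reference, "P1", rng,
                                    n_lesions=3)
        a = classify_trunk_branch_private(truth_as_calls(truth),
                                          sorted(truth["lesion"].unique()))
        assert clonal_verdict(a).verdict != "independent"

    def test_two_unrelated_clones_never_monoclonal(self, reference, default_panel):
        """Disjoint per-lesion variant sets (two clonal patches) stay independent."""
        for seed in range(5):
            cfg = SimConfig(n_germline=2, n_trunk=0, n_branch=0, n_private=4,
                            deamination_rate=0.0, seed=seed)
            rng = np.random.default_rng(seed)
            _, truth = simulate_patient(cfg, default_panel, reference, "P1", rng,
                                        n_lesions=2)
            a = classify_trunk_branch_private(truth_as_calls(truth),
                                              sorted(truth["lesion"].unique()))
            assert clonal_verdict(a).verdict == "independent"


class TestVenn:
    def test_shared_and_private_counts(self):
        rows = ([call_row(l, p, 0.4) for l in ("TN1", "TN2") for p in range(100, 105)]
                + [call_row("TN1", 500, 0.3), call_row("TN2", 600, 0.3)])
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        out = venn_summary(a).set_index("lesions")
        assert out.loc["TN1,TN2", "count"] == 5
        assert out.loc["TN1", "count"] == 1
        assert out.loc["TN2", "count"] == 1
        assert out["count"].sum() == 7

    def test_trunk_and_polymorphisms_in_full_intersection(self):
        rows = ([call_row(l, 263, 0.99, plasmy="homoplasmic", known=True)
                 for l in ("TN1", "TN2")]
                + [call_row(l, 650, 0.4) for l in ("TN1", "TN2")])
        a = classify_trunk_branch_private(pd.DataFrame(rows), ["TN1", "TN2"])
        out = venn_summary(a).set_index("lesions")
        assert out.loc["TN1,TN2", "count"] == 2

    def test_venn_counts_match_simulated_truth(self, reference, default_panel):
        cfg = SimConfig(n_germline=3, n_trunk=2, n_branch=1, n_private=2,
                        deamination_rate=0.0, seed=33)
        rng = np.random.default_rng(33)
        _, truth = simulate_patient(cfg, default_panel, reference, "P1", rng,
                                    n_lesions=3)
        a = classify_trunk_branch_private(truth_as_calls(truth), ["TN1", "TN2", "TN3"])
        out = venn_summary(a)
        expected = truth.groupby("label")["lesion"].apply(
            lambda s: ",".join(sorted(set(s)))).value_counts()
        got = dict(zip(out["lesions"], out["count"]))
        assert got == expected.to_dict()
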