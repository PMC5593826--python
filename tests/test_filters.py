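"""Cohort artifact heuristics: recurrence, amplicon ends, repeats, noise."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mtlineage.calling import assign_and_pileup, call_variants, calls_to_frame, classify_plasmy
from mtlineage.filters import (
    FilterError,
    amplicon_end_filter,
    apply_filters,
    cross_sample_filter,
    noise_filter,
    region_filter,
)
from mtlineage.panel import assign_pools, design_panel
from mtlineage.simulate import SimConfig, simulate_patient, simulate_reads


def make_row(patient, lesion, position, vaf, ref="A", alt="G", plasmy="heteroplasmic",
             known=False, flags=""):
    return dict(patient=patient, lesion=lesion, position=position, ref=ref, alt=alt,
                var_type="SNV", label=f"{ref}{position}{alt}", vaf=vaf, depth=1000,
                fwd_alt=int(500 * vaf), rev_alt=int(500 * vaf), strand_balance=0.5,
                plasmy=plasmy, known_polymorphism=known, flags=flags)


def frame(rows):
    return pd.DataFrame(rows)


class TestCrossSample:
    def test_recurrent_similar_vaf_flagged_in_all_carriers(self):
        df = frame([make_row(f"P{i}", "TN1", 500, v)
                    for i, v in enumerate([0.11, 0.12, 0.13, 0.115, 0.125])])
        out = cross_sample_filter(df)
        assert (out["flags"] == "recurrent_similar_vaf").all()

    def test_wide_vaf_spread_not_flagged(self):
        df = frame([make_row(f"P{i}", "TN1", 500, v)
                    for i, v in enumerate([0.10, 0.90, 0.10, 0.90, 0.50])])
        out = cross_sample_filter(df)
        assert (out["flags"] == "").all()

    def test_below_recurrence_floor_not_flagged(self):
        df = frame([make_row("P1", "TN1", 500, 0.11), make_row("P2", "TN1", 500, 0.12)])
        out = cross_sample_filter(df, min_patients=3)
        assert (out["flags"] == "").all()

    def test_known_homoplasmic_polymorphism_exempt(self):
        df = frame([make_row(f"P{i}", "TN1", 263, 0.99, plasmy="homoplasmic", known=True)
                    for i in range(5)])
        out = cross_sample_filter(df)
        assert (out["flags"] == "").all()

    def test_single_patient_is_warned_noop(self):
        df = frame([make_row("P1", "TN1", 500, 0.11), make_row("P1", "TN2", 500, 0.12)])
        with pytest.warns(UserWarning, match=">= 2 patients"):
            out = cross_sample_filter(df)
        assert (out["flags"] == "").all()


class TestAmpliconEnd:
    @pytest.fixture()
    def toy_panel(self, toy_reference):
        # 3 amplicons on a 300 bp circle, 10 bp overlaps
        return assign_pools(design_panel(toy_reference, 3, 110, 10), 3)

    def test_near_end_of_sole_covering_amplicon_flagged(self, toy_panel):
        # position 3 bp from amplicon 0's start boundary, once past the
        # wrap-around overlap with amplicon 2 (positions 1..10)
        amp0 = toy_panel.amplicons[0]
        covering_only_amp0 = [p for p in range(11, 101)]
        pos = covering_only_amp0[2]
        df = frame([make_row("P1", "TN1", pos, 0.2)])
        out = amplicon_end_filter(df, toy_panel)
        # within 5 of the boundary but interior to the single covering amplicon?
        dist = amp0.boundary_distance(pos, 300)
        assert ("amplicon_end" in out["flags"].iloc[0]) == (dist < 5)

    def test_overlap_zone_interior_exempt(self, toy_panel):
        # 105 is 6 bp into amplicon 1 (starts 101) and 6 bp from amplicon 0's
        # end (110): interior to neither margin
        df = frame([make_row("P1", "TN1", 106, 0.2)])
        out = amplicon_end_filter(df, toy_panel)
        assert out["flags"].iloc[0] == ""

    def test_mid_insert_not_flagged(self, toy_panel):
        df = frame([make_row("P1", "TN1", 55, 0.2)])
        out = amplicon_end_filter(df, toy_panel)
        assert out["flags"].iloc[0] == ""

    def test_position_near_both_boundaries_flagged(self, toy_panel):
        # 102 is 1 bp into amplicon 1 and 8 bp from amplicon 0's end... pick
        # 108: 2 bp from amp0's end (110) and 7 into amp1 -> exempt; 109: 1 bp
        # from amp0 end, 8 into amp1 -> exempt. True double-margin positions
        # need margin*2 > overlap; use margin 8.
        df = frame([make_row("P1", "TN1", 105, 0.2)])
        out = amplicon_end_filter(df, toy_panel, end_margin=8)
        assert out["flags"].iloc[0] == "amplicon_end"

    def test_off_panel_position_is_error(self, toy_reference):
        # linear-ish panel leaving a hole: design then drop one amplicon
        panel = assign_pools(design_panel(toy_reference, 3, 110, 10), 3)
        panel.amplicons.pop()
        df = frame([make_row("P1", "TN1", 250, 0.2)])
        with pytest.raises(FilterError, match="position off-panel"):
            amplicon_end_filter(df, panel)


class TestRegionFilter:
    @pytest.mark.parametrize("pos,flagged", [(16189, True), (310, True), (5000, False)])
    def test_microsatellite_positions(self, regions, pos, flagged):
        df = frame([make_row("P1", "TN1", pos, 0.3)])
        out = region_filter(df, regions, 16569)
        assert ("repetitive_region" in out["flags"].iloc[0]) == flagged


def _simulated_cohort(reference, panel, tmp_path, n_patients=3, depth=300.0,
                      deamination_rate=0.0, seed=100):
    cfg = SimConfig(n_germline=4, n_trunk=2, n_branch=0, n_private=1,
                    depth_mean=depth, deamination_rate=deamination_rate,
                    indel_fraction=0.0, seed=seed)
    frames, pileups, truths = [], {}, []
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_patients)):
        pid = f"P{i + 1}"
        rng = np.random.default_rng(child)
        _, truth = simulate_patient(cfg, panel, reference, pid, rng, n_lesions=2)
        truths.append(truth)
        for lesion in ("TN1", "TN2"):
            r1 = tmp_path / f"{pid}_{lesion}_1.fq"
            r2 = tmp_path / f"{pid}_{lesion}_2.fq"
            simulate_reads(truth, panel, cfg, lesion, rng, r1, r2, pid)
            pileup, _ = assign_and_pileup(r1, r2, panel, reference)
            calls = [classify_plasmy(c) for c in call_variants(pileup)]
            frames.append(calls_to_frame(calls, pid, lesion, reference.length))
            pileups[(pid, lesion)] = pileup
    cohort = pd.concat(frames, ignore_index=True)
    cohort["known_polymorphism"] = False
    return cohort, pileups, pd.concat(truths, ignore_index=True)


class TestNoiseFilter:
    def test_clean_simulation_has_no_noise_flags_on_true_variants(
        self, reference, default_panel, tmp_path
    ):
        cohort, pileups, truth = _simulated_cohort(reference, default_panel, tmp_path)
        out = noise_filter(cohort, pileups)
        true_keys = set(zip(truth.position, truth.alt))
        hit = out[out["flags"].str.contains("noisy_region")]
        for row in hit.itertuples():
            assert (row.position, row.alt) not in true_keys

    def test_carriers_excluded_planted_variants_never_self_flag(
        self, reference, default_panel, tmp_path
    ):
        # even homoplasmic planted variants (non-ref fraction ~1 in carriers)
        # must not be flagged, because carrier samples are excluded
        cohort, pileups, truth = _simulated_cohort(reference, default_panel, tmp_path)
        out = noise_filter(cohort, pileups)
        germ = truth[truth.true_vaf == 1.0]
        for row in out[out.position.isin(germ.position)].itertuples():
            assert "noisy_region" not in row.flags

    def test_too_few_samples_warns(self, reference, default_panel, tmp_path):
        cohort, pileups, _ = _simulated_cohort(reference, default_panel, tmp_path,
                                               n_patients=1)
        one = {k: v for k, v in list(pileups.items())[:2]}
        with pytest.warns(UserWarning, match=">= 3 samples"):
            noise_filter(cohort, one)


class TestApplyFilters:
    def test_partition_and_flag_union(self, reference, regions, default_panel, tmp_path):
        cohort, pileups, truth = _simulated_cohort(reference, default_panel, tmp_path)
        pass_t, review = apply_filters(cohort, default_panel, regions, pileups)
        assert len(pass_t) + len(review) == len(cohort)
        assert (review["flags"] != "").all()
        assert (pass_t["flags"] == "").all()
        assert review.needs_orthogonal_confirmation.all()

    def test_order_independence(self, reference, regions, default_panel, tmp_path):
        cohort, pileups, _ = _simulated_cohort(reference, default_panel, tmp_path)
        filters = {
            "cross": lambda df: cross_sample_filter(df),
            "ends": lambda df: amplicon_end_filter(df, default_panel),
            "region": lambda df: region_filter(df, regions, reference.length),
            "noise": lambda df: noise_filter(df, pileups),
        }
        results = []
        for perm in itertools.permutations(filters.values()):
            df = cohort.copy()
            for f in perm:
                df = f(df)
            results.append(sorted(df["flags"]))
        assert all(r == results[0] for r in results)

    def test_artifact_audit_across_cohort(self, reference, regions, default_panel, tmp_path):
        """True somatic calls overwhelmingly pass; artifact-origin calls are
        absent or review-routed when the filters run at study-scale depth."""
        cohort, pileups, truth = _simulated_cohort(
            reference, default_panel, tmp_path, depth=800.0, deamination_rate=0.003
        )
        pass_t, review = apply_filters(cohort, default_panel, regions, pileups)
        artifacts = truth[truth.origin == "artifact"]
        art_keys = set(zip(artifacts.patient, artifacts.lesion,
                           artifacts.position, artifacts.alt))
        leaked = [
            r for r in pass_t.itertuples()
            if (r.patient, r.lesion, r.position, r.alt) in art_keys
        ]
        assert leaked == []
        somatic = truth[truth.origin.isin(["trunk", "branch", "private"])]
        som_keys = set(zip(somatic.patient, somatic.lesion,
                           somatic.position, somatic.alt))
        pass_keys = set(zip(pass_t.patient, pass_t.lesion, pass_t.position, pass_t.alt))
        called_som = som_keys & set(
            zip(cohort.patient, cohort.lesion, cohort.position, cohort.alt))
        assert len(pass_keys & called_som) >= 0.95 * len(called_som)
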