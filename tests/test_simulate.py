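"""Synthetic-data generators: planted models, biopanning dynamics, planted
proteomes, assay series; reproducibility and recovery."""

import numpy as np
import pytest

from cleavspec.align import align_registers
from cleavspec.kinetics import initial_rate
from cleavspec.model import (
    classify_specificity_from_pwm,
    derive_consensus,
    information_content,
    modal_window,
    pfm_to_pwm,
)
from cleavspec.nomenclature import AA_INDEX, SPECIFICITY_CLASSES
from cleavspec.scan import ScanOptions, scan_proteins
from cleavspec.simulate import (
    BiopanningConfig,
    Plant,
    best_register_scores,
    make_truth_model,
    sample_cleaved_clones,
    simulate_assays,
    simulate_biopanning,
    simulate_library,
    simulate_proteome,
)

PLANTED_CLASS = {
    "polyR-tryptase": "tryptase",
    "aspase": "asp-ase",
    "FK-tryptase": "tryptase",
    "FY-chymase": "chymase",
}


class TestTruthModels:
    def test_aspase_p1_column_concentration(self):
        truth = make_truth_model("aspase", 0.9)
        p1 = truth.pfm.frequencies[truth.pfm.position_index("P1")]
        assert p1[AA_INDEX["D"]] == pytest.approx(0.9)

    def test_chymase_consensus_recovers_planted_preferences(self):
        truth = make_truth_model("FY-chymase", 0.7)
        pattern = derive_consensus(truth.pfm)
        p1 = pattern.allowed[pattern.positions.index("P1")]
        p2p = pattern.allowed[pattern.positions.index("P2'")]
        assert p1 is not None and {"F", "Y"} <= p1
        assert p2p == frozenset("L")

    def test_uniform_limit_gives_all_any_pattern(self):
        truth = make_truth_model("polyR-tryptase", 1 / 20)
        assert all(a is None for a in truth.pattern.allowed)

    def test_pattern_consistent_with_matrix(self, truth_model):
        assert derive_consensus(truth_model.pfm) == truth_model.pattern

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown truth model"):
            make_truth_model("collagenase")


class TestLibrary:
    def test_fixed_seed_reproducible(self):
        a = simulate_library(10, seed=5)
        assert a == simulate_library(10, seed=5)

    def test_degenerate_composition(self):
        comp = np.zeros(20)
        comp[AA_INDEX["A"]] = 1.0
        lib = simulate_library(5, composition=comp, seed=0)
        assert {p.sequence for p in lib} == {"AAAAAAAAA"}

    def test_pooled_residue_frequencies_near_uniform(self):
        lib = simulate_library(100_000, seed=1)
        counts = np.zeros(20)
        for p in lib:
            for aa in p.sequence:
                counts[AA_INDEX[aa]] += 1
        total = counts.sum()
        p = 1 / 20
        sd = np.sqrt(total * p * (1 - p))
        assert np.all(np.abs(counts - total * p) < 3.5 * sd)


class TestBiopanning:
    def test_bit_reproducible(self):
        truth = make_truth_model("polyR-tryptase", 0.9)
        cfg = BiopanningConfig(library_size=5000, sample_size=20, seed=3)
        s1, seq1 = simulate_biopanning(cfg, truth)
        s2, seq2 = simulate_biopanning(cfg, truth)
        assert seq1 == seq2
        assert [r.released_enzyme for r in s1] == [r.released_enzyme for r in s2]

    def test_null_selection_enrichment_near_one(self):
        # an unreachable score midpoint makes every clone release at the
        # background probability; expected enrichment fold is then 1
        truth = make_truth_model("polyR-tryptase", 0.9)
        folds = []
        for seed in range(40):
            cfg = BiopanningConfig(
                library_size=20_000, rounds=1, score_midpoint=1e9,
                p_background=0.002, sample_size=5, seed=seed,
            )
            summaries, _ = simulate_biopanning(cfg, truth)
            folds.append(summaries[0].enrichment_fold)
        mean = np.mean(folds)
        se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(mean - 1.0) < 3 * se + 1e-9

    def test_two_class_round_one_fold_matches_closed_form(self):
        # fraction f of perfect-motif clones at ~p_max, rest at background:
        # E[fold] = (f p_hi + (1-f) p_bg) / p_bg
        truth = make_truth_model("polyR-tryptase", 0.9)
        f, n = 0.02, 20_000
        strong = ["ARRRRAAAA"] * int(f * n)
        weak = ["AAAAQAAAA"] * (n - len(strong))
        from cleavspec.io import PeptideObservation

        library = [PeptideObservation(s) for s in strong + weak]
        cfg0 = BiopanningConfig(
            library_size=n, rounds=1, score_midpoint=0.0, score_slope=5.0,
            p_max=0.5, p_background=0.001, sample_size=5,
        )
        pwm = pfm_to_pwm(truth.pfm)
        p_hi = 0.001 + (0.5 - 0.001) / (
            1 + np.exp(-5.0 * float(best_register_scores([strong[0]], pwm)[0]))
        )
        expected = (f * p_hi + (1 - f) * 0.001) / 0.001
        enz, ctl = [], []
        for seed in range(30):
            cfg = BiopanningConfig(**{**cfg0.__dict__, "seed": seed})
            summaries, _ = simulate_biopanning(cfg, truth, library=library)
            enz.append(summaries[0].released_enzyme)
            ctl.append(summaries[0].released_control)
        # the closed form is a ratio of expectations; estimate it as the
        # ratio of means (a per-seed ratio is biased upward by small
        # Poisson-like control counts) with a delta-method standard error
        ex, cy = np.mean(enz), np.mean(ctl)
        ratio = ex / cy
        var = (np.var(enz, ddof=1) / len(enz)) / cy**2 + (
            ex**2 / cy**4
        ) * (np.var(ctl, ddof=1) / len(ctl))
        assert abs(ratio - expected) < 3 * np.sqrt(var)

    def test_selection_enriches_across_rounds(self):
        truth = make_truth_model("polyR-tryptase", 0.9)
        for seed in range(5):
            cfg = BiopanningConfig(library_size=30_000, sample_size=10, seed=seed)
            summaries, _ = simulate_biopanning(cfg, truth)
            assert summaries[-1].enrichment_fold > summaries[0].enrichment_fold
            assert summaries[-1].top_clone_fraction >= summaries[0].top_clone_fraction

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BiopanningConfig(p_background=0.5, p_max=0.2)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("name", list(PLANTED_CLASS))
    def test_biopanning_sample_recovers_planted_class(self, name):
        # full pipeline: selection -> sequencing -> register alignment ->
        # specificity call, with the cleavage-register gauge anchored by the
        # P1 class the chromogenic panel reports (as on the bench, where
        # substrate assays, not phage display, place the scissile bond)
        truth = make_truth_model(name, 0.9)
        panel = ["AARR", "AAFK", "WDSD", "AAPF", "AAPV"]
        series, _ = simulate_assays(truth, [(s, s) for s in panel], seed=0)
        from cleavspec.kinetics import classify_specificity_from_rates

        rate_call = classify_specificity_from_rates(
            [(s.substrate_sequence, initial_rate(s)) for s in series]
        )
        anchor = "".join(sorted(SPECIFICITY_CLASSES[rate_call.label]))
        summaries, sequenced = simulate_biopanning(BiopanningConfig(seed=0), truth)
        aligned = align_registers(sequenced, seed=0, p1_anchor=anchor)
        call = classify_specificity_from_pwm(aligned.pfm)
        assert call.label == PLANTED_CLASS[name]


class TestPlantedProteome:
    def test_explicit_octamer_plant_registered_at_coordinates(self):
        planted = simulate_proteome(
            n_proteins=2,
            length_range=(900, 999),
            planting_plan=[
                Plant(
                    protein=0, p1=838, window="EWFDVDYP",
                    positions=("P6", "P5", "P4", "P3", "P2", "P1", "P1'", "P2'"),
                )
            ],
            seed=4,
        )
        site = planted.registry[0]
        assert (site.protein_id, site.p1_position) == ("synprot1", 838)
        prot = planted.proteins[0]
        assert prot.sequence[832:840] == "EWFDVDYP"

    def test_consensus_plants_recovered_with_zero_mismatches(self):
        truth = make_truth_model("aspase", 0.9)
        plan = [Plant(protein=i, p1=100 + 7 * i) for i in range(5)]
        planted = simulate_proteome(
            n_proteins=10, truth=truth, planting_plan=plan, seed=2
        )
        opts = ScanOptions(report_start="P4", report_end="P3'")
        hits = scan_proteins(planted.proteins, truth.pattern, opts)
        found = {(h.protein_id, h.p1_position) for h in hits}
        for site in planted.registry:
            if not site.accidental and site.mismatches == 0:
                assert (site.protein_id, site.p1_position) in found

    def test_no_plants_registry_holds_only_accidentals(self):
        truth = make_truth_model("aspase", 0.9)
        planted = simulate_proteome(n_proteins=5, truth=truth, seed=0)
        assert all(site.accidental for site in planted.registry)

    def test_overlapping_plants_rejected(self):
        truth = make_truth_model("aspase", 0.9)
        with pytest.raises(ValueError, match="overlap"):
            simulate_proteome(
                n_proteins=1,
                truth=truth,
                planting_plan=[Plant(0, 100), Plant(0, 102)],
                seed=0,
            )

    def test_sampled_windows_record_their_mismatches(self):
        truth = make_truth_model("aspase", 0.9)
        planted = simulate_proteome(
            n_proteins=3,
            truth=truth,
            planting_plan=[Plant(i, 50, mode="sample") for i in range(3)],
            seed=8,
        )
        consensus = modal_window(truth.pfm)
        for site in planted.registry:
            if not site.accidental:
                expected = sum(a != b for a, b in zip(site.window, consensus))
                assert site.mismatches == expected


class TestAssaySimulation:
    def test_zero_noise_recovers_planted_slope_exactly(self):
        truth = make_truth_model("aspase", 0.9)
        series, _ = simulate_assays(
            truth, [("WDSD", "WDSD")], noise_sd=0.0, rate_max=0.002, seed=0
        )
        r = initial_rate(series[0])
        # WDSD is the best achievable substrate for this model: full rate
        assert r.rate == pytest.approx(0.002, rel=1e-9)
        assert r.sd == pytest.approx(0.0, abs=1e-12)

    def test_only_asp_p1_substrates_rise_above_noise(self):
        truth = make_truth_model("aspase", 0.9)
        series, _ = simulate_assays(
            truth, [("WDSD", "WDSD"), ("VEID", "VEID"), ("AAPF", "AAPF")], seed=0
        )
        rates = {s.substrate_id: initial_rate(s).rate for s in series}
        floor = 3e-5
        assert rates["WDSD"] > floor
        assert rates["AAPF"] < floor

    def test_timecourses_scale_with_register_score(self):
        truth = make_truth_model("polyR-tryptase", 0.9)
        _, courses = simulate_assays(
            truth,
            [("AARR", "AARR")],
            timecourse_substrates=[("good", "VVRRRAAAG"), ("bad", "VVAAAAAAG")],
            tc_noise_sd=0.0,
            seed=0,
        )
        by_name = {c.substrate_name: c for c in courses}
        assert by_name["good"].fraction_cleaved[-1] > by_name["bad"].fraction_cleaved[-1]

    def test_reproducible_for_fixed_seed(self):
        truth = make_truth_model("FY-chymase", 0.9)
        s1, c1 = simulate_assays(truth, seed=9, timecourse_substrates=[("x", "VVRFLSLLG")])
        s2, c2 = simulate_assays(truth, seed=9, timecourse_substrates=[("x", "VVRFLSLLG")])
        np.testing.assert_array_equal(s1[0].replicates, s2[0].replicates)
        np.testing.assert_array_equal(c1[0].fraction_cleaved, c2[0].fraction_cleaved)


class TestSampledClones:
    def test_reproducible_and_registered(self):
        truth = make_truth_model("FK-tryptase", 0.9)
        c1, p1 = sample_cleaved_clones(truth, 10, seed=2)
        c2, p2 = sample_cleaved_clones(truth, 10, seed=2)
        assert c1 == c2 and p1 == p2
        assert all(7 <= x <= 9 for x in p1)  # window kept inside the insert

    def test_information_scales_with_sharpness(self):
        lo = make_truth_model("aspase", 0.5)
        hi = make_truth_model("aspase", 0.95)
        assert information_content(hi.pfm).mean() > information_content(lo.pfm).mean()
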