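"""Synthetic trio cohort generator: marker maps, Mendelian transmission,
CNV implantation and signal rendering."""
import numpy as np
import pandas as pd
import pytest

from triocnv.core import LRR_STATE_MEANS
from triocnv.regions import NddRegion
from triocnv.sim import (CohortConfig, NoiseModel, TruthEvent,
                         base_allele_counts, build_marker_map, generate_cohort,
                         implant_cnv, render_signals, simulate_trio_genotypes,
                         trio_sample_ids)

NOISELESS = NoiseModel(lrr_sd=0.0, baf_sd=0.0, outlier_rate=0.0, wave_amplitude=0.0)


class TestMarkerMap:
    def test_requested_count_sorted_within_window(self):
        mm = build_marker_map({"1": 10_000_000}, 1000, seed=3)
        assert len(mm) == 1000
        assert np.all(np.diff(mm.pos) > 0)
        assert mm.pos[0] >= 1 and mm.pos[-1] <= 10_000_000

    def test_density_boost_concentrates_markers(self):
        region = NddRegion("r", "1", 4_000_001, 5_000_000)
        n = 2000
        mm = build_marker_map({"1": 10_000_000}, n, boost_regions=[region],
                              region_density_boost=5.0, seed=11)
        inside = int(((mm.pos >= region.start) & (mm.pos <= region.end)).sum())
        p = 5.0 / (5.0 + 9.0)     # boosted megabase vs nine unboosted
        expect = n * p
        sd = np.sqrt(n * p * (1 - p))
        assert abs(inside - expect) <= 3 * sd

    def test_deterministic_for_seed(self):
        a = build_marker_map({"1": 2_000_000, "2": 1_000_000}, 300, seed=5)
        b = build_marker_map({"1": 2_000_000, "2": 1_000_000}, 300, seed=5)
        assert np.array_equal(a.pos, b.pos) and np.array_equal(a.pfb, b.pfb)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_marker_map({"1": 1_000_000}, 0)
        with pytest.raises(ValueError):
            build_marker_map({"1": 0}, 10)
        with pytest.raises(ValueError):
            build_marker_map({"1": 1_000_000}, 10, region_density_boost=0.5)


class TestTrioGenotypes:
    def test_child_allele_always_from_parents(self):
        mm = build_marker_map({"1": 5_000_000}, 400, seed=0)
        gt = simulate_trio_genotypes(mm, 20, seed=1)
        for trio in (0, 7, 19):
            vm, vp = gt.child_alleles(trio)
            hap_m = gt.mother[trio]
            hap_p = gt.father[trio]
            assert np.all((vm == hap_m[0]) | (vm == hap_m[1]))
            assert np.all((vp == hap_p[0]) | (vp == hap_p[1]))

    def test_monomorphic_parents_force_child(self):
        # pfb ~ 1 makes everyone BB; children must be BB too
        mm = build_marker_map({"1": 1_000_000}, 100, seed=0,
                              pfb_range=(0.999, 0.9999))
        gt = simulate_trio_genotypes(mm, 5, seed=2)
        counts = base_allele_counts(gt)
        assert np.all(counts.b[:5] == 2.0)

    def test_child_heterozygosity_at_half_pfb(self):
        mm = build_marker_map({"1": 50_000_000}, 10_000, seed=0,
                              pfb_range=(0.499999, 0.500001))
        gt = simulate_trio_genotypes(mm, 1, seed=3)
        counts = base_allele_counts(gt)
        het = float((counts.b[0] == 1.0).mean())
        assert abs(het - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_reproducible(self):
        mm = build_marker_map({"1": 1_000_000}, 200, seed=0)
        a = simulate_trio_genotypes(mm, 10, seed=9)
        b = simulate_trio_genotypes(mm, 10, seed=9)
        assert np.array_equal(a.mother, b.mother)
        assert np.array_equal(a.trans_mat, b.trans_mat)


def _one_trio_setup(pfb=None, seed=0):
    mm = build_marker_map({"1": 2_000_000}, 100, seed=seed,
                          pfb_range=(pfb, pfb) if pfb else (0.1, 0.9))
    gt = simulate_trio_genotypes(mm, 1, seed=seed)
    counts = base_allele_counts(gt)
    return mm, gt, counts


class TestImplantCnv:
    def test_de_novo_deletion_keeps_only_other_parent(self):
        mm, gt, counts = _one_trio_setup(seed=4)
        ev = TruthEvent("fam00000", "c00000", "r", "1", 500_000, 1_500_000,
                        copy_number=1, mode="de_novo", origin_parent="maternal")
        implant_cnv(counts, gt, 0, ev, np.random.default_rng(0))
        span = mm.span_indices("1", ev.start, ev.end)
        vp = gt.father[0][gt.trans_pat[0, span].astype(np.int64), span]
        assert np.array_equal(counts.b[0, span], vp.astype(np.float32))
        assert np.all(counts.a[0, span] + counts.b[0, span] == 1.0)

    def test_de_novo_duplication_enumeration(self):
        # mother BB, father AA: child base AB; paternal dup adds an A -> A:2 B:1
        mm = build_marker_map({"1": 2_000_000}, 50, seed=1, pfb_range=(0.5, 0.5))
        gt = simulate_trio_genotypes(mm, 1, seed=1)
        gt.mother[0, :, :] = 1
        gt.father[0, :, :] = 0
        counts = base_allele_counts(gt)
        ev = TruthEvent("fam00000", "c00000", "r", "1", 1, 2_000_000,
                        copy_number=3, mode="de_novo", origin_parent="paternal")
        implant_cnv(counts, gt, 0, ev, np.random.default_rng(2))
        assert np.all(counts.a[0] == 2.0) and np.all(counts.b[0] == 1.0)

    def test_inherited_event_present_in_parent(self):
        mm, gt, counts = _one_trio_setup(seed=6)
        ev = TruthEvent("fam00000", "c00000", "r", "1", 400_000, 1_600_000,
                        copy_number=3, mode="inherited", origin_parent="paternal")
        implant_cnv(counts, gt, 0, ev, np.random.default_rng(3))
        span = mm.span_indices("1", ev.start, ev.end)
        father_row = counts.row(trio_sample_ids(0)[1])
        assert np.all(counts.a[father_row, span] + counts.b[father_row, span] == 3.0)
        assert np.all(counts.a[0, span] + counts.b[0, span] == 3.0)

    def test_mosaic_gain_shifts_het_bands(self):
        mm = build_marker_map({"1": 2_000_000}, 80, seed=2, pfb_range=(0.5, 0.5))
        gt = simulate_trio_genotypes(mm, 1, seed=5)
        counts = base_allele_counts(gt)
        ev = TruthEvent("fam00000", "c00000", "r", "1", 1, 2_000_000,
                        copy_number=3, mode="de_novo", origin_parent="maternal",
                        mosaic_fraction=0.4)
        implant_cnv(counts, gt, 0, ev, np.random.default_rng(7))
        sig = render_signals(counts, mm, NOISELESS, seed=0)
        f = 0.4
        expected = {0.0, 1.0, 1 / (2 + f), (1 + f) / (2 + f), f / (2 + f),
                    2 / (2 + f)}
        for value in np.unique(np.round(sig.baf[0], 5)):
            assert any(abs(value - e) < 1e-4 for e in expected)
        # both shifted heterozygous bands actually occur somewhere in the span
        assert np.any(np.abs(sig.baf[0] - 1 / 2.4) < 1e-4)

    def test_event_outside_map_rejected(self):
        mm, gt, counts = _one_trio_setup(seed=8)
        ev = TruthEvent("fam00000", "c00000", "r", "1", 5_000_000, 6_000_000,
                        copy_number=1, mode="de_novo", origin_parent="maternal")
        with pytest.raises(ValueError):
            implant_cnv(counts, gt, 0, ev, np.random.default_rng(0))

    def test_truth_event_validation(self):
        with pytest.raises(ValueError):
            TruthEvent("f", "c", "r", "1", 1, 2, copy_number=2,
                       mode="de_novo", origin_parent="maternal")
        with pytest.raises(ValueError):
            TruthEvent("f", "c", "r", "1", 1, 2, copy_number=3,
                       mode="de_novo", origin_parent="maternal",
                       mosaic_fraction=0.0)


class TestRenderSignals:
    def test_noise_free_diploid_bands(self):
        mm, gt, counts = _one_trio_setup(seed=9)
        sig = render_signals(counts, mm, NOISELESS, seed=0)
        assert np.all(sig.lrr == 0.0)
        assert set(np.unique(sig.baf)) <= {0.0, 0.5, 1.0}

    def test_noise_free_hemizygous_bands(self):
        mm, gt, counts = _one_trio_setup(seed=10)
        ev = TruthEvent("fam00000", "c00000", "r", "1", 1, 2_000_000,
                        copy_number=1, mode="de_novo", origin_parent="paternal")
        implant_cnv(counts, gt, 0, ev, np.random.default_rng(1))
        sig = render_signals(counts, mm, NOISELESS, seed=0)
        assert np.allclose(sig.lrr[0], LRR_STATE_MEANS[1])
        assert set(np.unique(sig.baf[0])) <= {0.0, 1.0}

    def test_trisomic_ab_band_is_one_third(self):
        mm = build_marker_map({"1": 1_000_000}, 30, seed=3, pfb_range=(0.5, 0.5))
        gt = simulate_trio_genotypes(mm, 1, seed=4)
        gt.mother[0, :, :] = 1
        gt.father[0, :, :] = 0
        counts = base_allele_counts(gt)
        ev = TruthEvent("fam00000", "c00000", "r", "1", 1, 1_000_000,
                        copy_number=3, mode="de_novo", origin_parent="paternal")
        implant_cnv(counts, gt, 0, ev, np.random.default_rng(0))
        sig = render_signals(counts, mm, NOISELESS, seed=0)
        assert np.allclose(sig.baf[0], 1 / 3, atol=1e-6)
        assert np.allclose(sig.lrr[0], LRR_STATE_MEANS[3])

    def test_unknown_copy_number_rejected(self):
        mm, gt, counts = _one_trio_setup(seed=11)
        counts.b[0, :] = 5.0
        with pytest.raises(ValueError):
            render_signals(counts, mm, NOISELESS, seed=0)


class TestGenerateCohort:
    def test_zero_rates_give_empty_truth_and_diploid_cohort(self):
        cfg = CohortConfig(n_trios=20, rates={}, marker_spacing_bp=50_000,
                           flank_bp=150_000, breakpoint_jitter_bp=100_000,
                           untransmitted_maternal_rate=0.0,
                           untransmitted_paternal_rate=0.0)
        cohort = generate_cohort(cfg, seed=0)
        assert cohort.truth.empty and cohort.parent_truth.empty
        assert np.all(cohort.counts.total == 2.0)

    def test_carrier_count_near_configured_rate(self):
        cfg = CohortConfig(
            n_trios=2000, rates={("17q12", "del"): 0.005},
            marker_spacing_bp=50_000, flank_bp=150_000,
            breakpoint_jitter_bp=100_000,
            untransmitted_maternal_rate=0.0, untransmitted_paternal_rate=0.0)
        cohort = generate_cohort(cfg, seed=12)
        n = len(cohort.truth)
        sd = np.sqrt(2000 * 0.005 * 0.995)
        assert abs(n - 10) <= 3 * sd

    def test_de_novo_fraction_matches_study_design(self):
        cfg = CohortConfig(
            n_trios=3000, rates={("17q12", "del"): 0.05},
            marker_spacing_bp=50_000, flank_bp=150_000,
            untransmitted_maternal_rate=0.0, untransmitted_paternal_rate=0.0)
        cohort = generate_cohort(cfg, seed=13)
        n = len(cohort.truth)
        dn = int((cohort.truth["mode"] == "de_novo").sum())
        p = 20 / 59
        assert abs(dn - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_inherited_events_have_carrying_parent(self):
        cfg = CohortConfig(n_trios=400, marker_spacing_bp=40_000,
                           flank_bp=200_000,
                           rates={("22q11.2", "dup"): 0.05})
        cohort = generate_cohort(cfg, seed=14)
        inh = cohort.truth[cohort.truth["mode"] == "inherited"]
        assert len(inh) > 0
        transmitted = cohort.parent_truth[cohort.parent_truth["transmitted"]]
        assert set(inh["family"]) == set(transmitted["family"])
        for _, ev in inh.iterrows():
            trio = int(ev["carrier"][1:])
            prow = cohort.counts.row(
                trio_sample_ids(trio)[2 if ev["origin_parent"] == "maternal" else 1])
            span = cohort.markers.span_indices(ev["chrom"], ev["start"], ev["end"])
            assert np.all(cohort.counts.total[prow, span] == 3.0)

    def test_bitwise_reproducible(self):
        cfg = CohortConfig(n_trios=50, marker_spacing_bp=50_000, flank_bp=150_000)
        a = generate_cohort(cfg, seed=21)
        b = generate_cohort(cfg, seed=21)
        assert np.array_equal(a.signals.lrr, b.signals.lrr)
        assert np.array_equal(a.signals.baf, b.signals.baf)
        assert a.truth.equals(b.truth)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_trios=10, rates={("1q21.1", "del"): 1.5})
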