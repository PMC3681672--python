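"""SGA caller: preprocessing, state calling, haplotypes, mixtures."""

import math

import numpy as np
import pandas as pd
import pytest

from sgaclock.calling import (
    CallerConfig,
    Event,
    SgaSegmentCall,
    SignalProfiles,
    ThresholdBox,
    build_profiles,
    call_individual,
    call_states,
    correct_dye_bias,
    detect_clone_mixture,
    exclude_low_intensity,
    identify_heterozygous,
    merge_adjacent,
    to_binary_matrix,
    union_breakpoints,
    validate_thresholds,
)
from sgaclock.evaluate import score_event_recovery


def frame(n, r=None, baf=None):
    r = np.ones(n) if r is None else np.asarray(r, dtype=float)
    baf = np.full(n, 0.5) if baf is None else np.asarray(baf, dtype=float)
    return pd.DataFrame(
        {
            "sample_id": "s", "chrom": "chr1", "pos": np.arange(n) * 1000,
            "X": r * (1 - baf), "Y": r * baf, "R": r, "BAF": baf,
        }
    )


class TestExclusion:
    def test_zero_fraction_is_identity(self):
        keep = exclude_low_intensity(frame(100), 0.0)
        assert keep.all()

    def test_fraction_removes_floor_count(self):
        rng = np.random.default_rng(0)
        control = frame(1000, r=rng.uniform(0.5, 2.0, 1000))
        keep = exclude_low_intensity(control, 0.002)
        assert (~keep).sum() == 2
        dropped_r = control["R"].to_numpy()[~keep]
        assert set(dropped_r) == set(np.sort(control["R"].to_numpy())[:2])

    def test_all_ties_drop_first_in_genomic_order(self):
        keep = exclude_low_intensity(frame(1000), 0.002)
        assert list(np.flatnonzero(~keep)) == [0, 1]

    def test_empty_probe_set_invalid(self):
        with pytest.raises(ValueError):
            exclude_low_intensity(frame(0), 0.002)


class TestHeterozygous:
    def test_midpoint_is_het_and_bounds_are_strict(self):
        control = frame(3, baf=[0.5, 0.33, 0.66])
        het = identify_heterozygous(control)
        assert het.tolist() == [True, False, False]

    def test_noisy_diploid_classification(self):
        rng = np.random.default_rng(1)
        true_het = rng.uniform(size=5000) < 0.3
        baf = np.where(true_het, 0.5, rng.choice([0.0, 1.0], 5000))
        baf = np.clip(baf + rng.normal(0, 0.02, 5000), 0, 1)
        het = identify_heterozygous(frame(5000, baf=baf))
        assert (het & true_het).sum() / true_het.sum() >= 0.99


class TestDyeBias:
    def test_recenters_shifted_median(self):
        rng = np.random.default_rng(2)
        baf = np.clip(0.53 + rng.normal(0, 0.01, 2001), 0, 1)
        out = correct_dye_bias({"s": frame(2001, baf=baf)}, np.ones(2001, bool))
        assert np.median(out["s"]["BAF"]) == pytest.approx(0.5, abs=1e-12)

    def test_idempotent_when_centered(self):
        rng = np.random.default_rng(3)
        baf = np.clip(0.5 + rng.normal(0, 0.01, 2000), 0, 1)
        first = correct_dye_bias({"s": frame(2000, baf=baf)}, np.ones(2000, bool))
        second = correct_dye_bias(first, np.ones(2000, bool))
        assert np.allclose(first["s"]["BAF"], second["s"]["BAF"], atol=1e-9)

    def test_homozygous_anchors_fixed(self):
        baf = np.array([0.0, 1.0, 0.53, 0.53, 0.53])
        het = np.array([False, False, True, True, True])
        out = correct_dye_bias({"s": frame(5, baf=baf)}, het)
        assert out["s"]["BAF"].iloc[0] == 0.0
        assert out["s"]["BAF"].iloc[1] == 1.0

    def test_no_het_probes_skips_with_warning(self, caplog):
        out = correct_dye_bias({"s": frame(5)}, np.zeros(5, bool))
        assert np.allclose(out["s"]["BAF"], 0.5)


class TestProfiles:
    def test_mbaf_formula(self):
        biopsy = frame(4, baf=[0.5, 1.0, 0.25, 0.0])
        control = frame(4)
        prof = build_profiles(biopsy, control, np.ones(4, bool))
        assert np.allclose(prof.mbaf, [0.0, 1.0, 0.5, 1.0])

    def test_equal_intensities_give_zero_log_ratios(self):
        prof = build_profiles(frame(10), frame(10), np.zeros(10, bool))
        assert np.allclose(prof.log2r_hom, 0.0)

    def test_nonpositive_control_r_dropped(self):
        control = frame(3, r=[1.0, 0.0, 1.0])
        prof = build_profiles(frame(3), control, np.zeros(3, bool))
        assert 1 not in prof.hom_idx


class TestUnionBreakpoints:
    def test_single_breakpoint_splits_chromosome(self):
        probes = frame(100)
        events = union_breakpoints([np.array([40])], probes)
        assert [(e.start, e.end) for e in events] == [(0, 40_000), (40_000, 99_001)]

    def test_union_across_samples(self):
        probes = frame(100)
        events = union_breakpoints([np.array([20]), np.array([60])], probes)
        assert [e.probe_lo for e in events] == [0, 20, 60]

    def test_no_breakpoints_one_event_per_chromosome(self):
        probes = pd.concat(
            [frame(50).assign(chrom="chr1"), frame(30).assign(chrom="chr2")],
            ignore_index=True,
        )
        events = union_breakpoints([], probes)
        assert len(events) == 2
        assert {e.chrom for e in events} == {"chr1", "chr2"}


class TestStateCalling:
    def _profiles_for(self, log2r, mbaf, n=100):
        half = n // 2
        return SignalProfiles(
            het_idx=np.arange(half),
            hom_idx=np.arange(half, n),
            log2r_het=np.full(half, log2r),
            log2r_hom=np.full(n - half, log2r),
            mbaf=np.full(half, mbaf),
            baf_het=np.full(half, 0.5 + mbaf / 2),
            mbaf_idx=np.arange(half),
        )

    CANONICAL = {
        "AB": (0.0, 0.0),
        "AA": (0.0, 1.0),
        "A": (-1.0, 1.0),
        "0": (-6.0, 0.0),
        "AAB": (math.log2(1.5), 1.0 / 3.0),
        "AAA": (math.log2(1.5), 1.0),
        "AAAA": (1.0, 1.0),
        "AABB": (1.0, 0.0),
    }

    @pytest.mark.parametrize("state", list(CANONICAL))
    def test_canonical_levels_round_trip(self, state):
        log2r, mbaf = self.CANONICAL[state]
        prof = self._profiles_for(log2r, mbaf)
        events = [Event("chr1", 0, 1000, 0, 100)]
        calls = call_states(prof, events)
        assert calls[0].state == state

    def test_unmet_thresholds_default_to_ab(self):
        prof = self._profiles_for(0.5, 0.0)  # gain-level log2R, balanced BAF
        calls = call_states(prof, [Event("chr1", 0, 1000, 0, 100)])
        assert calls[0].state == "AB"

    def test_overlapping_boxes_rejected(self):
        bad = {
            "AA": ThresholdBox((-0.3, 0.3), (0.5, 1.0)),
            "A": ThresholdBox((-0.2, 0.2), (0.6, 1.0)),
        }
        with pytest.raises(ValueError, match="overlapping"):
            validate_thresholds(bad)


class TestMergeAdjacent:
    def _call(self, start, end, state):
        return SgaSegmentCall("chr1", start, end, state)

    def test_identical_state_vectors_merge(self):
        calls = {
            "s1": [self._call(0, 10, "AB"), self._call(10, 20, "AB")],
            "s2": [self._call(0, 10, "AA"), self._call(10, 20, "AA")],
        }
        merged = merge_adjacent(calls)
        assert len(merged["s1"]) == 1
        assert merged["s2"][0].end == 20

    def test_differing_sample_blocks_merge(self):
        calls = {
            "s1": [self._call(0, 10, "AB"), self._call(10, 20, "AB")],
            "s2": [self._call(0, 10, "AA"), self._call(10, 20, "A")],
        }
        merged = merge_adjacent(calls)
        assert len(merged["s1"]) == 2

    def test_idempotent(self):
        calls = {
            "s1": [self._call(0, 10, "AB"), self._call(10, 20, "AA"),
                   self._call(20, 30, "AA")],
        }
        once = merge_adjacent(calls)
        twice = merge_adjacent(once)
        assert [(c.start, c.end, c.state) for c in once["s1"]] == [
            (c.start, c.end, c.state) for c in twice["s1"]
        ]


class TestBinaryMatrix:
    def test_all_normal_individual_yields_zero_columns(self):
        calls = {"s1": [SgaSegmentCall("chr1", 0, 10, "AB")]}
        m = to_binary_matrix(calls)
        assert m.n_characters == 0

    def test_haplotype_forms_are_distinct_characters(self):
        a = SgaSegmentCall("chr1", 0, 10, "AA", haplotype=1)
        b = SgaSegmentCall("chr1", 0, 10, "AA", haplotype=2)
        m = to_binary_matrix({"s1": [a], "s2": [b]})
        assert m.n_characters == 2
        assert m.data.sum() == 2


class TestMixtureDetection:
    def test_single_clone_not_flagged(self):
        calls = [SgaSegmentCall("chr1", 0, 10, "AA", split=1.0),
                 SgaSegmentCall("chr2", 0, 10, "AAB", split=1 / 3)]
        assert not detect_clone_mixture(calls)

    def test_half_mixture_on_two_chromosomes_flagged(self):
        # 50/50 mixture of AB and AA clones plateaus at split 0.5
        calls = [SgaSegmentCall("chr1", 0, 10, "AA", split=0.5),
                 SgaSegmentCall("chr2", 0, 10, "AA", split=0.5)]
        assert detect_clone_mixture(calls)

    def test_single_ambiguous_segment_not_enough(self):
        calls = [SgaSegmentCall("chr1", 0, 10, "AA", split=0.5)]
        assert not detect_clone_mixture(calls)


class TestEndToEnd:
    def test_noiseless_round_trip_matches_truth(self):
        from sgaclock.cohort import CohortConfig, simulate_individual

        cfg = CohortConfig(
            n_probes=20_000, n_biopsies=4, n_timepoints=2, followup_years=6.0,
            lam_off=0.8, lam_on=0.2, noise_sd=0.0, baf_noise_sd=0.0,
            mixture_prob=0.0, homoplasy_prob=0.0,
        )
        ind = simulate_individual(cfg, 21, with_signals=True)
        res = call_individual(ind.signals, ind.control_id, probes=ind.probes)
        scores = score_event_recovery(ind, res, min_probes=60, tolerance_probes=0)
        assert scores, "expected at least one scorable event"
        assert all(s.state_ok for s in scores)
        # noiseless breakpoints land on the exact probes
        assert all(s.max_breakpoint_error == 0 for s in scores)

    def test_haplotype_resolution_noiseless(self):
        from sgaclock.calling import IMBALANCE_STATES
        from sgaclock.cohort import CohortConfig, simulate_individual

        cfg = CohortConfig(
            n_probes=20_000, n_biopsies=4, n_timepoints=2, followup_years=6.0,
            lam_off=0.8, lam_on=0.2, noise_sd=0.0, baf_noise_sd=0.0,
            mixture_prob=0.0, homoplasy_prob=0.0,
        )
        ind = simulate_individual(cfg, 22, with_signals=True)
        res = call_individual(ind.signals, ind.control_id, probes=ind.probes)
        checked = 0
        for s in score_event_recovery(ind, res, min_probes=60):
            ev = s.event
            if ev.state not in IMBALANCE_STATES or not s.state_ok:
                continue
            for tip in ind.event_log.carriers[ev.event_id]:
                for c in res.calls_by_sample[tip]:
                    if (
                        c.chrom == ev.chrom and c.start < ev.end
                        and ev.start < c.end and c.state == ev.state
                        and c.haplotype is not None
                    ):
                        assert c.haplotype == ev.haplotype
                        checked += 1
        assert checked > 0
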