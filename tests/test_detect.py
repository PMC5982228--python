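"""Thresholding, region selection, two-stage search, refractory, fusion."""

import numpy as np
import pytest

from ltmbeat import MultileadSignal, SynthConfig, add_noise, synth_ecg
from ltmbeat.detect import (FusionConfig, PeakList, ThresholdParams,
                            adaptive_threshold, apply_refractory,
                            candidate_regions, coarse_peaks, detect_beats,
                            fine_peaks, fuse_leads)
from ltmbeat.io import plan_segments


class TestAdaptiveThreshold:
    def test_constant_signal(self):
        thr = adaptive_threshold(np.full(1200, 2.0),
                                 ThresholdParams(alpha=3.0, beta=0.5), fs=200.0)
        np.testing.assert_allclose(thr, 6.0)

    def test_window_formula(self):
        # one 3-s window with mean 1, std 0.5: threshold = 3*1 + 0.5*0.5
        y = np.concatenate([np.full(300, 0.5), np.full(300, 1.5)])
        thr = adaptive_threshold(y, ThresholdParams(3.0, 0.5, 3.0), fs=200.0)
        np.testing.assert_allclose(thr, 3.25)

    def test_defaults_match_transversal_tuning(self):
        p = ThresholdParams()
        assert p.alpha == 3.0 and p.beta == 0.5 and p.update_s == 3.0

    def test_flat_window_inherits_previous(self):
        y = np.concatenate([np.full(600, 1.0), np.zeros(600)])
        thr = adaptive_threshold(y, ThresholdParams(3.0, 0.5, 3.0), fs=200.0)
        np.testing.assert_allclose(thr[600:], thr[0])


class TestCandidateRegions:
    def test_all_below_threshold(self):
        assert candidate_regions(np.zeros(100), np.ones(100), 200.0) == []

    def test_single_sample_widened_75ms(self):
        y = np.zeros(1000)
        y[500] = 10.0
        regions = candidate_regions(y, np.ones(1000), 200.0, widen_ms=75.0)
        assert regions == [(485, 516)]  # 15 samples each side + the run

    def test_nearby_crossings_merge(self):
        y = np.zeros(1000)
        y[[500, 510]] = 10.0  # 50 ms apart at 200 Hz
        regions = candidate_regions(y, np.ones(1000), 200.0)
        assert len(regions) == 1

    def test_clipped_at_edges(self):
        y = np.zeros(100)
        y[[0, 99]] = 5.0
        regions = candidate_regions(y, np.ones(100), 200.0)
        assert regions[0][0] == 0 and regions[-1][1] == 100


class TestCoarsePeaks:
    def test_single_maximum(self):
        xf = np.zeros(100)
        xf[42] = -7.0  # magnitude counts
        pk = coarse_peaks([(30, 60)], xf)
        assert list(pk.indices) == [42]
        assert pk.amplitudes[0] == 7.0

    def test_tie_breaks_to_earliest(self):
        pk = coarse_peaks([(10, 20)], np.ones(100))
        assert list(pk.indices) == [10]

    def test_matches_brute_force(self, rng):
        xf = rng.standard_normal(500)
        regions = [(0, 50), (100, 180), (300, 301), (400, 500)]
        pk = coarse_peaks(regions, xf)
        for (s, e), k in zip(regions, pk.indices):
            expected = s + max(range(e - s), key=lambda i: (abs(xf[s + i]), -i))
            assert k == expected


class TestFinePeaks:
    def test_fixed_point(self):
        soft = np.zeros(1000)
        soft[500] = 1.0
        pk = fine_peaks(PeakList([500], 0), soft, 200.0)
        assert list(pk.indices) == [500]

    def test_snaps_offset_peak(self):
        soft = np.zeros(1000)
        soft[500] = 1.0
        pk = fine_peaks(PeakList([505], 0), soft, 200.0, window_ms=100.0)
        assert list(pk.indices) == [500]

    def test_edge_windows_clipped(self):
        soft = np.ones(50)
        pk = fine_peaks(PeakList([0, 49], 0), soft, 200.0)
        assert pk.indices.min() >= 0 and pk.indices.max() <= 49


class TestRefractory:
    def test_close_pair_keeps_larger(self):
        pk = PeakList([1000, 1020], 0, amplitudes=[1.0, 2.0])
        out = apply_refractory(pk, 250.0, 200.0)  # 20 samples = 100 ms apart
        assert list(out.indices) == [1020]

    def test_distant_pair_kept(self):
        pk = PeakList([1000, 1080], 0, amplitudes=[1.0, 2.0])  # 400 ms apart
        out = apply_refractory(pk, 250.0, 200.0)
        assert len(out) == 2

    def test_matches_brute_force_and_spacing(self, rng):
        fs, refractory_ms = 200.0, 250.0
        r = int(refractory_ms * fs / 1000)
        for _ in range(50):
            idx = np.unique(rng.integers(0, 3000, size=12))
            amp = rng.uniform(0.1, 5.0, size=idx.size)
            out = apply_refractory(PeakList(idx, 0, amp), refractory_ms, fs)
            assert np.all(np.diff(out.indices) >= r)
            # independent re-derivation of the greedy keep-larger scan
            kept = []
            for i, a in zip(idx, amp):
                if kept and i - kept[-1][0] < r:
                    if a > kept[-1][1]:
                        kept[-1] = (i, a)
                else:
                    kept.append((i, a))
            assert list(out.indices) == [k for k, _ in kept]


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def oracle_fuse(per_lead_indices, tol, quota):
    """Quadratic re-derivation: anchor-scan clustering + support counting."""
    events = sorted((int(i), l) for l, lst in enumerate(per_lead_indices)
                    for i in lst)
    out = []
    k = 0
    while k < len(events):
        anchor = events[k][0]
        members = [ev for ev in events[k:] if ev[0] - anchor <= tol]
        k += len(members)
        if len({l for _, l in members}) >= quota:
            out.append(int(np.median([i for i, _ in members])))
    return out


def _random_leadlists(rng, n_leads=3, n_base=8, fs=200.0):
    base = np.sort(rng.choice(np.arange(500, 20000, 60), n_base, replace=False))
    lists = []
    for _ in range(n_leads):
        jitter = rng.integers(-2, 3, size=n_base)
        present = rng.random(n_base) > 0.3
        idx = np.unique((base + jitter)[present])
        extra = rng.integers(0, 20000, size=rng.integers(0, 3))
        idx = np.unique(np.concatenate([idx, extra]))
        lists.append(PeakList(idx, 0, np.ones(idx.size)))
    return lists


class TestFusion:
    def test_full_agreement_poll(self):
        leads = [PeakList([1000], 0, [1.0]), PeakList([1001], 1, [1.0]),
                 PeakList([1000], 2, [1.0])]
        out = fuse_leads(leads, FusionConfig("poll"), fs=200.0)
        assert list(out.indices) == [1000]

    def test_minority_dropped_by_poll_kept_by_or(self):
        leads = [PeakList([1000], 0, [1.0]),
                 PeakList(np.empty(0, dtype=int), 1),
                 PeakList(np.empty(0, dtype=int), 2)]
        assert len(fuse_leads(leads, FusionConfig("poll"), 200.0)) == 0
        assert len(fuse_leads(leads, FusionConfig("or"), 200.0)) == 1

    def test_single_lead_degenerates(self):
        pl = PeakList([10, 200], 0, [1.0, 1.0])
        for m in ("and", "or", "poll"):
            out = fuse_leads([pl], FusionConfig(m), 200.0)
            np.testing.assert_array_equal(out.indices, pl.indices)

    def test_poll_equals_and_for_two_leads(self, rng):
        for _ in range(20):
            leads = _random_leadlists(rng, n_leads=2)
            a = fuse_leads(leads, FusionConfig("and"), 200.0).indices
            p = fuse_leads(leads, FusionConfig("poll"), 200.0).indices
            np.testing.assert_array_equal(a, p)

    def test_matches_oracle_all_methods(self, rng):
        tol = FusionConfig().tolerance_samples(200.0)
        quotas = {"and": 3, "poll": 2, "sc": 2, "or": 1}
        for _ in range(30):
            leads = _random_leadlists(rng, n_leads=3)
            raw = [list(pl.indices) for pl in leads]
            for m, q in quotas.items():
                got = list(fuse_leads(leads, FusionConfig(m), 200.0).indices)
                assert got == oracle_fuse(raw, tol, q), m

    def test_inclusion_chain_100_random_configs(self, rng):
        """AND <= POLL <= OR and AND <= SC <= OR as tolerance-matched sets."""
        tol = FusionConfig().tolerance_samples(200.0)

        def contained(small, big):
            return all(np.min(np.abs(np.asarray(big, dtype=float) - s), initial=np.inf) <= tol
                       for s in small)

        for _ in range(100):
            n_leads = int(rng.integers(2, 5))
            leads = _random_leadlists(rng, n_leads=n_leads)
            fused = {m: list(fuse_leads(leads, FusionConfig(m), 200.0).indices)
                     for m in ("and", "poll", "sc", "or")}
            assert contained(fused["and"], fused["poll"])
            assert contained(fused["poll"], fused["or"])
            assert contained(fused["and"], fused["sc"])
            assert contained(fused["sc"], fused["or"])

    def test_poll_equals_sc_for_three_leads(self, rng):
        for _ in range(20):
            leads = _random_leadlists(rng, n_leads=3)
            p = fuse_leads(leads, FusionConfig("poll"), 200.0).indices
            s = fuse_leads(leads, FusionConfig("sc"), 200.0).indices
            np.testing.assert_array_equal(p, s)


# ---------------------------------------------------------------------------
# End-to-end detection
# ---------------------------------------------------------------------------

class TestDetectBeats:
    def test_zero_record_no_detections(self):
        sig = MultileadSignal(np.zeros((4000, 2)), fs=200.0)
        out = detect_beats(sig, plan=plan_segments(sig, 10.0, 0.0))
        assert len(out) == 0

    def test_clean_poll_detects_everything(self, clean_5min_record):
        sig, ann = clean_5min_record
        out = detect_beats(sig, "poll-input")
        # every annotation matched within 150 ms, no extras
        assert len(out) >= len(ann) - 3
        d = np.abs(out.indices[:, None] - ann.indices[None, :]).min(axis=1)
        assert np.all(d <= 0.150 * sig.fs)

    def test_segment_vs_whole_equivalence(self):
        sig, _ = synth_ecg(SynthConfig(fs=200.0, duration_s=1200.0,
                                       n_leads=2, seed=2))
        whole = detect_beats(sig, plan=plan_segments(sig, 1200.0, 0.0))
        seg = detect_beats(sig, plan=plan_segments(sig, 300.0, 2.0))
        assert len(whole) == len(seg)
        tol = int(0.010 * sig.fs) + 1
        assert np.abs(whole.indices - seg.indices).max() <= tol

    def test_amplitude_scale_invariance(self, clean_record):
        sig, _ = clean_record
        plan = plan_segments(sig, 60.0, 0.0)
        base = detect_beats(sig, plan=plan)
        scaled = detect_beats(MultileadSignal(sig.samples * 10.0, sig.fs),
                              plan=plan)
        np.testing.assert_array_equal(base.indices, scaled.indices)

    def test_output_spacing_respects_refractory(self, clean_record):
        sig, _ = clean_record
        noisy = add_noise(sig, [("muscle", {"snr_db": 0.0})], seed=5)
        out = detect_beats(noisy, plan=plan_segments(sig, 60.0, 0.0))
        r = int(0.250 * sig.fs)
        assert np.all(np.diff(out.indices) >= r)

    def test_fusion_rule_ordering_on_noisy_input(self, clean_record):
        sig, _ = clean_record
        noisy = add_noise(sig, [("muscle", {"snr_db": -6.0})], seed=6)
        plan = plan_segments(sig, 60.0, 0.0)
        counts = {m: len(detect_beats(noisy, fusion=FusionConfig(m), plan=plan))
                  for m in ("and", "poll", "or")}
        assert counts["and"] <= counts["poll"] <= counts["or"]
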