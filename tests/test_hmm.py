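"""HMM segmentation: decoding, merging and breakpoint refinement."""
import numpy as np
import pytest

from triocnv.core import SignalMatrix
from triocnv.hmm import (STATE_COPIES, CnvCall, HmmParams, calls_to_frame,
                         decode_states, log_emissions, merge_adjacent,
                         refine_breakpoints, viterbi_segment)
from triocnv.sim import (NoiseModel, TruthEvent, base_allele_counts,
                         build_marker_map, implant_cnv, render_signals,
                         simulate_trio_genotypes)

from conftest import diploid_signals, make_map

NOISELESS = NoiseModel(lrr_sd=0.0, baf_sd=0.0, outlier_rate=0.0, wave_amplitude=0.0)


def brute_force_paths(log_em: np.ndarray, log_trans: np.ndarray,
                      log_prior: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive maximum-score path over all 6^m state sequences.

    log_em is (m, 6) for a single sample; returns (best path, best score).
    """
    m, k = log_em.shape
    paths = np.indices((k,) * m).reshape(m, -1).T        # (6^m, m)
    scores = log_prior[paths[:, 0]] + log_em[0, paths[:, 0]]
    for j in range(1, m):
        scores = scores + log_trans[j - 1, paths[:, j - 1], paths[:, j]]
        scores = scores + log_em[j, paths[:, j]]
    best = int(np.argmax(scores))
    return paths[best], float(scores[best])


def _implanted_signals(cn: int, noise: NoiseModel, n_markers=500, seed=0,
                       event=(4_000_001, 5_000_000)):
    """One 10 Mb chromosome with one implanted event; returns signals+map."""
    mm = build_marker_map({"1": 10_000_000}, n_markers, seed=seed)
    gt = simulate_trio_genotypes(mm, 1, seed=seed)
    counts = base_allele_counts(gt)
    ev = TruthEvent("fam00000", "c00000", "r", "1", event[0], event[1],
                    copy_number=cn, mode="de_novo",
                    origin_parent="maternal")
    implant_cnv(counts, gt, 0, ev, np.random.default_rng(seed))
    return render_signals(counts, mm, noise, seed=seed), ev


class TestViterbi:
    def test_noise_free_diploid_yields_no_calls(self):
        mm = make_map(400)
        sig = diploid_signals(mm, [f"s{i}" for i in range(5)], baf_pattern="hw",
                              seed=1)
        assert viterbi_segment(sig) == []

    @pytest.mark.parametrize("cn", [0, 1, 3, 4])
    def test_recovers_implanted_event(self, cn):
        sig, ev = _implanted_signals(cn, NoiseModel(0.12, 0.02, 0.0, 0.0), seed=cn)
        calls = viterbi_segment(sig)
        assert len(calls) == 1
        call = calls[0]
        assert call.copy_number == cn
        assert abs(call.start - ev.start) < 300_000
        assert abs(call.end - ev.end) < 300_000

    def test_decoded_path_beats_all_neutral(self):
        sig, _ = _implanted_signals(1, NoiseModel(0.15, 0.03, 0.002, 0.01))
        params = HmmParams()
        mm = sig.markers
        em = log_emissions(sig.lrr, sig.baf, mm.pfb, params)[0]
        log_trans = params.log_transitions(np.diff(mm.pos))
        path = decode_states(sig, params)[0]

        def score(p):
            s = params.log_prior()[p[0]] + em[0, p[0]]
            for j in range(1, len(p)):
                s += log_trans[j - 1, p[j - 1], p[j]] + em[j, p[j]]
            return s

        assert score(path) >= score(np.full(len(mm), 2))

    def test_matches_exhaustive_enumeration_small_instances(self):
        rng = np.random.default_rng(42)
        params = HmmParams()
        for _ in range(40):
            m = int(rng.integers(2, 8))
            mm = make_map(m, spacing=int(rng.integers(5_000, 80_000)),
                          seed=int(rng.integers(1_000_000)))
            lrr = rng.normal(0, 1.2, (1, m))
            baf = rng.random((1, m))
            sig = SignalMatrix(mm, ["s"], lrr, baf)
            em = log_emissions(lrr, baf, mm.pfb, params)[0].astype(float)
            log_trans = params.log_transitions(np.diff(mm.pos))
            expected, best = brute_force_paths(em, log_trans, params.log_prior())
            got = decode_states(sig, params)[0]
            assert np.array_equal(got, expected)

    def test_empty_sample_list(self):
        mm = make_map(10)
        sig = SignalMatrix(mm, [], np.empty((0, 10)), np.empty((0, 10)))
        assert viterbi_segment(sig) == []

    def test_calls_never_overlap_within_sample(self):
        rng = np.random.default_rng(3)
        mm = make_map(600, seed=3)
        lrr = rng.normal(0, 0.5, (4, 600))
        baf = np.clip(rng.random((4, 600)), 0, 1)
        sig = SignalMatrix(mm, [f"s{i}" for i in range(4)], lrr, baf)
        calls = sorted(viterbi_segment(sig), key=lambda c: (c.sample, c.start))
        for a, b in zip(calls, calls[1:]):
            if a.sample == b.sample:
                assert b.start > a.end


class TestMergeAdjacent:
    @staticmethod
    def _call(start, end, cn=1, n=12, sample="s", chrom="1"):
        return CnvCall(sample, chrom, start, end, cn, n, -0.6)

    def test_small_gap_merges(self):
        a = self._call(1, 100_000)
        b = self._call(110_001, 210_000)
        (m,) = merge_adjacent([a, b])
        assert (m.start, m.end, m.n_markers) == (1, 210_000, 24)

    def test_large_gap_stays_split(self):
        a = self._call(1, 100_000)
        b = self._call(200_001, 300_000)
        assert len(merge_adjacent([a, b])) == 2

    def test_empty_and_idempotent(self):
        assert merge_adjacent([]) == []
        calls = [self._call(1, 100_000), self._call(110_001, 210_000),
                 self._call(216_000, 300_000)]
        once = merge_adjacent(calls)
        assert merge_adjacent(once) == once
        assert len(once) == 1     # chain collapses at the fixpoint

    def test_order_independent(self):
        calls = [self._call(216_000, 300_000), self._call(1, 100_000),
                 self._call(110_001, 210_000)]
        assert merge_adjacent(calls) == merge_adjacent(calls[::-1])

    def test_different_cn_never_merge(self):
        a = self._call(1, 100_000, cn=1)
        b = self._call(100_500, 200_000, cn=0)
        assert len(merge_adjacent([a, b])) == 2

    def test_overlapping_conflicting_cn_rejected(self):
        a = self._call(1, 100_000, cn=1)
        b = self._call(50_000, 200_000, cn=3)
        with pytest.raises(ValueError):
            merge_adjacent([a, b])


class TestRefineBreakpoints:
    def test_neutral_flanks_leave_call_unchanged(self):
        sig, ev = _implanted_signals(3, NOISELESS, seed=5)
        calls = viterbi_segment(sig)
        refined = refine_breakpoints(calls[0], sig)
        assert (refined.start, refined.end) == (calls[0].start, calls[0].end)

    def test_extends_over_flanks_drawn_from_call_state(self):
        sig, ev = _implanted_signals(3, NOISELESS, seed=6)
        (call,) = viterbi_segment(sig)
        mm = sig.markers
        pos = mm.pos
        i0 = int(np.searchsorted(pos, call.start))
        # overwrite 5 markers left of the call with CN3-like signal
        left = slice(i0 - 5, i0)
        sig.lrr[0, left] = 0.40
        sig.baf[0, left] = 1 / 3
        refined = refine_breakpoints(call, sig)
        assert refined.start == int(pos[i0 - 5])
        assert refined.n_markers == call.n_markers + 5
        assert refined.end == call.end

    def test_infinite_margin_is_identity(self):
        sig, _ = _implanted_signals(1, NoiseModel(0.1, 0.02, 0.0, 0.0), seed=7)
        (call,) = viterbi_segment(sig)
        refined = refine_breakpoints(call, sig, margin=np.inf)
        assert (refined.start, refined.end) == (call.start, call.end)


def test_calls_to_frame_adds_class():
    df = calls_to_frame([CnvCall("s", "1", 1, 10, 1, 3, -0.6),
                         CnvCall("s", "1", 20, 40, 3, 4, 0.4)])
    assert list(df["svclass"]) == ["del", "dup"]
    assert calls_to_frame([]).empty
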