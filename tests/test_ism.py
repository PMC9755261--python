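"""In-silico mutagenesis: window extraction, random-swap profiles, peak calls
and single-base gain/loss scans against the toy predictor."""

import numpy as np
import pytest

from lncregnet.annotation_io import GenomicInterval, reverse_complement
from lncregnet.ism import (
    ISMSProfile,
    annotate_window,
    call_isms_peaks,
    extract_tss_window,
    isms_scan,
    single_base_mutagenesis,
)
from lncregnet.synthetic import toy_predictor


class ConstantPredictor:
    def __init__(self, window_length, value=0.7):
        self.window_length = window_length
        self.value = value

    def predict(self, sequence):
        return self.value


class GCFractionPredictor:
    """Deterministic nontrivial predictor for seeding/stride contracts."""

    def __init__(self, window_length):
        self.window_length = window_length

    def predict(self, sequence):
        return (sequence.count("G") + sequence.count("C")) / len(sequence)


class TestExtractTssWindow:
    GENOME = {"c1": "ACGTACGTACGTACGTACGT"}  # 20 bp

    def test_centered_extraction(self):
        w = extract_tss_window(self.GENOME, "c1", 10, "+", 10)
        assert w == self.GENOME["c1"][5:15]
        assert w[10 // 2] == self.GENOME["c1"][10]

    def test_left_edge_padding(self):
        w = extract_tss_window(self.GENOME, "c1", 2, "+", 10)
        assert w == "NNN" + self.GENOME["c1"][:7]

    def test_minus_strand_is_reverse_complement(self):
        plus = extract_tss_window(self.GENOME, "c1", 10, "+", 10)
        minus = extract_tss_window(self.GENOME, "c1", 10, "-", 10)
        assert minus == reverse_complement(plus)

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            extract_tss_window(self.GENOME, "nope", 5, "+", 10)


class TestIsmsScan:
    def _seq(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def test_constant_predictor_gives_all_zero(self):
        seq = self._seq()
        prof = isms_scan(seq, ConstantPredictor(len(seq)), window=50, stride=10, seed=0)
        assert np.all(prof.scores == 0)
        assert prof.peaks == []

    def test_same_seed_reproduces_profile(self):
        seq = self._seq()
        p1 = isms_scan(seq, GCFractionPredictor(len(seq)), window=50, stride=10, seed=3)
        p2 = isms_scan(seq, GCFractionPredictor(len(seq)), window=50, stride=10, seed=3)
        assert np.array_equal(p1.scores, p2.scores)

    def test_stride_profile_subsamples_stride_one(self):
        """Per-offset seeding: larger strides subsample, never reshuffle."""
        seq = self._seq(200)
        pred = GCFractionPredictor(len(seq))
        fine = isms_scan(seq, pred, window=20, stride=1, seed=5)
        coarse = isms_scan(seq, pred, window=20, stride=7, seed=5)
        lookup = dict(zip(fine.positions.tolist(), fine.scores))
        for pos, score in zip(coarse.positions.tolist(), coarse.scores):
            assert score == lookup[pos]

    def test_shift_invariance_of_predictor_output(self):
        """ISMS only sees |delta f|, so adding a constant changes nothing."""
        seq = self._seq(300)

        class Shifted(GCFractionPredictor):
            def predict(self, sequence):
                return super().predict(sequence) + 0.123

        base = isms_scan(seq, GCFractionPredictor(len(seq)), window=30, stride=10, seed=1)
        shifted = isms_scan(seq, Shifted(len(seq)), window=30, stride=10, seed=1)
        assert np.allclose(base.scores, shifted.scores)

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError):
            isms_scan("ACGT" * 10, ConstantPredictor(99), window=10, seed=0)


def make_profile(scores, stride=1):
    scores = np.asarray(scores, dtype=float)
    positions = np.arange(scores.size) * stride
    prof = ISMSProfile(
        tss=None, window_size=10, stride=stride, positions=positions,
        scores=scores, reference_score=0.5,
        z=np.zeros_like(scores), peaks=[], seed=0,
    )
    sd = scores.std()
    prof.z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    return prof


class TestPeakCalling:
    def test_flat_profile_has_no_peaks(self):
        prof = make_profile([1.0] * 50)
        with pytest.warns(UserWarning):
            assert call_isms_peaks(prof) == []

    def test_single_spike_single_position_peak(self):
        scores = [0.0] * 60
        scores[30] = 5.0
        prof = make_profile(scores)
        assert call_isms_peaks(prof) == [(30, 31)]

    def test_two_distant_spikes_give_two_peaks(self):
        scores = np.zeros(1200)
        scores[100:110] = 4.0
        scores[600:605] = 4.0
        prof = make_profile(scores, stride=10)
        peaks = call_isms_peaks(prof)
        assert peaks == [(1000, 1100), (6000, 6050)]


class TestSingleBaseMutagenesis:
    def test_insensitive_positions_score_zero(self):
        seq = "ACGT" * 25
        prof = single_base_mutagenesis(seq, ConstantPredictor(len(seq)), (10, 20))
        assert np.all(prof.gain == 0) and np.all(prof.loss == 0)

    def test_gain_never_below_loss(self):
        seq = "ACGT" * 25
        prof = single_base_mutagenesis(seq, GCFractionPredictor(len(seq)), (0, 40))
        assert np.all(prof.gain >= prof.loss)

    def test_region_bounds_enforced(self):
        seq = "ACGT" * 10
        with pytest.raises(ValueError):
            single_base_mutagenesis(seq, ConstantPredictor(len(seq)), (30, 50))

    def test_planted_motif_positions_carry_the_loss(self, dataset):
        pwm = dataset.motifs[0]
        rng = np.random.default_rng(0)
        L = 501
        seq = list("ACGT"[i] for i in rng.integers(0, 4, L))
        start = L // 2 - pwm.length // 2
        seq[start : start + pwm.length] = pwm.consensus()
        seq = "".join(seq)
        pred = toy_predictor([pwm], L, receptive_field=200)
        prof = single_base_mutagenesis(seq, pred, (start - 10, start + pwm.length + 10))
        in_footprint = (prof.positions >= start) & (prof.positions < start + pwm.length)
        assert np.all(prof.loss[in_footprint] < 0)
        assert np.all(prof.loss[~in_footprint] == 0)
        # the largest disruption sits inside the motif footprint
        assert in_footprint[np.argmin(prof.loss)]


class TestPlantedMotifRecovery:
    def test_profile_argmax_lands_on_planted_instance(self, dataset):
        motif_id, chrom, pos, _ = dataset.manifest.motif_instances[0]
        L, window, stride = 6001, 300, 20
        seq = extract_tss_window(dataset.genome, chrom, pos + 9, "+", L)
        pred = toy_predictor(dataset.motifs, L, receptive_field=2500)
        prof = isms_scan(seq, pred, window=window, stride=stride, seed=1)
        center = L // 2
        top = prof.positions[np.argmax(prof.scores)]
        assert center - window - 20 <= top <= center + 20

    def test_peak_recall_over_twenty_seeds(self):
        """Peaks recover a planted instance in every seed (recall 1.0)."""
        from lncregnet.synthetic import _consensus_pwm

        L, window, stride, rf = 6001, 300, 20, 2000
        recalled = 0
        spurious = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            pwm = _consensus_pwm(rng, "m", 18)
            seq = list("ACGT"[i] for i in rng.integers(0, 4, L))
            pos = L // 2 + int(rng.integers(-1400, 1400))
            seq[pos : pos + pwm.length] = pwm.consensus()
            seq = "".join(seq)
            pred = toy_predictor([pwm], L, receptive_field=rf)
            prof = isms_scan(seq, pred, window=window, stride=stride, seed=seed)
            lo, hi = pos - window, pos + pwm.length
            hit = any(s <= hi and e >= lo for s, e in prof.peaks)
            recalled += hit
            spurious += sum(1 for s, e in prof.peaks if not (s <= hi and e >= lo))
        assert recalled == 20
        # <= 1 spurious peak per 100 kb scanned (20 x ~6 kb = 120 kb)
        assert spurious <= 2


class TestAnnotateWindow:
    WINDOW = GenomicInterval("c1", 1000, 2000)

    def test_empty(self):
        assert annotate_window({}, self.WINDOW) == []

    def test_roles_and_clipping(self):
        feats = {
            "g1": ("gene", GenomicInterval("c1", 1100, 1200)),
            "tf1": ("tf", GenomicInterval("c1", 900, 1100)),  # spans the edge
            "lnc": ("lncrna", GenomicInterval("c1", 1500, 1600)),
            "far": ("gene", GenomicInterval("c1", 5000, 5100)),
        }
        recs = annotate_window(feats, self.WINDOW)
        assert [r.feature_id for r in recs] == ["tf1", "g1", "lnc"]
        by_id = {r.feature_id: r for r in recs}
        assert by_id["tf1"].clipped and by_id["tf1"].interval.start == 1000
        assert not by_id["g1"].clipped
        assert by_id["lnc"].role == "lncrna"
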