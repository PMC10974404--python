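"""Ratio feature extraction: windowing, AC/DC read-out, ratio identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoppg import (
    ACDCPair,
    DegenerateChannelError,
    NoiseConfig,
    Signal1D,
    SubjectRecord,
    UnusableRecordError,
    build_feature_vector,
    compute_ratios,
    extract_ac_dc,
    feature_labels,
    generate_ppg,
    pulse_waveform,
    segment_windows,
    theoretical_ratio_vector,
)
from hemoppg.features import Standardizer

FS = 100.0


class TestWindowing:
    @pytest.mark.parametrize("duration, expected", [(120, 24), (7, 1), (4, 0)])
    def test_window_counts(self, duration, expected):
        x = Signal1D(np.zeros(int(duration * FS)), FS)
        wins = segment_windows(x, win_len=5.0)
        assert len(wins) == expected
        assert all(len(w) == 500 for w in wins)


def _pulse_train(duration=5.0, dc=2.0, ac=0.1, rate_hz=1.2):
    t = np.arange(int(duration * FS)) / FS
    return dc + ac * pulse_waveform(t * rate_hz)


class TestExtractAcDc:
    def test_constructed_amplitudes_recovered(self):
        w = _pulse_train()
        pair = extract_ac_dc(w, w, FS)
        assert pair is not None
        assert pair.ac == pytest.approx(0.1, rel=0.05)
        assert pair.dc == pytest.approx(2.0 + 0.1 * np.mean(pulse_waveform(
            np.arange(500) / FS * 1.2)), rel=0.01)

    def test_constant_window_is_invalid(self):
        w = np.full(500, 3.0)
        assert extract_ac_dc(w, w, FS) is None

    def test_homogeneity(self):
        w = _pulse_train()
        p1 = extract_ac_dc(w, w, FS)
        p2 = extract_ac_dc(4.0 * w, 4.0 * w, FS)
        assert p2.ac == pytest.approx(4.0 * p1.ac, rel=1e-9)
        assert p2.dc == pytest.approx(4.0 * p1.dc, rel=1e-9)
        assert p2.perfusion == pytest.approx(p1.perfusion, rel=1e-9)


class TestComputeRatios:
    def test_identical_perfusion_gives_all_ones(self):
        pairs = [ACDCPair(0.02, 1.0, w) for w in range(8)]
        np.testing.assert_allclose(compute_ratios(pairs), 1.0)

    def test_pairwise_arithmetic(self):
        perf = [0.02, 0.04] + [0.03] * 6
        pairs = [ACDCPair(p, 1.0, w) for w, p in enumerate(perf)]
        ratios = compute_ratios(pairs)
        assert ratios[0] == pytest.approx(0.5)    # R_12
        assert ratios[7] == pytest.approx(2.0)    # R_21
        assert ratios.size == 56

    def test_zero_ac_channel_rejected(self):
        pairs = [ACDCPair(0.02, 1.0, w) for w in range(7)]
        pairs.append(ACDCPair(0.0, 1.0, 7))
        with pytest.raises(DegenerateChannelError):
            compute_ratios(pairs)

    @settings(max_examples=20, deadline=None)
    @given(perf=st.lists(st.floats(1e-4, 0.5), min_size=8, max_size=8))
    def test_reciprocity_always_holds(self, perf):
        pairs = [ACDCPair(p, 1.0, w) for w, p in enumerate(perf)]
        r = compute_ratios(pairs)
        from hemoppg import ordered_pairs
        idx = {pq: k for k, pq in enumerate(ordered_pairs(8))}
        for i in range(8):
            for j in range(i + 1, 8):
                assert r[idx[(i, j)]] * r[idx[(j, i)]] == pytest.approx(1.0, abs=1e-9)


class TestFeatureVector:
    def test_noiseless_record_matches_theory(self, state_normal, optics):
        ppg = generate_ppg(state_normal, optics, NoiseConfig.noiseless(),
                           duration=30, seed=2)
        rec = SubjectRecord("s", ppg, age=33.0, gender=0, hb_ref=14.0)
        fv = build_feature_vector(rec)
        np.testing.assert_allclose(
            fv.ratios, theoretical_ratio_vector(state_normal, optics), rtol=0.02
        )

    def test_vector_layout(self, clean_record):
        fv = build_feature_vector(clean_record)
        vals = fv.values
        assert vals.shape == (58,)
        assert vals[56] == clean_record.age
        assert vals[57] == float(clean_record.gender)
        labels = feature_labels(clean_record.ppg.wavelengths)
        assert labels[0] == "R_610_630" and labels[-2:] == ["age", "gender"]

    def test_constant_channels_unusable(self, optics):
        from hemoppg.synth import MultiChannelPPG
        ppg = MultiChannelPPG(np.ones((3000, 8)), FS, optics.wavelengths)
        rec = SubjectRecord("flat", ppg, age=30.0, gender=1, hb_ref=12.0)
        with pytest.raises(UnusableRecordError):
            build_feature_vector(rec)

    def test_intensity_invariance(self, state_normal, optics):
        """Scaling one channel's raw intensity must leave every ratio alone."""
        ppg = generate_ppg(state_normal, optics, NoiseConfig.noiseless(),
                           duration=30, seed=4)
        rec = SubjectRecord("a", ppg, age=50.0, gender=1, hb_ref=14.0)
        fv_a = build_feature_vector(rec)
        scaled = ppg.channels.copy()
        scaled[:, 2] *= 3.7
        from hemoppg.synth import MultiChannelPPG
        rec_b = SubjectRecord(
            "b", MultiChannelPPG(scaled, ppg.fs, ppg.wavelengths),
            age=50.0, gender=1, hb_ref=14.0,
        )
        fv_b = build_feature_vector(rec_b)
        np.testing.assert_allclose(fv_b.ratios, fv_a.ratios, rtol=1e-6)


class TestStandardizer:
    def test_zero_variance_column_passes_through(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        Z = Standardizer().fit_transform(X)
        assert Z[:, 0].std() == pytest.approx(1.0)
        np.testing.assert_allclose(Z[:, 1], 0.0)
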