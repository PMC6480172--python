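"""Filtering, segmentation and normalization contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from cecgkit import (
    FilterSpec,
    SyntheticRecord,
    assemble_dataset,
    bandpass,
    normalize_segment,
    segment_record,
)
from cecgkit.errors import (
    InvalidBandError,
    InvalidOverlapError,
    InvalidSignalError,
    MissingAnnotationError,
    ZeroVarianceError,
)
from cecgkit.preprocess import n_segments

FS = 300.0


def analytic_gain(freq: float, spec: FilterSpec = FilterSpec()) -> float:
    """Single-pass Butterworth magnitude at one frequency (design oracle)."""
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=FS, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
    return float(np.abs(h[0]))


def measured_gain(freq: float) -> float:
    """Amplitude transfer through the zero-phase filter, by projection on a
    long probe sinusoid (the slow 0.05 Hz pole makes edge windows unusable)."""
    t = np.arange(int(120 * FS)) / FS
    probe = np.sin(2 * np.pi * freq * t)
    out = bandpass(probe, FS)
    ctr = slice(int(30 * FS), int(90 * FS))
    return float(2 * np.mean(out[ctr] * probe[ctr]))


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(np.full(90000, 7.5), FS)
        assert np.abs(out[30000:60000]).max() < 1e-6

    @pytest.mark.parametrize("freq,rtol", [(10.0, 0.05), (100.0, 0.05)])
    def test_matches_squared_analytic_response(self, freq, rtol):
        # forward-backward application squares the single-pass response
        assert measured_gain(freq) == pytest.approx(analytic_gain(freq) ** 2, rel=rtol)

    def test_output_length_preserved(self):
        x = np.random.default_rng(0).normal(size=5000)
        assert bandpass(x, FS).shape == x.shape

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidBandError):
            bandpass(np.zeros(1000), FS, FilterSpec(band=(0.05, 200.0)))

    def test_non_finite_signal_rejected(self):
        x = np.zeros(1000)
        x[10] = np.nan
        with pytest.raises(InvalidSignalError):
            bandpass(x, FS)


class TestSegmentRecord:
    def test_30min_4s_no_overlap_gives_450(self):
        segs = segment_record(np.zeros(int(30 * 60 * FS)), FS, 4.0, 0.0)
        assert len(segs) == 450

    def test_30min_4s_half_overlap_gives_899(self):
        segs = segment_record(np.zeros(int(30 * 60 * FS)), FS, 4.0, 0.5)
        assert len(segs) == 899

    def test_short_signal_gives_empty_list(self):
        assert segment_record(np.zeros(100), FS, 4.0, 0.5) == []

    def test_segments_are_exact_signal_slices(self):
        x = np.random.default_rng(1).normal(size=4000)
        for seg in segment_record(x, FS, 2.0, 0.5):
            assert np.array_equal(seg.samples, x[seg.start_index:seg.start_index + 600])

    def test_zero_step_rejected(self):
        with pytest.raises(InvalidOverlapError):
            segment_record(np.zeros(5000), FS, 4.0, 0.99999)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(n=st.integers(0, 10_000), window=st.integers(1, 1200),
           step=st.integers(1, 1200))
    def test_count_formula_matches_enumeration(self, n, window, step):
        step = min(step, window)
        brute = sum(1 for start in range(0, max(n, 1), step) if start + window <= n)
        assert n_segments(n, window, step) == brute


class TestNormalizeSegment:
    def test_hand_computed_example(self):
        out = normalize_segment([1.0, 2.0, 3.0])
        assert np.allclose(out, [-1.224744871, 0.0, 1.224744871])
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, rng):
        x = rng.normal(size=600)
        z = normalize_segment(x)
        assert np.allclose(normalize_segment(z), z, atol=1e-9)

    def test_constant_segment_rejected(self):
        with pytest.raises(ZeroVarianceError):
            normalize_segment(np.full(600, 3.3))


def _single_interval_record(duration_s: float, quality="C1", position="S", seed=5):
    from cecgkit.simulate import DEFAULT_PROFILES, DEFAULT_QUALITY_SPECS, DEFAULT_TEMPLATE, degrade, render_position
    clean = render_position(DEFAULT_TEMPLATE, DEFAULT_PROFILES[position], FS,
                            duration_s, 60, 0.02, seed)
    samples = degrade(clean, DEFAULT_QUALITY_SPECS[quality], FS, seed)
    return SyntheticRecord(samples=samples, fs=FS, heart_rate_series=np.array([60.0]),
                           truth_intervals=[(0.0, duration_s, quality, position)],
                           seed=seed, record_id="test")


class TestAssembleDataset:
    def test_60s_interval_yields_29_labeled_segments(self):
        rec = _single_interval_record(60.0)
        ds = assemble_dataset([rec], seg_len_s=4.0, overlap_frac=0.5)
        assert len(ds) == 29
        assert all(q == "C1" for q in ds.quality)
        assert all(p == "S" for p in ds.position)
        assert ds.class_counts == {("C1", "S"): 29}

    def test_segment_samples_come_from_filtered_record(self):
        rec = _single_interval_record(30.0)
        ds = assemble_dataset([rec], seg_len_s=4.0, overlap_frac=0.5)
        filtered = bandpass(rec.samples, FS)
        seg0 = filtered[ds.start_indices[0]:ds.start_indices[0] + 1200]
        assert np.allclose(ds.X[0], normalize_segment(seg0), atol=1e-5)

    def test_straddling_segments_discarded(self):
        rec = _single_interval_record(30.0)
        # alternate labels every 3 s: no 4 s window fits inside one interval
        rec.truth_intervals = [(i * 3.0, (i + 1) * 3.0, "C1" if i % 2 else "C2", "S")
                               for i in range(10)]
        ds = assemble_dataset([rec], seg_len_s=4.0, overlap_frac=0.5)
        assert len(ds) == 0
        assert ds.n_discarded_straddling > 0

    def test_zero_variance_segments_excluded_and_counted(self):
        rec = _single_interval_record(30.0)
        rec.samples = np.zeros_like(rec.samples)
        ds = assemble_dataset([rec], seg_len_s=4.0, overlap_frac=0.5)
        assert len(ds) == 0
        assert ds.n_discarded_zero_variance == 14

    def test_noise_segments_carry_no_position_label(self):
        rec = _single_interval_record(30.0, quality="N", position="L")
        ds = assemble_dataset([rec], seg_len_s=4.0, overlap_frac=0.5)
        assert all(q == "N" for q in ds.quality)
        assert all(p is None for p in ds.position)

    def test_unlabeled_record_rejected_without_flag(self):
        rec = _single_interval_record(30.0)
        rec.truth_intervals = []
        with pytest.raises(MissingAnnotationError):
            assemble_dataset([rec], seg_len_s=4.0)
        ds = assemble_dataset([rec], seg_len_s=4.0, allow_unlabeled=True)
        assert len(ds) == 14
        assert all(q is None for q in ds.quality)
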