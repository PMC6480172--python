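"""Synthetic cECG generator: beat synthesis, projections, degradation, datasets."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import find_peaks

from cecgkit import (
    BeatTemplate,
    GeneratorConfig,
    QualitySpec,
    WaveParams,
    degrade,
    generate_dataset,
    render_position,
    segment_record,
    synth_beat,
)
from cecgkit.errors import (
    CapacityError,
    InvalidLabelError,
    InvalidParameterError,
    InvalidTemplateError,
)
from cecgkit.simulate import (
    DEFAULT_PROFILES,
    DEFAULT_QUALITY_SPECS,
    DEFAULT_TEMPLATE,
    _band_split,
    segment_snr_db,
    study_cell_counts,
)

FS = 300.0


class TestBeatTemplate:
    def test_r_wave_must_dominate(self):
        waves = {w: dataclasses.replace(p) for w, p in DEFAULT_TEMPLATE.waves.items()}
        waves["T"] = WaveParams(2.0, 0.65, 0.045)
        with pytest.raises(InvalidTemplateError):
            BeatTemplate(waves)

    def test_phase_centers_must_increase(self):
        waves = dict(DEFAULT_TEMPLATE.waves)
        waves["Q"] = WaveParams(-0.12, 0.50, 0.01)  # Q after R
        with pytest.raises(InvalidTemplateError):
            BeatTemplate(waves)


class TestSynthBeat:
    def test_zero_amplitudes_give_zero_vector(self):
        waves = {w: WaveParams(0.0, p.phase_center, p.width)
                 for w, p in DEFAULT_TEMPLATE.waves.items()}
        # relax the R-dominance check by building waves directly with equal zeros
        beat = synth_beat(BeatTemplate(waves), FS, 1.0)
        assert beat.shape == (300,)
        assert np.all(beat == 0)

    def test_length_and_r_peak_location(self):
        beat = synth_beat(DEFAULT_TEMPLATE, FS, 1.0)
        assert len(beat) == 300
        assert beat.argmax() == round(DEFAULT_TEMPLATE.waves["R"].phase_center * 300)

    def test_deterministic(self):
        a = synth_beat(DEFAULT_TEMPLATE, FS, 0.8)
        b = synth_beat(DEFAULT_TEMPLATE, FS, 0.8)
        assert np.array_equal(a, b)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth_beat(DEFAULT_TEMPLATE, 8.0, 1.0)


class TestRenderPosition:
    def test_left_lateral_amplitude_is_minimal(self):
        amps = {}
        for pos in "SLR":
            sig = render_position(DEFAULT_TEMPLATE, DEFAULT_PROFILES[pos], FS,
                                  duration=10, heart_rate=60, rr_jitter_sd=0.0,
                                  rng_seed=1)
            amps[pos] = np.ptp(sig)
        assert amps["L"] < amps["S"]
        assert amps["L"] < amps["R"]

    def test_amplitude_ordering_across_seeds(self):
        for seed in range(20):
            sigs = {pos: render_position(DEFAULT_TEMPLATE, DEFAULT_PROFILES[pos], FS,
                                         8, 65, 0.03, seed) for pos in "SLR"}
            assert np.ptp(sigs["L"]) < min(np.ptp(sigs["S"]), np.ptp(sigs["R"]))

    def test_polarity_flip_negates_signal(self):
        plus = dataclasses.replace(DEFAULT_PROFILES["S"], polarity=+1)
        minus = dataclasses.replace(DEFAULT_PROFILES["S"], polarity=-1)
        a = render_position(DEFAULT_TEMPLATE, plus, FS, 5, 60, 0.0, 3)
        b = render_position(DEFAULT_TEMPLATE, minus, FS, 5, 60, 0.0, 3)
        assert np.array_equal(a, -b)

    def test_beat_count_and_spacing_without_jitter(self):
        sig = render_position(DEFAULT_TEMPLATE, DEFAULT_PROFILES["S"], FS,
                              duration=10, heart_rate=60, rr_jitter_sd=0.0, rng_seed=0)
        peaks, _ = find_peaks(sig, height=0.5 * sig.max(), distance=FS / 3)
        assert len(peaks) == 10
        assert np.all(np.diff(peaks) == 300)

    def test_invalid_heart_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            render_position(DEFAULT_TEMPLATE, DEFAULT_PROFILES["S"], FS, 5, 500)

    def test_unknown_position_label_rejected(self):
        with pytest.raises(InvalidLabelError):
            dataclasses.replace(DEFAULT_PROFILES["S"], position="prone")


@pytest.fixture(scope="module")
def clean_supine():
    return render_position(DEFAULT_TEMPLATE, DEFAULT_PROFILES["S"], FS, 10, 60, 0.0, 1)


class TestDegrade:
    def test_identity_when_all_terms_off(self, clean_supine):
        spec = QualitySpec("C1", broadband_noise_sd=0.0, baseline_wander=(0.0, 0.3),
                           artifact_burst=(0.0, 0.0),
                           waveform_attenuation={w: 1.0 for w in "PQRST"})
        out = degrade(clean_supine, spec, FS, 0)
        assert np.allclose(out, clean_supine)

    def test_reproducible_from_seed(self, clean_supine):
        a = degrade(clean_supine, DEFAULT_QUALITY_SPECS["C2"], FS, 9)
        b = degrade(clean_supine, DEFAULT_QUALITY_SPECS["C2"], FS, 9)
        assert np.array_equal(a, b)

    def test_c1_barely_perturbs_the_waveform(self, clean_supine):
        out = degrade(clean_supine, DEFAULT_QUALITY_SPECS["C1"], FS, 4)
        ratio = np.mean((out - clean_supine) ** 2) / np.mean(clean_supine**2)
        assert ratio < 0.10

    def test_c2_keeps_r_peaks_but_blurs_pt(self, clean_supine):
        _, ecg, _ = degrade(clean_supine, DEFAULT_QUALITY_SPECS["C2"], FS, 5,
                            return_parts=True)
        peaks, _ = find_peaks(clean_supine, height=0.5 * clean_supine.max(),
                              distance=FS / 3)
        # R-peak cross-correlation against the clean signal stays above half
        # of the clean autocorrelation at those instants
        assert np.mean(ecg[peaks] * clean_supine[peaks]) > \
            0.5 * np.mean(clean_supine[peaks] ** 2)
        low_clean, _ = _band_split(clean_supine, FS)
        low_deg, _ = _band_split(ecg, FS)
        assert np.mean(low_deg**2) < 0.5 * np.mean(low_clean**2)

    def test_noise_class_swamps_the_ecg(self, clean_supine):
        out, ecg, noise = degrade(clean_supine, DEFAULT_QUALITY_SPECS["N"], FS, 6,
                                  return_parts=True)
        assert np.var(ecg) / np.var(out) < 0.5
        assert np.mean(noise**2) > np.mean(ecg**2)

    def test_negative_noise_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            QualitySpec("N", broadband_noise_sd=-0.1)


class TestGenerateDataset:
    def test_single_cell_request(self):
        cfg = GeneratorConfig(counts={("C1", "S"): 10})
        records = generate_dataset(cfg, seed=3)
        for rec in records:
            for (_, _, q, p) in rec.truth_intervals:
                assert (q, p) == ("C1", "S")

    def test_segment_counts_match_request(self):
        counts = study_cell_counts(600)
        cfg = GeneratorConfig(counts=counts)
        records = generate_dataset(cfg, seed=3)
        got = {}
        for rec in records:
            q, p = rec.truth_intervals[0][2], rec.truth_intervals[0][3]
            n = len(segment_record(rec.samples, cfg.fs, cfg.seg_len_s, cfg.overlap_frac))
            got[(q, p)] = got.get((q, p), 0) + n
        assert sum(counts.values()) == 600
        for cell, want in counts.items():
            assert abs(got[cell] - want) <= 1

    def test_same_seed_bitwise_identical(self):
        cfg = GeneratorConfig(counts={("C2", "L"): 8, ("N", "R"): 5})
        a = generate_dataset(cfg, seed=11)
        b = generate_dataset(cfg, seed=11)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)

    def test_capacity_cap_enforced(self):
        cfg = GeneratorConfig(counts={("C1", "S"): 5000}, records_per_cell=1,
                              max_record_s=60.0)
        with pytest.raises(CapacityError):
            generate_dataset(cfg, seed=0)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_dataset(GeneratorConfig(counts={("C1", "S"): 0}), seed=0)

    def test_snr_threshold_separates_c1_from_n(self):
        """Ground-truth segment SNR separates the C1 and N classes exactly."""
        cfg = GeneratorConfig(counts={("C1", p): 10 for p in "SLR"}
                              | {("N", p): 10 for p in "SLR"}, records_per_cell=2)
        records = generate_dataset(cfg, seed=21)
        window = int(round(cfg.fs * cfg.seg_len_s))
        step = window // 2
        snrs = {"C1": [], "N": []}
        for rec in records:
            q = rec.truth_intervals[0][2]
            for lo in range(0, len(rec.samples) - window + 1, step):
                snrs[q].append(segment_snr_db(rec.clean[lo:lo + window],
                                              rec.noise[lo:lo + window]))
        assert min(snrs["C1"]) > max(snrs["N"])
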