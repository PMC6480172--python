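"""Synthetic capacitive-ECG generator with labeled quality and position.

Real bed-sensor cECG recordings are not publicly deposited, so every
downstream stage of the package (preprocessing, CNN training, the
hierarchical annotator) is exercised against simulated records whose
ground truth is known by construction.  The generator emulates the two
properties that make cECG hard:

* **position-dependent morphology** — the cardiac dipole projected onto
  the bed-electrode axis changes with body orientation, so the waveform
  gain, polarity and relative wave amplitudes differ between supine (S),
  left-lateral (L) and right-lateral (R) positions, with the L projection
  yielding the smallest amplitude;
* **abruptly varying signal quality** — segments fall into three classes:
  C1 (clear waveform), C2 (blurry waveform whose R peaks remain clear)
  and N (noise dominating the ECG).

Beats are synthesised as a sum of five Gaussian bumps (P, Q, R, S, T), a
standard dynamical-template approach for ECG simulation; degradation adds
broadband Gaussian noise, sinusoid-plus-random-walk baseline wander,
Poisson-timed movement-artifact bursts, and spectral attenuation of the
P/T (low-band) versus QRS (high-band) content.

All randomness flows from a single root seed through
``numpy.random.SeedSequence.spawn``, so each record is independently and
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import (
    CapacityError,
    InvalidLabelError,
    InvalidParameterError,
    InvalidTemplateError,
)

__all__ = [
    "WaveParams",
    "BeatTemplate",
    "PositionProfile",
    "QualitySpec",
    "SyntheticRecord",
    "GeneratorConfig",
    "synth_beat",
    "render_position",
    "degrade",
    "generate_dataset",
    "segment_snr_db",
    "DEFAULT_TEMPLATE",
    "DEFAULT_PROFILES",
    "DEFAULT_QUALITY_SPECS",
    "study_cell_counts",
    "GENERATOR_VERSION",
]

GENERATOR_VERSION = "cecgkit-synth-1.0"

QUALITY_CLASSES = ("C1", "C2", "N")
POSITIONS = ("S", "L", "R")
WAVES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian bump of the PQRST template.

    amplitude is in signal units; phase_center and width are fractions of
    the beat duration.
    """

    amplitude: float
    phase_center: float
    width: float


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-sum PQRST morphology.

    Invariants: the R wave has the largest |amplitude|; phase centers are
    strictly increasing P < Q < R < S < T; widths are positive.
    """

    waves: dict[str, WaveParams]

    def __post_init__(self) -> None:
        missing = set(WAVES) - set(self.waves)
        if missing:
            raise InvalidTemplateError(f"template missing waves: {sorted(missing)}")
        amps = {w: abs(self.waves[w].amplitude) for w in WAVES}
        if any(amps[w] > amps["R"] for w in WAVES if w != "R"):
            raise InvalidTemplateError("R wave must have the largest |amplitude|")
        centers = [self.waves[w].phase_center for w in WAVES]
        if not all(0 <= c < 1 for c in centers):
            raise InvalidTemplateError("phase centers must lie in [0, 1)")
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise InvalidTemplateError("phase centers must be strictly increasing P<Q<R<S<T")
        if any(self.waves[w].width <= 0 for w in WAVES):
            raise InvalidTemplateError("wave widths must be > 0")

    def modulated(self, wave_modulation: dict[str, float]) -> "BeatTemplate":
        """Return a copy with per-wave amplitudes multiplied."""
        waves = {
            w: replace(p, amplitude=p.amplitude * wave_modulation.get(w, 1.0))
            for w, p in self.waves.items()
        }
        return BeatTemplate(waves)

    @property
    def r_phase(self) -> float:
        return self.waves["R"].phase_center


#: Generic adult PQRST morphology in arbitrary signal units (R wave ~1).
DEFAULT_TEMPLATE = BeatTemplate(
    {
        "P": WaveParams(0.15, 0.18, 0.025),
        "Q": WaveParams(-0.12, 0.36, 0.010),
        "R": WaveParams(1.00, 0.40, 0.012),
        "S": WaveParams(-0.25, 0.44, 0.010),
        "T": WaveParams(0.35, 0.65, 0.045),
    }
)


@dataclass(frozen=True)
class PositionProfile:
    """How one sleep position projects the cardiac dipole onto the electrode.

    ``gain`` scales the whole beat, ``polarity`` flips it, and
    ``wave_modulation`` rescales individual waves.  The left-lateral
    projection is the weakest, so gain(L) < gain(S) and gain(L) < gain(R).
    """

    position: str
    gain: float
    polarity: int
    wave_modulation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise InvalidLabelError(f"unknown position {self.position!r}; expected one of {POSITIONS}")
        if self.polarity not in (+1, -1):
            raise InvalidParameterError("polarity must be +1 or -1")
        if self.gain <= 0:
            raise InvalidParameterError("gain must be > 0")


#: Default projections: supine is the reference; right-lateral keeps the
#: polarity but slightly shrinks the slow P/T waves; left-lateral is weak
#: and inverted. Config values, not physical constants.
DEFAULT_PROFILES: dict[str, PositionProfile] = {
    "S": PositionProfile("S", gain=1.0, polarity=+1),
    "R": PositionProfile("R", gain=0.9, polarity=+1, wave_modulation={"P": 0.8, "T": 0.8}),
    "L": PositionProfile("L", gain=0.35, polarity=-1),
}


@dataclass(frozen=True)
class QualitySpec:
    """Degradation recipe for one signal-quality class.

    broadband_noise_sd: white Gaussian noise, signal units.
    baseline_wander: (amplitude, frequency Hz) sinusoid plus a matched
        random-walk component.
    artifact_burst: (rate events/s, amplitude) of Poisson-timed
        movement-artifact bursts.
    waveform_attenuation: per-wave multipliers, applied spectrally
        (P/T -> low band below the split frequency, Q/R/S -> high band).
    """

    quality_class: str
    broadband_noise_sd: float = 0.0
    baseline_wander: tuple[float, float] = (0.0, 0.3)
    artifact_burst: tuple[float, float] = (0.0, 0.0)
    waveform_attenuation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.quality_class not in QUALITY_CLASSES:
            raise InvalidLabelError(
                f"unknown quality class {self.quality_class!r}; expected one of {QUALITY_CLASSES}"
            )
        if self.broadband_noise_sd < 0:
            raise InvalidParameterError("broadband_noise_sd must be >= 0")
        if self.baseline_wander[0] < 0 or self.baseline_wander[1] < 0:
            raise InvalidParameterError("baseline wander amplitude/frequency must be >= 0")
        if self.artifact_burst[0] < 0 or self.artifact_burst[1] < 0:
            raise InvalidParameterError("artifact burst rate/amplitude must be >= 0")
        if any(v < 0 for v in self.waveform_attenuation.values()):
            raise InvalidParameterError("waveform attenuation must be >= 0")


#: Default recipes. C1 leaves the waveform essentially intact; C2 blurs the
#: P and T waves and adds visible noise but keeps R peaks well above the
#: noise floor; N drowns the (strongly attenuated) ECG in noise.
DEFAULT_QUALITY_SPECS: dict[str, QualitySpec] = {
    "C1": QualitySpec("C1", broadband_noise_sd=0.008, baseline_wander=(0.012, 0.25)),
    "C2": QualitySpec(
        "C2",
        broadband_noise_sd=0.08,
        baseline_wander=(0.15, 0.30),
        artifact_burst=(0.10, 0.30),
        waveform_attenuation={"P": 0.3, "Q": 0.8, "R": 1.0, "S": 0.8, "T": 0.25},
    ),
    "N": QualitySpec(
        "N",
        broadband_noise_sd=0.50,
        baseline_wander=(0.80, 0.40),
        artifact_burst=(1.0, 1.5),
        waveform_attenuation={w: 0.25 for w in WAVES},
    ),
}


@dataclass
class SyntheticRecord:
    """A simulated single-channel cECG record with interval ground truth.

    truth_intervals is a list of (start_s, end_s, quality, position); the
    position of an N interval is retained for bookkeeping but is flagged
    position-uninformative downstream.  ``clean`` and ``noise`` keep the
    additive decomposition used by SNR oracles; ``samples = clean + noise``
    up to the spectral attenuation stage.
    """

    samples: np.ndarray
    fs: float
    heart_rate_series: np.ndarray
    truth_intervals: list[tuple[float, float, str, str]]
    seed: int
    record_id: str = "synth"
    generator_version: str = GENERATOR_VERSION
    clean: np.ndarray | None = None
    noise: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def synth_beat(template: BeatTemplate, fs: float, beat_duration: float) -> np.ndarray:
    """Render one beat as a sum of five Gaussian bumps.

    Returns ``round(fs * beat_duration)`` samples; deterministic.
    """
    if beat_duration <= 0:
        raise InvalidParameterError("beat_duration must be > 0")
    n = int(round(fs * beat_duration))
    if n < 10:
        raise InvalidParameterError("fs * beat_duration must be >= 10 samples")
    t = np.arange(n) / fs
    beat = np.zeros(n)
    for w in WAVES:
        p = template.waves[w]
        center = p.phase_center * beat_duration
        width = p.width * beat_duration
        beat += p.amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)
    return beat


def render_position(
    template: BeatTemplate,
    profile: PositionProfile,
    fs: float,
    duration: float,
    heart_rate: float,
    rr_jitter_sd: float = 0.0,
    rng_seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Concatenate jittered beats scaled by a sleep-position projection.

    Each beat lasts one RR interval, drawn as 60/heart_rate plus Gaussian
    jitter (s), and is scaled by ``polarity * gain`` with per-wave
    modulation.  The output is trimmed/padded to ``round(fs*duration)``
    samples.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if not 30 <= heart_rate <= 220:
        raise InvalidParameterError("heart_rate must lie in [30, 220] bpm")
    rng = np.random.default_rng(rng_seed)
    shaped = template.modulated(profile.wave_modulation)
    n_total = int(round(fs * duration))
    mean_rr = 60.0 / heart_rate
    chunks: list[np.ndarray] = []
    n_done = 0
    while n_done < n_total:
        rr = mean_rr + (rng.normal(0.0, rr_jitter_sd) if rr_jitter_sd > 0 else 0.0)
        rr = max(rr, 60.0 / 220.0)
        beat = synth_beat(shaped, fs, rr)
        chunks.append(beat)
        n_done += beat.size
    out = np.concatenate(chunks)[:n_total]
    return profile.polarity * profile.gain * out


_PT_QRS_SPLIT_HZ = 5.0  # boundary between slow (P/T) and QRS spectral content; the
# narrow R bump keeps ~3/4 of its peak above 5 Hz while the broad T wave sits below


def _band_split(x: np.ndarray, fs: float, split_hz: float = _PT_QRS_SPLIT_HZ):
    """Zero-phase 4th-order Butterworth low/high split of a signal."""
    sos = sps.butter(4, split_hz, btype="low", fs=fs, output="sos")
    low = sps.sosfiltfilt(sos, x)
    return low, x - low


def degrade(
    clean: np.ndarray,
    spec: QualitySpec,
    fs: float,
    rng_seed: int | np.random.SeedSequence = 0,
    return_parts: bool = False,
):
    """Degrade a clean cECG according to a quality recipe.

    Applies, in order: spectral per-wave attenuation (P/T band scaled by
    the mean of the P and T multipliers, QRS band by the mean of Q, R, S),
    then additive broadband noise, baseline wander (sinusoid at a random
    phase plus a variance-matched random walk) and Poisson-timed artifact
    bursts (Gaussian-windowed oscillations).  Reproducible from the seed.

    With ``return_parts=True`` also returns the attenuated clean component
    and the total additive noise, for SNR ground truth.
    """
    clean = np.asarray(clean, dtype=float)
    if not np.all(np.isfinite(clean)):
        raise InvalidParameterError("clean signal must be finite-valued")
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    rng = np.random.default_rng(rng_seed)
    n = clean.size
    t = np.arange(n) / fs

    att = spec.waveform_attenuation
    if att:
        a_low = (att.get("P", 1.0) + att.get("T", 1.0)) / 2.0
        a_high = (att.get("Q", 1.0) + att.get("R", 1.0) + att.get("S", 1.0)) / 3.0
        if a_low == a_high:
            ecg = a_low * clean
        else:
            low, high = _band_split(clean, fs)
            ecg = a_low * low + a_high * high
    else:
        ecg = clean.copy()

    noise = np.zeros(n)
    if spec.broadband_noise_sd > 0:
        noise += rng.normal(0.0, spec.broadband_noise_sd, n)
    bw_amp, bw_freq = spec.baseline_wander
    if bw_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noise += bw_amp * np.sin(2 * np.pi * bw_freq * t + phase)
        # random-walk drift scaled to the same RMS as the sinusoid
        walk = np.cumsum(rng.normal(0.0, 1.0, n))
        walk -= walk.mean()
        rms = np.sqrt(np.mean(walk**2))
        if rms > 0:
            noise += (bw_amp / np.sqrt(2.0)) * walk / rms
    burst_rate, burst_amp = spec.artifact_burst
    if burst_rate > 0 and burst_amp > 0:
        n_bursts = rng.poisson(burst_rate * n / fs)
        for _ in range(n_bursts):
            center = rng.uniform(0, n / fs)
            width = rng.uniform(0.05, 0.3)  # s
            osc_f = rng.uniform(2.0, 12.0)  # Hz
            env = np.exp(-0.5 * ((t - center) / width) ** 2)
            noise += burst_amp * env * np.sin(2 * np.pi * osc_f * (t - center))

    out = ecg + noise
    if return_parts:
        return out, ecg, noise
    return out


def segment_snr_db(clean: np.ndarray, noise: np.ndarray) -> float:
    """Ground-truth SNR (dB) of a degraded stretch from its decomposition."""
    p_sig = float(np.mean(np.asarray(clean) ** 2))
    p_noise = float(np.mean(np.asarray(noise) ** 2))
    if p_noise == 0:
        return np.inf
    return 10.0 * np.log10(p_sig / max(p_noise, 1e-300))


#: Segment counts of the 4-s study dataset, per (quality, position).
_STUDY_4S_COUNTS = {
    ("C1", "L"): 928, ("C1", "R"): 1144, ("C1", "S"): 1903,
    ("C2", "L"): 583, ("C2", "R"): 335, ("C2", "S"): 170,
    ("N", "L"): 845, ("N", "R"): 73, ("N", "S"): 569,
}


def study_cell_counts(total: int = 600) -> dict[tuple[str, str], int]:
    """Scale the study's 4-s per-cell segment counts to ~``total`` segments.

    Largest-remainder rounding, so the returned counts sum exactly to
    ``total`` (cells that would round to 0 are kept at >= 1).
    """
    grand = sum(_STUDY_4S_COUNTS.values())
    raw = {k: total * v / grand for k, v in _STUDY_4S_COUNTS.items()}
    counts = {k: max(1, int(np.floor(r))) for k, r in raw.items()}
    remainders = sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)
    i = 0
    while sum(counts.values()) < total:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    return counts


@dataclass
class GeneratorConfig:
    """Study conditions for dataset generation.

    counts maps (quality, position) to the number of segments the cell
    must yield after downstream segmentation with ``seg_len_s`` windows
    and ``overlap_frac`` overlap.  Each cell is spread over
    ``records_per_cell`` records, and the j-th record of every cell uses
    ``heart_rates[j % len(heart_rates)]`` — a balanced design, so heart
    rate carries no information about quality or position and the
    classifiers must rely on waveform morphology.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=study_cell_counts)
    fs: float = 300.0
    seg_len_s: float = 4.0
    overlap_frac: float = 0.5
    records_per_cell: int = 3
    heart_rates: tuple[float, ...] = (58.0, 66.0, 74.0)
    rr_jitter_sd: float = 0.02
    max_record_s: float = 3600.0
    template: BeatTemplate = field(default_factory=lambda: DEFAULT_TEMPLATE)
    profiles: dict[str, PositionProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    quality_specs: dict[str, QualitySpec] = field(default_factory=lambda: dict(DEFAULT_QUALITY_SPECS))


def _record_duration_s(n_segments: int, cfg: GeneratorConfig) -> float:
    """Duration that yields exactly ``n_segments`` sliding windows."""
    win = int(round(cfg.fs * cfg.seg_len_s))
    step = int(round(win * (1.0 - cfg.overlap_frac)))
    return ((n_segments - 1) * step + win) / cfg.fs


def generate_dataset(config: GeneratorConfig, seed: int = 0) -> list[SyntheticRecord]:
    """Generate labeled records covering every requested (quality, position) cell.

    Each record carries a single truth interval spanning its whole extent,
    so downstream segmentation yields exactly the requested per-cell
    segment counts.  Per-record seeds are spawned from the root seed with
    ``SeedSequence.spawn``; the same (config, seed) produces bitwise
    identical sample streams.
    """
    if any(v < 0 for v in config.counts.values()):
        raise InvalidParameterError("requested counts must be >= 0")
    if not any(v > 0 for v in config.counts.values()):
        raise InvalidParameterError("at least one (quality, position) count must be > 0")

    cells = sorted((k, v) for k, v in config.counts.items() if v > 0)
    n_records = sum(min(config.records_per_cell, v) for _, v in cells)
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_records)

    records: list[SyntheticRecord] = []
    child_i = 0
    for (quality, position), n_seg in cells:
        if quality not in config.quality_specs:
            raise InvalidLabelError(f"no quality spec for {quality!r}")
        if position not in config.profiles:
            raise InvalidLabelError(f"no position profile for {position!r}")
        n_rec = min(config.records_per_cell, n_seg)
        base, extra = divmod(n_seg, n_rec)
        for j in range(n_rec):
            n_seg_rec = base + (1 if j < extra else 0)
            dur = _record_duration_s(n_seg_rec, config)
            if dur > config.max_record_s:
                raise CapacityError(
                    f"cell ({quality},{position}) needs a {dur:.0f}s record, "
                    f"cap is {config.max_record_s:.0f}s"
                )
            ss = children[child_i]
            child_i += 1
            hr = config.heart_rates[j % len(config.heart_rates)]
            render_ss, degrade_ss = ss.spawn(2)
            clean = render_position(
                config.template,
                config.profiles[position],
                config.fs,
                dur,
                heart_rate=hr,
                rr_jitter_sd=config.rr_jitter_sd,
                rng_seed=render_ss,
            )
            samples, ecg, noise = degrade(
                clean, config.quality_specs[quality], config.fs, rng_seed=degrade_ss,
                return_parts=True,
            )
            records.append(
                SyntheticRecord(
                    samples=samples,
                    fs=config.fs,
                    heart_rate_series=np.full(1, hr),
                    truth_intervals=[(0.0, dur, quality, position)],
                    seed=seed,
                    record_id=f"{quality}-{position}-{j:02d}",
                    clean=ecg,
                    noise=noise,
                )
            )
    return records
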