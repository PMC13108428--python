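"""Synthetic thermal-pain ECG sessions with known ground truth.

Emulates a tonic heat-pain protocol: five temperature levels, each applied
eight times for 10 s with 20-30 s rests, while the subject continuously
rates pain on a 0-100 computerized visual analog scale (CoVAS). Painful
stimuli modulate cardiac dynamics the way sympathetic activation does:
heart rate rises, beat-to-beat variability (SDNN) falls, the LF/HF balance
shifts sympathetic, and ECG amplitude grows with contractility. Effect
sizes are explicit :class:`AutonomicEffect` parameters, so downstream
feature extraction and models can be tested for parameter recovery against
a known truth.

The RR tachogram is produced by spectral synthesis - two Gaussian spectral
lobes (LF ~0.1 Hz, HF ~0.25 Hz) with powers in a prescribed ratio, inverse
FFT with random phases, variance scaled to the SDNN target - then
cumulative summation to beat times. ECG beats are sums of Gaussian bumps
(P, Q, R, S, T) placed at each beat.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import rng_for
from .errors import FormatError, ValidationError

__all__ = [
    "ProtocolSpec",
    "AutonomicEffect",
    "SessionRecord",
    "generate_rr_tachogram",
    "synthesize_ecg",
    "generate_session",
    "write_session_csv",
    "read_session_csv",
    "null_effect",
    "DEFAULT_COVAS_TARGETS",
]

#: CoVAS plateau targets per stimulus level (level 1..5). Level 1 is a warm,
#: non-painful stimulus (CoVAS 0); the rest span mild / moderate / severe pain.
DEFAULT_COVAS_TARGETS: tuple[float, ...] = (0.0, 15.0, 35.0, 60.0, 85.0)

_MOD_FS = 4.0  # Hz - sampling rate of the HRV modulation process
_LF_CENTER, _LF_SD = 0.10, 0.015  # Hz
_HF_CENTER, _HF_SD = 0.25, 0.030  # Hz
_MIN_RR_S = 0.25  # refractory floor for generated beats


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation protocol: which temperatures are applied, how often, for how long."""

    n_levels: int = 5
    reps_per_level: int = 8
    stim_duration_s: float = 10.0
    rest_range_s: tuple[float, float] = (20.0, 30.0)
    baseline_temp_c: float = 32.0
    level_temps_c: tuple[float, ...] = (40.0, 43.0, 45.0, 46.5, 48.0)
    randomized_order: bool = True
    covas_targets: tuple[float, ...] = DEFAULT_COVAS_TARGETS

    def __post_init__(self) -> None:
        if self.stim_duration_s <= 0:
            raise ValidationError("stim_duration_s must be positive")
        lo, hi = self.rest_range_s
        if lo > hi or lo < 0:
            raise ValidationError("rest_range_s must satisfy 0 <= min <= max")
        if self.n_levels != len(self.level_temps_c):
            raise ValidationError("n_levels must equal len(level_temps_c)")
        if len(self.covas_targets) != self.n_levels:
            raise ValidationError("covas_targets must have one entry per level")

    @property
    def n_stimuli(self) -> int:
        return self.n_levels * self.reps_per_level


@dataclass(frozen=True)
class AutonomicEffect:
    """Ground-truth autonomic response to pain.

    Gains are expressed per CoVAS unit (heart rate) or as fractions reached
    at maximal pain (CoVAS 100) so a plateau at CoVAS ``c`` produces
    ``baseline_hr_bpm + hr_gain_bpm_per_pain_unit * c`` bpm,
    ``baseline_sdnn_ms * (1 - sdnn_suppression_frac_at_max_pain * c/100)`` ms
    SDNN, and an ECG amplitude factor
    ``1 + amplitude_gain_frac_at_max_pain * c/100``.
    """

    baseline_hr_bpm: float = 70.0
    hr_gain_bpm_per_pain_unit: float = 0.15
    baseline_sdnn_ms: float = 50.0
    sdnn_suppression_frac_at_max_pain: float = 0.5
    amplitude_gain_frac_at_max_pain: float = 0.3
    lfhf_baseline: float = 1.5
    lfhf_gain: float = 2.0
    covas_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 30.0 < self.baseline_hr_bpm < 200.0:
            raise ValidationError("baseline_hr_bpm must lie in (30, 200) bpm")
        if self.sdnn_suppression_frac_at_max_pain >= 1.0:
            raise ValidationError("sdnn_suppression_frac_at_max_pain must be < 1")
        if self.covas_noise_sd < 0:
            raise ValidationError("covas_noise_sd must be >= 0")


def null_effect(covas_noise_sd: float = 0.0) -> AutonomicEffect:
    """An effect with all pain-modulated gains zero (negative-control sessions)."""
    return AutonomicEffect(
        hr_gain_bpm_per_pain_unit=0.0,
        sdnn_suppression_frac_at_max_pain=0.0,
        amplitude_gain_frac_at_max_pain=0.0,
        lfhf_gain=0.0,
        covas_noise_sd=covas_noise_sd,
    )


@dataclass
class SessionRecord:
    """One recorded session: aligned ECG, CoVAS and stimulus traces on a common clock."""

    ecg: np.ndarray  # mV
    fs_hz: float
    covas: np.ndarray  # 0-100
    stimulus_level: np.ndarray  # 0 = rest, 1..n_levels during stimuli
    seed: int
    truth: AutonomicEffect | None = None
    protocol: ProtocolSpec | None = None
    beat_times_s: np.ndarray | None = None  # ground-truth R times, for validation only

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.covas = np.asarray(self.covas, dtype=float)
        self.stimulus_level = np.asarray(self.stimulus_level, dtype=int)
        if not (len(self.ecg) == len(self.covas) == len(self.stimulus_level)):
            raise ValidationError("ecg, covas and stimulus_level must have equal length")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        if self.covas.size and (self.covas.min() < 0 or self.covas.max() > 100):
            raise ValidationError("covas values must lie in [0, 100]")

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs_hz

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(len(self.ecg)) / self.fs_hz


# ---------------------------------------------------------------------------
# RR tachogram


def _lobe_spectrum(freqs: np.ndarray, lf_hf_ratio: float) -> np.ndarray:
    """Amplitude spectrum of two Gaussian lobes with band powers in lf_hf_ratio."""
    lf = np.exp(-0.5 * ((freqs - _LF_CENTER) / _LF_SD) ** 2)
    hf = np.exp(-0.5 * ((freqs - _HF_CENTER) / _HF_SD) ** 2)
    # power of a lobe ~ amp^2 * sd; pick amplitudes so lf_power/hf_power = ratio
    a_lf = np.sqrt(lf_hf_ratio / _LF_SD)
    a_hf = np.sqrt(1.0 / _HF_SD)
    return a_lf * lf + a_hf * hf


def _band_limited_process(
    n: int, rng: np.random.Generator, lf_hf_ratio: float
) -> np.ndarray:
    """Zero-mean, unit-variance process with LF/HF Gaussian spectral lobes."""
    freqs = np.fft.rfftfreq(n, d=1.0 / _MOD_FS)
    amp = _lobe_spectrum(freqs, lf_hf_ratio)
    amp[0] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return (x - x.mean()) / sd


def generate_rr_tachogram(
    duration_s: float,
    mean_hr_bpm: float,
    sdnn_target_ms: float,
    lf_hf_ratio: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate RR intervals (seconds) with prescribed mean HR, SDNN and LF/HF.

    Variability is placed in the standard LF (~0.1 Hz) and HF (~0.25 Hz)
    bands by spectral synthesis, with total variance scaled so the SD of the
    RR series matches ``sdnn_target_ms``. Beats accumulate until the next
    beat would exceed ``duration_s``; the incomplete final interval is
    dropped, so the intervals sum to slightly less than the duration.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    if not 30.0 < mean_hr_bpm < 200.0:
        raise ValidationError("mean_hr_bpm must lie in (30, 200)")
    if sdnn_target_ms < 0:
        raise ValidationError("sdnn_target_ms must be >= 0")
    if lf_hf_ratio <= 0:
        raise ValidationError("lf_hf_ratio must be positive")

    mean_rr = 60.0 / mean_hr_bpm
    n_expected = int(np.ceil(duration_s / mean_rr)) + 8
    if sdnn_target_ms == 0:
        n = int(duration_s / mean_rr + 1e-9)
        return np.full(n, mean_rr)

    n_mod = max(int(np.ceil(duration_s * _MOD_FS)), 16)
    x = _band_limited_process(n_mod, rng_for(seed, "tachogram"), lf_hf_ratio)
    t_mod = np.arange(n_mod) / _MOD_FS

    rr: list[float] = []
    t = 0.0
    for _ in range(n_expected):
        mod = np.interp(t, t_mod, x)
        interval = max(mean_rr + (sdnn_target_ms / 1000.0) * mod, _MIN_RR_S)
        if t + interval > duration_s + 1e-12:
            break
        rr.append(interval)
        t += interval
    return np.asarray(rr)


# ---------------------------------------------------------------------------
# ECG synthesis

#: Default PQRST morphology: (offset from R in s, amplitude in mV, Gaussian width in s)
DEFAULT_MORPHOLOGY: tuple[tuple[float, float, float], ...] = (
    (-0.200, 0.15, 0.025),  # P
    (-0.028, -0.12, 0.010),  # Q
    (0.000, 1.00, 0.012),  # R
    (0.030, -0.20, 0.010),  # S
    (0.220, 0.30, 0.045),  # T
)


def _ecg_from_beats(
    beat_times_s: np.ndarray,
    beat_scales: np.ndarray,
    n_samples: int,
    fs_hz: float,
    morphology: Sequence[tuple[float, float, float]],
    noise_sd_mv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    sig = np.zeros(n_samples)
    span = 4.0 * max(w for _, _, w in morphology) + max(abs(o) for o, _, _ in morphology)
    for t_r, scale in zip(beat_times_s, beat_scales):
        i0 = max(int((t_r - span) * fs_hz), 0)
        i1 = min(int((t_r + span) * fs_hz) + 1, n_samples)
        if i1 <= i0:
            continue
        t_local = np.arange(i0, i1) / fs_hz - t_r
        beat = np.zeros(i1 - i0)
        for offset, amp, width in morphology:
            beat += amp * np.exp(-0.5 * ((t_local - offset) / width) ** 2)
        sig[i0:i1] += scale * beat
    if noise_sd_mv > 0:
        sig += rng.normal(0.0, noise_sd_mv, size=n_samples)
    return sig


def synthesize_ecg(
    rr_intervals: Sequence[float],
    fs_hz: float,
    amplitude_scale: float = 1.0,
    morphology_params: Sequence[tuple[float, float, float]] | None = None,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render an ECG voltage trace (mV) from RR intervals.

    Each beat is a sum of Gaussian bumps (P, Q, R, S, T); the whole beat
    template is multiplied by ``amplitude_scale``, so peak-to-peak amplitude
    of the noiseless signal scales exactly linearly. The first R wave is
    placed half an interval in, and output length is
    ``round(sum(rr) * fs_hz)`` samples.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.size == 0:
        return np.zeros(0)
    if fs_hz < 100:
        raise ValidationError("fs_hz must be >= 100 Hz")
    if np.any(rr <= 0.2):
        raise ValidationError("all RR intervals must exceed 0.2 s (unphysiological)")
    morphology = tuple(morphology_params) if morphology_params is not None else DEFAULT_MORPHOLOGY
    n = int(round(rr.sum() * fs_hz))
    beat_times = 0.5 * rr[0] + np.concatenate([[0.0], np.cumsum(rr[1:])])
    scales = np.full(len(beat_times), amplitude_scale)
    return _ecg_from_beats(
        beat_times, scales, n, fs_hz, morphology, noise_sd_mv, rng_for(seed, "ecg-noise")
    )


# ---------------------------------------------------------------------------
# Full session


def _build_schedule(
    protocol: ProtocolSpec, rng: np.random.Generator
) -> list[tuple[float, float, int]]:
    """Return [(start_s, duration_s, level), ...] for each stimulus."""
    order = np.repeat(np.arange(1, protocol.n_levels + 1), protocol.reps_per_level)
    if protocol.randomized_order:
        order = rng.permutation(order)
    lo, hi = protocol.rest_range_s
    schedule = []
    t = rng.uniform(lo, hi)
    for level in order:
        schedule.append((t, protocol.stim_duration_s, int(level)))
        t += protocol.stim_duration_s + rng.uniform(lo, hi)
    return schedule


def generate_session(
    protocol: ProtocolSpec | None = None,
    effect: AutonomicEffect | None = None,
    fs_hz: float = 250.0,
    seed: int = 0,
    ecg_noise_sd_mv: float = 0.02,
) -> SessionRecord:
    """Generate one complete session with ground-truth autonomic modulation.

    CoVAS is exactly 0 at rest; during each stimulus it sits on a
    level-dependent plateau (monotone in level, truncated-Gaussian noise on
    painful levels, clipped to [0, 100]). Heart rate, SDNN, LF/HF and ECG
    amplitude are modulated in proportion to the plateau CoVAS according to
    ``effect``. Deterministic given ``seed``.
    """
    protocol = protocol or ProtocolSpec()
    effect = effect or AutonomicEffect()

    schedule = _build_schedule(protocol, rng_for(seed, "schedule"))
    total_s = schedule[-1][0] + protocol.stim_duration_s + float(
        rng_for(seed, "tail-rest").uniform(*protocol.rest_range_s)
    )
    n = int(round(total_s * fs_hz))

    # per-stimulus CoVAS plateaus; levels with target 0 stay exactly at 0
    covas_rng = rng_for(seed, "covas")
    plateaus = []
    for _, _, level in schedule:
        target = protocol.covas_targets[level - 1]
        if target > 0 and effect.covas_noise_sd > 0:
            value = float(np.clip(target + covas_rng.normal(0.0, effect.covas_noise_sd), 0.0, 100.0))
        else:
            value = float(np.clip(target, 0.0, 100.0))
        plateaus.append(value)

    # modulation profiles on the 4 Hz grid
    n_mod = max(int(np.ceil(total_s * _MOD_FS)), 16)
    t_mod = np.arange(n_mod) / _MOD_FS
    covas_mod = np.zeros(n_mod)
    for (start, dur, _), plateau in zip(schedule, plateaus):
        covas_mod[(t_mod >= start) & (t_mod < start + dur)] = plateau
    pain_frac = covas_mod / 100.0
    hr_t = effect.baseline_hr_bpm + effect.hr_gain_bpm_per_pain_unit * covas_mod
    sdnn_t = effect.baseline_sdnn_ms * (1.0 - effect.sdnn_suppression_frac_at_max_pain * pain_frac)
    amp_t = 1.0 + effect.amplitude_gain_frac_at_max_pain * pain_frac
    lfhf_t = np.maximum(effect.lfhf_baseline + effect.lfhf_gain * pain_frac, 1e-3)

    # one LF and one HF unit process, mixed with time-varying sympathovagal weights
    freqs = np.fft.rfftfreq(n_mod, d=1.0 / _MOD_FS)

    def _single_lobe(center: float, sd: float, tag: str) -> np.ndarray:
        amp = np.exp(-0.5 * ((freqs - center) / sd) ** 2)
        amp[0] = 0.0
        phases = rng_for(seed, tag).uniform(0.0, 2.0 * np.pi, size=len(freqs))
        x = np.fft.irfft(amp * np.exp(1j * phases), n=n_mod)
        s = x.std()
        return x / s if s > 0 else x

    x_lf = _single_lobe(_LF_CENTER, _LF_SD, "lf-process")
    x_hf = _single_lobe(_HF_CENTER, _HF_SD, "hf-process")
    w_lf = np.sqrt(lfhf_t / (1.0 + lfhf_t))
    w_hf = np.sqrt(1.0 / (1.0 + lfhf_t))
    x_mod = w_lf * x_lf + w_hf * x_hf  # unit variance for independent components

    # beat-by-beat accumulation with locally varying HR / SDNN
    beat_times: list[float] = []
    beat_scales: list[float] = []
    t = 0.1
    while True:
        hr_now = float(np.interp(t, t_mod, hr_t))
        sdnn_now = float(np.interp(t, t_mod, sdnn_t))
        mod_now = float(np.interp(t, t_mod, x_mod))
        rr = max(60.0 / hr_now + (sdnn_now / 1000.0) * mod_now, _MIN_RR_S)
        if t + rr >= total_s:
            break
        beat_times.append(t)
        beat_scales.append(float(np.interp(t, t_mod, amp_t)))
        t += rr

    ecg = _ecg_from_beats(
        np.asarray(beat_times),
        np.asarray(beat_scales),
        n,
        fs_hz,
        DEFAULT_MORPHOLOGY,
        ecg_noise_sd_mv,
        rng_for(seed, "ecg-noise"),
    )

    t_samp = np.arange(n) / fs_hz
    covas = np.zeros(n)
    level_trace = np.zeros(n, dtype=int)
    for (start, dur, level), plateau in zip(schedule, plateaus):
        mask = (t_samp >= start) & (t_samp < start + dur)
        covas[mask] = plateau
        level_trace[mask] = level

    return SessionRecord(
        ecg=ecg,
        fs_hz=fs_hz,
        covas=covas,
        stimulus_level=level_trace,
        seed=seed,
        truth=effect,
        protocol=protocol,
        beat_times_s=np.asarray(beat_times),
    )


# ---------------------------------------------------------------------------
# CSV round-trip

_CSV_COLUMNS = ["t_s", "ecg_mv", "covas", "stimulus_level"]


def write_session_csv(record: SessionRecord, path: str | Path) -> None:
    """Write one row per sample (`t_s,ecg_mv,covas,stimulus_level`) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": np.round(record.t_s, 6),
            "ecg_mv": np.round(record.ecg, 6),
            "covas": np.round(record.covas, 6),
            "stimulus_level": record.stimulus_level,
        }
    )
    df.to_csv(path, index=False)
    meta: dict = {"fs_hz": record.fs_hz, "seed": record.seed}
    if record.protocol is not None:
        meta["protocol"] = dataclasses.asdict(record.protocol)
    if record.truth is not None:
        meta["effect"] = dataclasses.asdict(record.truth)
    if record.beat_times_s is not None:
        meta["beat_times_s"] = np.round(record.beat_times_s, 6).tolist()
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, sort_keys=True)


def read_session_csv(path: str | Path) -> SessionRecord:
    """Read a session written by :func:`write_session_csv`; validates invariants."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed rows, bad header
        raise FormatError(f"{path}: could not parse session CSV ({exc})") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    bad = df.index[(df["covas"] < 0) | (df["covas"] > 100)]
    if len(bad):
        # +2: header line plus 1-based line numbering
        raise ValidationError(f"{path}: covas outside [0,100] at line {bad[0] + 2}")

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    fs_hz, seed = None, 0
    protocol = effect = beats = None
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        fs_hz = meta.get("fs_hz")
        seed = meta.get("seed", 0)
        if "protocol" in meta:
            p = dict(meta["protocol"])
            for key in ("rest_range_s", "level_temps_c", "covas_targets"):
                if key in p:
                    p[key] = tuple(p[key])
            protocol = ProtocolSpec(**p)
        if "effect" in meta:
            effect = AutonomicEffect(**meta["effect"])
        if "beat_times_s" in meta:
            beats = np.asarray(meta["beat_times_s"])
    if fs_hz is None:
        t = df["t_s"].to_numpy()
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from < 2 samples")
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    return SessionRecord(
        ecg=df["ecg_mv"].to_numpy(),
        fs_hz=float(fs_hz),
        covas=df["covas"].to_numpy(),
        stimulus_level=df["stimulus_level"].to_numpy(),
        seed=int(seed),
        truth=effect,
        protocol=protocol,
        beat_times_s=beats,
    )
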