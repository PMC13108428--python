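"""Turn aligned session traces into labeled analysis windows.

Preprocessing follows the standard chain for stimulus-locked physiological
recordings: time-synchronize all channels onto one clock, resample to a
common 250 Hz, cut one 10-s window per stimulus plus a 10-s baseline
window ending at each onset, and label every window from its mean CoVAS
(no pain iff CoVAS = 0, pain iff CoVAS > 0). A fixed-length windowing mode
(default 1000 samples) is available as an alternative analysis unit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import signal

from .errors import ValidationError
from .synthdata import SessionRecord

__all__ = [
    "Window",
    "WindowSet",
    "Trace",
    "resample_trace",
    "synchronize",
    "segment_windows",
    "label_window",
    "TARGET_FS_HZ",
]

logger = logging.getLogger(__name__)

TARGET_FS_HZ = 250.0


@dataclass
class Window:
    """One analysis segment with its CoVAS value and pain label."""

    samples: np.ndarray  # ECG, mV
    fs_hz: float
    kind: Literal["stimulus", "baseline"]
    covas_value: float
    covas_label: Literal["pain", "no_pain"]
    stimulus_level: int
    t_start_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if (self.covas_label == "no_pain") != (self.covas_value == 0):
            raise ValidationError("covas_label must be no_pain iff covas_value == 0")
        if self.kind == "baseline" and self.stimulus_level != 0:
            raise ValidationError("baseline windows must have stimulus_level = 0")


@dataclass
class WindowSet:
    windows: list[Window] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


@dataclass
class Trace:
    """A single channel with its own clock: values sampled at fs_hz from t0_s."""

    values: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    @property
    def t_end_s(self) -> float:
        return self.t0_s + len(self.values) / self.fs_hz


def resample_trace(values: Sequence[float], fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling to ``fs_out``; length becomes round(n * fs_out / fs_in)."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValidationError("sampling rates must be positive")
    values = np.asarray(values, dtype=float)
    if fs_in == fs_out:
        return values.copy()
    if fs_out < fs_in:
        logger.debug("downsampling %g -> %g Hz (anti-alias filter applied)", fs_in, fs_out)
    ratio = Fraction(fs_out / fs_in).limit_denominator(10000)
    out = signal.resample_poly(values, ratio.numerator, ratio.denominator)
    n_target = int(round(len(values) * fs_out / fs_in))
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:
        out = np.pad(out, (0, n_target - len(out)), mode="edge")
    return out


def synchronize(
    traces: dict[str, Trace], fs_out: float = TARGET_FS_HZ
) -> tuple[dict[str, np.ndarray], float]:
    """Resample all channels to a common rate and crop to their overlapping interval.

    Returns (aligned arrays of equal length, start time of the common clock).
    Raises if the traces share no temporal overlap.
    """
    if not traces:
        raise ValidationError("no traces to synchronize")
    t0 = max(tr.t0_s for tr in traces.values())
    t1 = min(tr.t_end_s for tr in traces.values())
    if t1 <= t0:
        raise ValidationError("traces have no temporal overlap")
    n_out = int(np.floor((t1 - t0) * fs_out))
    aligned: dict[str, np.ndarray] = {}
    for name, tr in traces.items():
        res = resample_trace(tr.values, tr.fs_hz, fs_out)
        start = int(round((t0 - tr.t0_s) * fs_out))
        seg = res[start : start + n_out]
        if len(seg) < n_out:
            seg = np.pad(seg, (0, n_out - len(seg)), mode="edge")
        aligned[name] = seg
    return aligned, t0


def label_window(covas_values: Sequence[float]) -> tuple[float, str]:
    """Reduce a CoVAS trace over a window to (mean value, pain/no_pain label).

    The label rule is the binary ground-truth convention: no pain iff
    CoVAS = 0, pain iff CoVAS > 0.
    """
    covas = np.asarray(covas_values, dtype=float)
    if covas.size == 0:
        raise ValidationError("cannot label an empty CoVAS window")
    if covas.min() < 0 or covas.max() > 100:
        raise ValidationError("CoVAS values must lie in [0, 100]")
    value = float(covas.mean())
    return value, ("pain" if value > 0 else "no_pain")


def _stimulus_onsets(level_trace: np.ndarray) -> list[tuple[int, int]]:
    """Sample indices where stimulus_level transitions 0 -> k, with the level."""
    lv = np.asarray(level_trace)
    onsets = np.flatnonzero((lv[1:] > 0) & (lv[:-1] == 0)) + 1
    if lv.size and lv[0] > 0:
        onsets = np.concatenate([[0], onsets])
    return [(int(i), int(lv[i])) for i in onsets]


def segment_windows(
    record: SessionRecord,
    mode: Literal["stimulus_aligned", "fixed_length"] = "stimulus_aligned",
    window_len: int | None = None,
    stride: int | None = None,
    label_reduction: Literal["mean", "max"] = "mean",
    session_id: str = "",
) -> WindowSet:
    """Cut a session into labeled windows.

    stimulus_aligned (default): one window of the stimulus duration starting
    at each onset, plus a baseline window of the same length ending at the
    onset. A stimulus closer than one window length to the record start
    loses its baseline window (warning logged).

    fixed_length: consecutive windows of ``window_len`` samples (default
    1000) advanced by ``stride`` (default = window_len).
    """
    fs = record.fs_hz
    windows: list[Window] = []

    def _make(i0: int, i1: int, kind: str, level: int) -> Window:
        seg_covas = record.covas[i0:i1]
        if label_reduction == "max":
            value = float(seg_covas.max())
            label = "pain" if value > 0 else "no_pain"
        else:
            value, label = label_window(seg_covas)
        return Window(
            samples=record.ecg[i0:i1],
            fs_hz=fs,
            kind=kind,  # type: ignore[arg-type]
            covas_value=value,
            covas_label=label,  # type: ignore[arg-type]
            stimulus_level=level,
            t_start_s=i0 / fs,
        )

    if mode == "stimulus_aligned":
        stim_dur = record.protocol.stim_duration_s if record.protocol else 10.0
        n_win = int(round(stim_dur * fs))
        for i0, level in _stimulus_onsets(record.stimulus_level):
            i1 = min(i0 + n_win, len(record.ecg))
            windows.append(_make(i0, i1, "stimulus", level))
            if i0 >= n_win:
                windows.append(_make(i0 - n_win, i0, "baseline", 0))
            else:
                logger.warning(
                    "stimulus at t=%.1f s is closer than %.0f s to record start; "
                    "baseline window dropped",
                    i0 / fs,
                    stim_dur,
                )
    elif mode == "fixed_length":
        n_win = int(window_len or 1000)
        step = int(stride or n_win)
        for i0 in range(0, len(record.ecg) - n_win + 1, step):
            level = int(np.max(record.stimulus_level[i0 : i0 + n_win]))
            kind = "stimulus" if level > 0 else "baseline"
            windows.append(_make(i0, i0 + n_win, kind, level if kind == "stimulus" else 0))
    else:
        raise ValidationError(f"unknown segmentation mode: {mode!r}")

    cfg = f"{mode}:{window_len}:{stride}:{label_reduction}"
    digest = hashlib.sha1(cfg.encode()).hexdigest()[:8]
    return WindowSet(windows=windows, provenance=f"{session_id or record.seed}/{digest}")
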