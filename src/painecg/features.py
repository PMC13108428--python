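"""ECG / heart-rate-variability biomarker battery.

One row per analysis window with the standard candidate pain biomarkers:

* basic ECG statistics - RMS, peak-to-peak, signal power;
* statistical moments - kurtosis (Fisher excess) and skewness, both in
  uncorrected population form;
* first-derivative RMS (rate of change of the waveform, mV/s);
* time-domain HRV - RR mean, SDNN (sample SD, n-1), RMSSD, pNN50;
* frequency-domain HRV - Welch band powers in VLF (0.003-0.04 Hz),
  LF (0.04-0.15 Hz), HF (0.15-0.4 Hz) and the LF/HF ratio, computed on the
  RR tachogram interpolated to an even 4 Hz grid;
* geometric HRV - triangular index and TINN from the RR histogram at the
  conventional 1000/128 ms bin width;
* heart rate / interbeat interval summaries (hr_mean = 60000 / rr_mean).

R-peaks are detected with a bandpass + derivative-energy detector with an
adaptive threshold and a 250 ms refractory period. Windows where fewer
than two beats are found get NaN ("missing") HRV cells rather than zeros.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

from .errors import ValidationError
from .preprocess import Window, WindowSet

__all__ = [
    "RRSeries",
    "SpectralBands",
    "detect_r_peaks",
    "ecg_statistics",
    "derivative_statistics",
    "hrv_time_domain",
    "hrv_frequency_domain",
    "hrv_geometric",
    "build_feature_table",
    "FEATURE_COLUMNS",
    "HRV_BIN_WIDTH_MS",
    "BAND_EDGES_HZ",
]

logger = logging.getLogger(__name__)

#: Standard HRV histogram bin width (1000/128 ms).
HRV_BIN_WIDTH_MS = 1000.0 / 128.0

#: (low, high) in Hz for the VLF, LF and HF bands.
BAND_EDGES_HZ: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

FEATURE_COLUMNS: tuple[str, ...] = (
    "ecg_rms",
    "ecg_peak_to_peak",
    "ecg_power",
    "ecg_kurtosis",
    "ecg_skewness",
    "decg_rms",
    "rr_mean",
    "rr_std",
    "rr_rmssd",
    "pnn50",
    "sdnn",
    "vlf_power",
    "lf_power",
    "hf_power",
    "lf_hf",
    "tri_index",
    "tinn",
    "hr_mean",
    "ibi_mean",
)

_REFRACTORY_S = 0.25

_warned_short = False


def _warn_short_segment(record_s: float, segment_s: float) -> None:
    # warn once per process; short stimulus windows would otherwise flood the log
    global _warned_short
    if not _warned_short:
        logger.warning(
            "record (%.1f s) shorter than one Welch segment (%.0f s); "
            "shrinking segment to record length (repeated occurrences suppressed)",
            record_s,
            segment_s,
        )
        _warned_short = True
    else:
        logger.debug("Welch segment shrunk to %.1f s record", record_s)


@dataclass
class RRSeries:
    """Detected R-peak times (s) and the successive RR intervals (ms)."""

    r_peak_times_s: np.ndarray
    rr_ms: np.ndarray

    @classmethod
    def from_times(cls, times_s: np.ndarray) -> "RRSeries":
        times_s = np.asarray(times_s, dtype=float)
        return cls(times_s, np.diff(times_s) * 1000.0)

    @property
    def n_peaks(self) -> int:
        return len(self.r_peak_times_s)


@dataclass
class SpectralBands:
    vlf_power: float  # ms^2
    lf_power: float
    hf_power: float

    @property
    def lf_hf(self) -> float:
        return self.lf_power / self.hf_power if self.hf_power > 0 else np.nan


def detect_r_peaks(samples: np.ndarray, fs_hz: float) -> RRSeries:
    """Locate R-peaks via bandpass + squared-derivative energy with adaptive threshold.

    The QRS complex concentrates energy at 5-30 Hz; the squared derivative of
    the bandpassed signal is smoothed over 150 ms, peaks above an adaptive
    fraction of the envelope maximum are kept with a 250 ms refractory
    period, and each detection is refined to the raw-signal maximum within
    +/-60 ms. Returns an empty series (missing HRV downstream) when no
    credible beats exist, e.g. on a flat line.
    """
    x = np.asarray(samples, dtype=float)
    if fs_hz < 100:
        raise ValidationError("fs_hz must be >= 100 Hz for R-peak detection")
    if len(x) < 2 * fs_hz:
        raise ValidationError("window must be at least 2 s long")
    if np.ptp(x) == 0:
        return RRSeries.from_times(np.array([]))

    nyq = fs_hz / 2.0
    sos = signal.butter(3, [5.0 / nyq, min(30.0, 0.9 * nyq) / nyq], btype="band", output="sos")
    band = signal.sosfiltfilt(sos, x)
    energy = np.gradient(band) ** 2
    win = max(int(0.150 * fs_hz), 1)
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_level = np.max(envelope)
    if peak_level <= 0:
        return RRSeries.from_times(np.array([]))
    locs, _ = signal.find_peaks(
        envelope, height=0.20 * peak_level, distance=max(int(_REFRACTORY_S * fs_hz), 1)
    )
    # refine to the raw R apex near each envelope peak
    half = int(0.060 * fs_hz)
    refined = []
    for loc in locs:
        i0, i1 = max(loc - half, 0), min(loc + half + 1, len(x))
        refined.append(i0 + int(np.argmax(x[i0:i1])))
    refined = np.unique(refined)
    # re-apply refractory after refinement
    kept: list[int] = []
    for idx in refined:
        if not kept or (idx - kept[-1]) >= _REFRACTORY_S * fs_hz:
            kept.append(int(idx))
        elif x[idx] > x[kept[-1]]:
            kept[-1] = int(idx)
    return RRSeries.from_times(np.asarray(kept) / fs_hz)


def ecg_statistics(samples: np.ndarray) -> dict[str, float]:
    """RMS, peak-to-peak, power, excess kurtosis and skewness of the raw window."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 4:
        raise ValidationError("need at least 4 samples for ECG statistics")
    power = float(np.mean(x**2))
    out = {
        "ecg_rms": float(np.sqrt(power)),
        "ecg_peak_to_peak": float(np.ptp(x)),
        "ecg_power": power,
    }
    if np.var(x) == 0:
        out["ecg_kurtosis"] = np.nan
        out["ecg_skewness"] = np.nan
    else:
        out["ecg_kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=True))
        out["ecg_skewness"] = float(stats.skew(x, bias=True))
    return out


def derivative_statistics(samples: np.ndarray, fs_hz: float) -> float:
    """RMS of the first derivative (first difference scaled by fs), in mV/s."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least 2 samples for a derivative")
    dx = np.diff(x) * fs_hz
    return float(np.sqrt(np.mean(dx**2)))


def hrv_time_domain(rr_ms: np.ndarray) -> dict[str, float]:
    """RR mean, SDNN (n-1), RMSSD and pNN50 (strict > 50 ms) in conventional units."""
    rr = np.asarray(rr_ms, dtype=float)
    out = {"rr_mean": np.nan, "rr_std": np.nan, "rr_rmssd": np.nan, "pnn50": np.nan}
    if rr.size >= 1:
        out["rr_mean"] = float(rr.mean())
    if rr.size >= 3:
        out["rr_std"] = float(rr.std(ddof=1))
        diffs = np.diff(rr)
        out["rr_rmssd"] = float(np.sqrt(np.mean(diffs**2)))
        out["pnn50"] = float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / len(diffs))
    return out


def hrv_frequency_domain(
    rr_series: RRSeries,
    band_edges: dict[str, tuple[float, float]] | None = None,
    interp_fs_hz: float = 4.0,
    segment_s: float = 60.0,
) -> SpectralBands:
    """Welch band powers of the RR tachogram (ms^2) over the VLF/LF/HF bands.

    The unevenly sampled tachogram is cubic-interpolated onto an even
    ``interp_fs_hz`` grid and mean-removed; Welch uses Hann windows of
    ``segment_s`` with 50% overlap, shrunk (with a warning) when the record
    is shorter than one segment. Band power is the trapezoidal integral of
    the PSD over each band.
    """
    bands = band_edges or BAND_EDGES_HZ
    t, rr = rr_series.r_peak_times_s[1:], rr_series.rr_ms
    if len(rr) < 4:
        return SpectralBands(np.nan, np.nan, np.nan)
    grid = np.arange(t[0], t[-1], 1.0 / interp_fs_hz)
    if len(grid) < 8:
        return SpectralBands(np.nan, np.nan, np.nan)
    kind = "cubic" if len(rr) >= 4 else "linear"
    tachogram = interpolate.interp1d(t, rr, kind=kind)(grid)
    tachogram = tachogram - tachogram.mean()
    if np.allclose(tachogram, 0.0):
        return SpectralBands(0.0, 0.0, 0.0)
    nperseg = int(segment_s * interp_fs_hz)
    if nperseg > len(tachogram):
        _warn_short_segment(len(tachogram) / interp_fs_hz, segment_s)
        nperseg = len(tachogram)
    freqs, psd = signal.welch(
        tachogram, fs=interp_fs_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    return SpectralBands(
        vlf_power=band_power(*bands["vlf"]),
        lf_power=band_power(*bands["lf"]),
        hf_power=band_power(*bands["hf"]),
    )


def hrv_geometric(
    rr_ms: np.ndarray, bin_width_ms: float = HRV_BIN_WIDTH_MS
) -> tuple[float, float]:
    """Triangular index and TINN (ms) from the RR histogram.

    tri_index = n / height of the modal bin. TINN is the base width of the
    least-squares best-fit triangle to the histogram: the triangle rises
    linearly from zero at N to the modal height at the modal bin and falls
    to zero at M; N and M are grid-searched over bin centers.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        return np.nan, np.nan
    if rr.size < 20:
        logger.debug("geometric HRV from %d intervals; low confidence", rr.size)
    lo = np.floor(rr.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil(rr.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    counts, _ = np.histogram(rr, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mode_idx = int(np.argmax(counts))
    height = counts[mode_idx]
    tri_index = float(len(rr) / height)
    if len(counts) == 1 or np.count_nonzero(counts) == 1:
        return tri_index, float(bin_width_ms)

    # grid search the triangle feet; pad one bin either side so the feet can
    # sit outside the observed range
    pad = 2
    grid = np.concatenate(
        [
            centers[0] - bin_width_ms * np.arange(pad, 0, -1),
            centers,
            centers[-1] + bin_width_ms * np.arange(1, pad + 1),
        ]
    )
    x_mode, y_mode = centers[mode_idx], float(height)
    best = (np.inf, bin_width_ms)
    left_candidates = grid[grid < x_mode]
    right_candidates = grid[grid > x_mode]
    for n_ft in left_candidates:
        for m_ft in right_candidates:
            tri = np.zeros_like(centers, dtype=float)
            rising = (centers >= n_ft) & (centers <= x_mode)
            falling = (centers > x_mode) & (centers <= m_ft)
            tri[rising] = y_mode * (centers[rising] - n_ft) / (x_mode - n_ft)
            tri[falling] = y_mode * (m_ft - centers[falling]) / (m_ft - x_mode)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, float(m_ft - n_ft))
    return tri_index, best[1]


def _window_features(window: Window) -> dict[str, float]:
    feats = ecg_statistics(window.samples)
    feats["decg_rms"] = derivative_statistics(window.samples, window.fs_hz)
    rr_series = detect_r_peaks(window.samples, window.fs_hz)
    if rr_series.n_peaks < 2:
        for col in FEATURE_COLUMNS:
            feats.setdefault(col, np.nan)
        return feats
    td = hrv_time_domain(rr_series.rr_ms)
    feats.update(td)
    feats["sdnn"] = td["rr_std"]
    bands = hrv_frequency_domain(rr_series)
    feats["vlf_power"] = bands.vlf_power
    feats["lf_power"] = bands.lf_power
    feats["hf_power"] = bands.hf_power
    feats["lf_hf"] = bands.lf_hf
    feats["tri_index"], feats["tinn"] = hrv_geometric(rr_series.rr_ms)
    feats["hr_mean"] = 60000.0 / td["rr_mean"] if td["rr_mean"] else np.nan
    feats["ibi_mean"] = td["rr_mean"]
    return feats


def build_feature_table(window_set: WindowSet) -> pd.DataFrame:
    """One FeatureVector row per window, plus window metadata and CoVAS labels.

    Columns are emitted in a fixed order: metadata (kind, t_start_s,
    stimulus_level), the feature battery, then covas_value / covas_label.
    Windows with unusable ECG keep their row with NaN HRV cells; the count
    of such rows is logged.
    """
    rows = []
    n_missing = 0
    # Welch-segment warnings fire once per short window; summarize instead
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for w in window_set:
            feats = _window_features(w)
            if np.isnan(feats.get("rr_mean", np.nan)):
                n_missing += 1
            row = {
                "kind": w.kind,
                "t_start_s": w.t_start_s,
                "stimulus_level": w.stimulus_level,
                **{c: feats.get(c, np.nan) for c in FEATURE_COLUMNS},
                "covas_value": w.covas_value,
                "covas_label": w.covas_label,
            }
            rows.append(row)
    if n_missing:
        logger.info("%d of %d windows had unusable ECG (missing HRV cells)", n_missing, len(rows))
    cols = ["kind", "t_start_s", "stimulus_level", *FEATURE_COLUMNS, "covas_value", "covas_label"]
    return pd.DataFrame(rows, columns=cols)
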