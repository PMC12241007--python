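"""Spike-waveform features and fast-spiking vs regular-spiking classification.

Features follow the usual extracellular-waveform conventions: the trough is
the global minimum, the peak is the maximum after the trough, and the end
slope is the local slope of the waveform 0.5 ms after the trough.

Classification: a unit is fast-spiking (FS) when its trough-to-peak duration
is below 0.26 ms, its peak/trough amplitude ratio exceeds 0.8, and its end
slope is negative; otherwise it is regular-spiking (RS). All boundaries are
strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FS = "FS"
RS = "RS"

#: Default classification boundaries (strict inequalities).
TROUGH_PEAK_MS_MAX = 0.26
PEAK_TROUGH_RATIO_MIN = 0.8
END_SLOPE_MAX = 0.0

#: Delay after the trough at which the end slope is measured.
END_SLOPE_DELAY_MS = 0.5


class WaveformFeatureError(ValueError):
    """The waveform does not contain the required trough/peak structure."""


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar shape descriptors of a mean spike waveform.

    trough_peak_ms
        Time from the global trough to the subsequent maximum, in ms.
    peak_trough_ratio
        |peak amplitude| / |trough amplitude|.
    end_slope
        Signed slope (amplitude units per ms) 0.5 ms after the trough.
    """

    trough_peak_ms: float
    peak_trough_ratio: float
    end_slope: float


def extract_features(waveform: np.ndarray, sampling_rate_hz: float) -> WaveformFeatures:
    """Compute trough-to-peak duration, peak/trough ratio, and end slope."""
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise WaveformFeatureError("waveform must be a 1-D array with >= 3 samples")
    if not np.all(np.isfinite(w)):
        raise WaveformFeatureError("waveform contains non-finite samples")

    i_trough = int(np.argmin(w))
    if i_trough >= w.size - 1:
        raise WaveformFeatureError("trough at final sample: no post-trough peak")
    i_peak = i_trough + 1 + int(np.argmax(w[i_trough + 1 :]))

    dt_ms = 1000.0 / sampling_rate_hz
    trough_peak_ms = (i_peak - i_trough) * dt_ms

    trough_amp = abs(w[i_trough])
    if trough_amp == 0:
        raise WaveformFeatureError("zero trough amplitude")
    ratio = abs(w[i_peak]) / trough_amp

    # Central difference at the sample nearest trough + 0.5 ms.
    i_slope = i_trough + int(round(END_SLOPE_DELAY_MS / dt_ms))
    i_slope = min(max(i_slope, 1), w.size - 2)
    end_slope = (w[i_slope + 1] - w[i_slope - 1]) / (2.0 * dt_ms)

    return WaveformFeatures(
        trough_peak_ms=float(trough_peak_ms),
        peak_trough_ratio=float(ratio),
        end_slope=float(end_slope),
    )


def classify_unit(
    features: WaveformFeatures,
    trough_peak_ms_max: float = TROUGH_PEAK_MS_MAX,
    peak_trough_ratio_min: float = PEAK_TROUGH_RATIO_MIN,
    end_slope_max: float = END_SLOPE_MAX,
) -> str:
    """Classify a unit as ``"FS"`` or ``"RS"`` from its waveform features."""
    f = features
    if not all(np.isfinite([f.trough_peak_ms, f.peak_trough_ratio, f.end_slope])):
        raise ValueError("features must be finite")
    is_fs = (
        f.trough_peak_ms < trough_peak_ms_max
        and f.peak_trough_ratio > peak_trough_ratio_min
        and f.end_slope < end_slope_max
    )
    return FS if is_fs else RS


def make_waveform(
    trough_peak_ms: float,
    peak_trough_ratio: float,
    end_slope_per_ms: float,
    sampling_rate_hz: float = 30_000.0,
    trough_amp: float = -100.0,
    pre_ms: float = 0.3,
    tail_ms: float = 1.0,
) -> np.ndarray:
    """Synthesize a piecewise-linear waveform with controlled features.

    Baseline at zero, a linear dip to ``trough_amp``, a linear rise to the
    peak ``trough_peak_ms`` after the trough, then a linear tail with slope
    ``end_slope_per_ms``. For durations below ``END_SLOPE_DELAY_MS`` the
    measured end slope equals ``end_slope_per_ms`` exactly (the 0.5 ms point
    falls in the tail); the trough-to-peak duration is quantized to the
    sample grid.
    """
    if trough_peak_ms <= 0:
        raise ValueError("trough_peak_ms must be > 0")
    if peak_trough_ratio < 0:
        raise ValueError("peak_trough_ratio must be >= 0")
    dt_ms = 1000.0 / sampling_rate_hz
    n_pre = max(int(round(pre_ms / dt_ms)), 1)
    n_dip = 3
    n_rise = max(int(round(trough_peak_ms / dt_ms)), 1)
    n_tail = max(int(round(tail_ms / dt_ms)), 2)

    peak_amp = peak_trough_ratio * abs(trough_amp)
    pre = np.zeros(n_pre)
    dip = np.linspace(0.0, trough_amp, n_dip + 1)[1:]
    rise = np.linspace(trough_amp, peak_amp, n_rise + 1)[1:]
    tail = peak_amp + end_slope_per_ms * dt_ms * np.arange(1, n_tail + 1)
    return np.concatenate([pre, dip, rise, tail])
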