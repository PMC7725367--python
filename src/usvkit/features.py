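"""Spectro-temporal features of detected vocalizations.

Four features are computed per element: length (ms), mean frequency (kHz),
mean amplitude (dB) and slope (kHz/ms).  The slope is the ordinary
least-squares regression coefficient of frequency on time over all points
of the detected frequency track; it is a crude one-number summary of the
frequency contour (a symmetric chevron regresses to ~0).  Track-derived
features are reported as missing (NaN) when the track carries fewer than
``min_track_points`` points — the "too short or faint" case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detect import Element

__all__ = [
    "length_ms",
    "mean_frequency_khz",
    "mean_amplitude_db",
    "slope_khz_per_ms",
    "latency_to_first",
    "feature_table",
]

DEFAULT_MIN_TRACK_POINTS = 3

FEATURE_COLUMNS = [
    "start_s",
    "end_s",
    "length_ms",
    "mean_freq_khz",
    "mean_amp_db",
    "slope_khz_ms",
    "quality",
    "n_points",
]


def length_ms(e: Element) -> float:
    return (e.end_s - e.start_s) * 1000.0


def _track_points(e: Element) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = e.track.present
    return e.track.times_s[m], e.track.freqs_khz[m], e.track.amps_db[m]


def mean_frequency_khz(
    e: Element, min_track_points: int = DEFAULT_MIN_TRACK_POINTS
) -> float:
    """Unweighted mean of track frequencies; NaN if the track is too short."""
    _, freqs, _ = _track_points(e)
    if freqs.size < min_track_points:
        return float("nan")
    return float(freqs.mean())


def mean_amplitude_db(
    e: Element, min_track_points: int = DEFAULT_MIN_TRACK_POINTS
) -> float:
    """Mean of per-frame peak magnitudes; NaN if the track is too short."""
    _, _, amps = _track_points(e)
    if amps.size < min_track_points:
        return float("nan")
    return float(amps.mean())


def slope_khz_per_ms(
    e: Element, min_track_points: int = DEFAULT_MIN_TRACK_POINTS
) -> float:
    """OLS slope of frequency (kHz) on time (ms) over the track points."""
    times, freqs, _ = _track_points(e)
    if freqs.size < min_track_points:
        return float("nan")
    t_ms = times * 1000.0
    if np.ptp(t_ms) == 0:
        raise ValueError("degenerate time spread: all track points coincide")
    t_c = t_ms - t_ms.mean()
    return float((t_c @ (freqs - freqs.mean())) / (t_c @ t_c))


def latency_to_first(elements: list[Element], trial_duration_s: float = 600.0) -> float:
    """Start time of the earliest element; the full trial duration if the
    animal never vocalized."""
    if trial_duration_s <= 0:
        raise ValueError("trial_duration_s must be positive")
    if not elements:
        return float(trial_duration_s)
    return min(e.start_s for e in elements)


def feature_table(
    elements: list[Element], min_track_points: int = DEFAULT_MIN_TRACK_POINTS
) -> pd.DataFrame:
    """One row per element, ordered by start time; missing values are NaN."""
    rows = []
    for e in sorted(elements, key=lambda e: e.start_s):
        rows.append(
            {
                "start_s": e.start_s,
                "end_s": e.end_s,
                "length_ms": length_ms(e),
                "mean_freq_khz": mean_frequency_khz(e, min_track_points),
                "mean_amp_db": mean_amplitude_db(e, min_track_points),
                "slope_khz_ms": slope_khz_per_ms(e, min_track_points)
                if e.track.n_points >= min_track_points
                else float("nan"),
                "quality": e.quality,
                "n_points": e.track.n_points,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
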