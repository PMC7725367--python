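"""Vocalization-element detection on the spectrogram frequency track.

The detector follows the structure of automatic mouse-ultrasound detection
tools: estimate a per-bin noise floor, track the dominant in-band frequency
frame by frame, keep frames whose peak rises far enough above the floor,
merge nearby frames into elements, drop elements shorter than an adjustable
minimum duration (10 ms by default; 5 ms recovers shorter calls at the cost
of more false positives), and grade every element with an integer quality
score from 0 (likely noise) to 9 (clearly a vocalization), with scores >= 5
considered good quality.

The quality score combines the two ways an element can be dubious — being
faint and being fragmentary:

    score = round(9 * min(1, median_snr_db / 30) * continuity)

where continuity is the fraction of frames inside the element that carry a
track point, and rounding is half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_erosion, uniform_filter1d

from .spectro import Spectrogram, SpectrogramParams, Waveform, compute_spectrogram

__all__ = [
    "DetectionParams",
    "FrequencyTrack",
    "Element",
    "estimate_noise_floor",
    "extract_frequency_track",
    "segment_elements",
    "quality_score",
    "detect_file",
    "filter_by_quality",
]

#: median SNR (dB) at which the quality score saturates at 9
SNR_SATURATION_DB = 30.0


@dataclass(frozen=True)
class DetectionParams:
    band_lo_khz: float = 20.0
    band_hi_khz: float = 140.0
    snr_threshold_db: float = 8.0
    min_duration_ms: float = 10.0
    max_gap_ms: float = 5.0
    min_track_points: int = 3
    smooth_frames: int = 9

    def __post_init__(self) -> None:
        if not self.band_lo_khz < self.band_hi_khz:
            raise ValueError("band_lo_khz must be < band_hi_khz")
        if self.min_duration_ms <= 0:
            raise ValueError("min_duration_ms must be positive")
        if self.max_gap_ms < 0:
            raise ValueError("max_gap_ms must be >= 0")


@dataclass(frozen=True)
class FrequencyTrack:
    """Per-frame dominant frequency; absent frames hold NaN."""

    times_s: np.ndarray
    freqs_khz: np.ndarray
    amps_db: np.ndarray
    snr_db: np.ndarray

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.freqs_khz)

    @property
    def n_points(self) -> int:
        return int(self.present.sum())

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class Element:
    """One detected putative vocalization, half-open [start_s, end_s)."""

    start_s: float
    end_s: float
    track: FrequencyTrack
    quality: int = 0

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("element must have end_s > start_s")
        if not 0 <= self.quality <= 9:
            raise ValueError("quality must be in 0..9")

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


def estimate_noise_floor(s: Spectrogram, min_frames: int = 10) -> np.ndarray:
    """Per-bin noise level: the median magnitude of each frequency bin
    across frames.  Robust to sparse vocalizations, which occupy only a
    small fraction of frames."""
    if s.n_frames < min_frames:
        raise ValueError(
            f"need >= {min_frames} frames to estimate noise floor, got {s.n_frames}"
        )
    return np.median(s.magnitude_db, axis=0)


def extract_frequency_track(
    s: Spectrogram, p: DetectionParams, floor: np.ndarray
) -> FrequencyTrack:
    """Dominant in-band frequency per frame, thresholded on SNR.

    A frame carries a track point iff its in-band peak magnitude exceeds
    that bin's noise floor by at least ``snr_threshold_db``.  Spectral
    power is first averaged over ``smooth_frames`` adjacent frames: taking
    a per-frame maximum across ~100 bins would otherwise let raw noise
    fluctuations clear any usable threshold, while time-averaging shrinks
    their variance far below it and leaves tonal calls (which persist
    across frames) untouched.
    """
    in_band = (s.bin_freqs_khz >= p.band_lo_khz) & (s.bin_freqs_khz <= p.band_hi_khz)
    if not in_band.any():
        raise ValueError("detection band contains no spectrogram bins")
    band_idx = np.flatnonzero(in_band)
    band_mag = s.magnitude_db[:, band_idx]
    if p.smooth_frames > 1:
        power = 10.0 ** (band_mag / 10.0)
        power = uniform_filter1d(power, size=p.smooth_frames, axis=0, mode="nearest")
        band_mag = 10.0 * np.log10(np.maximum(power, 1e-30))
    peak_pos = np.argmax(band_mag, axis=1)
    rows = np.arange(s.n_frames)
    peak_bin = band_idx[peak_pos]
    peak_amp = band_mag[rows, peak_pos]
    snr = peak_amp - floor[peak_bin]
    present = snr >= p.snr_threshold_db
    if p.smooth_frames > 1:
        # time-averaging smears a call's power ~half a window past its true
        # edges; eroding the mask by the same amount restores the boundary
        half = p.smooth_frames // 2
        present = binary_erosion(present, structure=np.ones(2 * half + 1))
    freqs = np.where(present, s.bin_freqs_khz[peak_bin], np.nan)
    amps = np.where(present, peak_amp, np.nan)
    return FrequencyTrack(
        times_s=s.frame_times_s.copy(),
        freqs_khz=freqs,
        amps_db=amps,
        snr_db=np.where(present, snr, np.nan),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def segment_elements(t: FrequencyTrack, p: DetectionParams) -> list[Element]:
    """Merge present frames into elements.

    Absent gaps no longer than ``max_gap_ms`` are bridged; merged runs
    shorter than ``min_duration_ms`` are discarded.  Element boundaries are
    placed half a hop outside the first/last frame center, so an n-frame
    run spans n hops.
    """
    if len(t) == 0 or not t.present.any():
        return []
    hop_s = float(t.times_s[1] - t.times_s[0]) if len(t) > 1 else 0.0
    runs = _runs(t.present)
    # bridge gaps <= max_gap_ms between consecutive runs
    max_gap_frames = int(np.floor(p.max_gap_ms / 1000.0 / hop_s)) if hop_s else 0
    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= max_gap_frames:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    elements = []
    for start, stop in merged:
        dur_ms = (stop - start) * hop_s * 1000.0
        if dur_ms < p.min_duration_ms:
            continue
        sl = slice(start, stop)
        track = FrequencyTrack(
            times_s=t.times_s[sl],
            freqs_khz=t.freqs_khz[sl],
            amps_db=t.amps_db[sl],
            snr_db=t.snr_db[sl],
        )
        elements.append(
            Element(
                start_s=float(t.times_s[start] - hop_s / 2),
                end_s=float(t.times_s[stop - 1] + hop_s / 2),
                track=track,
            )
        )
    return elements


def quality_score(e: Element) -> int:
    """Integer 0-9 confidence that an element is a true vocalization."""
    present = e.track.present
    if not present.any():
        return 0
    med_snr = float(np.median(e.track.snr_db[present]))
    continuity = present.mean()
    raw = 9.0 * min(1.0, med_snr / SNR_SATURATION_DB) * continuity
    return int(np.clip(np.floor(raw + 0.5), 0, 9))


def detect_file(
    w: Waveform,
    sp: SpectrogramParams | None = None,
    dp: DetectionParams | None = None,
) -> list[Element]:
    """Full detection chain: spectrogram -> noise floor -> frequency track
    -> segmentation -> quality scoring.  Deterministic."""
    dp = dp or DetectionParams()
    s = compute_spectrogram(w, sp)
    floor = estimate_noise_floor(s)
    track = extract_frequency_track(s, dp, floor)
    elements = segment_elements(track, dp)
    return [replace(e, quality=quality_score(e)) for e in elements]


def filter_by_quality(elements: list[Element], min_score: int) -> list[Element]:
    """Keep elements with quality >= min_score (order preserved)."""
    if not 0 <= min_score <= 9:
        raise ValueError("min_score must be in 0..9")
    return [e for e in elements if e.quality >= min_score]
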