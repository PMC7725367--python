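"""Rule-based syllable-type classification.

Mouse vocalizations are conventionally sorted into a vocabulary of 15
ultrasonic syllable types plus two sonic categories: low-frequency
vocalizations (LFV) — USV-like calls below 20 kHz — and squeaks, harmonic
calls starting in the sonic range.  Published repertoires are usually
labelled by a human rater; this module provides a deterministic surrogate,
a fixed-order decision list over measurable shape descriptors (duration,
mean frequency, frequency jumps, direction changes, harmonic content) whose
thresholds are all configurable, so the scheme can be aligned with any
particular rater's definitions.

The decision order is: sonic split at exactly 20 kHz -> ultra-high ->
duration classes (ultra-short, short) -> jump classes -> harmonic ->
complexity/shape classes -> unclassified fallback.  Every element receives
exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Element
from .features import (
    DEFAULT_MIN_TRACK_POINTS,
    length_ms,
    mean_frequency_khz,
    slope_khz_per_ms,
)
from .spectro import Spectrogram

__all__ = [
    "SyllableVocabulary",
    "ClassificationRules",
    "ShapeDescriptors",
    "ClassifiedVocalization",
    "DEFAULT_VOCABULARY",
    "shape_descriptors",
    "classify_element",
    "counts_by_type",
]

#: frequency separating sonic from ultrasonic vocalizations (kHz); fixed
SONIC_CUT_KHZ = 20.0

#: default 15-type ultrasonic vocabulary.  The first five abbreviations
#: (complex, uh, s, us, uc) are standard; the remaining ten follow a common
#: mouse-USV taxonomy and are freely renamable.
DEFAULT_ULTRASONIC_TYPES = (
    "complex",  # >= 2 direction changes
    "uh",       # ultra-high: mean frequency >= 90 kHz
    "s",        # short, simple contour
    "us",       # ultra-short (< 5 ms)
    "uc",       # unclassified / unstructured
    "f",        # flat
    "u",        # upward
    "d",        # downward
    "ch",       # chevron (one direction change)
    "w",        # wave
    "ju",       # one upward frequency jump
    "jd",       # one downward frequency jump
    "jm",       # multiple jumps
    "h",        # harmonic
    "cm",       # composite
)
SONIC_TYPES = ("lfv", "squeak")


@dataclass(frozen=True)
class SyllableVocabulary:
    ultrasonic_types: tuple[str, ...] = DEFAULT_ULTRASONIC_TYPES
    sonic_types: tuple[str, ...] = SONIC_TYPES

    def __post_init__(self) -> None:
        required = {"complex", "uh", "s", "us", "uc"}
        labels = set(self.ultrasonic_types)
        if len(self.ultrasonic_types) != 15 or len(labels) != 15:
            raise ValueError("vocabulary needs exactly 15 unique ultrasonic labels")
        if not required <= labels:
            raise ValueError(f"vocabulary must include {sorted(required)}")

    @property
    def all_types(self) -> tuple[str, ...]:
        return self.ultrasonic_types + self.sonic_types


DEFAULT_VOCABULARY = SyllableVocabulary()


@dataclass(frozen=True)
class ClassificationRules:
    us_max_ms: float = 5.0
    s_max_ms: float = 12.0
    uh_min_khz: float = 90.0
    jump_khz: float = 10.0
    direction_eps_khz: float = 2.0
    harmonic_snr_db: float = 6.0
    flat_max_range_khz: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "us_max_ms", "s_max_ms", "uh_min_khz", "jump_khz",
            "direction_eps_khz", "harmonic_snr_db", "flat_max_range_khz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ShapeDescriptors:
    n_jumps: int
    n_direction_changes: int
    freq_range_khz: float
    has_harmonic: bool
    first_jump_up: bool = False


@dataclass(frozen=True)
class ClassifiedVocalization:
    element: Element
    type_label: str
    is_ultrasonic: bool


def _count_direction_changes(freqs: np.ndarray, eps: float) -> int:
    """Direction reversals with hysteresis: a reversal counts only once the
    contour has retreated >= eps from its running extreme."""
    changes = 0
    direction = 0
    ref = freqs[0]
    for f in freqs[1:]:
        if direction == 0:
            if abs(f - ref) >= eps:
                direction = 1 if f > ref else -1
                ref = f
        elif (f - ref) * direction >= 0:
            ref = f
        elif abs(f - ref) >= eps:
            changes += 1
            direction = -direction
            ref = f
    return changes


def _harmonic_fraction(
    e: Element, s: Spectrogram, floor: np.ndarray, snr_db: float
) -> float:
    """Fraction of track frames with a secondary peak near twice the
    fundamental exceeding floor + snr_db."""
    present = e.track.present
    if not present.any():
        return 0.0
    bw = s.bin_width_khz
    hits = 0
    idx = np.searchsorted(s.frame_times_s, e.track.times_s[present])
    for frame_i, f0 in zip(idx, e.track.freqs_khz[present]):
        target = 2.0 * f0
        if target > s.bin_freqs_khz[-1]:
            continue
        b = int(round(target / bw))
        lo, hi = max(b - 2, 0), min(b + 3, s.n_bins)
        frame_i = min(frame_i, s.n_frames - 1)
        window = s.magnitude_db[frame_i, lo:hi] - floor[lo:hi]
        if window.size and window.max() >= snr_db:
            hits += 1
    return hits / present.sum()


def shape_descriptors(
    e: Element,
    rules: ClassificationRules | None = None,
    spectrogram: Spectrogram | None = None,
    floor: np.ndarray | None = None,
) -> ShapeDescriptors:
    """Jump count, hysteresis direction changes, frequency range and
    harmonic presence for one element.  Harmonic detection needs the
    spectrogram and noise floor; without them ``has_harmonic`` is False.
    """
    rules = rules or ClassificationRules()
    freqs = e.track.freqs_khz[e.track.present]
    if freqs.size == 0:
        return ShapeDescriptors(0, 0, 0.0, False)
    steps = np.diff(freqs)
    jump_mask = np.abs(steps) > rules.jump_khz
    n_jumps = int(jump_mask.sum())
    first_jump_up = bool(steps[jump_mask][0] > 0) if n_jumps else False
    # direction changes on the jump-free contour: split at jumps, count within
    segments = np.split(freqs, np.flatnonzero(jump_mask) + 1)
    n_dir = sum(
        _count_direction_changes(seg, rules.direction_eps_khz)
        for seg in segments
        if seg.size >= 2
    )
    has_harm = False
    if spectrogram is not None and floor is not None:
        has_harm = (
            _harmonic_fraction(e, spectrogram, floor, rules.harmonic_snr_db) >= 0.5
        )
    return ShapeDescriptors(
        n_jumps=n_jumps,
        n_direction_changes=int(n_dir),
        freq_range_khz=float(np.ptp(freqs)),
        has_harmonic=has_harm,
        first_jump_up=first_jump_up,
    )


def classify_element(
    e: Element,
    rules: ClassificationRules | None = None,
    vocab: SyllableVocabulary | None = None,
    spectrogram: Spectrogram | None = None,
    floor: np.ndarray | None = None,
    min_track_points: int = DEFAULT_MIN_TRACK_POINTS,
) -> str:
    """Assign one vocabulary label via the fixed-order decision list.

    Total: every element gets exactly one label; an element whose track is
    too sparse to measure is `uc`.
    """
    rules = rules or ClassificationRules()
    vocab = vocab or DEFAULT_VOCABULARY
    mean_f = mean_frequency_khz(e, min_track_points)
    if np.isnan(mean_f):
        return "uc"
    desc = shape_descriptors(e, rules, spectrogram, floor)
    if mean_f < SONIC_CUT_KHZ:
        return "squeak" if desc.has_harmonic else "lfv"
    dur = length_ms(e)
    if mean_f >= rules.uh_min_khz:
        return "uh"
    if dur < rules.us_max_ms:
        return "us"
    if (
        dur < rules.s_max_ms
        and desc.n_jumps == 0
        and desc.n_direction_changes == 0
    ):
        return "s"
    if desc.n_jumps == 1:
        return "ju" if desc.first_jump_up else "jd"
    if desc.n_jumps >= 2:
        return "jm"
    if desc.has_harmonic:
        return "h"
    if desc.n_direction_changes >= 2:
        return "complex"
    if desc.n_direction_changes == 1:
        return "ch"
    if desc.freq_range_khz < rules.flat_max_range_khz:
        return "f"
    slope = slope_khz_per_ms(e, min_track_points)
    if np.isnan(slope):
        return "uc"
    return "u" if slope > 0 else "d"


def classify_all(
    elements: list[Element],
    rules: ClassificationRules | None = None,
    vocab: SyllableVocabulary | None = None,
    spectrogram: Spectrogram | None = None,
    floor: np.ndarray | None = None,
) -> list[ClassifiedVocalization]:
    out = []
    for e in elements:
        label = classify_element(e, rules, vocab, spectrogram, floor)
        mean_f = mean_frequency_khz(e)
        out.append(
            ClassifiedVocalization(
                element=e,
                type_label=label,
                is_ultrasonic=bool(not np.isnan(mean_f) and mean_f >= SONIC_CUT_KHZ),
            )
        )
    return out


def counts_by_type(
    labels: list[str] | list[ClassifiedVocalization],
    vocab: SyllableVocabulary | None = None,
) -> pd.Series:
    """Dense count vector over the full vocabulary (zeros included)."""
    vocab = vocab or DEFAULT_VOCABULARY
    names = [
        x.type_label if isinstance(x, ClassifiedVocalization) else x for x in labels
    ]
    unknown = set(names) - set(vocab.all_types)
    if unknown:
        raise ValueError(f"labels not in vocabulary: {sorted(unknown)}")
    counts = pd.Series(0, index=list(vocab.all_types), dtype=int)
    for n in names:
        counts[n] += 1
    return counts
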