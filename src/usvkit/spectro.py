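"""Audio input and calibrated time-frequency analysis.

Recordings of mouse vocalizations are typically made at very high sample
rates (300 kHz for ultrasound work) and analysed on a short-time Fourier
transform with a small FFT (256 points), giving ~1.17 kHz frequency
resolution and sub-millisecond hop at 50% overlap.  This module reads PCM
WAV files into a :class:`Waveform` and turns them into a dB-scaled
:class:`Spectrogram` whose magnitudes are referenced to digital full scale,
so a full-scale sine reads ~0 dB and a -40 dBFS tone reads ~-40 dB.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window

__all__ = [
    "Waveform",
    "SpectrogramParams",
    "Spectrogram",
    "read_wav",
    "compute_spectrogram",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio signal with samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("waveform must be a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")
        if int(self.sample_rate_hz) <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate_hz", int(self.sample_rate_hz))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT parameters; defaults match common ultrasound practice
    (256-point FFT, Hann window, 50% overlap)."""

    fft_size: int = 256
    hop: int | None = None
    window: str = "hann"
    db_floor: float = -120.0

    def __post_init__(self) -> None:
        if self.fft_size < 16:
            raise ValueError("fft_size must be >= 16")
        hop = self.hop if self.hop is not None else self.fft_size // 2
        if not (0 < hop <= self.fft_size):
            raise ValueError("hop must satisfy 0 < hop <= fft_size")
        object.__setattr__(self, "hop", int(hop))


@dataclass(frozen=True)
class Spectrogram:
    """frames x bins magnitude matrix in dB re full scale."""

    magnitude_db: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_khz: np.ndarray
    params: SpectrogramParams
    sample_rate_hz: int = field(default=0)

    @property
    def n_frames(self) -> int:
        return self.magnitude_db.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitude_db.shape[1]

    @property
    def hop_s(self) -> float:
        return self.params.hop / self.sample_rate_hz

    @property
    def bin_width_khz(self) -> float:
        return float(self.bin_freqs_khz[1] - self.bin_freqs_khz[0])


def read_wav(path: str | os.PathLike, channel: int | None = None) -> Waveform:
    """Read a PCM (or float) RIFF WAV file into a :class:`Waveform`.

    Integer formats are scaled by their full-scale value so the most
    negative 16-bit sample (-32768) maps to exactly -1.0.  Multichannel
    files require an explicit ``channel`` index.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such WAV file: {path}")
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path} has {data.shape[1]} channels; pass channel=<index>"
            )
        data = data[:, channel]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format: {data.dtype}")
    return Waveform(samples=samples, sample_rate_hz=int(rate))


def write_wav(path: str | os.PathLike, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV (round-trip safe to 1 LSB)."""
    clipped = np.clip(w.samples, -1.0, 32767.0 / 32768.0)
    pcm = np.round(clipped * 32768.0).astype(np.int16)
    wavfile.write(path, w.sample_rate_hz, pcm)


def compute_spectrogram(w: Waveform, p: SpectrogramParams | None = None) -> Spectrogram:
    """Short-time Fourier magnitude in dB re digital full scale.

    Frames start at sample 0 without padding, so the frame count is
    ``floor((n - fft_size)/hop) + 1`` and frame times are window centers.
    Magnitudes are scaled by 2/sum(window): a unit-amplitude sine lands at
    ~0 dB in its peak bin.  Values are clipped below at ``db_floor``.
    """
    p = p or SpectrogramParams()
    n = w.samples.size
    if n < p.fft_size:
        raise ValueError(
            f"waveform has {n} samples, shorter than fft_size={p.fft_size}"
        )
    win = get_window(p.window, p.fft_size, fftbins=True)
    frames = sliding_window_view(w.samples, p.fft_size)[:: p.hop]
    spec = np.fft.rfft(frames * win, axis=1)
    # amplitude calibration: full-scale sine -> |X| = sum(win)/2 at its bin
    amp = np.abs(spec) * (2.0 / win.sum())
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(amp)
    mag_db = np.maximum(mag_db, p.db_floor)
    n_frames = mag_db.shape[0]
    frame_times = (np.arange(n_frames) * p.hop + p.fft_size / 2) / w.sample_rate_hz
    bin_freqs_khz = (
        np.fft.rfftfreq(p.fft_size, d=1.0 / w.sample_rate_hz) / 1000.0
    )
    return Spectrogram(
        magnitude_db=mag_db,
        frame_times_s=frame_times,
        bin_freqs_khz=bin_freqs_khz,
        params=p,
        sample_rate_hz=w.sample_rate_hz,
    )
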