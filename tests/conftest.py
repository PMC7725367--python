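import numpy as np
import pytest

from usvkit.detect import Element, FrequencyTrack

HOP_S = 128 / 300_000  # default hop at 300 kHz


def build_element(
    freqs_khz,
    hop_s: float = HOP_S,
    t0_s: float = 1.0,
    amps_db=None,
    snr_db=None,
    quality: int = 0,
):
    """Element with a hand-specified frequency track (NaN = absent frame)."""
    freqs = np.asarray(freqs_khz, dtype=float)
    n = freqs.size
    times = t0_s + np.arange(n) * hop_s
    amps = np.full(n, -40.0) if amps_db is None else np.asarray(amps_db, float)
    snr = np.full(n, 30.0) if snr_db is None else np.asarray(snr_db, float)
    absent = np.isnan(freqs)
    amps = np.where(absent, np.nan, amps)
    snr = np.where(absent, np.nan, snr)
    track = FrequencyTrack(times_s=times, freqs_khz=freqs, amps_db=amps, snr_db=snr)
    return Element(
        start_s=t0_s - hop_s / 2,
        end_s=t0_s + (n - 1) * hop_s + hop_s / 2,
        track=track,
        quality=quality,
    )


@pytest.fixture
def element_factory():
    return build_element


@pytest.fixture
def tone_waveform():
    """1-second 50 kHz unit sine at 300 kHz."""
    from usvkit.spectro import Waveform

    fs = 300_000
    t = np.arange(fs) / fs
    return Waveform(np.sin(2 * np.pi * 50_000 * t) * 0.5, fs)
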