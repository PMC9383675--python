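"""Time-frequency analysis of audio tracks.

The spectrogram is the magnitude of the short-time Fourier transform:
the track is cut into windowed frames of ``window_length`` samples
advanced by ``hop_length``, each frame is Fourier transformed, and the
one-sided magnitudes are stacked column per frame. No padding is
applied, so the column count is exactly
``floor((n_samples - window_length) / hop_length) + 1``.

``frequency_offset`` shifts a track upward in frequency by single-
sideband modulation of the analytic signal (Hilbert transform), which
moves a tone at f to f + offset without creating a mirror image below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window, hilbert

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sonification import AudioTrack  # noqa: E402

__all__ = [
    "Spectrogram",
    "stft_spectrogram",
    "frequency_offset",
    "render_spectrogram",
    "render_spectrogram_pair",
]

DEFAULT_WINDOW = 256
DEFAULT_HOP = 128
DEFAULT_WINDOW_NAME = "hann"
DEFAULT_DB_FLOOR = -80.0


@dataclass(frozen=True)
class Spectrogram:
    """Linear STFT magnitudes (frequency rows x time columns)."""

    magnitudes: np.ndarray = field(repr=False)
    freq_axis: np.ndarray = field(repr=False)  # Hz per row, 0 .. rate/2
    time_axis: np.ndarray = field(repr=False)  # frame-center seconds per column
    window_length: int
    hop_length: int
    window_name: str
    sample_rate: int

    def to_db(self, floor: float = DEFAULT_DB_FLOOR) -> np.ndarray:
        """Magnitudes in dB relative to the global peak, clipped at floor."""
        ref = self.magnitudes.max()
        if ref == 0:
            return np.full_like(self.magnitudes, floor)
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(self.magnitudes / ref)
        return np.maximum(db, floor)


def stft_spectrogram(
    track: AudioTrack,
    window_length: int = DEFAULT_WINDOW,
    hop_length: int = DEFAULT_HOP,
    window_name: str = DEFAULT_WINDOW_NAME,
) -> Spectrogram:
    """Magnitude STFT of a track; requires at least one full window."""
    if track.samples.size < window_length:
        raise ValueError(
            f"track has {track.samples.size} samples, shorter than one "
            f"window of {window_length}"
        )
    if hop_length < 1:
        raise ValueError("hop_length must be >= 1")
    win = get_window(window_name, window_length, fftbins=True)
    frames = sliding_window_view(track.samples, window_length)[::hop_length]
    mags = np.abs(np.fft.rfft(frames * win, axis=1)).T
    freqs = np.fft.rfftfreq(window_length, d=1.0 / track.sample_rate)
    times = (np.arange(frames.shape[0]) * hop_length + window_length / 2) / track.sample_rate
    return Spectrogram(
        magnitudes=mags,
        freq_axis=freqs,
        time_axis=times,
        window_length=window_length,
        hop_length=hop_length,
        window_name=window_name,
        sample_rate=track.sample_rate,
    )


def _band_edge(samples: np.ndarray, sample_rate: int, rel_threshold: float = 1e-4) -> float:
    """Highest frequency whose magnitude exceeds rel_threshold of the peak."""
    spec = np.abs(np.fft.rfft(samples))
    peak = spec.max()
    if peak == 0:
        return 0.0
    freqs = np.fft.rfftfreq(samples.size, d=1.0 / sample_rate)
    return float(freqs[spec > rel_threshold * peak].max())


def frequency_offset(track: AudioTrack, offset_hz: float) -> AudioTrack:
    """Shift the whole track upward in frequency by ``offset_hz``.

    Single-sideband shift: the analytic signal is modulated by
    exp(2*pi*i*offset*t) and the real part taken, so a pure tone at f
    lands at f + offset with no mirror sideband. Content pushed past
    the Nyquist frequency (rate/2) is an error, not an alias.
    """
    if offset_hz < 0:
        raise ValueError("offset_hz must be nonnegative")
    if offset_hz == 0:
        return track
    nyquist = track.sample_rate / 2
    edge = _band_edge(track.samples, track.sample_rate)
    if edge + offset_hz > nyquist:
        raise ValueError(
            f"offset of {offset_hz} Hz pushes signal content at {edge:.1f} Hz "
            f"past the Nyquist frequency ({nyquist:.0f} Hz)"
        )
    t = np.arange(track.samples.size) / track.sample_rate
    shifted = np.real(hilbert(track.samples) * np.exp(2j * np.pi * offset_hz * t))
    top = np.abs(shifted).max()
    if top > 1.0:  # SSB envelope can overshoot the original peak slightly
        shifted = shifted / top
    meta = dict(track.source_meta)
    meta["frequency_offset_hz"] = meta.get("frequency_offset_hz", 0.0) + offset_hz
    return AudioTrack(samples=shifted, sample_rate=track.sample_rate, source_meta=meta)


def render_spectrogram(
    spec: Spectrogram,
    path: str | Path,
    db_floor: float = DEFAULT_DB_FLOOR,
    title: str | None = None,
    axis_offset_hz: float = 0.0,
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Render a spectrogram as a labeled raster image (dB color scale).

    ``axis_offset_hz`` relabels the frequency axis without touching the
    data, for plots where an offset is cosmetic rather than applied to
    the signal.
    """
    fig, ax = plt.subplots(figsize=(8, 4))
    _draw(ax, spec, db_floor, title, axis_offset_hz, vmin, vmax, fig)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_spectrogram_pair(
    spec_a: Spectrogram,
    spec_b: Spectrogram,
    path: str | Path,
    db_floor: float = DEFAULT_DB_FLOOR,
    titles: tuple[str, str] = ("a", "b"),
    axis_offset_hz: float = 0.0,
) -> None:
    """Two spectrograms side by side on a shared dB color scale."""
    fig, axes = plt.subplots(1, 2, figsize=(14, 4), sharey=True)
    for ax, spec, title in zip(axes, (spec_a, spec_b), titles):
        _draw(ax, spec, db_floor, title, axis_offset_hz, db_floor, 0.0, fig)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _draw(ax, spec, db_floor, title, axis_offset_hz, vmin, vmax, fig):
    db = spec.to_db(db_floor)
    mesh = ax.pcolormesh(
        spec.time_axis,
        spec.freq_axis + axis_offset_hz,
        db,
        shading="nearest",
        cmap="magma",
        vmin=db_floor if vmin is None else vmin,
        vmax=0.0 if vmax is None else vmax,
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="dB")
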