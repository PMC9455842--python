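"""Windowed spectral power, band averaging, ERSP and global field power.

Power is estimated by a sliding short-time Fourier transform with a
single Hanning taper: 100 ms windows, 50% overlap, and the squared
DFT magnitude divided by the sampling rate,
``S = |DFT(w · x)|² / Fs``.  The 100 ms window gives 10 Hz native
resolution; the 1 Hz analysis bins from 4 to 40 Hz are obtained by
zero-padding the DFT (pad factor 10 by default) and interpolating the
padded spectrum onto the integer-frequency grid.  Band averages use
the canonical delimitations theta 4–8, alpha 8–12, beta 12–30,
gamma 30–40 Hz (inclusive integer bins; delta is excluded from the
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import EpochSet

__all__ = [
    "SpectralConfig",
    "TFDecomposition",
    "BandPower",
    "BAND_BINS",
    "tf_power",
    "band_average",
    "ersp",
    "window_mean",
    "gfp",
    "dgfp",
]

BAND_BINS = {
    "theta": (4, 8),
    "alpha": (8, 12),
    "beta": (12, 30),
    "gamma": (30, 40),
}


@dataclass(frozen=True)
class SpectralConfig:
    window_ms: float = 100.0
    overlap: float = 0.5
    freqs_hz: tuple = tuple(range(4, 41))
    taper: str = "hanning"
    pad_factor: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.taper != "hanning":
            raise ValueError("only the hanning taper is implemented")


@dataclass
class TFDecomposition:
    """Time–frequency power: (..., freqs, windows), units µV²/Hz."""

    power: np.ndarray
    window_centers_ms: np.ndarray
    freqs_hz: np.ndarray
    units: str = "uV^2/Hz"

    def __post_init__(self) -> None:
        if self.units == "uV^2/Hz" and np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class BandPower:
    """Band-averaged power with the same leading axes as the input TF."""

    bands: dict  # name -> array (..., windows) or (...,) if collapsed
    window_centers_ms: np.ndarray | None

    def band_names(self) -> list[str]:
        return list(self.bands)


def _window_geometry(es_fs: float, n_samples: int, cfg: SpectralConfig) -> tuple[int, int, np.ndarray]:
    n_win = int(round(cfg.window_ms * es_fs / 1000.0))
    if n_win < 2:
        raise ValueError("window shorter than two samples")
    if n_win > n_samples:
        raise ValueError(
            f"window ({n_win} samples) longer than epoch ({n_samples} samples)"
        )
    hop = max(1, int(round(n_win * (1.0 - cfg.overlap))))
    starts = np.arange(0, n_samples - n_win + 1, hop)
    return n_win, hop, starts


def tf_power(es: EpochSet, cfg: SpectralConfig = SpectralConfig()) -> TFDecomposition:
    """Sliding-window Hanning power of an epoch set.

    Returns power with axes (trials, channels, freqs, windows).  Edge
    windows are not padded: the first and last window centers are
    chosen so every window lies inside the epoch.
    """
    max_f = max(cfg.freqs_hz)
    if max_f >= es.fs / 2:
        raise ValueError(f"max analysis frequency {max_f} ≥ Nyquist ({es.fs / 2})")
    n_win, hop, starts = _window_geometry(es.fs, es.n_samples, cfg)
    taper = np.hanning(n_win)
    nfft = int(cfg.pad_factor * n_win)
    native = np.fft.rfftfreq(nfft, 1.0 / es.fs)
    freqs = np.asarray(cfg.freqs_hz, dtype=float)
    times = es.times_ms
    centers = np.array([times[s] + 1000.0 * (n_win - 1) / (2 * es.fs) for s in starts])
    nt, nc = es.n_trials, es.n_channels
    out = np.empty((nt, nc, len(freqs), len(starts)))
    for w, s in enumerate(starts):
        seg = es.data[:, :, s : s + n_win] * taper
        spec = np.abs(np.fft.rfft(seg, n=nfft, axis=2)) ** 2 / es.fs
        # interpolate padded spectrum onto the requested 1 Hz bins
        out[:, :, :, w] = _interp_freqs(spec, native, freqs)
    return TFDecomposition(power=out, window_centers_ms=centers, freqs_hz=freqs)


def _interp_freqs(spec: np.ndarray, native: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(native, freqs)
    idx = np.clip(idx, 1, len(native) - 1)
    f0, f1 = native[idx - 1], native[idx]
    w1 = np.where(f1 > f0, (freqs - f0) / np.where(f1 > f0, f1 - f0, 1.0), 0.0)
    return spec[..., idx - 1] * (1.0 - w1) + spec[..., idx] * w1


def band_average(tf: TFDecomposition, bands: dict = BAND_BINS) -> BandPower:
    """Arithmetic mean of power over each band's inclusive integer bins."""
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (tf.freqs_hz >= lo) & (tf.freqs_hz <= hi)
        if not sel.any():
            raise ValueError(f"band {name} ({lo}-{hi} Hz) has no frequency bins")
        out[name] = tf.power[..., sel, :].mean(axis=-2)
    return BandPower(bands=out, window_centers_ms=tf.window_centers_ms.copy())


def ersp(tf: TFDecomposition, baseline_window_ms: tuple[float, float] | None = None) -> TFDecomposition:
    """Event-related spectral perturbation in dB.

    ``10·log10(power / baseline)`` with the baseline the mean power per
    trial, channel and frequency over the baseline windows (default:
    all pre-stimulus window centers).
    """
    centers = tf.window_centers_ms
    if baseline_window_ms is None:
        mask = centers < 0
    else:
        a, b = baseline_window_ms
        mask = (centers >= a) & (centers < b)
    if not mask.any():
        raise ValueError("baseline window covers no STFT windows")
    base = tf.power[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power is zero; ERSP undefined")
    db = 10.0 * np.log10(tf.power / base)
    return TFDecomposition(
        power=db,
        window_centers_ms=tf.window_centers_ms.copy(),
        freqs_hz=tf.freqs_hz.copy(),
        units="dB",
    )


def window_mean(bp: BandPower, window_ms: tuple[float, float]) -> BandPower:
    """Collapse the window axis to its mean over centers in [a, b) ms."""
    if bp.window_centers_ms is None:
        raise ValueError("band power already collapsed")
    a, b = window_ms
    mask = (bp.window_centers_ms >= a) & (bp.window_centers_ms < b)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms contains no STFT window centers")
    return BandPower(
        bands={k: v[..., mask].mean(axis=-1) for k, v in bp.bands.items()},
        window_centers_ms=None,
    )


def gfp(es: EpochSet, label: str | None = None) -> np.ndarray:
    """Global field power of a condition-mean topography per time point.

    The condition mean is taken over trials (optionally restricted to
    one outcome label); GFP(t) is the population standard deviation
    across channels of that mean topography.
    """
    data = es.data if label is None else es.data[es.labels == label]
    if data.shape[0] == 0:
        raise ValueError(f"no trials with label {label!r}")
    topo = data.mean(axis=0)  # (channels, samples)
    return topo.std(axis=0, ddof=0)


def dgfp(es: EpochSet, label_a: str = "remembered", label_b: str = "forgotten") -> np.ndarray:
    """GFP of the difference wave between two condition means."""
    for lab in (label_a, label_b):
        if not np.any(es.labels == lab):
            raise ValueError(f"no trials with label {lab!r}")
    diff = es.data[es.labels == label_a].mean(axis=0) - es.data[es.labels == label_b].mean(axis=0)
    return diff.std(axis=0, ddof=0)
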