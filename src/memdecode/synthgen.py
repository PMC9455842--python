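"""Synthetic behavior and EEG with planted subsequent-memory effects.

The generator inverts the measurement model the analysis assumes:
cortical dipoles emit band-limited oscillations whose variance depends
on the trial's later memory outcome, the spherical-head lead field
projects them to the scalp, and spatially correlated 1/f background
noise plus occasional high-amplitude artifacts are added.  Everything
is reproducible from one master seed; sub-streams are derived by fixed
offsets.

The behavioral model follows a declarative-memory paradigm: a list of
encoding words each judged abstract/concrete, then a retrieval list of
the old words plus new foils rated on a 1–4 recognition-confidence
scale.  Old words rated 3–4 are "remembered", 1–2 "forgotten"; new
words rated 3–4 are "false remembered".  Reaction times are log-normal
per outcome class with the ordering remembered < false remembered <
forgotten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .io_formats import Montage
from .sourceloc import LeadField

__all__ = [
    "RTModel",
    "SourceScenario",
    "TrialTiming",
    "RawRecording",
    "BANDS_HZ",
    "generate_behavior",
    "generate_raw",
]

BANDS_HZ = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 40.0),
}

# fixed offsets for deriving independent sub-streams from the master seed
_STREAM_BEHAVIOR = 11
_STREAM_SOURCES = 23
_STREAM_NOISE = 37
_STREAM_ARTIFACT = 53


@dataclass(frozen=True)
class RTModel:
    """Log-normal reaction-time parameters per outcome class (ms).

    ``median_ms`` maps outcome class to the log-normal median; ``sigma``
    is the common log-scale spread.  Defaults order the retrieval
    medians remembered < false_remembered < forgotten.
    """

    median_ms: dict = field(
        default_factory=lambda: {
            "remembered": 500.0,
            "false_remembered": 750.0,
            "forgotten": 1200.0,
            "encoding": 780.0,
        }
    )
    sigma: float = 0.35


@dataclass(frozen=True)
class SourceScenario:
    """Planted class-dependent source effects plus noise description.

    ``active_sources`` entries are
    ``(grid_index, band, gain_remembered, gain_forgotten, window)`` with
    ``window`` in {"pre", "ongoing"}; the gains multiply the oscillation
    *variance* for trials of each outcome class.  ``snr_db`` is the
    scalp-level signal-to-noise ratio in dB (non-finite disables the
    background noise entirely); ``noise_exponent`` is the 1/f slope of
    the background; ``artifact_rate`` the per-trial probability of a
    > 200 µV excursion.
    """

    active_sources: tuple = ()
    noise_exponent: float = 1.0
    artifact_rate: float = 0.0
    snr_db: float = 0.0
    seed: int = 0
    n_noise_dipoles: int = 40
    sensor_noise_frac: float = 0.1
    target_rms_uv: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        for src in self.active_sources:
            if len(src) != 5:
                raise ValueError(
                    "active source entries are (grid_index, band, "
                    "gain_remembered, gain_forgotten, window)"
                )
            _, band, gr, gf, window = src
            if band not in BANDS_HZ:
                raise ValueError(f"unknown band {band!r}")
            if window not in ("pre", "ongoing"):
                raise ValueError(f"unknown window {window!r}")
            if gr < 0 or gf < 0:
                raise ValueError("class gains are variance factors, must be >= 0")


@dataclass(frozen=True)
class TrialTiming:
    """Per-trial timeline in ms: fixation/pre interval, stimulus, gap."""

    pre_ms: float = 1000.0
    stim_ms: float = 2000.0
    iti_ms: float = 500.0

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.stim_ms + self.iti_ms


@dataclass
class RawRecording:
    """Continuous multichannel recording (µV) with event markers."""

    data: np.ndarray  # (channels, samples)
    fs: float
    events: list  # [(sample_index, event_code)]
    montage_ref: str = "montage62"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event sample index outside data bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(
    n_encoding: int = 250,
    n_new: int = 150,
    p_remember: float = 0.8,
    p_false_remember: float = 0.2,
    rt_model: RTModel = RTModel(),
    seed: int = 0,
    p_judged_remembered: float = 0.95,
    p_judged_forgotten: float = 0.83,
) -> pd.DataFrame:
    """Behavioral table for one synthetic subject.

    One row per trial: ``n_encoding`` encoding rows followed by
    ``n_encoding + n_new`` retrieval rows (old plus new words,
    shuffled).  Confidence is only assigned on retrieval rows; each old
    word draws remembered (confidence 3–4) with probability
    ``p_remember``, each new word draws false-remembered with
    probability ``p_false_remember``.  Encoding rows record the
    abstract/concrete judgment, made with a class-dependent completion
    probability (remembered items are judged more often).
    """
    if not 0.0 < p_remember < 1.0 and p_remember != 1.0:
        raise ValueError("p_remember must be in (0, 1]")
    if not 0.0 <= p_false_remember <= 1.0:
        raise ValueError("p_false_remember must be in [0, 1]")
    if n_encoding <= 0 or n_new <= 0:
        raise ValueError("word counts must be positive")
    rng = np.random.default_rng([seed, _STREAM_BEHAVIOR])

    old_ids = np.arange(1, n_encoding + 1)
    new_ids = np.arange(n_encoding + 1, n_encoding + n_new + 1)

    remembered = rng.random(n_encoding) < p_remember
    false_rem = rng.random(n_new) < p_false_remember
    conf_old = np.where(remembered, rng.integers(3, 5, n_encoding), rng.integers(1, 3, n_encoding))
    conf_new = np.where(false_rem, rng.integers(3, 5, n_new), rng.integers(1, 3, n_new))

    def _rt(cls: str, n: int) -> np.ndarray:
        mu = np.log(rt_model.median_ms[cls])
        return np.exp(rng.normal(mu, rt_model.sigma, n))

    # encoding rows -------------------------------------------------------
    judged = np.where(
        remembered,
        rng.random(n_encoding) < p_judged_remembered,
        rng.random(n_encoding) < p_judged_forgotten,
    )
    judgment = np.where(judged, np.where(rng.random(n_encoding) < 0.5, "abstract", "concrete"), "NA")
    enc = pd.DataFrame(
        {
            "word_id": old_ids,
            "phase": "encoding",
            "is_old": True,
            "judgment": judgment,
            "confidence": np.nan,
            "rt_ms": _rt("encoding", n_encoding),
        }
    )

    # retrieval rows ------------------------------------------------------
    ret = pd.DataFrame(
        {
            "word_id": np.concatenate([old_ids, new_ids]),
            "phase": "retrieval",
            "is_old": np.concatenate([np.ones(n_encoding, bool), np.zeros(n_new, bool)]),
            "judgment": "NA",
            "confidence": np.concatenate([conf_old, conf_new]).astype(float),
        }
    )
    ret = ret.iloc[rng.permutation(len(ret))].reset_index(drop=True)
    cls = np.where(
        ret["is_old"],
        np.where(ret["confidence"] >= 3, "remembered", "forgotten"),
        np.where(ret["confidence"] >= 3, "false_remembered", "remembered"),
    )
    # correct rejections draw from the fast (confident) RT distribution
    rts = np.empty(len(ret))
    for c in np.unique(cls):
        m = cls == c
        rts[m] = _rt(c if c in rt_model.median_ms else "remembered", int(m.sum()))
    ret["rt_ms"] = rts
    return pd.concat([enc, ret], ignore_index=True)


def encoding_outcomes(behavior: pd.DataFrame) -> np.ndarray:
    """Later-memory outcome per encoding trial, in encoding row order."""
    ret = behavior[behavior["phase"] == "retrieval"]
    conf = dict(zip(ret["word_id"], ret["confidence"]))
    enc = behavior[behavior["phase"] == "encoding"]
    out = np.array(
        [
            "unlabeled"
            if w not in conf or not np.isfinite(conf[w])
            else ("remembered" if conf[w] >= 3 else "forgotten")
            for w in enc["word_id"]
        ],
        dtype=object,
    )
    return out


def retrieval_outcomes(behavior: pd.DataFrame) -> np.ndarray:
    """Outcome class per retrieval trial (correct rejections unlabeled)."""
    ret = behavior[behavior["phase"] == "retrieval"]
    out = np.where(
        ret["is_old"],
        np.where(ret["confidence"] >= 3, "remembered", "forgotten"),
        np.where(ret["confidence"] >= 3, "false_remembered", "unlabeled"),
    )
    return out.astype(object)


# ---------------------------------------------------------------------------
# EEG synthesis


def _bandlimited_noise(rng: np.random.Generator, band: tuple[float, float], n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (Hz)."""
    low, high = band
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal(n + int(fs))  # pad to flush filter transient
    y = sp_signal.sosfilt(sos, x)[int(fs) :]
    sd = y.std()
    return y / sd if sd > 0 else y


def _one_over_f_noise(rng: np.random.Generator, exponent: float, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Rows of 1/f^exponent noise via spectral shaping, unit variance."""
    n_rows, n = shape
    nf = n // 2 + 1
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.ones(nf)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = (rng.standard_normal((n_rows, nf)) + 1j * rng.standard_normal((n_rows, nf))) * amp
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_raw(
    montage: Montage,
    leadfield: LeadField,
    behavior: pd.DataFrame,
    scenario: SourceScenario,
    fs: float = 1000.0,
    trial_timing: TrialTiming = TrialTiming(),
    phase: str = "encoding",
) -> RawRecording:
    """Continuous scalp EEG for one task phase of one subject.

    Per trial, each scenario source emits a band-limited oscillation in
    its window (pre-stimulus or on-going stimulus) whose variance is
    multiplied by the class gain matching the trial's memory outcome;
    scalp data is ``leadfield · sources`` plus spatially correlated
    1/f background, plus forced > 200 µV excursions on an
    ``artifact_rate`` fraction of trials.  ``snr_db`` is interpreted
    per band: each source's unit-gain scalp power is set relative to
    the background power inside that source's frequency band, so a
    planted alpha oscillation rides on the (strong) low-frequency
    background just as a gamma oscillation rides on the (weak)
    high-frequency tail — the 1/f model makes a broadband SNR
    meaningless.  Background RMS is scaled to
    ``scenario.target_rms_uv`` µV.  Event markers (code 1) sit at each
    stimulus onset.
    """
    if leadfield.gain.shape[0] != montage.n_channels:
        raise ValueError(
            f"leadfield channel axis ({leadfield.gain.shape[0]}) does not "
            f"match montage ({montage.n_channels} channels)"
        )
    n_src = leadfield.grid.n_sources
    for src in scenario.active_sources:
        if not 0 <= src[0] < n_src:
            raise ValueError(f"grid_index {src[0]} invalid for {n_src}-source grid")

    rows = behavior[behavior["phase"] == phase].reset_index(drop=True)
    if phase == "encoding":
        outcomes = encoding_outcomes(behavior)
    else:
        outcomes = retrieval_outcomes(behavior)
    n_trials = len(rows)
    slot = int(round(trial_timing.total_ms * fs / 1000.0))
    pre = int(round(trial_timing.pre_ms * fs / 1000.0))
    stim = int(round(trial_timing.stim_ms * fs / 1000.0))
    n_samples = n_trials * slot + slot  # trailing pad keeps last epoch in bounds
    n_ch = montage.n_channels
    onsets = pre + slot * np.arange(n_trials)

    # background first: planted oscillations are scaled against it per band
    rng_noise = np.random.default_rng([scenario.seed, _STREAM_NOISE])
    band_noise_power: dict = {}
    if np.isfinite(scenario.snr_db):
        # spatially correlated background: 1/f dipole noise through the
        # lead field, plus a white sensor-noise floor
        k = min(scenario.n_noise_dipoles, n_src)
        idx = rng_noise.choice(n_src, size=k, replace=False)
        moments = rng_noise.standard_normal((k, 3))
        moments /= np.linalg.norm(moments, axis=1, keepdims=True)
        mix = np.einsum("cqa,qa->cq", leadfield.gain[:, idx, :], moments)  # (ch, k)
        src_noise = _one_over_f_noise(rng_noise, scenario.noise_exponent, (k, n_samples), fs)
        noise = mix @ src_noise
        noise /= max(noise.std(), 1e-30)
        sensor = rng_noise.standard_normal((n_ch, n_samples))
        noise = (1.0 - scenario.sensor_noise_frac) * noise + scenario.sensor_noise_frac * (
            sensor / sensor.std()
        )
        noise *= scenario.target_rms_uv / max(noise.std(), 1e-30)
        # realized channel-summed background power per band (Parseval)
        spec = np.abs(np.fft.rfft(noise, axis=1)) ** 2
        freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
        total = spec.sum()
        for band, (lo, hi) in BANDS_HZ.items():
            sel = (freqs >= lo) & (freqs <= hi)
            band_noise_power[band] = spec[:, sel].sum() / total * noise.var() * n_ch
        data = noise
    else:
        data = np.zeros((n_ch, n_samples))

    rng_src = np.random.default_rng([scenario.seed, _STREAM_SOURCES])
    snr_lin = 10.0 ** (scenario.snr_db / 10.0) if np.isfinite(scenario.snr_db) else 1.0
    # radial unit moment at each active source: strongest scalp projection
    for grid_index, band, g_rem, g_forg, window in scenario.active_sources:
        p = leadfield.grid.positions[grid_index]
        r = np.linalg.norm(p)
        orient = p / r if r > 0 else np.array([0.0, 0.0, 1.0])
        topo = leadfield.gain[:, grid_index, :] @ orient  # (channels,)
        topo_power = float(topo @ topo)
        if band_noise_power:
            # unit class gain -> channel-summed in-band power snr_db above
            # the in-band background
            amp = np.sqrt(snr_lin * band_noise_power[band] / topo_power)
        else:
            amp = scenario.target_rms_uv / np.sqrt(max(topo_power / n_ch, 1e-30))
        for t in range(n_trials):
            gain = g_rem if outcomes[t] == "remembered" else g_forg
            if gain == 0.0:
                continue
            if window == "pre":
                a, b = onsets[t] - pre, onsets[t]
            else:
                a, b = onsets[t], onsets[t] + stim
            wave = _bandlimited_noise(rng_src, BANDS_HZ[band], b - a, fs)
            data[:, a:b] += amp * np.sqrt(gain) * topo[:, None] * wave[None, :]

    rng_art = np.random.default_rng([scenario.seed, _STREAM_ARTIFACT])
    art_len = int(round(0.2 * fs))
    bump = 400.0 * np.hanning(art_len)  # guaranteed > 200 µV excursion
    for t in range(n_trials):
        if rng_art.random() < scenario.artifact_rate:
            ch = rng_art.choice(n_ch, size=4, replace=False)
            start = onsets[t] - pre + int(rng_art.integers(0, pre + stim - art_len))
            sign = 1.0 if rng_art.random() < 0.5 else -1.0
            data[np.ix_(ch, np.arange(start, start + art_len))] += sign * bump

    events = [(int(s), 1) for s in onsets]
    return RawRecording(data=data, fs=fs, events=events, montage_ref=montage_reference_name(montage))


def montage_reference_name(montage: Montage) -> str:
    return f"montage{montage.n_channels}"
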