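"""Preprocessing chain for continuous and epoched EEG.

Fixed stage order: downsample → band-pass → re-reference → epoch →
baseline-correct → amplitude rejection → channel interpolation →
outcome labeling.  Filtering is zero-phase (forward–backward
Butterworth), so passband latencies are preserved and the effective
attenuation is the squared single-pass magnitude response.  Amplitude
rejection uses strict exceedance: a trial is removed iff
``max |x| > threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .io_formats import EpochSet, Montage
from .synthgen import RawRecording

__all__ = [
    "downsample",
    "bandpass",
    "bandpass_epochs",
    "rereference_average",
    "epoch",
    "baseline_correct",
    "reject_amplitude",
    "interpolate_channels",
    "label_trials",
    "run_preprocess",
]

logger = logging.getLogger(__name__)


def downsample(raw: RawRecording, target_fs: float) -> RawRecording:
    """Resample with anti-alias filtering; events snap to the new grid.

    The resampling ratio must be rational (it always is for integer
    rates).  Event indices are remapped by the ratio and rounded to the
    nearest sample, ties to even.
    """
    if target_fs >= raw.fs:
        raise ValueError(f"target_fs ({target_fs}) must be below fs ({raw.fs})")
    frac = Fraction(target_fs / raw.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = sp_signal.resample_poly(raw.data, up, down, axis=1)
    ratio = target_fs / raw.fs
    events = [(int(np.rint(s * ratio)), code) for s, code in raw.events]
    events = [(min(s, data.shape[1] - 1), c) for s, c in events]
    return RawRecording(data=data, fs=float(target_fs), events=events, montage_ref=raw.montage_ref)


def _butter_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={fs}")
    return sp_signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(raw: RawRecording, low: float = 0.5, high: float = 40.0, order: int = 5) -> RawRecording:
    """Zero-phase Butterworth band-pass on a continuous recording.

    Forward–backward application of an ``order``-th order filter:
    -3 dB per pass at each cutoff, no group delay.  Implemented with
    second-order sections for numerical stability.
    """
    sos = _butter_sos(low, high, order, raw.fs)
    data = sp_signal.sosfiltfilt(sos, raw.data, axis=1)
    return RawRecording(data=data, fs=raw.fs, events=list(raw.events), montage_ref=raw.montage_ref)


def bandpass_epochs(es: EpochSet, low: float, high: float, order: int = 5) -> EpochSet:
    """Zero-phase band-pass applied per trial along the sample axis."""
    sos = _butter_sos(low, high, order, es.fs)
    data = sp_signal.sosfiltfilt(sos, es.data, axis=2)
    return replace(es, data=data, meta=es.meta.copy())


def rereference_average(obj: RawRecording | EpochSet):
    """Subtract the instantaneous mean across channels (idempotent)."""
    if isinstance(obj, RawRecording):
        if obj.n_channels < 2:
            raise ValueError("average reference needs at least two channels")
        data = obj.data - obj.data.mean(axis=0, keepdims=True)
        return RawRecording(data=data, fs=obj.fs, events=list(obj.events), montage_ref=obj.montage_ref)
    if obj.n_channels < 2:
        raise ValueError("average reference needs at least two channels")
    data = obj.data - obj.data.mean(axis=1, keepdims=True)
    return replace(obj, data=data, meta=obj.meta.copy())


def epoch(
    raw: RawRecording,
    behavior_rows: pd.DataFrame | None = None,
    window_ms: tuple[float, float] = (-1000.0, 1000.0),
    montage_ref: str | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> EpochSet:
    """Cut trials around event markers, half-open window in ms.

    ``behavior_rows`` (one row per event, in event order) becomes the
    per-trial metadata; events too close to a recording edge are
    dropped with a logged warning, together with their metadata rows.
    """
    a_ms, b_ms = window_ms
    a = int(round(a_ms * raw.fs / 1000.0))
    b = int(round(b_ms * raw.fs / 1000.0))
    if b <= a:
        raise ValueError("empty epoch window")
    trials, kept = [], []
    for i, (s, _code) in enumerate(raw.events):
        lo, hi = s + a, s + b
        if lo < 0 or hi > raw.n_samples:
            logger.warning("event %d at sample %d lacks full window coverage; dropped", i, s)
            continue
        trials.append(raw.data[:, lo:hi])
        kept.append(i)
    if behavior_rows is not None:
        if len(behavior_rows) != len(raw.events):
            raise ValueError(
                f"behavior rows ({len(behavior_rows)}) must match events ({len(raw.events)})"
            )
        meta = behavior_rows.iloc[kept].reset_index(drop=True)
    else:
        meta = pd.DataFrame({"event_index": kept})
    data = np.stack(trials) if trials else np.empty((0, raw.n_channels, b - a))
    return EpochSet(
        data=data,
        fs=raw.fs,
        t0_offset_ms=1000.0 * a / raw.fs,
        labels=np.array(["unlabeled"] * len(trials), dtype=object),
        meta=meta,
        montage_ref=montage_ref or raw.montage_ref,
        space="sensor",
        channel_names=channel_names,
    )


def baseline_correct(es: EpochSet, mode: str = "whole") -> EpochSet:
    """Remove the per-trial per-channel mean.

    ``mode="whole"`` demeans over the entire epoch; ``mode="prestim"``
    subtracts the mean of samples before stimulus onset instead.
    """
    if mode == "whole":
        base = es.data.mean(axis=2, keepdims=True)
    elif mode == "prestim":
        mask = es.times_ms < 0
        if not mask.any():
            raise ValueError("no pre-stimulus samples for baseline")
        base = es.data[:, :, mask].mean(axis=2, keepdims=True)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return replace(es, data=es.data - base, meta=es.meta.copy())


def reject_amplitude(es: EpochSet, threshold_uv: float = 200.0) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose peak absolute amplitude strictly exceeds the threshold.

    A trial peaking at exactly the threshold is kept.  Returns the
    pruned epochs and the indices of rejected trials.
    """
    peaks = np.max(np.abs(es.data), axis=(1, 2))
    rejected = np.where(peaks > threshold_uv)[0]
    keep = np.setdiff1d(np.arange(es.n_trials), rejected)
    return es.select_trials(keep), rejected


def _perrin_g(x: np.ndarray, m: int = 4, n_terms: int = 20) -> np.ndarray:
    """Spherical-spline kernel g(cos angle), order-m Legendre expansion."""
    out = np.zeros_like(x, dtype=float)
    p_prev = np.ones_like(out)
    p_cur = np.asarray(x, dtype=float).copy()
    for n in range(1, n_terms + 1):
        if n > 1:
            p_next = ((2 * n - 1) * x * p_cur - (n - 1) * p_prev) / n
            p_prev, p_cur = p_cur, p_next
        out += (2 * n + 1) / (n * (n + 1)) ** m * p_cur
    return out / (4.0 * np.pi)


def interpolate_channels(
    es: EpochSet,
    bad: list[str],
    montage: Montage,
    m: int = 4,
    n_terms: int = 20,
    reg: float = 1e-8,
) -> EpochSet:
    """Replace bad channels by spherical-spline interpolation.

    Classic thin-plate spline on the sphere (order-``m`` Legendre
    kernel) fitted to the good channels with a constant term; good
    channels are untouched.  Reproduces constants exactly.
    """
    if not bad:
        return replace(es, data=es.data.copy(), meta=es.meta.copy())
    unknown = set(bad) - set(montage.labels)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    bad_idx = np.array([montage.index(ch) for ch in bad])
    good_idx = np.setdiff1d(np.arange(montage.n_channels), bad_idx)
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    pos = montage.positions
    Ggg = _perrin_g(pos[good_idx] @ pos[good_idx].T, m, n_terms)
    Gbg = _perrin_g(pos[bad_idx] @ pos[good_idx].T, m, n_terms)
    ng = len(good_idx)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = Ggg + reg * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    Ainv = np.linalg.pinv(A)
    # linear operator: bad values = M @ good values
    M = np.hstack([Gbg, np.ones((len(bad_idx), 1))]) @ Ainv[:, :ng]
    data = es.data.copy()
    data[:, bad_idx, :] = np.einsum("bg,tgs->tbs", M, es.data[:, good_idx, :])
    return replace(es, data=data, meta=es.meta.copy())


def label_trials(es: EpochSet, behavior: pd.DataFrame) -> EpochSet:
    """Assign memory-outcome labels from the retrieval confidences.

    Encoding trials: remembered if the word was later rated 3–4,
    forgotten if rated 1–2.  Retrieval trials: old words follow the
    same rule; new words rated 3–4 are false_remembered, and correct
    rejections stay unlabeled.  Encoding trials are never labeled
    false_remembered.
    """
    if "word_id" not in es.meta.columns or "phase" not in es.meta.columns:
        raise ValueError("epoch metadata must carry word_id and phase")
    ret = behavior[behavior["phase"] == "retrieval"]
    conf = dict(zip(ret["word_id"], ret["confidence"]))
    labels = np.empty(es.n_trials, dtype=object)
    for i, row in es.meta.iterrows():
        w = row["word_id"]
        c = conf.get(w, np.nan)
        if row["phase"] == "encoding":
            if not np.isfinite(c):
                labels[i] = "unlabeled"
            else:
                labels[i] = "remembered" if c >= 3 else "forgotten"
        else:
            if not np.isfinite(c):
                labels[i] = "unlabeled"
            elif row["is_old"]:
                labels[i] = "remembered" if c >= 3 else "forgotten"
            else:
                labels[i] = "false_remembered" if c >= 3 else "unlabeled"
    return replace(es, labels=labels, meta=es.meta.copy())


def run_preprocess(
    raw: RawRecording,
    behavior: pd.DataFrame,
    montage: Montage,
    phase: str = "encoding",
    target_fs: float | None = 250.0,
    band: tuple[float, float] = (0.5, 40.0),
    filter_order: int = 5,
    window_ms: tuple[float, float] = (-1000.0, 1000.0),
    baseline_mode: str = "whole",
    reject_uv: float = 200.0,
    bad_channels: list[str] | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Full chain on one recording; returns epochs and rejected indices."""
    if target_fs is not None and target_fs < raw.fs:
        raw = downsample(raw, target_fs)
    raw = bandpass(raw, band[0], band[1], filter_order)
    raw = rereference_average(raw)
    rows = behavior[behavior["phase"] == phase].reset_index(drop=True)
    es = epoch(raw, rows, window_ms, channel_names=montage.labels)
    es = baseline_correct(es, baseline_mode)
    es, rejected = reject_amplitude(es, reject_uv)
    es = interpolate_channels(es, bad_channels or [], montage)
    es = label_trials(es, behavior)
    n_rem = int(np.sum(es.labels == "remembered"))
    n_forg = int(np.sum(es.labels == "forgotten"))
    logger.info(
        "preprocess: %d trials kept (%d rejected); remembered=%d forgotten=%d",
        es.n_trials, len(rejected), n_rem, n_forg,
    )
    return es, rejected
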