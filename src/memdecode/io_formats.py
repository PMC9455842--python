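"""Containers and file formats shared by every pipeline stage.

Two in-memory types carry the data between stages: :class:`Montage`
(channel labels plus unit-sphere positions) and :class:`EpochSet`
(trials × channels × samples with per-trial behavioral metadata).
On disk, epochs live in an NPZ container with a JSON metadata record
embedded alongside the arrays; montages and behavior tables are plain
TSV.  All time bookkeeping is in milliseconds relative to stimulus
onset, with extraction windows half-open ``[a, b)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "EpochSet",
    "FormatError",
    "read_montage",
    "default_montage",
    "read_epochs",
    "write_epochs",
    "read_behavior",
    "write_behavior",
    "write_report",
    "read_report",
]

TRIAL_LABELS = ("remembered", "forgotten", "false_remembered", "unlabeled")


class FormatError(ValueError):
    """Malformed input file or inconsistent container contents."""


@dataclass(frozen=True)
class Montage:
    """EEG sensor layout on a unit sphere, head-centered.

    Parameters
    ----------
    labels
        Unique channel names (10–20 nomenclature for the shipped cap).
    positions
        ``(n_channels, 3)`` coordinates, each row unit-norm.
    reference
        Recording reference: a channel label, ``"average"``, or
        ``"FCz-physical"`` for a physical FCz reference that is not one
        of the recorded channels.
    ground
        Ground electrode label (bookkeeping only).
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    reference: str = "FCz-physical"
    ground: str = "FPz"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise FormatError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise FormatError(f"duplicate channel labels: {dupes}")
        if not np.all(np.isfinite(pos)):
            raise FormatError("non-finite channel coordinates")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise FormatError("positions must be unit-norm (renormalize on read)")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def read_montage(path: str | Path) -> Montage:
    """Read a montage TSV with columns ``label, x, y, z``.

    Coordinates are renormalized to unit radius, so any consistent
    length unit on input yields the same montage.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: montage needs columns {sorted(required)}")
    labels = [str(l) for l in df["label"]]
    seen: set[str] = set()
    for i, lab in enumerate(labels):
        if lab in seen:
            raise FormatError(f"{path}: line {i + 2}: duplicate label {lab!r}")
        seen.add(lab)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        bad = int(np.where(~np.isfinite(pos).all(axis=1))[0][0])
        raise FormatError(f"{path}: line {bad + 2}: non-finite coordinates")
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        bad = int(np.where(norms == 0)[0][0])
        raise FormatError(f"{path}: line {bad + 2}: zero-length position")
    pos = pos / norms[:, None]
    return Montage(labels=tuple(labels), positions=pos)


def default_montage() -> Montage:
    """The shipped 62-channel 10–20 cap (FCz reference, FPz ground)."""
    with resources.as_file(
        resources.files("memdecode.data").joinpath("montage62.tsv")
    ) as p:
        return read_montage(p)


@dataclass
class EpochSet:
    """Epoched data: ``trials × channels × samples`` plus metadata.

    ``space`` distinguishes sensor-level voltages (µV) from source- or
    parcel-level current estimates; ``montage_ref`` names the montage
    (sensor space) or source grid / parcellation (source space) the
    channel axis refers to.  ``t0_offset_ms`` is the time of sample 0
    relative to stimulus onset (negative for pre-stimulus samples).
    """

    data: np.ndarray
    fs: float
    t0_offset_ms: float
    labels: np.ndarray
    meta: pd.DataFrame
    montage_ref: str = "montage62"
    space: str = "sensor"
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("data must be trials × channels × samples")
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.data.shape[0],):
            raise FormatError(
                f"labels axis {self.labels.shape} does not match "
                f"{self.data.shape[0]} trials"
            )
        bad = set(self.labels) - set(TRIAL_LABELS)
        if bad:
            raise FormatError(f"unknown trial labels: {sorted(bad)}")
        if len(self.meta) != self.data.shape[0]:
            raise FormatError("meta rows must match trial axis")
        if self.channel_names is not None:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.data.shape[1]:
                raise FormatError("channel_names length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample times in ms relative to stimulus onset."""
        return self.t0_offset_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for the half-open window [a, b) ms."""
        a, b = window_ms
        t = self.times_ms
        return (t >= a) & (t < b)

    def crop(self, window_ms: tuple[float, float]) -> "EpochSet":
        mask = self.time_mask(window_ms)
        if not mask.any():
            raise ValueError(f"window {window_ms} covers no samples")
        first = int(np.argmax(mask))
        return replace(
            self,
            data=self.data[:, :, mask],
            t0_offset_ms=float(self.times_ms[first]),
            meta=self.meta.copy(),
        )

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )


def write_epochs(es: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to an NPZ container.

    Arrays are stored at full float64 precision; metadata (fs, offsets,
    labels, behavior table) is embedded as one JSON record so the file
    is self-describing.
    """
    path = Path(path)
    meta_json = json.dumps(
        {
            "fs": es.fs,
            "t0_offset_ms": es.t0_offset_ms,
            "montage_ref": es.montage_ref,
            "space": es.space,
            "channel_names": list(es.channel_names) if es.channel_names else None,
            "meta_table": es.meta.to_json(orient="split"),
        }
    )
    np.savez_compressed(
        path,
        data=es.data,
        labels=np.asarray(es.labels, dtype=str),
        meta_json=np.asarray(meta_json),
    )


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        if "meta_json" not in npz or "data" not in npz or "labels" not in npz:
            raise FormatError(f"{path}: not an epoch container (missing arrays)")
        info = json.loads(str(npz["meta_json"]))
        meta = pd.read_json(pd.io.common.StringIO(info["meta_table"]), orient="split")
        ch = info.get("channel_names")
        return EpochSet(
            data=npz["data"],
            fs=float(info["fs"]),
            t0_offset_ms=float(info["t0_offset_ms"]),
            labels=npz["labels"].astype(object),
            meta=meta,
            montage_ref=info["montage_ref"],
            space=info["space"],
            channel_names=tuple(ch) if ch else None,
        )


BEHAVIOR_COLUMNS = [
    "word_id",
    "phase",
    "is_old",
    "judgment",
    "confidence",
    "rt_ms",
]


def write_behavior(records: pd.DataFrame, path: str | Path) -> None:
    """Write the behavior/event table as TSV (one row per trial)."""
    missing = set(BEHAVIOR_COLUMNS) - set(records.columns)
    if missing:
        raise FormatError(f"behavior table missing columns {sorted(missing)}")
    records[BEHAVIOR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: behavior table missing {sorted(missing)}")
    return df


def write_report(table: pd.DataFrame, path: str | Path, units: dict | None = None) -> None:
    """Emit a result table as TSV plus a JSON twin with explicit units.

    Used for the AUC summary tables (feature space × band × model cells
    with mean ± sd across folds/subjects) and statistical summaries.
    """
    path = Path(path)
    table.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    payload = {
        "units": units or {},
        "columns": list(table.columns),
        "rows": json.loads(table.to_json(orient="records")),
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=1))


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    return pd.read_csv(path.with_suffix(".tsv"), sep="\t")


def read_brainvision(vhdr_path: str | Path):
    """Optional BrainVision (.vhdr/.vmrk/.eeg) reader via MNE.

    Returns a :class:`memdecode.synthgen.RawRecording`.  Requires the
    optional ``mne`` dependency; only reading is supported.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover - interop extra
        raise ImportError("BrainVision reading requires the 'mne' extra") from e
    from .synthgen import RawRecording

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    events, _ = mne.events_from_annotations(raw, verbose="error")
    return RawRecording(
        data=raw.get_data() * 1e6,  # MNE stores volts; we carry µV
        fs=float(raw.info["sfreq"]),
        events=[(int(s), int(code)) for s, _, code in events],
        montage_ref="brainvision",
    )
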