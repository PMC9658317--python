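"""Epoched-EEG data model and on-disk trial container.

A :class:`TrialSet` is the currency passed between every stage of the
pipeline: a ``trials x channels x samples`` tensor of epoched EEG (µV), one
integer label per trial in {1, 2}, the sampling rate, and ordered channel
names.  The on-disk container is deliberately simple and language-agnostic:
one JSON metadata file plus one raw little-endian float64 matrix per trial
(channels-major), which round-trips bit-exactly.

An optional importer epochs a continuous multichannel recording stored in a
MATLAB MAT-file laid out like the public BCI Competition III IVa release
(``cnt`` continuous data, ``mrk`` cue positions/labels, ``nfo`` channel
names and sampling rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TrialSet",
    "Montage",
    "write_trialset",
    "read_trialset",
    "import_competition_mat",
]

_METADATA_FILE = "trialset.json"

#: the 17 sensorimotor-area channels used with the public dataset layout
SENSORIMOTOR_17 = [
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
]


@dataclass
class TrialSet:
    """Epoched multichannel EEG trials with class labels.

    Parameters
    ----------
    data:
        Real array of shape ``(n_trials, n_channels, n_samples)`` in µV.
    labels:
        Integer label per trial; fitting operations require both classes
        (1 and 2) to be present.
    fs:
        Sampling rate in Hz.
    channel_names:
        Ordered, duplicate-free channel names, one per channel.
    t0:
        Time of the first sample relative to the cue, in seconds.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = list(self.channel_names)
        self.validate()

    # -- shape accessors -------------------------------------------------
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
    def times(self) -> np.ndarray:
        """Sample times relative to the cue (s)."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def validate(self, require_both_classes: bool = False) -> None:
        """Raise ``ValueError`` naming the offending field on violation."""
        if self.data.ndim != 3:
            raise ValueError(
                f"data: expected 3-D (trials, channels, samples), got {self.data.ndim}-D"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels: expected {self.data.shape[0]} entries, got {self.labels.shape}"
            )
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise ValueError(f"labels: values must be in {{1, 2}}, found {sorted(bad)}")
        if not self.fs > 0:
            raise ValueError(f"fs: must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"channel_names: expected {self.data.shape[1]} names, "
                f"got {len(self.channel_names)}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names: duplicate names")
        if not np.isfinite(self.data).all():
            raise ValueError("data: contains non-finite values")
        if require_both_classes:
            present = set(np.unique(self.labels))
            if present != {1, 2}:
                raise ValueError(
                    f"labels: both classes required for fitting, present: {sorted(present)}"
                )

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def subset(self, idx) -> "TrialSet":
        """Row-subset (trials) view; shares no mutable state."""
        return TrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            t0=self.t0,
        )


@dataclass
class Montage:
    """Ordered channel names with optional 2-D head-schematic coordinates."""

    channel_names: list[str]
    coordinates: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.channel_names = list(self.channel_names)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names: duplicate names")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (len(self.channel_names), 2):
                raise ValueError(
                    "coordinates: expected one (x, y) pair per channel, got "
                    f"shape {self.coordinates.shape}"
                )


# ---------------------------------------------------------------------------
# on-disk container
# ---------------------------------------------------------------------------

def write_trialset(ts: TrialSet, path) -> None:
    """Write a :class:`TrialSet` to ``path`` (a directory).

    Layout: ``trialset.json`` with fs, t0, labels, channel names, dtype and
    per-trial shape, plus ``trial_00000.bin`` ... one raw little-endian
    float64 matrix per trial, channels-major (C order).  Units are metadata
    only; no rescaling is applied.
    """
    ts.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "cissacsp-trialset-v1",
        "fs": float(ts.fs),
        "t0": float(ts.t0),
        "n_trials": int(ts.n_trials),
        "labels": [int(x) for x in ts.labels],
        "channel_names": ts.channel_names,
        "dtype": "<f8",
        "trial_shape": [int(ts.n_channels), int(ts.n_samples)],
        "layout": "channels-major",
    }
    (path / _METADATA_FILE).write_text(json.dumps(meta, indent=1))
    for i in range(ts.n_trials):
        ts.data[i].astype("<f8").tofile(path / f"trial_{i:05d}.bin")


def read_trialset(path) -> TrialSet:
    """Read a :class:`TrialSet` written by :func:`write_trialset`.

    Raises ``FileNotFoundError`` when the metadata file is absent and
    ``ValueError`` naming the offending file on any shape mismatch.
    """
    path = Path(path)
    meta_path = path / _METADATA_FILE
    if not meta_path.is_file():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    C, P = (int(x) for x in meta["trial_shape"])
    n = int(meta["n_trials"])
    dtype = np.dtype(meta["dtype"])
    data = np.empty((n, C, P), dtype=np.float64)
    for i in range(n):
        fname = path / f"trial_{i:05d}.bin"
        if not fname.is_file():
            raise ValueError(f"{fname.name}: declared in metadata but missing")
        raw = np.fromfile(fname, dtype=dtype)
        if raw.size != C * P:
            raise ValueError(
                f"{fname.name}: expected {C * P} values for shape ({C}, {P}), "
                f"got {raw.size}"
            )
        data[i] = raw.reshape(C, P)
    return TrialSet(
        data=data,
        labels=np.asarray(meta["labels"], dtype=np.int64),
        fs=float(meta["fs"]),
        channel_names=list(meta["channel_names"]),
        t0=float(meta.get("t0", 0.0)),
    )


# ---------------------------------------------------------------------------
# competition MAT-file import
# ---------------------------------------------------------------------------

def import_competition_mat(
    path,
    channel_subset: list[str] | None = None,
    epoch_length: float = 3.5,
) -> TrialSet:
    """Epoch a continuous recording stored in the public competition layout.

    The MAT-file must contain ``cnt`` (samples x channels continuous EEG),
    ``mrk`` with fields ``pos`` (cue sample positions, 1-based) and ``y``
    (labels), and ``nfo`` with fields ``fs`` and ``clab``.  Each cue yields
    the half-open epoch ``[cue, cue + epoch_length)`` seconds, i.e.
    ``round(epoch_length * fs)`` samples.  Integer-typed ``cnt`` is scaled
    by 0.1 to µV (the public release convention); floating data are taken
    as-is.  Cues whose label is missing (NaN, the competition's held-out
    trials) are dropped.  No re-referencing or detrending is applied.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    missing = [k for k in ("cnt", "mrk", "nfo") if k not in mat]
    if missing:
        raise ValueError(f"MAT-file missing required variables: {missing}")
    cnt = np.asarray(mat["cnt"])
    if cnt.ndim == 1:  # squeeze_me collapses single-channel recordings
        cnt = cnt[:, None]
    if np.issubdtype(cnt.dtype, np.integer):
        cnt = cnt.astype(np.float64) * 0.1
    else:
        cnt = cnt.astype(np.float64)
    mrk, nfo = mat["mrk"], mat["nfo"]
    pos = np.atleast_1d(np.asarray(mrk.pos)).astype(np.int64)
    y = np.atleast_1d(np.asarray(mrk.y, dtype=np.float64))
    fs = float(nfo.fs)
    clab = [str(c) for c in np.atleast_1d(np.asarray(nfo.clab, dtype=object))]

    if channel_subset is not None:
        index = {name: i for i, name in enumerate(clab)}
        unknown = [name for name in channel_subset if name not in index]
        if unknown:
            raise KeyError(
                f"unknown channel names {unknown}; available: {clab}"
            )
        chan_idx = [index[name] for name in channel_subset]
        names = list(channel_subset)
    else:
        chan_idx = list(range(len(clab)))
        names = clab

    P = int(round(epoch_length * fs))
    keep = np.isfinite(y)
    pos, y = pos[keep], y[keep]
    trials = []
    for p in pos:
        start = int(p) - 1  # 1-based cue position -> 0-based sample index
        seg = cnt[start : start + P, chan_idx]
        if seg.shape[0] != P:
            raise ValueError(
                f"cue at sample {p}: epoch of {P} samples exceeds recording"
            )
        trials.append(seg.T)
    data = (
        np.stack(trials) if trials else np.empty((0, len(chan_idx), P))
    )
    return TrialSet(
        data=data,
        labels=y.astype(np.int64),
        fs=fs,
        channel_names=names,
        t0=0.0,
    )
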