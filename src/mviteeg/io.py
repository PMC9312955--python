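"""Clip data model and readers/writers.

All EEG enters the pipeline as :class:`EEGClip` objects: an ``N x D`` array of
amplitudes in microvolts with a sampling rate, channel names, a clip-level
label and a subject identity.  Three on-disk forms are supported:

* EDF recordings (scalp-EEG style, e.g. 256 Hz / 23 channels) read through
  :mod:`mne`, cut into labelled 10-min clips from interval annotations;
* competition-style 10-min clip containers (MAT v5 or HDF5), one clip per
  file, label carried in the file or inferred from the file name;
* the package's own archive: a ``.npz`` holding the samples plus a JSON
  sidecar manifest (subject, label, fs, shape, provenance) — lossless, used
  for synthetic data and intermediates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError

VALID_LABELS = ("preictal", "interictal", "unlabeled")

#: Scalp-EEG channel budget: recordings with more electrodes are reduced to
#: the first channels in recording order.
MAX_SCALP_CHANNELS = 23

CLIP_LEN_S = 600.0  # canonical 10-min clip


@dataclass
class EEGClip:
    """One labelled multichannel EEG clip.

    data is an ``(n_channels, n_samples)`` float array in microvolts.
    """

    subject_id: str
    clip_id: str
    label: str
    fs: float
    channel_names: list[str]
    data: np.ndarray
    provenance: str = "real"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError(f"clip data must be 2-D (channels x samples), got {self.data.ndim}-D")
        if self.data.shape[0] < 1:
            raise DataError("clip must have at least one channel")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in VALID_LABELS:
            raise DataError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class LabeledInterval:
    """Half-open time interval ``[start_s, end_s)`` with a class label."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise DataError(f"empty interval [{self.start_s}, {self.end_s})")
        if self.label not in VALID_LABELS:
            raise DataError(f"bad interval label {self.label!r}")


def seizure_label_intervals(
    seizure_onsets_s: Sequence[float],
    record_len_s: float,
    preictal_horizon_s: float = 3600.0,
    preictal_offset_s: float = 300.0,
    interictal_gap_s: float = 4 * 3600.0,
) -> list[LabeledInterval]:
    """Derive labelled intervals from seizure onset times.

    Preictal covers the hour before each seizure minus a 5-min offset
    immediately preceding onset, i.e. ``[onset - 65 min, onset - 5 min)``.
    Interictal is every stretch more than 4 h away from any seizure onset.
    Intervals are clamped to ``[0, record_len_s)``.
    """
    intervals: list[LabeledInterval] = []
    onsets = sorted(float(t) for t in seizure_onsets_s)
    for t in onsets:
        lo = max(0.0, t - preictal_horizon_s - preictal_offset_s)
        hi = min(record_len_s, t - preictal_offset_s)
        if hi > lo:
            intervals.append(LabeledInterval(lo, hi, "preictal"))
    # interictal: complement of the merged +/- gap neighbourhoods of the onsets
    excluded: list[list[float]] = []
    for t in onsets:
        lo = max(0.0, t - interictal_gap_s)
        hi = min(record_len_s, t + interictal_gap_s)
        if excluded and lo <= excluded[-1][1]:
            excluded[-1][1] = max(excluded[-1][1], hi)
        else:
            excluded.append([lo, hi])
    cursor = 0.0
    for lo, hi in excluded:
        if lo > cursor:
            intervals.append(LabeledInterval(cursor, lo, "interictal"))
        cursor = max(cursor, hi)
    if record_len_s > cursor:
        intervals.append(LabeledInterval(cursor, record_len_s, "interictal"))
    return sorted(intervals, key=lambda iv: iv.start_s)


def _check_no_contradiction(intervals: Sequence[LabeledInterval]) -> None:
    ivs = sorted(intervals, key=lambda iv: iv.start_s)
    for a, b in zip(ivs, ivs[1:]):
        if b.start_s < a.end_s and a.label != b.label:
            raise DataError(
                f"contradictory overlapping labels: [{a.start_s},{a.end_s}) {a.label} vs "
                f"[{b.start_s},{b.end_s}) {b.label}"
            )


def cut_clips(
    data: np.ndarray,
    fs: float,
    intervals: Sequence[LabeledInterval],
    subject_id: str,
    clip_len_s: float = CLIP_LEN_S,
    channel_names: Sequence[str] | None = None,
    provenance: str = "real",
) -> list[EEGClip]:
    """Cut fixed-length clips out of labelled intervals of a recording.

    Each interval yields ``floor(len / clip_len_s)`` contiguous non-overlapping
    clips; the partial trailing remainder is dropped.
    """
    _check_no_contradiction(intervals)
    n_ch, n_samp = data.shape
    if channel_names is None:
        channel_names = [f"ch{i:02d}" for i in range(n_ch)]
    clip_samples = int(round(clip_len_s * fs))
    clips: list[EEGClip] = []
    for iv in intervals:
        i0 = int(round(iv.start_s * fs))
        i1 = int(round(iv.end_s * fs))
        if i1 > n_samp:
            raise DataError(
                f"interval [{iv.start_s},{iv.end_s}) s exceeds record length "
                f"{n_samp / fs:.1f} s"
            )
        n_clips = (i1 - i0) // clip_samples
        for k in range(n_clips):
            a = i0 + k * clip_samples
            seg = data[:, a : a + clip_samples]
            clips.append(
                EEGClip(
                    subject_id=subject_id,
                    clip_id=f"{subject_id}_{iv.label}_{iv.start_s:.0f}s_{k:03d}",
                    label=iv.label,
                    fs=fs,
                    channel_names=list(channel_names),
                    data=seg.copy(),
                    provenance=provenance,
                )
            )
    return clips


def read_edf_clips(
    path: str | Path,
    label_spec: Sequence[LabeledInterval],
    clip_len_s: float = CLIP_LEN_S,
    max_channels: int = MAX_SCALP_CHANNELS,
) -> list[EEGClip]:
    """Read an EDF recording and cut labelled 10-min clips from it.

    Amplitudes are converted to microvolts.  Recordings with more than
    ``max_channels`` channels keep the first ``max_channels`` in recording
    order (scalp montages with surplus electrodes).
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for malformed files
        raise DataError(f"unreadable EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts
    names = list(raw.ch_names)
    if data.shape[0] > max_channels:
        data = data[:max_channels]
        names = names[:max_channels]
    subject_id = path.stem
    return cut_clips(
        data,
        fs=float(raw.info["sfreq"]),
        intervals=label_spec,
        subject_id=subject_id,
        clip_len_s=clip_len_s,
        channel_names=names,
    )


# ---------------------------------------------------------------------------
# single-clip containers


def _label_from_name(path: Path) -> str | None:
    name = path.name.lower()
    # 'interictal' contains 'ictal' but not 'preictal'; test longest first
    if "preictal" in name:
        return "preictal"
    if "interictal" in name:
        return "interictal"
    return None


def write_clip(clip: EEGClip, path: str | Path) -> Path:
    """Write a clip container; format chosen by suffix.

    ``.mat`` -> MAT v5 competition-style container (fields ``data``, ``fs``,
    ``channel_names``, ``label``, ``subject_id``, ``clip_id``).
    ``.npz`` -> package archive + JSON sidecar manifest.
    Amplitudes round-trip bit-exactly in both.
    """
    path = Path(path)
    if path.suffix == ".mat":
        from scipy.io import savemat

        savemat(
            str(path),
            {
                "data": clip.data,
                "fs": float(clip.fs),
                "channel_names": np.array(clip.channel_names, dtype=object),
                "label": clip.label,
                "subject_id": clip.subject_id,
                "clip_id": clip.clip_id,
            },
        )
    elif path.suffix == ".npz":
        np.savez(path, data=clip.data)
        manifest = {
            "subject_id": clip.subject_id,
            "clip_id": clip.clip_id,
            "label": clip.label,
            "fs": clip.fs,
            "channel_names": clip.channel_names,
            "n_channels": clip.n_channels,
            "n_samples": clip.n_samples,
            "duration_s": clip.duration_s,
            "provenance": clip.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    else:
        raise DataError(f"unsupported clip container suffix {path.suffix!r}")
    return path


def read_competition_clip(path: str | Path) -> EEGClip:
    """Read a competition-style 10-min clip container (MAT v5 or HDF5).

    The container must hold a channels-by-samples ``data`` array and an ``fs``
    field; the label comes from a ``label`` field or, failing that, from the
    file name ('preictal'/'interictal').
    """
    path = Path(path)
    fields: dict = {}
    try:
        from scipy.io import loadmat

        mat = loadmat(str(path), squeeze_me=True)
        fields = {k: v for k, v in mat.items() if not k.startswith("__")}
    except (NotImplementedError, ValueError):
        # MAT v7.3 and friends are HDF5 underneath
        import h5py

        with h5py.File(path, "r") as f:
            for k in f.keys():
                v = f[k][()]
                fields[k] = v
            # HDF5 MAT dialects store arrays transposed
            if "data" in fields and fields["data"].ndim == 2:
                fields["data"] = np.asarray(fields["data"]).T
    except OSError as exc:
        raise DataError(f"unreadable clip container {path}: {exc}") from exc

    if "data" not in fields:
        raise DataError(f"{path}: container has no 'data' array")
    if "fs" not in fields:
        raise DataError(f"{path}: container has no 'fs' field")
    data = np.asarray(fields["data"], dtype=np.float64)
    fs = float(np.asarray(fields["fs"]).ravel()[0])

    def _as_str(x) -> str:
        if isinstance(x, bytes):
            return x.decode()
        if isinstance(x, np.ndarray):
            return "".join(chr(c) for c in x.ravel()) if x.dtype.kind in "ui" else str(x.item())
        return str(x)

    label = _as_str(fields["label"]) if "label" in fields else _label_from_name(path)
    if label is None:
        raise DataError(f"{path}: label neither stored nor inferable from file name")
    if "channel_names" in fields:
        raw_names = fields["channel_names"]
        if isinstance(raw_names, np.ndarray):
            names = [_as_str(n) for n in np.atleast_1d(raw_names)]
        else:
            names = [_as_str(raw_names)]
    else:
        names = [f"ch{i:02d}" for i in range(data.shape[0])]
    subject_id = _as_str(fields.get("subject_id", path.stem.split("_")[0]))
    clip_id = _as_str(fields.get("clip_id", path.stem))
    return EEGClip(subject_id, clip_id, label, fs, names, data)


def read_clip(path: str | Path) -> EEGClip:
    """Read any supported single-clip container (dispatch on suffix)."""
    path = Path(path)
    if path.suffix == ".npz":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise DataError(f"{path}: missing JSON sidecar manifest")
        meta = json.loads(sidecar.read_text())
        with np.load(path) as npz:
            data = npz["data"]
        return EEGClip(
            subject_id=meta["subject_id"],
            clip_id=meta["clip_id"],
            label=meta["label"],
            fs=meta["fs"],
            channel_names=list(meta["channel_names"]),
            data=data,
            provenance=meta.get("provenance", "real"),
        )
    return read_competition_clip(path)


# ---------------------------------------------------------------------------
# clip-collection store


def write_dataset(clips: Sequence[EEGClip], out_dir: str | Path) -> Path:
    """Write a clip collection as one ``.npz``+sidecar per clip plus a
    ``manifest.json`` listing subject, clip id, label, fs, channels, duration.
    Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for clip in clips:
        fname = f"{clip.clip_id}.npz"
        write_clip(clip, out_dir / fname)
        entries.append(
            {
                "file": fname,
                "subject_id": clip.subject_id,
                "clip_id": clip.clip_id,
                "label": clip.label,
                "fs": clip.fs,
                "n_channels": clip.n_channels,
                "duration_s": clip.duration_s,
                "provenance": clip.provenance,
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"clips": entries}, indent=1, sort_keys=True))
    return manifest_path


def read_dataset(in_dir: str | Path) -> list[EEGClip]:
    """Read back a clip collection written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"{in_dir}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    return [read_clip(in_dir / e["file"]) for e in manifest["clips"]]
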