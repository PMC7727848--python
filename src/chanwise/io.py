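"""Loading, validation and labelling of multichannel EEG recordings.

Recordings are always oriented channels x samples. Sample indices are
0-based and every window is half-open ``[start, stop)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RawRecording",
    "EmotionLabel",
    "SCHEME_CLASSES",
    "load_recording",
    "save_recording",
    "trim_prestimulus",
    "binarize_rating",
    "quadrant_label",
    "load_deap_trial",
    "load_seed_trial",
]

#: Class names for each supported label scheme, in canonical order.
SCHEME_CLASSES: dict[str, tuple[str, ...]] = {
    "valence2": ("low", "high"),
    "arousal2": ("low", "high"),
    "quadrant4": ("HVHA", "HVLA", "LVHA", "LVLA"),
    "seed3": ("positive", "neutral", "negative"),
}


@dataclass(frozen=True)
class EmotionLabel:
    """A categorical emotion label under a fixed scheme.

    Parameters
    ----------
    scheme
        One of ``valence2``, ``arousal2``, ``quadrant4``, ``seed3``.
    value
        Class index in ``[0, n_classes)``.
    """

    scheme: str
    value: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_CLASSES:
            raise ValueError(f"unknown label scheme {self.scheme!r}")
        n = len(SCHEME_CLASSES[self.scheme])
        if not 0 <= int(self.value) < n:
            raise ValueError(
                f"label value {self.value} out of range for scheme "
                f"{self.scheme!r} with {n} classes"
            )

    @property
    def class_names(self) -> tuple[str, ...]:
        return SCHEME_CLASSES[self.scheme]

    @property
    def name(self) -> str:
        return self.class_names[self.value]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class RawRecording:
    """One trial of multichannel EEG: a ``C x M`` matrix plus metadata."""

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...] = ()
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data is not a channels x samples matrix")
        c, m = self.data.shape
        if c < 2:
            raise ValueError(f"need at least 2 channels, got {c}")
        if m < 1:
            raise ValueError("recording has no samples")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(c))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if len(set(self.channel_names)) != c:
            raise ValueError("channel names are not unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate


def _orient(arr: np.ndarray, channel_names: Sequence[str] | None) -> np.ndarray:
    """Orient a 2-D array as channels x samples.

    If ``channel_names`` is given its length disambiguates which axis is
    channels; otherwise the shorter axis is assumed to be channels.
    """
    if arr.ndim != 2:
        raise ValueError("not a channels x samples matrix")
    if channel_names is not None:
        c = len(channel_names)
        if arr.shape[0] == c:
            return arr
        if arr.shape[1] == c:
            return arr.T
        raise ValueError(
            f"neither array axis {arr.shape} matches {c} channel names"
        )
    return arr if arr.shape[0] <= arr.shape[1] else arr.T


def load_recording(
    path: str | Path,
    format: str | None = None,
    rate: float | None = None,
    channel_names: Sequence[str] | None = None,
    key: str | None = None,
) -> RawRecording:
    """Load a recording from an NPZ/NPY, MAT or EDF container.

    Parameters
    ----------
    path
        File to read.
    format
        ``npz``, ``mat`` or ``edf``; inferred from the suffix if omitted.
    rate
        Sampling rate in Hz.  Required unless the container (EDF, or an NPZ
        sidecar written by :func:`save_recording`) carries one.
    channel_names
        Montage labels; used to orient ambiguous arrays.
    key
        Array name inside NPZ/MAT containers holding the signal; defaults
        to the single 2-D numeric array present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"npy": "npz"}.get(suffix, suffix)
    if format == "npz":
        return _load_npz(path, rate, channel_names, key)
    if format == "mat":
        return _load_mat(path, rate, channel_names, key)
    if format == "edf":
        return _load_edf(path, channel_names)
    raise ValueError(f"unsupported format {format!r}")


def _require_rate(rate: float | None) -> float:
    if rate is None:
        raise ValueError("sampling rate is required for this container")
    return float(rate)


def _pick_array(arrays: dict[str, np.ndarray], key: str | None) -> np.ndarray:
    if key is not None:
        if key not in arrays:
            raise KeyError(f"array {key!r} not found; have {sorted(arrays)}")
        return arrays[key]
    cands = {
        k: v
        for k, v in arrays.items()
        if isinstance(v, np.ndarray)
        and v.ndim == 2
        and np.issubdtype(v.dtype, np.number)
        and not k.startswith("__")
    }
    if len(cands) != 1:
        raise ValueError(
            f"expected exactly one 2-D numeric array, found {sorted(cands)}; "
            "pass key="
        )
    return next(iter(cands.values()))


def _load_npz(path, rate, channel_names, key):
    obj = np.load(path, allow_pickle=False)
    meta: dict = {}
    if isinstance(obj, np.ndarray):
        arr = obj
    else:
        arrays = dict(obj)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        arr = _pick_array({k: v for k, v in arrays.items() if k != "labels"}, key)
    rate = rate if rate is not None else meta.get("rate")
    names = channel_names if channel_names is not None else meta.get("channel_names")
    rec = RawRecording(
        data=_orient(np.asarray(arr, dtype=float), names),
        rate=_require_rate(rate),
        channel_names=tuple(names) if names else (),
        subject_id=str(meta.get("subject_id", "")),
        trial_id=str(meta.get("trial_id", "")),
    )
    return rec


def _load_mat(path, rate, channel_names, key):
    try:
        from scipy.io import loadmat

        arrays = loadmat(path)
    except NotImplementedError:  # MATLAB >= v7.3 is HDF5 underneath
        import h5py

        with h5py.File(path, "r") as f:
            arrays = {k: np.asarray(f[k]) for k in f.keys()}
    arr = _pick_array(arrays, key)
    return RawRecording(
        data=_orient(np.asarray(arr, dtype=float), channel_names),
        rate=_require_rate(rate),
        channel_names=tuple(channel_names) if channel_names else (),
    )


def _load_edf(path, channel_names):
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires the optional dependency pyedflib"
        ) from exc
    with pyedflib.EdfReader(str(path)) as f:  # pragma: no cover
        labels = f.getSignalLabels()
        idx = (
            range(f.signals_in_file)
            if channel_names is None
            else [labels.index(n) for n in channel_names]
        )
        data = np.vstack([f.readSignal(i) for i in idx])
        rate = float(f.getSampleFrequency(next(iter(idx))))
        names = channel_names or [labels[i] for i in idx]
    return RawRecording(data=data, rate=rate, channel_names=tuple(names))


def save_recording(
    rec: RawRecording, path: str | Path, label: EmotionLabel | None = None
) -> Path:
    """Write a recording as NPZ plus a JSON metadata sidecar.

    The sidecar carries rate, channel names, subject/trial ids and the
    optional label, so :func:`load_recording` can round-trip without extra
    arguments.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, data=rec.data)
    meta = {
        "rate": rec.rate,
        "channel_names": list(rec.channel_names),
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
    }
    if label is not None:
        meta["label"] = {"scheme": label.scheme, "value": int(label.value)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_saved(path: str | Path) -> tuple[RawRecording, EmotionLabel | None]:
    """Load a recording written by :func:`save_recording`, with its label."""
    path = Path(path)
    rec = load_recording(path, format="npz")
    label = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "label" in meta:
            label = EmotionLabel(**meta["label"])
    return rec, label


def trim_prestimulus(rec: RawRecording, skip_seconds: float) -> RawRecording:
    """Drop the first ``skip_seconds`` of a trial (stimulus onset period)."""
    if skip_seconds < 0:
        raise ValueError("skip_seconds must be non-negative")
    n_skip = int(round(skip_seconds * rec.rate))
    if n_skip >= rec.n_samples:
        raise ValueError(
            f"cannot skip {skip_seconds} s ({n_skip} samples) of a "
            f"{rec.n_samples}-sample recording"
        )
    return replace(rec, data=rec.data[:, n_skip:])


def binarize_rating(
    rating: float, dimension: str, tie: str = "low"
) -> EmotionLabel | None:
    """Binarize a 1-9 self-assessment rating at 5.

    Ratings above 5 map to ``high``, below 5 to ``low``.  A rating of
    exactly 5 follows ``tie``: ``"low"`` (default), ``"high"``, or
    ``"drop"`` which returns ``None``.
    """
    if not 1 <= rating <= 9:
        raise ValueError(f"rating {rating} outside the 1-9 scale")
    if dimension not in ("valence", "arousal"):
        raise ValueError(f"unknown rating dimension {dimension!r}")
    scheme = "valence2" if dimension == "valence" else "arousal2"
    if rating > 5:
        return EmotionLabel(scheme, 1)
    if rating < 5:
        return EmotionLabel(scheme, 0)
    if tie == "drop":
        return None
    if tie not in ("low", "high"):
        raise ValueError(f"unknown tie policy {tie!r}")
    return EmotionLabel(scheme, 1 if tie == "high" else 0)


def quadrant_label(valence: EmotionLabel, arousal: EmotionLabel) -> EmotionLabel:
    """Combine binary valence and arousal into a four-quadrant label.

    Class order is HVHA, HVLA, LVHA, LVLA.
    """
    if valence.scheme != "valence2" or arousal.scheme != "arousal2":
        raise ValueError(
            f"expected (valence2, arousal2) schemes, got "
            f"({valence.scheme}, {arousal.scheme})"
        )
    hv = valence.value == 1
    ha = arousal.value == 1
    value = {(True, True): 0, (True, False): 1, (False, True): 2, (False, False): 3}[
        (hv, ha)
    ]
    return EmotionLabel("quadrant4", value)


# ---------------------------------------------------------------------------
# Dataset layout adapters.  Thin mappers from each benchmark's documented
# on-disk layout to RawRecording; exercised only by optional tests guarded
# on file presence.

DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "P3", "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4",
    "F8", "FC6", "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8",
    "PO4", "O2",
)


def load_deap_trial(
    path: str | Path, trial: int, subject_id: str = ""
) -> tuple[RawRecording, dict[str, float]]:
    """Load one trial from a DEAP-style preprocessed container.

    Expects arrays ``data`` of shape (trials, 40, 8064) — first 32 rows are
    EEG at 128 Hz — and ``labels`` of shape (trials, 4) holding valence,
    arousal, dominance, liking ratings.
    """
    from scipy.io import loadmat

    mat = loadmat(Path(path))
    data = np.asarray(mat["data"], dtype=float)
    labels = np.asarray(mat["labels"], dtype=float)
    rec = RawRecording(
        data=data[trial, :32, :],
        rate=128.0,
        channel_names=DEAP_CHANNELS,
        subject_id=subject_id or Path(path).stem,
        trial_id=str(trial),
    )
    ratings = {"valence": labels[trial, 0], "arousal": labels[trial, 1]}
    return rec, ratings


#: SEED clip labels per session, in clip order (1=positive, 0=neutral,
#: -1=negative per the dataset docs); mapped onto the seed3 scheme.
_SEED3_FROM_SIGN = {1: 0, 0: 1, -1: 2}


def load_seed_trial(
    path: str | Path,
    clip: int,
    clip_sign: int,
    channel_names: Sequence[str] | None = None,
    subject_id: str = "",
) -> tuple[RawRecording, EmotionLabel]:
    """Load one film-clip trial from a SEED-style MAT container.

    Expects per-clip arrays named ``*_eeg<clip+1>`` of shape (62, samples)
    at 200 Hz; ``clip_sign`` is the dataset's 1/0/-1 clip label.
    """
    from scipy.io import loadmat

    mat = loadmat(Path(path))
    suffix = f"_eeg{clip + 1}"
    matches = [k for k in mat if k.endswith(suffix)]
    if len(matches) != 1:
        raise KeyError(f"expected one key ending in {suffix!r}, got {matches}")
    rec = RawRecording(
        data=np.asarray(mat[matches[0]], dtype=float),
        rate=200.0,
        channel_names=tuple(channel_names) if channel_names else (),
        subject_id=subject_id or Path(path).stem,
        trial_id=str(clip),
    )
    return rec, EmotionLabel("seed3", _SEED3_FROM_SIGN[int(clip_sign)])
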