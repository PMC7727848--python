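"""Windowing, segment-mean features, channel-wise Pearson matrices and
sliding-window training-example construction.

A window of ``L*K*N`` consecutive samples per channel is reshaped into a
``C x L x K x N`` tensor (time-major over ``n``, then ``k``: segment
``(k, n)`` covers samples ``[((n*K)+k)*L, ((n*K)+k+1)*L)`` relative to the
window start).  Each segment is reduced to its mean; for each of the ``N``
time steps the ``C x C`` Pearson correlation matrix of the ``K`` segment
means is computed, and its strict upper triangle (row-major, ``x < y``) is
flattened into a vector of length ``C*(C-1)/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .io import EmotionLabel, RawRecording

__all__ = [
    "WindowingParams",
    "WindowTensor",
    "SingleChannelFeatures",
    "ChannelWiseFeature",
    "FeatureSequence",
    "LabeledExample",
    "extract_window",
    "single_channel_features",
    "channel_wise_feature",
    "flatten_upper_triangle",
    "unflatten_upper_triangle",
    "feature_sequence",
    "make_training_examples",
    "n_pairs",
]


@dataclass(frozen=True)
class WindowingParams:
    """Windowing hyperparameters.

    Attributes
    ----------
    L
        Samples per segment.
    K
        Segments per channel-wise feature (the Pearson sample size).
    N
        Channel-wise features per sequence, i.e. LSTM time steps.
    """

    L: int = 2
    K: int = 8
    N: int = 10

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if self.K < 2:
            raise ValueError(f"K must be >= 2 (Pearson needs >= 2 points), got {self.K}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")

    @property
    def window_samples(self) -> int:
        """Samples consumed by one window: ``L*K*N``."""
        return self.L * self.K * self.N

    @property
    def stride_samples(self) -> int:
        """Sliding-window stride ``L*K`` — one feature's worth of samples."""
        return self.L * self.K

    def window_seconds(self, rate: float) -> float:
        """Duration of one window at sampling rate ``rate``."""
        return self.window_samples / rate


def n_pairs(C: int) -> int:
    """Number of unordered channel pairs, ``C*(C-1)/2``."""
    return C * (C - 1) // 2


@dataclass(frozen=True)
class WindowTensor:
    """A ``C x L x K x N`` window of raw samples."""

    values: np.ndarray
    params: WindowingParams
    subject_id: str = ""
    trial_id: str = ""
    start_sample: int = 0

    def __post_init__(self) -> None:
        expected = (-1, self.params.L, self.params.K, self.params.N)
        v = self.values
        if v.ndim != 4 or v.shape[1:] != expected[1:]:
            raise ValueError(
                f"window tensor shape {v.shape} does not match params "
                f"(C, L={self.params.L}, K={self.params.K}, N={self.params.N})"
            )

    @property
    def C(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SingleChannelFeatures:
    """Segment means, a ``C x K x N`` tensor."""

    values: np.ndarray
    params: WindowingParams

    @property
    def C(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ChannelWiseFeature:
    """One ``C x C`` symmetric correlation matrix for time step ``time_index``."""

    matrix: np.ndarray
    time_index: int = 0

    @property
    def C(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FeatureSequence:
    """``N`` flattened upper-triangle vectors of length ``C*(C-1)/2``."""

    vectors: np.ndarray  # (N, C*(C-1)/2)
    params: WindowingParams
    C: int

    def __post_init__(self) -> None:
        if self.vectors.shape != (self.params.N, n_pairs(self.C)):
            raise ValueError(
                f"vectors shape {self.vectors.shape} != "
                f"({self.params.N}, {n_pairs(self.C)})"
            )


@dataclass(frozen=True)
class LabeledExample:
    """A feature sequence paired with its trial label."""

    sequence: FeatureSequence
    label: EmotionLabel
    subject_id: str = ""
    trial_id: str = ""


def extract_window(
    rec: RawRecording, start_sample: int, params: WindowingParams
) -> WindowTensor:
    """Cut one ``L*K*N``-sample window starting at ``start_sample``."""
    w = params.window_samples
    if start_sample < 0:
        raise ValueError("start_sample must be non-negative")
    if start_sample + w > rec.n_samples:
        raise ValueError(
            f"window [{start_sample}, {start_sample + w}) exceeds recording "
            f"of {rec.n_samples} samples"
        )
    chunk = rec.data[:, start_sample : start_sample + w]
    # samples ordered n-major then k then l -> reshape (C, N, K, L), then
    # put axes into the (C, L, K, N) convention.
    values = chunk.reshape(rec.n_channels, params.N, params.K, params.L)
    values = np.ascontiguousarray(values.transpose(0, 3, 2, 1))
    return WindowTensor(
        values=values,
        params=params,
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        start_sample=start_sample,
    )


def single_channel_features(E: WindowTensor) -> SingleChannelFeatures:
    """Reduce each length-``L`` segment to its arithmetic mean."""
    return SingleChannelFeatures(values=E.values.mean(axis=1), params=E.params)


def _pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of ``X`` (shape ``C x K``).

    Zero-variance rows get 0 off-diagonals and a unit diagonal; entries are
    clipped to [-1, 1] only to absorb floating-point overshoot.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ck,ck->c", Xc, Xc))
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} channel(s) with zero-variance segment "
            "means; their correlations are set to 0",
            stacklevel=3,
        )
        norms = np.where(degenerate, 1.0, norms)
    F = (Xc / norms[:, None]) @ (Xc / norms[:, None]).T
    F = (F + F.T) / 2.0
    np.clip(F, -1.0, 1.0, out=F)
    if degenerate.any():
        F[degenerate, :] = 0.0
        F[:, degenerate] = 0.0
    np.fill_diagonal(F, 1.0)
    return F


def channel_wise_feature(S: SingleChannelFeatures, n: int) -> ChannelWiseFeature:
    """Pearson correlation matrix of the ``K`` segment means at time step ``n``."""
    if not 0 <= n < S.params.N:
        raise IndexError(f"time index {n} out of range [0, {S.params.N})")
    return ChannelWiseFeature(matrix=_pearson_matrix(S.values[:, :, n]), time_index=n)


def flatten_upper_triangle(F: ChannelWiseFeature | np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major order (``x < y``), diagonal excluded."""
    m = F.matrix if isinstance(F, ChannelWiseFeature) else np.asarray(F)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def unflatten_upper_triangle(v: np.ndarray, C: int) -> ChannelWiseFeature:
    """Inverse of :func:`flatten_upper_triangle`, with unit diagonal."""
    v = np.asarray(v, dtype=float)
    if v.shape != (n_pairs(C),):
        raise ValueError(
            f"vector of length {v.size} does not match C={C} "
            f"(expected {n_pairs(C)})"
        )
    m = np.eye(C)
    iu = np.triu_indices(C, k=1)
    m[iu] = v
    m[iu[1], iu[0]] = v
    return ChannelWiseFeature(matrix=m)


def feature_sequence(E: WindowTensor) -> FeatureSequence:
    """Full pipeline for one window: segment means -> N correlation matrices
    -> N flattened upper-triangle vectors."""
    S = single_channel_features(E)
    vectors = np.stack(
        [
            flatten_upper_triangle(channel_wise_feature(S, n))
            for n in range(E.params.N)
        ]
    )
    return FeatureSequence(vectors=vectors, params=E.params, C=E.C)


def iter_window_starts(n_samples: int, params: WindowingParams) -> Iterator[int]:
    """Start samples of the sliding-window augmentation: stride ``L*K``,
    window ``L*K*N``; trailing partial windows dropped."""
    w, s = params.window_samples, params.stride_samples
    return iter(range(0, n_samples - w + 1, s))


def make_training_examples(
    rec: RawRecording, params: WindowingParams, label: EmotionLabel
) -> list[LabeledExample]:
    """Sliding-window augmentation of one trial.

    Adjacent windows overlap by ``(N-1)/N`` of their length, so consecutive
    examples share all but one channel-wise feature.  Windows never span
    trial boundaries; a trial shorter than one window is an error.
    """
    if rec.n_samples < params.window_samples:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"window of {params.window_samples}"
        )
    examples = []
    for start in iter_window_starts(rec.n_samples, params):
        seq = feature_sequence(extract_window(rec, start, params))
        examples.append(
            LabeledExample(
                sequence=seq,
                label=label,
                subject_id=rec.subject_id,
                trial_id=rec.trial_id,
            )
        )
    return examples


def examples_to_arrays(
    examples: list[LabeledExample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into ``(X, y)``: ``X`` of shape (n, N, P), ``y`` int."""
    if not examples:
        raise ValueError("no examples")
    X = np.stack([ex.sequence.vectors for ex in examples])
    y = np.array([ex.label.value for ex in examples], dtype=int)
    return X, y
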