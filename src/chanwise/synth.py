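"""Synthetic multichannel recordings with controlled correlation structure.

Each subject has a base inter-channel correlation matrix; each emotion adds
a sparse symmetric perturbation shared across subjects.  Signals are AR(1)
noise mixed through the Cholesky factor of the combined correlation matrix,
so segment means inherit that structure and the channel-wise Pearson
features recover it.  Subject patterns dominate; emotion rides on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SCHEME_CLASSES, EmotionLabel, RawRecording
from .features import n_pairs

__all__ = [
    "SubjectProfile",
    "EmotionEffect",
    "SynthConfig",
    "make_subject_profile",
    "make_emotion_effects",
    "combined_correlation",
    "generate_recording",
    "generate_dataset",
    "nearest_correlation",
]


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    base_correlation: np.ndarray  # C x C, symmetric PD, unit diagonal
    channel_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class EmotionEffect:
    label: EmotionLabel
    delta: np.ndarray  # C x C, symmetric, zero diagonal
    magnitude: float


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 4
    n_trials_per_emotion: int = 2
    trial_seconds: float = 10.0
    rate: float = 128.0
    C: int = 8
    scheme: str = "valence2"
    magnitude: float = 0.6
    effect_density: float = 0.1  # fraction of channel pairs perturbed
    noise_sd: float = 0.0  # additive white measurement noise
    ar_coeff: float = 0.5  # AR(1) temporal smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_trials_per_emotion) < 1:
            raise ValueError("counts must be >= 1")
        if self.C < 2:
            raise ValueError("need at least 2 channels")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if self.scheme not in SCHEME_CLASSES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def n_emotions(self) -> int:
        return len(SCHEME_CLASSES[self.scheme])

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_seconds * self.rate))


def nearest_correlation(
    m: np.ndarray, eig_floor: float = 1e-3, max_offdiag: float = 0.99
) -> np.ndarray:
    """Project a symmetric matrix to a nearby valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor``, the diagonal renormalized to
    1 and off-diagonals clipped into ``(-1, 1)``.
    """
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    m = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.clip(m, -max_offdiag, max_offdiag, out=m)
    np.fill_diagonal(m, 1.0)
    # clipping can nudge it slightly off PD; one cheap repair pass
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        m = nearest_correlation(m, eig_floor, max_offdiag)
    return m


def make_subject_profile(
    C: int, seed: int, subject_id: str = "", strength: float = 1.0
) -> SubjectProfile:
    """Draw a random valid correlation matrix via random factor loadings.

    ``A`` is a C x f loading matrix plus diagonal noise; ``A A^T + D``
    normalized to unit diagonal is symmetric positive-definite with
    off-diagonals in (-1, 1).  ``strength`` scales how far off-diagonals
    sit from zero.
    """
    if C < 2:
        raise ValueError("need at least 2 channels")
    rng = np.random.default_rng(seed)
    f = max(2, C // 2)
    A = rng.standard_normal((C, f)) * strength
    cov = A @ A.T + np.eye(C)
    d = np.sqrt(np.diag(cov))
    base = cov / np.outer(d, d)
    return SubjectProfile(
        subject_id=subject_id or f"s{seed}",
        base_correlation=base,
        channel_names=tuple(f"ch{i}" for i in range(C)),
    )


def make_emotion_effects(cfg: SynthConfig) -> list[EmotionEffect]:
    """Sparse symmetric perturbations, one per emotion class, shared across
    subjects so the emotion signal generalizes."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    C = cfg.C
    iu = np.triu_indices(C, k=1)
    n_active = max(1, int(round(cfg.effect_density * n_pairs(C))))
    effects = []
    for cls in range(cfg.n_emotions):
        delta = np.zeros((C, C))
        pick = rng.choice(n_pairs(C), size=n_active, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_active)
        vals = signs * cfg.magnitude
        delta[iu[0][pick], iu[1][pick]] = vals
        delta[iu[1][pick], iu[0][pick]] = vals
        effects.append(
            EmotionEffect(
                label=EmotionLabel(cfg.scheme, cls),
                delta=delta,
                magnitude=cfg.magnitude,
            )
        )
    return effects


def combined_correlation(
    profile: SubjectProfile, effect: EmotionEffect | None
) -> np.ndarray:
    """Base + emotion delta, repaired to the nearest valid correlation."""
    m = profile.base_correlation
    if effect is not None:
        m = m + effect.delta
    return nearest_correlation(m)


def _ar1_noise(rng: np.random.Generator, C: int, M: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series per channel, independent rows."""
    eps = rng.standard_normal((C, M))
    if phi == 0.0:
        return eps
    x = np.empty((C, M))
    x[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, M):
        x[:, t] = phi * x[:, t - 1] + scale * eps[:, t]
    return x


def generate_recording(
    profile: SubjectProfile,
    effect: EmotionEffect | None,
    cfg: SynthConfig,
    trial_seed: int | np.random.SeedSequence,
    trial_id: str = "",
) -> RawRecording:
    """One trial: AR(1) noise mixed by the Cholesky factor of the combined
    correlation matrix, plus optional white measurement noise."""
    target = combined_correlation(profile, effect)
    try:
        L = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:
        raise ValueError("combined correlation matrix is not positive-definite") from exc
    rng = np.random.default_rng(trial_seed)
    M = cfg.trial_samples
    z = _ar1_noise(rng, cfg.C, M, cfg.ar_coeff)
    x = L @ z
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal((cfg.C, M))
    return RawRecording(
        data=x,
        rate=cfg.rate,
        channel_names=profile.channel_names,
        subject_id=profile.subject_id,
        trial_id=trial_id,
    )


def generate_dataset(cfg: SynthConfig) -> list[tuple[RawRecording, EmotionLabel]]:
    """Fully seeded dataset: for each subject a base profile, for each
    emotion its shared effect, ``n_trials_per_emotion`` trials each."""
    root = np.random.SeedSequence(cfg.seed)
    profile_seeds = root.spawn(cfg.n_subjects)
    effects = make_emotion_effects(cfg)
    out: list[tuple[RawRecording, EmotionLabel]] = []
    for s, pseed in enumerate(profile_seeds):
        profile = make_subject_profile(
            cfg.C, np.random.default_rng(pseed).integers(2**31), subject_id=f"s{s:02d}"
        )
        trial_seeds = iter(pseed.spawn(cfg.n_emotions * cfg.n_trials_per_emotion))
        for effect in effects:
            for t in range(cfg.n_trials_per_emotion):
                rec = generate_recording(
                    profile,
                    effect,
                    cfg,
                    next(trial_seeds),
                    trial_id=f"{effect.label.name}-{t}",
                )
                out.append((rec, effect.label))
    return out
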