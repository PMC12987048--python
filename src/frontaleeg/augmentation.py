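"""Label-preserving training-time augmentations.

Two recipes exist: the hybrid-model recipe (additive Gaussian noise, slow
linear drift, per-channel amplitude scaling, each gated by its own
Bernoulli draw, plus optional batch-level MixUp), and the SE-baseline
recipe (noise, joint circular temporal shift, amplitude scaling, each with
probability 0.5).  All magnitudes are in z-units, small by construction
after per-recording standardization.  The inference path never calls any
of these operators; evaluation is always on unaugmented windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AugmentConfig:
    """Hybrid-model training augmentations.

    Drift adds a per-channel linear ramp from 0 to d, with |d| at most
    drift_max_frac of that channel's within-window peak-to-peak amplitude
    (the amplitude reference for the "~3% of signal amplitude" rule).
    """

    noise_sd: float = 0.01
    p_noise: float = 0.7
    drift_max_frac: float = 0.03
    p_drift: float = 0.3
    scale_sd: float = 0.1
    p_scale: float = 0.5
    mixup_alpha: float = 0.2
    mixup_enabled: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (self.p_noise, self.p_drift, self.p_scale):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.noise_sd, self.scale_sd, self.drift_max_frac) < 0:
            raise ValueError("magnitudes must be nonnegative")


@dataclass(frozen=True)
class SEAugmentConfig:
    """SE-baseline recipe: three ops, each with probability 0.5."""

    noise_sd: float = 0.02
    shift_max_frac: float = 0.10
    scale_sd: float = 0.05
    p_op: float = 0.5
    seed: int = 42


def augment_window(
    w: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply noise -> drift -> scale, each with its configured probability.

    Output shape equals input shape; a config with all probabilities zero is
    the identity.
    """
    out = np.array(w, dtype=np.float64, copy=True)
    L = out.shape[0]
    if rng.random() < cfg.p_noise:
        out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
    if rng.random() < cfg.p_drift:
        ptp = out.max(axis=0) - out.min(axis=0)
        d = rng.uniform(-1.0, 1.0, size=out.shape[1]) * cfg.drift_max_frac * ptp
        ramp = np.linspace(0.0, 1.0, L)[:, None]
        out += ramp * d[None, :]
    if rng.random() < cfg.p_scale:
        factors = rng.normal(1.0, cfg.scale_sd, size=out.shape[1])
        out *= factors[None, :]
    return out


def se_augment_window(
    w: np.ndarray, cfg: SEAugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """SE recipe: noise, joint circular shift (wrap-around), per-channel scale."""
    out = np.array(w, dtype=np.float64, copy=True)
    L = out.shape[0]
    if rng.random() < cfg.p_op:
        out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
    if rng.random() < cfg.p_op:
        max_shift = int(cfg.shift_max_frac * L)
        shift = int(rng.integers(-max_shift, max_shift + 1))
        out = np.roll(out, shift, axis=0)
    if rng.random() < cfg.p_op:
        factors = rng.normal(1.0, cfg.scale_sd, size=out.shape[1])
        out *= factors[None, :]
    return out


def mixup_batch(
    inputs: tuple[np.ndarray, ...],
    y: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[tuple[np.ndarray, ...], np.ndarray]:
    """MixUp within a mini-batch: convex combinations with Beta(alpha, alpha).

    Each item is paired with a random permutation partner; the same lambda
    mixes every input representation (raw, map, glob) and the one-hot
    labels, so mixed label rows stay on the simplex.  A singleton batch
    passes through unchanged.
    """
    n = y.shape[0]
    if n < 2:
        return inputs, y
    perm = rng.permutation(n)
    lam = rng.beta(alpha, alpha, size=n)
    mixed_inputs = []
    for x in inputs:
        lam_x = lam.reshape((n,) + (1,) * (x.ndim - 1))
        mixed_inputs.append(lam_x * x + (1.0 - lam_x) * x[perm])
    y_mixed = lam[:, None] * y + (1.0 - lam[:, None]) * y[perm]
    return tuple(mixed_inputs), y_mixed
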