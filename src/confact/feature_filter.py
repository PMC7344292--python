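"""Noise-feature removal via a non-negative autoencoder.

Features that play no role in differentiating patients are removed before
factor analysis. A one-hidden-layer autoencoder is trained on the
min-max-scaled matrix (each feature mapped to [0, 1], so a feature's
gradient budget is proportional to its dynamic structure) with its encoder
weights clamped non-negative after every optimizer step, so each encoder weight measures a (positive)
association between an input feature and a latent unit. A feature whose
weights vary strongly across hidden units contributes distinct information
to several latent directions; a feature whose weights are uniformly small
or flat is redundant or noise. The per-feature variance of encoder weights
is the selection score.

The autoencoder is implemented directly in numpy (linear encoder/decoder,
mean-squared reconstruction error, minibatch SGD with momentum) — the matrices involved
are small enough that no deep-learning framework is warranted. A
``variance`` method (top features by raw variance) is available as a fast
deterministic alternative.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FeatureIndexSet, OmicsMatrix, WeightProfile
from .errors import NumericalError, ValidationError
from .rng import derive_rng

__all__ = ["train_weight_profile", "select_features", "filter_matrix", "variance_profile"]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng[rng == 0] = 1.0  # constant features map to 0
    return (x - lo) / rng


def train_weight_profile(
    m: OmicsMatrix,
    hidden_dim: int = 50,
    epochs: int = 50,
    seed: int = 0,
    batch_size: int = 32,
    lr: float = 0.1,
    momentum: float = 0.9,
) -> WeightProfile:
    """Train the non-negative autoencoder and score feature variability.

    ``variability[j]`` is the variance of feature ``j``'s encoder weights
    across the ``hidden_dim`` latent units after training. Deterministic
    given ``seed``.
    """
    n, p = m.values.shape
    if n < 10:
        raise ValidationError("autoencoder training requires at least 10 patients")
    if hidden_dim >= p:
        raise ValidationError(f"hidden_dim ({hidden_dim}) must be < p_features ({p})")
    if not np.isfinite(m.values).all():
        raise ValidationError("non-finite values in input matrix")

    x = _minmax(m.values)
    rng = derive_rng(seed, "autoencoder", m.data_type)

    # Encoder starts at exactly zero: a feature's weights only move if its
    # values carry reconstruction gradient, so dead features score zero
    # variability. The random decoder breaks symmetry between hidden units.
    w_enc = np.zeros((p, hidden_dim))
    b_enc = np.zeros(hidden_dim)
    w_dec = rng.normal(0.0, np.sqrt(1.0 / hidden_dim), (hidden_dim, p))
    b_dec = np.zeros(p)

    params = [w_enc, b_enc, w_dec, b_dec]
    vel = [np.zeros_like(q) for q in params]
    losses = []

    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = x[idx]
            h = xb @ w_enc + b_enc
            xr = h @ w_dec + b_dec
            err = xr - xb
            epoch_loss += float(np.mean(err**2)) * len(idx)

            scale = 2.0 / err.size
            g_dec = scale * (h.T @ err)
            gb_dec = scale * err.sum(axis=0)
            g_h = scale * (err @ w_dec.T)
            g_enc = xb.T @ g_h
            gb_enc = g_h.sum(axis=0)

            for q, g, v in zip(params, [g_enc, gb_enc, g_dec, gb_dec], vel):
                v *= momentum
                v += g
                q -= lr * v
            np.maximum(w_enc, 0.0, out=w_enc)  # non-negativity constraint
        losses.append(epoch_loss / n)

    if not all(np.isfinite(q).all() for q in params):
        raise NumericalError(
            "autoencoder training diverged (non-finite weights); lower the learning rate"
        )
    variability = w_enc.var(axis=1)
    return WeightProfile(
        variability=variability,
        hidden_dim=hidden_dim,
        training_meta={"epochs": epochs, "seed": seed, "final_loss": losses[-1], "loss_curve": losses},
    )


def variance_profile(m: OmicsMatrix) -> WeightProfile:
    """Deterministic alternative scoring: raw per-feature variance."""
    return WeightProfile(
        variability=m.values.var(axis=0),
        hidden_dim=0,
        training_meta={"method": "variance"},
    )


def select_features(w: WeightProfile, n_keep: int) -> FeatureIndexSet:
    """Indices of the ``n_keep`` highest-variability features.

    Ties break toward the lower index; ``n_keep ≥ p`` returns all features.
    """
    if n_keep < 1:
        raise ValidationError("n_keep must be ≥ 1")
    p = len(w.variability)
    if n_keep >= p:
        return FeatureIndexSet(np.arange(p))
    # stable sort on (-score, index): mergesort keeps lower indices first on ties
    order = np.argsort(-w.variability, kind="mergesort")
    return FeatureIndexSet(np.sort(order[:n_keep]))


def filter_matrix(m: OmicsMatrix, s: FeatureIndexSet) -> OmicsMatrix:
    """Column-subset ``m`` to the selected features, preserving patient order."""
    if (s.indices >= m.p_features).any():
        raise ValidationError(
            f"feature index out of range for {m.data_type} (p={m.p_features})"
        )
    return OmicsMatrix(
        m.values[:, s.indices],
        list(m.patient_ids),
        [m.feature_ids[i] for i in s.indices],
        m.data_type,
    )


def apply_filter(m: OmicsMatrix, cfg, seed: int) -> OmicsMatrix:
    """Config-driven filtering used by the pipelines.

    Skips work entirely when selection would keep every feature.
    """
    if not cfg.enabled or cfg.n_keep >= m.p_features:
        return m
    if cfg.method == "variance":
        profile = variance_profile(m)
    else:
        profile = train_weight_profile(m, cfg.hidden_dim, cfg.epochs, seed)
    return filter_matrix(m, select_features(profile, cfg.n_keep))
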