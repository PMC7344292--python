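"""Patient-space minimum-residual factor analysis.

Instead of the classical feature-feature correlation, the factor model is
fitted to the n × n **patient** correlation matrix: features are
standardized, each patient's profile is correlated with every other
patient's, and a loading matrix Λ (n_patients × k) is sought so that ΛΛᵀ
reproduces the off-diagonal correlations. The diagonal (communalities) is
free, which is exactly the minimum-residual (MINRES) formulation: minimize

    f(Λ) = Σ_{i≠j} (C_ij − (ΛΛᵀ)_ij)²

The rows of Λ are the low-dimensional patient embedding used downstream.
Working in patient space keeps the problem size at n² regardless of the
feature count, and preserving patient-patient correlations is what the
clustering and risk models actually consume.

Fitting is deterministic: initialization takes the k leading eigenpairs of
C (Λ₀ = V√λ₊, each eigenvector's largest-magnitude element made positive)
and L-BFGS-B refines it; the returned residual never exceeds the
initialization's.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .datatypes import FactorRepresentation, OmicsMatrix
from .errors import NumericalError, ValidationError

__all__ = [
    "CorrelationMatrix",
    "patient_correlation",
    "fit_factor_model",
    "generate_representations",
]


class CorrelationMatrix:
    """Symmetric patient-patient Pearson correlation matrix (unit diagonal)."""

    def __init__(self, values: np.ndarray, patient_ids: list[str]):
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        if values.ndim != 2 or values.shape[1] != n:
            raise ValidationError("correlation matrix must be square")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if np.abs(values).max() > 1 + 1e-10:
            raise ValidationError("correlation entries must lie in [-1, 1]")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 1.0)
        self.values = values
        self.patient_ids = list(patient_ids)

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]


def patient_correlation(m: OmicsMatrix) -> CorrelationMatrix:
    """Pearson correlation between patients' standardized feature profiles.

    Features are standardized (mean 0, sd 1 across patients) first so that
    high-magnitude platforms do not dominate; zero-variance features are
    dropped. A patient whose standardized profile has zero variance has no
    defined correlation and is reported by ID.
    """
    x = m.values
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 features with nonzero variance")
    x = (x - x.mean(axis=0)) / x.std(axis=0)

    row_sd = x.std(axis=1)
    dead = np.where(row_sd < 1e-10)[0]  # flat up to floating-point noise
    if dead.size:
        names = [m.patient_ids[i] for i in dead[:5]]
        raise ValidationError(f"patients with zero-variance profiles: {names}")
    xc = (x - x.mean(axis=1, keepdims=True)) / row_sd[:, None]
    c = (xc @ xc.T) / x.shape[1]
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c, m.patient_ids)


def _offdiag_rmse(c: np.ndarray, lam: np.ndarray) -> float:
    r = c - lam @ lam.T
    np.fill_diagonal(r, 0.0)
    n = c.shape[0]
    return float(np.sqrt((r**2).sum() / (n * (n - 1))))


def _eigen_init(c: np.ndarray, k: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(c)
    idx = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[idx], vecs[:, idx]
    # fixed sign convention: largest-|.| element of each eigenvector positive
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def fit_factor_model(
    c: CorrelationMatrix, k: int, max_iter: int = 1000, tol: float = 1e-6
) -> FactorRepresentation:
    """Minimum-residual fit of ΛΛᵀ to the off-diagonal of ``c``.

    Deterministic; the objective value never increases from the
    eigen-initialization (the initialization is returned if the optimizer
    fails to improve on it).
    """
    n = c.n_patients
    if not (1 <= k <= n - 1):
        raise ValidationError(f"k must lie in [1, {n - 1}], got {k}")

    cm = c.values
    lam0 = _eigen_init(cm, k)

    def objective(flat: np.ndarray):
        lam = flat.reshape(n, k)
        r = cm - lam @ lam.T
        np.fill_diagonal(r, 0.0)
        f = float((r**2).sum())
        grad = (-4.0 * r @ lam).ravel()
        return f, grad

    res = minimize(
        objective,
        lam0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise NumericalError(f"factor fit diverged at k={k}: {res.message}")
    lam = res.x.reshape(n, k)
    if _offdiag_rmse(cm, lam) > _offdiag_rmse(cm, lam0):
        lam = lam0  # optimizer must never do worse than its start
    return FactorRepresentation(
        scores=lam,
        k=k,
        source={"k": k},
        fit_residual=_offdiag_rmse(cm, lam),
    )


def generate_representations(
    m: OmicsMatrix, factor_counts, max_iter: int = 1000, tol: float = 1e-6
) -> list[FactorRepresentation]:
    """One factor representation per requested k, sharing one correlation
    matrix. Order follows ``factor_counts``."""
    counts = list(factor_counts)
    if not counts:
        raise ValidationError("factor_counts must be non-empty")
    c = patient_correlation(m)
    out = []
    for k in counts:
        try:
            rep = fit_factor_model(c, k, max_iter, tol)
        except (ValidationError, NumericalError) as exc:
            raise type(exc)(f"{m.data_type}, k={k}: {exc}") from exc
        rep.source = {"data_type": m.data_type, "k": k}
        out.append(rep)
    return out
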