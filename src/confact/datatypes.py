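"""Core containers shared across the pipeline.

Conventions: every matrix is patients-in-rows. Patient alignment between
objects is always by ID, never by row position. Containers validate their
invariants at construction time and raise :class:`~confact.errors.ValidationError`
on violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


def _as_str_index(ids: Sequence[str], what: str) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        dupes = sorted({i for i in out if out.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return out


@dataclass
class OmicsMatrix:
    """One data type's patients × features matrix.

    Parameters
    ----------
    values
        Numeric matrix, shape ``(n_patients, p_features)``; units are
        platform-specific (e.g. log expression, methylation beta).
    patient_ids, feature_ids
        Unique row / column identifiers.
    data_type
        Platform label, e.g. ``"mRNA"``, ``"methylation"``, ``"miRNA"``.
    """

    values: np.ndarray
    patient_ids: list[str]
    feature_ids: list[str]
    data_type: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("omics values must be a 2-D matrix")
        self.patient_ids = _as_str_index(self.patient_ids, "patient IDs")
        self.feature_ids = _as_str_index(self.feature_ids, "feature IDs")
        n, p = self.values.shape
        if n != len(self.patient_ids) or p != len(self.feature_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients × {len(self.feature_ids)} features"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError(f"non-finite values in {self.data_type} matrix")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def p_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.feature_ids)

    def reindex_patients(self, patient_ids: Sequence[str]) -> "OmicsMatrix":
        """Row-reorder to ``patient_ids`` (must be a permutation of ours)."""
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in patient_ids if p not in pos]
        if missing or len(patient_ids) != self.n_patients:
            raise ValidationError(
                f"{self.data_type}: patient set mismatch (missing {missing[:5]})"
            )
        idx = [pos[p] for p in patient_ids]
        return OmicsMatrix(self.values[idx], list(patient_ids), list(self.feature_ids), self.data_type)


@dataclass
class SurvivalTable:
    """Right-censored follow-up: observed time (days) and event indicator."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = _as_str_index(self.patient_ids, "patient IDs")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.patient_ids) == len(self.time) == len(self.event)):
            raise ValidationError("survival table columns have unequal lengths")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            raise ValidationError("survival times must be finite and strictly positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValidationError("event indicator must be 0 (censored) or 1 (event)")

    def __len__(self) -> int:
        return len(self.patient_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event}, index=self.patient_ids
        )

    def subset(self, patient_ids: Sequence[str]) -> "SurvivalTable":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in patient_ids if p not in pos]
        if missing:
            raise ValidationError(f"patients without survival rows: {missing[:5]}")
        idx = [pos[p] for p in patient_ids]
        return SurvivalTable(list(patient_ids), self.time[idx], self.event[idx])


@dataclass
class WeightProfile:
    """Per-feature variability of non-negative encoder weights."""

    variability: np.ndarray
    hidden_dim: int
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variability = np.asarray(self.variability, dtype=float)
        if self.variability.ndim != 1:
            raise ValidationError("variability must be a vector")
        if (self.variability < 0).any() or not np.isfinite(self.variability).all():
            raise ValidationError("variability scores must be finite and non-negative")


@dataclass
class FeatureIndexSet:
    """Sorted column positions into a source omics matrix."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValidationError("feature index set may not be empty")
        if (self.indices < 0).any():
            raise ValidationError("negative feature index")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class FactorRepresentation:
    """A k-factor embedding of patients (loading matrix of the patient-
    correlation factor model)."""

    scores: np.ndarray
    k: int
    source: dict = field(default_factory=dict)
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != self.k:
            raise ValidationError("scores must be n_patients × k")
        if self.k < 1:
            raise ValidationError("k must be ≥ 1")
        if not np.isfinite(self.scores).all():
            raise ValidationError("non-finite factor scores")
        if self.fit_residual < 0:
            raise ValidationError("fit_residual must be ≥ 0")

    @property
    def n_patients(self) -> int:
        return self.scores.shape[0]


@dataclass
class Partition:
    """One k-means clustering of one representation (labels are 1..k)."""

    labels: np.ndarray
    k: int
    sse: float
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValidationError(
                f"labels must use every id in 1..{self.k}; saw {sorted(present)}"
            )


@dataclass
class ConnectivityMatrix:
    """Binary co-membership indicator for one partition."""

    values: np.ndarray
    patient_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValidationError("connectivity matrix must be square")
        if not np.isin(self.values, [0.0, 1.0]).all():
            raise ValidationError("connectivity entries must be 0/1")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("connectivity matrix must be symmetric")
        if not (np.diag(self.values) == 1.0).all():
            raise ValidationError("connectivity diagonal must be 1")


@dataclass
class SubtypeResult:
    """Final consensus subtypes plus provenance."""

    labels: np.ndarray
    k_final: int
    consensus: np.ndarray
    partitions: list[Partition]
    patient_weights: np.ndarray
    patient_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.consensus = np.asarray(self.consensus, dtype=float)
        self.patient_weights = np.asarray(self.patient_weights, dtype=float)
        if self.k_final < 2:
            raise ValidationError("k_final must be ≥ 2")
        if (self.consensus < -1e-12).any() or (self.consensus > 1 + 1e-12).any():
            raise ValidationError("consensus entries must lie in [0, 1]")


@dataclass
class CoxModel:
    """Penalized Cox coefficients for one factor representation."""

    beta: np.ndarray
    k: int
    penalty: dict = field(default_factory=dict)
    cv_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.k,):
            raise ValidationError("beta length must equal the representation dimension")
        lam = self.penalty.get("lambda", 0.0)
        mix = self.penalty.get("alpha_mix", 0.5)
        if lam < 0 or not (0.0 <= mix <= 1.0):
            raise ValidationError("invalid penalty parameters")


@dataclass
class RiskResult:
    """Aggregated per-patient relative-hazard scores exp(Σ β·x)."""

    patient_ids: list[str]
    risk: np.ndarray
    per_representation_risks: np.ndarray

    def __post_init__(self) -> None:
        self.risk = np.asarray(self.risk, dtype=float)
        self.per_representation_risks = np.asarray(self.per_representation_risks, dtype=float)
        if (self.risk <= 0).any() or (self.per_representation_risks <= 0).any():
            raise ValidationError("risk scores must be strictly positive")


@dataclass
class SyntheticCohort:
    """Multi-omics cohort with planted subtypes and survival structure."""

    omics: list[OmicsMatrix]
    true_labels: np.ndarray
    true_risk: np.ndarray | None = None
    survival: SurvivalTable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        ref = self.omics[0].patient_ids
        for m in self.omics[1:]:
            if m.patient_ids != ref:
                raise ValidationError("omics matrices must share patient-ID ordering")

    @property
    def patient_ids(self) -> list[str]:
        return self.omics[0].patient_ids
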