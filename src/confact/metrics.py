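"""Survival and clustering evaluation metrics.

Cox likelihood-ratio p-value across subtypes, Harrell's concordance index,
adjusted Rand index and normalized mutual information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .datatypes import SurvivalTable
from .errors import NumericalError, ValidationError

__all__ = [
    "EvaluationReport",
    "cox_subtype_pvalue",
    "concordance_index",
    "adjusted_rand_index",
    "normalized_mutual_information",
]


@dataclass
class EvaluationReport:
    """Bundle of evaluation metrics; fields are None when not computable
    from the supplied inputs."""

    cox_p: float | None = None
    c_index: float | None = None
    ari: float | None = None
    nmi: float | None = None
    n_pairs_comparable: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def cox_subtype_pvalue(labels, surv: SurvivalTable) -> float:
    """Likelihood-ratio p-value of a Cox model with subtype as a
    categorical covariate (Efron tie handling), against the null of no
    survival difference between subtypes. Invariant to relabeling."""
    labels = np.asarray(labels)
    if len(labels) != len(surv):
        raise ValidationError("labels and survival table have different lengths")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValidationError("need at least 2 subtypes for a survival comparison")
    if surv.n_events == 0:
        raise ValidationError("no events observed")
    for g in groups:
        if surv.event[labels == g].sum() < 1:
            raise ValidationError(f"subtype {g} has no events")

    dummies = pd.get_dummies(pd.Categorical(labels), prefix="g", drop_first=True)
    df = pd.DataFrame(
        {"time": surv.time, "event": surv.event}, index=range(len(labels))
    ).join(dummies.astype(float).set_axis(range(len(labels))))
    # quasi-separation (a tiny subtype with one extreme event) can keep the
    # unpenalized fit from converging; fall back to a vanishingly small
    # ridge term that leaves the LRT essentially unchanged
    last_exc: Exception | None = None
    for penalizer in (0.0, 1e-6, 1e-4, 1e-2):
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # ill-conditioning is handled by the ladder
                cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            last_exc = exc
            continue
        return float(cph.log_likelihood_ratio_test().p_value)
    raise NumericalError(f"Cox model failed to converge: {last_exc}")


def concordance_index(risk, surv: SurvivalTable, return_pairs: bool = False):
    """Harrell's C by exhaustive pair enumeration.

    A pair is comparable when the strictly earlier observed time belongs to
    an event (tied observed times are never comparable, including
    event/event ties). Concordant pairs have the higher risk on the earlier
    event; tied risks score 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(surv):
        raise ValidationError("risk vector and survival table have different lengths")
    time, event = surv.time, surv.event
    n = len(risk)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[i] < time[j]:
                comparable += 1
                if risk[i] > risk[j]:
                    concordant += 1.0
                elif risk[i] == risk[j]:
                    concordant += 0.5
    if comparable == 0:
        raise ValidationError("no comparable pairs (check censoring pattern)")
    c = concordant / comparable
    return (c, comparable) if return_pairs else c


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValidationError("partitions have different lengths")
    if len(a) < 2:
        raise ValidationError("partitions must contain at least 2 items")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    a, b = _check_pair(a, b)
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(a, b) -> float:
    """Mutual information normalized by the arithmetic mean of the
    entropies; 0 when both partitions are constant (no information)."""
    a, b = _check_pair(a, b)
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def evaluate(
    labels=None,
    surv: SurvivalTable | None = None,
    risk=None,
    truth=None,
) -> EvaluationReport:
    """Compute every metric the supplied inputs allow."""
    report = EvaluationReport()
    if labels is not None and surv is not None:
        report.cox_p = cox_subtype_pvalue(labels, surv)
    if risk is not None and surv is not None:
        c, pairs = concordance_index(risk, surv, return_pairs=True)
        report.c_index = c
        report.n_pairs_comparable = pairs
    if labels is not None and truth is not None:
        report.ari = adjusted_rand_index(labels, truth)
        report.nmi = normalized_mutual_information(labels, truth)
    return report
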