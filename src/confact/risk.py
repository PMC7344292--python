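"""Supervised risk scoring via an ensemble of penalized Cox models.

Training and test cohorts are merged per omics, filtered, and embedded by
the same patient-correlation factor analysis used for subtyping. For every
factor representation a Cox proportional-hazards model with an elastic-net
penalty is fitted on the training rows (glmnet-style coordinate descent via
scikit-survival), with the regularization strength λ chosen by k-fold
cross-validated partial-likelihood deviance over a log-spaced path. A
patient's risk under one representation is the relative hazard
exp(Σ_i β_i x_i); the final score is the geometric mean of the risks from
all representations of all data types.

Representations whose cross-validation fails (e.g. a fold without events)
are dropped from the ensemble with a warning rather than failing the run.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .config import RunConfig
from .datatypes import (
    CoxModel,
    FactorRepresentation,
    OmicsMatrix,
    RiskResult,
    SurvivalTable,
)
from .errors import ValidationError
from .factor import generate_representations
from .feature_filter import apply_filter
from .rng import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["fit_cox_elastic_net", "risk_score", "aggregate_risk", "predict_risk"]


def _breslow_loglik(x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray) -> float:
    """Breslow partial log-likelihood of ``beta`` on a held-out fold."""
    eta = x @ beta
    order = np.argsort(-time, kind="mergesort")  # decreasing time
    eta, ev = eta[order], event[order]
    # stable running log-sum-exp over the (growing) risk set
    log_risk = np.empty_like(eta)
    run = -np.inf
    acc = 0.0
    for i, e in enumerate(eta):
        if e > run:
            acc = acc * np.exp(run - e) + 1.0
            run = e
        else:
            acc += np.exp(e - run)
        log_risk[i] = run + np.log(acc)
    return float(np.sum((eta - log_risk)[ev == 1]))


def fit_cox_elastic_net(
    rep_train: FactorRepresentation,
    surv: SurvivalTable,
    folds: int = 5,
    alpha_mix: float = 0.5,
    seed: int = 0,
    n_lambdas: int = 20,
) -> CoxModel:
    """Cross-validated elastic-net Cox fit on one factor representation.

    λ is selected by maximizing the summed held-out Breslow partial
    log-likelihood across event-stratified folds (ties toward the stronger
    penalty), then the model is refitted on all training rows at that λ.
    Deterministic given ``seed``.
    """
    x = rep_train.scores
    n, k = x.shape
    if len(surv) != n:
        raise ValidationError("representation and survival table are misaligned")
    if surv.n_events < 2:
        raise ValidationError("need at least 2 events to fit a Cox model")
    if surv.n_events < folds:
        raise ValidationError(f"need at least {folds} events for {folds}-fold CV")
    if not (0.0 <= alpha_mix <= 1.0):
        raise ValidationError("alpha_mix must lie in [0, 1]")

    meta = {"folds": folds, "seed": seed}
    if x.std(axis=0).max() == 0.0:
        # no variation in any predictor: the penalized optimum is the null model
        return CoxModel(np.zeros(k), k, {"alpha_mix": alpha_mix, "lambda": np.inf}, meta)

    # coxnet's l1_ratio must be > 0; approximate pure ridge with a tiny value
    l1 = max(alpha_mix, 1e-6)
    y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)

    path = CoxnetSurvivalAnalysis(l1_ratio=l1, n_alphas=n_lambdas, alpha_min_ratio=0.01)
    with warnings.catch_warnings():
        # the strongest penalty zeroing every coefficient is a legitimate
        # outcome (null model), not a user error
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        path.fit(x, y)
    alphas = np.asarray(path.alphas_)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=derive_seed(seed, "cv"))
    scores = np.zeros(len(alphas))
    for tr, te in skf.split(x, surv.event):
        if surv.event[tr].sum() < 2 or surv.event[te].sum() < 1:
            raise ValidationError("a CV fold has too few events")
        fold = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=alphas)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="all coefficients are zero")
            fold.fit(x[tr], y[tr])
        fold_alphas = list(fold.alphas_)
        for ai, a in enumerate(alphas):
            if a in fold_alphas:
                beta = fold.coef_[:, fold_alphas.index(a)]
            else:  # path truncated in this fold: fall back to strongest fitted penalty
                beta = fold.coef_[:, 0]
            scores[ai] += _breslow_loglik(x[te], surv.time[te], surv.event[te], beta)

    # ties toward larger alpha (alphas are sorted decreasing in sksurv)
    best = int(np.flatnonzero(scores == scores.max())[0])
    lam = float(alphas[best])
    beta = path.coef_[:, best].copy()
    return CoxModel(beta, k, {"alpha_mix": alpha_mix, "lambda": lam}, meta)


def risk_score(model: CoxModel, rep: FactorRepresentation) -> np.ndarray:
    """Relative hazard exp(Σ β_i x_i) per patient; strictly positive."""
    if rep.k != model.k:
        raise ValidationError(
            f"representation dimension {rep.k} != model dimension {model.k}"
        )
    return np.exp(rep.scores @ model.beta)


def aggregate_risk(per_rep: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean of per-representation risks."""
    per_rep = np.asarray(per_rep, dtype=float)
    if per_rep.ndim == 1:
        per_rep = per_rep[:, None]
    if per_rep.shape[1] < 1:
        raise ValidationError("need at least one representation")
    if (per_rep <= 0).any():
        raise ValidationError("risk scores must be strictly positive")
    return np.exp(np.log(per_rep).mean(axis=1))


def _project_scores(rep_train: FactorRepresentation, c_cross: np.ndarray) -> np.ndarray:
    """Out-of-sample loading rows: least-squares fit of test-to-train
    correlations onto the training loading matrix (leakage-free variant)."""
    lam = rep_train.scores
    sol, *_ = np.linalg.lstsq(lam, c_cross.T, rcond=None)
    return sol.T


def predict_risk(
    train_omics: list[OmicsMatrix],
    train_survival: SurvivalTable,
    test_omics: list[OmicsMatrix],
    config: RunConfig | None = None,
) -> RiskResult:
    """Ensemble risk prediction for test patients.

    Per omics: merge train and test rows, filter, embed with the factor
    grid; per representation: fit the penalized Cox model on training rows
    and score test rows; aggregate flat across all representations of all
    omics by geometric mean.
    """
    cfg = (config or RunConfig()).validate()
    if len(train_omics) != len(test_omics):
        raise ValidationError("train and test must provide the same omics types")

    train_ids = train_omics[0].patient_ids
    test_ids = test_omics[0].patient_ids
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValidationError(f"patient IDs appear in both train and test: {sorted(overlap)[:5]}")
    surv = train_survival.subset(train_ids)

    from .consensus import align_omics  # local import to avoid a cycle

    train_omics = align_omics(train_omics)
    test_omics = align_omics(test_omics)

    n_train, n_test = len(train_ids), len(test_ids)
    per_rep_risks: list[np.ndarray] = []
    rep_names: list[str] = []

    for tr_m, te_m in zip(train_omics, test_omics):
        if tr_m.data_type != te_m.data_type:
            raise ValidationError(
                f"omics order mismatch: {tr_m.data_type} vs {te_m.data_type}"
            )
        missing = set(tr_m.feature_ids) ^ set(te_m.feature_ids)
        if missing:
            raise ValidationError(
                f"{tr_m.data_type}: train/test feature spaces differ; offenders include "
                f"{sorted(missing)[:5]}"
            )
        # align test columns to the training feature order
        col = {f: i for i, f in enumerate(te_m.feature_ids)}
        te_vals = te_m.values[:, [col[f] for f in tr_m.feature_ids]]

        merged = OmicsMatrix(
            np.vstack([tr_m.values, te_vals]),
            train_ids + test_ids,
            list(tr_m.feature_ids),
            tr_m.data_type,
        )
        fseed = derive_seed(cfg.seed, "filter", tr_m.data_type)
        counts = [k for k in cfg.fa.factor_counts if k <= merged.n_patients - 1]

        if cfg.risk.fit_fa_on_train_only:
            fm_train = apply_filter(tr_m, cfg.filter, fseed)
            reps = generate_representations(fm_train, counts, cfg.fa.max_iter, cfg.fa.tol)
            from .factor import patient_correlation

            fm_test = OmicsMatrix(
                te_vals[:, [tr_m.feature_ids.index(f) for f in fm_train.feature_ids]]
                if fm_train.feature_ids != tr_m.feature_ids
                else te_vals,
                test_ids,
                list(fm_train.feature_ids),
                tr_m.data_type,
            )
            both = OmicsMatrix(
                np.vstack([fm_train.values, fm_test.values]),
                train_ids + test_ids,
                list(fm_train.feature_ids),
                tr_m.data_type,
            )
            c_all = patient_correlation(both).values
            c_cross = c_all[n_train:, :n_train]
            rep_pairs = [
                (rep, FactorRepresentation(_project_scores(rep, c_cross), rep.k, rep.source))
                for rep in reps
            ]
        else:
            fm = apply_filter(merged, cfg.filter, fseed)
            reps = generate_representations(fm, counts, cfg.fa.max_iter, cfg.fa.tol)
            rep_pairs = [
                (
                    FactorRepresentation(rep.scores[:n_train], rep.k, rep.source),
                    FactorRepresentation(rep.scores[n_train:], rep.k, rep.source),
                )
                for rep in reps
            ]

        for rep_train, rep_test in rep_pairs:
            name = f"{tr_m.data_type}/k={rep_train.k}"
            try:
                model = fit_cox_elastic_net(
                    rep_train,
                    surv,
                    cfg.risk.folds,
                    cfg.risk.alpha_mix,
                    derive_seed(cfg.seed, "cox", name),
                    cfg.risk.n_lambdas,
                )
            except (ValidationError, ArithmeticError) as exc:
                logger.warning("dropping representation %s from risk ensemble: %s", name, exc)
                continue
            per_rep_risks.append(risk_score(model, rep_test))
            rep_names.append(name)

    if not per_rep_risks:
        raise ValidationError("every representation failed Cox cross-validation")
    mat = np.column_stack(per_rep_risks)
    return RiskResult(
        patient_ids=test_ids,
        risk=aggregate_risk(mat),
        per_representation_risks=mat,
    )
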