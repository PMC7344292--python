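"""Synthetic multi-omics cohorts with planted subtypes and survival.

The generator emulates the statistical structure the pipeline assumes: a
shared subtype signal expressed independently in every data type, plus
survival whose hazard depends on the subtype. Each omics matrix carries
``n_informative`` features whose subtype means are shifted by
``effect_size`` noise standard deviations; all remaining features are pure
Gaussian noise. Values live on a log-like continuous scale — realistic count
distributions, batch effects and missingness are deliberately out of scope.

With ``signal_split=True``, omics ``m`` elevates its informative features in
subtype ``m mod G`` only, so no single data type separates all subtypes —
the setting used to show that integration beats any individual data type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .datatypes import OmicsMatrix, SurvivalTable, SyntheticCohort
from .errors import ValidationError
from .rng import derive_rng

__all__ = [
    "OmicsSpec",
    "generate_multiomics",
    "generate_survival",
    "generate_cohort",
    "split_cohort",
    "permute_survival",
]


@dataclass
class OmicsSpec:
    """Feature budget for one synthetic data type."""

    n_features: int
    n_informative: int
    data_type: str = "omics"


def _planted_labels(n: int, proportions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subtype labels 1..G with counts matching ``proportions`` exactly
    (largest-remainder rounding) in a random order.

    Deterministic counts guarantee that every subtype is present whenever
    n ≥ G, which the downstream recovery tests rely on.
    """
    g = len(proportions)
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    # guarantee presence of every subtype
    while (counts == 0).any() and n >= g:
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    labels = np.repeat(np.arange(1, g + 1), counts)
    rng.shuffle(labels)
    return labels


def generate_multiomics(
    n_patients: int,
    subtype_proportions,
    omics_specs,
    effect_size: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    signal_split: bool = False,
) -> SyntheticCohort:
    """Generate omics matrices sharing planted subtype structure.

    Parameters
    ----------
    subtype_proportions
        Probability vector over G subtypes (must sum to 1).
    omics_specs
        One :class:`OmicsSpec` (or ``{"n_features", "n_informative"}`` dict)
        per data type; each data type draws an independent informative set.
    effect_size
        Subtype mean separation for informative features, in units of
        ``noise_sd``. 0 plants no signal.
    signal_split
        Restrict each omics' informative contrast to a single subtype, so
        integration across omics is required to separate all subtypes.
    """
    props = np.asarray(subtype_proportions, dtype=float)
    if (props < 0).any() or abs(props.sum() - 1.0) > 1e-8:
        raise ValidationError("subtype proportions must be non-negative and sum to 1")
    g = len(props)
    if not (1 <= g <= n_patients):
        raise ValidationError("need n_patients ≥ number of subtypes ≥ 1")
    if effect_size < 0 or noise_sd <= 0:
        raise ValidationError("effect_size ≥ 0 and noise_sd > 0 required")

    specs = [
        s if isinstance(s, OmicsSpec) else OmicsSpec(**s) for s in omics_specs
    ]
    for s in specs:
        if s.n_informative > s.n_features:
            raise ValidationError(
                f"{s.data_type}: n_informative ({s.n_informative}) > n_features ({s.n_features})"
            )

    rng = derive_rng(seed, "multiomics")
    labels = _planted_labels(n_patients, props, rng)
    patient_ids = [f"P{i:04d}" for i in range(n_patients)]

    omics = []
    for m, spec in enumerate(specs):
        orng = derive_rng(seed, "omics", m)
        base = orng.normal(0.0, 2.0, spec.n_features)          # per-feature baseline level
        x = base + orng.normal(0.0, noise_sd, (n_patients, spec.n_features))
        info = np.sort(orng.choice(spec.n_features, spec.n_informative, replace=False))
        if signal_split:
            target = np.full(spec.n_informative, (m % g) + 1)
        else:
            target = orng.integers(1, g + 1, spec.n_informative)
        shift = effect_size * noise_sd
        for j, f in enumerate(info):
            x[labels == target[j], f] += shift
        name = spec.data_type if spec.data_type != "omics" else f"omics{m + 1}"
        omics.append(OmicsMatrix(x, patient_ids, [f"{name}_f{j}" for j in range(spec.n_features)], name))

    return SyntheticCohort(omics=omics, true_labels=labels, seed=seed)


def _censoring_rate_for(risk: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate c with mean censored fraction ≈ censor_rate.

    For event hazard h and independent Exp(c) censoring, P(censored) =
    c/(h + c); solve mean over patients = censor_rate.
    """
    if censor_rate <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (risk + c)) - censor_rate)

    hi = float(risk.max()) * censor_rate / (1 - censor_rate) + 1e-9
    while frac(hi) < 0:
        hi *= 2
    return brentq(frac, 1e-12, hi)


def generate_survival(
    true_labels=None,
    true_risk=None,
    baseline_scale: float = 365.0,
    hazard_ratios=None,
    censor_rate: float = 0.0,
    seed: int = 0,
    shape: float = 1.0,
    patient_ids=None,
) -> tuple[SurvivalTable, np.ndarray]:
    """Survival times from a proportional-hazards exponential/Weibull model.

    Per-patient hazard multiplier is either ``hazard_ratios[label]`` or the
    given ``true_risk``. On the standardized scale U ~ Exp(risk); observed
    time = ``baseline_scale * min(U, C)**(1/shape)`` with independent
    exponential censoring C calibrated so the expected censored fraction is
    ``censor_rate``. ``shape`` = 1 gives the exponential model (mean time
    ``baseline_scale / risk``); ``shape`` ≠ 1 gives a Weibull baseline.

    Returns the table and the per-patient risk multipliers used.
    """
    if not (0.0 <= censor_rate < 1.0):
        raise ValidationError("censor_rate must lie in [0, 1)")
    if baseline_scale <= 0 or shape <= 0:
        raise ValidationError("baseline_scale and shape must be positive")
    if true_risk is not None:
        risk = np.asarray(true_risk, dtype=float)
        if (risk <= 0).any():
            raise ValidationError("true_risk must be strictly positive")
    else:
        if true_labels is None or hazard_ratios is None:
            raise ValidationError("provide true_risk, or true_labels with hazard_ratios")
        labels = np.asarray(true_labels, dtype=int)
        hr = np.asarray(hazard_ratios, dtype=float)
        if (hr <= 0).any():
            raise ValidationError("hazard ratios must be positive")
        if labels.min() < 1 or labels.max() > len(hr):
            raise ValidationError("labels must index hazard_ratios (1-based)")
        risk = hr[labels - 1]

    n = len(risk)
    rng = derive_rng(seed, "survival")
    u_event = rng.exponential(1.0 / risk)
    c = _censoring_rate_for(risk, censor_rate)
    if c > 0:
        u_cens = rng.exponential(1.0 / c, n)
        event = (u_event <= u_cens).astype(int)
        u_obs = np.minimum(u_event, u_cens)
    else:
        event = np.ones(n, dtype=int)
        u_obs = u_event
    time = baseline_scale * np.power(u_obs, 1.0 / shape)
    time = np.maximum(time, 1e-9)
    ids = list(patient_ids) if patient_ids is not None else [f"P{i:04d}" for i in range(n)]
    return SurvivalTable(ids, time, event), risk


def split_cohort(cohort: SyntheticCohort, frac: float = 0.5, seed: int = 0):
    """Random patient split for train/test experiments.

    Returns ``(train_omics, train_survival, test_omics, test_survival,
    test_true_risk, test_true_labels)``; the split is deterministic given
    ``seed`` and patient order within each side is sorted by original index.
    """
    if not (0.0 < frac < 1.0):
        raise ValidationError("frac must lie in (0, 1)")
    if cohort.survival is None:
        raise ValidationError("cohort has no survival table to split")
    n = len(cohort.true_labels)
    rng = derive_rng(seed, "split")
    perm = rng.permutation(n)
    n_tr = int(round(n * frac))
    tr, te = np.sort(perm[:n_tr]), np.sort(perm[n_tr:])

    def sub(m: OmicsMatrix, idx: np.ndarray) -> OmicsMatrix:
        return OmicsMatrix(
            m.values[idx], [m.patient_ids[i] for i in idx], m.feature_ids, m.data_type
        )

    ids = cohort.patient_ids
    train = [sub(m, tr) for m in cohort.omics]
    test = [sub(m, te) for m in cohort.omics]
    surv_tr = cohort.survival.subset([ids[i] for i in tr])
    surv_te = cohort.survival.subset([ids[i] for i in te])
    risk_te = cohort.true_risk[te] if cohort.true_risk is not None else None
    return train, surv_tr, test, surv_te, risk_te, cohort.true_labels[te]


def permute_survival(surv: SurvivalTable, seed: int = 0) -> SurvivalTable:
    """Randomly reassign (time, event) rows to patients — a survival table
    carrying no relationship to any covariate; used for null calibration."""
    rng = derive_rng(seed, "permute")
    p = rng.permutation(len(surv))
    return SurvivalTable(surv.patient_ids, surv.time[p], surv.event[p])


def generate_cohort(
    n_patients: int = 150,
    subtype_proportions=(1 / 3, 1 / 3, 1 / 3),
    omics_specs=None,
    effect_size: float = 5.0,
    noise_sd: float = 1.0,
    hazard_ratios=(4.0, 2.0, 1.0),
    baseline_scale: float = 365.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    signal_split: bool = False,
) -> SyntheticCohort:
    """Full cohort: omics + labels + survival, with study-condition defaults
    (150 patients, 3 balanced subtypes, 3 omics of 500 features with 100
    informative each, 5-sd effects, subtype hazard ratios 4:2:1, 20%
    censoring, 1-year baseline scale)."""
    if omics_specs is None:
        omics_specs = [
            OmicsSpec(500, 100, "mRNA"),
            OmicsSpec(500, 100, "methylation"),
            OmicsSpec(500, 100, "miRNA"),
        ]
    cohort = generate_multiomics(
        n_patients, subtype_proportions, omics_specs, effect_size, noise_sd, seed, signal_split
    )
    surv, risk = generate_survival(
        true_labels=cohort.true_labels,
        baseline_scale=baseline_scale,
        hazard_ratios=hazard_ratios,
        censor_rate=censor_rate,
        seed=seed,
        patient_ids=cohort.patient_ids,
    )
    cohort.survival = surv
    cohort.true_risk = risk
    return cohort
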