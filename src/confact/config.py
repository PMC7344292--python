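"""Run configuration.

All defaults resolve without a config file; YAML configs may override any
subset. Unknown keys are rejected so that typos fail loudly rather than
silently running with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any

import yaml

from .errors import ValidationError


@dataclass
class FilterConfig:
    enabled: bool = True
    hidden_dim: int = 50
    epochs: int = 50
    n_keep: int = 2000          # per omics; effective n_keep = min(n_keep, p)
    method: str = "autoencoder"  # autoencoder | variance

    def validate(self) -> None:
        if self.method not in ("autoencoder", "variance"):
            raise ValidationError(f"filter.method must be autoencoder|variance, got {self.method!r}")
        if self.n_keep < 1 or self.hidden_dim < 1 or self.epochs < 1:
            raise ValidationError("filter parameters must be positive")


@dataclass
class FAConfig:
    factor_counts: list[int] = field(default_factory=lambda: list(range(2, 11)))
    max_iter: int = 1000
    tol: float = 1e-6

    def validate(self) -> None:
        if not self.factor_counts or any(k < 1 for k in self.factor_counts):
            raise ValidationError("fa.factor_counts must be a non-empty list of positive ints")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("fa.max_iter must be ≥ 1 and fa.tol > 0")


@dataclass
class ClusterConfig:
    k_min: int = 2
    k_max: int = 10
    n_starts: int = 20
    delta: float = 0.05  # BSS/TSS gain plateau threshold
    k_final: Any = "auto"

    def validate(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValidationError("need 2 ≤ cluster.k_min ≤ cluster.k_max")
        if self.n_starts < 1 or self.delta <= 0:
            raise ValidationError("cluster.n_starts ≥ 1 and cluster.delta > 0 required")


@dataclass
class RiskConfig:
    folds: int = 5
    alpha_mix: float = 0.5
    n_lambdas: int = 20
    fit_fa_on_train_only: bool = False

    def validate(self) -> None:
        if self.folds < 2:
            raise ValidationError("risk.folds must be ≥ 2")
        if not (0.0 <= self.alpha_mix <= 1.0):
            raise ValidationError("risk.alpha_mix must lie in [0, 1]")


@dataclass
class IOConfig:
    delimiter: str = "\t"
    na_policy: float = 0.2  # drop rows/columns with more than this missing fraction


@dataclass
class RunConfig:
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    fa: FAConfig = field(default_factory=FAConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    risk: RiskConfig = field(default_factory=RiskConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def validate(self) -> "RunConfig":
        for section in (self.filter, self.fa, self.cluster, self.risk):
            section.validate()
        return self

    def replace(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)


_SECTIONS = {
    "filter": FilterConfig,
    "fa": FAConfig,
    "cluster": ClusterConfig,
    "risk": RiskConfig,
    "io": IOConfig,
}


def _build_section(cls: type, data: dict, prefix: str) -> Any:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(prefix + k for k in unknown)}")
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a nested dict, rejecting unknown keys."""
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, dict):
                raise ValidationError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, f"{name}.")
    if data:
        raise ValidationError(f"unknown config key(s): {sorted(data)}")
    return RunConfig(**kwargs).validate()


def load_config(path: str | None = None) -> RunConfig:
    """Load a YAML config file; ``None`` yields pure defaults."""
    if path is None:
        return RunConfig().validate()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
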