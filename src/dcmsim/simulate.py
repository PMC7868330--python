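"""Synthetic data generation for the simulation study.

Attribute profiles come from a thresholded multivariate normal: each
respondent draws a latent A-vector with mean zero, unit variances and an
exchangeable pairwise correlation (default 0.70, a typical subdomain
correlation on large-scale educational assessments); attribute ``a`` is
mastered when the draw exceeds the threshold that leaves a ``base_rate``
proportion of masters in the population.  Item responses are then
independent Bernoulli draws with probabilities from the submodel's item
response function.

Generating item parameters default to the medium-quality values used across
the study: intercept -1.1, main effects 1.3, e parameter 3, interaction 0.24,
so a two-attribute item separates full masters from non-masters by
0.85 - 0.25 = 0.60 in probability.  Single-attribute items use the increment
3, which reproduces the same 0.25/0.87 guessing/mastery anchor (the lone
value that matches the stated item quality); it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .design import DesignCondition, QMatrix, enumerate_profiles, profile_to_class
from .models import ItemParams, make_item_params, probability_table

DEFAULT_RHO = 0.70

#: medium-quality generating values (log-odds metric)
GENERATING_VALUES = {
    "intercept": -1.1,
    "main": 1.3,
    "e_param": 3.0,
    "interaction": 0.24,
    "single_attribute_increment": 3.0,
}


@dataclass(frozen=True)
class ProfileSimConfig:
    """Latent-normal profile generator settings."""

    n_attributes: int
    base_rate: float = 0.50
    rho: float = DEFAULT_RHO

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must be in (0, 1)")
        a = self.n_attributes
        if a >= 2 and not (-1.0 / (a - 1) < self.rho < 1):
            raise ValueError(
                "exchangeable correlation must satisfy -1/(A-1) < rho < 1 "
                "for a positive-definite latent correlation matrix"
            )

    @property
    def threshold(self) -> float:
        return mastery_threshold(self.base_rate)

    @property
    def correlation_matrix(self) -> np.ndarray:
        a = self.n_attributes
        return np.full((a, a), self.rho) + (1 - self.rho) * np.eye(a)


@dataclass
class DatasetBundle:
    """One simulated replication: responses plus the truth that produced them."""

    responses: np.ndarray
    true_profiles: np.ndarray
    true_params: list[ItemParams]
    qmatrix: QMatrix
    model_spec: np.ndarray
    condition: DesignCondition | None = None
    seed: int | None = None

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]


def mastery_threshold(base_rate: float) -> float:
    """Latent z threshold tau with P(Z > tau) = base_rate."""
    if not 0 < base_rate < 1:
        raise ValueError("base_rate must be in (0, 1)")
    return float(norm.ppf(1.0 - base_rate))


def simulate_profiles(cfg: ProfileSimConfig, n: int, rng) -> np.ndarray:
    """Draw n binary attribute profiles from the dichotomized latent normal."""
    rng = np.random.default_rng(rng)
    z = rng.multivariate_normal(
        np.zeros(cfg.n_attributes), cfg.correlation_matrix, size=n,
        method="cholesky",
    )
    return (z > cfg.threshold).astype(np.int8)


def generating_parameters(
    qmatrix: QMatrix,
    model_spec: np.ndarray,
    intercept: float = GENERATING_VALUES["intercept"],
    main: float = GENERATING_VALUES["main"],
    e_param: float = GENERATING_VALUES["e_param"],
    interaction: float = GENERATING_VALUES["interaction"],
    single_attribute_increment: float = GENERATING_VALUES["single_attribute_increment"],
) -> list[ItemParams]:
    """True item parameters for every item of a design."""
    params = []
    for i in range(qmatrix.n_items):
        qrow = qmatrix.entries[i]
        model = model_spec[i]
        n_req = int(qrow.sum())
        if n_req == 1:
            if model in ("DINA", "DINO"):
                p = make_item_params(
                    qrow, model, intercept, e_param=single_attribute_increment
                )
            else:
                p = make_item_params(
                    qrow, model, intercept, mains=[single_attribute_increment]
                )
        elif model in ("DINA", "DINO"):
            p = make_item_params(qrow, model, intercept, e_param=e_param)
        elif model == "CRUM":
            p = make_item_params(qrow, model, intercept, mains=[main, main])
        elif model == "LCDM":
            p = make_item_params(
                qrow, model, intercept, mains=[main, main], interaction=interaction
            )
        else:
            raise ValueError(f"unknown submodel {model!r}")
        params.append(p)
    return params


def simulate_responses(
    profiles: np.ndarray,
    item_params: list[ItemParams],
    qmatrix: QMatrix,
    model_spec: np.ndarray,
    rng,
    condition: DesignCondition | None = None,
    seed: int | None = None,
) -> DatasetBundle:
    """Bernoulli responses for given profiles under the item response functions."""
    rng = np.random.default_rng(rng)
    all_profiles = enumerate_profiles(qmatrix.n_attributes)
    table = probability_table(item_params, qmatrix, model_spec, all_profiles)
    class_idx = profile_to_class(profiles)
    probs = table.T[class_idx]  # N x k
    responses = (rng.random(probs.shape) < probs).astype(np.int8)
    return DatasetBundle(
        responses=responses,
        true_profiles=np.asarray(profiles, dtype=np.int8),
        true_params=item_params,
        qmatrix=qmatrix,
        model_spec=model_spec,
        condition=condition,
        seed=seed,
    )


def simulate_condition(
    condition: DesignCondition,
    rng,
    rho: float = DEFAULT_RHO,
    seed: int | None = None,
    **generating_overrides,
) -> DatasetBundle:
    """Simulate one full replication of a design condition."""
    from .design import assign_item_models, build_qmatrix

    rng = np.random.default_rng(rng)
    q = build_qmatrix(condition.n_attributes, condition.n_items)
    spec = assign_item_models(q, condition.model)
    params = generating_parameters(q, spec, **generating_overrides)
    cfg = ProfileSimConfig(condition.n_attributes, condition.base_rate, rho)
    profiles = simulate_profiles(cfg, condition.n_respondents, rng)
    return simulate_responses(
        profiles, params, q, spec, rng, condition=condition, seed=seed
    )
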