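"""Item response functions for the log-linear family of diagnostic models.

Every submodel here is a constrained version of the saturated log-linear
cognitive diagnosis model (LCDM): the logit of a correct response is an
intercept plus increments earned by mastering the attributes the item
requires.

* LCDM  (two-attribute item): intercept + main effects + two-way interaction.
* C-RUM: main effects only (compensatory, no interaction).
* DINA:  intercept + a single ``e`` increment earned only when *all* required
  attributes are mastered (conjunctive).
* DINO:  intercept + ``e`` earned when *at least one* required attribute is
  mastered (disjunctive).

For items requiring a single attribute the four parameterizations coincide.
Each item is represented by a small design matrix over the 2^A latent
classes, so a parameter vector maps to class kernels by a dot product; this
is what both the simulator and the EM M-step operate on.  Parameters are
stored on the log-odds scale; guessing/slipping views are derived.

Only items requiring at most two attributes are supported, which covers the
built-in designs (no item requires three or more attributes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .design import QMatrix, enumerate_profiles

#: parameter families reported by the recovery metrics
PARAM_FAMILIES = ("intercept", "main", "e_param", "interaction")


@dataclass(frozen=True)
class ItemParams:
    """Log-linear parameters of one item, aligned with its design matrix columns."""

    model_type: str
    values: np.ndarray
    names: tuple[str, ...]
    families: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.names),) or len(self.names) != len(self.families):
            raise ValueError("values, names and families must align")
        object.__setattr__(self, "values", vals)

    @property
    def intercept(self) -> float:
        return float(self.values[0])

    @property
    def mains(self) -> np.ndarray:
        return self.values[[f == "main" for f in self.families]]

    @property
    def e_param(self) -> float | None:
        sel = [f == "e_param" for f in self.families]
        return float(self.values[sel][0]) if any(sel) else None

    @property
    def interaction(self) -> float | None:
        sel = [f == "interaction" for f in self.families]
        return float(self.values[sel][0]) if any(sel) else None


def item_term_structure(qrow: np.ndarray, model_type: str) -> tuple[tuple, tuple]:
    """(names, families) of the free parameters of an item under a submodel.

    Single-attribute items carry one increment whose family follows the
    submodel (``e_param`` for DINA/DINO, ``main`` otherwise); their design
    matrices are identical.
    """
    req = np.flatnonzero(np.asarray(qrow))
    if req.size == 0:
        raise ValueError("item requires no attribute")
    if req.size > 2:
        raise ValueError("items requiring more than two attributes are not supported")
    if req.size == 1:
        a = req[0] + 1
        if model_type in ("DINA", "DINO"):
            return ("intercept", "e"), ("intercept", "e_param")
        return ("intercept", f"main({a})"), ("intercept", "main")
    a1, a2 = req + 1
    if model_type == "LCDM":
        names = ("intercept", f"main({a1})", f"main({a2})", f"int({a1},{a2})")
        fams = ("intercept", "main", "main", "interaction")
    elif model_type == "CRUM":
        names = ("intercept", f"main({a1})", f"main({a2})")
        fams = ("intercept", "main", "main")
    elif model_type in ("DINA", "DINO"):
        names, fams = ("intercept", "e"), ("intercept", "e_param")
    else:
        raise ValueError(f"unknown submodel {model_type!r}")
    return names, fams


def item_design_matrix(
    qrow: np.ndarray, model_type: str, profiles: np.ndarray
) -> np.ndarray:
    """Class-by-parameter design matrix D so that kernel(class) = D @ values."""
    qrow = np.asarray(qrow)
    profiles = np.atleast_2d(np.asarray(profiles))
    req = np.flatnonzero(qrow)
    if req.size == 0 or req.size > 2:
        raise ValueError("items must require one or two attributes")
    ones = np.ones(profiles.shape[0])
    m = profiles[:, req].astype(float)
    if req.size == 1:
        return np.column_stack([ones, m[:, 0]])
    if model_type == "LCDM":
        return np.column_stack([ones, m[:, 0], m[:, 1], m[:, 0] * m[:, 1]])
    if model_type == "CRUM":
        return np.column_stack([ones, m[:, 0], m[:, 1]])
    if model_type == "DINA":
        return np.column_stack([ones, m[:, 0] * m[:, 1]])
    if model_type == "DINO":
        return np.column_stack([ones, 1.0 - (1.0 - m[:, 0]) * (1.0 - m[:, 1])])
    raise ValueError(f"unknown submodel {model_type!r}")


def make_item_params(
    qrow: np.ndarray,
    model_type: str,
    intercept: float,
    mains=None,
    e_param: float | None = None,
    interaction: float | None = None,
) -> ItemParams:
    """Assemble an ItemParams from named components, validating the submodel."""
    names, fams = item_term_structure(qrow, model_type)
    mains = np.atleast_1d(mains).astype(float) if mains is not None else np.array([])
    vals = [float(intercept)]
    main_iter = iter(mains)
    for fam in fams[1:]:
        if fam == "main":
            try:
                vals.append(next(main_iter))
            except StopIteration:
                raise ValueError(f"{model_type} item needs main effects") from None
        elif fam == "e_param":
            if e_param is None:
                raise ValueError(f"{model_type} item needs an e parameter")
            vals.append(float(e_param))
        elif fam == "interaction":
            if interaction is None:
                raise ValueError("saturated LCDM item needs an interaction term")
            vals.append(float(interaction))
    return ItemParams(model_type, np.array(vals), names, fams)


def kernel_value(params: ItemParams, qrow, profile) -> float:
    """Log-odds of a correct response for one profile."""
    d = item_design_matrix(qrow, params.model_type, profile)
    return float(np.squeeze(d @ params.values))


def response_probability(params: ItemParams, qrow, profile) -> float:
    return float(expit(kernel_value(params, qrow, profile)))


def probability_table(
    item_params: list[ItemParams],
    qmatrix: QMatrix,
    model_spec: np.ndarray,
    profiles: np.ndarray | None = None,
) -> np.ndarray:
    """Item-by-class matrix of correct-response probabilities P(X_ic=1|alpha_c)."""
    if profiles is None:
        profiles = enumerate_profiles(qmatrix.n_attributes)
    k = qmatrix.n_items
    if len(item_params) != k or len(model_spec) != k:
        raise ValueError("item_params / model_spec length must match the Q-matrix")
    table = np.empty((k, profiles.shape[0]))
    for i in range(k):
        if item_params[i].model_type != model_spec[i]:
            raise ValueError(f"item {i + 1}: parameter/model mismatch")
        d = item_design_matrix(qmatrix.entries[i], model_spec[i], profiles)
        table[i] = expit(d @ item_params[i].values)
    return table


def guessing_slipping(params: ItemParams, qrow) -> tuple[float, float]:
    """(g, 1 - s): correct-response probabilities of a non-master and a full master."""
    qrow = np.asarray(qrow)
    none = np.zeros_like(qrow)
    g = response_probability(params, qrow, none)
    one_minus_s = response_probability(params, qrow, qrow)
    return g, one_minus_s
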