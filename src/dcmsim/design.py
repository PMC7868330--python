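"""Study design: Q-matrices, item submodel assignment, profile enumeration, condition grid.

The built-in Q-matrices are the balanced designs used throughout the simulation
study: a three-attribute test whose 36 rows cycle through the six non-trivial
patterns on up to two attributes, and a five-attribute test cycling through the
five single-attribute indicators followed by the seven pairs involving
attributes 1 or 2.  Shorter tests (12, 24 items) are the leading rows of the
36-item design, so designs are nested by test length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

MODEL_NAMES = ("LCDM", "CRUM", "DINA", "DINO")
GENERATING_MODELS = MODEL_NAMES + ("LCDMREDUCED",)

#: submodel cycle assigned by item position on a mixed-model (LCDMREDUCED) test
ITEM_TYPE_CYCLE = ("LCDM", "DINA", "DINO", "CRUM")

_BLOCK_A3 = np.array(
    [
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 0],
        [1, 0, 1],
        [0, 1, 1],
    ],
    dtype=np.int8,
)

_BLOCK_A5 = np.array(
    [
        [1, 0, 0, 0, 0],
        [0, 1, 0, 0, 0],
        [0, 0, 1, 0, 0],
        [0, 0, 0, 1, 0],
        [0, 0, 0, 0, 1],
        [1, 1, 0, 0, 0],
        [1, 0, 1, 0, 0],
        [1, 0, 0, 1, 0],
        [1, 0, 0, 0, 1],
        [0, 1, 1, 0, 0],
        [0, 1, 0, 1, 0],
        [0, 1, 0, 0, 1],
    ],
    dtype=np.int8,
)

SUPPORTED_DESIGNS = tuple(itertools.product((3, 5), (12, 24, 36)))


@dataclass(frozen=True)
class QMatrix:
    """Item-by-attribute binary requirement matrix."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.entries, dtype=np.int8)
        if q.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional (items x attributes)")
        if not np.isin(q, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        if (q.sum(axis=1) < 1).any():
            raise ValueError("every item must require at least one attribute")
        if (q.sum(axis=0) < 1).any():
            raise ValueError("every attribute must be required by at least one item")
        object.__setattr__(self, "entries", q)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        """Read a user Q-matrix from CSV (rows = items, columns = attributes)."""
        df = pd.read_csv(path)
        return cls(df.to_numpy())

    def to_csv(self, path) -> None:
        cols = [f"att_{a + 1}" for a in range(self.n_attributes)]
        pd.DataFrame(self.entries, columns=cols).to_csv(path, index=False)


def build_qmatrix(n_attributes: int, n_items: int) -> QMatrix:
    """Return the built-in Q-matrix for one of the supported (A, k) designs.

    The 12- and 24-item designs are the first rows of the 36-item design.
    """
    if (n_attributes, n_items) not in SUPPORTED_DESIGNS:
        raise ValueError(
            f"unsupported design (A={n_attributes}, k={n_items}); "
            f"built-in designs are A in (3, 5) x k in (12, 24, 36). "
            "Use QMatrix directly (or QMatrix.from_csv) for other designs."
        )
    block = _BLOCK_A3 if n_attributes == 3 else _BLOCK_A5
    reps = int(np.ceil(n_items / block.shape[0]))
    return QMatrix(np.tile(block, (reps, 1))[:n_items])


def assign_item_models(qmatrix: QMatrix, generating_model: str) -> np.ndarray:
    """Per-item submodel labels for a generating model.

    Homogeneous tests repeat the model name; the mixed LCDMREDUCED test cycles
    LCDM -> DINA -> DINO -> C-RUM by item position.
    """
    if generating_model not in GENERATING_MODELS:
        raise ValueError(
            f"unknown model {generating_model!r}; expected one of {GENERATING_MODELS}"
        )
    k = qmatrix.n_items
    if generating_model == "LCDMREDUCED":
        cycle = itertools.cycle(ITEM_TYPE_CYCLE)
        return np.array([next(cycle) for _ in range(k)])
    return np.array([generating_model] * k)


def enumerate_profiles(n_attributes: int) -> np.ndarray:
    """All 2^A attribute profiles, last attribute varying fastest.

    Class c (0-based) is the A-bit binary representation of c with attribute 1
    as the most significant bit, i.e. [0,..,0], [0,..,1], ..., [1,..,1].
    """
    if n_attributes < 1:
        raise ValueError("need at least one attribute")
    return np.array(
        list(itertools.product((0, 1), repeat=n_attributes)), dtype=np.int8
    )


def profile_to_class(profiles: np.ndarray) -> np.ndarray:
    """Map binary profiles (…, A) to class indices in enumerate_profiles order."""
    profiles = np.asarray(profiles)
    a = profiles.shape[-1]
    weights = 2 ** np.arange(a - 1, -1, -1)
    return profiles @ weights


@dataclass(frozen=True)
class DesignCondition:
    """One cell of the crossed simulation design."""

    n_respondents: int
    n_items: int
    n_attributes: int
    base_rate: float
    model: str
    n_replications: int = 1

    def __post_init__(self) -> None:
        if self.model not in GENERATING_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.base_rate < 1:
            raise ValueError("base rate must be in (0, 1)")
        if self.n_replications < 1:
            raise ValueError("need at least one replication")

    @property
    def label(self) -> str:
        return (
            f"{self.n_attributes}ATT{self.n_items}ITEM"
            f"{int(round(self.base_rate * 100))}BR_N{self.n_respondents}_{self.model}"
        )


#: factor levels of the full crossed study design (384 conditions)
STUDY_FACTOR_LEVELS = {
    "sample_sizes": (50, 100, 200, 300, 400, 500, 1000, 5000),
    "test_lengths": (12, 24, 36),
    "attribute_counts": (3, 5),
    "base_rates": (0.25, 0.50),
    "models": ("CRUM", "DINA", "DINO", "LCDMREDUCED"),
}


def build_condition_grid(
    sample_sizes=None,
    test_lengths=None,
    attribute_counts=None,
    base_rates=None,
    models=None,
    n_replications: int = 1,
) -> list[DesignCondition]:
    """Full cross of the five design factors (defaults: the 384-cell study grid)."""
    levels = {
        "sample_sizes": sample_sizes,
        "test_lengths": test_lengths,
        "attribute_counts": attribute_counts,
        "base_rates": base_rates,
        "models": models,
    }
    for key, val in levels.items():
        if val is None:
            levels[key] = STUDY_FACTOR_LEVELS[key]
        elif len(val) == 0:
            raise ValueError(f"factor {key} has no levels")
    return [
        DesignCondition(n, k, a, br, m, n_replications)
        for n in levels["sample_sizes"]
        for k in levels["test_lengths"]
        for a in levels["attribute_counts"]
        for br in levels["base_rates"]
        for m in levels["models"]
    ]
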