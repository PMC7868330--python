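"""Plain-CSV readers/writers for response matrices, profiles and parameter tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ItemParams
from .simulate import DatasetBundle


def write_responses(responses: np.ndarray, path) -> None:
    k = responses.shape[1]
    cols = [f"item_{i + 1}" for i in range(k)]
    pd.DataFrame(responses, columns=cols).to_csv(path, index=False)


def read_responses(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.int8)


def write_profiles(profiles: np.ndarray, path) -> None:
    a = profiles.shape[1]
    cols = [f"att_{i + 1}" for i in range(a)]
    pd.DataFrame(profiles, columns=cols).to_csv(path, index=False)


def read_profiles(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.int8)


def params_to_frame(item_params: list[ItemParams]) -> pd.DataFrame:
    """Long-format parameter table: item, model, term, family, value."""
    rows = []
    for i, p in enumerate(item_params):
        for name, fam, val in zip(p.names, p.families, p.values):
            rows.append(
                {"item": i + 1, "model": p.model_type, "term": name,
                 "family": fam, "value": float(val)}
            )
    return pd.DataFrame(rows)


def frame_to_params(df: pd.DataFrame) -> list[ItemParams]:
    params = []
    for item, g in df.groupby("item", sort=True):
        params.append(
            ItemParams(
                g["model"].iloc[0],
                g["value"].to_numpy(dtype=float),
                tuple(g["term"]),
                tuple(g["family"]),
            )
        )
    return params


def write_bundle(bundle: DatasetBundle, out_dir) -> None:
    """Write one simulated replication: responses, profiles, params, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_responses(bundle.responses, out / "responses.csv")
    write_profiles(bundle.true_profiles, out / "profiles.csv")
    params_to_frame(bundle.true_params).to_csv(out / "params.csv", index=False)
    bundle.qmatrix.to_csv(out / "qmatrix.csv")
    manifest = {
        "seed": bundle.seed,
        "n_respondents": int(bundle.responses.shape[0]),
        "n_items": int(bundle.responses.shape[1]),
        "n_attributes": int(bundle.true_profiles.shape[1]),
        "model_spec": list(map(str, bundle.model_spec)),
    }
    if bundle.condition is not None:
        c = bundle.condition
        manifest["condition"] = {
            "n_respondents": c.n_respondents, "n_items": c.n_items,
            "n_attributes": c.n_attributes, "base_rate": c.base_rate,
            "model": c.model,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
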