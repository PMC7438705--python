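"""File-format helpers: hierarchy/study configs (YAML/JSON), response CSVs,
and fitted-model serialization.

Response data travels either long (``examinee,time,item,response``) or wide
(one row per examinee, columns ``t{t}_i{i}``); attributes and items are
1-based in every file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import (
    FitResult,
    LongitudinalModel,
    ModelSpec,
    ResponseData,
)
from .hierarchy import AttributeHierarchy
from .measurement import ItemParams
from .qmatrix import QMatrix
from .structural import InitialPrevalence, TransitionSet


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def hierarchy_from_file(path) -> AttributeHierarchy:
    cfg = load_config(path)
    return AttributeHierarchy.from_config(cfg.get("hierarchy", cfg))


def responses_to_long(data: ResponseData) -> pd.DataFrame:
    n, t_len, i_len = data.y.shape
    nn, tt, ii = np.meshgrid(
        np.arange(n), np.arange(t_len), np.arange(i_len), indexing="ij"
    )
    return pd.DataFrame(
        {
            "examinee": nn.ravel() + 1,
            "time": tt.ravel() + 1,
            "item": ii.ravel() + 1,
            "response": data.y.ravel(),
        }
    )


def responses_from_long(df: pd.DataFrame) -> ResponseData:
    n = int(df["examinee"].max())
    t_len = int(df["time"].max())
    i_len = int(df["item"].max())
    y = np.full((n, t_len, i_len), -1, dtype=np.int8)
    y[df["examinee"] - 1, df["time"] - 1, df["item"] - 1] = df["response"]
    if (y < 0).any():
        raise ValueError("long response table does not cover every cell")
    return ResponseData(y)


def responses_to_wide(data: ResponseData) -> pd.DataFrame:
    n, t_len, i_len = data.y.shape
    cols = {
        f"t{t+1}_i{i+1}": data.y[:, t, i]
        for t in range(t_len)
        for i in range(i_len)
    }
    out = pd.DataFrame(cols)
    out.insert(0, "examinee", np.arange(1, n + 1))
    return out


def responses_from_wide(df: pd.DataFrame) -> ResponseData:
    rcols = [c for c in df.columns if c.startswith("t") and "_i" in c]
    t_len = max(int(c.split("_")[0][1:]) for c in rcols)
    i_len = max(int(c.split("_i")[1]) for c in rcols)
    n = len(df)
    y = np.zeros((n, t_len, i_len), dtype=np.int8)
    for c in rcols:
        t = int(c.split("_")[0][1:]) - 1
        i = int(c.split("_i")[1]) - 1
        y[:, t, i] = df[c]
    return ResponseData(y)


def read_responses(path) -> ResponseData:
    df = pd.read_csv(path)
    if {"examinee", "time", "item", "response"} <= set(df.columns):
        return responses_from_long(df)
    return responses_from_wide(df)


def model_to_json_dict(fit: FitResult) -> dict:
    m = fit.model
    spec = m.spec
    return {
        "variant": spec.variant,
        "hierarchy": {
            "attributes": spec.hierarchy.n_attributes,
            "edges": sorted(list(e) for e in spec.hierarchy.edges),
            "kind": spec.hierarchy.kind_label,
        },
        "qmatrix": m.spec.qmatrix.entries.tolist(),
        "n_times": spec.n_times,
        "stationary": spec.stationary,
        "forbid_regression": spec.forbid_regression,
        "monotone": spec.monotone,
        "item_params": [p.to_json_dict() for p in m.item_params],
        "delta": m.initial.delta.tolist(),
        "tau": [t.tolist() for t in m.transitions.matrices],
        "tau_mask": None
        if m.transitions.mask is None
        else m.transitions.mask.astype(int).tolist(),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_free_parameters": fit.n_free_parameters,
        "aic": fit.aic,
        "bic": fit.bic,
        "seed": fit.seed,
        "n_starts": fit.n_starts,
    }


def model_from_json_dict(d: dict) -> LongitudinalModel:
    hierarchy = AttributeHierarchy(
        d["hierarchy"]["attributes"],
        [tuple(e) for e in d["hierarchy"]["edges"]],
        d["hierarchy"].get("kind", "custom"),
    )
    spec = ModelSpec(
        hierarchy=hierarchy,
        qmatrix=QMatrix(np.asarray(d["qmatrix"])),
        variant=d["variant"],
        n_times=d["n_times"],
        forbid_regression=d.get("forbid_regression", False),
        stationary=d.get("stationary", False),
        monotone=d.get("monotone", True),
    )
    mask = d.get("tau_mask")
    return LongitudinalModel(
        spec,
        [ItemParams.from_json_dict(p) for p in d["item_params"]],
        InitialPrevalence(np.asarray(d["delta"])),
        TransitionSet(
            [np.asarray(t) for t in d["tau"]],
            stationary=spec.stationary,
            mask=None if mask is None else np.asarray(mask, dtype=bool),
        ),
    )


def save_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(model_to_json_dict(fit), indent=1))


def load_model(path) -> LongitudinalModel:
    return model_from_json_dict(json.loads(Path(path).read_text()))
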