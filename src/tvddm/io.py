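"""Reading behavioral tables, serializing posterior draws, and run
configuration.

RTs are stored in seconds everywhere; CSV input in milliseconds is
detected heuristically (median rt > 100 cannot be seconds for human
two-choice decisions) and converted with a warning unless the unit is
forced.  Posterior draws round-trip through netCDF (a self-describing
array container) with the parameter names, burn-in and run metadata stored
as attributes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .sampler import PosteriorDraws

__all__ = [
    "read_behavioral_csv",
    "response_codes",
    "save_draws",
    "load_draws",
    "config_hash",
]

_REQUIRED = ("participant", "condition", "stimulus", "response", "rt")


def read_behavioral_csv(path, rt_unit: str = "auto",
                        correct_mapping: dict | None = None) -> pd.DataFrame:
    """Read and validate a behavioral trial table.

    Required columns: participant, condition, stimulus, response, rt (plus
    correct, unless it can be derived from ``correct_mapping``, a
    stimulus -> correct-response dict).  ``rt_unit`` is "s", "ms" or
    "auto" (heuristic: median rt > 100 means milliseconds).  Schema
    violations are reported with the offending row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad = df.index[rt.isna()].tolist()
    if bad:
        raise ValueError(f"non-numeric rt in row(s) {bad[:20]}")
    df = df.assign(rt=rt.astype(float))

    if rt_unit == "auto" and df["rt"].median() > 100:
        warnings.warn(
            "rt column looks like milliseconds (median > 100); converting to "
            "seconds — pass rt_unit='s' or 'ms' to silence this",
            stacklevel=2,
        )
        rt_unit = "ms"
    if rt_unit == "ms":
        df = df.assign(rt=df["rt"] / 1000.0)
    elif rt_unit not in ("s", "auto"):
        raise ValueError(f"unknown rt_unit {rt_unit!r}")

    neg = df.index[df["rt"] <= 0].tolist()
    if neg:
        raise ValueError(f"non-positive rt in row(s) {neg[:20]}")

    if "correct" not in df.columns:
        if correct_mapping is None:
            raise ValueError(
                "missing 'correct' column and no stimulus -> response mapping supplied"
            )
        expected = df["stimulus"].map(correct_mapping)
        unknown = df.index[expected.isna()].tolist()
        if unknown:
            raise ValueError(f"stimulus without mapping in row(s) {unknown[:20]}")
        df = df.assign(correct=(df["response"] == expected))
    df = df.assign(correct=df["correct"].astype(bool))

    known = set(df["stimulus"].unique())
    bad_resp = df.index[~df["response"].isin(known)].tolist()
    if bad_resp:
        raise ValueError(f"unknown response code in row(s) {bad_resp[:20]}")
    return df


def response_codes(table: pd.DataFrame) -> np.ndarray:
    """Boundary coding of responses: correct -> 1 (upper), error -> 0."""
    return table["correct"].to_numpy().astype(int)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Serialize posterior draws to netCDF (scipy backend, netCDF3)."""
    ds = xr.Dataset(
        {
            "samples": (("chain", "draw", "param"), draws.samples),
        },
        attrs={
            "param_names": json.dumps(list(draws.param_names)),
            "burn_in": draws.burn_in,
            "meta": json.dumps(draws.meta, default=float),
        },
    )
    if draws.log_likelihood is not None:
        ds["log_likelihood"] = (("chain", "draw"), draws.log_likelihood)
    ds.to_netcdf(path, engine="scipy")


def load_draws(path) -> PosteriorDraws:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    ll = ds["log_likelihood"].values if "log_likelihood" in ds else None
    return PosteriorDraws(
        samples=ds["samples"].values,
        param_names=tuple(json.loads(ds.attrs["param_names"])),
        burn_in=int(ds.attrs["burn_in"]),
        log_likelihood=ll,
        meta=json.loads(ds.attrs["meta"]),
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def config_hash(config) -> str:
    """Stable hash of a (dataclass) configuration for provenance stamps."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
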