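"""CSV and config-file interfaces.

Model parameters serialize to a flat CSV, one row per species, with
matrix-valued fields in wide columns; round-trips are lossless to full
float precision (17 significant digits). Effect matrices are species x
stressor CSVs; interaction tensors use long-format (species, l1, l2,
value) triples. Experiment configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .communities import BatchResult, CommunitySpec
from .models import (
    LVParams,
    MacArthurParams,
    ModelParams,
    ResourceLogistic,
    StompParams,
)

__all__ = [
    "params_to_csv", "params_from_csv",
    "effects_to_csv", "effects_from_csv",
    "interactions_to_csv", "interactions_from_csv",
    "write_batch", "load_config",
]

_FLOAT = "%.17g"


def _wide(prefix: str, values: np.ndarray) -> dict:
    return {f"{prefix}{k}": values[..., k] for k in range(values.shape[-1])}


def params_to_csv(params: ModelParams, path) -> None:
    path = Path(path)
    if isinstance(params, LVParams):
        df = pd.DataFrame({"model": "lotka_volterra", "mu": params.mu,
                           **_wide("alpha_", params.alpha)})
    elif isinstance(params, MacArthurParams):
        g = params.resource_growth
        df = pd.DataFrame({"model": "macarthur", "w": params.w, "m": params.m,
                           **_wide("c_", params.c)})
        # resource rows ride along in dedicated columns (r may differ from n)
        for k in range(params.r):
            df[f"resource_rate_{k}"] = g.rate[k]
            df[f"resource_capacity_{k}"] = g.capacity[k]
    elif isinstance(params, StompParams):
        df = pd.DataFrame({"model": "stomp", "phi": params.phi,
                           "loss": params.loss, "depth": params.depth,
                           "n_depth": params.n_depth,
                           **_wide("absorption_", params.absorption_spectra)})
        for k, wl in enumerate(params.wavelengths):
            df[f"wavelength_{k}"] = wl
            df[f"incident_{k}"] = params.incident_spectrum[k]
            df[f"background_{k}"] = params.background_attenuation[k]
    else:
        raise TypeError(f"unknown model parameters: {type(params)!r}")
    df.to_csv(path, index=False, float_format=_FLOAT)


def _cols(df: pd.DataFrame, prefix: str) -> np.ndarray:
    names = sorted((c for c in df.columns if c.startswith(prefix)),
                   key=lambda c: int(c[len(prefix):]))
    return df[names].to_numpy(dtype=float)


def params_from_csv(path) -> ModelParams:
    df = pd.read_csv(path, float_precision="round_trip")
    model = df["model"].iloc[0]
    if model == "lotka_volterra":
        return LVParams(mu=df["mu"].to_numpy(float), alpha=_cols(df, "alpha_"))
    if model == "macarthur":
        rate = _cols(df, "resource_rate_")[0]
        cap = _cols(df, "resource_capacity_")[0]
        return MacArthurParams(
            w=df["w"].to_numpy(float), c=_cols(df, "c_"),
            m=df["m"].to_numpy(float),
            resource_growth=ResourceLogistic(rate=rate, capacity=cap))
    if model == "stomp":
        return StompParams(
            phi=df["phi"].to_numpy(float), loss=df["loss"].to_numpy(float),
            depth=float(df["depth"].iloc[0]),
            wavelengths=_cols(df, "wavelength_")[0],
            absorption_spectra=_cols(df, "absorption_"),
            incident_spectrum=_cols(df, "incident_")[0],
            background_attenuation=_cols(df, "background_")[0],
            n_depth=int(df["n_depth"].iloc[0]))
    raise ValueError(f"unknown model tag {model!r} in {path}")


def effects_to_csv(E: np.ndarray, path) -> None:
    E = np.asarray(E, dtype=float)
    pd.DataFrame(E, columns=[f"stressor_{l}" for l in range(E.shape[1])]) \
        .to_csv(path, index_label="species", float_format=_FLOAT)


def effects_from_csv(path) -> np.ndarray:
    return pd.read_csv(path, index_col="species",
                       float_precision="round_trip").to_numpy(dtype=float)


def interactions_to_csv(eta: np.ndarray, path) -> None:
    eta = np.asarray(eta, dtype=float)
    n, s, _ = eta.shape
    i, l1, l2 = np.meshgrid(range(n), range(s), range(s), indexing="ij")
    df = pd.DataFrame({"species": i.ravel(), "l1": l1.ravel(),
                       "l2": l2.ravel(), "eta": eta.ravel()})
    df = df[df.l1 < df.l2]  # symmetric with zero diagonal: store upper triangle
    df.to_csv(path, index=False, float_format=_FLOAT)


def interactions_from_csv(path, n: int, s: int) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    eta = np.zeros((n, s, s))
    ii = df["species"].to_numpy(int)
    l1 = df["l1"].to_numpy(int)
    l2 = df["l2"].to_numpy(int)
    eta[ii, l1, l2] = df["eta"].to_numpy(float)
    eta[ii, l2, l1] = df["eta"].to_numpy(float)
    return eta


def write_batch(batch: BatchResult, spec: CommunitySpec, out_dir) -> Path:
    """One directory per batch: manifest.json plus per-community CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "model": spec.model,
        "n_species": spec.n_species,
        "n_communities": len(batch.communities),
        "attempts": batch.attempts,
        "acceptance_rate": batch.acceptance_rate,
        "seeds": batch.seeds,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, params in enumerate(batch.communities):
        params_to_csv(params, out / f"community_{i:04d}.csv")
    return out


def load_config(path) -> dict:
    """YAML experiment configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
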