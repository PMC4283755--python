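"""YAML/JSON configuration files mirroring the model and design fields."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .trial_model import EndpointModel, TrialDesign

__all__ = ["load_config", "parse_config"]

_MODEL_KEYS = {"mu_b", "mu_B", "sigma0", "sigma", "rho_w"}
_DESIGN_KEYS = {"k", "N1", "n1", "n2", "alpha", "w1", "w2"}


def parse_config(raw: dict, overrides: dict | None = None) -> tuple[EndpointModel, TrialDesign]:
    """Build the endpoint model and design from a flat key/value mapping."""
    data = dict(raw)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    unknown = set(data) - _MODEL_KEYS - _DESIGN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"mu_b", "mu_B", "sigma0", "sigma", "rho_w", "N1", "n1", "n2"} - set(data)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    model = EndpointModel(
        mu_b=np.asarray(data["mu_b"], dtype=float),
        mu_B=np.asarray(data["mu_B"], dtype=float),
        sigma0=float(data["sigma0"]),
        sigma=float(data["sigma"]),
        rho_w=float(data["rho_w"]),
    )
    k = int(data.get("k", model.k))
    if k != model.k:
        raise ValueError("k inconsistent with length of mu_b")
    design_kwargs = {
        "k": k,
        "N1": int(data["N1"]),
        "n1": int(data["n1"]),
        "n2": int(data["n2"]),
    }
    if "alpha" in data:
        design_kwargs["alpha"] = float(data["alpha"])
    if "w1" in data or "w2" in data:
        design_kwargs["w1"] = float(data["w1"])
        design_kwargs["w2"] = float(data["w2"])
    return model, TrialDesign(**design_kwargs)


def load_config(path: str | Path, overrides: dict | None = None) -> tuple[EndpointModel, TrialDesign]:
    """Load a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of field names to values")
    return parse_config(raw, overrides)
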