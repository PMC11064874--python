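"""CSV signal I/O and YAML configuration loading."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .bemd import SiftConfig
from .core import Signal
from .errors import InvalidInputError, InvalidParameterError
from .nlm import NLMParams
from .pipeline import PipelineConfig

__all__ = ["read_signal_csv", "write_signal_csv", "load_pipeline_config", "write_metrics_json"]


def read_signal_csv(path: str | Path, fs: float) -> Signal:
    """Read a one-sample-per-line CSV/text vector (optional header line)."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if not lines:
        raise InvalidInputError(f"{path} is empty")
    start = 0
    try:
        float(lines[0].split(",")[0])
    except ValueError:
        start = 1  # header
    try:
        samples = np.array(
            [float(line.split(",")[0]) for line in lines[start:] if line.strip()]
        )
    except ValueError as exc:
        raise InvalidInputError(f"could not parse {path}: {exc}") from exc
    return Signal(samples=samples, fs=fs)


def write_signal_csv(path: str | Path, signal: Signal) -> None:
    np.savetxt(path, signal.samples, fmt="%.12g")


def _nlm_from_dict(d: dict) -> NLMParams:
    return NLMParams(
        lam=d.get("lam"),
        patch_half_width=int(d.get("patch_half_width", 1)),
        neighborhood_half_width=int(d.get("neighborhood_half_width", 5)),
        sigma=float(d.get("sigma", 0.0)),
    )


def load_pipeline_config(path: str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (missing keys keep defaults)."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"{path} does not contain a mapping")
    kwargs: dict = {}
    if "sift" in raw:
        kwargs["sift"] = SiftConfig(**raw["sift"])
    if "nlm" in raw:
        kwargs["nlm"] = _nlm_from_dict(raw["nlm"])
    if "per_bimf" in raw and raw["per_bimf"]:
        kwargs["per_bimf"] = {int(k): _nlm_from_dict(v) for k, v in raw["per_bimf"].items()}
    for key in (
        "median_window",
        "apply_preprocess",
        "apply_nlm",
        "clip_negative_magnitude",
        "sigma_mode",
        "ist_method",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise InvalidParameterError(f"bad config {path}: {exc}") from exc


def write_metrics_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
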