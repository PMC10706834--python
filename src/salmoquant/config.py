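"""Run configuration: YAML config file, K-source resolution, run logging."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import PUBLISHED_K
from .errors import FormatError, InputError
from .quantification import DEFAULT_LOD_PCT
from .simulate import SimConfig
from .validation import DEFAULT_MAX_ABS_DEVIATION_PCT

#: Wells with fewer droplets than this are conventionally discarded.
DEFAULT_MIN_DROPLETS = 10000


@dataclass(frozen=True)
class RunConfig:
    k_value: float | None = PUBLISHED_K
    k_file: str | None = None
    lod_pct: float = DEFAULT_LOD_PCT
    loq_max_abs_deviation_pct: float = DEFAULT_MAX_ABS_DEVIATION_PCT
    min_droplets: int = DEFAULT_MIN_DROPLETS
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "."

    def __post_init__(self) -> None:
        if (self.k_value is None) == (self.k_file is None):
            raise InputError(
                "exactly one K source must be set (fixed k_value or k_file)"
            )

    def resolve_k(self) -> float:
        """Fixed K, or the k_mean column of a calibration report file."""
        if self.k_value is not None:
            return self.k_value
        df = pd.read_csv(self.k_file)
        if "k_mean" not in df.columns:
            raise FormatError(f"{self.k_file}: calibration file lacks 'k_mean'")
        return float(df["k_mean"].iloc[0])


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected to catch typos."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config must be a mapping")
    sim_doc = doc.pop("sim", {})
    known = {
        "k_value", "k_file", "lod_pct", "loq_max_abs_deviation_pct",
        "min_droplets", "seed", "outdir",
    }
    unknown = set(doc) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    if "k_file" in doc and "k_value" not in doc:
        doc["k_value"] = None
    try:
        sim = SimConfig(seed=doc.get("seed", 0), **sim_doc)
    except TypeError as exc:
        raise FormatError(f"{path}: bad sim block ({exc})") from exc
    return RunConfig(sim=sim, **doc)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {**{k: getattr(cfg, k) for k in (
            "k_value", "k_file", "lod_pct", "loq_max_abs_deviation_pct",
            "min_droplets", "seed", "outdir")},
         "sim": cfg.sim.__dict__},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_run_log(cfg: RunConfig, outdir) -> Path:
    """Record config hash, seed and package version next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = outdir / "run_log.json"
    log.write_text(
        json.dumps(
            {
                "config_hash": config_hash(cfg),
                "seed": cfg.seed,
                "version": __version__,
            },
            indent=2,
        )
        + "\n"
    )
    return log
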