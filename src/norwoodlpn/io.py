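"""Configuration, file I/O and provenance for the pipeline driver."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .meta import PopulationTargets, load_study_table, write_study_csv

logger = logging.getLogger("norwoodlpn")

__all__ = [
    "PipelineConfig",
    "read_study_csv",
    "write_study_csv",
    "write_targets",
    "read_targets",
    "write_report",
    "config_hash",
    "write_manifest",
]


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serialisable to YAML."""

    stage: str = "post_s1"
    study_table: str | None = None        # None -> packaged fixture
    weighting: str = "inverse_sd2"
    period_s: float | None = None
    dt_s: float | None = None
    max_cycles: int = 10
    periodicity_tol: float = 0.01
    inner_tol: float = 0.02
    co_tol: float = 0.02
    blood_rho: float = 1.06
    blood_mu: float = 0.04
    shunt_K: float = 2.0
    pinch_fraction: float = 0.10
    solve_shunt_pinch: bool | None = None
    seed: int = 0
    out_dir: str = "norwood_out"

    def validate(self) -> None:
        if self.stage not in ("post_s1", "pre_s2"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.study_table is not None and not Path(self.study_table).exists():
            raise FileNotFoundError(self.study_table)
        for name in ("periodicity_tol", "inner_tol", "co_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_study_csv(path):
    """Validated study records from CSV (see :mod:`norwoodlpn.meta`)."""
    return load_study_table(path)





def write_targets(targets: PopulationTargets, path) -> None:
    path = Path(path)
    data = targets.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def read_targets(path) -> dict:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(path.read_text())
    return json.loads(path.read_text())


def write_report(report, path) -> None:
    report.to_json(path)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(config: PipelineConfig, out_dir, extra: dict | None = None) -> Path:
    import numpy
    import scipy

    from . import __version__

    manifest = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "norwoodlpn": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    manifest.update(extra or {})
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
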