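"""Dataset, result and configuration readers/writers.

Datasets travel as comma-separated UTF-8 text in long format (one row per
individual; empty fields are missing values) with a parallel latent
sidecar CSV and a small JSON manifest naming the columns and design.  Fit
and effect summaries are emitted as JSON; study configurations are YAML.
Every CLI run writes exactly one run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datagen import DESIGNS, MultilevelDataset, PartiallyNestedDataset
from .simstudy import StudyConfig

__all__ = [
    "RunManifest",
    "write_dataset",
    "read_dataset",
    "write_json",
    "load_study_config",
    "write_tables",
]


@dataclass
class RunManifest:
    """Provenance record of one command-line run."""

    command: str
    config_hash: str
    master_seed: int | None
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        payload = {
            "command": self.command,
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "outputs": self.outputs,
            "version": self.version,
            "timestamp": self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def config_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def write_dataset(dataset, stem: Path | str) -> list[Path]:
    """Write data CSV, latent sidecar CSV and a JSON column manifest.

    ``stem`` is a path prefix: ``<stem>.csv``, ``<stem>_latents.csv``,
    ``<stem>_manifest.json``.  Values are written at full double precision.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    data_path = stem.with_suffix(".csv")
    dataset.data.to_csv(data_path, index=False)
    paths.append(data_path)
    if dataset.sidecar is not None:
        side_path = stem.parent / f"{stem.name}_latents.csv"
        dataset.sidecar.to_csv(side_path, index=False)
        paths.append(side_path)
    manifest = {
        "kind": ("partially_nested"
                 if isinstance(dataset, PartiallyNestedDataset) else "mlsem"),
        "design": getattr(dataset, "design", "pn"),
        "columns": list(dataset.data.columns),
        "sidecar_columns": (list(dataset.sidecar.columns)
                            if dataset.sidecar is not None else []),
        "version": __version__,
    }
    man_path = stem.parent / f"{stem.name}_manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    paths.append(man_path)
    return paths


def read_dataset(stem: Path | str):
    """Read a dataset written by :func:`write_dataset`."""
    stem = Path(stem)
    if stem.suffix == ".csv":
        stem = stem.with_suffix("")
    man_path = stem.parent / f"{stem.name}_manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"missing manifest {man_path}")
    manifest = json.loads(man_path.read_text())
    data = pd.read_csv(stem.with_suffix(".csv"))
    side_path = stem.parent / f"{stem.name}_latents.csv"
    sidecar = pd.read_csv(side_path) if side_path.exists() else None
    if manifest["kind"] == "partially_nested":
        return PartiallyNestedDataset(data=data, sidecar=sidecar)
    return MultilevelDataset(data=data, design=manifest["design"],
                             sidecar=sidecar)


def write_json(obj: dict, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=float))
    return path


def load_study_config(path: Path | str) -> StudyConfig:
    """Load a YAML study configuration.

    Recognised keys: ``study``, ``designs``, ``estimators``, ``grid``
    (list of [n2, n1] pairs), ``replications``, ``master_seed``.
    Unknown keys raise with the offending field path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("study config must be a mapping")
    known = {"study", "designs", "estimators", "grid", "replications",
             "master_seed"}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown study config field: {key}")
    kwargs = {}
    if "study" in raw:
        if raw["study"] not in ("fully_nested", "partially_nested"):
            raise ValueError("study: must be fully_nested or partially_nested")
        kwargs["study"] = raw["study"]
    if "designs" in raw:
        bad = set(raw["designs"]) - set(DESIGNS)
        if bad:
            raise ValueError(f"designs: unknown entries {sorted(bad)}")
        kwargs["designs"] = tuple(raw["designs"])
    if "estimators" in raw:
        bad = set(raw["estimators"]) - {"fs", "croon"}
        if bad:
            raise ValueError(f"estimators: unknown entries {sorted(bad)}")
        kwargs["estimators"] = tuple(raw["estimators"])
    if "grid" in raw:
        try:
            kwargs["grid"] = tuple((int(a), int(b)) for a, b in raw["grid"])
        except (TypeError, ValueError) as exc:
            raise ValueError("grid: must be a list of [n2, n1] pairs") from exc
    if "replications" in raw:
        kwargs["replications"] = int(raw["replications"])
    if "master_seed" in raw:
        kwargs["master_seed"] = int(raw["master_seed"])
    return StudyConfig(**kwargs)


def write_tables(tables: dict[str, pd.DataFrame], out_dir: Path | str,
                 decimals: int = 2) -> list[Path]:
    """Write study tables as CSV (full precision) plus rounded renderings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        paths.append(p)
        rounded = out_dir / f"{name}_rounded.csv"
        table.round(decimals).to_csv(rounded, index=False)
        paths.append(rounded)
    return paths
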