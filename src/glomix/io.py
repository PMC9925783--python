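"""Readers, writers, configuration, and run manifests.

Response tables travel as long-format CSV/TSV with columns
``animal, odor, roi, value`` and an optional ``repeat`` column for
trial-resolved data.  Odor role labels come from a sidecar YAML/JSON
mapping (odor -> role); when absent the package's default 20-odor panel
roles are assumed.  Image data are multi-page TIFF; ROI ground truth is
a label-image TIFF.  Every CLI run emits a JSON manifest with the
config hash, seeds, and input/output paths.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .noise import NoiseModel
from .synthetic import DEFAULT_ROLES, GlomerularAtlas, TrialSet


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"animal", "odor", "roi", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric value in row {bad[0]} "
                         f"(column 'value')")
    return df


def read_response_table(path, roles: dict | None = None,
                        noise: NoiseModel | None = None):
    """Load a long-format response table.

    Returns a :class:`GlomerularAtlas` (no ``repeat`` column) or a
    :class:`TrialSet` (with one).  Duplicate keys are an error.
    """
    df = _read_table(path)
    roles = dict(DEFAULT_ROLES) if roles is None else roles
    animals = df["animal"].unique()
    if len(animals) != 1:
        raise ValueError("expected exactly one animal per table")
    odors = tuple(pd.unique(df["odor"]))
    rois = np.sort(pd.unique(df["roi"]))
    has_repeat = "repeat" in df.columns
    keys = ["odor", "roi"] + (["repeat"] if has_repeat else [])
    if df.duplicated(keys).any():
        raise ValueError("duplicate (odor, roi[, repeat]) keys")
    if not has_repeat:
        mat = (df.pivot(index="odor", columns="roi", values="value")
               .reindex(index=odors, columns=rois).to_numpy())
        return GlomerularAtlas(mean_z=mat, odors=odors,
                               odor_roles={o: roles.get(o, "novel") for o in odors},
                               animal_id=str(animals[0]))
    reps = np.sort(pd.unique(df["repeat"]))
    cube = np.empty((len(odors), len(rois), len(reps)))
    for k, r in enumerate(reps):
        sub = df[df["repeat"] == r].pivot(index="odor", columns="roi",
                                          values="value")
        cube[:, :, k] = sub.reindex(index=odors, columns=rois).to_numpy()
    if not np.all(np.isfinite(cube)):
        raise ValueError("trial table is not a complete odor x roi x repeat grid")
    nm = noise or NoiseModel(cv=0.0, cv_uncorr=0.0, sigma_noise=0.0,
                             sigma_uncorr_noise=0.0, genotype="unknown")
    return TrialSet(trials=cube, odors=odors, noise=nm, seed=-1)


def write_response_table(obj, path) -> None:
    """Write an atlas or trial set as long-format CSV/TSV."""
    path = Path(path)
    df = obj.to_frame()
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def read_roles(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_movie(path, stack) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def write_labels(path, labels) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def load_config(path) -> dict:
    """YAML config (JSON accepted: valid JSON is valid YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    timestamp: str = ""

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str)
                .encode()).hexdigest()[:16],
            "inputs": [str(p) for p in self.inputs],
            "outputs": [str(p) for p in self.outputs],
            "timestamp": self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2))
        return path
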