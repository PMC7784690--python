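"""Readers/writers for the interchange formats and run configuration.

CSV dialect is fixed (comma, UTF-8, header row, times in seconds from
injection start) — no autodetection, to avoid silent unit errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulate import GpptDataset, SimConfig

__all__ = [
    "RunConfig",
    "read_gppt_dataset",
    "write_gppt_dataset",
    "write_results",
    "results_table",
]


@dataclass
class RunConfig:
    """Analysis options shared across pipeline stages."""

    temperature: Optional[float] = None  # K; None = dataset value
    match_window: float = 5.0  # s
    agg: str = "median"
    linear_intercept: bool = False
    overlapping_windows: bool = True
    include_linear_mounds: bool = False
    alpha: float = 0.05
    p_adjust: str = "holm"
    cooks_threshold: Optional[float] = None  # None = 4/n
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def _check_monotone(df: pd.DataFrame, path) -> None:
    t = df["time_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: time_s not strictly increasing at row {int(bad[0]) + 1} "
            f"(t={t[bad[0] + 1]} after t={t[bad[0]]})"
        )


def read_gppt_dataset(
    ch4_path,
    ar_path,
    background: Optional[tuple] = None,
    config=None,
    mound_id: Optional[str] = None,
) -> GpptDataset:
    """Read one mound's GPPT record from the CSV pair.

    ``ch4_path`` needs columns time_s, phase, ch4_ppmv; ``ar_path``
    needs time_s, phase, ar_fraction.  ``config`` may be a SimConfig, a
    path to the YAML sidecar, or None (sidecar ``<ar_path stem>.yaml``
    is tried).  The background defaults to the config values unless a
    (ch4_bg, ar_bg) tuple is given.
    """
    ch4 = pd.read_csv(ch4_path)
    ar = pd.read_csv(ar_path)
    _require_columns(ch4, ("time_s", "phase", "ch4_ppmv"), ch4_path)
    _require_columns(ar, ("time_s", "phase", "ar_fraction"), ar_path)
    _check_monotone(ch4, ch4_path)
    _check_monotone(ar, ar_path)
    known = {"background", "injection", "extraction"}
    for df, path in ((ch4, ch4_path), (ar, ar_path)):
        unknown = set(df["phase"]) - known
        if unknown:
            raise ValueError(f"{path}: unknown phase labels {sorted(unknown)}")
    n_ext = int((ar["phase"] == "extraction").sum())
    if n_ext < 3:
        raise ValueError(
            f"{ar_path}: only {n_ext} extraction-phase Ar samples; >= 3 required "
            "for the kinetic analysis"
        )
    if config is None:
        sidecar = Path(ar_path).with_suffix(".yaml")
        if sidecar.exists():
            config = sidecar
        else:
            raise ValueError("no config given and no YAML sidecar found")
    if not isinstance(config, SimConfig):
        with open(config) as fh:
            config = SimConfig.from_dict(yaml.safe_load(fh))
    if background is None:
        background = (config.ch4_bg, config.ar_bg)
    return GpptDataset(
        ch4_series=ch4,
        ar_samples=ar,
        background=background,
        config_echo=config,
        mound_id=mound_id or config.mound_id,
    )


def write_gppt_dataset(dataset: GpptDataset, out_dir, stem: Optional[str] = None) -> dict:
    """Write the CSV pair plus YAML sidecar; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or dataset.mound_id
    paths = {
        "ch4": out / f"{stem}_ch4.csv",
        "ar": out / f"{stem}_ar.csv",
        "config": out / f"{stem}_ar.yaml",
    }
    dataset.ch4_series.to_csv(paths["ch4"], index=False)
    dataset.ar_samples.to_csv(paths["ar"], index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataset.config_echo.to_dict(), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(objects: dict, out_dir, config=None, seed: Optional[int] = None) -> dict:
    """Serialise result objects and write a provenance manifest.

    ``objects`` maps a name to either a dict/list (written as JSON) or a
    DataFrame (written as TSV).  The manifest lists every file with its
    sha256, plus the config hash and seed; identical inputs and config
    reproduce byte-identical payloads.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict() if hasattr(config, "to_dict") else (config or {})
    config_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=_json_default).encode()
    ).hexdigest()
    entries = []
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False)
        else:
            path = out / f"{name}.json"
            payload = dict(obj) if isinstance(obj, dict) else obj
            if isinstance(payload, dict):
                payload = {"config_hash": config_hash, "seed": seed, **payload}
            path.write_text(
                json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
            )
        entries.append({"path": path.name, "sha256": _sha256(path)})
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "files": sorted(entries, key=lambda e: e["path"]),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def results_table(results) -> pd.DataFrame:
    """One-row-per-mound TSV summary of GpptKineticsResults objects."""
    rows = []
    for r in results:
        k = r.kinetics
        rows.append(
            {
                "mound_id": r.mound_id,
                "k": r.activity.k,
                "k_se": r.activity.k_se,
                "r2": r.activity.r2,
                "km": k.km,
                "vmax": k.vmax,
                "selected_model": k.selected_model,
                "aic_mm": k.aic_mm,
                "aic_lin": k.aic_lin,
                "n_segments": len(k.segments),
                "no_detectable_oxidation": r.activity.no_detectable_oxidation,
            }
        )
    return pd.DataFrame(rows)
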