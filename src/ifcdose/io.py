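"""Delimited-text tables, image files, and YAML configuration.

All tables are UTF-8 tab-delimited with fixed documented headers
(:data:`PER_SAMPLE_COLUMNS`, :data:`PER_CELL_COLUMNS`); images are plain
TIFF, one file per channel per event, linked to ground truth through a
tab-delimited manifest.  No proprietary cytometry formats are read or
written.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .imaging import GateConfig
from .knn import KnnConfig
from .synthdata import PER_CELL_COLUMNS, PER_SAMPLE_COLUMNS, CellImage, SimulationParams

__all__ = [
    "PER_CELL_COLUMNS",
    "PER_SAMPLE_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "write_estimates_table",
    "save_cell_images",
    "load_cell_images",
    "PipelineConfig",
    "load_config",
    "save_config",
]

_SCHEMAS = {"per_sample": PER_SAMPLE_COLUMNS, "per_cell": PER_CELL_COLUMNS}


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a per-cell or per-sample feature table as tab-delimited text."""
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path, kind: str = "auto") -> pd.DataFrame:
    """Read and validate a feature table.

    ``kind`` is ``per_sample``, ``per_cell`` or ``auto`` (inferred from the
    header).  Raises naming unknown/missing columns, and rejects malformed
    rows (negative dose, non-integral per-cell spot count) with their
    1-based data line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if kind == "auto":
        for name, schema in _SCHEMAS.items():
            if set(cols) == set(schema):
                kind = name
                break
        else:
            raise ValueError(f"header matches no known schema: {cols}")
    schema = _SCHEMAS[kind]
    missing = [c for c in schema if c not in cols]
    extra = [c for c in cols if c not in schema]
    if missing or extra:
        raise ValueError(f"bad {kind} header: missing columns {missing}, unknown columns {extra}")
    df = df.loc[:, schema]

    bad = df.index[df["dose_gy"] < 0].tolist()
    if bad:
        raise ValueError(f"negative dose_gy at data line(s) {[i + 1 for i in bad]}")
    if kind == "per_cell":
        frac = df["spot_count"].to_numpy(dtype=float)
        bad = df.index[frac != np.round(frac)].tolist()
        if bad:
            raise ValueError(f"non-integral per-cell spot_count at data line(s) {[i + 1 for i in bad]}")
    return df


def write_estimates_table(estimates, sample_ids, truths, path) -> None:
    """Write a dose-estimates table: sample_id, dose_hat, ci_low, ci_high,
    method, and the delivered dose when known."""
    rows = [
        {
            "sample_id": sid,
            "dose_hat": e.dose_hat,
            "ci_low": e.ci_low,
            "ci_high": min(e.ci_high, 1e6),
            "method": e.method,
            "dose_gy": t,
        }
        for sid, e, t in zip(sample_ids, estimates, truths)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def save_cell_images(images, out_dir, prefix: str = "event") -> Path:
    """Write one TIFF per channel per event plus a manifest linking events to
    labels and ground-truth focus annotations.  Returns the manifest path."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img in enumerate(images):
        bf = out_dir / f"{prefix}{i:05d}_bf.tif"
        fl = out_dir / f"{prefix}{i:05d}_fl.tif"
        tifffile.imwrite(bf, img.brightfield.astype(np.float32))
        tifffile.imwrite(fl, img.fluorescence.astype(np.float32))
        truth = (
            ";".join(f"{r:.3f},{c:.3f},{a:.6g}" for r, c, a in img.truth) if img.truth is not None else ""
        )
        rows.append({"event": i, "brightfield": bf.name, "fluorescence": fl.name, "label": img.label, "truth": truth})
    manifest = out_dir / f"{prefix}_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cell_images(manifest_path) -> list[CellImage]:
    """Reload events written by :func:`save_cell_images`."""
    import tifffile

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", keep_default_na=False)
    images = []
    for _, row in df.iterrows():
        truth_field = row["truth"]
        truth = None
        if truth_field != "":
            truth = [tuple(float(x) for x in item.split(",")) for item in truth_field.split(";")]
        elif row["label"] in ("apoptotic", "debris"):
            truth = []
        images.append(
            CellImage(
                brightfield=tifffile.imread(base / row["brightfield"]).astype(float),
                fluorescence=tifffile.imread(base / row["fluorescence"]).astype(float),
                truth=truth if truth is not None else [],
                label=row["label"],
            )
        )
    return images


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, mirrored field-for-field in YAML."""

    out_dir: str = "ifcdose_run"
    seed: int = 0
    sim: SimulationParams = dataclasses.field(default_factory=SimulationParams)
    gate: GateConfig = dataclasses.field(default_factory=GateConfig)
    knn: KnnConfig = dataclasses.field(default_factory=KnnConfig)
    n_donors: int = 10
    n_validation: int = 75
    n_validation_donors: int = 9
    triage_threshold_gy: float = 2.0
    bootstrap_ci: bool = False
    log_level: str = "INFO"
    calibration_table: Optional[str] = None  # pre-existing inputs skip simulation
    query_table: Optional[str] = None


def _as_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("sim", "gate", "knn"):
        d[key] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d[key].items()}
    return d


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimulationParams(**raw.pop("sim", {}))
    gate_raw = raw.pop("gate", {})
    for k in ("area_range", "aspect_ratio_range"):
        if k in gate_raw and isinstance(gate_raw[k], list):
            gate_raw[k] = tuple(gate_raw[k])
    gate = GateConfig(**gate_raw)
    knn = KnnConfig(**raw.pop("knn", {}))
    return PipelineConfig(sim=sim, gate=gate, knn=knn, **raw)
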