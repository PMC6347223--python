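"""Stage orchestration, configuration and reproducibility metadata.

``run_all`` executes the analysis chain

    simulate (optional) -> extract (optional, image inputs) -> metrics
      -> classify -> statistics

writing every intermediate CSV plus a run manifest with the config hash,
seed and SHA-256 checksums of all tabular outputs.  Re-running with an
identical config and seed reproduces identical checksums for every CSV:
the one global seed fans out through a spawned per-cell seed sequence in a
fixed iteration order, so any subset of the cohort reproduces
independently of the rest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CellObservation, ClassThresholds, score_cohort
from .extraction import ExtractionConfig, extract_filaments, max_intensity_projection
from .io import read_tiff, validate_inputs, write_csv
from .metrics import FilamentSet, metrics_frame
from .stats import summarize_cohort
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_all", "load_config",
           "alterations_from_tables"]


@dataclass
class PipelineConfig:
    out_dir: str = "cryoactin_out"
    seed: int = 0
    simulate: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    image_glob: str | None = None    # TIFF inputs for the extract stage
    filament_csv: str | None = None  # pre-computed filament table input
    manifest_csv: str | None = None
    control_condition: str = "control"
    compare: str = "control_vs_each"
    bonferroni: bool = False
    log_level: str = "INFO"


def _config_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _config_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_dict(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(_config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: dict
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON, keeping defaults for
    unspecified fields."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key == "generator":
            sub = dataclasses.replace(GeneratorConfig(), **_load_generator_fields(val))
            cfg.generator = sub
        elif key == "extraction":
            cfg.extraction = dataclasses.replace(ExtractionConfig(), **val)
        elif key == "thresholds":
            cfg.thresholds = dataclasses.replace(ClassThresholds(), **val)
        elif hasattr(cfg, key):
            setattr(cfg, key, val)
        else:
            raise KeyError(f"unknown config key {key!r}")
    return cfg


def _load_generator_fields(val: dict) -> dict:
    from .synthetic import StratumParams
    out = dict(val)
    if "damage_params" in out:
        parsed = {}
        for key, sp in out["damage_params"].items():
            cond, t = (key.rsplit("@", 1) if isinstance(key, str) else key)
            parsed[(cond, int(t))] = StratumParams(**sp)
        out["damage_params"] = parsed
    for tup in ("conditions", "recovery_times_min", "filament_count_range",
                "cell_semi_axes_um", "annexin_positive_sd_range",
                "annexin_negative_sd_range"):
        if tup in out:
            out[tup] = tuple(out[tup])
    if "thresholds" in out:
        out["thresholds"] = ClassThresholds(**out["thresholds"])
    return out


def alterations_from_tables(filament_table: pd.DataFrame, manifest: pd.DataFrame,
                            thresholds: ClassThresholds = ClassThresholds()) -> pd.DataFrame:
    """Score a cohort given its filament table and manifest CSV contents."""
    pairs = []
    by_cell = dict(tuple(filament_table.groupby("cell_id", sort=False)))
    for _, row in manifest.iterrows():
        cid = row["cell_id"]
        sub = by_cell.get(cid)
        meta = dict(condition=row["condition"], recovery_min=int(row["recovery_min"]),
                    replicate_id=str(row["replicate"]))
        pre_fs = FilamentSet(cell_id=cid)
        post_fs = FilamentSet(cell_id=cid)
        if sub is not None:
            pre_fs = FilamentSet.from_frame(sub[sub["stage"] == "pre"], cell_id=cid)
            post_fs = FilamentSet.from_frame(sub[sub["stage"] == "post"], cell_id=cid)
        pre = CellObservation(cell_id=cid, stage="pre", filaments=pre_fs, **meta)
        if bool(row["detached"]):
            pairs.append((pre, None))
            continue
        sd = row["annexin_sd"]
        post = CellObservation(cell_id=cid, stage="post", filaments=post_fs,
                               annexin_sd_au=None if pd.isna(sd) else float(sd),
                               detached=False, **meta)
        pairs.append((pre, post))
    return score_cohort(pairs, thresholds)


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Execute the configured stages end to end; see the module docstring."""
    started = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    try:
        if cfg.simulate:
            cohort = generate_cohort(cfg.generator, seed=cfg.seed)
            filament_table = cohort.filament_table
            manifest = cohort.manifest
            outputs["filaments"] = write_csv(filament_table, out / "filaments.csv")
            outputs["manifest"] = write_csv(manifest, out / "manifest.csv")
            outputs["ground_truth"] = write_csv(cohort.ground_truth, out / "ground_truth.csv")
        else:
            if cfg.filament_csv is None and cfg.image_glob is None:
                raise ValueError("need filament_csv or image_glob when simulate=False")
            if cfg.image_glob is not None:
                filament_table = _extract_stage(cfg, out, outputs)
            else:
                filament_table = pd.read_csv(cfg.filament_csv)
            if cfg.manifest_csv is None:
                raise ValueError("manifest_csv is required for classification")
            rep = validate_inputs(manifest_csvs=[cfg.manifest_csv])
            if not rep.ok:
                raise ValueError(f"manifest validation failed:\n{rep}")
            manifest = pd.read_csv(cfg.manifest_csv)
    except Exception as exc:
        raise RuntimeError(f"[simulate/ingest] stage failed: {exc}") from exc

    try:
        mtab = metrics_frame(filament_table)
        outputs["metrics"] = write_csv(mtab, out / "metrics.csv")
    except Exception as exc:
        raise RuntimeError(f"[metrics] stage failed: {exc}") from exc

    try:
        alterations = alterations_from_tables(filament_table, manifest, cfg.thresholds)
        outputs["alterations"] = write_csv(alterations, out / "alterations.csv")
    except Exception as exc:
        raise RuntimeError(f"[classify] stage failed: {exc}") from exc

    try:
        summary = summarize_cohort(alterations, cfg.control_condition,
                                   cfg.compare, cfg.bonferroni)
        outputs["fractions"] = write_csv(summary.fractions, out / "summary_fractions.csv")
        outputs["deltas"] = write_csv(summary.deltas, out / "summary_deltas.csv")
        outputs["tests"] = write_csv(summary.tests, out / "summary_tests.csv")
        (out / "summary.json").write_text(
            json.dumps(_jsonable(summary.to_json_dict()), indent=2, sort_keys=True))
        outputs["summary_json"] = out / "summary.json"
    except Exception as exc:
        raise RuntimeError(f"[stats] stage failed: {exc}") from exc

    manifest_obj = RunManifest(
        config_hash=config_hash(cfg), seed=cfg.seed, version=__version__,
        checksums={k: _sha256(p) for k, p in sorted(outputs.items())},
        started=started, finished=time.time())
    (out / "run_manifest.json").write_text(manifest_obj.to_json())
    return manifest_obj


def _extract_stage(cfg: PipelineConfig, out: Path, outputs: dict) -> pd.DataFrame:
    import glob

    rows = []
    paths = sorted(glob.glob(cfg.image_glob))
    if not paths:
        raise FileNotFoundError(f"no images match {cfg.image_glob!r}")
    for p in paths:
        img = read_tiff(p)
        if img.ndim == 3:
            img = max_intensity_projection(img)
        cell_id = Path(p).stem
        stage = "post" if cell_id.endswith("_post") else "pre"
        cell_id = cell_id.removesuffix("_pre").removesuffix("_post")
        fs = extract_filaments(img, cfg.extraction, cell_id=cell_id)
        df = fs.to_frame()
        df.insert(0, "stage", stage)
        df.insert(0, "cell_id", cell_id)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    outputs["filaments"] = write_csv(table, out / "filaments.csv")
    return table


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
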