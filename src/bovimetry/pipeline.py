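"""End-to-end scan-day pipeline on a synthetic herd.

simulate -> build meshes -> (inject defects) -> (reconstruct from points)
-> measure -> quality-score -> predict BW -> summarize. Every artifact is
written under a run directory with a manifest (config, seed, version,
content hashes); the run is fully deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .growth import stage_summary, surface_to_volume_curve
from .io import write_mesh, write_traits, write_weights
from .morphometrics import measure_all
from .quality import score_quality
from .reconstruction import reconstruct_surface
from .records import WeighRecord
from .synthetic import (
    default_growth_params,
    growth_state_at_age,
    inject_skirt,
    remove_region,
    sample_point_cloud,
    simulate_herd,
    solve_shape,
)
from .weight_models import get_model, predict_bw

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, artifacts: list | None = None):
        self.stage = stage
        self.artifacts = artifacts or []
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_animals: int = 3
    visit_ages: list = field(default_factory=lambda: [62, 140, 220, 300, 369, 450])
    resolution: int = 64
    skirt_probability: float = 0.0
    missing_head_probability: float = 0.0
    reconstruct: bool = False
    reconstruction_method: str = "implicit"
    reconstruction_depth: int = 7
    n_points: int = 60000
    point_noise_sd: float = 0.002
    model_name: str = "eq8"
    stages: dict | None = None
    out_dir: str = "run"

    def validate(self) -> None:
        for p in (self.skirt_probability, self.missing_head_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"defect probability {p} outside [0, 1]")
        get_model(self.model_name)  # unknown model fails before any simulation
        if list(self.visit_ages) != sorted(self.visit_ages):
            raise ValueError("visit_ages must be ascending")
        if self.n_animals < 1 or self.resolution < 8:
            raise ValueError("need n_animals >= 1 and resolution >= 8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh_dir = out / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    artifacts: list[Path] = []
    growth = default_growth_params()
    stage = "simulate"
    try:
        traits_target, weighs = simulate_herd(
            growth, config.n_animals, list(config.visit_ages), seed=config.seed
        )
        weights_csv = out / "weights.csv"
        write_weights(weighs, weights_csv)
        artifacts.append(weights_csv)
    except Exception as err:
        raise PipelineError(stage, str(err), artifacts) from err

    measured = []
    qc_reports = {}
    rng = np.random.default_rng(config.seed + 10_000)
    for rec in traits_target:
        key = f"{rec.animal_id}_{int(rec.age)}d"
        stage = f"mesh:{key}"
        try:
            shape = solve_shape(
                wh=rec.wh, cd=rec.cd, hg=rec.hg, kw=rec.kw, volume=rec.volume
            )
            from .synthetic import build_heifer_mesh

            mesh, _ = build_heifer_mesh(shape, resolution=config.resolution)
            if rng.random() < config.skirt_probability:
                mesh = inject_skirt(mesh, severity=1.0, seed=int(rng.integers(2**31)))
                log.info("%s: skirt injected", key)
            if rng.random() < config.missing_head_probability:
                mesh = remove_region(mesh, "head")
                log.info("%s: head removed", key)
            if config.reconstruct:
                cloud = sample_point_cloud(
                    mesh,
                    config.n_points,
                    config.point_noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                mesh = reconstruct_surface(
                    cloud,
                    config.reconstruction_method,
                    {"depth": config.reconstruction_depth},
                )
            path = mesh_dir / f"{key}.ply"
            write_mesh(mesh, path)
            artifacts.append(path)
            stage = f"measure:{key}"
            m = measure_all(mesh, animal_id=rec.animal_id, age=rec.age)
            measured.append(m)
            qc_reports[key] = score_quality(mesh).as_dict()
            log.info("%s: quality %d", key, m.quality)
        except Exception as err:
            raise PipelineError(stage, str(err), artifacts) from err

    stage = "tables"
    try:
        traits_csv = out / "traits.csv"
        write_traits(measured, traits_csv)
        artifacts.append(traits_csv)
        qc_json = out / "qc.json"
        qc_json.write_text(json.dumps(qc_reports, indent=2, sort_keys=True))
        artifacts.append(qc_json)
    except Exception as err:
        raise PipelineError(stage, str(err), artifacts) from err

    stage = "predict"
    try:
        model = get_model(config.model_name)
        rows = []
        for rec in measured:
            if rec.quality < 3:
                log.info(
                    "%s %sd: quality %d, excluded from BW prediction",
                    rec.animal_id, rec.age, rec.quality,
                )
                continue
            try:
                bw = predict_bw(model, rec)
            except ValueError:
                continue
            rows.append(
                WeighRecord(animal_id=rec.animal_id, age=rec.age, bw=bw)
            )
        bw_csv = out / "bw_predicted.csv"
        write_weights(rows, bw_csv)
        artifacts.append(bw_csv)
    except Exception as err:
        raise PipelineError(stage, str(err), artifacts) from err

    stage = "summarize"
    try:
        summaries = stage_summary(measured, weighs, config.stages)
        summary_csv = out / "summary.csv"
        import pandas as pd

        pd.DataFrame(
            [
                {"stage": s.stage, "mean_age": s.mean_age, "n": s.n}
                | {f"{t}_mean": v for t, v in s.means.items()}
                | {f"{t}_sd": v for t, v in s.sds.items()}
                for s in summaries
            ]
        ).to_csv(summary_csv, index=False)
        artifacts.append(summary_csv)
    except Exception as err:
        raise PipelineError(stage, str(err), artifacts) from err

    stage = "sv-curve"
    try:
        curve_json = out / "curve.json"
        try:
            fit = surface_to_volume_curve(measured, weighs)
            curve = {"form": fit.form, "a": fit.a, "b": fit.b, "n": len(fit.ratios)}
        except ValueError as err:
            curve = {"error": str(err)}
        curve_json.write_text(json.dumps(curve, indent=2))
        artifacts.append(curve_json)
    except Exception as err:
        raise PipelineError(stage, str(err), artifacts) from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
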