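"""End-to-end orchestration: development atlas -> measurement -> validation.

Mirrors the method's lifecycle: a development sample of knees with marked
denudation builds the frequency atlas and fixes the informative locations;
a separate validation cohort is measured at baseline and 24 months (with a
reliability subset measured twice); the validation statistics are assembled
into a report. Every artifact is stamped with the config hash and seed, and
a rerun with the same config reproduces every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import atlas as atlas_mod
from . import measure as measure_mod
from . import stats as stats_mod
from . import synthetic
from .coords import FEMUR, SURFACES, TIBIA, build_surface_frame

log = logging.getLogger("cdi")


class PhantomConfig(BaseModel):
    n_slices: int = 48
    in_plane_shape: tuple[int, int] = (96, 120)
    spacing: tuple[float, float, float] = synthetic.DEFAULT_SPACING
    base_thickness_mm: dict[str, float] = Field(
        default_factory=lambda: {FEMUR: 2.2, TIBIA: 1.8}
    )


class DevelopmentConfig(BaseModel):
    n_knees: int = 20
    lesion_prob: float = 0.75
    hotspot_uv: tuple[float, float, float, float] = (0.55, 0.35, 0.30, 0.30)


class AtlasConfig(BaseModel):
    grid: int = 100
    threshold_quantile: float = 0.75
    margin_uv: float = 0.05


class CohortConfig(BaseModel):
    n_per_grade: int = 10
    remeasure_noise_sd: float = 0.06


class MeasureConfig(BaseModel):
    ml_factor_mm: float = measure_mod.DEFAULT_ML_FACTOR_MM
    ray_step_mm: float = measure_mod.DEFAULT_RAY_STEP_MM


class StatsConfig(BaseModel):
    n_permutations: int = 2000


class PipelineConfig(BaseModel):
    seed: int = 0
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    development: DevelopmentConfig = Field(default_factory=DevelopmentConfig)
    atlas: AtlasConfig = Field(default_factory=AtlasConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    measure: MeasureConfig = Field(default_factory=MeasureConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def build_development_atlas(
    config: PipelineConfig, seed: int, outdir: Path | None = None
) -> dict[str, atlas_mod.LocationSet]:
    """Rasterize a development sample and derive per-surface location sets."""
    rng = np.random.default_rng(seed)
    location_sets: dict[str, atlas_mod.LocationSet] = {}
    for surface in SURFACES:
        masks, frames = [], []
        for _k in range(config.development.n_knees):
            lesions = (
                synthetic.sample_lesions(rng, config.development.hotspot_uv)
                if rng.random() < config.development.lesion_prob
                else ()
            )
            spec = synthetic.PhantomSpec(
                surface=surface,
                n_slices=config.phantom.n_slices,
                in_plane_shape=config.phantom.in_plane_shape,
                spacing=config.phantom.spacing,
                base_thickness_mm=config.phantom.base_thickness_mm[surface],
                lesions=lesions,
            )
            result = synthetic.rasterize_phantom(spec)
            frames.append(build_surface_frame(result.volume, surface))
            masks.append(result.denudation_mask)
        freq, locs = atlas_mod.build_atlas(
            masks,
            frames,
            surface,
            grid_shape=(config.atlas.grid, config.atlas.grid),
            threshold_quantile=config.atlas.threshold_quantile,
            margin_uv=config.atlas.margin_uv,
        )
        location_sets[surface] = locs
        if outdir is not None:
            freq.to_csv(outdir / f"frequency_{surface}.csv")
            freq.to_png(outdir / f"frequency_{surface}.png")
            locs.to_json(outdir / f"atlas_{surface}.json")
    return location_sets


def measure_cohort(
    cohort: synthetic.Cohort,
    location_sets: dict[str, atlas_mod.LocationSet],
    config: PipelineConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """Measure every record at both visits plus the reliability re-reads."""
    rng = np.random.default_rng(seed)
    noise_sd = cohort.spec.remeasure_noise_sd
    ml = config.measure.ml_factor_mm

    def frame_for(records: list[synthetic.KneeRecord], rng) -> pd.DataFrame:
        rows = []
        for r in records:
            res = measure_mod.measure_record(
                r, location_sets, rng=rng, noise_sd=noise_sd, ml_factor_mm=ml
            )
            rows.append(
                {
                    "knee_id": r.knee_id,
                    "visit": r.visit,
                    "femur_cdi": res.femur_cdi,
                    "tibia_cdi": res.tibia_cdi,
                    "total_cdi": res.total_cdi,
                    "jsn": r.jsn_grade,
                    "kl": r.kl_grade,
                    "jsw_mm": r.jsw_mm,
                    "hka_deg": r.hka_deg,
                    "height_m": r.height_m,
                    "true_volume_mm3": r.true_cartilage_volume_mm3,
                }
            )
        return pd.DataFrame(rows)

    baseline = frame_for(cohort.baseline(), rng)
    followup = frame_for(cohort.month24(), rng)

    rel_records = [r for r in cohort.baseline() if r.knee_id in set(cohort.reliability_ids)]
    reliability: dict[str, np.ndarray] = {}
    reads = []
    for rseed in cohort.remeasure_seeds:
        reads.append(frame_for(rel_records, np.random.default_rng(rseed)))
    for c in stats_mod.CDI_COLUMNS:
        reliability[c] = np.column_stack([df[c].to_numpy() for df in reads])
    return baseline, followup, reliability


def run_end_to_end(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run development -> atlas -> cohort -> measurement -> report.

    Returns the run directory; artifacts: ``atlas_<surface>.json``,
    ``frequency_<surface>.csv/.png``, ``cohort.csv``, ``measurements.csv``,
    ``report.json``, ``per_grade_means.csv``, ``rank_pairs.csv``,
    ``run_meta.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    ss = np.random.SeedSequence(config.seed)
    seed_atlas, seed_cohort, seed_measure = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    )

    log.info("stage 1/4: development atlas (%d knees/surface)", config.development.n_knees)
    try:
        location_sets = build_development_atlas(config, seed_atlas, outdir)
    except Exception as e:  # noqa: BLE001
        raise StageError("development-atlas", str(e)) from e

    log.info("stage 2/4: validation cohort (%d knees/grade)", config.cohort.n_per_grade)
    try:
        cohort = synthetic.generate_cohort(
            synthetic.CohortSpec(
                n_per_grade=config.cohort.n_per_grade,
                remeasure_noise_sd=config.cohort.remeasure_noise_sd,
                seed=seed_cohort,
            )
        )
        cohort.to_frame().to_csv(outdir / "cohort.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("generate-cohort", str(e)) from e

    log.info("stage 3/4: CDI measurement (both visits + reliability)")
    try:
        baseline, followup, reliability = measure_cohort(
            cohort, location_sets, config, seed_measure
        )
        pd.concat([baseline, followup]).to_csv(outdir / "measurements.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("measure", str(e)) from e

    log.info("stage 4/4: validation report")
    try:
        report = stats_mod.build_validation_report(
            baseline,
            followup,
            reliability,
            n_permutations=config.stats.n_permutations,
            seed=config.seed,
        )
        report.spearman["total_cdi"]["true_volume_mm3"] = stats_mod.spearman_rho(
            baseline["total_cdi"].to_numpy(), baseline["true_volume_mm3"].to_numpy()
        )
        report.to_json(outdir / "report.json")
        report.per_grade_means.to_csv(outdir / "per_grade_means.csv", index=False)
        report.rank_pairs.to_csv(outdir / "rank_pairs.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("validate", str(e)) from e

    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "config": config.model_dump()}
    (outdir / "run_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    log.info("run complete: %s", outdir)
    return outdir
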