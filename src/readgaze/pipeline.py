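"""Configuration, file formats, and the end-to-end pipeline.

Stages: simulate -> detect -> features -> screen -> model (x2 responses)
-> crossval -> report. Every stage reads and writes plain-text columnar
formats (CSV with a config-hash comment line, JSON sidecars), and the run
manifest keeps the per-stage event-count ledger so a run can be audited
the way the analysis itself reports its filtering steps.

All outputs carry the configuration hash; stages refuse inputs whose hash
does not match their own configuration (no silent mixing of runs).
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import platform
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import features as ft
from . import models as md
from . import screening as sc
from . import simulate as sim

logger = logging.getLogger(__name__)

HASH_COMMENT = "# readgaze-config: "
SESSION_FILE_RE = re.compile(r"P(\d+)_A(\d+)\.csv$")


@dataclass
class DetectionParams:
    min_fixation_ms: float = 80.0
    dispersion_deg: float = 1.0
    regression_px: float = 20.0
    max_gap_intervals: float = 2.0


@dataclass
class FilteringParams:
    iqr_multiplier: float = 4.0
    r_threshold: float = 0.95


@dataclass
class ModelingParams:
    stepwise_criterion: str = "aic"
    loess_span: float = 0.75


@dataclass
class PipelineConfig:
    geometry: ev.ScreenGeometry = field(default_factory=ev.ScreenGeometry)
    detection: DetectionParams = field(default_factory=DetectionParams)
    filtering: FilteringParams = field(default_factory=FilteringParams)
    modeling: ModelingParams = field(default_factory=ModelingParams)
    generator: sim.GeneratorConfig = field(
        default_factory=sim.GeneratorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_fixation_ms", "dispersion_deg", "regression_px"):
            if getattr(self.detection, name) <= 0:
                raise ValueError(f"detection.{name} must be positive")
        if self.filtering.iqr_multiplier <= 0:
            raise ValueError("filtering.iqr_multiplier must be positive")
        if not 0 < self.filtering.r_threshold <= 1:
            raise ValueError("filtering.r_threshold must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            geometry=ev.ScreenGeometry(**d.get("geometry", {})),
            detection=DetectionParams(**d.get("detection", {})),
            filtering=FilteringParams(**d.get("filtering", {})),
            modeling=ModelingParams(**d.get("modeling", {})),
            generator=sim.GeneratorConfig(**d.get("generator", {})),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        d = self.to_dict()
        d["seed"] = seed
        d["generator"]["rng_seed"] = seed
        return PipelineConfig.from_dict(d)


# ---------------------------------------------------------------------------
# Hash-tagged readers/writers


def write_csv(df: pd.DataFrame, path: str | Path, cfg_hash: str) -> None:
    buf = io.StringIO()
    buf.write(HASH_COMMENT + cfg_hash + "\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_csv(path: str | Path, expect_hash: str | None = None):
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(HASH_COMMENT):
            found = first[len(HASH_COMMENT):].strip()
            df = pd.read_csv(fh, low_memory=False)
        else:
            found = None
            df = pd.read_csv(io.StringIO(first + fh.read()),
                             low_memory=False)
    if expect_hash is not None and found is not None and found != expect_hash:
        raise ValueError(f"{path}: config hash {found} does not match "
                         f"{expect_hash}; refusing mixed-config inputs")
    return df, found


def write_json(obj, path: str | Path, cfg_hash: str | None = None) -> None:
    payload = dict(obj)
    if cfg_hash is not None:
        payload["config_hash"] = cfg_hash
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Study I/O (the raw-data dialect)


def write_study(study: sim.SyntheticStudy, out_dir: str | Path,
                cfg_hash: str) -> None:
    """Write a generated study in its on-disk dialect: one gaze CSV per
    session (``P{pp}_A{aa}.csv``), one AOI JSON per article, a ratings CSV
    and the latent ground truth."""
    out = Path(out_dir)
    gaze_dir = out / "gaze"
    aoi_dir = out / "aoi"
    gaze_dir.mkdir(parents=True, exist_ok=True)
    aoi_dir.mkdir(parents=True, exist_ok=True)
    for (p, a), stream in study.gaze.items():
        write_csv(stream, gaze_dir / f"P{p:02d}_A{a:02d}.csv", cfg_hash)
    for a, layout in study.layouts.items():
        write_json(layout.aois, aoi_dir / f"A{a:02d}.json", cfg_hash)
    write_csv(study.ratings, out / "ratings.csv", cfg_hash)
    write_csv(study.latents, out / "latents.csv", cfg_hash)


def read_gaze_dir(gaze_dir: str | Path, expect_hash: str | None = None
                  ) -> dict:
    gaze = {}
    for path in sorted(Path(gaze_dir).glob("*.csv")):
        m = SESSION_FILE_RE.search(path.name)
        if not m:
            raise ValueError(f"unrecognized gaze file name: {path.name}")
        df, _ = read_csv(path, expect_hash)
        gaze[(int(m.group(1)), int(m.group(2)))] = df
    if not gaze:
        raise FileNotFoundError(f"no gaze CSV files found in {gaze_dir}")
    return gaze


def read_aoi_dir(aoi_dir: str | Path) -> dict:
    aois = {}
    for path in sorted(Path(aoi_dir).glob("*.json")):
        m = re.search(r"A(\d+)\.json$", path.name)
        if not m:
            raise ValueError(f"unrecognized AOI file name: {path.name}")
        d = json.loads(path.read_text())
        aois[int(m.group(1))] = {k: v for k, v in d.items()
                                 if k in ("title", "content")}
    if not aois:
        raise FileNotFoundError(f"no AOI JSON files found in {aoi_dir}")
    return aois


# ---------------------------------------------------------------------------
# Stage functions


def events_to_tidy(fixations: pd.DataFrame,
                   saccades: pd.DataFrame) -> pd.DataFrame:
    """Combined tidy event table: one row per event with a ``type``
    column; fields not applicable to a type are left empty."""
    fx = fixations.copy()
    fx["type"] = "fixation"
    sa = saccades.copy()
    sa["type"] = "saccade"
    return pd.concat([fx, sa], ignore_index=True, sort=False)


def tidy_to_events(tidy: pd.DataFrame):
    fix = tidy[tidy["type"] == "fixation"].dropna(axis=1, how="all")
    sac = tidy[tidy["type"] == "saccade"].dropna(axis=1, how="all")
    fix = fix.drop(columns="type").reset_index(drop=True)
    sac = sac.drop(columns="type").reset_index(drop=True)
    # CSV round trips leave flag/index columns as objects/floats
    if "fix_index" in fix.columns:
        fix["fix_index"] = fix["fix_index"].astype(int)
    for col, typ in (("is_blink", bool), ("is_regression", bool),
                     ("fix_from", int), ("fix_to", int)):
        if col in sac.columns:
            sac[col] = sac[col].map(
                lambda v: v == "True" if isinstance(v, str) else v
            ).astype(typ)
    return fix, sac


def detect_stage(gaze: dict, aois: dict, blocks: dict,
                 config: PipelineConfig):
    det = config.detection
    return ft.extract_study_events(
        gaze, aois, blocks=blocks, geometry=config.geometry,
        min_duration_ms=det.min_fixation_ms,
        dispersion_deg=det.dispersion_deg,
        regression_threshold_px=det.regression_px)


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 input_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the run manifest.

    Without ``input_dir`` a synthetic study is generated from
    ``config.generator`` (seeded by ``config.seed``) and written under
    ``out_dir/sim``; otherwise raw inputs (gaze/, aoi/, ratings.csv) are
    read from ``input_dir``. Any stage failure aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    manifest: dict = {"config_hash": h, "seed": config.seed, "stages": {},
                      "versions": _versions()}
    stage = "simulate"
    try:
        if input_dir is None:
            study = sim.generate_study(config.generator,
                                       rng_seed=config.seed)
            write_study(study, out / "sim", h)
            gaze = study.gaze
            aois = {a: lay.aois for a, lay in study.layouts.items()}
            ratings = study.ratings
        else:
            inp = Path(input_dir)
            gaze = read_gaze_dir(inp / "gaze", expect_hash=None)
            aois = read_aoi_dir(inp / "aoi")
            ratings, _ = read_csv(inp / "ratings.csv")
        blocks = {(int(r.participant), int(r.article)): int(r.block)
                  for r in ratings.itertuples(index=False)}
        manifest["stages"]["simulate"] = {
            "sessions_with_gaze": len(gaze),
            "appraisal_records": len(ratings),
        }

        stage = "detect"
        fixations, saccades, sessions = detect_stage(gaze, aois, blocks,
                                                     config)
        write_csv(events_to_tidy(fixations, saccades), out / "events.csv", h)
        manifest["stages"]["detect"] = {
            "fixations": len(fixations),
            "saccades": int((~saccades["is_blink"]).sum())
            if len(saccades) else 0,
            "blink_saccades": int(saccades["is_blink"].sum())
            if len(saccades) else 0,
        }

        stage = "features"
        table, ft_manifest = ft.build_feature_table(
            fixations, saccades, sessions, ratings=ratings,
            iqr_multiplier=config.filtering.iqr_multiplier)
        write_csv(table, out / "study_table.csv", h)
        write_json(ft_manifest, out / "study_table_manifest.json", h)
        manifest["stages"]["features"] = ft_manifest["stage_counts"] | {
            "rows": len(table), "columns": table.shape[1]}
        manifest["cronbach_alpha"] = ft_manifest.get("cronbach_alpha", {})

        stage = "screen"
        screened, report = sc.screen(
            table, r_threshold=config.filtering.r_threshold)
        write_csv(screened, out / "screened.csv", h)
        write_json(report.to_dict(), out / "screening.json", h)
        manifest["stages"]["screen"] = {
            "rows_removed": report.rows_removed,
            "columns_removed": report.columns_removed,
            "final_dims": list(report.final_dims),
        }

        manifest["models"] = {}
        for response in md.APPRAISALS:
            stage = f"model:{response}"
            model = md.fit_stepwise(screened, response)
            write_json(model.to_dict(), out / f"model_{response}.json", h)

            stage = f"crossval:{response}"
            cv = md.loocv(screened, model.predictors, response)
            cv_df = screened[["participant", "article"]].copy()
            cv_df["actual"] = cv.actual
            cv_df["predicted"] = cv.predicted
            write_csv(cv_df, out / f"cv_{response}.csv", h)

            stage = f"report:{response}"
            rep = md.prediction_report(
                cv, span=config.modeling.loess_span,
                out_png=str(out / f"report_{response}.png"))
            write_json(rep, out / f"report_{response}.json", h)
            manifest["models"][response] = {
                "n_predictors": len(model.predictors),
                "r_squared_pct": model.r_squared_pct,
                "f_statistic": model.f_statistic,
                "df": [model.df_model, model.df_resid],
                "loocv_r": cv.pearson_r,
                "nrmse": cv.nrmse,
                "baselines_pct": rep["baselines_pct"],
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_json(manifest, out / "run_manifest.json", h)
    return manifest


def _versions() -> dict:
    import scipy
    import statsmodels
    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
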