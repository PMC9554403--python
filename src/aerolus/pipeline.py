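"""End-to-end orchestration: simulate -> features -> CT -> grade -> fit -> report.

A single :class:`RunConfig` drives a reproducible run that writes, into the
output directory:

* ``manifest.csv`` — cohort manifest (lamb, side, pressure, phase, truth);
* ``features.csv`` — per-clip pooled imaging statistics;
* ``ct_proportions.csv`` — measured superficial air proportions;
* ``grade_summary.csv`` — median (IQR) air % per grade;
* ``simple_models.csv`` — four statistics x {all, inflation, deflation};
* ``multivariate.json`` — final model, elimination trace;
* ``predictions.csv`` — per-observation predictions with 95% PI;
* ``group_tests.json`` — Kruskal-Wallis across grades, backsliding t-test;
* ``observed_vs_predicted.png`` — scatter with PI band;
* ``run_metadata.json`` — full config including the seed.

Tables are byte-identical across reruns with the same config and seed.
Observations with grades {0, 0.5, 3} are excluded from every regression
stage but appear in the grade summary and group tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .ct_aeration import measure_superficial_air
from .errors import AerolusError, DomainError
from .grading import grade_vs_air_summary
from .lus_features import DEFAULT_BAND, clip_features, features_to_row
from .models import (
    MULTIVARIATE_COVARIATES,
    fit_multivariate,
    fit_simple_regression,
    kruskal_wallis,
    log_linearize,
    paired_t_test,
    predict_air_proportion,
)
from .simulate import (
    PairedObservation,
    Phase,
    PressureSchedule,
    SimulationConfig,
    default_rois,
    generate_cohort,
    observations_to_frame,
)

logger = logging.getLogger("aerolus")

#: Statistics entering the simple-model grid (Table-style report).  The
#: parallel spectral AUC is modeled on the log10 scale.
SIMPLE_MODEL_STATS = ("mpi", "cov", "auc_parallel_log", "auc_perpendicular")
SUBSETS = ("all", "inflation", "deflation")
#: Only type 1 and type 2 clips enter the regression stages.
REGRESSION_GRADES = (1.0, 2.0)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    n_lambs: int = 7
    simulation: SimulationConfig = field(default_factory=SimulationConfig.desk_scale)
    schedule: PressureSchedule = field(default_factory=PressureSchedule.default)
    band: tuple[float, float] = DEFAULT_BAND
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "aerolus_run"
    save_images: bool = False

    def to_dict(self) -> dict:
        return {
            "n_lambs": self.n_lambs,
            "simulation": dataclasses.asdict(self.simulation),
            "schedule": [[p, ph.value] for p, ph in self.schedule.steps],
            "band": list(self.band),
            "alpha": self.alpha,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "save_images": self.save_images,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = d.get("simulation", {})
        for key in ("grade_thresholds", "ct_shape", "ct_voxel_size_mm"):
            if key in sim:
                sim[key] = tuple(sim[key])
        return cls(
            n_lambs=d.get("n_lambs", 7),
            simulation=SimulationConfig(**sim),
            schedule=PressureSchedule(
                tuple((float(p), Phase(ph)) for p, ph in d.get("schedule", []))
            )
            if d.get("schedule")
            else PressureSchedule.default(),
            band=tuple(d.get("band", DEFAULT_BAND)),
            alpha=d.get("alpha", 0.05),
            seed=d.get("seed", 0),
            output_dir=d.get("output_dir", "aerolus_run"),
            save_images=d.get("save_images", False),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def observation_id(obs: PairedObservation, step: int) -> str:
    return f"{obs.lamb_id}_{obs.lung_side}_step{step:02d}"


def build_feature_table(
    observations: Sequence[PairedObservation],
    config: SimulationConfig,
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Per-clip pooled statistics for a simulated cohort."""
    rois = default_rois(config)
    rows = []
    step = 0
    prev_lung = None
    for obs in observations:
        lung = (obs.lamb_id, obs.lung_side)
        step = step + 1 if lung == prev_lung else 0
        prev_lung = lung
        fv = clip_features(obs.clip, rois, band=band)
        row = features_to_row(observation_id(obs, step), fv)
        rows.append(row)
    return pd.DataFrame(rows)


def build_ct_table(observations: Sequence[PairedObservation]) -> pd.DataFrame:
    rows = []
    step = 0
    prev_lung = None
    for obs in observations:
        lung = (obs.lamb_id, obs.lung_side)
        step = step + 1 if lung == prev_lung else 0
        prev_lung = lung
        result = measure_superficial_air(obs.ct)
        rows.append(
            {
                "clip_id": observation_id(obs, step),
                "air_voxels": result.air_voxels,
                "region_voxels": result.region_voxels,
                "proportion_air_pct": 100.0 * result.proportion,
            }
        )
    return pd.DataFrame(rows)


def merge_analysis_table(
    manifest: pd.DataFrame, features: pd.DataFrame, ct: pd.DataFrame
) -> pd.DataFrame:
    """Join manifest + features + CT into the modeling table."""
    df = manifest.copy()
    df["clip_id"] = features["clip_id"].to_numpy()
    df = df.merge(features, on="clip_id").merge(
        ct[["clip_id", "proportion_air_pct"]], on="clip_id"
    )
    df["auc_parallel_log"] = log_linearize(df["auc_parallel"])
    df["grade"] = df["true_grade"]
    return df


def _subset_frame(df: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return df
    return df[df["phase"] == subset]


def fit_simple_models(df: pd.DataFrame) -> pd.DataFrame:
    """Table-2-style grid: each statistic x {all, inflation, deflation}.

    ``df`` must already be restricted to type-1/2 observations.  Fits with
    too few points or a degenerate covariate are reported with NaN values
    and a status message instead of aborting the run.
    """
    rows = []
    for stat in SIMPLE_MODEL_STATS:
        for subset in SUBSETS:
            sub = _subset_frame(df, subset)
            record = {"statistic": stat, "subset": subset, "n": len(sub)}
            try:
                fit = fit_simple_regression(
                    sub[stat].to_numpy(), sub["proportion_air_pct"].to_numpy(), stat
                )
                record.update(
                    slope=fit.slopes[stat],
                    intercept=fit.intercept,
                    r_squared=fit.r_squared,
                    p_value=fit.coefficient_p_values[stat],
                    pi95_halfwidth_pct=fit.pi95_halfwidth_at_mean,
                    status="ok",
                )
            except (AerolusError, ValueError) as exc:
                record.update(
                    slope=np.nan,
                    intercept=np.nan,
                    r_squared=np.nan,
                    p_value=np.nan,
                    pi95_halfwidth_pct=np.nan,
                    status=f"skipped: {exc}",
                )
                logger.warning("simple model %s/%s skipped: %s", stat, subset, exc)
            rows.append(record)
    return pd.DataFrame(rows)


def backslide_pairs(observations: Sequence[PairedObservation]) -> tuple[list[float], list[float]]:
    """Per lung: (max inflation air %, air % at first deflation grade-2 -> 1 drop)."""
    peak: dict[tuple[str, str], float] = {}
    reached2: dict[tuple[str, str], bool] = {}
    backslide: dict[tuple[str, str], float] = {}
    for obs in observations:
        key = (obs.lamb_id, obs.lung_side)
        if obs.phase == Phase.INFLATION:
            peak[key] = max(peak.get(key, 0.0), obs.true_air_fraction)
            reached2[key] = reached2.get(key, False) or obs.true_grade >= 2.0
        elif obs.phase == Phase.DEFLATION and reached2.get(key) and key not in backslide:
            if obs.true_grade == 1.0:
                backslide[key] = obs.true_air_fraction
    keys = sorted(backslide)
    return (
        [100.0 * peak[k] for k in keys],
        [100.0 * backslide[k] for k in keys],
    )


def run_end_to_end(config: RunConfig) -> dict:
    """Run the whole pipeline and write the report bundle.

    Returns a dict of the in-memory artifacts (DataFrames, fits, traces).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s starting", name)
        return t0

    t0 = stage("simulate")
    observations = generate_cohort(
        config.n_lambs, config.schedule, config.simulation, config.seed
    )
    manifest = observations_to_frame(observations)
    manifest.insert(0, "clip_id", "")
    step = 0
    prev = None
    ids = []
    for obs in observations:
        lung = (obs.lamb_id, obs.lung_side)
        step = step + 1 if lung == prev else 0
        prev = lung
        ids.append(observation_id(obs, step))
    manifest["clip_id"] = ids
    if config.save_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        clip_paths, ct_paths = [], []
        for obs, cid in zip(observations, ids):
            clip_paths.append(str(aio.write_clip_tiff(obs.clip, img_dir / f"{cid}.tif")))
            g, _ = aio.write_ct_nifti(
                obs.ct, img_dir / f"{cid}_ct.nii.gz", img_dir / f"{cid}_mask.nii.gz"
            )
            ct_paths.append(str(g))
        manifest["clip_path"] = clip_paths
        manifest["ct_path"] = ct_paths
    # units: proportions are fractions in the manifest, percent elsewhere
    manifest = manifest.rename(columns={"true_air_fraction": "true_air_fraction (0-1)"})
    manifest.to_csv(out / "manifest.csv", index=False)
    logger.info("stage simulate done in %.1fs (%d observations)", time.perf_counter() - t0, len(observations))

    t0 = stage("features")
    features = build_feature_table(observations, config.simulation, config.band)
    features.to_csv(out / "features.csv", index=False)
    logger.info("stage features done in %.1fs", time.perf_counter() - t0)

    t0 = stage("ct")
    ct_table = build_ct_table(observations)
    ct_table = ct_table.rename(columns={"proportion_air_pct": "proportion_air (%)"})
    ct_table.to_csv(out / "ct_proportions.csv", index=False)
    ct_table = ct_table.rename(columns={"proportion_air (%)": "proportion_air_pct"})
    logger.info("stage ct done in %.1fs", time.perf_counter() - t0)

    t0 = stage("grade")
    summary = grade_vs_air_summary(observations)
    summary_out = summary.copy()
    for col in ("median_air_pct", "iqr_low_pct", "iqr_high_pct"):
        summary_out[col] = summary_out[col].round(1)
    summary_out = summary_out.rename(
        columns={
            "median_air_pct": "median_air (%)",
            "iqr_low_pct": "iqr_low (%)",
            "iqr_high_pct": "iqr_high (%)",
        }
    )
    summary_out.to_csv(out / "grade_summary.csv", index=False)

    group_tests: dict = {}
    groups = [
        (100.0 * manifest.loc[manifest["true_grade"] == g, "true_air_fraction (0-1)"]).tolist()
        for g in sorted(manifest["true_grade"].unique())
    ]
    groups = [g for g in groups if g]
    try:
        kw = kruskal_wallis(groups)
        group_tests["kruskal_wallis_air_by_grade"] = {
            "H": kw.statistic,
            "p_value": kw.p_value,
            "n_groups": len(groups),
        }
    except AerolusError as exc:
        group_tests["kruskal_wallis_air_by_grade"] = {"status": f"skipped: {exc}"}
    peaks, slid = backslide_pairs(observations)
    if len(peaks) >= 2:
        tt = paired_t_test(peaks, slid)
        group_tests["backslide_paired_t"] = {
            "t": tt.statistic,
            "p_value": tt.p_value,
            "n_lungs": len(peaks),
            "mean_peak_air_pct": tt.group_summaries[0]["mean"],
            "mean_backslide_air_pct": tt.group_summaries[1]["mean"],
        }
    else:
        group_tests["backslide_paired_t"] = {
            "status": f"skipped: only {len(peaks)} lungs backslid"
        }
    (out / "group_tests.json").write_text(json.dumps(group_tests, indent=1, sort_keys=True))
    logger.info("stage grade done in %.1fs", time.perf_counter() - t0)

    t0 = stage("fit")
    merged = merge_analysis_table(
        manifest.rename(columns={"true_air_fraction (0-1)": "true_air_fraction"}).drop(
            columns=[c for c in ("clip_path", "ct_path") if c in manifest.columns]
        ),
        features,
        ct_table,
    )
    model_df = merged[merged["true_grade"].isin(REGRESSION_GRADES)].reset_index(drop=True)
    simple = fit_simple_models(model_df)
    simple.to_csv(out / "simple_models.csv", index=False)

    multivariate: dict = {}
    predictions = pd.DataFrame()
    fit = trace = None
    try:
        fit, trace = fit_multivariate(
            model_df, model_df["proportion_air_pct"].to_numpy(), alpha=config.alpha
        )
        multivariate = {
            "fit": fit.to_dict(),
            "elimination_trace": {
                "removed": [[name, p] for name, p in trace.removed],
                "final_covariates": list(trace.final_covariates),
            },
            "alpha": config.alpha,
        }
        rows = []
        for _, row in model_df.iterrows():
            pr = predict_air_proportion(fit, row)
            point, lo, hi = pr.clamped()
            rows.append(
                {
                    "clip_id": row["clip_id"],
                    "observed_air (%)": row["proportion_air_pct"],
                    "predicted_air (%)": point,
                    "pi95_low (%)": lo,
                    "pi95_high (%)": hi,
                }
            )
        predictions = pd.DataFrame(rows)
    except (AerolusError, ValueError) as exc:
        multivariate = {"status": f"skipped: {exc}"}
        logger.warning("multivariate model skipped: %s", exc)
    (out / "multivariate.json").write_text(json.dumps(multivariate, indent=1, sort_keys=True))
    predictions.to_csv(out / "predictions.csv", index=False)
    logger.info("stage fit done in %.1fs", time.perf_counter() - t0)

    if not predictions.empty:
        _plot_observed_vs_predicted(predictions, out / "observed_vs_predicted.png")

    (out / "run_metadata.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True)
    )

    artifacts.update(
        observations=observations,
        manifest=manifest,
        features=features,
        ct_table=ct_table,
        grade_summary=summary,
        group_tests=group_tests,
        simple_models=simple,
        multivariate=multivariate,
        multivariate_fit=fit,
        elimination_trace=trace,
        predictions=predictions,
        model_table=model_df,
    )
    return artifacts


def _plot_observed_vs_predicted(predictions: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    obs = predictions["observed_air (%)"]
    pred = predictions["predicted_air (%)"]
    order = np.argsort(obs.to_numpy())
    ax.scatter(obs, pred, s=12, color="tab:blue", label="observations")
    ax.plot([0, 100], [0, 100], color="tab:blue", lw=1, label="perfect model")
    ax.plot(
        obs.to_numpy()[order],
        predictions["pi95_low (%)"].to_numpy()[order],
        color="tab:orange",
        lw=1,
        label="95% PI",
    )
    ax.plot(
        obs.to_numpy()[order],
        predictions["pi95_high (%)"].to_numpy()[order],
        color="tab:orange",
        lw=1,
    )
    ax.set_xlabel("Observed proportion of air on CT (%)")
    ax.set_ylabel("Predicted proportion of air (%)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
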