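"""End-to-end orchestration: counts -> traits -> models -> power -> report.

``run_pipeline`` executes the full analysis over either real inputs (COCO
detections + sample metadata CSV) or the synthetic generator, and writes
all result tables plus a run manifest to an output directory. Re-running
with the same configuration and seed reproduces identical tables: all
randomness flows from the single top-level seed, fanned out to named
substreams.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import counts_from_image, read_coco, read_sample_table, samples_to_frame
from .power import PowerTestSpec, pairwise_power_analysis, plan_sample_mass
from .simulate import GeneratorConfig, generate_experiment
from .stats import (
    anova_type1,
    estimate_variance_components,
    fit_proportion_model,
    pca_biplot,
    repeatability,
    select_count_model,
    twgss,
)
from .traits import DEFAULT_LAMBDA, build_trait_table

log = logging.getLogger("seedpe")

PCA_TRAITS = [
    "p_ip", "p_ws", "p_ss", "pe", "pe_ws", "pe_ss", "nopgs", "nopgm",
    "total_objects",
]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of (``detections_path`` + ``samples_path``) or
    ``simulation`` must be supplied; ``counts_are_predictions`` controls
    whether detection post-processing (confidence floor then NMS) is
    applied before counting.
    """

    output_dir: str = "results"
    seed: int = 0
    lambda_: float = DEFAULT_LAMBDA
    confidence_floor: float = 0.1
    nms_iou: float = 0.5
    counts_are_predictions: bool = True
    detections_path: str | None = None
    samples_path: str | None = None
    simulation: GeneratorConfig | None = None
    power: PowerTestSpec = field(default_factory=PowerTestSpec)
    holdout_fraction: float = 0.2

    def validate(self) -> None:
        real = self.detections_path is not None or self.samples_path is not None
        if real and self.simulation is not None:
            raise ValueError("supply either real inputs or a simulation config, not both")
        if real and (self.detections_path is None or self.samples_path is None):
            raise ValueError("real inputs need both detections_path and samples_path")
        if not real and self.simulation is None:
            self.simulation = GeneratorConfig()
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda must lie in [0,1]")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0,1)")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _jsonable(obj):
    """Recursively make a config dict JSON-serialisable (tuple keys -> str)."""
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "|".join(map(str, np.atleast_1d(k)))):
                _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim_seed = int(rng.integers(2**31))
    split_seed = int(rng.integers(2**31))

    stage = "inputs"
    try:
        if config.simulation is not None:
            samples = None
            frame, counts = generate_experiment(config.simulation, seed=sim_seed)
            samples_df = frame
            input_mode = "simulation"
        else:
            images = read_coco(config.detections_path)
            records, design = read_sample_table(config.samples_path)
            samples_df = samples_to_frame(records)
            counts = {}
            for im in images:
                if im.sample_id is None:
                    raise ValueError(f"image {im.image_id} lacks a sample_id link")
                counts[im.sample_id] = counts_from_image(
                    im,
                    is_prediction=config.counts_are_predictions,
                    confidence_floor=config.confidence_floor,
                    nms_iou=config.nms_iou,
                )
            input_mode = "real"
            log.info("design completeness: %s", design["status"])

        stage = "traits"
        table = build_trait_table(samples_df, counts, lambda_=config.lambda_)
        traits = table.frame
        if table.n_degenerate:
            log.warning(
                "%d degenerate sample(s) excluded: %s",
                table.n_degenerate, table.degenerate_ids,
            )
        _write(traits, out / "traits.csv")

        stage = "count_model"
        holdout = (
            np.random.default_rng(split_seed).random(len(traits))
            < config.holdout_fraction
        )
        count_fit, link_comparison = select_count_model(traits, holdout)
        _write(link_comparison, out / "count_model_links.csv")
        anova = anova_type1(traits).reset_index(names="term")
        _write(anova, out / "count_model_anova.csv")

        stage = "proportion_models"
        prop_summaries = []
        for resp in ("p_ip", "p_ws", "p_ss", "pe"):
            fit = fit_proportion_model(traits, resp)
            prop_summaries.append(
                {
                    "response": resp,
                    "lrt_stat": fit.extra["lrt_stat"],
                    "lrt_df": fit.extra["lrt_df"],
                    "lrt_p": fit.extra["lrt_p"],
                    "nagelkerke_r2": fit.extra["nagelkerke_r2"],
                    "separation": fit.extra["separation"],
                }
            )
        prop_df = pd.DataFrame(prop_summaries)
        _write(prop_df, out / "proportion_models.csv")

        stage = "repeatability"
        tr = traits.copy()
        tr["environment"] = (
            tr["processing_method"].astype(str) + ":" + tr["nominal_mass_g"].astype(str)
        )
        rep_rows = []
        for trait_name in ("pe", "pe_ws", "pe_ss"):
            vc = estimate_variance_components(tr, trait_name, "variety", "environment")
            rep_rows.append(
                {
                    "trait": trait_name,
                    "sigma2_g": vc.sigma2_g,
                    "sigma2_e": vc.sigma2_e,
                    "sigma2_gxe": vc.sigma2_gxe,
                    "sigma2_resid": vc.sigma2_resid,
                    "r": vc.r,
                    "e": vc.e,
                    "repeatability": repeatability(vc),
                }
            )
        rep_df = pd.DataFrame(rep_rows)
        _write(rep_df, out / "repeatability.csv")

        stage = "clustering"
        twgss_rows = []
        for method, gdf in traits.groupby("processing_method"):
            pts = gdf[["nopgs", "nopgm"]].to_numpy()
            twgss_rows.append(
                {
                    "processing_method": method,
                    "twgss": twgss(pts, gdf["variety"].to_numpy()),
                    "n": len(gdf),
                }
            )
        twgss_df = pd.DataFrame(twgss_rows)
        _write(twgss_df, out / "twgss.csv")

        stage = "pca"
        pca = pca_biplot(traits[PCA_TRAITS])
        _write(pca.scores.iloc[:, :2].assign(sample_id=traits["sample_id"].values),
               out / "pca_scores.csv")
        _write(pca.loadings.reset_index(names="trait"), out / "pca_loadings.csv")
        pca_var = pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(pca.variance_explained))],
             "variance_fraction": pca.variance_explained}
        )
        _write(pca_var, out / "pca_variance.csv")

        stage = "power"
        pairs, group_summary = pairwise_power_analysis(traits, config.power)
        _write(pairs, out / "power_pairs.csv")
        _write(group_summary, out / "power_groups.csv")
        mean_opg = float(traits["nopgs"].mean())
        plan = plan_sample_mass(
            objects_per_gram=round(mean_opg),
            target_diff=config.power.max_diff,
            center=0.5,
            spec=config.power,
        )
        _write(plan.per_gram, out / "power_plan.csv")
        _write(plan.curve.to_frame(), out / "power_curve_worst.csv")
        best = plan_sample_mass(
            objects_per_gram=round(mean_opg),
            target_diff=config.power.max_diff,
            center=0.85,
            spec=config.power,
        )
        _write(best.curve.to_frame(), out / "power_curve_best.csv")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    report = {
        "input_mode": input_mode,
        "n_samples": int(len(traits)),
        "n_degenerate": table.n_degenerate,
        "selected_count_link": count_fit.link,
        "count_model_rmse": count_fit.rmse,
        "count_model_mae": count_fit.mae,
        "repeatability": {r["trait"]: r["repeatability"] for r in rep_rows},
        "twgss": {r["processing_method"]: r["twgss"] for r in twgss_rows},
        "pca_var_first_two": float(pca.variance_explained[:2].sum()),
        "power_groups": group_summary.to_dict(orient="records"),
        "mean_objects_per_gram": mean_opg,
        "recommended_min_sample_mass_g": plan.recommended_grams,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    manifest = {
        "seed": config.seed,
        "substream_seeds": {"simulation": sim_seed, "holdout_split": split_seed},
        "config": _jsonable(asdict(config)),
        "versions": {
            "seedpe": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
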