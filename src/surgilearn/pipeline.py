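"""End-to-end pipeline: simulate -> features -> fit -> compare.

``run_pipeline`` drives a full synthetic study: generate the cohort and
recordings, extract the 12 gaze + 20 EEG features, fit the GLMM-LASSO
performance model (BIC-selected penalty) and the forward-selection
learning-rate model (after LOF outlier exclusion), compare skill levels,
and write every artifact plus a machine-readable run manifest to the
output directory.  Reruns with the same configuration and seed reproduce
byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_levels
from .models import (
    build_learning_rate_dataset,
    lambda_grid_search,
    lof_outliers,
    forward_select_loocv,
    model_metrics,
    standardize,
)
from .names import ALL_FEATURES, EXPERIENCE_FEATURES
from .simulate import SimulationConfig, simulate_study
from .tables import write_cohort_csv, write_feature_table, write_ground_truth_json

log = logging.getLogger("surgilearn")


@dataclass
class PipelineConfig:
    """Run-level configuration binding the stage parameter blocks.

    The ``simulation`` block feeds :class:`SimulationConfig`; model and
    comparison knobs sit beside it.  Unknown keys are rejected so typos
    fail loudly instead of silently using defaults.
    """

    out_dir: str = "run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    lof_neighbors: int = 10
    lof_threshold: float = 1.5
    n_lambdas: int = 20
    contrast_adjust: str = "tukey"
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``manifest.json``).  On stage failure a FAILED marker file is written
    and the exception re-raised."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    manifest: dict = {
        "package": "surgilearn",
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{k: getattr(config, k) for k in ("lof_neighbors", "lof_threshold", "n_lambdas", "contrast_adjust")},
            "simulation": dict(config.simulation),
        },
        "stages": {},
    }
    try:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)

        log.info("stage simulate: %d participants x %d attempts", sim_cfg.n_participants, sim_cfg.n_attempts)
        table, truth, cohort = simulate_study(sim_cfg)
        write_cohort_csv(cohort, out / "cohort.csv")
        write_feature_table(table, out / "features.csv")
        write_ground_truth_json(truth, out / "ground_truth.json")
        manifest["stages"]["simulate"] = {
            "rows": len(table),
            "participants": int(cohort.shape[0]),
            "features_sha256": _sha256(out / "features.csv"),
        }

        # ---- performance model ------------------------------------------
        feat_cols = [c for c in ALL_FEATURES if c in table.columns]
        std_table, scaling = standardize(table, feat_cols)
        fit = lambda_grid_search(
            std_table,
            response="score",
            groups="participant_id",
            features=[c for c in feat_cols if c in std_table.columns],
        )
        refit = fit.post_refit.set_index("predictor") if fit.post_refit is not None else None
        rows = []
        for f in fit.features:
            beta = fit.fixed_coefficients[f]
            row = {"predictor": f, "estimate": beta, "selected": int(beta != 0.0)}
            if refit is not None and f in refit.index:
                row["refit_estimate"] = float(refit.loc[f, "estimate"])
                row["std_error"] = float(refit.loc[f, "std_error"])
                row["p_value"] = float(refit.loc[f, "p_value"])
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "performance_fit.csv", index=False)
        perf_metrics = model_metrics(std_table["score"], fit.predict(std_table))
        perf_block = {
            **perf_metrics,
            "n_observations": fit.n_obs,
            "lambda": fit.lam,
            "bic": fit.bic,
            "support_size": len(fit.selected_support),
        }
        (out / "performance_metrics.json").write_text(json.dumps(perf_block, indent=2, sort_keys=True))
        manifest["stages"]["fit_performance"] = {
            "predictor_rows": len(rows),
            "support_size": len(fit.selected_support),
        }

        # ---- learning-rate model ----------------------------------------
        lr = build_learning_rate_dataset(table)
        lr_feat = ["baseline_score"] + [c for c in ALL_FEATURES if c in lr.columns]
        lr_std, _ = standardize(lr, lr_feat + ["learning_rate"])
        cand = [c for c in lr_feat if c in lr_std.columns]
        if len(lr_std) > config.lof_neighbors:
            scores, excluded = lof_outliers(
                lr_std[cand + ["learning_rate"]].to_numpy(),
                k=config.lof_neighbors,
                threshold=config.lof_threshold,
            )
            for pid, sc in zip(lr_std.loc[excluded, "participant_id"], scores[excluded]):
                log.info("excluded participant %s (reason=LOF score %.2f)", pid, sc)
            lr_std = lr_std.loc[~excluded].reset_index(drop=True)
        else:
            excluded = np.zeros(len(lr_std), dtype=bool)
        lr_fit = forward_select_loocv(lr_std, "learning_rate", cand)
        lr_rows = [
            {
                "predictor": nm,
                "estimate": lr_fit.coefficients[nm],
                "ci_low": lr_fit.conf_int[nm][0],
                "ci_high": lr_fit.conf_int[nm][1],
                "p_value": lr_fit.p_values[nm],
            }
            for nm in ["intercept", *lr_fit.selected_features]
        ]
        pd.DataFrame(lr_rows).to_csv(out / "learning_rate_fit.csv", index=False)
        lr_block = {
            "r_squared": lr_fit.r_squared,
            "loocv_mae": lr_fit.loocv_mae,
            "loocv_rmse": lr_fit.loocv_rmse,
            "n_observations": lr_fit.n_observations,
            "n_excluded_lof": int(excluded.sum()),
        }
        (out / "learning_rate_metrics.json").write_text(json.dumps(lr_block, indent=2, sort_keys=True))
        manifest["stages"]["fit_learning_rate"] = {
            "rows": int(lr_fit.n_observations),
            "selected": lr_fit.selected_features,
            "excluded_lof": int(excluded.sum()),
        }

        # ---- level comparison -------------------------------------------
        level_table = table.merge(cohort[["participant_id", "level"]], on="participant_id")
        comp = compare_levels(level_table, adjust=config.contrast_adjust)
        comp_rows = comp.contrasts.copy()
        comp_rows["kind"] = "contrast"
        lsm_rows = comp.lsm.copy()
        lsm_rows["kind"] = "lsm"
        pd.concat([comp_rows, lsm_rows]).to_csv(out / "level_comparison.csv", index=False)
        manifest["stages"]["compare_levels"] = {
            "anova_f": round(float(comp.anova_f), 10),
            "anova_p": round(float(comp.anova_p), 10),
            "n_contrasts": len(comp.contrasts),
        }
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
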