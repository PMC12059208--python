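"""End-to-end study analysis: filter -> diversity -> join -> models -> Moran.

The orchestration is deliberately thin: every stage is a call into one of the
analysis modules, wrapped so a failure surfaces as a stage-named error while
partial outputs already written stay on disk next to a failure marker.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (
    LassoResult,
    correlation_matrix,
    cv_select_lambda,
    per_species_analysis,
    significance_label,
    univariate_ols,
)
from .diversity import diversity_table
from .errors import PipelineStageError
from .marker_data import MarkerMatrix, filter_dataset, read_marker_matrix
from .env_grid import read_env_table
from .spatial import build_weights, knn_neighbors, morans_i

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full study run; defaults mirror the reference analysis."""

    marker_paths: list[str] = field(default_factory=list)
    env_table_path: str | None = None
    out_dir: str = "divscape_out"
    min_individuals: int = 5
    min_populations: int = 5
    species_threshold: int = 20
    cv_folds: int = 1000
    grid_size: int = 100
    lambda_min_ratio: float = 1e-4
    k_neighbors: int = 4
    weight_style: str = "row-standardized"
    distance_metric: str = "haversine"
    moran_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _lasso_summary(res: LassoResult) -> dict:
    return {
        "lambda_opt": res.lambda_opt,
        "n_nonzero": res.n_nonzero,
        "frac_var_explained": res.frac_var_explained,
        "pct_var_explained": round(100.0 * res.frac_var_explained, 2),
        "n_folds": res.n_folds,
        "n_obs": res.n_obs,
        "best_predictor": res.best_predictor() if res.n_nonzero else None,
        "nonzero_coefficients": {
            k: float(v) for k, v in res.nonzero.items()
        },
        "intercept": res.intercept,
    }


def run_study_analysis(
    config: RunConfig,
    markers: dict[str, MarkerMatrix] | None = None,
    env_table: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis chain and write the report bundle.

    ``markers``/``env_table`` may be passed in memory (e.g. from the
    synthetic generator); otherwise they are read from the configured paths.
    Returns a dict with the main result objects; all tables plus a JSON
    manifest land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failure_marker = out / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()

    def stage(name: str):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                failure_marker.write_text(f"{name}: {exc}\n")
                raise PipelineStageError(name, str(exc)) from exc
        return deco

    def load_markers():
        if markers is not None:
            return dict(markers)
        loaded = {}
        for p in config.marker_paths:
            m = read_marker_matrix(p)
            loaded[m.species or Path(p).stem] = m
        if not loaded:
            raise ValueError("no marker matrices provided")
        return loaded

    raw_markers = stage("read_markers")(load_markers)
    filtered = stage("filter")(lambda: {
        sp: filter_dataset(m, config.min_individuals, config.min_populations)
        for sp, m in raw_markers.items()
    })

    def build_diversity():
        tables = [diversity_table(m) for m in filtered.values()]
        return pd.concat(tables, ignore_index=True)

    div = stage("diversity")(build_diversity)

    def load_env():
        env = env_table if env_table is not None else read_env_table(
            config.env_table_path)
        merged = div.merge(env.drop(columns=["species"], errors="ignore"),
                           on="population_id", how="left", validate="1:1")
        missing = merged["lon"].isna().sum() if "lon" in merged else 0
        if missing:
            logger.warning("%d populations lack environmental rows", missing)
        return merged

    joined = stage("env_join")(load_env)
    env_cols = [c for c in joined.columns
                if c not in {"species", "population_id", "n_individuals",
                             "n_loci_used", "Hs", "rarity", "lon", "lat"}]

    corr = stage("correlation")(
        lambda: correlation_matrix(joined[["Hs", "rarity"]], joined[env_cols]))

    lasso_results: dict[str, LassoResult] = {}
    for response in ("Hs", "rarity"):
        lasso_results[response] = stage(f"lasso_{response}")(
            lambda r=response: cv_select_lambda(
                joined[env_cols], joined[r],
                folds=config.cv_folds, grid_size=config.grid_size,
                lambda_min_ratio=config.lambda_min_ratio, seed=config.seed,
            ))

    def pick_best():
        res = lasso_results["Hs"]
        if res.n_nonzero:
            return res.best_predictor()
        # CV chose the empty model; fall back to the first predictor entering
        # the path so the univariate follow-up stays well-defined
        from .assoc import first_active_predictor, lasso_fit
        logger.warning("CV selected the empty model for Hs; using the first "
                       "predictor entering the path")
        return first_active_predictor(
            lasso_fit(joined[env_cols], joined["Hs"],
                      grid_size=config.grid_size,
                      lambda_min_ratio=config.lambda_min_ratio))

    best = stage("best_predictor")(pick_best)

    pooled = stage("pooled_ols")(lambda: {
        r: univariate_ols(joined[r], joined[best]) for r in ("Hs", "rarity")
    })

    per_species = stage("per_species_ols")(lambda: per_species_analysis(
        joined, predictor=best, min_populations=config.species_threshold))

    def moran_stage():
        rows = []
        for sp, df in joined.groupby("species", sort=True):
            if len(df) <= config.k_neighbors:
                logger.warning("species %r has too few populations for k=%d "
                               "neighbours; skipped", sp, config.k_neighbors)
                continue
            nb = knn_neighbors(df[["lon", "lat"]].to_numpy(),
                               k=config.k_neighbors,
                               metric=config.distance_metric)
            w = build_weights(nb, style=config.weight_style)
            for var in ("Hs", best):
                res = morans_i(df[var].to_numpy(), w,
                               n_permutations=config.moran_permutations,
                               seed=config.seed)
                rows.append({"species": sp, "variable": var, "I": res.I,
                             "expected": res.expected, "p_value": res.p_value,
                             "n_permutations": res.n_permutations})
        return pd.DataFrame(rows)

    moran = stage("moran")(moran_stage)

    def write_outputs():
        joined.to_csv(out / "diversity_env.csv", index=False)
        corr.to_csv(out / "correlations.csv")
        for r, res in lasso_results.items():
            pd.DataFrame({"lambda": res.lambda_grid,
                          "cv_error": res.cv_error}).to_csv(
                out / f"lasso_{r}_cv_path.csv", index=False)
            with open(out / f"lasso_{r}.json", "w") as fh:
                json.dump(_lasso_summary(res), fh, indent=2, sort_keys=True)
        pooled_df = pd.DataFrame([
            {"response": r, "predictor": best, "slope": o.slope,
             "intercept": o.intercept, "r_squared": o.r_squared,
             "p_value": o.p_value, "n": o.n,
             "significance": significance_label(o.p_value)}
            for r, o in pooled.items()
        ])
        pooled_df.to_csv(out / "ols_pooled.csv", index=False)
        rows = []
        for sp, by_resp in per_species.items():
            for r, o in by_resp.items():
                rows.append({"species": sp, "response": r, "predictor": best,
                             "slope": o.slope, "r_squared": o.r_squared,
                             "p_value": o.p_value, "n": o.n,
                             "significance": significance_label(o.p_value)})
        pd.DataFrame(rows).to_csv(out / "ols_per_species.csv", index=False)
        moran.to_csv(out / "moran.csv", index=False)
        manifest = {
            "settings": asdict(config),
            "inputs": {
                "marker_paths": list(config.marker_paths),
                "env_table_path": config.env_table_path,
                "in_memory": markers is not None,
                "n_species": len(filtered),
                "n_populations": int(len(joined)),
            },
            "best_predictor": best,
            "seed": config.seed,
            "versions": {
                "divscape": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "note": "no multiple-testing correction applied across the "
                    "per-species tests",
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage("write_outputs")(write_outputs)
    return {
        "diversity_env": joined,
        "correlations": corr,
        "lasso": lasso_results,
        "best_predictor": best,
        "pooled_ols": pooled,
        "per_species_ols": per_species,
        "moran": moran,
        "out_dir": str(out),
    }
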