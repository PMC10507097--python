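"""End-to-end orchestration: regimes → environment metrics → growth models.

:func:`run_pipeline` composes the whole analysis from one configuration on
synthetic inputs: it generates template field seasons, compiles the averaged
and single-season chamber regimes, scores all pairwise environment
similarities, fits the logistic growth model with environment contrasts,
clusters the genotype × environment height matrix at the mean field
inflection time, models tasseling, and runs repeatability and the positional
variance decomposition.  The report bundle is machine-readable JSON; every
payload carries the producing operation and the configuration hash, and
reruns with the same config and seed are byte-identical (wall-clock times go
only to the side log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import envmetrics, growth, regime as regime_mod, simulate
from .regime import RegimeConfig, compile_season_regime, export_regime, regime_to_series

logger = logging.getLogger("phenoclim")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "phenoclim_report"
    weather: simulate.WeatherGenConfig = field(
        default_factory=lambda: simulate.WeatherGenConfig(n_years=4)
    )
    regime: RegimeConfig = field(default_factory=RegimeConfig)
    phenotypes: simulate.PhenoGenConfig = field(
        default_factory=simulate.PhenoGenConfig
    )
    tassel: simulate.TasselGenConfig = field(default_factory=simulate.TasselGenConfig)
    homogeneity: simulate.HomogeneityGenConfig = field(
        default_factory=simulate.HomogeneityGenConfig
    )
    repeatability: simulate.RepeatabilityGenConfig = field(
        default_factory=simulate.RepeatabilityGenConfig
    )
    trait: str = "plant_height"
    n_params: int = 3
    time_axis: str = "das"
    n_boot: int = 200
    #: "means" uses per-genotype arithmetic means as the per-date estimates
    #: (identical to the mixed-model BLUEs on balanced data and much faster);
    #: "mixed" runs the full per-date REML model.
    blue_method: str = "means"


def _config_hash(config: PipelineConfig) -> str:
    fields = asdict(config)
    fields.pop("out_dir", None)  # the destination is not part of the analysis
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj):
        return asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write(out_dir: Path, name: str, operation: str, cfg_hash: str, payload) -> dict:
    doc = {"operation": operation, "config_hash": cfg_hash, "result": payload}
    path = out_dir / name
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_jsonable)
    return doc


def _blues(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    if config.blue_method == "means":
        out = (
            table.groupby(["environment", "genotype", "das"])[config.trait]
            .mean()
            .rename("value")
            .reset_index()
        )
        return out
    # the synthetic tables carry the field design's positional factors
    designs = {
        env: growth.DESIGNS["field"] for env in table["environment"].unique()
    }
    return growth.blues_over_time(table, designs, config.trait)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    cfg = config or PipelineConfig()
    cfg_hash = _config_hash(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = [f"config_hash={cfg_hash}", f"seed={cfg.seed}"]
    report: dict = {"config_hash": cfg_hash, "seed": cfg.seed}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                run_log.append(f"{name}: FAILED ({exc})")
                (out_dir / "run.log").write_text("\n".join(run_log) + "\n")
                raise StageError(name, exc) from exc
            run_log.append(f"{name}: ok ({time.perf_counter() - t0:.2f}s)")
            return out

        return deco

    # 1 — weather templates + chamber regimes
    @stage("weather")
    def years():
        return simulate.generate_weather(cfg.weather, seed=cfg.seed)

    @stage("regimes")
    def regimes():
        avg = compile_season_regime("averaged", years=years[:3], config=cfg.regime)
        sim = compile_season_regime(
            "single_season", template_year=years[0], config=cfg.regime
        )
        export_regime(avg, out_dir / "regime_averaged.csv")
        export_regime(sim, out_dir / "regime_single_season.csv")
        return avg, sim

    avg_regime, sim_regime = regimes

    # 2 — seven environments and all pairwise comparisons
    @stage("env_metrics")
    def comparisons():
        envs = {y.environment_id.replace("synthetic", "field"): y for y in years}
        envs["glasshouse"] = simulate.glasshouse_series(
            season_days=cfg.weather.season_days
        )
        envs["chamber_avg"] = regime_to_series(avg_regime, "chamber_avg")
        envs["chamber_sim"] = regime_to_series(sim_regime, "chamber_sim")
        names = list(envs)
        out = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                cmp_ = envmetrics.compare_environments(
                    envs[names[i]], envs[names[j]], "temperature"
                )
                out.append(cmp_.to_dict())
        return out

    report["comparisons"] = _write(
        out_dir, "comparisons.json", "compare_environments", cfg_hash, comparisons
    )["result"]

    # 3 — growth model on per-date genotype estimates
    @stage("growth_fit")
    def fitted():
        table, truth = simulate.generate_phenotypes(cfg.phenotypes, seed=cfg.seed)
        blues = _blues(table, cfg)
        fit = growth.fit_logistic_population(
            blues, n_params=cfg.n_params, time_axis=cfg.time_axis
        )
        contrasts = growth.parameter_contrasts(fit)
        return table, truth, fit, contrasts

    table, truth, fit, contrasts = fitted
    report["fit"] = _write(
        out_dir,
        "fit.json",
        "fit_logistic_population",
        cfg_hash,
        {
            "fixed": fit.fixed,
            "random": fit.random,
            "residual_sd": fit.residual_sd,
            "variance_components": {
                p: {"genotype": v[0], "stage2": v[1]}
                for p, v in fit.variance_components.items()
            },
            "diagnostics": fit.diagnostics,
            "log": fit.log,
            "contrasts": contrasts.to_dict(orient="records"),
        },
    )["result"]

    # 4 — clustering at the mean field-like inflection time
    @stage("clustering")
    def clustering():
        field_envs = [e for e in fit.environments if e.startswith("field")]
        x_ref = float(np.mean([fit.fixed["xmid"][e] for e in field_envs or fit.environments]))
        mat = growth.height_matrix_at(fit, x_ref)
        clust = growth.cluster_environments(mat)
        return x_ref, clust

    x_ref, clust = clustering
    report["clustering"] = _write(
        out_dir,
        "clustering.json",
        "cluster_environments",
        cfg_hash,
        {
            "reference_time": x_ref,
            "leaf_order": clust.leaf_order,
            "merge_heights": clust.merge_heights.tolist(),
            "two_clusters": clust.cut(2),
        },
    )["result"]

    # 5 — tasseling
    @stage("tassel")
    def tassel():
        data = simulate.generate_tassel(cfg.tassel, seed=cfg.seed)
        return growth.fit_tassel_model(data)

    report["tassel"] = _write(
        out_dir,
        "tassel.json",
        "fit_tassel_model",
        cfg_hash,
        {
            "params": tassel.params.to_dict(orient="index"),
            "anova_fitted": tassel.anova_fitted.to_dict(),
            "anova_residuals": tassel.anova_residuals.to_dict(),
            "log": tassel.log,
        },
    )["result"]

    # 6 — repeatability and positional variance decomposition
    @stage("repeatability")
    def rep():
        rep_table = simulate.generate_repeatability_table(
            cfg.repeatability, seed=cfg.seed
        )
        return growth.repeatability(rep_table, cfg.trait)

    report["repeatability"] = _write(
        out_dir,
        "repeatability.json",
        "repeatability",
        cfg_hash,
        {
            "R_genotype": rep.repeatability,
            "r2_marginal": rep.r2_marginal,
            "r2_conditional": rep.r2_conditional,
            "variance_components": rep.variance_components,
        },
    )["result"]

    @stage("variance_decomposition")
    def decomp():
        hom = simulate.generate_homogeneity_trial(cfg.homogeneity, seed=cfg.seed)
        return growth.variance_decomposition(
            hom, cfg.trait, n_boot=cfg.n_boot, seed=cfg.seed
        )

    report["variance_decomposition"] = _write(
        out_dir,
        "decomposition.json",
        "variance_decomposition",
        cfg_hash,
        {"shares": decomp.shares, "ci": decomp.ci, "n_boot": decomp.n_boot},
    )["result"]

    # summary
    summary = {
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "n_environment_pairs": len(report["comparisons"]),
        "xmid_by_environment": fit.fixed["xmid"],
        "clustering_leaf_order": clust.leaf_order,
        "repeatability": rep.repeatability,
        "genotype_variance_share": decomp.shares["genotype"],
        "regime_clamp_events": {
            "averaged": avg_regime.clamp_events,
            "single_season": sim_regime.clamp_events,
        },
        "model_reduction_log": fit.log,
    }
    report["summary"] = _write(out_dir, "summary.json", "run_pipeline", cfg_hash, summary)[
        "result"
    ]
    (out_dir / "run.log").write_text("\n".join(run_log) + "\n")
    return report
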