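"""End-to-end orchestration: spatial profiles → model selection → ranking.

``run_pipeline`` reproduces the full analysis from a cave table on disk or
a simulation config: per-response multi-scale autocorrelation profiles, the
full mixed model, LRT backward elimination plus interaction search, final
model tables, residual correlograms, the indicator-score relevance ranking
and its comparison with reported relevance. Every artifact is written under
one output directory with a manifest recording the exact config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import relevance as rel
from .formula import ModelSpec
from .io import load_cave_table, save_cave_table, validate_cave_table
from .selection import (SelectionTrace, backward_eliminate,
                        interaction_search, residual_profile)
from .simulate import SimulationConfig, simulate_landscape
from .spatial import scale_profile

__all__ = ["PipelineConfig", "run_pipeline", "collinearity_check",
           "default_predictors"]

log = logging.getLogger("cavenet")

DEFAULT_RESPONSES = ("richness", "rare_troglobites", "troglobites", "bat_population")

#: Candidate predictors: every meaningful cave attribute; the response's own
#: indicator is excluded per response.
CANDIDATE_PREDICTORS = ("log(area_m2)", "guano", "detritus", "roots",
                        "water_reservoirs", "percolating_water", "bat_population")


def default_predictors(response: str) -> tuple[str, ...]:
    return tuple(p for p in CANDIDATE_PREDICTORS if p != response)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    schema: dict | None = None
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    predictors: dict = field(default_factory=dict)  # response -> term tuple
    alpha: float = 0.05
    n_bands: int = 20
    style: str = "W"
    weights: dict = field(default_factory=lambda: dict(rel.DEFAULT_WEIGHTS))
    group: str = "report_id"
    outdir: str = "cavenet_out"
    seed: int = 0
    make_plots: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_path or simulation")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.style not in ("W", "B", "C"):
            raise ValueError("style must be one of W/B/C")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["responses"] = list(self.responses)
        d["predictors"] = {k: list(v) for k, v in self.predictors.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "responses" in d:
            d["responses"] = tuple(d["responses"])
        if "predictors" in d:
            d["predictors"] = {k: tuple(v) for k, v in d["predictors"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def collinearity_check(table: pd.DataFrame) -> dict:
    """PCA of the correlation matrix of log length / area / volume.

    Returns per-component variance shares; a first component explaining
    ~95% of variance justifies collapsing the three size measures into one
    proxy (area).
    """
    cols = ["length_m", "area_m2", "volume_m3"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"size columns missing: {missing}")
    sub = table[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete size rows")
    if (sub <= 0).any().any():
        raise ValueError("size measures must be positive for the log transform")
    logs = np.log(sub.to_numpy(dtype=float))
    sd = logs.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant size column; PCA undefined")
    corr = np.corrcoef(logs, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    shares = eigvals / eigvals.sum()
    return {
        "explained_share": shares.tolist(),
        "first_component_share": float(shares[0]),
        "n": int(len(sub)),
        "advice": "use area_m2 as the single cave-size proxy"
                  if shares[0] > 0.8 else "size measures are not collinear",
    }


def _model_stage(table: pd.DataFrame, response: str, predictors, config,
                 outdir: Path, manifest: dict) -> SelectionTrace | None:
    family = "gaussian" if response == "richness" else "bernoulli"
    spec = ModelSpec(response=response, family=family,
                     fixed_terms=tuple(predictors), group=config.group)
    stage: dict = {"response": response, "family": family,
                   "predictors": list(predictors)}
    manifest["models"][response] = stage
    try:
        trace = backward_eliminate(spec, table, alpha=config.alpha)
        trace = interaction_search(trace, table, alpha=config.alpha)
    except Exception as exc:
        stage["error"] = str(exc)
        log.error("model selection failed for %s: %s", response, exc)
        return None
    stage["n_obs"] = int(trace.final_model.n_obs)
    stage["final_terms"] = list(trace.final_spec.all_terms)

    (outdir / f"trace_{response}.json").write_text(
        json.dumps(trace.to_dict(), indent=2))
    trace.final_model.summary_frame().to_csv(
        outdir / f"model_{response}.csv", index=False)
    stage["trace"] = f"trace_{response}.json"
    stage["model_table"] = f"model_{response}.csv"

    rows = trace.final_model.row_index
    coords = table.loc[rows, ["x_m", "y_m"]].to_numpy(dtype=float)
    try:
        rprof = residual_profile(trace.final_model, coords,
                                 n_bands=config.n_bands, style=config.style)
        rprof.to_frame().to_csv(outdir / f"residual_profile_{response}.csv",
                                index=False)
        stage["residual_profile"] = f"residual_profile_{response}.csv"
    except ValueError as exc:
        stage["residual_profile_error"] = str(exc)
    return trace


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "outputs": [],
                      "profiles": {}, "models": {}, "errors": []}

    if config.simulation is not None:
        sim = config.simulation
        table = simulate_landscape(sim)
        save_cave_table(table, outdir / "landscape.csv")
        manifest["outputs"].append("landscape.csv")
        manifest["validation"] = validate_cave_table(table)
    else:
        table, report = load_cave_table(config.input_path, schema=config.schema)
        manifest["validation"] = report

    for resp in config.responses:
        if resp not in table.columns:
            raise KeyError(f"configured response column {resp!r} not in table")
    for resp, preds in config.predictors.items():
        for p in preds:
            from .formula import term_source_columns
            for col in term_source_columns(p):
                if col not in table.columns:
                    raise KeyError(
                        f"configured predictor column {col!r} not in table")

    try:
        manifest["collinearity"] = collinearity_check(table)
    except (KeyError, ValueError) as exc:
        manifest["errors"].append(f"collinearity check: {exc}")

    coords_all = table[["x_m", "y_m"]].to_numpy(dtype=float)

    # ---- per-response autocorrelation profiles -------------------------------
    for resp in config.responses:
        stat = "moran" if resp == "richness" else "joincount"
        vals = pd.to_numeric(table[resp], errors="coerce")
        ok = vals.notna().to_numpy()
        try:
            prof = scale_profile(coords_all[ok], vals[ok].to_numpy(dtype=float),
                                 stat=stat, n_bands=config.n_bands,
                                 style=config.style)
            fname = f"profile_{resp}.csv"
            prof.to_frame().to_csv(outdir / fname, index=False)
            manifest["profiles"][resp] = fname
            if config.make_plots:
                from .plots import plot_correlogram
                plot_correlogram(prof, title=resp,
                                 path=outdir / f"profile_{resp}.png")
                manifest["outputs"].append(f"profile_{resp}.png")
        except ValueError as exc:
            manifest["errors"].append(f"profile {resp}: {exc}")

    # ---- model selection -----------------------------------------------------
    for resp in config.responses:
        preds = config.predictors.get(resp, default_predictors(resp))
        _model_stage(table, resp, preds, config, outdir, manifest)

    # ---- relevance ranking ---------------------------------------------------
    try:
        scores = rel.score_caves(table, weights=config.weights)
        ranking = rel.rank_caves(scores)
        ranking.table.to_csv(outdir / "ranking.csv", index=False)
        manifest["outputs"].append("ranking.csv")
        summary = {
            "richness_threshold": ranking.richness_threshold,
            "category_shares": ranking.category_shares,
            "offset_share": ranking.offset_share,
            "n_scored": ranking.n_scored,
            "n_missing_score": ranking.n_missing,
        }
        if "reported_relevance" in table.columns:
            comp = rel.compare_to_reported(ranking, table)
            comp.crosstab.to_csv(outdir / "crosstab.csv")
            manifest["outputs"].append("crosstab.csv")
            summary.update(
                reported_high_or_above_share=comp.reported_high_or_above_share,
                median_area_score3plus=comp.median_area_score3plus,
                association_chi2=comp.chi2, association_df=comp.chi2_df,
            )
            if config.make_plots:
                from .plots import plot_indicator_areas
                plot_indicator_areas(ranking, table,
                                     path=outdir / "indicators_vs_area.png")
                manifest["outputs"].append("indicators_vs_area.png")
        (outdir / "ranking_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["outputs"].append("ranking_summary.json")
        manifest["ranking"] = summary
    except (KeyError, ValueError) as exc:
        manifest["errors"].append(f"ranking: {exc}")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
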