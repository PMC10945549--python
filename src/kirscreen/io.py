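"""Readers, writers, configuration and the full-pipeline driver.

All tabular inputs are TSV/CSV with a header row of kinase/cytokine ids and
a first column of drug ids. Validation failures name the offending cell.
Fitted models serialize to one JSON report per cytokine; the pipeline
writes a manifest (config hash, seed, per-stage artifact paths) so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kir_core import (ElasticNetSolution, KiRModel, ModelQuality,
                       fit_kir_models, predict_out_of_panel)
from . import drug_explorer, network_explorer, screen_stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"

def read_matrix(path, kind: str = "drug_target") -> pd.DataFrame:
    """Read and validate a drugs x kinases (``kind='drug_target'``) or
    drugs x cytokines (``kind='response'``) matrix.

    Duplicate ids, blank cells and non-numeric cells are rejected with the
    offending row/column coordinates. Drug-target values must be finite and
    >= 0 (residual activity in percent); responses must be finite.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate drug id(s): {dup}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate column id(s): {dup}")
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[i, j]
        what = "blank" if cell == "" else f"non-numeric ({cell!r})"
        raise ValueError(
            f"{path}: {what} cell at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}")
    num = num.astype(float)
    if not np.isfinite(num.to_numpy()).all():
        i, j = np.argwhere(~np.isfinite(num.to_numpy()))[0]
        raise ValueError(f"{path}: non-finite cell at row {num.index[i]!r}, "
                         f"column {num.columns[j]!r}")
    if kind == "drug_target" and (num.to_numpy() < 0).any():
        i, j = np.argwhere(num.to_numpy() < 0)[0]
        raise ValueError(
            f"{path}: negative residual activity at row {num.index[i]!r}, "
            f"column {num.columns[j]!r}")
    return num


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path))


def read_secretome(path) -> pd.DataFrame:
    """Long-format replicate table (factor, condition, replicate, value)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in ("factor", "condition", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if "fda_approved" in df.columns:
        df["fda_approved"] = df["fda_approved"].astype(str).str.lower().isin(
            ("true", "1", "yes"))
    return df


# ---------------------------------------------------------------------------
# model reports
# ---------------------------------------------------------------------------

def model_to_dict(model: KiRModel) -> dict:
    best = model.best_solution
    return {
        "cytokine": model.cytokine_id,
        "alpha_grid": list(model.alpha_grid),
        "solutions": [
            {
                "alpha": s.alpha, "lambda": s.lam, "intercept": s.intercept,
                "loocv_mse": s.loocv_mse,
                "coefficients": {k: float(v) for k, v in s.coefficients.items()
                                 if v != 0.0},
            }
            for s in model.solutions
        ],
        "kinase_ids": list(model.solutions[0].coefficients.index),
        "best_alpha": best.alpha,
        "quality": {
            "nrmse": model.quality.nrmse,
            "pearson_r": model.quality.pearson_r,
            "accepted": bool(model.quality.accepted),
            "reason": model.quality.reason,
        },
        "informative_kinases": sorted(model.informative_kinases),
    }


def model_from_dict(d: dict) -> KiRModel:
    kinases = d["kinase_ids"]
    sols = []
    for s in d["solutions"]:
        coef = pd.Series(0.0, index=kinases)
        for k, v in s["coefficients"].items():
            coef[k] = v
        sols.append(ElasticNetSolution(
            alpha=s["alpha"], lam=s["lambda"], intercept=s["intercept"],
            coefficients=coef, loocv_mse=s["loocv_mse"],
            loocv_predictions=np.empty(0)))
    q = d["quality"]
    model = KiRModel(cytokine_id=d["cytokine"], solutions=sols)
    model.quality = ModelQuality(nrmse=q["nrmse"], pearson_r=q["pearson_r"],
                                 accepted=q["accepted"],
                                 reason=q.get("reason", ""))
    model.informative_kinases = set(d["informative_kinases"])
    return model


def write_models(models: dict[str, KiRModel], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cyt in sorted(models):
        p = outdir / f"{cyt}_model.json"
        p.write_text(json.dumps(model_to_dict(models[cyt]), indent=1,
                                allow_nan=True))
        paths.append(p)
    return paths


def read_models(models_dir) -> dict[str, KiRModel]:
    models = {}
    for p in sorted(Path(models_dir).glob("*_model.json")):
        m = model_from_dict(json.loads(p.read_text()))
        models[m.cytokine_id] = m
    if not models:
        raise FileNotFoundError(f"no *_model.json under {models_dir}")
    return models


# ---------------------------------------------------------------------------
# pipeline configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a full run needs; analysis thresholds live here, never
    hard-coded downstream."""

    x_screen: str = ""
    y_screen: str = ""
    x_panel: str = ""
    secretome: str = ""
    annotations: str = ""
    reference_network: str = ""
    outdir: str = "kirscreen_out"
    # analysis parameters
    n_alphas: int = 11
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    nrmse_threshold: float = 0.1
    pearson_threshold: float = 0.85
    inhibition_threshold: float = 50.0
    fdr: float = 0.05
    max_hops: int = 2
    top_k: int = 10
    cytokines_of_interest: list = dataclasses.field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.nrmse_threshold:
            raise ValueError("nrmse_threshold must be positive")
        if not -1 <= self.pearson_threshold <= 1:
            raise ValueError("pearson_threshold must be in [-1, 1]")
        if not 0 < self.inhibition_threshold <= 100:
            raise ValueError("inhibition_threshold must be in (0, 100]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _alpha_grid(n: int) -> tuple[float, ...]:
    return tuple(np.round(np.linspace(0.0, 1.0, n), 10))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """diff -> fit -> predict -> rank -> kinase matrix -> networks.

    Stages without configured inputs are skipped and recorded as such; any
    stage failure aborts with the stage name and cause. Returns the run
    manifest (also written to ``outdir/manifest.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": dataclasses.asdict(cfg),
                      "config_hash": cfg.digest(), "seed": cfg.seed,
                      "stages": {}}
    stage = "configure"
    try:
        if not cfg.x_screen or not cfg.y_screen:
            raise FileNotFoundError(
                "x_screen and y_screen are required inputs")

        if cfg.secretome:
            stage = "diff"
            raw = read_secretome(cfg.secretome)
            diff = screen_stats.differential_secretion(
                raw, "control", "LPS", fdr=cfg.fdr)
            p = outdir / "differential_secretion.tsv"
            diff.to_csv(p, sep="\t")
            manifest["stages"]["diff"] = {
                "output": str(p), "n_significant": int(diff["significant"].sum())}
        else:
            manifest["stages"]["diff"] = {"skipped": "no secretome input"}

        stage = "fit"
        X = read_matrix(cfg.x_screen, "drug_target")
        Y = read_matrix(cfg.y_screen, "response")
        models = fit_kir_models(
            X, Y, alpha_grid=_alpha_grid(cfg.n_alphas),
            n_lambdas=cfg.n_lambdas, lambda_min_ratio=cfg.lambda_min_ratio,
            nrmse_threshold=cfg.nrmse_threshold,
            pearson_threshold=cfg.pearson_threshold)
        model_paths = write_models(models, outdir / "models")
        accepted = sorted(c for c, m in models.items() if m.quality.accepted)
        manifest["stages"]["fit"] = {
            "outputs": [str(p) for p in model_paths],
            "n_models": len(models), "n_accepted": len(accepted),
            # hits are aggregated over gate-passing models only
            "n_informative_kinases": len(set().union(
                *(models[c].informative_kinases for c in accepted), set())),
        }

        stage = "kinase_matrix"
        mat = drug_explorer.build_kinase_cytokine_matrix(
            models, kinase_ids=list(X.columns))
        p = outdir / "kinase_cytokine_matrix.tsv"
        mat.to_csv(p, sep="\t")
        manifest["stages"]["kinase_matrix"] = {"output": str(p)}

        if cfg.x_panel:
            stage = "predict"
            X_panel = read_matrix(cfg.x_panel, "drug_target")
            pred = predict_out_of_panel(models, X_panel)
            p = outdir / "panel_predictions.tsv"
            flat = pred.stack().rename("predicted_level").rename_axis(
                ["drug", "cytokine"]).reset_index()
            flat.to_csv(p, sep="\t", index=False)
            manifest["stages"]["predict"] = {
                "output": str(p), "n_drugs": len(pred),
                "n_cytokines": pred.shape[1]}

            stage = "rank"
            eff = drug_explorer.compute_efficacy(pred)
            selection = cfg.cytokines_of_interest or list(eff.columns)
            selection = [c for c in selection if c in eff.columns]
            ann = read_annotations(cfg.annotations) if cfg.annotations else None
            chart, table = drug_explorer.rank_drugs(
                eff, selection, k=cfg.top_k,
                inhibition_threshold=cfg.inhibition_threshold,
                X_panel=X_panel, annotations=ann)
            p1, p2 = outdir / "drug_ranking_top.tsv", outdir / "drug_ranking_full.tsv"
            chart.to_csv(p1, sep="\t")
            table.to_csv(p2, sep="\t")
            counts = drug_explorer.count_broadly_inhibited(
                eff, cfg.inhibition_threshold)
            p3 = outdir / "broadly_inhibited_counts.tsv"
            counts.to_csv(p3, sep="\t")
            manifest["stages"]["rank"] = {
                "outputs": [str(p1), str(p2), str(p3)],
                "top_drug": chart.index[0] if len(chart) else None}
        else:
            manifest["stages"]["predict"] = {"skipped": "no panel matrix"}
            manifest["stages"]["rank"] = {"skipped": "no panel matrix"}

        if cfg.reference_network:
            stage = "networks"
            net = network_explorer.load_reference_network(cfg.reference_network)
            net_dir = outdir / "networks"
            written = []
            for cyt in accepted:
                if cyt not in net:
                    logger.warning("no anchor node for %s in reference "
                                   "network; skipping", cyt)
                    continue
                sub = network_explorer.extract_cytokine_network(
                    net, cyt, models[cyt].informative_kinases,
                    max_hops=cfg.max_hops, cytokine_id=cyt)
                written += [str(p) for p in
                            network_explorer.write_subnetwork(sub, net_dir)]
            manifest["stages"]["networks"] = {"outputs": written}
        else:
            manifest["stages"]["networks"] = {"skipped": "no reference network"}
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
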