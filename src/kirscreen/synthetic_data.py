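"""In-silico kinase-inhibitor secretion screens with planted ground truth.

Emulates the four data surfaces of a real screen so every downstream stage
has a parameter-recovery test surface:

* a drug x kinase residual-activity matrix (percent of uninhibited control,
  0--100), for both the screened panel and a larger unscreened panel;
* a drug x cytokine response table on the fraction-of-LPS-control scale,
  generated by the same linear model the KiR regression assumes:
  ``y = b0 + (X/100) @ beta + noise``, clipped at zero;
* a control-vs-LPS secretome replicate table with a chosen number of truly
  shifted factors;
* a drug annotation table with an FDA-approval flag.

The planted coefficient structure is sparse and nonnegative: each cytokine
is driven by exactly ``k_planted`` kinases with effects drawn from
Uniform(0.05, 0.3) on the fraction-of-control scale, so that fully
inhibiting one planted kinase removes 5--30% of the control-level signal.
Baselines are set so a drug that inhibits nothing sits at level 1.0 (the
LPS-only control); when the planted effects of a cytokine sum above 0.95
they are rescaled to keep the baseline nonnegative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig", "GroundTruth",
    "simulate_drug_target_matrix", "simulate_ground_truth",
    "simulate_responses", "simulate_secretome", "simulate_drug_annotations",
    "simulate_screen", "write_ground_truth_json",
]

# residual-activity jitter for uninhibited entries: Normal(100, 2) truncated
# to the assay range
UNINHIBITED_MEAN = 100.0
UNINHIBITED_SD = 2.0
# strongly inhibited entries are uniform on [0, 50): below the conventional
# half-activity cutoff
INHIBITED_MAX = 50.0
COEF_LOW, COEF_HIGH = 0.05, 0.3
MAX_TOTAL_EFFECT = 0.95


@dataclass(frozen=True)
class SimulationConfig:
    """Dimensions and noise of a simulated screen.

    Defaults mirror the real study's screen: 34 inhibitors profiled against
    a kinase panel, a larger unscreened prediction panel, responses measured
    as fraction of the LPS-only control. ``selectivity`` is the mean
    fraction of kinases each drug strongly inhibits (residual < 50%);
    ``noise_sd`` is the s.d. of additive Gaussian noise on the response
    scale.
    """

    n_screen_drugs: int = 34
    n_panel_drugs: int = 100
    n_kinases: int = 50
    n_cytokines: int = 10
    k_planted: int = 5
    noise_sd: float = 0.02
    selectivity: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_screen_drugs", "n_panel_drugs", "n_kinases",
                     "n_cytokines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.k_planted < 0:
            raise ValueError("k_planted must be >= 0")
        if self.k_planted > self.n_kinases:
            raise ValueError(
                f"k_planted ({self.k_planted}) exceeds n_kinases "
                f"({self.n_kinases})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.selectivity <= 1:
            raise ValueError("selectivity must be in (0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic stream per simulated surface."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class GroundTruth:
    """Planted linear model: kinase x cytokine effect matrix, per-cytokine
    baselines, and the planted support (kinases with positive effect)."""

    coefficients: pd.DataFrame  # kinases x cytokines, >= 0
    intercepts: pd.Series       # per cytokine
    support: dict[str, set[str]] = field(default_factory=dict)

    def control_level(self) -> pd.Series:
        """Expected level of an LPS-only pseudo-drug (residual activity 100
        everywhere): b0 + sum(beta)."""
        return self.intercepts + self.coefficients.sum(axis=0)


def _drug_ids(n: int, prefix: str = "drug") -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(1, n + 1)]


def _kinase_ids(n: int) -> list[str]:
    return [f"KIN{j:03d}" for j in range(1, n + 1)]


def _cytokine_ids(n: int) -> list[str]:
    return [f"CYT{c:02d}" for c in range(1, n + 1)]


def simulate_drug_target_matrix(cfg: SimulationConfig, panel: bool = False,
                                jitter_sd: float = UNINHIBITED_SD,
                                inhibited_max: float = INHIBITED_MAX,
                                min_coverage: int = 2,
                                ) -> pd.DataFrame:
    """Residual-activity matrix for the screen (or, with ``panel=True``, the
    larger unscreened panel, drawn from an independent stream).

    Each drug strongly inhibits a Bernoulli(selectivity) subset of kinases
    (residual ~ Uniform[0, inhibited_max)); everything else sits near 100
    with truncated-normal jitter. All entries lie in [0, 100].

    The screen emulates a computationally chosen inhibitor panel: each
    kinase is guaranteed at least ``min_coverage`` strongly inhibiting
    drugs (extra inhibition events are assigned to random drugs), because
    a kinase the screen never perturbs is unidentifiable to the regression
    and a hazard for out-of-panel extrapolation. The unscreened prediction
    panel (``panel=True``) has no such guarantee.
    ``selectivity=1, jitter_sd=0, inhibited_max=0`` is the degenerate
    everything-fully-inhibited screen.
    """
    if not 0 <= inhibited_max <= 100:
        raise ValueError("inhibited_max must be in [0, 100]")
    rng = cfg.rng(stream=2 if panel else 1)
    n = cfg.n_panel_drugs if panel else cfg.n_screen_drugs
    p = cfg.n_kinases
    inhibited = rng.random((n, p)) < cfg.selectivity
    if not panel:
        need = min(min_coverage, n)
        for j in range(p):
            short = need - int(inhibited[:, j].sum())
            if short > 0:
                free = np.flatnonzero(~inhibited[:, j])
                inhibited[rng.choice(free, short, replace=False), j] = True
    vals = np.clip(rng.normal(UNINHIBITED_MEAN, jitter_sd, (n, p)), 0.0, 100.0)
    vals[inhibited] = rng.uniform(0.0, inhibited_max, int(inhibited.sum()))
    prefix = "panel" if panel else "drug"
    return pd.DataFrame(vals, index=_drug_ids(n, prefix), columns=_kinase_ids(p))


def simulate_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Plant exactly ``k_planted`` positive kinase effects per cytokine.

    Effects ~ Uniform(0.05, 0.3); columns summing above 0.95 are rescaled to
    0.95 so the baseline b0 = 1 - sum(beta) stays nonnegative and the
    LPS-only control level is exactly 1.0.
    """
    rng = cfg.rng(stream=3)
    kinases, cytokines = _kinase_ids(cfg.n_kinases), _cytokine_ids(cfg.n_cytokines)
    beta = pd.DataFrame(0.0, index=kinases, columns=cytokines)
    support: dict[str, set[str]] = {}
    for cyt in cytokines:
        chosen = rng.choice(cfg.n_kinases, size=cfg.k_planted, replace=False)
        effects = rng.uniform(COEF_LOW, COEF_HIGH, cfg.k_planted)
        total = effects.sum()
        if total > MAX_TOTAL_EFFECT:
            effects *= MAX_TOTAL_EFFECT / total
        beta.iloc[chosen, beta.columns.get_loc(cyt)] = effects
        support[cyt] = {kinases[j] for j in chosen}
    intercepts = 1.0 - beta.sum(axis=0)
    return GroundTruth(coefficients=beta, intercepts=intercepts, support=support)


def simulate_responses(X: pd.DataFrame, gt: GroundTruth,
                       cfg: SimulationConfig,
                       noiseless: bool = False) -> pd.DataFrame:
    """Responses from the planted linear model on the fraction-of-control
    scale: ``y = b0 + (X/100) @ beta + Normal(0, noise_sd)``, clipped at 0.

    A drug inhibiting nothing (all residual activity 100) averages exactly
    the control level b0 + sum(beta). ``noiseless=True`` returns the
    deterministic mean surface (used as prediction ground truth).
    """
    if list(X.columns) != list(gt.coefficients.index):
        raise ValueError("kinase ids of X and ground truth do not match")
    mean = gt.intercepts.to_numpy()[None, :] + \
        (X.to_numpy() / 100.0) @ gt.coefficients.to_numpy()
    if noiseless or cfg.noise_sd == 0:
        vals = mean
    else:
        rng = cfg.rng(stream=4)
        vals = mean + rng.normal(0.0, cfg.noise_sd, mean.shape)
    return pd.DataFrame(np.clip(vals, 0.0, None), index=X.index,
                        columns=gt.coefficients.columns)


def simulate_secretome(n_factors: int = 191, n_shifted: int = 34,
                       n_replicates: int = 3, fold_change: float = 4.0,
                       cv: float = 0.15, baseline_mean: float = 500.0,
                       seed: int = 0) -> pd.DataFrame:
    """Control-vs-LPS replicate table in long format (factor, condition,
    replicate, value), emulating a multiplexed secretome readout.

    The first ``n_shifted`` factors truly respond to LPS: half up, half down
    by ``fold_change``. Readouts are log-normal around each factor's
    condition mean with coefficient of variation ``cv``; baselines are
    log-uniform over two decades around ``baseline_mean``.
    """
    if n_shifted > n_factors:
        raise ValueError("n_shifted exceeds n_factors")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(5,)))
    factors = [f"F{k:03d}" for k in range(1, n_factors + 1)]
    base = baseline_mean * 10 ** rng.uniform(-1, 1, n_factors)
    fc = np.ones(n_factors)
    fc[: n_shifted // 2] = fold_change
    fc[n_shifted // 2: n_shifted] = 1.0 / fold_change
    sigma = np.sqrt(np.log1p(cv ** 2))
    rows = []
    for cond, level in (("control", base), ("LPS", base * fc)):
        for r in range(1, n_replicates + 1):
            vals = level * np.exp(rng.normal(-sigma ** 2 / 2, sigma, n_factors))
            rows.append(pd.DataFrame({
                "factor": factors, "condition": cond, "replicate": r,
                "value": vals,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_drug_annotations(cfg: SimulationConfig, panel: bool = True,
                              fda_fraction: float = 0.1) -> pd.DataFrame:
    """Drug annotation table (name + FDA-approval flag) for the panel."""
    rng = cfg.rng(stream=6)
    n = cfg.n_panel_drugs if panel else cfg.n_screen_drugs
    ids = _drug_ids(n, "panel" if panel else "drug")
    return pd.DataFrame({
        "drug": ids,
        "fda_approved": rng.random(n) < fda_fraction,
    }).set_index("drug")


def simulate_screen(cfg: SimulationConfig) -> dict:
    """One call for the complete synthetic study: screen and panel drug-
    target matrices, planted truth, noisy screen responses, the noiseless
    panel surface, secretome replicates and drug annotations."""
    gt = simulate_ground_truth(cfg)
    X_screen = simulate_drug_target_matrix(cfg, panel=False)
    X_panel = simulate_drug_target_matrix(cfg, panel=True)
    return {
        "ground_truth": gt,
        "X_screen": X_screen,
        "X_panel": X_panel,
        "Y_screen": simulate_responses(X_screen, gt, cfg),
        "Y_panel_true": simulate_responses(X_panel, gt, cfg, noiseless=True),
        "secretome": simulate_secretome(seed=cfg.seed),
        "annotations": simulate_drug_annotations(cfg),
        "config": cfg,
    }


def write_ground_truth_json(gt: GroundTruth, path) -> None:
    """Support lists and baselines as JSON (coefficient matrix goes to TSV
    via the generic matrix writer)."""
    payload = {
        "support": {c: sorted(s) for c, s in gt.support.items()},
        "intercepts": {c: float(v) for c, v in gt.intercepts.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_simulated_screen(sim: dict, outdir) -> dict[str, Path]:
    """Write every simulated surface as TSV (+ ground-truth JSON); returns
    the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("X_screen", "X_panel", "Y_screen", "Y_panel_true"):
        p = outdir / f"{name}.tsv"
        sim[name].to_csv(p, sep="\t")
        paths[name] = p
    p = outdir / "secretome.tsv"
    sim["secretome"].to_csv(p, sep="\t", index=False)
    paths["secretome"] = p
    p = outdir / "annotations.tsv"
    sim["annotations"].to_csv(p, sep="\t")
    paths["annotations"] = p
    p = outdir / "ground_truth_coefficients.tsv"
    sim["ground_truth"].coefficients.to_csv(p, sep="\t")
    paths["ground_truth_coefficients"] = p
    p = outdir / "ground_truth.json"
    write_ground_truth_json(sim["ground_truth"], p)
    paths["ground_truth"] = p
    p = outdir / "config.json"
    p.write_text(json.dumps(asdict(sim["config"]), indent=1))
    paths["config"] = p
    return paths
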