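"""Result surfaces over fitted KiR models: the binary kinase-cytokine hit
matrix, per-drug efficacy tables and ranked drug summaries.

Efficacy of a drug on a factor is the percent suppression relative to the
LPS-only control: ``100 * (1 - level)`` for levels on the fraction-of-
control scale, so 0% means no effect and 100% complete suppression. A drug
"affects" a factor when its efficacy reaches the inhibition threshold
(default 50%, configurable -- the threshold is a display convention, not a
biological constant). Drug "specificity" is reported as one minus the
normalized Shannon entropy of the drug's nonnegative efficacy profile: a
stand-in definition, declared as such, since no operational one is
established for these summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kir_core import KiRModel

logger = logging.getLogger(__name__)

DEFAULT_INHIBITION_THRESHOLD = 50.0
RESIDUAL_ACTIVITY_CUTOFF = 50.0  # a kinase counts as inhibited below this


@dataclass(frozen=True)
class DrugSummary:
    drug_id: str
    avg_efficacy: float          # mean % suppression over the selection
    pct_selection_affected: float
    n_selection_affected: int
    affects_all: bool            # affects every factor in the selection
    selectivity: float           # fraction of panel kinases inhibited
    specificity: float
    fda_approved: bool | None = None


def _models_dict(models) -> dict[str, KiRModel]:
    if isinstance(models, KiRModel):
        return {models.cytokine_id: models}
    if isinstance(models, dict):
        return models
    return {m.cytokine_id: m for m in models}


def build_kinase_cytokine_matrix(models, kinase_ids=None, selection=None,
                                 accepted_only: bool = True) -> pd.DataFrame:
    """Binary kinase x cytokine matrix: 1 where the kinase is informative
    for the cytokine, 0 otherwise. Row sums give per-kinase counts; with a
    ``selection`` of cytokines of interest, two count columns are appended
    (affected within the selection and among all modeled factors).

    Only models passing the quality gate contribute hits by default (a
    rejected model's kinase calls are not trustworthy); columns of rejected
    models are all zero unless ``accepted_only=False``.
    """
    models = _models_dict(models)
    if not models:
        raise ValueError("no models supplied")
    cytokines = sorted(models)
    contributing = {c: m for c, m in models.items()
                    if not accepted_only or m.quality.accepted}
    if kinase_ids is None:
        kinase_ids = sorted(set().union(
            *(m.informative_kinases for m in contributing.values()), set()))
    mat = pd.DataFrame(0, index=list(kinase_ids), columns=cytokines, dtype=int)
    for cyt, m in contributing.items():
        present = [k for k in m.informative_kinases if k in mat.index]
        mat.loc[present, cyt] = 1
    if selection is not None:
        unknown = set(selection) - set(cytokines)
        if unknown:
            raise KeyError(f"unknown cytokine(s) in selection: {sorted(unknown)}")
        mat["n_selected"] = mat[list(selection)].sum(axis=1)
        mat["n_total"] = mat[cytokines].sum(axis=1)
    return mat


def compute_efficacy(predicted: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """Percent suppression per (drug, factor): ``100 * (1 - level)``.

    Levels must be on the fraction-of-control scale; negative levels are
    clipped to 0 (logged) before conversion, so efficacy never exceeds 100.
    An optional display floor clips strongly potentiated factors (negative
    efficacy) from below.
    """
    vals = predicted.to_numpy(dtype=float)
    n_neg = int((vals < 0).sum())
    if n_neg:
        logger.warning("clipping %d negative predicted level(s) to 0", n_neg)
        vals = np.clip(vals, 0.0, None)
    eff = 100.0 * (1.0 - vals)
    if floor is not None:
        eff = np.clip(eff, floor, None)
    return pd.DataFrame(eff, index=predicted.index, columns=predicted.columns)


def drug_selectivity(X_panel: pd.DataFrame,
                     cutoff: float = RESIDUAL_ACTIVITY_CUTOFF) -> pd.Series:
    """Fraction of profiled kinases each drug inhibits (residual < cutoff)."""
    return (X_panel < cutoff).mean(axis=1)


def drug_specificity(eff_row: np.ndarray) -> float:
    """1 - normalized Shannon entropy of the nonnegative efficacy profile;
    1.0 = all effect on a single factor, 0.0 = perfectly even profile."""
    w = np.clip(np.asarray(eff_row, dtype=float), 0.0, None)
    total = w.sum()
    if total == 0 or len(w) < 2:
        return 0.0
    p = w[w > 0] / total
    h = -(p * np.log(p)).sum() / np.log(len(w))
    return float(1.0 - h)


def rank_drugs(eff: pd.DataFrame, selection, k: int = 10,
               inhibition_threshold: float = DEFAULT_INHIBITION_THRESHOLD,
               X_panel: pd.DataFrame | None = None,
               annotations: pd.DataFrame | None = None,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank panel drugs by mean efficacy over the selected cytokines.

    Returns ``(chart, table)``: the top-k chart rows and the full ranked
    table over every drug. Sorting is by average efficacy descending, ties
    broken by the number of selected factors affected (efficacy >=
    threshold), then drug id; row order of the input never matters.
    """
    selection = list(selection)
    if not selection:
        raise ValueError("selection must be non-empty")
    unknown = [c for c in selection if c not in eff.columns]
    if unknown:
        raise KeyError(f"unknown cytokine(s) in selection: {unknown}")
    sub = eff[selection]
    affected = sub >= inhibition_threshold
    table = pd.DataFrame({
        "avg_efficacy": sub.mean(axis=1),
        "n_selection_affected": affected.sum(axis=1),
        "pct_selection_affected": 100.0 * affected.mean(axis=1),
        "affects_all": affected.all(axis=1),
        "specificity": [drug_specificity(row) for row in sub.to_numpy()],
    })
    if X_panel is not None:
        table["selectivity"] = drug_selectivity(X_panel).reindex(table.index)
    if annotations is not None and "fda_approved" in annotations.columns:
        table["fda_approved"] = (annotations["fda_approved"]
                                 .reindex(table.index, fill_value=False)
                                 .astype(bool))
    # stable sort of an id-sorted frame => residual ties broken by drug id
    table = (table.rename_axis("drug")
             .sort_index(kind="mergesort")
             .sort_values(["avg_efficacy", "n_selection_affected"],
                          ascending=[False, False], kind="mergesort"))
    table["rank"] = np.arange(1, len(table) + 1)
    return table.head(k), table


def count_broadly_inhibited(eff: pd.DataFrame,
                            inhibition_threshold: float = DEFAULT_INHIBITION_THRESHOLD,
                            ) -> pd.Series:
    """Per-drug count of factors suppressed at or above the threshold --
    the 'inhibits the release of over N cytokines' summary."""
    if not 0 < inhibition_threshold <= 100:
        raise ValueError("inhibition_threshold must be in (0, 100]")
    return (eff >= inhibition_threshold).sum(axis=1).rename("n_inhibited")


def efficacy_profile(eff: pd.DataFrame, drug_id: str, selection=None) -> dict:
    """Per-drug drill-down: efficacy on each (selected) factor, JSON-ready."""
    if drug_id not in eff.index:
        raise KeyError(f"unknown drug {drug_id!r}")
    row = eff.loc[drug_id]
    if selection is not None:
        row = row[list(selection)]
    return {"drug": drug_id,
            "efficacy": {c: float(v) for c, v in row.items()}}
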