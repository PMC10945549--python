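"""Secretome screen statistics: normalization to the LPS-only control and
per-factor differential-secretion testing.

The raw screen measures up to ~191 secreted factors (cytokines, chemokines,
growth factors) across conditions (control, LPS, LPS+drug) with replicate
readouts. Differential secretion between two conditions is assessed with a
Welch (unequal-variance) t-test on log-transformed readouts, corrected
across factors by Benjamini-Hochberg; a factor is flagged when q < fdr.
Readouts are offset by +1 before the log so zero measurements are tolerated
(configurable).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("factor", "condition", "value")


def _check_long(raw: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"secretome table lacks column(s): {missing}")


def normalize_to_control(raw: pd.DataFrame, control_label: str = "LPS",
                         value_col: str = "value") -> pd.DataFrame:
    """Divide each factor's readouts by its mean control-condition level.

    Returns the long table with a ``normalized`` column (control maps to
    1.0 on average). Factors whose control mean is zero cannot be expressed
    on the fraction-of-control scale and are excluded with a logged reason.
    """
    _check_long(raw)
    if control_label not in set(raw["condition"]):
        raise ValueError(f"control condition {control_label!r} not present")
    ctrl = (raw[raw["condition"] == control_label]
            .groupby("factor")[value_col].mean())
    bad = set(ctrl.index[ctrl == 0]) | (set(raw["factor"]) - set(ctrl.index))
    if bad:
        logger.warning("excluding %d unquantifiable factor(s) "
                       "(zero or missing control): %s", len(bad), sorted(bad)[:5])
    out = raw[~raw["factor"].isin(bad)].copy()
    out["normalized"] = out[value_col] / out["factor"].map(ctrl)
    return out


def differential_secretion(raw: pd.DataFrame, cond_a: str, cond_b: str,
                           fdr: float = 0.05,
                           log_offset: float = 1.0) -> pd.DataFrame:
    """Per-factor differential test of condition b vs condition a.

    For each factor with >= 2 replicates in both conditions, a two-sided
    Welch t-test compares log(value + log_offset) between conditions;
    log2FC is the difference of log2 means (b over a). p-values are BH-
    adjusted across tested factors; ``significant`` means q < fdr. Factors
    with insufficient replication are returned with a reason and no test.
    """
    _check_long(raw)
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    rows, skipped = [], []
    for factor, grp in raw.groupby("factor", sort=True):
        a = grp.loc[grp["condition"] == cond_a, "value"].to_numpy(float)
        b = grp.loc[grp["condition"] == cond_b, "value"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            skipped.append(factor)
            continue
        la, lb = np.log(a + log_offset), np.log(b + log_offset)
        if np.ptp(la) == 0 and np.ptp(lb) == 0 and np.allclose(la.mean(), lb.mean()):
            p = 1.0  # identical readouts: no evidence, avoid 0/0 variance
        else:
            p = float(stats.ttest_ind(lb, la, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        log2fc = float(np.log2(b.mean() + log_offset) - np.log2(a.mean() + log_offset))
        rows.append({"factor": factor, "log2fc": log2fc, "p": p})
    if skipped:
        logger.warning("excluded %d factor(s) with < 2 replicates: %s",
                       len(skipped), skipped[:5])
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["q"] < fdr
    else:
        res = pd.DataFrame(columns=["factor", "log2fc", "p", "q", "significant"])
    if skipped:
        res = pd.concat([res, pd.DataFrame({
            "factor": skipped, "log2fc": np.nan, "p": np.nan, "q": np.nan,
            "significant": False})], ignore_index=True)
    return res.set_index("factor")


def detection_filter(raw: pd.DataFrame, min_level: float,
                     condition: str = "LPS") -> list[str]:
    """Factors whose mean readout in ``condition`` reaches ``min_level`` --
    a simple reliable-signal filter whose cutoff is user-chosen."""
    _check_long(raw)
    means = raw[raw["condition"] == condition].groupby("factor")["value"].mean()
    return sorted(means.index[means >= min_level])
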