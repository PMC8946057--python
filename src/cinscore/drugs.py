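"""Drug-sensitivity index and candidate-compound selection versus CIN.

Dose-response AUC quantifies resistance; the sensitivity index rescales it to
[0, 1] as 1 - (AUC - min)/(max - min) so that 1 is the highest possible
sensitivity.  By default min and max are taken over the whole screen (one
common scale, so per-compound median sensitivities are comparable); a
per-compound normalisation is available as an option.  Candidate compounds
are those whose sensitivity correlates with a CIN score at BH FDR <= 5% and
whose median sensitivity across cell lines exceeds 0.5; the sign of the
correlation says whether they preferentially target high- or low-CIN cells.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr

MIN_LINES = 3


def sensitivity_index(auc: pd.DataFrame, per_compound: bool = False) -> pd.DataFrame:
    """1 - min-max normalised AUC (compound x cell-line, missing preserved).

    Global normalisation (default) uses one min and one range for the whole
    screen; ``per_compound`` rescales each row separately.  A zero range (all
    observed AUC identical) is an error.
    """
    vals = auc.to_numpy(dtype=float)
    if per_compound:
        lo = np.nanmin(vals, axis=1, keepdims=True)
        hi = np.nanmax(vals, axis=1, keepdims=True)
    else:
        lo = np.nanmin(vals)
        hi = np.nanmax(vals)
    rng = hi - lo
    if np.any(rng <= 0):
        raise ValueError("AUC range is zero; sensitivity index undefined")
    sens = 1.0 - (vals - lo) / rng
    return pd.DataFrame(sens, index=auc.index, columns=auc.columns)


def select_candidates(
    sensitivity: pd.DataFrame,
    scores: pd.Series,
    fdr_max: float = 0.05,
    median_min: float = 0.5,
    min_lines: int = MIN_LINES,
) -> pd.DataFrame:
    """Per-compound Spearman rho vs score, FDR, median sensitivity, call.

    A compound is a candidate iff FDR <= fdr_max and median sensitivity >
    median_min; direction 'targets-high-CIN' for positive rho,
    'targets-low-CIN' for negative.  Compounds overlapping fewer than
    ``min_lines`` scored cell lines are reported untested (excluded from the
    FDR family), not as nulls.
    """
    scores = pd.Series(scores, dtype=float)
    common = sensitivity.columns.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("no shared cell lines between sensitivity and scores")
    sens = sensitivity[common]
    y = scores.loc[common].to_numpy(dtype=float)

    rows = []
    for compound in sens.index:
        x = sens.loc[compound].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        med = float(np.nanmedian(x)) if n else float("nan")
        if n < min_lines or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
            rows.append((compound, np.nan, np.nan, med, n, False))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append((compound, float(rho), float(p), med, n, True))
    out = pd.DataFrame(
        rows, columns=["compound", "rho", "p_value", "median_sensitivity",
                       "n", "tested"],
    )
    out["fdr"] = bh_fdr(out["p_value"].where(out["tested"]))
    out["direction"] = np.where(
        out["rho"] >= 0, "targets-high-CIN", "targets-low-CIN"
    )
    out.loc[out["rho"].isna(), "direction"] = ""
    out["candidate"] = (
        out["tested"]
        & (out["fdr"] <= fdr_max)
        & (out["median_sensitivity"] > median_min)
    )
    return out[["compound", "rho", "p_value", "fdr", "median_sensitivity",
                "direction", "candidate", "n", "tested"]]
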