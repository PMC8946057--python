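"""Score-vs-feature screens, recurrence filtering and alteration regression.

Three screens mirror the downstream stages of a pan-cancer CIN analysis:
Spearman correlation of a CIN score against continuous features (expression
or pathway activity), per cohort or pan-cancer; a recurrence filter keeping
features strongly positively correlated (rho >= 0.3 at FDR < 5%) in at least
seven cohorts; and ordinary least squares of a CIN score on binary
alteration status plus cohort fixed effects, whose alteration coefficient is
the mean score difference of altered versus wild-type samples.
Benjamini-Hochberg FDR is applied within each screen.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cinscore")

MIN_CORR_N = 3


def bh_fdr(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaN p-values stay NaN."""
    p = pd.Series(p, dtype=float)
    out = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _align(scores, matrix: pd.DataFrame) -> pd.DataFrame:
    """Align a score Series with a samples x features matrix on sample id."""
    scores = pd.Series(scores, dtype=float)
    common = matrix.index.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("no shared samples between scores and feature matrix")
    return matrix.loc[common], scores.loc[common]


def spearman_screen(
    scores: pd.Series,
    matrix: pd.DataFrame,
    cohorts: Optional[pd.Series] = None,
    per_cohort: bool = False,
    min_n: int = MIN_CORR_N,
) -> pd.DataFrame:
    """Spearman rho of score vs every feature, with BH FDR within the screen.

    Missing values are handled pairwise-complete.  With ``per_cohort`` the
    screen runs within every cohort and FDR is adjusted within each cohort's
    family of features (the per-cancer-type screen of a pan-cancer study);
    otherwise a single pan-cancer family.  Constant features yield records with missing
    estimates, excluded from the FDR family and logged.
    """
    matrix, scores = _align(scores, matrix)
    if per_cohort:
        if cohorts is None:
            raise ValueError("per_cohort screen requires cohort labels")
        cohorts = pd.Series(cohorts).reindex(matrix.index)
        parts = []
        for cohort, idx in matrix.groupby(cohorts).groups.items():
            sub = spearman_screen(
                scores.loc[idx], matrix.loc[idx], per_cohort=False, min_n=min_n
            )
            sub["cohort"] = cohort
            parts.append(sub)
        return pd.concat(parts, ignore_index=True)

    records = []
    n_constant = 0
    y = scores.to_numpy(dtype=float)
    for feature in matrix.columns:
        x = matrix[feature].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < min_n or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
            n_constant += 1
            records.append((feature, np.nan, np.nan, n))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        records.append((feature, rho, p, n))
    if n_constant:
        logger.info("spearman_screen: %d constant/underpowered feature(s)", n_constant)
    out = pd.DataFrame(records, columns=["feature", "estimate", "p_value", "n"])
    out["fdr"] = bh_fdr(out["p_value"])
    out["cohort"] = "pan-cancer"
    out["kind"] = "spearman_rho"
    return out[["feature", "cohort", "kind", "estimate", "p_value", "fdr", "n"]]


def recurrence_filter(
    records: pd.DataFrame,
    rho_min: float = 0.3,
    min_cohorts: int = 7,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Recurrently, strongly positively correlated features across cohorts.

    A cohort passes for a feature iff rho >= rho_min with FDR < fdr_max
    there; the feature passes the filter iff at least ``min_cohorts`` cohorts
    pass.  Only positive correlations count.
    """
    req = {"feature", "cohort", "estimate", "fdr"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must contain columns {sorted(req)}")
    passing = records[
        (records["estimate"] >= rho_min) & (records["fdr"] < fdr_max)
    ]
    by_feature = passing.groupby("feature")["cohort"].agg(list)
    rows = []
    for feature in records["feature"].unique():
        cohorts = sorted(by_feature.get(feature, []))
        rows.append(
            (feature, len(cohorts), ",".join(map(str, cohorts)),
             len(cohorts) >= min_cohorts)
        )
    return pd.DataFrame(
        rows, columns=["feature", "n_cohorts_passing", "passing_cohorts",
                       "passes_filter"],
    )


def regress_alterations(
    scores: pd.Series,
    alterations: pd.DataFrame,
    cohorts: Optional[pd.Series] = None,
    min_group: int = 20,
) -> pd.DataFrame:
    """OLS of score on alteration status with cohort fixed effects.

    For each alteration with at least ``min_group`` samples in both the
    altered and the wild-type group, fit score ~ intercept + alteration +
    cohort dummies; the alteration coefficient is the mean difference in the
    score attributable to carrying the alteration, adjusted for cohort.
    Two-sided classical t-test p-values; BH FDR across the tested
    alterations.  Alterations perfectly confounded with cohort are flagged
    and excluded from the FDR family.
    """
    alterations, scores = _align(scores, alterations)
    vals = alterations.to_numpy()
    if not np.isin(vals[~np.isnan(vals.astype(float))], (0, 1)).all():
        raise ValueError("alteration matrix must be binary {0,1}")
    y = scores.to_numpy(dtype=float)
    n = len(y)

    base_cols = [np.ones(n)]
    if cohorts is not None:
        cohorts = pd.Series(cohorts).reindex(alterations.index)
        if cohorts.isna().any():
            raise ValueError("cohort label missing for some samples")
        levels = sorted(cohorts.unique())
        for lev in levels[1:]:
            base_cols.append((cohorts == lev).to_numpy(dtype=float))
    base = np.column_stack(base_cols)
    # residual-maker for the base design: detects alterations fully explained
    # by cohort membership (perfect confounding)
    q, _ = np.linalg.qr(base)

    records = []
    for gene in alterations.columns:
        a = alterations[gene].to_numpy(dtype=float)
        n_alt = int(np.nansum(a))
        n_wt = int(n - n_alt)
        if min(n_alt, n_wt) < min_group:
            records.append((gene, np.nan, np.nan, np.nan, np.nan, n, n_alt, "too_few"))
            continue
        resid_a = a - q @ (q.T @ a)
        if float(resid_a @ resid_a) < 1e-10 * n:
            records.append(
                (gene, np.nan, np.nan, np.nan, np.nan, n, n_alt, "collinear")
            )
            continue
        X = np.column_stack([base, a])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = n - X.shape[1]
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        coef = float(beta[-1])
        t = coef / se
        p = 2.0 * stats.t.sf(abs(t), df)
        tcrit = stats.t.ppf(0.975, df)
        records.append(
            (gene, coef, p, coef - tcrit * se, coef + tcrit * se, n, n_alt, "ok")
        )
    out = pd.DataFrame(
        records,
        columns=["feature", "estimate", "p_value", "ci_low", "ci_high",
                 "n", "n_altered", "status"],
    )
    out["fdr"] = bh_fdr(out["p_value"].where(out["status"] == "ok"))
    out["kind"] = "linear_coefficient"
    return out[["feature", "kind", "estimate", "ci_low", "ci_high",
                "p_value", "fdr", "n", "n_altered", "status"]]


def exclude_hypermutated(
    data: pd.DataFrame,
    min_flag: Optional[str] = "min_flag",
    min_score: Optional[str] = None,
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Drop hypermutated microsatellite-instable (MIN) samples.

    Either a boolean flag column or a numeric MIN-score column with an
    explicit user-supplied cutoff must be available; no universal MIN-score
    cutoff exists, so the score-based mode requires one explicitly.
    """
    if min_flag is not None and min_flag in data.columns:
        keep = ~data[min_flag].fillna(False).astype(bool)
    elif min_score is not None and min_score in data.columns:
        if cutoff is None:
            raise ValueError("a cutoff is required when excluding by MIN score")
        keep = ~(data[min_score] > cutoff)
    else:
        raise ValueError("no MIN flag or score annotation available")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("exclude_hypermutated: removed %d sample(s)", n_drop)
    return data.loc[keep]
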