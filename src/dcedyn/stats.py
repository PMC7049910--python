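"""Association of per-subject scores with clinical covariates.

Two analyses per (region unit, descriptor) cell, mirroring the study:
a Kruskal-Wallis test of score differences across total-SVD-score groups
(rank-based H with tie correction, chi-square reference with g-1 degrees
of freedom) and a standardized multiple linear regression

    score = b0 + b_Age*Age + b_WMH*WMH + b_Sex*Sex + b_Lac*Lac

where the response and all predictors (binary ones included) are z-scored,
so each beta is a standardized coefficient.  Sex is coded female=1/male=0
and stroke lesion type lacunar=1/cortical=0.  No multiplicity correction
gates the results; a Benjamini-Hochberg column is emitted alongside for
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = ["KwResult", "RegressionResult", "CollinearityError", "kruskal_wallis",
           "standardized_regression", "run_validation", "PREDICTORS"]

PREDICTORS = ["age", "wmh_fraction", "sex", "lacunar"]
_BETA_KEYS = {"age": "Age", "wmh_fraction": "WMH", "sex": "Sex", "lacunar": "Lac"}


class CollinearityError(ValueError):
    """Predictors are (numerically) collinear."""


@dataclass
class KwResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class RegressionResult:
    adjusted_r2: float
    model_p: float
    betas: dict          # {"Age": b, "WMH": b, "Sex": b, "Lac": b}
    p_values: dict
    n: int


def kruskal_wallis(scores: np.ndarray, groups: np.ndarray) -> KwResult:
    """Rank-based H test of score differences between groups."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    if np.all(scores == scores[0]):
        raise ValueError("all scores identical; the rank test is undefined")
    arrays = [scores[groups == g] for g in labels]
    stat, p = sstats.kruskal(*arrays)
    return KwResult(chi_square=float(stat), df=len(labels) - 1, p_value=float(p))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def _code_predictors(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding: female=1/male=0, lacunar=1/cortical=0."""
    out = pd.DataFrame(index=covariates.index)
    out["age"] = covariates["age"].astype(float)
    out["wmh_fraction"] = covariates["wmh_fraction"].astype(float)
    sex = covariates["sex"]
    out["sex"] = (sex == "female").astype(float) if sex.dtype == object \
        else sex.astype(float)
    out["lacunar"] = covariates["lacunar"].astype(float)
    return out


def standardized_regression(scores: np.ndarray, covariates: pd.DataFrame,
                            predictors: list[str] | None = None,
                            cond_threshold: float = 1e8) -> RegressionResult:
    """OLS of z-scored response on z-scored predictors.

    ``predictors`` selects covariate columns (default the four study
    predictors age, WMH fraction, sex, lesion type).
    """
    y = np.asarray(scores, dtype=float)
    if predictors is None:
        X = _code_predictors(covariates)
    else:
        X = covariates[predictors].astype(float)
    n, p = len(y), X.shape[1]
    if n != len(X):
        raise ValueError("scores and covariates disagree on subject count")
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} subjects, got {n}")
    Z = np.column_stack([_zscore(X[c].to_numpy()) for c in X.columns])
    if np.linalg.cond(Z) > cond_threshold:
        raise CollinearityError("predictor matrix is numerically collinear")
    yz = _zscore(y)
    model = sm.OLS(yz, sm.add_constant(Z)).fit()
    betas = {_BETA_KEYS.get(c, c): float(model.params[i + 1])
             for i, c in enumerate(X.columns)}
    pvals = {_BETA_KEYS.get(c, c): float(model.pvalues[i + 1])
             for i, c in enumerate(X.columns)}
    return RegressionResult(adjusted_r2=float(model.rsquared_adj),
                            model_p=float(model.f_pvalue),
                            betas=betas, p_values=pvals, n=n)


def run_validation(score_table: pd.DataFrame, covariates: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One KW row and one regression row per (unit, descriptor) cell.

    ``score_table`` has columns subject_id, unit, descriptor, score.
    Degenerate cells (e.g. constant scores) are flagged in the ``note``
    column and skipped rather than aborting the run.  BH-adjusted p-value
    columns are appended for reference; they gate nothing.
    """
    required = {"subject_id", "unit", "descriptor", "score"}
    if not required.issubset(score_table.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    cov = covariates.set_index("subject_id")
    ids = set(score_table["subject_id"])
    if not ids.issubset(cov.index):
        missing = sorted(ids - set(cov.index))[:5]
        raise KeyError(f"subjects missing from covariate table: {missing}")

    kw_rows, reg_rows = [], []
    for (unit, desc), cell in score_table.groupby(["unit", "descriptor"],
                                                  sort=True):
        cell = cell.set_index("subject_id")
        sub = cov.loc[cell.index]
        y = cell["score"].to_numpy(dtype=float)

        kw_row = {"unit": unit, "descriptor": desc, "chi2": np.nan,
                  "df": np.nan, "p": np.nan, "note": ""}
        try:
            res = kruskal_wallis(y, sub["svd_score"].to_numpy())
            kw_row.update(chi2=res.chi_square, df=res.df, p=res.p_value)
        except ValueError as exc:
            kw_row["note"] = str(exc)
        kw_rows.append(kw_row)

        reg_row = {"unit": unit, "descriptor": desc, "adj_r2": np.nan,
                   "model_p": np.nan, "note": ""}
        reg_row.update({f"beta_{k}": np.nan for k in _BETA_KEYS.values()})
        reg_row.update({f"p_{k}": np.nan for k in _BETA_KEYS.values()})
        try:
            rr = standardized_regression(y, sub)
            reg_row.update(adj_r2=rr.adjusted_r2, model_p=rr.model_p)
            reg_row.update({f"beta_{k}": v for k, v in rr.betas.items()})
            reg_row.update({f"p_{k}": v for k, v in rr.p_values.items()})
        except ValueError as exc:
            reg_row["note"] = str(exc)
        reg_rows.append(reg_row)

    kw_df = pd.DataFrame(kw_rows)
    reg_df = pd.DataFrame(reg_rows)
    for df, col in ((kw_df, "p"), (reg_df, "model_p")):
        adj = np.full(len(df), np.nan)
        ok = df[col].notna().to_numpy()
        if ok.any():
            adj[ok] = multipletests(df.loc[ok, col], method="fdr_bh")[1]
        df[f"{col}_bh"] = adj
    return kw_df, reg_df
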