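"""Outcome-prediction regression pipeline.

Fits and validates least-squares linear models of discharge Motricity Index
scores (elbow flexion, shoulder abduction, upper-limb total) from baseline
robot-measured kinematic metrics, adjusted for age, sex, stroke-onset time
and the admission score of the same outcome.

Two validation procedures are provided:

* **Split-sample validation (SSV)** -- a single random 75/25 train/validation
  partition, with a between-set balance-test battery (chi-square for
  categorical variables; ANOVA or Mann-Whitney for continuous ones depending
  on a normality pre-test; plus a four-group Kruskal-Wallis check with
  Bonferroni correction).
* **Leave-one-out cross-validation (LOOCV)** -- n fits, each predicting the
  single held-out record; the evaluation panel is computed on the pooled
  out-of-fold predictions and a final model is fitted on all records.

Continuous predictors (age, onset time, kinematic metrics) are standardized
to zero mean and unit variance across the cohort before modelling, so
coefficients are score points per standard deviation of the predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .evaluation import ValidationReport, evaluate_predictions
from .scales import get_scale

__all__ = [
    "PUBLISHED_LOOCV_MODELS",
    "PUBLISHED_SSV_BETAS",
    "OUTCOMES",
    "RMK_COLUMNS",
    "STANDARDIZED_COLUMNS",
    "RegressionModel",
    "SplitResult",
    "SSVResult",
    "LOOCVResult",
    "zscore",
    "Standardizer",
    "design_matrix",
    "fit_ols",
    "select_significant",
    "split_sample",
    "balance_tests",
    "run_ssv",
    "run_loocv",
    "predict_published",
]

#: Final single-predictor LOOCV models reported by the study:
#: discharge score = intercept + slope * standardized baseline MPE_C.
PUBLISHED_LOOCV_MODELS: dict[str, tuple[float, float]] = {
    "ELBOW": (12.99, -4.89),
    "SHOULDER": (13.70, -4.26),
    "UL": (32.50, -11.99),
}

#: Significant kinematic coefficients of the SSV training fits on the study's
#: own cohort, kept as documentation constants (that cohort is not public, so
#: these are reference values, not reproducible targets).
PUBLISHED_SSV_BETAS: dict[str, dict[str, float]] = {
    "ELBOW": {"mpe_c": -5.16, "mpe_d": 3.37},
    "SHOULDER": {"mpe_c": -5.02, "mpe_d": 3.37},
    "UL": {"mpe_c": -13.52, "mpe_d": 8.26},
}

OUTCOMES: tuple[str, ...] = ("ELBOW", "SHOULDER", "UL")
RMK_COLUMNS: tuple[str, ...] = ("mpe_a", "mpe_c", "mpe_d", "ms_b")
#: Continuous variables standardized before modelling.
STANDARDIZED_COLUMNS: tuple[str, ...] = ("age", "onset_days") + RMK_COLUMNS

_OUTCOME_COLUMNS: dict[str, tuple[str, str]] = {
    "ELBOW": ("mi_elbow_t1", "mi_elbow_t2"),
    "SHOULDER": ("mi_shoulder_t1", "mi_shoulder_t2"),
    "UL": ("mi_ul_t1", "mi_ul_t2"),
}


def predict_published(outcome: str, mpe_c_std: float) -> float:
    """Evaluate the published final LOOCV model for one outcome.

    ``mpe_c_std`` is the baseline movement path error toward the body,
    standardized across the cohort; at 0 the prediction equals the model
    intercept.  The returned value is continuous -- snap it with
    :func:`rmkpredict.scales.nearest_valid_score` when a reportable discrete
    score is needed.
    """
    key = outcome.upper()
    if key not in PUBLISHED_LOOCV_MODELS:
        raise KeyError(
            f"unknown outcome {outcome!r}; expected one of {sorted(PUBLISHED_LOOCV_MODELS)}"
        )
    if not math.isfinite(mpe_c_std):
        raise ValueError("mpe_c_std must be finite")
    intercept, slope = PUBLISHED_LOOCV_MODELS[key]
    return intercept + slope * mpe_c_std


# ---------------------------------------------------------------------------
# standardization


def zscore(values: Iterable[float]) -> tuple[np.ndarray, float, float]:
    """Standardize a vector: subtract the mean, scale to unit variance.

    Returns ``(z, mean, sd)`` with the sample (n-1 denominator) standard
    deviation, so the transform can be applied to new cases.
    """
    v = np.asarray(list(values), dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("standardization needs at least two distinct values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (v - mean) / sd, mean, sd


class Standardizer:
    """Column-wise z-score transform fitted on a reference cohort.

    Stores per-column means and sample standard deviations so that held-out
    or future records can be projected with the same transform.
    """

    def __init__(self, columns: Sequence[str] = STANDARDIZED_COLUMNS):
        self.columns = tuple(columns)
        self.means: pd.Series | None = None
        self.sds: pd.Series | None = None

    def fit(self, df: pd.DataFrame) -> "Standardizer":
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in cohort table: {missing}")
        means, sds = {}, {}
        for col in self.columns:
            v = df[col].to_numpy(dtype=float)
            if v.size < 2 or np.unique(v).size < 2:
                raise ValueError(
                    f"variable {col!r} is degenerate: needs >=2 distinct values"
                )
            sd = float(np.std(v, ddof=1))
            if sd == 0:
                raise ValueError(f"variable {col!r} has zero standard deviation")
            means[col] = float(np.mean(v))
            sds[col] = sd
        self.means = pd.Series(means)
        self.sds = pd.Series(sds)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.means is None:
            raise RuntimeError("Standardizer must be fitted before transform")
        out = df.copy()
        for col in self.columns:
            out[col] = (df[col].astype(float) - self.means[col]) / self.sds[col]
        return out

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class RegressionModel:
    """A fitted least-squares linear model.

    Coefficients are in score points per unit of the (standardized)
    predictor; p-values are two-sided from the t distribution with
    ``n - p - 1`` residual degrees of freedom.
    """

    outcome: str
    predictors: list[str]
    intercept: float
    coefficients: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    df_resid: float
    resid_var: float
    r2: float
    r2_adj: float

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        """Predict outcomes for rows of a design-matrix data frame."""
        X = design[self.predictors].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients.to_numpy(dtype=float)

    def coefficient_table(self) -> pd.DataFrame:
        """Intercept and slopes with standard errors and p-values."""
        idx = ["intercept"] + self.predictors
        return pd.DataFrame(
            {
                "coefficient": [self.intercept, *self.coefficients],
                "std_error": [self.bse.get("const", np.nan), *[self.bse[p] for p in self.predictors]],
                "p_value": [self.pvalues.get("const", np.nan), *[self.pvalues[p] for p in self.predictors]],
            },
            index=idx,
        )


def design_matrix(
    df: pd.DataFrame,
    outcome: str,
    rmk_columns: Sequence[str] = RMK_COLUMNS,
    covariates: Sequence[str] | None = None,
) -> tuple[np.ndarray | None, pd.DataFrame]:
    """Build the response vector and predictor matrix for one outcome.

    The default adjustment set is age, sex (0/1 indicator for male), stroke
    onset time and the admission score of the same outcome; the kinematic
    metrics are appended after it.  Returns ``(y, X)``; ``y`` is ``None``
    when the discharge column is absent (pure prediction use).
    """
    key = outcome.upper()
    if key not in _OUTCOME_COLUMNS:
        raise KeyError(f"unknown outcome {outcome!r}")
    t1_col, t2_col = _OUTCOME_COLUMNS[key]
    if covariates is None:
        covariates = ("age", "sex_male", "onset_days", t1_col)

    X = pd.DataFrame(index=df.index)
    for col in covariates:
        if col == "sex_male" and col not in df.columns:
            X[col] = (df["sex"] == "male").astype(float)
        else:
            X[col] = df[col].astype(float)
    for col in rmk_columns:
        X[col] = df[col].astype(float)

    y = df[t2_col].to_numpy(dtype=float) if t2_col in df.columns else None
    return y, X


def _collinear_columns(Xc: pd.DataFrame) -> list[str]:
    """Columns whose removal does not reduce the rank of the design."""
    full_rank = np.linalg.matrix_rank(Xc.to_numpy())
    return [
        col
        for col in Xc.columns
        if col != "const"
        and np.linalg.matrix_rank(Xc.drop(columns=[col]).to_numpy()) == full_rank
    ]


def fit_ols(
    y: Iterable[float], X: pd.DataFrame, outcome: str = "y"
) -> RegressionModel:
    """Ordinary least squares with an intercept.

    Raises when the design (with intercept) is rank deficient, listing the
    columns involved in the collinearity, or when there are not more
    observations than parameters.
    """
    y = np.asarray(list(y), dtype=float)
    X = pd.DataFrame(X).astype(float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("response and design have different lengths")
    if n <= p + 1:
        raise ValueError(
            f"need more observations ({n}) than parameters ({p + 1})"
        )
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(Xc)}"
        )
    res = sm.OLS(y, Xc).fit()

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2 = float(res.rsquared)
        r2_adj = float(res.rsquared_adj)
    else:  # constant response: variance explained undefined
        r2 = math.nan
        r2_adj = math.nan

    return RegressionModel(
        outcome=outcome,
        predictors=list(X.columns),
        intercept=float(res.params["const"]),
        coefficients=res.params.drop("const"),
        bse=res.bse,
        pvalues=res.pvalues,
        n=n,
        df_resid=float(res.df_resid),
        resid_var=float(res.mse_resid),
        r2=r2,
        r2_adj=r2_adj,
    )


def select_significant(
    y: Iterable[float],
    X: pd.DataFrame,
    alpha: float = 0.05,
    eliminable: Sequence[str] | None = None,
    outcome: str = "y",
) -> RegressionModel:
    """Backward elimination of non-significant kinematic predictors.

    Repeatedly refits the model and drops the least-significant eliminable
    predictor with p > ``alpha`` until every remaining eliminable predictor
    is significant.  By default only the kinematic metrics are eliminable and
    the clinical adjustment covariates are always kept; pass ``eliminable``
    to change that.  May return a model with no kinematic predictors left.
    """
    X = pd.DataFrame(X).copy()
    if eliminable is None:
        eliminable = [c for c in X.columns if c in RMK_COLUMNS]
    eliminable = [c for c in eliminable if c in X.columns]

    while True:
        model = fit_ols(y, X, outcome=outcome)
        candidates = [
            (float(model.pvalues[c]), c)
            for c in eliminable
            if c in X.columns and float(model.pvalues[c]) > alpha
        ]
        if not candidates:
            return model
        _, worst = max(candidates)
        X = X.drop(columns=[worst])


# ---------------------------------------------------------------------------
# split-sample machinery


@dataclass
class SplitResult:
    """A train/validation partition with its balance diagnostics."""

    train_ids: list
    valid_ids: list
    seed: int
    train_frac: float
    balance: pd.DataFrame | None = None
    subgroup_balance: pd.DataFrame | None = None

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_valid(self) -> int:
        return len(self.valid_ids)


def split_sample(
    df: pd.DataFrame, train_frac: float = 0.75, seed: int = 0
) -> SplitResult:
    """Random train/validation partition without replacement.

    The training size is ``train_frac * n`` rounded half up (66 records at
    75% give a 50/16 split); the remainder forms the validation set.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    n = len(df)
    if n < 4:
        raise ValueError("need at least 4 records to split")
    n_train = int(math.floor(train_frac * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    ids = df["id"].tolist() if "id" in df.columns else list(df.index)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_ids = sorted((ids[i] for i in perm[:n_train]), key=ids.index)
    valid_ids = sorted((ids[i] for i in perm[n_train:]), key=ids.index)
    return SplitResult(train_ids, valid_ids, seed=seed, train_frac=train_frac)


_CATEGORICAL_BALANCE = ("sex", "side", "etiology")
_CONTINUOUS_BALANCE = (
    "age",
    "onset_days",
    "mi_elbow_t1",
    "mi_shoulder_t1",
    "mi_ul_t1",
) + RMK_COLUMNS


def _normalish(values: np.ndarray) -> bool:
    """Shapiro-Wilk normality pre-test at alpha = 0.05."""
    if values.size < 3 or np.unique(values).size < 3:
        return False
    return stats.shapiro(values).pvalue > 0.05


def balance_tests(
    df: pd.DataFrame,
    split: SplitResult,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check that the training and validation sets are exchangeable.

    Per variable: chi-square on the contingency table for categorical
    variables (Fisher's exact test when an expected cell count falls below
    one in a 2x2 table); for continuous variables, ANOVA when both sets pass
    a Shapiro-Wilk normality pre-test, otherwise the Mann-Whitney test.
    Categorical levels absent from both sets are dropped.

    Additionally the cohort is randomly divided into four equal groups and
    every pair of groups is compared with the Kruskal-Wallis test under
    Bonferroni correction (raw p times the number of pairs, capped at 1).

    Returns ``(per_variable, four_group)`` tables; rows with p <= ``alpha``
    are flagged as significant imbalance.
    """
    ids = df["id"] if "id" in df.columns else pd.Series(df.index, index=df.index)
    in_train = ids.isin(split.train_ids).to_numpy()
    if not in_train.any() or in_train.all():
        raise ValueError("both sets must be non-empty")

    rows = []
    for col in _CATEGORICAL_BALANCE:
        if col not in df.columns:
            continue
        table = pd.crosstab(in_train, df[col])
        table = table.loc[:, table.sum(axis=0) > 0]  # drop empty levels
        if table.shape[1] < 2:
            rows.append((col, "chi-square", 1.0))
            continue
        chi2, p, _, expected = stats.chi2_contingency(table)
        test = "chi-square"
        if table.shape == (2, 2) and expected.min() < 1:
            _, p = stats.fisher_exact(table)
            test = "fisher-exact"
        rows.append((col, test, float(p)))

    for col in _CONTINUOUS_BALANCE:
        if col not in df.columns:
            continue
        a = df.loc[in_train, col].to_numpy(dtype=float)
        b = df.loc[~in_train, col].to_numpy(dtype=float)
        if _normalish(a) and _normalish(b):
            p = float(stats.f_oneway(a, b).pvalue)
            if not math.isfinite(p):  # F rounds to <= 0 for identical groups
                p = 1.0
            test = "anova"
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            test = "mann-whitney"
        rows.append((col, test, p))

    balance = pd.DataFrame(rows, columns=["variable", "test", "p_value"])
    balance["significant"] = balance["p_value"] <= alpha

    # four-group Kruskal-Wallis battery
    n = len(df)
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(4), int(np.ceil(n / 4)))[:n]
    rng.shuffle(groups)
    sub_rows = []
    n_pairs = 6
    for col in _CONTINUOUS_BALANCE:
        if col not in df.columns:
            continue
        v = df[col].to_numpy(dtype=float)
        for g1 in range(4):
            for g2 in range(g1 + 1, 4):
                a, b = v[groups == g1], v[groups == g2]
                try:
                    p_raw = float(stats.kruskal(a, b).pvalue)
                except ValueError:  # all values identical in both groups
                    p_raw = 1.0
                sub_rows.append(
                    (col, f"{g1 + 1}-{g2 + 1}", p_raw, min(1.0, p_raw * n_pairs))
                )
    subgroup = pd.DataFrame(
        sub_rows, columns=["variable", "groups", "p_raw", "p_bonferroni"]
    )
    subgroup["significant"] = subgroup["p_bonferroni"] <= alpha
    return balance, subgroup


# ---------------------------------------------------------------------------
# validation procedures


@dataclass
class SSVResult:
    """Per-outcome result of the split-sample validation procedure."""

    outcome: str
    split: SplitResult
    full_model: RegressionModel
    model: RegressionModel
    train_report: ValidationReport
    valid_report: ValidationReport
    train_predictions: pd.Series
    valid_predictions: pd.Series
    standardizer: Standardizer


@dataclass
class LOOCVResult:
    """Per-outcome result of leave-one-out cross-validation."""

    outcome: str
    oof_predictions: pd.Series
    report: ValidationReport
    full_model: RegressionModel
    final_model: RegressionModel
    n_fits: int


def _prepared(df: pd.DataFrame) -> pd.DataFrame:
    out = df.reset_index(drop=True).copy()
    if "sex_male" not in out.columns and "sex" in out.columns:
        out["sex_male"] = (out["sex"] == "male").astype(float)
    return out


def run_ssv(
    df: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOMES,
    seed: int = 0,
    train_frac: float = 0.75,
    alpha: float = 0.05,
    select: bool = True,
    standardize_scope: str = "cohort",
    do_balance: bool = True,
    mae_denominator: str = "mean_observed",
) -> dict[str, SSVResult]:
    """Split-sample validation of every requested outcome.

    Pipeline: random 75/25 split -> balance tests -> fit the adjusted model
    on the training set (optionally reduced by backward elimination) ->
    evaluate on the training set and on the held-out validation set with the
    training model.

    ``standardize_scope`` chooses where the z-score transform is estimated:
    ``"cohort"`` (default) fits it once on all records before splitting;
    ``"train"`` fits it on the training set only and projects the validation
    set, avoiding any information flow from held-out records.
    """
    df = _prepared(df)
    split = split_sample(df, train_frac=train_frac, seed=seed)
    if do_balance:
        split.balance, split.subgroup_balance = balance_tests(df, split, seed=seed)

    ids = df["id"] if "id" in df.columns else pd.Series(df.index, index=df.index)
    train_mask = ids.isin(split.train_ids).to_numpy()

    if standardize_scope == "cohort":
        std = Standardizer().fit(df)
    elif standardize_scope == "train":
        std = Standardizer().fit(df.loc[train_mask])
    else:
        raise ValueError("standardize_scope must be 'cohort' or 'train'")
    sdf = std.transform(df)

    results: dict[str, SSVResult] = {}
    for outcome in outcomes:
        key = outcome.upper()
        scale = get_scale(key)
        y, X = design_matrix(sdf, key)
        y_tr, X_tr = y[train_mask], X.loc[train_mask]
        y_va, X_va = y[~train_mask], X.loc[~train_mask]

        full_model = fit_ols(y_tr, X_tr, outcome=key)
        model = (
            select_significant(y_tr, X_tr, alpha=alpha, outcome=key)
            if select
            else full_model
        )
        pred_tr = model.predict(X_tr)
        pred_va = model.predict(X_va)
        results[key] = SSVResult(
            outcome=key,
            split=split,
            full_model=full_model,
            model=model,
            train_report=evaluate_predictions(
                y_tr, pred_tr, scale, n_predictors=len(model.predictors),
                mae_denominator=mae_denominator,
            ),
            valid_report=evaluate_predictions(
                y_va, pred_va, scale, n_predictors=len(model.predictors),
                mae_denominator=mae_denominator,
            ),
            train_predictions=pd.Series(pred_tr, index=ids[train_mask].tolist()),
            valid_predictions=pd.Series(pred_va, index=ids[~train_mask].tolist()),
            standardizer=std,
        )
    return results


def run_loocv(
    df: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOMES,
    alpha: float = 0.05,
    select: bool = True,
    standardize_scope: str = "cohort",
    mae_denominator: str = "mean_observed",
) -> dict[str, LOOCVResult]:
    """Leave-one-out cross-validation of every requested outcome.

    For each of the n records the adjusted model is fitted on the remaining
    n - 1 and used to predict the held-out record; the evaluation panel is
    computed on the n pooled out-of-fold predictions.  The returned
    ``final_model`` is the full-data fit reduced by backward elimination --
    the deployable analogue of the published single-predictor equations.

    With ``standardize_scope="fold"`` the z-score transform is re-estimated
    on each fold's n - 1 training records; the default estimates it once on
    the full cohort, which keeps the design fixed across folds.
    """
    df = _prepared(df)
    n = len(df)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 records")
    ids = df["id"] if "id" in df.columns else pd.Series(df.index, index=df.index)

    if standardize_scope not in ("cohort", "fold"):
        raise ValueError("standardize_scope must be 'cohort' or 'fold'")

    results: dict[str, LOOCVResult] = {}
    for outcome in outcomes:
        key = outcome.upper()
        scale = get_scale(key)
        oof = np.empty(n)
        n_fits = 0
        if standardize_scope == "cohort":
            sdf = Standardizer().fit_transform(df)
            y, X = design_matrix(sdf, key)
            for i in range(n):
                mask = np.arange(n) != i
                model_i = fit_ols(y[mask], X.loc[mask], outcome=key)
                oof[i] = model_i.predict(X.iloc[[i]])[0]
                n_fits += 1
        else:
            y_all, _ = design_matrix(df, key)
            y = y_all
            for i in range(n):
                mask = np.arange(n) != i
                std = Standardizer().fit(df.loc[mask])
                sdf_i = std.transform(df)
                y_i, X_i = design_matrix(sdf_i, key)
                model_i = fit_ols(y_i[mask], X_i.loc[mask], outcome=key)
                oof[i] = model_i.predict(X_i.iloc[[i]])[0]
                n_fits += 1
            sdf = Standardizer().fit_transform(df)
            _, X = design_matrix(sdf, key)

        full_model = fit_ols(y, X, outcome=key)
        final_model = (
            select_significant(y, X, alpha=alpha, outcome=key) if select else full_model
        )
        results[key] = LOOCVResult(
            outcome=key,
            oof_predictions=pd.Series(oof, index=ids.tolist()),
            report=evaluate_predictions(
                y, oof, scale, n_predictors=X.shape[1],
                mae_denominator=mae_denominator,
            ),
            full_model=full_model,
            final_model=final_model,
            n_fits=n_fits,
        )
    return results
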