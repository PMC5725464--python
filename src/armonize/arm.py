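"""Alternating Regression Model (ARM) over method log2FC profiles.

Each method's profile serves in turn as the OLS response with the remaining
methods as regressors ("y ~ model" with rotation). Regressors whose
coefficients are not significant are eliminated; a rotation in which no
regressor survives is *non-predictable* — its fitted values are excluded
from the ensemble average, while the method itself still acts as a
(neutralized) regressor in the other rotations. The rotation-averaged
predicted profile is then thresholded with Tukey boxplot fences
[Q1 - k*IQR, Q3 + k*IQR]: values strictly outside are the high-confidence
coreset.

This module is fully deterministic; all stochasticity lives in
:mod:`armonize.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .errors import ConfigError, FitError, NumericalError, RankDeficiencyError, SelectionError
from .io import ProfileMatrix

INTERCEPT = "intercept"


@dataclass(frozen=True)
class ArmConfig:
    """Knobs of the alternating regression.

    alpha
        Two-sided significance level for coefficient retention (default 0.05).
    missing_policy
        ``complete_case`` restricts each fit to genes where the response and
        all current regressors are observed; ``mean_fill`` imputes a missing
        regressor cell with that regressor's mean over the response's domain.
    elimination
        ``backward`` repeatedly drops the worst regressor with p >= alpha and
        refits; ``single_pass`` fits once and only reports significance.
    multiplicity
        ``bonferroni`` (default) compares each coefficient p-value against
        alpha divided by the number of initial candidate regressors, so the
        chance of falsely declaring an unrelated response predictable is
        controlled familywise; ``none`` compares against alpha directly.
    summary_stat
        Which rotation-average (mean or median of fitted values) feeds the
        IQR selection.
    iqr_k
        Fence multiplier for the coreset selection (3 preferred for ARM
        predictions; 1.5 gives standard boxplot whiskers).
    """

    alpha: float = 0.05
    missing_policy: str = "complete_case"
    include_intercept: bool = True
    elimination: str = "backward"
    multiplicity: str = "bonferroni"
    summary_stat: str = "mean"
    iqr_k: float = 3.0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.multiplicity not in ("bonferroni", "none"):
            raise ConfigError("multiplicity must be 'bonferroni' or 'none'")
        if self.missing_policy not in ("complete_case", "mean_fill"):
            raise ConfigError("missing_policy must be 'complete_case' or 'mean_fill'")
        if self.elimination not in ("backward", "single_pass"):
            raise ConfigError("elimination must be 'backward' or 'single_pass'")
        if self.summary_stat not in ("mean", "median"):
            raise ConfigError("summary_stat must be 'mean' or 'median'")
        if self.iqr_k <= 0:
            raise ConfigError("iqr_k must be > 0")


@dataclass
class ArmFit:
    """One rotation's result: retained regressors, coefficients, fitted profile."""

    response: str
    regressors_initial: list[str]
    regressors_retained: list[str]
    coefficients: pd.Series
    coef_pvalues: pd.Series
    fitted: pd.Series
    r2: float
    n_obs: int
    predictable: bool


def _design(df: pd.DataFrame, rows: pd.Index, regressors: Sequence[str],
            response: str, cfg: ArmConfig):
    X = df.loc[rows, list(regressors)].copy()
    if cfg.missing_policy == "mean_fill":
        X = X.fillna(X.mean())
    y = df.loc[rows, response]
    if cfg.include_intercept:
        X = sm.add_constant(X, has_constant="add").rename(columns={"const": INTERCEPT})
    return y, X


def _check_rank(X: pd.DataFrame, response: str) -> None:
    arr = X.to_numpy(float)
    if arr.shape[1] == 0:
        return
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < arr.shape[1]:
        dependent = [X.columns[i] for i in piv[rank:] if X.columns[i] != INTERCEPT]
        raise RankDeficiencyError(
            f"rank-deficient design for response '{response}': "
            f"columns {dependent} are linearly dependent",
            dependent_columns=dependent,
        )


def _usable_rows(df: pd.DataFrame, response: str, regressors: Sequence[str],
                 cfg: ArmConfig) -> pd.Index:
    ok = df[response].notna()
    if cfg.missing_policy == "complete_case" and regressors:
        ok &= df[list(regressors)].notna().all(axis=1)
    return df.index[ok]


def fit_response(matrix: ProfileMatrix, response: str,
                 cfg: ArmConfig = ArmConfig()) -> ArmFit:
    """OLS of one method's profile on the remaining methods, with
    significance-driven regressor retention.

    Predictability is decided in two stages. First the full model must pass
    the overall F-test at ``alpha`` — a response none of the methods jointly
    explain is non-predictable outright. Then, under ``backward``
    elimination, the regressor with the largest non-significant p-value is
    dropped and the model refitted (the usable gene rows re-expand as
    regressors leave) until every retained coefficient is significant at
    the (multiplicity-corrected) alpha. If none survives the response is
    flagged non-predictable and an intercept-only record is returned.
    """
    if response not in matrix.methods:
        raise ConfigError(f"response '{response}' not among methods {matrix.methods}")
    df = matrix.data
    initial = [m for m in matrix.methods if m != response]
    current = list(initial)
    threshold = cfg.alpha / len(initial) if cfg.multiplicity == "bonferroni" else cfg.alpha

    result = None
    first_fit = True
    while current:
        rows = _usable_rows(df, response, current, cfg)
        if len(rows) < len(current) + 2:
            raise FitError(
                f"response '{response}': only {len(rows)} usable genes for "
                f"{len(current)} regressors"
            )
        y, X = _design(df, rows, current, response, cfg)
        _check_rank(X, response)
        result = sm.OLS(y.to_numpy(float), X).fit()
        if first_fit:
            # global gate: a response none of the methods jointly explain is
            # non-predictable outright, before any per-coefficient pruning
            f_p = float(result.f_pvalue)
            if np.isfinite(f_p) and f_p >= cfg.alpha:
                current = []
                break
            first_fit = False
        pvals = result.pvalues.drop(INTERCEPT, errors="ignore")
        if cfg.elimination == "single_pass":
            retained = [m for m in current if pvals[m] < threshold]
            if retained:
                return _package(response, initial, retained, result, X, rows,
                                predictable=True)
            current = []
            break
        worst = pvals.idxmax()
        if pvals[worst] < threshold:
            break  # everything retained is significant
        current.remove(worst)
        result = None

    if current:
        rows = _usable_rows(df, response, current, cfg)
        return _package(response, initial, current, result, None, rows,
                        predictable=True, frame=df, cfg=cfg)

    # nothing survived: intercept-only record, excluded from ensemble averaging
    rows = df.index[df[response].notna()]
    y = df.loc[rows, response].to_numpy(float)
    n = len(y)
    const = float(np.mean(y)) if cfg.include_intercept else 0.0
    coef = pd.Series({INTERCEPT: const}) if cfg.include_intercept else pd.Series(dtype=float)
    fitted = pd.Series(const, index=rows, name=response)
    return ArmFit(
        response=response,
        regressors_initial=initial,
        regressors_retained=[],
        coefficients=coef,
        coef_pvalues=pd.Series(dtype=float),
        fitted=fitted,
        r2=0.0,
        n_obs=n,
        predictable=False,
    )


def _package(response, initial, retained, result, X, rows, predictable,
             frame=None, cfg=None) -> ArmFit:
    if X is None:  # recompute fitted values for the final backward model
        y, X = _design(frame, rows, retained, response, cfg)
    fitted = pd.Series(np.asarray(result.predict(X)), index=rows, name=response)
    coefficients = result.params.copy()
    pvalues = result.pvalues.drop(INTERCEPT, errors="ignore")
    return ArmFit(
        response=response,
        regressors_initial=list(initial),
        regressors_retained=list(retained),
        coefficients=coefficients,
        coef_pvalues=pvalues,
        fitted=fitted,
        r2=float(result.rsquared),
        n_obs=len(rows),
        predictable=predictable,
    )


def rotate(matrix: ProfileMatrix, cfg: ArmConfig = ArmConfig()) -> list[ArmFit]:
    """Fit every rotation: one :class:`ArmFit` per method used as response.

    Each fit's gene domain adapts to its response (and to the regressors
    that survive elimination). Deterministic given matrix and config.
    """
    if len(matrix.methods) < 3:
        raise ConfigError("rotation needs >= 3 methods so every fit has >= 2 regressors")
    fits = []
    for m in matrix.methods:
        try:
            fits.append(fit_response(matrix, m, cfg))
        except NumericalError as e:
            raise type(e)(f"rotation with response '{m}' failed: {e}") from e
    return fits


@dataclass
class EnsembleProfile:
    """Rotation-averaged predicted profile.

    ``table`` holds per-gene mean and median of fitted values across the
    included (predictable) rotations plus the number contributing.
    """

    table: pd.DataFrame  # columns: mean, median, n_contributing
    included_responses: list[str]
    excluded_responses: dict[str, str] = field(default_factory=dict)

    def summary(self, stat: str = "mean") -> pd.Series:
        return self.table[stat]


def ensemble_average(fits: Sequence[ArmFit], cfg: ArmConfig = ArmConfig()) -> EnsembleProfile:
    """Average fitted profiles across predictable rotations.

    Non-predictable responses are excluded (with reason recorded) but remain
    neutralized regressors inside the other fits. Per gene, the mean and
    median are taken over the fitted values of the included rotations that
    cover that gene; genes covered by none are absent.
    """
    included = [f for f in fits if f.predictable]
    excluded = {
        f.response: "no significant regressors (non-predictable response)"
        for f in fits
        if not f.predictable
    }
    if not included:
        raise NumericalError("no predictable rotation: nothing to average")
    F = pd.DataFrame({f.response: f.fitted for f in included})
    table = pd.DataFrame(
        {
            "mean": F.mean(axis=1),
            "median": F.median(axis=1),
            "n_contributing": F.notna().sum(axis=1).astype(int),
        }
    )
    table = table[table["n_contributing"] >= 1]
    table.index.name = "gene_id"
    return EnsembleProfile(
        table=table,
        included_responses=[f.response for f in included],
        excluded_responses=excluded,
    )


@dataclass
class SelectionResult:
    """A boxplot-fence gene selection with the quartiles that produced it."""

    statistic_name: str
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    k: float
    selected: set[str]
    direction: pd.Series  # 'above' / 'below' per selected gene
    values: pd.Series  # the finite input values the fences were computed on

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.selected)
        return pd.DataFrame(
            {
                "value": self.values.reindex(genes),
                "direction": self.direction.reindex(genes),
            },
            index=pd.Index(genes, name="gene_id"),
        )


def iqr_select(values, k: float, statistic_name: str = "value") -> SelectionResult:
    """Tukey boxplot selection: keep values strictly outside
    [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation of the order statistics at positions
    (n-1) * {0.25, 0.75}. Values exactly on a fence are not selected.
    """
    v = pd.Series(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        raise SelectionError(f"iqr_select needs >= 4 finite values, got {len(v)}")
    q1, q3 = np.quantile(v.to_numpy(), [0.25, 0.75])
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    below = v < lower
    above = v > upper
    direction = pd.concat(
        [
            pd.Series("below", index=v.index[below]),
            pd.Series("above", index=v.index[above]),
        ]
    )
    return SelectionResult(
        statistic_name=statistic_name,
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(lower),
        upper_fence=float(upper),
        k=float(k),
        selected=set(v.index[below | above]),
        direction=direction,
        values=v,
    )


def fits_frame(fits: Sequence[ArmFit]) -> pd.DataFrame:
    """Flatten rotation fits into a per-coefficient report table."""
    rows = []
    for f in fits:
        for name, est in f.coefficients.items():
            rows.append(
                {
                    "response": f.response,
                    "term": name,
                    "estimate": est,
                    "pvalue": f.coef_pvalues.get(name, np.nan),
                    "retained": name == INTERCEPT or name in f.regressors_retained,
                    "r2": f.r2,
                    "n_obs": f.n_obs,
                    "predictable": f.predictable,
                }
            )
    return pd.DataFrame(rows)
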