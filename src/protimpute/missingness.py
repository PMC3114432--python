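"""Logistic modelling of why proteins go undetected.

The outcome is binary: 1 when a protein is undetected in a condition after
replicate collapse, 0 when measured. The linear predictor uses the
conventional display scaling of the covariates (mRNA abundance and gene
length on log2; instability index, aliphatic index and Nc divided by 10;
CAI, N_MFE, GRAVY and the correspondence axes multiplied by 10), which
leaves the fit invariant but makes odds ratios per "one displayed unit"
readable. Coefficients are maximum-likelihood (Newton/IRLS via
statsmodels), standard errors come from the inverse observed information,
and 95% Wald limits use z = 1.959964. Stepwise selection adds/removes
whole logical predictors by likelihood-ratio tests at a 0.05 threshold,
after a correlation pre-filter (|r| > 0.95 drops the later candidate).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Z_95",
    "StandardizedFeatures",
    "MissingnessModel",
    "standardize",
    "logistic_probability",
    "fit_logistic",
    "stepwise_select",
    "odds_ratio_table",
    "DEFAULT_CANDIDATES",
]

#: two-sided 95% normal quantile used for Wald limits
Z_95 = 1.959964

_DIV10 = ("InstabilityIndex", "AliphaticIndex", "Nc")
_MUL10 = (
    "CAI",
    "N_MFE",
    "GRAVY",
    "AA_axis1",
    "AA_axis2",
    "AA_axis3",
    "AA_axis4",
    "CR_axis1",
    "CR_axis2",
    "CR_axis3",
    "CR_axis4",
)

#: default candidate predictors for stepwise selection, in entry-tie order
DEFAULT_CANDIDATES = (
    "mRNA_log2",
    "InstabilityIndex",
    "gene_length_log2",
    "Nc",
    "CAI",
    "GRAVY",
    "AliphaticIndex",
    "AA_axis1",
    "AA_axis2",
    "AA_axis3",
    "AA_axis4",
    "CR_axis1",
    "CR_axis2",
    "CR_axis3",
    "CR_axis4",
    "A3s",
    "T3s",
    "C3s",
    "G3s",
    "GC3s",
    "GC",
)


@dataclasses.dataclass
class StandardizedFeatures:
    """Display-scaled covariates plus the binary undetected outcome."""

    X: pd.DataFrame
    y: pd.Series  # 1 = undetected
    scalings: dict[str, str]

    def __post_init__(self) -> None:
        if not set(pd.unique(self.y)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")


def standardize(features: pd.DataFrame, outcome: pd.Series) -> StandardizedFeatures:
    """Apply the display scalings and align covariates with the outcome.

    Columns already named ``*_log2`` are taken as pre-logged; raw ``mRNA``
    or ``gene_length`` columns are log2-transformed (errors name the first
    offending gene). Unknown columns pass through unchanged.
    """
    X = features.copy()
    scalings: dict[str, str] = {}
    for raw, logged in (("mRNA", "mRNA_log2"), ("gene_length", "gene_length_log2")):
        if raw in X.columns:
            bad = X.index[X[raw] <= 0]
            if len(bad):
                raise ValueError(f"non-positive {raw} for gene {bad[0]}: log2 undefined")
            X[logged] = np.log2(X.pop(raw))
            scalings[logged] = "log2"
    for col in X.columns:
        if col in _DIV10:
            X[col] = X[col] / 10.0
            scalings[col] = "/10"
        elif col in _MUL10:
            X[col] = X[col] * 10.0
            scalings[col] = "*10"
        else:
            scalings.setdefault(col, "unchanged")
    y = outcome.reindex(X.index).astype(float)
    if y.isna().any():
        X = X.loc[y.notna()]
        y = y.dropna()
    return StandardizedFeatures(X=X, y=y.astype(int), scalings=scalings)


def logistic_probability(beta, x):
    """p = e^eta / (e^eta + 1) for eta = beta . x, numerically stable."""
    eta = np.asarray(np.dot(np.atleast_1d(x), np.atleast_1d(beta)), dtype=float)
    return stats.logistic.cdf(eta)


@dataclasses.dataclass
class MissingnessModel:
    """Fitted logistic model for the probability a protein is undetected."""

    selected_features: list[str]
    beta: pd.Series
    se: pd.Series
    log_likelihood: float
    n_obs: int
    converged: bool
    selection_trace: list[dict] = dataclasses.field(default_factory=list)

    @property
    def odds_ratio(self) -> pd.Series:
        return np.exp(self.beta)

    @property
    def ci95(self) -> pd.DataFrame:
        lower = np.exp(self.beta - Z_95 * self.se)
        upper = np.exp(self.beta + Z_95 * self.se)
        return pd.DataFrame({"lower": lower, "upper": upper})

    def predict(self, X: pd.DataFrame) -> pd.Series:
        Xd = sm.add_constant(X[self.selected_features], has_constant="add")
        eta = Xd.to_numpy() @ self.beta.to_numpy()
        return pd.Series(stats.logistic.cdf(eta), index=X.index)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema": "protimpute-missingness/1",
            "selected_features": self.selected_features,
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "selection_trace": self.selection_trace,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _design(X: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    return sm.add_constant(X[list(columns)], has_constant="add")


def _fit_mle(Xd: pd.DataFrame, y: pd.Series):
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(y.to_numpy(), Xd.to_numpy()).fit(
                method="newton", maxiter=200, disp=0
            )
        except (np.linalg.LinAlgError, RuntimeWarning, Exception) as exc:
            name = type(exc).__name__
            if "Separation" in name or isinstance(
                exc, (np.linalg.LinAlgError, RuntimeWarning)
            ):
                raise ValueError(
                    f"logistic fit failed ({name}) for features "
                    f"{[c for c in Xd.columns if c != 'const']}: "
                    "possible complete separation or singular information"
                ) from exc
            raise
    if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.bse)):
        raise ValueError(
            "logistic fit did not converge for features "
            f"{[c for c in Xd.columns if c != 'const']}"
        )
    return res


def fit_logistic(
    data: StandardizedFeatures, feature_subset: Sequence[str] | None = None
) -> MissingnessModel:
    """Maximum-likelihood logistic fit of a fixed feature subset."""
    cols = list(feature_subset) if feature_subset is not None else list(data.X.columns)
    y = data.y
    complete = data.X[cols].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"dropping {int((~complete).sum())} row(s) with missing covariates",
            stacklevel=2,
        )
        data = StandardizedFeatures(
            X=data.X.loc[complete], y=y.loc[complete], scalings=data.scalings
        )
        y = data.y
    if y.nunique() < 2:
        raise ValueError("outcome has a single class")
    if len(y) <= len(cols) + 1:
        raise ValueError(f"n={len(y)} too small for {len(cols)} features")
    Xd = _design(data.X, cols)
    res = _fit_mle(Xd, y)
    names = ["intercept"] + cols
    return MissingnessModel(
        selected_features=cols,
        beta=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        log_likelihood=float(res.llf),
        n_obs=int(len(y)),
        converged=True,
    )


def _loglik(X: pd.DataFrame, y: pd.Series, cols: Sequence[str]) -> float:
    if cols:
        return float(_fit_mle(_design(X, cols), y).llf)
    p = y.mean()
    n = len(y)
    if p in (0.0, 1.0):
        return 0.0
    k = y.sum()
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def _lr_pvalue(ll_full: float, ll_reduced: float, df: int) -> float:
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    return float(stats.chi2.sf(stat, df))


def _expand(
    candidates: Sequence[str | tuple[str, Sequence[str]]]
) -> list[tuple[str, list[str]]]:
    out = []
    for c in candidates:
        if isinstance(c, str):
            out.append((c, [c]))
        else:
            name, cols = c
            out.append((name, list(cols)))
    return out


def correlation_prefilter(
    X: pd.DataFrame,
    candidates: Sequence[str | tuple[str, Sequence[str]]],
    threshold: float = 0.95,
) -> tuple[list[tuple[str, list[str]]], list[dict]]:
    """Drop the later of any single-column candidate pair with |r| above
    ``threshold``; multi-column (one-hot) blocks are never dropped."""
    expanded = _expand(candidates)
    kept: list[tuple[str, list[str]]] = []
    events: list[dict] = []
    for name, cols in expanded:
        drop_against = None
        if len(cols) == 1:
            for kname, kcols in kept:
                if len(kcols) != 1:
                    continue
                r = X[cols[0]].corr(X[kcols[0]])
                if np.isfinite(r) and abs(r) > threshold:
                    drop_against = (kname, float(r))
                    break
        if drop_against is None:
            kept.append((name, cols))
        else:
            events.append(
                {"action": "prefilter_drop", "feature": name,
                 "correlated_with": drop_against[0], "r": drop_against[1]}
            )
    return kept, events


def stepwise_select(
    data: StandardizedFeatures,
    candidates: Sequence[str | tuple[str, Sequence[str]]] | None = None,
    alpha_enter: float = 0.05,
    alpha_stay: float = 0.05,
    corr_threshold: float = 0.95,
) -> MissingnessModel:
    """Classic stepwise logistic selection with likelihood-ratio tests.

    Each iteration adds the candidate with the smallest LR p-value below
    ``alpha_enter`` (ties broken by candidate order), then removes any
    included predictor whose LR p-value exceeds ``alpha_stay``, until a
    fixed point. A candidate may be a column name or a named group of
    columns (e.g. a one-hot cellular-role block) tested jointly with df =
    block size. Inestimable candidates are skipped with a warning.
    """
    if candidates is None:
        candidates = [c for c in DEFAULT_CANDIDATES if c in data.X.columns] or list(
            data.X.columns
        )
    if not len(candidates):
        raise ValueError("no candidate features")
    pool, trace = correlation_prefilter(data.X, candidates, corr_threshold)
    # complete-case on the full candidate panel, so nested likelihood-ratio
    # tests always compare fits on identical rows
    all_cols = [c for _, cs in pool for c in cs]
    complete = data.X[all_cols].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"dropping {int((~complete).sum())} row(s) with missing covariates",
            stacklevel=2,
        )
    X, y = data.X.loc[complete], data.y.loc[complete]
    if y.nunique() < 2:
        raise ValueError("outcome has a single class")
    included: list[tuple[str, list[str]]] = []

    def cols_of(groups: Sequence[tuple[str, list[str]]]) -> list[str]:
        return [c for _, cs in groups for c in cs]

    ll_current = _loglik(X, y, cols_of(included))
    changed = True
    while changed:
        changed = False
        # forward step
        best: tuple[float, int] | None = None
        for i, (name, cols) in enumerate(pool):
            if any(name == n for n, _ in included):
                continue
            try:
                ll_new = _loglik(X, y, cols_of(included) + cols)
            except ValueError as exc:
                warnings.warn(f"skipping candidate {name}: {exc}", stacklevel=2)
                continue
            p = _lr_pvalue(ll_new, ll_current, df=len(cols))
            if p < alpha_enter and (best is None or p < best[0]):
                best = (p, i)
        if best is not None:
            p, i = best
            included.append(pool[i])
            ll_current = _loglik(X, y, cols_of(included))
            trace.append({"action": "add", "feature": pool[i][0], "p": p})
            changed = True
        # backward step: drop the worst predictor while any exceeds alpha_stay
        dropping = True
        while dropping and included:
            dropping = False
            worst: tuple[float, int] | None = None
            for i, (name, cols) in enumerate(included):
                reduced = [g for j, g in enumerate(included) if j != i]
                ll_red = _loglik(X, y, cols_of(reduced))
                p = _lr_pvalue(ll_current, ll_red, df=len(cols))
                if p > alpha_stay and (worst is None or p > worst[0]):
                    worst = (p, i)
            if worst is not None:
                p, i = worst
                trace.append({"action": "remove", "feature": included[i][0], "p": p})
                del included[i]
                ll_current = _loglik(X, y, cols_of(included))
                dropping = True
                changed = True

    final_cols = cols_of(included)
    filtered = StandardizedFeatures(X=X, y=y, scalings=data.scalings)
    if final_cols:
        model = fit_logistic(filtered, final_cols)
    else:
        # intercept-only model
        p = y.mean()
        n = len(y)
        beta0 = float(np.log(p / (1 - p)))
        se0 = float(np.sqrt(1.0 / (n * p * (1 - p))))
        model = MissingnessModel(
            selected_features=[],
            beta=pd.Series({"intercept": beta0}),
            se=pd.Series({"intercept": se0}),
            log_likelihood=_loglik(X, y, []),
            n_obs=n,
            converged=True,
        )
    model.selection_trace = trace
    return model


def odds_ratio_table(model: MissingnessModel, decimals: int | None = 3) -> pd.DataFrame:
    """Per-feature odds ratios with 95% Wald confidence limits.

    Rows: every selected feature (intercept excluded). ``decimals=None``
    returns unrounded values.
    """
    if not model.converged:
        raise ValueError("model did not converge")
    ors = model.odds_ratio.drop("intercept")
    ci = model.ci95.drop("intercept")
    table = pd.DataFrame(
        {
            "point_estimate": ors,
            "wald_lower_95": ci["lower"],
            "wald_upper_95": ci["upper"],
        }
    )
    table.index.name = "effect"
    return table.round(decimals) if decimals is not None else table
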