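"""Recurrence-association screening and gene-low survival stratification.

The screen fits one univariate Cox proportional-hazards model per gene on
z-scored expression against follow-up time and a binary recurrence event,
corrects Wald p-values across genes (Benjamini-Hochberg by default), and
splits significant genes by coefficient sign. Gene-low groups are called
against a normal-tissue reference: a tumor sample is "low" when its
lower-tail probability under a Normal fitted to the reference is below a
cutoff. Group outcome differences are summarized by a log-rank test and a
binary-covariate Cox hazard ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxScreenResult",
    "GroupComparison",
    "cox_screen",
    "multivariable_residual_test",
    "gene_low_groups",
    "quantile_split_groups",
    "compare_groups",
]


@dataclass
class CoxScreenResult:
    gene: str
    coefficient: float
    hr: float
    p: float
    q: float
    direction: str  # "positive" | "negative"
    significant: bool


@dataclass
class GroupComparison:
    labels: pd.Series  # "low" / "high" per sample
    hr: float
    logrank_p: float
    n_low: int
    frac_low: float


def _align(expression: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    missing = set(survival.index) - set(expression.columns)
    if missing:
        raise ValueError(f"expression lacks samples: {sorted(missing)[:5]} ...")
    return expression[survival.index.tolist()]


def cox_screen(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.01,
    method: str = "fdr_bh",
) -> list[CoxScreenResult]:
    """Univariate Cox screen of every gene against the recurrence endpoint.

    Expression is z-scored per gene so coefficients are log hazard ratios
    per standard deviation. Zero-variance and non-converging genes are
    skipped with a warning. A gene is significant when its corrected
    p-value (q) is below ``alpha``.
    """
    if int(survival["event"].sum()) < 10:
        raise ValueError("need at least 10 events for a stable screen")
    expr = _align(expression, survival)
    results: list[tuple[str, float, float]] = []  # gene, coef, p
    base = survival[["time", "event"]].copy()
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"gene {gene} has zero variance; skipped")
            continue
        df = base.copy()
        df["x"] = (x - x.mean()) / sd
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as err:  # non-convergence / singular fit
            warnings.warn(f"Cox fit failed for gene {gene}: {err}")
            continue
        results.append(
            (gene, float(cph.params_["x"]), float(cph.summary.loc["x", "p"]))
        )
    if not results:
        return []
    pvals = np.array([p for _, _, p in results])
    _, qvals, _, _ = multipletests(pvals, method=method)
    out = []
    for (gene, coef, p), q in zip(results, qvals):
        out.append(
            CoxScreenResult(
                gene=gene,
                coefficient=coef,
                hr=float(np.exp(coef)),
                p=p,
                q=float(q),
                direction="positive" if coef >= 0 else "negative",
                significant=bool(q < alpha),
            )
        )
    return out


def multivariable_residual_test(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    gene: str,
    covariates: list[str],
) -> dict[str, float]:
    """Wald p-values from a multivariable Cox fit of gene + clinical covariates.

    Tests whether the gene carries prognostic information beyond the listed
    covariates (its residual association). Collinear covariates surface as
    a fit error with the underlying diagnostic attached.
    """
    for c in covariates:
        if c not in survival.columns:
            raise ValueError(f"covariate {c!r} not in survival table")
    expr = _align(expression, survival)
    x = expr.loc[gene].to_numpy(dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError(f"gene {gene} has zero variance")
    df = survival[["time", "event", *covariates]].copy()
    df[gene] = (x - x.mean()) / sd
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:
        raise RuntimeError(f"multivariable Cox fit failed: {err}") from err
    return {term: float(cph.summary.loc[term, "p"]) for term in cph.params_.index}


def gene_low_groups(
    tumor_expr: pd.Series,
    reference_expr: pd.Series | np.ndarray,
    p_cut: float = 0.01,
) -> pd.Series:
    """Label tumors "low" whose lower-tail probability under a Normal fitted
    to the reference (moment estimates) is below ``p_cut``."""
    ref = np.asarray(reference_expr, dtype=float)
    if ref.size < 5:
        raise ValueError("need at least 5 reference samples")
    mu, sigma = ref.mean(), ref.std(ddof=1)
    if sigma == 0:
        raise ValueError("reference has zero variance")
    tail = stats.norm.cdf(np.asarray(tumor_expr, dtype=float), loc=mu, scale=sigma)
    labels = np.where(tail < p_cut, "low", "high")
    return pd.Series(labels, index=tumor_expr.index, name="group")


def quantile_split_groups(tumor_expr: pd.Series, frac_low: float) -> pd.Series:
    """Label the lowest ``ceil(frac_low * n)`` samples "low"; boundary ties
    are included in the low group."""
    if not 0 < frac_low < 1:
        raise ValueError("frac_low must lie in (0, 1)")
    values = tumor_expr.to_numpy(dtype=float)
    k = int(np.ceil(frac_low * len(values)))
    cutoff = np.sort(values)[k - 1]
    labels = np.where(values <= cutoff, "low", "high")
    return pd.Series(labels, index=tumor_expr.index, name="group")


def compare_groups(groups: pd.Series, survival: pd.DataFrame) -> GroupComparison:
    """Log-rank test and Cox hazard ratio of the low vs high group."""
    common = groups.index.intersection(survival.index)
    groups = groups.loc[common]
    surv = survival.loc[common]
    low = groups == "low"
    if low.all() or (~low).all():
        raise ValueError("both groups must be non-empty")
    if int(surv["event"].sum()) < 1:
        raise ValueError("need at least one event")
    lr = logrank_test(
        surv.loc[low.values, "time"],
        surv.loc[~low.values, "time"],
        event_observed_A=surv.loc[low.values, "event"],
        event_observed_B=surv.loc[~low.values, "event"],
    )
    df = surv[["time", "event"]].copy()
    df["low"] = low.astype(int).values
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return GroupComparison(
        labels=groups,
        hr=float(np.exp(cph.params_["low"])),
        logrank_p=float(lr.p_value),
        n_low=int(low.sum()),
        frac_low=float(low.mean()),
    )
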