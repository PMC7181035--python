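"""Cluster–health-index association statistics.

Three layers, mirroring how small-area health indicators are usually
related to a categorical exposure:

* tertile discretization of each indicator (equal-count thirds) followed by
  a Pearson chi-squared test of independence on the K × 3 cluster-by-tertile
  contingency table;
* univariate multinomial logistic regression of cluster membership on a
  single indicator (continuous, or tertile dummies with the first tertile
  as reference), reporting per-contrast odds ratios against a baseline
  cluster, the standard error of the coefficient, and Wald p-values;
* multivariate multinomial regression with backward stepwise selection on
  AIC, removing the term group (all dummy columns of one variable at once)
  whose removal most decreases AIC until no removal helps.

Rows with missing values are removed per variable for univariate runs and
once up front, across all candidate variables, for the multivariate run.
No multiple-testing correction is applied; raw p-values and their negative
base-10 logarithms are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

__all__ = [
    "TertileScheme",
    "ContingencyTable",
    "MultinomialFit",
    "discretize_tertiles",
    "contingency_chi2",
    "tertile_dummies",
    "fit_multinomial",
    "backward_stepwise_aic",
    "chi2_summary_table",
]


@dataclass(frozen=True)
class TertileScheme:
    """Empirical cut points splitting a variable into equal-count thirds."""

    lower_cut: float
    upper_cut: float
    counts: tuple[int, int, int]


@dataclass
class ContingencyTable:
    counts: pd.DataFrame  # K × 3, rows = clusters, columns = tertiles
    chi2_statistic: float
    dof: int
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        # clip so a numerically-zero p still yields a finite bar height
        return float(-np.log10(max(self.p_value, 1e-300)))


@dataclass
class MultinomialFit:
    """Per-contrast coefficients of a multinomial logit vs a baseline cluster.

    ``table`` has one row per (contrast, term): beta, OR = exp(beta), SE of
    beta, and the Wald p-value.
    """

    baseline_cluster: int
    contrasts: list[int]
    table: pd.DataFrame
    aic: float
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    _result: object = field(default=None, repr=False)


def discretize_tertiles(values) -> tuple[TertileScheme, np.ndarray]:
    """Assign each observation to tertile 1, 2 or 3 of its distribution.

    Cuts sit at the 1/3 and 2/3 empirical quantiles; ties are broken by
    stable rank so category counts are as equal as possible.  Missing
    values stay missing (NaN in the returned float vector).
    """
    v = np.asarray(values, dtype=float)
    obs = np.where(~np.isnan(v))[0]
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanmin(v) == np.nanmax(v):
        raise ValueError("constant vector cannot be discretized")
    order = obs[np.argsort(v[obs], kind="stable")]
    m = len(obs)
    cats = np.full(v.shape, np.nan)
    counts = [0, 0, 0]
    for rank, idx in enumerate(order):
        c = (rank * 3) // m  # 0, 1 or 2
        cats[idx] = c + 1
        counts[c] += 1
    scheme = TertileScheme(
        lower_cut=float(np.quantile(v[obs], 1 / 3)),
        upper_cut=float(np.quantile(v[obs], 2 / 3)),
        counts=tuple(counts),
    )
    return scheme, cats


def contingency_chi2(cluster_labels, categories) -> ContingencyTable:
    """Pearson chi-squared test of cluster-tertile independence.

    Rows with a missing category are dropped.  Degrees of freedom are
    (K - 1) * 2 for K clusters and three tertiles.
    """
    labels = np.asarray(cluster_labels)
    cats = np.asarray(categories, dtype=float)
    keep = ~np.isnan(cats)
    table = pd.crosstab(
        pd.Series(labels[keep], name="cluster"),
        pd.Series(cats[keep].astype(int), name="tertile"),
    ).reindex(columns=[1, 2, 3], fill_value=0)
    if len(table) < 2:
        raise ValueError("need at least 2 clusters for a chi-squared test")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero margin")
    stat, p, dof, _ = chi2_contingency(table.to_numpy(), correction=False)
    return ContingencyTable(
        counts=table, chi2_statistic=float(stat), dof=int(dof), p_value=float(p)
    )


def tertile_dummies(categories, name: str) -> pd.DataFrame:
    """Two dummy columns for tertiles 2 and 3, tertile 1 as reference."""
    cats = np.asarray(categories, dtype=float)
    return pd.DataFrame(
        {f"{name}__t2": (cats == 2).astype(float),
         f"{name}__t3": (cats == 3).astype(float)}
    )


def fit_multinomial(
    predictors: pd.DataFrame, cluster_labels, baseline: int = 1
) -> MultinomialFit:
    """Maximum-likelihood multinomial logit of cluster on the predictors.

    Rows with any missing predictor are removed first.  Each non-baseline
    cluster is contrasted against ``baseline``; per-term standard errors
    come from the observed information matrix and p-values are Wald tests.
    AIC is 2 * n_params - 2 * logLik.
    """
    labels = np.asarray(cluster_labels)
    x = predictors.reset_index(drop=True)
    keep = ~x.isna().any(axis=1).to_numpy()
    x, labels = x.loc[keep].reset_index(drop=True), labels[keep]
    clusters = sorted(set(labels.tolist()))
    if baseline not in clusters:
        raise ValueError(f"baseline cluster {baseline} absent from labels")
    # statsmodels uses the first category as baseline; put `baseline` first
    order = [baseline] + [c for c in clusters if c != baseline]
    codes = np.array([order.index(c) for c in labels])
    exog = sm.add_constant(x, has_constant="add")
    fit_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MNLogit(codes, exog)
        try:
            res = model.fit(method="newton", maxiter=200, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res, converged = None, False
        if not converged:
            # Newton struggles under quasi-complete separation (the MLE sits
            # at infinity and the Hessian degenerates); BFGS walks up the
            # plateau instead, and convergence is judged by the relative
            # log-likelihood improvement falling below 1e-8
            bfgs = model.fit(method="bfgs", maxiter=1000, gtol=1e-8, disp=0)
            if res is None or bfgs.llf >= res.llf:
                res = bfgs
                converged = bool(bfgs.mle_retvals.get("converged", False))
            for _ in range(20):
                if converged:
                    break
                cont = model.fit(
                    start_params=res.params, method="bfgs", maxiter=50, disp=0
                )
                if cont.llf < res.llf:
                    break
                rel = abs(cont.llf - res.llf) / max(abs(res.llf), 1.0)
                res = cont
                if rel < 1e-8:
                    converged = True
        fit_warnings = [str(w.message) for w in caught]
    contrasts = order[1:]
    rows = []
    params = np.asarray(res.params)  # (n_terms, K-1)
    try:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bse = np.asarray(res.bse)
            pvals = np.asarray(res.pvalues)
        if not np.all(np.isfinite(bse)):
            raise ValueError("non-finite standard errors")
    except (ValueError, np.linalg.LinAlgError):
        # observed information is singular at the boundary (separation);
        # fall back to its pseudo-inverse for Wald quantities
        from scipy.stats import norm as _norm

        try:
            hess = np.asarray(model.hessian(params.ravel(order="F")), dtype=float)
            hess[~np.isfinite(hess)] = 0.0
            cov = np.linalg.pinv(-hess)
            se_flat = np.sqrt(np.clip(np.diag(cov), 0, None))
            bse = se_flat.reshape(params.shape, order="F")
            fit_warnings.append("singular information matrix; SEs from pseudo-inverse")
        except np.linalg.LinAlgError:
            bse = np.full(params.shape, np.nan)
            fit_warnings.append("information matrix unusable; SEs unavailable")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = params / bse
        pvals = 2 * _norm.sf(np.abs(z))
    terms = list(exog.columns)
    for j, contrast in enumerate(contrasts):
        for i, term in enumerate(terms):
            rows.append(
                {
                    "contrast": contrast,
                    "term": term,
                    "beta": params[i, j],
                    "OR": float(np.exp(params[i, j])),
                    "SE": bse[i, j],
                    "p": pvals[i, j],
                }
            )
    n_params = params.size
    return MultinomialFit(
        baseline_cluster=baseline,
        contrasts=contrasts,
        table=pd.DataFrame(rows),
        aic=float(2 * n_params - 2 * res.llf),
        loglik=float(res.llf),
        n_params=int(n_params),
        n_obs=int(len(labels)),
        converged=converged,
        warnings=fit_warnings,
        _result=res,
    )


def backward_stepwise_aic(
    term_groups: dict[str, list[str]],
    predictors: pd.DataFrame,
    cluster_labels,
    baseline: int = 1,
) -> tuple[list[str], MultinomialFit, pd.DataFrame]:
    """Backward elimination of term groups by AIC.

    At every step the group whose removal most decreases AIC is dropped;
    the procedure stops when no single removal decreases AIC.  All columns
    of one variable (e.g. its two tertile dummies) leave together.  Rows
    with any missing value across all candidate columns are removed once,
    up front.  Returns the retained group names, the final fit, and a step
    log with the AIC at each accepted step.
    """
    all_cols = [c for cols in term_groups.values() for c in cols]
    x = predictors[all_cols].reset_index(drop=True)
    labels = np.asarray(cluster_labels)
    keep = ~x.isna().any(axis=1).to_numpy()
    x, labels = x.loc[keep].reset_index(drop=True), labels[keep]

    current = list(term_groups)

    def fit_for(groups: list[str]) -> MultinomialFit:
        cols = [c for g in groups for c in term_groups[g]]
        return fit_multinomial(x[cols], labels, baseline=baseline)

    fit = fit_for(current)
    if not fit.converged:
        raise RuntimeError("full model did not converge")
    log = [{"step": 0, "removed": None, "aic": fit.aic, "n_groups": len(current)}]
    step = 0
    while len(current) > 1:
        candidates = []
        for g in current:
            reduced = [h for h in current if h != g]
            candidates.append((g, fit_for(reduced)))
        g_best, fit_best = min(candidates, key=lambda gf: gf[1].aic)
        if fit_best.aic >= fit.aic:
            break
        step += 1
        current = [h for h in current if h != g_best]
        fit = fit_best
        log.append(
            {"step": step, "removed": g_best, "aic": fit.aic, "n_groups": len(current)}
        )
    return current, fit, pd.DataFrame(log)


def chi2_summary_table(
    block_indexes: pd.DataFrame, cluster_labels, indicators: list[str]
) -> pd.DataFrame:
    """Tertile chi-squared tests for every indicator; one row per variable."""
    rows = []
    for ind in indicators:
        _, cats = discretize_tertiles(block_indexes[ind].to_numpy())
        ct = contingency_chi2(cluster_labels, cats)
        rows.append(
            {
                "variable": ind,
                "chi2": ct.chi2_statistic,
                "dof": ct.dof,
                "p": ct.p_value,
                "neg_log10_p": ct.neg_log10_p,
            }
        )
    return pd.DataFrame(rows)
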