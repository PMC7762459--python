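"""Survival estimation and clinical association for molecular subclasses.

Thin, validated wrappers around lifelines (Kaplan-Meier product-limit
estimator, multivariate log-rank test) plus Fisher/ANOVA association of
subclass labels with clinical variables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import gammaln

from .multitest import bh_adjust

logger = logging.getLogger(__name__)


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate.

    Censored subjects leave the risk set without a drop.  Returns a step
    table with columns ``time`` and ``survival`` (S(0) = 1 included).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) < 1:
        raise ValueError("need at least one record")
    if (time < 0).any():
        raise ValueError("negative survival time")
    km = KaplanMeierFitter().fit(time, event)
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank_test(time, event, groups):
    """K-sample log-rank test (observed minus expected over event times).

    Returns ``(chi2, df, p)`` with df = n_groups - 1.  With no events
    anywhere the statistic is 0 and p = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    df = len(uniq) - 1
    if event.sum() == 0:
        return 0.0, df, 1.0
    res = multivariate_logrank_test(time, groups, event)
    stat = float(res.test_statistic)
    if np.isnan(stat):
        return 0.0, df, 1.0
    return stat, df, float(res.p_value)


def fisher_exact_table(table: np.ndarray, n_mc: int = 20000,
                       seed: int = 0) -> float:
    """Two-sided Fisher's exact p for an r x c contingency table.

    2x2 tables use the exact conditional test; larger tables use Monte
    Carlo over tables with the observed margins, counting tables whose
    conditional probability does not exceed the observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)

    def log_pmf(t):
        n = t.sum()
        return (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                - gammaln(n + 1) - gammaln(t + 1).sum())

    obs = log_pmf(table)
    dist = stats.random_table(rows, cols)
    draws = dist.rvs(n_mc, random_state=np.random.default_rng(seed))
    lp = np.array([log_pmf(t) for t in draws])
    return float((1 + np.sum(lp <= obs + 1e-9)) / (n_mc + 1))


def associate_clinical(labels: pd.Series, clinical: pd.DataFrame,
                       variable_types: dict,
                       seed: int = 0) -> pd.DataFrame:
    """Test each clinical variable against subclass labels.

    ``variable_types`` maps column name to ``'categorical'`` (Fisher's
    exact test) or ``'continuous'`` (one-way ANOVA F-test across
    subclasses).  Variables with a single level, or continuous variables
    with zero variance in every group, are skipped/flagged; p-values are
    BH-adjusted across the tested variables.
    """
    common = labels.index.intersection(clinical.index)
    lab = labels.loc[common]
    rows = []
    for var, kind in variable_types.items():
        if var not in clinical.columns:
            logger.warning("associate_clinical: %s absent, skipped", var)
            continue
        x = clinical.loc[common, var]
        ok = x.notna()
        if kind == "categorical":
            if x[ok].nunique() < 2:
                logger.warning("associate_clinical: %s has a single level, "
                               "skipped", var)
                continue
            table = pd.crosstab(lab[ok], x[ok]).to_numpy()
            p = fisher_exact_table(table, seed=seed)
            rows.append((var, kind, np.nan, p, ""))
        elif kind == "continuous":
            groups = [x[ok][lab[ok] == g].to_numpy(float)
                      for g in sorted(lab[ok].unique())]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                continue
            if all(np.var(g) == 0 for g in groups):
                rows.append((var, kind, np.nan, np.nan, "degenerate"))
                continue
            f, p = stats.f_oneway(*groups)
            rows.append((var, kind, float(f), float(p), ""))
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var}")
    out = pd.DataFrame(rows, columns=["variable", "type", "statistic", "p",
                                      "note"])
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out
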