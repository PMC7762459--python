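"""Downstream statistics: ssGSEA, E2F/TP53 subgroups, mutual exclusivity,
over-representation, and rank tests.

ssGSEA follows the weighted Kolmogorov-Smirnov running-sum form: per
sample, genes are ranked by expression and the enrichment score integrates
the deviation between the weighted in-set CDF and the uniform out-of-set
CDF.  Mutual exclusivity of two binary alteration events uses a one-sided
binomial test against the product-of-marginals co-occurrence null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (each non-empty, ids unique within a set)."""
    sets: dict
    source: str = ""

    def __post_init__(self):
        clean = {}
        for name, genes in self.sets.items():
            genes = list(dict.fromkeys(genes))
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = genes
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, genes... per tab-separated line)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets, source or str(path))


def ssgsea(expr_col: pd.Series, gene_set,
           weight_exponent: float = 0.75) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ranked by expression (descending; ties broken by gene name
    for determinism).  Walking down the ranking, the running sum gains
    ``|x|^w / sum_set |x|^w`` at in-set genes and loses ``1/(N - n_set)``
    at out-of-set genes; the enrichment score is the sum of the running
    sum over all positions (integrated form).  Positive scores mean the
    set concentrates at the top of the ranking.
    """
    genes = list(expr_col.index)
    inset = set(gene_set) & set(genes)
    if not inset:
        raise ValueError("gene set does not intersect the expression index")
    order = sorted(genes, key=lambda g: (-float(expr_col[g]), g))
    x = np.array([float(expr_col[g]) for g in order])
    hit = np.array([g in inset for g in order])
    n = len(order)
    n_set = int(hit.sum())
    if n_set == n:
        raise ValueError("gene set covers the whole expression index")
    w = np.abs(x) ** weight_exponent
    denom = w[hit].sum()
    steps = np.where(hit,
                     w / denom if denom > 0 else 1.0 / n_set,
                     -1.0 / (n - n_set))
    return float(np.cumsum(steps).sum())


def ssgsea_matrix(expr: pd.DataFrame, collection: GeneSetCollection,
                  weight_exponent: float = 0.75) -> pd.DataFrame:
    """Enrichment scores for every (set, sample); sets x samples."""
    out = {}
    for name, genes in collection.sets.items():
        out[name] = [ssgsea(expr[c], genes, weight_exponent)
                     for c in expr.columns]
    return pd.DataFrame(out, index=expr.columns).T


SUBGROUPS = ("TP53m.E2Fh", "TP53m.E2Fl", "TP53w.E2Fh", "TP53w.E2Fl")


def subgroup_e2f_tp53(expr: pd.DataFrame, tp53_mut: pd.Series,
                      activity: pd.Series | None = None):
    """Four tumor subgroups from E2F expression and TP53 mutation status.

    The E2F score per tumor is the mean of the standardized E2F1 and E2F2
    expression rows; E2F-high means above the cohort median.  Crossing
    with TP53 mutation status yields the four subgroups.  Samples without
    mutation data are excluded (logged).  If a per-sample pathway
    ``activity`` vector is supplied, pairwise Wilcoxon rank-sum
    comparisons across the subgroups are returned as well.

    Returns ``labels`` or ``(labels, comparisons)``.
    """
    for g in ("E2F1", "E2F2"):
        if g not in expr.index:
            raise ValueError(f"expression matrix must contain row {g}")
    known = tp53_mut.reindex(expr.columns)
    keep = known.notna()
    if (~keep).any():
        logger.warning("subgroup_e2f_tp53: %d samples lack TP53 status, "
                       "excluded", int((~keep).sum()))
    cols = expr.columns[keep]
    z = expr.loc[["E2F1", "E2F2"], cols]
    z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1).replace(0, 1), axis=0)
    score = z.mean(axis=0)
    high = score > score.median()
    mut = known[cols].astype(bool)
    labels = pd.Series(
        np.where(mut, np.where(high, "TP53m.E2Fh", "TP53m.E2Fl"),
                 np.where(high, "TP53w.E2Fh", "TP53w.E2Fl")),
        index=cols, name="subgroup")
    if activity is None:
        return labels
    rows = []
    present = [g for g in SUBGROUPS if (labels == g).any()]
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            xa = activity[labels.index[labels == a]].dropna()
            xb = activity[labels.index[labels == b]].dropna()
            stat, p = rank_tests(xa.to_numpy(), xb.to_numpy(),
                                 kind="wilcoxon")
            rows.append((a, b, float(xa.median()), float(xb.median()),
                         stat, p))
    comparisons = pd.DataFrame(rows, columns=["group_a", "group_b",
                                              "median_a", "median_b",
                                              "statistic", "p"])
    return labels, comparisons


def mutual_exclusivity(events_a, events_b, method: str = "binomial",
                       n_perm: int = 10000, seed: int | None = None):
    """One-sided test for fewer co-occurrences than expected.

    Under the default binomial null, the co-occurrence probability is the
    product of the two marginal event frequencies; with observed overlap
    k the p-value is P(X <= k) for X ~ Binomial(n, fA * fB).  Small p
    means mutual exclusivity.  ``method='permutation'`` instead permutes
    one event vector and counts overlaps at most k.

    Returns ``(k, p)``.
    """
    a = np.asarray(events_a, dtype=bool)
    b = np.asarray(events_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("event vectors must share the sample axis")
    n = a.size
    k = int(np.sum(a & b))
    fa, fb = a.mean(), b.mean()
    if fa == 0 or fb == 0:
        logger.warning("mutual_exclusivity: zero-frequency event, p = 1")
        return k, 1.0
    if method == "binomial":
        return k, float(stats.binom.cdf(k, n, fa * fb))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        hits = sum(int(np.sum(rng.permutation(a) & b)) <= k
                   for _ in range(n_perm))
        return k, float((1 + hits) / (n_perm + 1))
    raise ValueError(f"unknown method {method!r}")


def ora(query, collection: GeneSetCollection, background) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each set.

    ``background`` is either the background size (int; sets are assumed
    to lie within it) or the background gene list (sets are intersected
    with it; a set disjoint from the background is skipped).  One-sided
    upper-tail hypergeometric p per set, BH-adjusted across sets.
    """
    query = list(dict.fromkeys(query))
    if isinstance(background, int):
        n_bg = background
        bg = None
    else:
        bg = set(background)
        n_bg = len(bg)
        if not set(query) <= bg:
            raise ValueError("query must be a subset of the background")
    rows = []
    for name, genes in collection.sets.items():
        gset = set(genes) if bg is None else set(genes) & bg
        if not gset:
            logger.info("ora: set %s disjoint from background, skipped",
                        name)
            continue
        k = len(gset & set(query))
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(gset), len(query)))
        rows.append((name, len(gset), k, p))
    out = pd.DataFrame(rows, columns=["set", "n_set", "overlap", "p"])
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out


def rank_tests(x, y, kind: str = "wilcoxon"):
    """Two-sided rank-based tests.

    ``wilcoxon``: Wilcoxon rank-sum (Mann-Whitney) between the two value
    vectors, exact when both groups have at most 8 untied values;
    ``chi_square``: Pearson chi-square (no continuity correction) of the
    2 x C table whose rows are the two count vectors.

    Returns ``(statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if kind == "wilcoxon":
        ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method=method)
        return float(res.statistic), float(res.pvalue)
    if kind == "chi_square":
        table = np.vstack([x, y])
        if table.min() < 0:
            raise ValueError("chi-square requires non-negative counts")
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    raise ValueError(f"unknown test kind {kind!r}")
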