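"""Consensus clustering per platform and cluster-of-clusters (COCA).

Level one clusters each molecular platform's driver-feature matrix by
repeated subsampled clustering (NMF for non-negative matrices, k-means on
standardized features otherwise); the cluster number is chosen by the
cophenetic correlation between the consensus dissimilarity and its
hierarchical dendrogram.  Level two stacks the per-platform cluster
memberships into a binary indicator matrix and consensus-clusters the
samples over it, choosing the subclass number by the consensus-CDF
delta-area criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from sklearn.exceptions import ConvergenceWarning
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

logger = logging.getLogger(__name__)


@dataclass
class PlatformClustering:
    """One platform's consensus clustering."""
    labels: pd.Series
    k: int
    consensus: pd.DataFrame          # sample x sample co-clustering freq.
    cophenetic: dict                 # candidate k -> cophenetic coefficient
    method: str


@dataclass
class SubtypeAssignment:
    """Second-level (COCA) subclass labels with model-selection diagnostics."""
    coca_labels: pd.Series
    k: int
    indicator: pd.DataFrame          # sample x (sum of platform clusters)
    consensus: pd.DataFrame
    cdf_area: dict                   # candidate k -> area under consensus CDF
    delta_area: dict                 # candidate k -> relative gain


def _subsampled_consensus(data: np.ndarray, sample_ids, k: int,
                          n_resamples: int, subsample: float,
                          rng: np.random.Generator, method: str):
    """Consensus matrix over co-sampled pairs for one k."""
    n = len(sample_ids)
    hits = np.zeros((n, n))
    both = np.zeros((n, n))
    m = max(k + 1, int(round(subsample * n)))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, m, replace=False))
        sub = data[idx]
        seed = int(rng.integers(2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if method == "nmf":
                nmf = NMF(n_components=k, init="nndsvda", random_state=seed,
                          max_iter=400)
                w = nmf.fit_transform(np.maximum(sub, 0))
                lab = np.argmax(w, axis=1)
            else:
                lab = KMeans(n_clusters=k, n_init=5,
                             random_state=seed).fit_predict(sub)
        same = lab[:, None] == lab[None, :]
        hits[np.ix_(idx, idx)] += same
        both[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        cons = np.where(both > 0, hits / np.maximum(both, 1), 0.0)
    np.fill_diagonal(cons, 1.0)
    cons = 0.5 * (cons + cons.T)
    return pd.DataFrame(cons, index=sample_ids, columns=sample_ids)


def _hierarchical_cut(consensus: pd.DataFrame, k: int):
    d = squareform(np.clip(1.0 - consensus.to_numpy(), 0, None),
                   checks=False)
    link = average(d)
    labels = fcluster(link, k, criterion="maxclust")
    coph = cophenet(link, d)[0] if d.std() > 0 else 0.0
    return labels, float(np.nan_to_num(coph))


def consensus_cluster_platform(features: pd.DataFrame,
                               k_range=range(2, 7),
                               n_resamples: int = 100,
                               subsample: float = 0.8,
                               seed: int | None = None,
                               method: str = "auto") -> PlatformClustering:
    """Consensus-cluster one platform's samples over driver features.

    ``features`` is driver-feature x sample.  ``method`` is ``'nmf'``,
    ``'kmeans'`` or ``'auto'`` (NMF when the matrix is non-negative).  For
    each candidate k the consensus matrix of ``n_resamples`` subsampled
    clusterings is built; k is chosen by the maximal cophenetic
    correlation between 1 - consensus and its average-linkage dendrogram,
    and final labels come from the hierarchical cut of the chosen
    consensus.
    """
    n = features.shape[1]
    if max(k_range) >= n:
        raise ValueError("k must be smaller than the number of samples")
    if features.to_numpy().std() == 0:
        raise ValueError("constant feature matrix cannot be clustered")
    if method == "auto":
        method = "nmf" if (features.to_numpy() >= 0).all() else "kmeans"
    data = features.to_numpy(float).T        # samples x features
    if method == "kmeans":
        sd = data.std(axis=0)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)
    results = {}
    coph = {}
    for k in k_range:
        cons = _subsampled_consensus(data, list(features.columns), k,
                                     n_resamples, subsample, rng, method)
        labels, c = _hierarchical_cut(cons, k)
        results[k] = (cons, labels)
        coph[k] = c
    best_k = max(coph, key=lambda k: (coph[k], -k))
    cons, labels = results[best_k]
    return PlatformClustering(
        labels=pd.Series(labels, index=features.columns, name="cluster"),
        k=best_k, consensus=cons, cophenetic=coph, method=method)


def membership_indicator(clusterings: dict) -> pd.DataFrame:
    """Binary sample x (platform, cluster) membership matrix.

    Platforms are ordered by name so the construction is invariant to the
    order the clusterings are supplied in.  A sample missing from a
    platform's labeling gets an all-zero block for that platform (logged).
    """
    platforms = sorted(clusterings)
    all_samples = sorted({s for p in platforms
                          for s in _labels_of(clusterings[p]).index})
    cols = {}
    for p in platforms:
        lab = _labels_of(clusterings[p])
        missing = set(all_samples) - set(lab.index)
        if missing:
            logger.info("coca: %d samples missing platform %s",
                        len(missing), p)
        for c in sorted(lab.unique()):
            col = pd.Series(0, index=all_samples, dtype=int)
            col[lab.index[lab == c]] = 1
            cols[f"{p}:{c}"] = col
    return pd.DataFrame(cols, index=all_samples)


def _labels_of(obj) -> pd.Series:
    return obj.labels if isinstance(obj, PlatformClustering) else obj


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    x = np.sort(consensus[iu])
    m = len(x)
    # sum_{i>=2} (x_i - x_{i-1}) * F(x_{i-1}) with F the empirical CDF
    return float(np.sum(np.diff(x) * (np.arange(1, m) / m)))


def coca(clusterings: dict,
         k_range=range(2, 9),
         n_resamples: int = 100,
         subsample: float = 0.8,
         seed: int | None = None,
         delta_threshold: float = 0.025) -> SubtypeAssignment:
    """Cluster-of-clusters over per-platform cluster memberships.

    ``clusterings`` maps platform name to a :class:`PlatformClustering` or
    a label Series.  With a single platform the assignment reduces to that
    platform's labels.  The subclass number is the largest candidate k
    whose relative delta-area of the consensus CDF exceeds
    ``delta_threshold``.
    """
    if len(clusterings) == 0:
        raise ValueError("need at least one platform clustering")
    indicator = membership_indicator(clusterings)
    if len(clusterings) == 1:
        lab = _labels_of(next(iter(clusterings.values())))
        return SubtypeAssignment(
            coca_labels=lab.copy(), k=int(lab.nunique()),
            indicator=indicator,
            consensus=pd.DataFrame(np.eye(len(lab)), index=lab.index,
                                   columns=lab.index),
            cdf_area={}, delta_area={})
    rng = np.random.default_rng(seed)
    data = indicator.to_numpy(float)
    samples = list(indicator.index)
    k_range = [k for k in k_range if k < len(samples)]
    results, area = {}, {}
    for k in k_range:
        cons = _subsampled_consensus(data, samples, k, n_resamples,
                                     subsample, rng, "kmeans")
        results[k] = cons
        area[k] = _cdf_area(cons.to_numpy())
    delta = {}
    ks = sorted(area)
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    chosen = [k for k in ks if delta[k] > delta_threshold]
    best_k = max(chosen) if chosen else ks[0]
    labels, _ = _hierarchical_cut(results[best_k], best_k)
    return SubtypeAssignment(
        coca_labels=pd.Series(labels, index=samples, name="subclass"),
        k=best_k, indicator=indicator, consensus=results[best_k],
        cdf_area=area, delta_area=delta)


class COCA:
    """Cluster-of-clusters model over per-platform driver-feature matrices.

    Parameters
    ----------
    platform_features : dict of str -> DataFrame
        Per-platform feature x sample matrices restricted to driver
        features.
    """

    def __init__(self, platform_features: dict):
        if len(platform_features) == 0:
            raise ValueError("need at least one platform matrix")
        self.platform_features = dict(platform_features)

    def fit(self, k_range_platform=range(2, 7), k_range_coca=range(2, 9),
            n_resamples: int = 100, subsample: float = 0.8,
            seed: int | None = None,
            method: str = "auto") -> "COCAResults":
        ss = np.random.SeedSequence(seed)
        child = ss.spawn(len(self.platform_features) + 1)
        platform_clusterings = {}
        for i, p in enumerate(sorted(self.platform_features)):
            platform_clusterings[p] = consensus_cluster_platform(
                self.platform_features[p], k_range=k_range_platform,
                n_resamples=n_resamples, subsample=subsample,
                seed=child[i], method=method)
        subtypes = coca(platform_clusterings, k_range=k_range_coca,
                        n_resamples=n_resamples, subsample=subsample,
                        seed=child[-1])
        return COCAResults(self, platform_clusterings, subtypes)


@dataclass
class COCAResults:
    """Fitted COCA: per-platform clusterings plus second-level subclasses."""
    model: COCA
    platform_clusterings: dict
    subtypes: SubtypeAssignment

    def survival_association(self, clinical: pd.DataFrame):
        """Log-rank test of the COCA subclasses against a clinical table
        with columns ``time`` and ``event``."""
        from .survival import logrank_test
        common = clinical.index.intersection(self.subtypes.coca_labels.index)
        sub = clinical.loc[common]
        return logrank_test(sub["time"], sub["event"],
                            self.subtypes.coca_labels.loc[common])

    def summary(self) -> str:
        lines = ["Cluster-of-clusters (COCA)", "=========================="]
        for p, pc in sorted(self.platform_clusterings.items()):
            lines.append(f"platform {p}: k={pc.k} ({pc.method}), "
                         f"cophenetic={pc.cophenetic[pc.k]:.3f}")
        sizes = self.subtypes.coca_labels.value_counts().sort_index()
        lines.append(f"COCA subclasses: k={self.subtypes.k}, sizes="
                     + ", ".join(f"C{c}:{n}" for c, n in sizes.items()))
        return "\n".join(lines)
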