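"""Regulation programs and driver selection on top of consensus modules.

Each module gets a regulation program: a shallow binary tree over the
tumor samples, built by recursively splitting the module's mean-expression
profile at its best two-means cut.  Candidate regulators never define the
splits (preventing self-fulfilling scores); at every internal node each
regulator receives a soft separation score in (0, 1) for how well its
profile separates the two child sample blocks, calibrated against random
relabelings.  Regulator-to-module scores aggregate the significant node
scores; drivers are the union of the per-module top quantile and the
global top quantile by summed score.

The :class:`ModuleNetwork` model bundles the whole stage: Gibbs chains,
consensus modules, regulation trees, regulator scores and driver
selection, returning a :class:`ModuleNetworkResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import CandidateRegulatorSet
from .gibbs import (NormalGammaPrior, gibbs_cluster, consensus_modules,
                    ModuleAssignment)

PLATFORM_GROUPS = {
    "mutation": {"mutation"},
    "cnv": {"cnv_amp", "cnv_del"},
    "methylation": {"methylation"},
    "mirna": {"mirna"},
    "mrna": {"tf", "literature"},
}


@dataclass
class TreeNode:
    """Internal node: a bisection of its samples with regulator scores."""
    samples: np.ndarray          # positional sample indices at this node
    left: np.ndarray
    right: np.ndarray
    threshold: float             # cut on the module mean profile
    weight: float                # fraction of module samples at this node
    reg_scores: np.ndarray       # per-regulator separation score in [0, 1)
    reg_pvals: np.ndarray        # empirical p from random relabelings
    depth: int


@dataclass
class RegulationTree:
    """Per-module regulation program (list of internal nodes, root first)."""
    module_id: int
    nodes: list = field(default_factory=list)
    leaves: list = field(default_factory=list)  # sample blocks at the leaves

    @property
    def n_internal(self) -> int:
        return len(self.nodes)


@dataclass
class RegulatorScore:
    """Regulator x module score matrix and per-regulator summed score."""
    score: pd.DataFrame          # regulators (keys) x modules, >= 0
    summed: pd.Series            # row sums

    @classmethod
    def from_matrix(cls, score: pd.DataFrame) -> "RegulatorScore":
        return cls(score, score.sum(axis=1))


@dataclass
class DriverList:
    """Selected drivers with provenance of the selection rule.

    ``table`` has one row per driver key with columns ``id, platforms,
    summed_score, n_modules, by_module_rule, by_global_rule``.
    """
    table: pd.DataFrame
    per_module_q: float
    global_q: float

    @property
    def ids(self) -> list[str]:
        return sorted(self.table["id"].unique())

    def __len__(self) -> int:
        return len(self.table)


def _best_two_means_split(values: np.ndarray):
    """Optimal 1-D two-means cut: returns (mask_left, threshold, gain).

    Exact via prefix sums over the sorted values; ties broken by the first
    optimal cut.  Returns None when all values are equal.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return None
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)                       # left sizes
    sse_left = np.cumsum(v ** 2)[:-1] - csum[:-1] ** 2 / k
    right_sum = total - csum[:-1]
    sse_right = ((v ** 2).sum() - np.cumsum(v ** 2)[:-1]
                 - right_sum ** 2 / (n - k))
    valid = v[1:] > v[:-1]                    # cut only between distinct values
    sse = np.where(valid, sse_left + sse_right, np.inf)
    cut = int(np.argmin(sse))
    mask_left = np.zeros(n, dtype=bool)
    mask_left[order[:cut + 1]] = True
    threshold = 0.5 * (v[cut] + v[cut + 1])
    return mask_left, float(threshold), float(np.var(values) * n - sse[cut])


def _separation_scores(profiles: np.ndarray, left: np.ndarray,
                       right: np.ndarray) -> np.ndarray:
    """Soft separation score per regulator for a (left, right) sample split.

    z = |mean difference| / pooled SD, mapped through 2*sigmoid(z) - 1 so a
    constant profile scores exactly 0 and perfect separation approaches 1.
    """
    nl, nr = len(left), len(right)
    pl = profiles[:, left]
    pr = profiles[:, right]
    diff = pl.mean(axis=1) - pr.mean(axis=1)
    var_l = pl.var(axis=1, ddof=1) if nl > 1 else np.zeros(len(profiles))
    var_r = pr.var(axis=1, ddof=1) if nr > 1 else np.zeros(len(profiles))
    dof = max(nl + nr - 2, 1)
    pooled = np.sqrt(((nl - 1) * var_l + (nr - 1) * var_r) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(diff) / pooled
    z = np.where(pooled == 0, np.where(diff == 0, 0.0, np.inf), z)
    return np.where(np.isinf(z), 1.0, 2.0 / (1.0 + np.exp(-z)) - 1.0)


def fit_regulation_tree(module_mean: pd.Series,
                        candidate_profiles: pd.DataFrame,
                        module_id: int = 0,
                        max_depth: int = 3,
                        min_leaf: int = 5,
                        n_rand: int = 100,
                        seed: int | None = None) -> RegulationTree:
    """Fit one module's regulation program.

    ``module_mean`` is the module's mean expression per tumor sample;
    ``candidate_profiles`` is the regulator x sample covariate matrix on
    the same samples.  Samples are recursively bisected by the best
    two-means cut of the module mean; every internal node scores all
    regulators and calibrates each score against ``n_rand`` random
    relabelings of the node's samples into blocks of the same sizes
    (empirical p with the +1 correction).
    """
    samples = list(module_mean.index)
    prof = candidate_profiles.loc[:, samples].to_numpy(float)
    mean = module_mean.to_numpy(float)
    rng = np.random.default_rng(seed)
    tree = RegulationTree(module_id=module_id)
    n_total = len(samples)

    def recurse(idx: np.ndarray, depth: int):
        if depth >= max_depth or len(idx) < 2 * min_leaf:
            tree.leaves.append(idx)
            return
        split = _best_two_means_split(mean[idx])
        if split is None:
            tree.leaves.append(idx)
            return
        mask_left, threshold, _ = split
        left, right = idx[mask_left], idx[~mask_left]
        if len(left) < min_leaf or len(right) < min_leaf:
            tree.leaves.append(idx)
            return
        obs = _separation_scores(prof, left, right)
        exceed = np.zeros(len(prof))
        nl = len(left)
        for _ in range(n_rand):
            perm = rng.permutation(idx)
            rnd = _separation_scores(prof, perm[:nl], perm[nl:])
            exceed += rnd >= obs - 1e-12
        pvals = (1.0 + exceed) / (n_rand + 1.0)
        tree.nodes.append(TreeNode(
            samples=idx, left=left, right=right, threshold=threshold,
            weight=len(idx) / n_total, reg_scores=obs, reg_pvals=pvals,
            depth=depth))
        recurse(left, depth + 1)
        recurse(right, depth + 1)

    recurse(np.arange(n_total), 0)
    return tree


def score_regulators(trees: dict[int, RegulationTree],
                     regulator_keys,
                     p_threshold: float = 0.05) -> RegulatorScore:
    """Aggregate node scores into the regulator x module score matrix.

    score(r, m) = sum over internal nodes of module m's tree of
    node weight x r's node score, counting only nodes where r's empirical
    p is at most ``p_threshold``.
    """
    keys = list(regulator_keys)
    modules = sorted(trees)
    mat = np.zeros((len(keys), len(modules)))
    for j, m in enumerate(modules):
        for node in trees[m].nodes:
            sig = node.reg_pvals <= p_threshold
            mat[:, j] += np.where(sig, node.weight * node.reg_scores, 0.0)
    score = pd.DataFrame(mat, index=keys, columns=modules)
    return RegulatorScore.from_matrix(score)


def select_drivers(scores: RegulatorScore,
                   entries: pd.DataFrame | None = None,
                   per_module_q: float = 0.01,
                   global_q: float = 0.10) -> DriverList:
    """Quantile driver selection: per-module top 1% union global top 10%.

    Per module, regulators are ranked by score(., m) and the top
    ``ceil(per_module_q * R)`` with nonzero score are kept (boundary ties
    all included); globally, the top ``ceil(global_q * R)`` by summed
    score.  Zero-score regulators are never selected by either rule.
    ``entries`` (a candidate entry table with columns key/id/platform)
    maps profile keys back to ids and platform tags.
    """
    score = scores.score
    R = score.shape[0]
    if R < 1:
        raise ValueError("need at least one regulator")
    by_module: dict[str, list] = {}
    k_m = math.ceil(per_module_q * R)
    for m in score.columns:
        col = score[m]
        nz = col[col > 0].sort_values(ascending=False)
        if nz.empty:
            continue
        cutoff = nz.iloc[min(k_m, len(nz)) - 1]
        for key in nz[nz >= cutoff].index:
            by_module.setdefault(key, []).append(m)
    k_g = math.ceil(global_q * R)
    summed_nz = scores.summed[scores.summed > 0].sort_values(ascending=False)
    global_keys: set = set()
    if not summed_nz.empty:
        cutoff = summed_nz.iloc[min(k_g, len(summed_nz)) - 1]
        global_keys = set(summed_nz[summed_nz >= cutoff].index)

    selected = sorted(set(by_module) | global_keys)
    if entries is not None:
        key_id = dict(zip(entries["key"], entries["id"]))
        key_plat = dict(zip(entries["key"], entries["platform"]))
    else:
        key_id = {k: k for k in selected}
        key_plat = {k: "" for k in selected}
    rows = [{
        "key": k,
        "id": key_id.get(k, k),
        "platforms": key_plat.get(k, ""),
        "summed_score": float(scores.summed[k]),
        "n_modules": len(by_module.get(k, [])),
        "modules": by_module.get(k, []),
        "by_module_rule": k in by_module,
        "by_global_rule": k in global_keys,
    } for k in selected]
    cols = ["key", "id", "platforms", "summed_score", "n_modules",
            "modules", "by_module_rule", "by_global_rule"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values("summed_score",
                                  ascending=False).reset_index(drop=True)
    return DriverList(table, per_module_q, global_q)


def driver_module_counts(drivers: DriverList) -> pd.Series:
    """Per-driver count of modules where it passed the per-module rule.

    A driver selected only by the global rule has count 0.
    """
    return pd.Series(drivers.table["n_modules"].to_numpy(),
                     index=drivers.table["key"].to_numpy(),
                     name="n_modules")


class ModuleNetwork:
    """Module-network model: expression clustered into modules whose
    condition-dependent mean expression is predicted by candidate
    regulators.

    Parameters
    ----------
    expression : DataFrame
        Downstream (differentially expressed) genes x tumor samples,
        log2 scale.  Rows are standardized internally.
    candidates : CandidateRegulatorSet
        Regulator profiles over the same tumor samples.
    prior : NormalGammaPrior
        Cell-likelihood prior of the Gibbs sampler.
    """

    def __init__(self, expression: pd.DataFrame,
                 candidates: CandidateRegulatorSet,
                 prior: NormalGammaPrior = NormalGammaPrior()):
        missing = [s for s in expression.columns
                   if s not in candidates.profiles.columns]
        if missing:
            raise ValueError(f"candidate profiles missing samples: "
                             f"{missing[:5]}")
        self.expression = expression
        self.candidates = candidates
        self.prior = prior

    def fit(self, n_chains: int = 10, n_iter: int = 100,
            seed: int | None = None,
            co_clustering_threshold: float = 0.8,
            min_module_size: int = 5,
            max_depth: int = 3, min_leaf: int = 5, n_rand: int = 100,
            node_p_threshold: float = 0.05,
            per_module_q: float = 0.01,
            global_q: float = 0.10) -> "ModuleNetworkResults":
        """Run chains, form consensus modules, fit regulation programs,
        score regulators and select drivers."""
        ss = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
        chain_seed, tree_seed = ss.spawn(2)
        chains = gibbs_cluster(self.expression, n_chains=n_chains,
                               n_iter=n_iter, seed=chain_seed,
                               prior=self.prior)
        modules = consensus_modules(
            chains, co_clustering_threshold=co_clustering_threshold,
            min_module_size=min_module_size)
        trees = {}
        profiles = self.candidates.profiles[self.expression.columns]
        tree_seeds = tree_seed.spawn(max(modules.n_modules, 1))
        for i, m in enumerate(range(1, modules.n_modules + 1)):
            genes = modules.module_of_gene.index[
                modules.module_of_gene == m]
            mean = self.expression.loc[genes].mean(axis=0)
            trees[m] = fit_regulation_tree(
                mean, profiles, module_id=m, max_depth=max_depth,
                min_leaf=min_leaf, n_rand=n_rand, seed=tree_seeds[i])
        scores = score_regulators(trees, profiles.index,
                                  p_threshold=node_p_threshold)
        drivers = select_drivers(scores, self.candidates.entries,
                                 per_module_q=per_module_q,
                                 global_q=global_q)
        return ModuleNetworkResults(self, chains, modules, trees, scores,
                                    drivers)


@dataclass
class ModuleNetworkResults:
    """Fitted module network: modules, regulation programs, drivers."""
    model: ModuleNetwork
    chains: list
    modules: ModuleAssignment
    trees: dict
    scores: RegulatorScore
    drivers: DriverList

    def summary(self) -> str:
        lines = [
            "Module network",
            "==============",
            f"genes: {len(self.model.expression)}  "
            f"samples: {self.model.expression.shape[1]}  "
            f"candidate regulators: {len(self.model.candidates)}",
            f"chains: {len(self.chains)}  "
            f"consensus modules: {self.modules.n_modules}  "
            f"unassigned genes: "
            f"{int((self.modules.module_of_gene == 0).sum())}",
            f"drivers selected: {len(self.drivers)} "
            f"(per-module top {self.drivers.per_module_q:.0%}, "
            f"global top {self.drivers.global_q:.0%})",
            "",
            "id                platform      summed   modules",
        ]
        for _, r in self.drivers.table.head(20).iterrows():
            lines.append(f"{r['id']:<17} {r['platforms']:<13} "
                         f"{r['summed_score']:>7.3f}   {r['n_modules']}")
        return "\n".join(lines)
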