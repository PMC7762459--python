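"""Two-way Gibbs sampling of co-expression modules.

Genes are partitioned into modules and, within each module, samples into
blocks; the score of a configuration is the product over (module, sample
block) cells of the Normal-Gamma marginal likelihood of the cell's values.
Each sweep resamples every gene's module (Chinese-restaurant prior over
existing modules plus a new one) and every sample's block within each
module, proportional to the Bayesian score change of the move.  The
maximum-score sweep per chain is reported; tight consensus modules are
formed from the gene-gene co-clustering frequency across chains.

The sweep kernel is compiled with numba; :func:`partition_log_score` is the
plain-numpy scoring reference used for oracle checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass(frozen=True)
class NormalGammaPrior:
    """Conjugate Normal-Gamma prior on each cell's mean/precision.

    Defaults (mu0=0, lam0=0.1, a0=0.1, b0=0.1) are weakly informative and
    appropriate for row-standardized expression.
    """
    mu0: float = 0.0
    lam0: float = 0.1
    a0: float = 0.1
    b0: float = 0.1


@dataclass
class ModuleAssignment:
    """A gene -> module partition with optional per-module sample partitions.

    ``module_of_gene`` maps genes to integer module ids (0 = unassigned
    background, used by consensus assignments); ``sample_partitions`` maps
    module id to a list of disjoint sample-id blocks covering the sample
    set; ``trace`` is the per-sweep log-score of the producing chain and
    ``best_trace`` its running maximum (non-decreasing by construction).
    """
    module_of_gene: pd.Series
    n_modules: int
    sample_partitions: dict | None = None
    trace: np.ndarray | None = None
    best_score: float | None = None

    @property
    def best_trace(self) -> np.ndarray | None:
        if self.trace is None:
            return None
        return np.maximum.accumulate(self.trace)


def normal_gamma_logml(n, s, ss, prior: NormalGammaPrior = NormalGammaPrior()):
    """Log marginal likelihood of n observations with sum s and sum of
    squares ss under the Normal-Gamma prior (vectorized; n = 0 gives 0)."""
    from scipy.special import gammaln
    n = np.asarray(n, dtype=float)
    s = np.asarray(s, dtype=float)
    ss = np.asarray(ss, dtype=float)
    lam_n = prior.lam0 + n
    a_n = prior.a0 + 0.5 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), 0.0)
        b_n = (prior.b0 + 0.5 * (ss - n * mean ** 2)
               + 0.5 * prior.lam0 * n * (mean - prior.mu0) ** 2 / lam_n)
        out = (gammaln(a_n) - gammaln(prior.a0)
               + prior.a0 * np.log(prior.b0) - a_n * np.log(b_n)
               + 0.5 * (np.log(prior.lam0) - np.log(lam_n))
               - 0.5 * n * np.log(2.0 * np.pi))
    return np.where(n > 0, out, 0.0)


def partition_log_score(X: np.ndarray,
                        gene_labels,
                        sample_blocks: Mapping | None = None,
                        prior: NormalGammaPrior = NormalGammaPrior()) -> float:
    """Total log score of a (gene partition, per-module sample partition).

    ``X`` is gene x sample; ``gene_labels`` assigns each row a module;
    ``sample_blocks`` optionally maps a module label to per-sample block
    labels (default: one block holding every sample).  The score is the sum
    over (module, block) cells of the Normal-Gamma log marginal likelihood
    and is invariant to exchanging genes within a module.
    """
    X = np.asarray(X, dtype=float)
    gene_labels = np.asarray(gene_labels)
    total = 0.0
    for m in np.unique(gene_labels):
        sub = X[gene_labels == m]
        blocks = (np.zeros(X.shape[1], dtype=int) if sample_blocks is None
                  else np.asarray(sample_blocks[m]))
        for b in np.unique(blocks):
            vals = sub[:, blocks == b].ravel()
            total += float(normal_gamma_logml(vals.size, vals.sum(),
                                              (vals ** 2).sum(), prior))
    return total


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _logml(n, s, ss, lam0, a0, b0, lgam_a0, mu0=0.0):
    if n <= 0.0:
        return 0.0
    lam_n = lam0 + n
    a_n = a0 + 0.5 * n
    mean = s / n
    b_n = (b0 + 0.5 * (ss - n * mean * mean)
           + 0.5 * lam0 * n * (mean - mu0) ** 2 / lam_n)
    return (math.lgamma(a_n) - lgam_a0 + a0 * math.log(b0)
            - a_n * math.log(b_n) + 0.5 * (math.log(lam0) - math.log(lam_n))
            - 0.5 * n * math.log(2.0 * math.pi))


@njit(cache=True)
def _sample_index(logp, k):
    """Draw from categorical proportional to exp(logp[:k])."""
    mx = logp[0]
    for i in range(1, k):
        if logp[i] > mx:
            mx = logp[i]
    tot = 0.0
    for i in range(k):
        logp[i] = math.exp(logp[i] - mx)
        tot += logp[i]
    u = np.random.random() * tot
    acc = 0.0
    for i in range(k):
        acc += logp[i]
        if u <= acc:
            return i
    return k - 1


@njit(cache=True)
def _run_chain(X, n_iter, seed, alpha_gene, alpha_block, kmax, bmax,
               lam0, a0, b0):
    G, S = X.shape
    lgam_a0 = math.lgamma(a0)
    np.random.seed(seed)

    z = np.empty(G, dtype=np.int64)
    gc = np.zeros(kmax, dtype=np.int64)
    w = np.zeros((kmax, S), dtype=np.int64)
    nb = np.zeros(kmax, dtype=np.int64)
    bc = np.zeros((kmax, bmax), dtype=np.int64)
    N = np.zeros((kmax, bmax))
    S1 = np.zeros((kmax, bmax))
    S2 = np.zeros((kmax, bmax))

    # init: random modules, two random sample blocks per module
    M = min(kmax, max(2, G // 10))
    for g in range(G):
        z[g] = np.random.randint(0, M)
        gc[z[g]] += 1
    for m in range(M):
        if gc[m] == 0:  # ensure no empty initial module
            g = np.random.randint(0, G)
            while gc[z[g]] <= 1:
                g = np.random.randint(0, G)
            gc[z[g]] -= 1
            z[g] = m
            gc[m] += 1
        nb[m] = 2
        for s in range(S):
            w[m, s] = np.random.randint(0, 2)
    # build stats
    for g in range(G):
        m = z[g]
        for s in range(S):
            b = w[m, s]
            x = X[g, s]
            N[m, b] += 1.0
            S1[m, b] += x
            S2[m, b] += x * x
    for m in range(M):
        for s in range(S):
            bc[m, w[m, s]] += 1

    logp = np.empty(kmax + 1)
    ts = np.empty(bmax)
    tss = np.empty(bmax)
    s1 = np.empty(S)
    s2 = np.empty(S)
    trace = np.empty(n_iter)
    best_score = -1.0e300
    best_z = np.empty(G, dtype=np.int64)
    best_w = np.zeros((kmax, S), dtype=np.int64)
    best_nb = np.zeros(kmax, dtype=np.int64)
    best_M = 0

    for it in range(n_iter):
        # ---- gene sweep ----
        for g in range(G):
            m0 = z[g]
            # remove gene g from m0
            gc[m0] -= 1
            for s in range(S):
                b = w[m0, s]
                x = X[g, s]
                N[m0, b] -= 1.0
                S1[m0, b] -= x
                S2[m0, b] -= x * x
            if gc[m0] == 0:
                last = M - 1
                if m0 != last:
                    gc[m0] = gc[last]
                    nb[m0] = nb[last]
                    for s in range(S):
                        w[m0, s] = w[last, s]
                    for b in range(bmax):
                        bc[m0, b] = bc[last, b]
                        N[m0, b] = N[last, b]
                        S1[m0, b] = S1[last, b]
                        S2[m0, b] = S2[last, b]
                    for gg in range(G):
                        if z[gg] == last:
                            z[gg] = m0
                gc[last] = 0
                nb[last] = 0
                for b in range(bmax):
                    bc[last, b] = 0
                    N[last, b] = 0.0
                    S1[last, b] = 0.0
                    S2[last, b] = 0.0
                M -= 1
            # proposals
            for m in range(M):
                for b in range(nb[m]):
                    ts[b] = 0.0
                    tss[b] = 0.0
                for s in range(S):
                    b = w[m, s]
                    x = X[g, s]
                    ts[b] += x
                    tss[b] += x * x
                d = 0.0
                for b in range(nb[m]):
                    d += (_logml(N[m, b] + bc[m, b], S1[m, b] + ts[b],
                                 S2[m, b] + tss[b], lam0, a0, b0, lgam_a0)
                          - _logml(N[m, b], S1[m, b], S2[m, b],
                                   lam0, a0, b0, lgam_a0))
                logp[m] = math.log(gc[m]) + d
            nopt = M
            if M < kmax:
                sx = 0.0
                sxx = 0.0
                for s in range(S):
                    x = X[g, s]
                    sx += x
                    sxx += x * x
                logp[M] = math.log(alpha_gene) + _logml(
                    float(S), sx, sxx, lam0, a0, b0, lgam_a0)
                nopt = M + 1
            choice = _sample_index(logp, nopt)
            if choice == M:
                # open a new module with a single sample block
                nb[M] = 1
                for s in range(S):
                    w[M, s] = 0
                bc[M, 0] = S
                M += 1
            z[g] = choice
            gc[choice] += 1
            for s in range(S):
                b = w[choice, s]
                x = X[g, s]
                N[choice, b] += 1.0
                S1[choice, b] += x
                S2[choice, b] += x * x

        # ---- sample sweep (per module) ----
        for m in range(M):
            for s in range(S):
                s1[s] = 0.0
                s2[s] = 0.0
            for g in range(G):
                if z[g] == m:
                    for s in range(S):
                        x = X[g, s]
                        s1[s] += x
                        s2[s] += x * x
            gm = float(gc[m])
            for s in range(S):
                b0_ = w[m, s]
                bc[m, b0_] -= 1
                N[m, b0_] -= gm
                S1[m, b0_] -= s1[s]
                S2[m, b0_] -= s2[s]
                if bc[m, b0_] == 0:
                    last = nb[m] - 1
                    if b0_ != last:
                        bc[m, b0_] = bc[m, last]
                        N[m, b0_] = N[m, last]
                        S1[m, b0_] = S1[m, last]
                        S2[m, b0_] = S2[m, last]
                        for s2_ in range(S):
                            if w[m, s2_] == last:
                                w[m, s2_] = b0_
                    bc[m, last] = 0
                    N[m, last] = 0.0
                    S1[m, last] = 0.0
                    S2[m, last] = 0.0
                    nb[m] -= 1
                for b in range(nb[m]):
                    logp[b] = math.log(bc[m, b]) + (
                        _logml(N[m, b] + gm, S1[m, b] + s1[s],
                               S2[m, b] + s2[s], lam0, a0, b0, lgam_a0)
                        - _logml(N[m, b], S1[m, b], S2[m, b],
                                 lam0, a0, b0, lgam_a0))
                nopt = nb[m]
                if nb[m] < bmax:
                    logp[nb[m]] = math.log(alpha_block) + _logml(
                        gm, s1[s], s2[s], lam0, a0, b0, lgam_a0)
                    nopt += 1
                choice = _sample_index(logp, nopt)
                if choice == nb[m]:
                    nb[m] += 1
                    bc[m, choice] = 0
                    N[m, choice] = 0.0
                    S1[m, choice] = 0.0
                    S2[m, choice] = 0.0
                w[m, s] = choice
                bc[m, choice] += 1
                N[m, choice] += gm
                S1[m, choice] += s1[s]
                S2[m, choice] += s2[s]

        # ---- score & best tracking ----
        score = 0.0
        for m in range(M):
            for b in range(nb[m]):
                score += _logml(N[m, b], S1[m, b], S2[m, b],
                                lam0, a0, b0, lgam_a0)
        trace[it] = score
        if score > best_score:
            best_score = score
            best_M = M
            for g in range(G):
                best_z[g] = z[g]
            for m in range(M):
                best_nb[m] = nb[m]
                for s in range(S):
                    best_w[m, s] = w[m, s]

    return best_z, best_w, best_nb, best_M, trace, best_score


# --------------------------------------------------------------------------
# public wrappers
# --------------------------------------------------------------------------

def standardize_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize to mean 0, SD 1 (constant rows become 0)."""
    x = expr.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=expr.index, columns=expr.columns)


def gibbs_cluster(expr: pd.DataFrame,
                  n_chains: int = 10,
                  n_iter: int = 100,
                  seed: int | None = None,
                  prior: NormalGammaPrior = NormalGammaPrior(),
                  alpha_gene: float = 1.0,
                  alpha_block: float = 1.0,
                  kmax: int = 60,
                  bmax: int = 20,
                  standardize: bool = True) -> list[ModuleAssignment]:
    """Run independent Gibbs chains and return each chain's best sweep.

    Rows are standardized before sampling.  Each returned assignment
    carries module ids 1..K (relabeled by decreasing size), the per-module
    sample partition of the best sweep, the log-score trace, and the best
    score.  Fewer than 2 genes yields a single trivial module.
    """
    if prior.mu0 != 0.0:
        raise ValueError("the sweep kernel assumes prior.mu0 == 0 "
                         "(appropriate for row-standardized data)")
    if standardize:
        expr = standardize_rows(expr)
    X = np.ascontiguousarray(expr.to_numpy(float))
    genes = list(expr.index)
    samples = list(expr.columns)
    if len(genes) < 2:
        labels = pd.Series(1, index=genes, name="module")
        return [ModuleAssignment(labels, 1, {1: [samples]},
                                 np.zeros(1), 0.0)]
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    seeds = ss.generate_state(n_chains) % (2 ** 31)
    out = []
    for c in range(n_chains):
        bz, bw, bnb, bM, trace, bscore = _run_chain(
            X, n_iter, int(seeds[c]), alpha_gene, alpha_block, kmax, bmax,
            prior.lam0, prior.a0, prior.b0)
        # relabel modules by decreasing size
        sizes = np.bincount(bz, minlength=bM)
        order = np.argsort(-sizes[:bM], kind="stable")
        relabel = np.empty(bM, dtype=int)
        relabel[order] = np.arange(1, bM + 1)
        labels = pd.Series(relabel[bz], index=genes, name="module")
        partitions = {}
        for m in range(bM):
            blocks = [[samples[s] for s in range(len(samples))
                       if bw[m, s] == b] for b in range(bnb[m])]
            partitions[int(relabel[m])] = [blk for blk in blocks if blk]
        out.append(ModuleAssignment(labels, int(bM), partitions,
                                    trace.copy(), float(bscore)))
    return out


def consensus_modules(assignments: list[ModuleAssignment],
                      co_clustering_threshold: float = 0.8,
                      min_module_size: int = 5) -> ModuleAssignment:
    """Tight consensus modules from gene-gene co-clustering across chains.

    Genes are linked when their co-clustering frequency across chains is at
    least the threshold; connected components of the link graph with at
    least ``min_module_size`` members become consensus modules (ids 1..K
    by decreasing size); all other genes are unassigned (module 0).
    """
    if len(assignments) < 2:
        raise ValueError("need at least 2 chains for a consensus")
    genes = assignments[0].module_of_gene.index
    G = len(genes)
    co = np.zeros((G, G))
    for a in assignments:
        lab = a.module_of_gene.to_numpy()
        co += (lab[:, None] == lab[None, :])
    co /= len(assignments)
    adj = co >= co_clustering_threshold
    np.fill_diagonal(adj, True)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(comp)
    labels = np.zeros(G, dtype=int)
    kept = [c for c in range(n_comp) if sizes[c] >= min_module_size]
    if not kept:
        import logging
        logging.getLogger(__name__).warning(
            "consensus_modules: no component reaches min_module_size=%d",
            min_module_size)
    for new_id, c in enumerate(sorted(kept, key=lambda c: -sizes[c]), start=1):
        labels[comp == c] = new_id
    return ModuleAssignment(pd.Series(labels, index=genes, name="module"),
                            n_modules=len(kept))
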