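"""Planted-truth benchmark runs used by the acceptance checks.

Each function regenerates its synthetic inputs from a seed, runs the
relevant pipeline stage end to end, and measures recovery against the
planted ground truth.  Study conditions (cohort sizes, effect sizes,
chain counts) are fixed here; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import simulate
from .candidates import candidates_from_cohort, differential_expression
from .coca import COCA
from .gibbs import consensus_modules, gibbs_cluster
from .pipeline import driver_recovery, run_driver_pipeline
from .survival import logrank_test

#: module-recovery study conditions: 200 genes, 5 planted modules,
#: 60 tumors, effect 2 SD, noise 1 SD (the SimConfig defaults)
MODULE_RECOVERY_CONFIG = dict(
    n_genes=200, n_modules=5, genes_per_module=30, n_tumor=60, n_normal=30,
    effect_size=2.0, noise_sd=1.0)

#: driver-recovery study conditions: one planted regulator per module,
#: eight modules, mix balanced over the four molecular platforms (the
#: scaled-down analogue of cohort-scale candidate pools, where the
#: per-module top-1% rule admits ~37 regulators per module instead of 1)
DRIVER_RECOVERY_CONFIG = dict(
    n_genes=200, n_modules=8, genes_per_module=20, regulators_per_module=1,
    effect_size=2.0, noise_sd=1.0,
    platform_mix={"mutation": 0.25, "cnv": 0.25, "methylation": 0.25,
                  "mirna": 0.25, "expression": 0.0})

SINGLE_PLATFORMS = ("mutation", "cnv", "methylation", "mirna")


def _seed_stream(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def module_recovery(seed: int = 0, n_seeds: int = 10,
                    n_chains: int = 10, n_iter: int = 100) -> dict:
    """Consensus-module recovery (ARI vs planted modules) over cohorts."""
    aris = []
    for s in _seed_stream(seed, n_seeds):
        cohort, truth = simulate.generate_cohort(
            simulate.SimConfig(seed=s, **MODULE_RECOVERY_CONFIG))
        de = differential_expression(cohort.expression, cohort.tumor_flags)
        expr = cohort.expression.loc[de.index[de["significant"]],
                                     cohort.tumors]
        chains = gibbs_cluster(expr, n_chains=n_chains, n_iter=n_iter,
                               seed=s)
        cons = consensus_modules(chains)
        aris.append(adjusted_rand_score(
            truth.module_of_gene.reindex(expr.index), cons.module_of_gene))
    return {"aris": aris, "median_ari": float(np.median(aris)),
            "n": n_seeds}


def driver_recovery_benchmark(seed: int = 0, n_seeds: int = 10,
                              single_platforms=SINGLE_PLATFORMS) -> dict:
    """Integrated driver recovery vs every single-platform restriction."""
    recalls, precisions = [], []
    single_recalls = {p: [] for p in single_platforms}
    for s in _seed_stream(seed, n_seeds):
        cohort, truth = simulate.generate_cohort(
            simulate.SimConfig(seed=s, **DRIVER_RECOVERY_CONFIG))
        cand = candidates_from_cohort(cohort, seed=s)
        res = run_driver_pipeline(cohort, seed=s + 1, candidates=cand)
        m = driver_recovery(res.drivers, truth)
        recalls.append(m["recall"])
        precisions.append(m["precision"])
        for p in single_platforms:
            rp = run_driver_pipeline(cohort, seed=s + 1, candidates=cand,
                                     platform=p)
            single_recalls[p].append(
                driver_recovery(rp.drivers, truth)["recall"])
    return {
        "median_recall": float(np.median(recalls)),
        "median_precision": float(np.median(precisions)),
        "median_single_recall": {p: float(np.median(v))
                                 for p, v in single_recalls.items()},
        "recalls": recalls, "precisions": precisions, "n": n_seeds,
    }


def coca_recovery(seed: int = 0, n_seeds: int = 10, n_samples: int = 120,
                  snr: float = 3.0) -> dict:
    """COCA subtype recovery on 4 subtypes split across 4 platforms."""
    coca_aris, best_single = [], []
    for s in _seed_stream(seed, n_seeds):
        mats, truth = simulate.generate_subtype_platforms(
            n_samples=n_samples, n_subtypes=4, snr=snr, seed=s)
        res = COCA(mats).fit(seed=s + 1)
        coca_aris.append(adjusted_rand_score(
            truth, res.subtypes.coca_labels.loc[truth.index]))
        best_single.append(max(
            adjusted_rand_score(truth, pc.labels.loc[truth.index])
            for pc in res.platform_clusterings.values()))
    return {"median_coca_ari": float(np.median(coca_aris)),
            "median_best_single_ari": float(np.median(best_single)),
            "coca_aris": coca_aris, "best_single_aris": best_single,
            "n": n_seeds}


def logrank_type1_error(seed: int = 0, n_rep: int = 1000,
                        n_per_group: int = 50,
                        alpha: float = 0.05) -> dict:
    """Rejection rate of the log-rank test under the null (HR = 1)."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["a", "b"], n_per_group)
    rejections = 0
    for _ in range(n_rep):
        t = rng.exponential(1.0, 2 * n_per_group)
        _, _, p = logrank_test(t, np.ones(2 * n_per_group, dtype=int),
                               groups)
        rejections += p < alpha
    return {"type1_error": rejections / n_rep, "n": n_rep}


def enhancer_recovery(seed: int = 0, n_seeds: int = 5,
                      n_windows: int = 2000, fold: float = 4.0,
                      noise_cv: float = 0.1) -> dict:
    """Gain/loss recovery of the fold-change call on planted tracks."""
    from .enhancers import enhancer_differential
    precisions, recalls = [], []
    for s in _seed_stream(seed, n_seeds):
        tum, nor, truth = simulate.generate_signal_tracks(
            n_windows, n_gain=100, n_loss=100, fold=fold,
            noise_cv=noise_cv, seed=s)
        out = enhancer_differential(tum, nor, fold=2.0)
        called = out["status"] != "stable"
        planted = truth["status"] != "stable"
        agree = (out["status"] == truth["status"])
        tp = (called & planted & agree).sum()
        precisions.append(tp / called.sum() if called.sum() else 0.0)
        recalls.append(tp / planted.sum())
    return {"precision": float(np.median(precisions)),
            "recall": float(np.median(recalls)), "n": n_seeds}
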