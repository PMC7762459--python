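"""Per-platform candidate-regulator selection.

Each selector reproduces one single-platform analysis feeding the module
network: differential expression (Welch t + BH FDR), differential and
transcriptionally predictive methylation (beta-mixture, BIC-selected),
miRNA-target anticorrelation (Spearman + BH FDR), mutation frequency, and
CNV amplification/deletion frequency.  Background-model-heavy external
callers (mutation significance, segment-level CNV) are accepted as
precomputed lists; the frequency thresholds are the synthetic-run fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .multitest import bh_adjust

logger = logging.getLogger(__name__)

CANDIDATE_PLATFORMS = ("mutation", "cnv_amp", "cnv_del", "methylation",
                       "mirna", "tf", "literature")


@dataclass
class CandidateRegulatorSet:
    """Candidate regulators with platform provenance and covariate profiles.

    ``entries`` has one row per (id, platform) pair with columns
    ``id, platform, statistic, q_value, direction, key``; ``profiles`` is a
    regulator x sample matrix indexed by ``key`` (``"platform:id"``) holding
    the covariate handed to the module network (mutation indicator, CNV
    state, beta value, miRNA expression, or the expression row for
    TF/literature regulators).
    """
    entries: pd.DataFrame
    profiles: pd.DataFrame

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return sorted(self.entries["id"].unique())

    def restrict(self, platforms) -> "CandidateRegulatorSet":
        """Subset to the given candidate platforms."""
        keep = self.entries["platform"].isin(set(platforms))
        ent = self.entries.loc[keep].reset_index(drop=True)
        prof = self.profiles.loc[ent["key"]]
        return CandidateRegulatorSet(ent, prof)


def differential_expression(expr: pd.DataFrame, tumor_flags: pd.Series,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test tumor vs normal with BH adjustment.

    Returns a DataFrame indexed by gene with columns ``t``, ``lfc`` (mean
    log2 fold-change tumor - normal), ``p``, ``q``, ``significant``
    (q < alpha) and ``degenerate`` (zero variance in both groups, p forced
    to 1).
    """
    flags = tumor_flags.reindex(expr.columns).astype(bool)
    xt = expr.loc[:, flags.values].to_numpy(float)
    xn = expr.loc[:, ~flags.values].to_numpy(float)
    if xt.shape[1] < 2 or xn.shape[1] < 2:
        raise ValueError("need >= 2 tumors and >= 2 normals")
    degenerate = (xt.var(axis=1) == 0) & (xn.var(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate | np.isnan(p), 1.0, p)
    out = pd.DataFrame({
        "t": t,
        "lfc": xt.mean(axis=1) - xn.mean(axis=1),
        "p": p,
        "q": bh_adjust(p),
        "degenerate": degenerate,
    }, index=expr.index)
    out["significant"] = out["q"] < alpha
    return out


def differential_methylation(beta: pd.DataFrame, expr: pd.DataFrame,
                             tumor_flags: pd.Series,
                             alpha: float = 0.05,
                             min_delta_beta: float = 0.1,
                             max_components: int = 3,
                             seed: int = 0) -> pd.DataFrame:
    """Differentially and transcriptionally predictive methylated genes.

    For each gene a 1-``max_components`` Gaussian mixture is fitted to the
    tumor beta values (components selected by BIC); the gene is
    hypermethylated (hypomethylated) if some mixture component with weight
    >= 0.1 has a mean at least ``min_delta_beta`` above (below) the mean
    normal beta.  "Transcriptionally predictive" additionally requires a
    negative Spearman correlation between beta and the gene's own
    expression across tumors at BH q < ``alpha``.

    Returns one row per candidate gene with columns ``delta_beta``
    (extreme component mean minus normal mean), ``rho``, ``p``, ``q`` and
    ``direction`` ('down' for hypermethylated, 'up' for hypomethylated:
    the expected expression effect).
    """
    genes = beta.index.intersection(expr.index)
    flags = tumor_flags.reindex(beta.columns).astype(bool)
    tum = beta.columns[flags.values]
    nor = beta.columns[~flags.values]
    rows = []
    for g in genes:
        bt = beta.loc[g, tum].to_numpy(float)
        bn_mean = float(beta.loc[g, nor].mean())
        if np.ptp(bt) < 1e-12:
            logger.warning("differential_methylation: constant beta for %s, "
                           "skipped", g)
            continue
        # cheap prefilter: no observation deviates enough for any mixture
        # component mean to clear min_delta_beta
        if np.max(np.abs(bt - bn_mean)) < min_delta_beta:
            continue
        delta = _mixture_delta(bt, bn_mean, max_components, seed)
        if delta is None or abs(delta) < min_delta_beta:
            continue
        et = expr.loc[g, tum].to_numpy(float)
        rho, p = stats.spearmanr(bt, et)
        if np.isnan(rho):
            continue
        rows.append((g, delta, rho, p))
    out = pd.DataFrame(rows, columns=["id", "delta_beta", "rho", "p"])
    if out.empty:
        out["q"] = out["direction"] = []
        return out.set_index("id")
    out["q"] = bh_adjust(out["p"])
    out["direction"] = np.where(out["delta_beta"] > 0, "down", "up")
    out = out[(out["rho"] < 0) & (out["q"] < alpha)]
    return out.set_index("id")


def _mixture_delta(bt: np.ndarray, normal_mean: float,
                   max_components: int, seed: int) -> float | None:
    """Most extreme (weight >= 0.1) component mean minus normal mean."""
    x = bt.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        if len(bt) < 2 * k:
            break
        try:
            gm = GaussianMixture(n_components=k, random_state=seed,
                                 n_init=1, reg_covar=1e-6).fit(x)
        except ValueError:  # pragma: no cover - degenerate input
            continue
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    if best is None:
        return None
    means = best.means_.ravel()
    ok = best.weights_ >= 0.1
    if not ok.any():
        return None
    deltas = means[ok] - normal_mean
    return float(deltas[np.argmax(np.abs(deltas))])


def mirna_candidates(mirna_expr: pd.DataFrame, mrna_expr: pd.DataFrame,
                     interactions: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """miRNAs with at least one significantly anticorrelated annotated target.

    Spearman rho is computed per annotated (miRNA, target) pair across the
    shared samples; pairs with rho < 0 and BH q < ``alpha`` are kept.
    Interactions referencing unknown ids are skipped and logged.

    Returns the pair table with columns ``mirna, target, rho, p, q, kept``;
    candidate miRNAs are ``result.loc[result.kept, 'mirna'].unique()``.
    """
    samples = mirna_expr.columns.intersection(mrna_expr.columns)
    rows = []
    for mir, tgt in interactions[["mirna", "target"]].itertuples(index=False):
        if mir not in mirna_expr.index or tgt not in mrna_expr.index:
            logger.warning("mirna_candidates: unknown pair (%s, %s) skipped",
                           mir, tgt)
            continue
        rho, p = stats.spearmanr(mirna_expr.loc[mir, samples],
                                 mrna_expr.loc[tgt, samples])
        rows.append((mir, tgt, rho, p))
    out = pd.DataFrame(rows, columns=["mirna", "target", "rho", "p"])
    if out.empty:
        out["q"] = out["kept"] = []
        return out
    out["q"] = bh_adjust(out["p"])
    out["kept"] = (out["rho"] < 0) & (out["q"] < alpha)
    return out


def mutation_candidates(mutation: pd.DataFrame,
                        tumor_flags: pd.Series | None = None,
                        min_frequency: float = 0.02,
                        external_list=None) -> list[str]:
    """Recurrently mutated genes (or a user-supplied significance list).

    If ``external_list`` is given (e.g. from a covariate-aware mutation
    significance caller) it is intersected with the matrix rows; otherwise
    genes mutated in >= ``min_frequency`` of tumors are kept.
    """
    if external_list is not None:
        kept = [g for g in external_list if g in mutation.index]
        missing = set(external_list) - set(kept)
        if missing:
            logger.warning("mutation_candidates: %d external genes absent "
                           "from matrix", len(missing))
        return kept
    cols = (mutation.columns[tumor_flags.reindex(mutation.columns).astype(bool).values]
            if tumor_flags is not None else mutation.columns)
    freq = (mutation[cols] != 0).mean(axis=1)
    kept = list(mutation.index[freq >= min_frequency])
    if not kept:
        logger.warning("mutation_candidates: no gene reaches frequency %g",
                       min_frequency)
    return kept


def cnv_candidates(cnv: pd.DataFrame,
                   tumor_flags: pd.Series | None = None,
                   min_frequency: float = 0.1,
                   external_amp=None, external_del=None
                   ) -> tuple[list[str], list[str]]:
    """Frequently amplified and deleted genes.

    A gene is an amplification candidate if its state is >= +1 in at least
    ``min_frequency`` of tumors, a deletion candidate symmetrically; the
    rules are applied independently, so a gene may appear in both lists
    (logged).  Precomputed region-level lists override the frequency rule.
    """
    if external_amp is not None or external_del is not None:
        amp = [g for g in (external_amp or []) if g in cnv.index]
        dele = [g for g in (external_del or []) if g in cnv.index]
        return amp, dele
    cols = (cnv.columns[tumor_flags.reindex(cnv.columns).astype(bool).values]
            if tumor_flags is not None else cnv.columns)
    x = cnv[cols]
    amp = list(cnv.index[(x >= 1).mean(axis=1) >= min_frequency])
    dele = list(cnv.index[(x <= -1).mean(axis=1) >= min_frequency])
    both = set(amp) & set(dele)
    if both:
        logger.info("cnv_candidates: %d genes in both amp and del lists",
                    len(both))
    return amp, dele


def assemble_candidates(samples,
                        expr: pd.DataFrame,
                        mutation_list=(), mutation_matrix=None,
                        cnv_amp=(), cnv_del=(), cnv_matrix=None,
                        methylation_table: pd.DataFrame | None = None,
                        beta_matrix: pd.DataFrame | None = None,
                        mirna_list=(), mirna_matrix: pd.DataFrame | None = None,
                        tf_list=(), literature_list=(),
                        statistics: dict | None = None
                        ) -> CandidateRegulatorSet:
    """Union of per-platform candidates with provenance and profiles.

    A gene may carry several platform tags (one entry each); duplicated
    (id, platform) pairs collapse.  Profile rows over ``samples``: binary
    mutation indicator, numeric CNV state, methylation beta, miRNA
    expression, or the expression row for TF/literature regulators.
    Regulators lacking a profile source are dropped with a warning.
    """
    samples = list(samples)
    entries, profiles = [], {}

    def add(rid, platform, statistic, q, direction, profile_source):
        key = f"{platform}:{rid}"
        if key in profiles:
            return
        if profile_source is None or rid not in profile_source.index:
            logger.warning("assemble_candidates: %s (%s) has no profile "
                           "source, dropped", rid, platform)
            return
        profiles[key] = profile_source.loc[rid, samples].to_numpy(float)
        entries.append((rid, platform, statistic, q, direction, key))

    stat = statistics or {}
    for g in mutation_list:
        add(g, "mutation", stat.get(("mutation", g), np.nan), np.nan, "na",
            mutation_matrix)
    for g in cnv_amp:
        add(g, "cnv_amp", stat.get(("cnv_amp", g), np.nan), np.nan, "up",
            cnv_matrix)
    for g in cnv_del:
        add(g, "cnv_del", stat.get(("cnv_del", g), np.nan), np.nan, "down",
            cnv_matrix)
    if methylation_table is not None:
        for g, row in methylation_table.iterrows():
            add(g, "methylation", row.get("rho", np.nan),
                row.get("q", np.nan), row.get("direction", "na"), beta_matrix)
    for m in mirna_list:
        add(m, "mirna", stat.get(("mirna", m), np.nan), np.nan, "down",
            mirna_matrix)
    for g in tf_list:
        add(g, "tf", np.nan, np.nan, "na", expr)
    for g in literature_list:
        add(g, "literature", np.nan, np.nan, "na", expr)

    entries_df = pd.DataFrame(
        entries,
        columns=["id", "platform", "statistic", "q_value", "direction", "key"])
    prof_df = pd.DataFrame(
        {k: profiles[k] for k in entries_df["key"]},
        index=samples).T
    prof_df.index.name = "key"
    return CandidateRegulatorSet(entries_df, prof_df)


def candidates_from_cohort(cohort, alpha: float = 0.05,
                           mutation_min_frequency: float = 0.02,
                           cnv_min_frequency: float = 0.1,
                           min_delta_beta: float = 0.1,
                           seed: int = 0) -> CandidateRegulatorSet:
    """Run every single-platform selector on a cohort and assemble the set.

    Profiles are restricted to tumor samples (the covariates of the module
    network, which models tumor expression).
    """
    mut = mutation_candidates(cohort.mutation, cohort.tumor_flags,
                              min_frequency=mutation_min_frequency)
    amp, dele = cnv_candidates(cohort.cnv, cohort.tumor_flags,
                               min_frequency=cnv_min_frequency)
    meth = differential_methylation(cohort.methylation, cohort.expression,
                                    cohort.tumor_flags, alpha=alpha,
                                    min_delta_beta=min_delta_beta, seed=seed)
    pairs = mirna_candidates(cohort.mirna, cohort.expression,
                             cohort.mirna_targets, alpha=alpha)
    mirs = (sorted(pairs.loc[pairs["kept"], "mirna"].unique())
            if len(pairs) else [])
    return assemble_candidates(
        samples=cohort.tumors,
        expr=cohort.expression,
        mutation_list=mut, mutation_matrix=cohort.mutation,
        cnv_amp=amp, cnv_del=dele, cnv_matrix=cohort.cnv,
        methylation_table=meth, beta_matrix=cohort.methylation,
        mirna_list=mirs, mirna_matrix=cohort.mirna,
        tf_list=cohort.tf_list, literature_list=cohort.literature_list)
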