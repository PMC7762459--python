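"""Synthetic multi-omics cohorts with planted regulatory ground truth.

The generator emulates the data model of a tumor/normal multi-omics study:
co-expression modules whose mean expression is driven by planted regulators
acting through different platforms (somatic mutation, copy-number dosage,
promoter hypermethylation, miRNA repression, transcription-factor
expression), tumor subtype structure with survival differences, and paired
tumor/normal histone-mark signal tracks with planted enhancer gains and
losses.  Every quantity downstream stages are expected to recover is
recorded in a :class:`GroundTruth` object.

Expression is log2-scale throughout; module effects are additive shifts of
log2 means.  Methylation beta values are generated on the logit scale and
inverse-transformed so they always lie in (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

PLATFORMS = ("mutation", "cnv", "methylation", "mirna", "expression")

#: fraction of tumors in which a planted regulator is active, per platform.
#: Mutation regulators are active in 30% of tumors, mimicking the low
#: per-gene mutation frequencies that make single-platform mutation
#: analysis underpowered.
ACTIVE_FRACTION = {
    "mutation": 0.30,
    "cnv": 0.30,
    "methylation": 0.50,
    "mirna": 0.40,
    "expression": 0.40,
}

_DEFAULT_MIX = {
    "mutation": 0.25,
    "cnv": 0.25,
    "methylation": 0.20,
    "mirna": 0.20,
    "expression": 0.10,
}


@dataclass
class SimConfig:
    """Configuration of a synthetic multi-omics cohort.

    Attributes
    ----------
    n_tumor, n_normal : int
        Tumor and paired-normal sample counts.
    n_genes : int
        Total protein-coding genes on the expression/mutation/CNV/
        methylation platforms.
    n_modules, genes_per_module : int
        Planted co-expression modules; remaining genes are unstructured
        background (module 0).
    regulators_per_module : int
        Planted regulators per module (1-3).
    platform_mix : dict
        Sampling proportions over regulator platforms; must sum to 1.
    effect_size : float
        Standardized mean shift (in units of SD, log2 scale) a regulator's
        activation adds to its module genes.
    noise_sd : float
        Residual expression SD (log2 scale).
    n_subtypes : int
        Planted tumor subtypes (drive survival).
    subtype_hazard_ratios : sequence of float
        Per-subtype hazard ratios relative to baseline.
    baseline_hazard : float
        Exponential event rate of an HR=1 subtype (per unit time).
    censor_rate : float
        Fraction of subjects censored (uniformly before their event).
    n_mirna : int
        miRNAs on the miRNA platform.
    seed : int
        Global seed; spawns one child stream per generation stage.
    """

    n_tumor: int = 60
    n_normal: int = 30
    n_genes: int = 200
    n_modules: int = 5
    genes_per_module: int = 30
    regulators_per_module: int = 2
    platform_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX))
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_subtypes: int = 4
    subtype_hazard_ratios: Sequence[float] = (1.0, 3.0, 0.5, 1.0)
    baseline_hazard: float = 0.1
    censor_rate: float = 0.2
    n_mirna: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tumor", "n_normal", "n_genes", "n_modules",
                     "genes_per_module", "regulators_per_module",
                     "n_subtypes", "n_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (1 <= self.regulators_per_module <= 3):
            raise ValueError("regulators_per_module must be in 1..3")
        mix = dict(self.platform_mix)
        unknown = set(mix) - set(PLATFORMS)
        if unknown:
            raise ValueError(f"unknown platforms in platform_mix: {unknown}")
        if abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ValueError("platform_mix proportions must sum to 1")
        if self.genes_per_module * self.n_modules > self.n_genes:
            raise ValueError(
                "infeasible config: genes_per_module * n_modules exceeds "
                "n_genes")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if len(self.subtype_hazard_ratios) != self.n_subtypes:
            raise ValueError(
                "subtype_hazard_ratios must have one entry per subtype")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be >= 0")


@dataclass
class PlantedRegulator:
    """One planted regulator: identity, platform, target module and sign."""
    id: str
    platform: str
    module: int
    sign: int
    active_tumors: np.ndarray  # positional indices into the tumor samples


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort (module 0 = background)."""
    module_of_gene: pd.Series
    planted_regulators: list
    subtype_of_sample: pd.Series
    enhancer_truth: pd.DataFrame | None = None

    @property
    def regulator_ids(self) -> list[str]:
        return [r.id for r in self.planted_regulators]


@dataclass
class OmicsCohort:
    """Aligned multi-platform matrices plus the clinical table.

    All matrices are feature x sample (samples in columns) and share the
    sample axis; mutation and CNV are zero in normals, and the clinical
    table covers tumors only.
    """
    sample_ids: list[str]
    tumor_flags: pd.Series  # bool per sample
    expression: pd.DataFrame
    mutation: pd.DataFrame
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    mirna: pd.DataFrame
    clinical: pd.DataFrame
    mirna_targets: pd.DataFrame
    tf_list: list[str]
    literature_list: list[str]

    @property
    def tumors(self) -> list[str]:
        return [s for s in self.sample_ids if self.tumor_flags[s]]

    @property
    def normals(self) -> list[str]:
        return [s for s in self.sample_ids if not self.tumor_flags[s]]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # One global seed feeds a per-stage seed sequence so stages can be
    # regenerated independently.
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: SimConfig) -> tuple[OmicsCohort, GroundTruth]:
    """Generate a multi-omics cohort with planted modules and regulators.

    Module genes follow ``baseline + effect_size * sum(regulator
    activations) + Normal(0, noise_sd)``; activations are realized per
    platform (binary mutation indicator, CNV dosage scaled to state/2,
    methylation silencing with negative sign, miRNA repression with
    negative sign, TF overexpression).  Normal samples carry no
    activations.  Fully reproducible given ``config.seed``.
    """
    cfg = config
    rng_assign, rng_expr, rng_mut, rng_cnv, rng_meth, rng_mir, rng_clin = \
        _child_rngs(cfg.seed, 7)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tumors = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    normals = [f"N{i:03d}" for i in range(cfg.n_normal)]
    samples = tumors + normals
    n_s = len(samples)
    tumor_flags = pd.Series([True] * cfg.n_tumor + [False] * cfg.n_normal,
                            index=samples)

    # --- gene -> module assignment ------------------------------------
    perm = rng_assign.permutation(cfg.n_genes)
    module_of_gene = np.zeros(cfg.n_genes, dtype=int)
    for m in range(1, cfg.n_modules + 1):
        idx = perm[(m - 1) * cfg.genes_per_module: m * cfg.genes_per_module]
        module_of_gene[idx] = m
    background_idx = list(perm[cfg.n_modules * cfg.genes_per_module:])

    # --- planted regulators -------------------------------------------
    mirna_ids = [f"miR-{i:03d}" for i in range(cfg.n_mirna)]
    plat_names = list(cfg.platform_mix)
    plat_probs = np.array([cfg.platform_mix[p] for p in plat_names])
    planted: list[PlantedRegulator] = []
    bg_pos = 0
    mir_pos = 0
    # realize platform_mix exactly over the planted regulators (largest
    # remainder quotas, then a random permutation) so small cohorts carry
    # the stated platform composition rather than a noisy draw of it
    n_reg = cfg.n_modules * cfg.regulators_per_module
    quota = np.floor(plat_probs * n_reg).astype(int)
    rem = plat_probs * n_reg - quota
    for i in np.argsort(-rem)[: n_reg - quota.sum()]:
        quota[i] += 1
    plat_sequence = [p for p, q in zip(plat_names, quota) for _ in range(q)]
    plat_sequence = [plat_sequence[i]
                     for i in rng_assign.permutation(n_reg)]
    for m in range(1, cfg.n_modules + 1):
        # each module is a coherently regulated program: all its planted
        # regulators push it the same way (direction drawn per module)
        direction = int(rng_assign.choice([-1, 1]))
        for _ in range(cfg.regulators_per_module):
            plat = plat_sequence.pop()
            if plat == "mirna":
                if mir_pos >= cfg.n_mirna:
                    raise ValueError("infeasible config: not enough miRNAs "
                                     "for planted miRNA regulators")
                rid = mirna_ids[mir_pos]
                mir_pos += 1
            else:
                if bg_pos >= len(background_idx):
                    raise ValueError("infeasible config: not enough "
                                     "background genes to host regulators")
                rid = genes[background_idx[bg_pos]]
                bg_pos += 1
            frac = ACTIVE_FRACTION[plat]
            n_active = max(1, int(round(frac * cfg.n_tumor)))
            active = np.sort(rng_assign.choice(cfg.n_tumor, n_active,
                                               replace=False))
            planted.append(PlantedRegulator(rid, plat, m, direction, active))

    # signed activation per regulator over all samples (normals = 0)
    def activation(reg: PlantedRegulator) -> np.ndarray:
        a = np.zeros(n_s)
        a[reg.active_tumors] = reg.sign
        return a

    # --- platform matrices --------------------------------------------
    mutation = np.zeros((cfg.n_genes, n_s), dtype=int)
    mutation[:, :cfg.n_tumor] = (
        rng_mut.random((cfg.n_genes, cfg.n_tumor)) < 0.01).astype(int)

    cnv = np.zeros((cfg.n_genes, n_s), dtype=int)
    bg_mask = rng_cnv.random((cfg.n_genes, cfg.n_tumor)) < 0.03
    bg_sign = rng_cnv.choice([-1, 1], size=(cfg.n_genes, cfg.n_tumor))
    cnv[:, :cfg.n_tumor] = np.where(bg_mask, bg_sign, 0)

    # methylation on the logit scale: baseline beta ~ 0.2
    beta = expit(logit(0.2) + 0.5 * rng_meth.standard_normal((cfg.n_genes, n_s)))

    mirna = 5.0 + rng_mir.standard_normal((cfg.n_mirna, n_s))

    baseline = 8.0 + rng_expr.standard_normal(cfg.n_genes)
    expression = baseline[:, None] + cfg.noise_sd * rng_expr.standard_normal(
        (cfg.n_genes, n_s))

    gene_pos = {g: i for i, g in enumerate(genes)}
    mir_pos_of = {m: i for i, m in enumerate(mirna_ids)}
    target_rows = []
    for reg in planted:
        act = activation(reg)
        module_rows = np.where(module_of_gene == reg.module)[0]
        expression[module_rows] += cfg.effect_size * act
        if reg.platform == "mutation":
            mutation[gene_pos[reg.id], reg.active_tumors] = 1
        elif reg.platform == "cnv":
            # amplification drives up-modules, deletion down-modules
            gi = gene_pos[reg.id]
            cnv[gi, reg.active_tumors] = 2 * reg.sign
            expression[gi] += cfg.effect_size * act
        elif reg.platform == "methylation":
            # down-module: hypermethylation silences (beta 0.2 -> 0.8);
            # up-module: loss of methylation activates (beta 0.8 -> 0.2).
            # The regulator's own transcript follows, making it
            # transcriptionally predictive (negative beta-expression rho).
            gi = gene_pos[reg.id]
            lo, hi = (0.2, 0.8) if reg.sign < 0 else (0.8, 0.2)
            base_row = expit(logit(lo) + 0.5 * rng_meth.standard_normal(n_s))
            beta[gi] = base_row
            beta[gi, reg.active_tumors] = expit(
                logit(hi) + 0.5 * rng_meth.standard_normal(
                    len(reg.active_tumors)))
            expression[gi] += cfg.effect_size * act
        elif reg.platform == "mirna":
            # repressor miRNA: gained in active tumors of down-modules,
            # lost in active tumors of up-modules (de-repression)
            mi = mir_pos_of[reg.id]
            mirna[mi, reg.active_tumors] -= 2.0 * reg.sign
            n_tg = min(10, cfg.genes_per_module)
            targets = rng_assign.choice(module_rows, n_tg, replace=False)
            for t in targets:
                target_rows.append((reg.id, genes[t]))
        elif reg.platform == "expression":
            gi = gene_pos[reg.id]
            expression[gi] += cfg.effect_size * act

    # decoy miRNA-target annotations on unplanted miRNAs
    for mi in range(mir_pos, cfg.n_mirna):
        for t in rng_assign.choice(cfg.n_genes, 2, replace=False):
            target_rows.append((mirna_ids[mi], genes[t]))
    mirna_targets = pd.DataFrame(target_rows, columns=["mirna", "target"])

    # TF / literature lists: planted expression regulators plus decoys
    planted_gene_ids = {r.id for r in planted if r.platform != "mirna"}
    decoy_pool = [genes[i] for i in background_idx[bg_pos:]
                  if genes[i] not in planted_gene_ids]
    tf_list = sorted(r.id for r in planted if r.platform == "expression")
    tf_list += decoy_pool[:5]
    literature_list = decoy_pool[5:8]

    # --- subtypes and survival ----------------------------------------
    reps = int(np.ceil(cfg.n_tumor / cfg.n_subtypes))
    subtype = np.tile(np.arange(1, cfg.n_subtypes + 1), reps)[:cfg.n_tumor]
    subtype = subtype[rng_clin.permutation(cfg.n_tumor)]
    subtype_of_sample = pd.Series(subtype, index=tumors, name="subtype")
    hr = {s + 1: float(cfg.subtype_hazard_ratios[s])
          for s in range(cfg.n_subtypes)}
    clinical = generate_survival(subtype_of_sample, hr,
                                 baseline_rate=cfg.baseline_hazard,
                                 censor_rate=cfg.censor_rate, rng=rng_clin)
    clinical["age"] = np.round(rng_clin.normal(60, 10, cfg.n_tumor), 1)
    clinical["subtype"] = subtype_of_sample

    cohort = OmicsCohort(
        sample_ids=samples,
        tumor_flags=tumor_flags,
        expression=pd.DataFrame(expression, index=genes, columns=samples),
        mutation=pd.DataFrame(mutation, index=genes, columns=samples),
        cnv=pd.DataFrame(cnv, index=genes, columns=samples),
        methylation=pd.DataFrame(beta, index=genes, columns=samples),
        mirna=pd.DataFrame(mirna, index=mirna_ids, columns=samples),
        clinical=clinical,
        mirna_targets=mirna_targets,
        tf_list=tf_list,
        literature_list=literature_list,
    )
    truth = GroundTruth(
        module_of_gene=pd.Series(module_of_gene, index=genes, name="module"),
        planted_regulators=planted,
        subtype_of_sample=subtype_of_sample,
    )
    return cohort, truth


def generate_survival(subtype_of_sample: pd.Series,
                      hazard_ratios: Mapping,
                      baseline_rate: float = 0.1,
                      censor_rate: float = 0.0,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Exponential survival times with per-subtype hazards.

    Event time for a subject of subtype ``s`` is Exponential with rate
    ``baseline_rate * hazard_ratios[s]``.  A fraction ``censor_rate`` of
    subjects (Bernoulli per subject) is censored at a uniform time before
    their event.

    Returns a clinical table indexed by sample with columns ``time``
    (non-negative) and ``event`` (1 = death observed).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    missing = set(subtype_of_sample.unique()) - set(hazard_ratios)
    if missing:
        raise ValueError(f"no hazard ratio for subtypes: {missing}")
    for s, h in hazard_ratios.items():
        if h <= 0:
            raise ValueError(f"hazard ratio for subtype {s} must be positive")
    n = len(subtype_of_sample)
    rates = baseline_rate * subtype_of_sample.map(hazard_ratios).to_numpy(float)
    t_event = rng.exponential(1.0 / rates)
    censored = rng.random(n) < censor_rate
    time = np.where(censored, rng.random(n) * t_event, t_event)
    return pd.DataFrame({"time": time,
                         "event": (~censored).astype(int)},
                        index=subtype_of_sample.index)


def generate_signal_tracks(n_windows: int,
                           window_bp: int = 50,
                           n_gain: int = 50,
                           n_loss: int = 50,
                           fold: float = 2.5,
                           noise_cv: float = 0.1,
                           seed: int | None = None,
                           chrom: str = "chr1",
                           baseline_median: float = 10.0):
    """Paired tumor/normal windowed signal tracks with planted gains/losses.

    A shared log-normal baseline is multiplied by ``fold`` in tumor gain
    windows and divided by ``fold`` in loss windows; multiplicative
    log-normal noise with coefficient of variation ``noise_cv`` is applied
    independently to each track.  Windows are 0-based half-open and
    ``window_bp`` wide.

    Returns ``(tumor, normal, truth)`` where the tracks are DataFrames with
    columns ``chrom, start, end, value`` and ``truth`` adds a ``status``
    column in {gain, loss, stable}.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if n_gain + n_loss > n_windows:
        raise ValueError("n_gain + n_loss must not exceed n_windows")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    base = baseline_median * rng.lognormal(0.0, 0.5, n_windows)
    # differential enhancers are planted on marked windows: a "lost
    # enhancer" at near-zero signal is not an enhancer, and the
    # pseudocount of the fold-change call rightly damps such windows
    eligible = np.where(base >= 0.5 * baseline_median)[0]
    if len(eligible) < n_gain + n_loss:
        raise ValueError("too few adequately marked windows to plant "
                         "gains/losses; lower n_gain/n_loss")
    chosen = rng.choice(eligible, n_gain + n_loss, replace=False)
    gain_idx, loss_idx = chosen[:n_gain], chosen[n_gain:]
    factor = np.ones(n_windows)
    factor[gain_idx] = fold
    factor[loss_idx] = 1.0 / fold

    def noisy(values):
        if noise_cv == 0:
            return values.copy()
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        return values * rng.lognormal(-0.5 * sigma ** 2, sigma, n_windows)

    starts = np.arange(n_windows) * window_bp
    grid = {"chrom": chrom, "start": starts, "end": starts + window_bp}
    tumor = pd.DataFrame({**grid, "value": noisy(base * factor)})
    normal = pd.DataFrame({**grid, "value": noisy(base)})
    status = np.array(["stable"] * n_windows, dtype=object)
    status[gain_idx] = "gain"
    status[loss_idx] = "loss"
    truth = pd.DataFrame({**grid, "status": status})
    return tumor, normal, truth


def generate_subtype_platforms(n_samples: int = 120,
                               n_subtypes: int = 4,
                               platforms: Sequence[str] = ("cnv",
                                                           "methylation",
                                                           "mrna", "mirna"),
                               n_features: int = 20,
                               snr: float = 3.0,
                               noise_sd: float = 1.0,
                               split: bool = True,
                               seed: int | None = None):
    """Per-platform driver-feature matrices carrying planted subtype signal.

    With ``split=True`` (the interesting regime for cluster-of-clusters
    analysis) each platform only sees a two-way merge of the subtypes:
    platform ``p`` separates the subtypes by bit ``p mod ceil(log2(K))`` of
    the subtype index, so no single platform can resolve all subtypes but
    their combination identifies every subtype uniquely.  The separation
    between the two merged groups is ``snr * noise_sd``.

    Returns ``(platform_matrices, subtype_of_sample)`` with matrices as
    feature x sample DataFrames.
    """
    rng = np.random.default_rng(seed)
    reps = int(np.ceil(n_samples / n_subtypes))
    labels = np.tile(np.arange(1, n_subtypes + 1), reps)[:n_samples]
    labels = labels[rng.permutation(n_samples)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    nbits = max(1, int(np.ceil(np.log2(n_subtypes))))
    delta = snr * noise_sd
    out = {}
    for p, name in enumerate(platforms):
        feats = [f"{name}_f{j:02d}" for j in range(n_features)]
        signs = rng.choice([-1.0, 1.0], n_features)
        if split:
            group = ((labels - 1) >> (p % nbits)) & 1
            mean = np.outer(signs, delta * (group - 0.5))
        else:
            centers = rng.normal(0.0, delta / 2.0, (n_features, n_subtypes))
            mean = centers[:, labels - 1]
        x = mean + noise_sd * rng.standard_normal((n_features, n_samples))
        out[name] = pd.DataFrame(x, index=feats, columns=sample_ids)
    return out, pd.Series(labels, index=sample_ids, name="subtype")


def generate_e2f_tp53_cohort(n_tumor: int = 120,
                             e2f_effect: float = 1.0,
                             tp53_effect: float = 1.0,
                             interaction: float = 1.0,
                             noise_sd: float = 0.5,
                             n_pathway_genes: int = 15,
                             n_background_genes: int = 60,
                             seed: int | None = None):
    """Tumors with E2F overexpression, TP53 mutation and a driven pathway.

    A latent pathway activity increases additively with E2F
    overexpression and TP53 mutation plus a positive interaction, so the
    double-hit group carries the highest activity.  The expression matrix
    holds E2F1/E2F2, ``n_pathway_genes`` pathway genes whose expression
    tracks the latent activity, and unstructured background genes — so a
    per-sample enrichment score of the pathway set recovers the planted
    ordering.

    Returns ``(expr, tp53_mut, activity, pathway_genes, truth)``.
    """
    rng = np.random.default_rng(seed)
    samples = [f"T{i:03d}" for i in range(n_tumor)]
    e2f_high = rng.random(n_tumor) < 0.5
    tp53 = rng.random(n_tumor) < 0.5
    e1 = 8.0 + 2.0 * e2f_high + 0.5 * rng.standard_normal(n_tumor)
    e2 = 7.0 + 2.0 * e2f_high + 0.5 * rng.standard_normal(n_tumor)
    activity = (e2f_effect * e2f_high + tp53_effect * tp53
                + interaction * (e2f_high & tp53)
                + noise_sd * rng.standard_normal(n_tumor))
    pathway_genes = [f"CC{i:02d}" for i in range(n_pathway_genes)]
    background = [f"BG{i:02d}" for i in range(n_background_genes)]
    pw_rows = (5.0 + activity
               + 0.3 * rng.standard_normal((n_pathway_genes, n_tumor)))
    bg_rows = 5.0 + rng.standard_normal((n_background_genes, n_tumor))
    expr = pd.DataFrame(
        np.vstack([[e1, e2], pw_rows, bg_rows]),
        index=["E2F1", "E2F2"] + pathway_genes + background,
        columns=samples)
    truth = pd.DataFrame({"e2f_high": e2f_high, "tp53_mut": tp53},
                         index=samples)
    return (expr, pd.Series(tp53, index=samples, name="tp53_mut"),
            pd.Series(activity, index=samples, name="activity"),
            pathway_genes, truth)
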