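"""End-to-end driver discovery: DE genes -> candidates -> module network.

``run_driver_pipeline`` is the integrated analysis; ``run_single_platform``
restricts the candidate set to one platform so integrated and
single-platform driver recovery can be compared on cohorts with planted
regulators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .candidates import (CandidateRegulatorSet, candidates_from_cohort,
                         differential_expression)
from .modnet import ModuleNetwork, ModuleNetworkResults, PLATFORM_GROUPS
from .simulate import OmicsCohort, GroundTruth


def run_driver_pipeline(cohort: OmicsCohort,
                        seed: int | None = None,
                        candidates: CandidateRegulatorSet | None = None,
                        platform: str | None = None,
                        de_alpha: float = 0.05,
                        **fit_kwargs) -> ModuleNetworkResults:
    """Differential expression, candidate assembly, module-network fit.

    ``platform`` (one of mutation/cnv/methylation/mirna/mrna) restricts
    the candidate set to a single platform; ``None`` runs the integrated
    analysis.  Candidate selection can be precomputed and passed in so the
    integrated and single-platform runs share identical inputs.
    """
    ss = np.random.SeedSequence(seed)
    cand_seed, fit_seed = ss.spawn(2)
    if candidates is None:
        candidates = candidates_from_cohort(
            cohort, seed=int(cand_seed.generate_state(1)[0] % (2 ** 31)))
    if platform is not None:
        if platform not in PLATFORM_GROUPS:
            raise ValueError(f"unknown platform {platform!r}; expected one "
                             f"of {sorted(PLATFORM_GROUPS)}")
        candidates = candidates.restrict(PLATFORM_GROUPS[platform])
    de = differential_expression(cohort.expression, cohort.tumor_flags,
                                 alpha=de_alpha)
    de_genes = de.index[de["significant"]]
    expr = cohort.expression.loc[de_genes, cohort.tumors]
    if len(candidates) == 0:
        return _empty_results(expr, candidates)
    model = ModuleNetwork(expr, candidates)
    return model.fit(seed=fit_seed, **fit_kwargs)


def run_single_platform(cohort: OmicsCohort, platform: str,
                        seed: int | None = None,
                        candidates: CandidateRegulatorSet | None = None,
                        **fit_kwargs) -> ModuleNetworkResults:
    """The integrated pipeline restricted to one platform's candidates."""
    return run_driver_pipeline(cohort, seed=seed, candidates=candidates,
                               platform=platform, **fit_kwargs)


def _empty_results(expr, candidates) -> ModuleNetworkResults:
    from .gibbs import ModuleAssignment
    from .modnet import DriverList, RegulatorScore, ModuleNetworkResults
    empty = ModuleAssignment(
        pd.Series(0, index=expr.index, name="module"), 0)
    score = RegulatorScore.from_matrix(
        pd.DataFrame(index=candidates.profiles.index, columns=[], dtype=float))
    cols = ["key", "id", "platforms", "summed_score", "n_modules",
            "modules", "by_module_rule", "by_global_rule"]
    drivers = DriverList(pd.DataFrame(columns=cols), 0.01, 0.10)
    return ModuleNetworkResults(None, [], empty, {}, score, drivers)


def driver_recovery(drivers, truth: GroundTruth) -> dict:
    """Recall and precision of selected drivers against planted regulators.

    Planted regulators and selected drivers are compared by id (a planted
    regulator found under any platform tag counts as recovered).
    """
    planted = set(truth.regulator_ids)
    selected = set(drivers.ids) if len(drivers) else set()
    tp = planted & selected
    recall = len(tp) / len(planted) if planted else float("nan")
    precision = len(tp) / len(selected) if selected else 0.0
    return {"recall": recall, "precision": precision,
            "n_selected": len(selected), "n_planted": len(planted),
            "true_positives": sorted(tp)}
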