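"""Shared multiple-testing correction.

Every FDR adjustment in the package routes through :func:`bh_adjust` so the
Benjamini-Hochberg behaviour (step-up, monotone, q >= p) is implemented and
tested exactly once.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through as NaN and do not count toward the number
    of tests.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray of the same length.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
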