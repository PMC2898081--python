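"""Expression-level and tissue-specificity partitions of genes.

The per-gene median of normalized (log2-scale) expression across tissues is
bimodal and is split into low/high classes with the same two-component
Gaussian mixture machinery used for CpG islands.  Tissue specificity uses the
tau index

    tau(g) = sum_i (1 - x_i / max_i x_i) / (n_tissues - 1)

which is 0 for a uniform profile and 1 for single-tissue expression; genes
are then cut into low/medium/high specificity groups either by tertiles or by
explicit score cut-points (cut-point mode is first-class because observed
group sizes in real cohorts are generally unequal).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cpg_islands import GmmFit, classify_two_component, fit_univariate_gmm

__all__ = [
    "median_expression_partition",
    "tissue_specificity",
    "specificity_partition",
    "EXPRESSION_LABELS",
    "SPECIFICITY_LABELS",
]

EXPRESSION_LABELS = ("L_E", "H_E")
SPECIFICITY_LABELS = ("L_S", "M_S", "H_S")


def median_expression_partition(expr: pd.DataFrame, seed: int = 0):
    """Split genes into low/high expression by a GMM on median expression.

    ``expr`` is a genes x tissues frame of finite normalized values.  Returns
    ``(labels, fit)`` where labels maps gene -> "L_E"/"H_E" (low-mean
    component = L_E).  A degenerate (unimodal) fit is flagged on ``fit``
    rather than raising.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    if expr.shape[0] < 200:
        raise ValueError("need at least 200 genes")
    if not np.isfinite(expr.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    med = expr.median(axis=1)
    fit = fit_univariate_gmm(med.to_numpy(), seed=seed)
    hi, _ = classify_two_component(fit, med.to_numpy(), allow_unconverged=True)
    labels = pd.Series(np.where(hi, EXPRESSION_LABELS[1], EXPRESSION_LABELS[0]),
                       index=expr.index, name="expression_group")
    return labels, fit


def tissue_specificity(expr: pd.DataFrame, method: str = "tau") -> pd.Series:
    """Per-gene tissue-specificity score in [0, 1].

    Only the tau index is implemented; expression must be non-negative.
    All-zero genes have undefined specificity and get NaN (with a warning).
    """
    if method != "tau":
        raise ValueError(f"unknown specificity method {method!r}")
    x = expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression values")
    n_tissues = x.shape[1]
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rowmax = x.max(axis=1)
    zero = rowmax == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero genes have undefined specificity",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - x / rowmax[:, None]).sum(axis=1) / (n_tissues - 1)
    tau[zero] = np.nan
    return pd.Series(tau, index=expr.index, name="tau")


def specificity_partition(scores: pd.Series, n_groups: int = 3,
                          bounds: Optional[Sequence[float]] = None) -> pd.Series:
    """Partition genes by specificity score.

    With ``bounds`` (ascending cut-points, length ``n_groups - 1``) genes are
    binned by score value, which reproduces unequal group sizes; otherwise
    groups are rank quantiles of equal size.  For three groups labels are
    L_S / M_S / H_S (lowest to highest specificity); NaN scores get NaN.
    """
    valid = scores.dropna()
    if len(valid) < n_groups:
        raise ValueError("fewer scored genes than groups")
    if bounds is not None:
        if len(bounds) != n_groups - 1 or list(bounds) != sorted(bounds):
            raise ValueError("bounds must be ascending with length n_groups - 1")
        idx = np.searchsorted(np.asarray(bounds, dtype=float), valid.to_numpy(),
                              side="right")
        part = pd.Series(idx, index=valid.index)
    else:
        from .chip_profiles import quantile_partition

        part = quantile_partition(valid, n_groups)
    if n_groups == 3:
        names = dict(enumerate(SPECIFICITY_LABELS))
    else:
        names = {i: f"S{i}" for i in range(n_groups)}
    out = part.map(names).reindex(scores.index)
    out.name = "specificity_group"
    return out
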