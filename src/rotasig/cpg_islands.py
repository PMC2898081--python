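"""Model-based CpG-island classification of promoters.

Rather than ad hoc length/GC thresholds, promoters are scored by the CpG
observed/expected ratio over a window around the TSS and split by a
two-component Gaussian mixture fitted by EM: the high-mean component is the
CpG-island class.  The mixture machinery is univariate and is shared with
the expression-level partition.

cpg_oe = (#CG dinucleotides x L) / (#C x #G), with L the number of non-N
bases in the window and 0 when #C.#G = 0; gc_frac = (#C + #G) / L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .coords import display_to_offset
from .tss_io import AlignedSeqSet

__all__ = [
    "CpGFeature",
    "GmmFit",
    "cpg_feature",
    "cpg_features",
    "fit_univariate_gmm",
    "fit_cpg_gmm",
    "classify_two_component",
    "classify_cpg",
]


@dataclass
class CpGFeature:
    tss_id: str
    cpg_oe: float
    gc_frac: float
    window: tuple[int, int]  # display coordinates


@dataclass
class GmmFit:
    """Two-component univariate normal mixture, components ordered by mean."""

    means: np.ndarray  # (2,)
    sds: np.ndarray
    weights: np.ndarray
    converged: bool
    loglik: float
    n_iter: int
    degenerate: bool = False  # components not meaningfully separated


def _counts(seq: str):
    up = seq.upper()
    n_c = up.count("C")
    n_g = up.count("G")
    n_cg = sum(1 for i in range(len(up) - 1) if up[i] == "C" and up[i + 1] == "G")
    n_valid = sum(1 for c in up if c in "ACGT")
    return n_c, n_g, n_cg, n_valid


def cpg_feature(seq: str, tss_id: str = "", window: tuple[int, int] = (-500, 500)) -> CpGFeature:
    """CpG observed/expected and GC fraction of a promoter window string."""
    if len(seq) < 200:
        raise ValueError("window must be at least 200 bp")
    n_c, n_g, n_cg, n_valid = _counts(seq)
    if n_valid == 0:
        raise ValueError(f"all-N window for {tss_id!r}")
    if n_valid / len(seq) < 0.5:
        raise ValueError(f"window for {tss_id!r} is more than half N")
    oe = (n_cg * n_valid / (n_c * n_g)) if n_c * n_g > 0 else 0.0
    return CpGFeature(tss_id, float(oe), (n_c + n_g) / n_valid, window)


def cpg_features(seqs: AlignedSeqSet, window: tuple[int, int] = (-500, 500)) -> pd.DataFrame:
    """Per-promoter CpG features over a TSS-relative display window.

    The default window (-500, +500) spans 1,000 bases centred on the TSS.
    Returns a DataFrame indexed by tss_id with columns cpg_oe, gc_frac.
    """
    lo = seqs.offset_of_tss + display_to_offset(window[0])
    hi = seqs.offset_of_tss + display_to_offset(window[1]) + 1
    if lo < 0 or hi > seqs.length:
        raise ValueError("window exceeds sequence bounds")
    if hi - lo < 200:
        raise ValueError("window must be at least 200 bp")
    codes = seqs.codes[:, lo:hi]
    is_c = codes == 1
    is_g = codes == 2
    n_c = is_c.sum(axis=1)
    n_g = is_g.sum(axis=1)
    n_cg = (is_c[:, :-1] & is_g[:, 1:]).sum(axis=1)
    n_valid = (codes < 4).sum(axis=1)
    frac = n_valid / (hi - lo)
    bad = np.flatnonzero(frac < 0.5)
    if bad.size:
        ids = [seqs.source_ids[i] for i in bad[:10]]
        raise ValueError(f"windows more than half N for {ids}")
    prod = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(prod > 0, n_cg * n_valid / np.maximum(prod, 1), 0.0)
    gc = (n_c + n_g) / n_valid
    return pd.DataFrame({"cpg_oe": oe, "gc_frac": gc},
                        index=pd.Index(seqs.source_ids, name="tss_id"))


# ---------------------------------------------------------------------------
# Two-component univariate mixture

def fit_univariate_gmm(values, seed: int = 0, max_iter: int = 500,
                       tol: float = 1e-6) -> GmmFit:
    """EM fit of a 2-component normal mixture, deterministic given ``seed``.

    Means are initialized at the 25th/75th percentiles (so the fit does not
    depend on a random restart), weights at 1/2 and variances at the sample
    variance.  Non-convergence returns a flagged partial fit rather than
    raising.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 finite values for the mixture fit")
    q25, q75 = np.percentile(x, [25, 75])
    var = max(x.var(), 1e-12)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="diag",
        means_init=[[q25], [q75]],
        weights_init=[0.5, 0.5],
        precisions_init=[[1.0 / var], [1.0 / var]],
        random_state=seed,
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        reg_covar=1e-10,
    )
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    pooled_sd = float(np.sqrt(weights @ sds**2))
    separation = abs(means[1] - means[0]) / max(pooled_sd, 1e-12)
    loglik = float(gm.score(x[:, None]) * x.size)
    return GmmFit(means, sds, weights, bool(gm.converged_), loglik,
                  int(gm.n_iter_), degenerate=separation < 1.0)


def fit_cpg_gmm(features, seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> GmmFit:
    """Fit the CpG o/e mixture (accepts an array or the cpg_features frame)."""
    if isinstance(features, pd.DataFrame):
        features = features["cpg_oe"].to_numpy()
    return fit_univariate_gmm(features, seed=seed, max_iter=max_iter, tol=tol)


def classify_two_component(fit: GmmFit, values, allow_unconverged: bool = False):
    """Assign each value to a mixture component.

    Returns ``(labels, posterior)`` where ``labels`` is True for the high-mean
    component and ``posterior`` is the posterior probability of the assigned
    component (ties break to the high-mean component, so the assigned
    posterior is always >= 0.5).
    """
    if not fit.converged and not allow_unconverged:
        raise ValueError("mixture fit did not converge (pass allow_unconverged=True to override)")
    x = np.asarray(values, dtype=float).ravel()
    logp = np.stack([
        np.log(max(fit.weights[i], 1e-300)) + stats.norm.logpdf(x, fit.means[i], fit.sds[i])
        for i in (0, 1)
    ])
    m = logp.max(axis=0)
    post_hi = np.exp(logp[1] - m) / np.exp(logp - m).sum(axis=0)
    labels = post_hi >= 0.5
    posterior = np.where(labels, post_hi, 1.0 - post_hi)
    return labels, posterior


def classify_cpg(fit: GmmFit, features, allow_unconverged: bool = False):
    """CpG-island calls: True = high-mean (island) component.

    Accepts an array of cpg_oe values or the :func:`cpg_features` frame, in
    which case a DataFrame with label and posterior columns is returned.
    """
    if isinstance(features, pd.DataFrame):
        labels, post = classify_two_component(fit, features["cpg_oe"].to_numpy(),
                                              allow_unconverged)
        out = features.copy()
        out["cpg_island"] = labels
        out["posterior"] = post
        return out
    return classify_two_component(fit, features, allow_unconverged)
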