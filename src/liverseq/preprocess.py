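"""Expression filtering, log transformation, batch adjustment and normalization.

Two preprocessing branches feed the differential-expression stage:

* perfusion branch: expression filter -> TMM normalization -> CPM;
* cold-storage branch: expression filter -> log2 -> empirical-Bayes
  location/scale batch adjustment -> back-transform -> CPM.

The batch adjustment is the parametric location/scale empirical-Bayes
scheme (per-gene standardization, per-batch location gamma and scale
delta estimates shrunk toward batch-level normal / inverse-gamma priors,
then removal and restoration of the grand location/scale).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import BatchModel, CountMatrix, NormalizationFactors


def filter_expressed(cm: CountMatrix, n_subjects: int) -> CountMatrix:
    """Keep genes whose number of samples with a nonzero count strictly
    exceeds ``n_subjects``; gene order is preserved."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    nonzero = (cm.counts > 0).sum(axis=1)
    keep = nonzero > n_subjects
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return CountMatrix(cm.counts.loc[keep], cm.meta)


def log2_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(counts + pseudocount)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch: np.ndarray, g_hat, d_hat, g_bar, t2, a, b,
            conv: float = 1e-4, max_iter: int = 200):
    """Standard iterative solution for the EB-shrunken batch parameters."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ssq = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(ssq, n, a, b)
        change = max(np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
                     np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def batch_adjust(logmat: pd.DataFrame, batches: pd.Series) -> tuple[pd.DataFrame, BatchModel]:
    """Remove per-batch location/scale effects from log2 expression.

    Parameters
    ----------
    logmat
        genes x samples log2 expression.
    batches
        per-sample batch labels aligned to ``logmat`` columns.

    Returns the adjusted matrix and the fitted :class:`BatchModel`.  With a
    single batch the input is returned unchanged with an identity model.
    A final per-gene recentering pins the grand mean of the output to the
    input's, so shrinkage residue cannot shift absolute expression levels.
    """
    batches = pd.Series(batches, index=logmat.columns) if not isinstance(batches, pd.Series) \
        else batches.loc[logmat.columns]
    labels = pd.unique(batches)
    if len(labels) == 1:
        return logmat.copy(), BatchModel.identity(logmat.index, labels)
    counts_per_batch = batches.value_counts()
    if (counts_per_batch < 2).any():
        small = counts_per_batch[counts_per_batch < 2].index.tolist()
        raise ValueError(f"every batch needs >= 2 samples; too small: {small}")

    Y = logmat.to_numpy(dtype=float)
    sample_batch = batches.to_numpy()
    n_total = Y.shape[1]
    batch_idx = {b: np.flatnonzero(sample_batch == b) for b in labels}
    n_b = {b: len(ix) for b, ix in batch_idx.items()}

    batch_means = np.column_stack([Y[:, batch_idx[b]].mean(axis=1) for b in labels])
    weights = np.array([n_b[b] / n_total for b in labels])
    grand = batch_means @ weights
    # residual variance about per-batch means, pooled over all samples
    fitted = np.empty_like(Y)
    for i, b in enumerate(labels):
        fitted[:, batch_idx[b]] = batch_means[:, [i]]
    var_pooled = ((Y - fitted) ** 2).sum(axis=1) / n_total
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)

    Z = (Y - grand[:, None]) / sd[:, None]

    gamma_star = np.empty((len(labels), Y.shape[0]))
    delta2_star = np.empty_like(gamma_star)
    for i, b in enumerate(labels):
        zb = Z[:, batch_idx[b]]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b_pr = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b_pr)
        gamma_star[i] = g_star
        delta2_star[i] = np.maximum(d_star, 1e-12)

    Z_adj = Z.copy()
    for i, b in enumerate(labels):
        ix = batch_idx[b]
        Z_adj[:, ix] = (Z[:, ix] - gamma_star[i][:, None]) / np.sqrt(delta2_star[i])[:, None]
    adjusted = Z_adj * sd[:, None] + grand[:, None]
    # pin the per-gene grand mean to the input's
    adjusted += (Y.mean(axis=1) - adjusted.mean(axis=1))[:, None]

    out = pd.DataFrame(adjusted, index=logmat.index, columns=logmat.columns)
    model = BatchModel(
        gamma=pd.DataFrame(gamma_star * sd[None, :],
                           index=pd.Index(labels, name="batch"), columns=logmat.index),
        delta2=pd.DataFrame(delta2_star, index=pd.Index(labels, name="batch"),
                            columns=logmat.index),
        grand_mean=pd.Series(grand, index=logmat.index),
        pooled_var=pd.Series(var_pooled, index=logmat.index),
    )
    return out, model


def back_transform(logmat: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Invert :func:`log2_transform`, clipping negatives to zero."""
    return np.maximum(np.exp2(logmat) - pseudocount, 0.0)


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    usable = (obs > 0) & (ref > 0)
    o, r = obs[usable].astype(float), ref[usable].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # precision weights from the delta method on binomial counts
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = len(m)
    if n == 0:
        return 1.0
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = (m[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, reference: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors, centered to geometric mean 1.

    The reference sample defaults to the one whose 75th-percentile
    count fraction is closest to the across-sample mean of that quantity.
    """
    lib = cm.library_sizes.astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    counts = cm.counts.to_numpy(dtype=float)
    if reference is None:
        f75 = np.percentile(counts / lib.to_numpy()[None, :], 75, axis=0)
        reference = cm.samples[int(np.argmin(np.abs(f75 - f75.mean())))]
    ref_col = cm.counts[reference].to_numpy(dtype=float)
    lib_ref = float(lib[reference])

    factors = {}
    for s in cm.samples:
        if s == reference:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_pair(cm.counts[s].to_numpy(dtype=float), ref_col,
                                   float(lib[s]), lib_ref, trim_m, trim_a)
    f = pd.Series(factors).loc[cm.samples]
    f /= np.exp(np.log(f).mean())  # geometric-mean centering
    return NormalizationFactors(factors=f, library_sizes=cm.library_sizes)


def to_cpm(counts: pd.DataFrame, factors: NormalizationFactors | None = None,
           library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over (optionally TMM-adjusted) library sizes.

    ``library_sizes`` overrides the column sums; ignored when ``factors``
    is given (its effective sizes are used).
    """
    if factors is not None:
        eff = factors.effective_library_sizes.loc[counts.columns]
    elif library_sizes is not None:
        eff = library_sizes.loc[counts.columns]
    else:
        eff = counts.sum(axis=0)
    if (eff <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts / eff * 1e6
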