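"""Negative-binomial GLM testing for differential expression.

Counts for gene g in sample j are modelled as NB with mean
``mu_gj = exp(x_j' beta_g + o_j)`` and variance ``mu + phi_g mu^2``,
where ``o_j = log(L_j f_j)`` is the effective-library-size offset.
Gene-wise dispersions are estimated by Cox-Reid adjusted profile
likelihood: a common dispersion maximizes the summed adjusted profile
likelihood, and tagwise values maximize each gene's adjusted profile
likelihood plus a prior weight times the shared one (shrinkage toward
the common value).  Contrasts are tested with likelihood-ratio chi-square
tests between nested fits, and p-values pass through Benjamini-Hochberg.

All fits run as one vectorized IRLS across genes: the design matrix is
shared, so the per-iteration weighted least-squares solves batch into a
single ``numpy.linalg.solve`` over a stack of p x p systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix, NormalizationFactors

LN2 = float(np.log(2.0))


@dataclass
class DesignSpec:
    """Design matrix, tested coefficients, and per-sample offsets."""

    X: pd.DataFrame                 # samples x coefficients
    tested: list                    # coefficient names under test
    offsets: pd.Series              # log effective library size per sample

    def __post_init__(self) -> None:
        Xv = self.X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
            raise ValueError("design matrix is rank deficient")
        missing = [c for c in self.tested if c not in self.X.columns]
        if missing:
            raise ValueError(f"tested coefficients not in design: {missing}")
        if not np.isfinite(self.offsets.to_numpy(dtype=float)).all():
            raise ValueError("offsets must be finite")

    @property
    def reduced(self) -> "DesignSpec":
        kept = [c for c in self.X.columns if c not in self.tested]
        return DesignSpec(self.X[kept], tested=[], offsets=self.offsets)

    @property
    def residual_df(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


def unpaired_design(meta: pd.DataFrame, baseline: str, treated: str,
                    offsets: pd.Series) -> DesignSpec:
    """Intercept + group indicator for a two-group comparison."""
    sub = meta[meta["group"].isin([baseline, treated])]
    X = pd.DataFrame({"intercept": 1.0,
                      f"{treated}_vs_{baseline}": (sub["group"] == treated).astype(float)},
                     index=sub.index)
    return DesignSpec(X, [f"{treated}_vs_{baseline}"], offsets.loc[sub.index])


def paired_design(meta: pd.DataFrame, baseline_tp: str, treated_tp: str,
                  offsets: pd.Series) -> DesignSpec:
    """Intercept + donor indicators + timepoint indicator, within one group.

    Donors missing either timepoint are excluded with a warning.
    """
    sub = meta[meta["timepoint"].isin([baseline_tp, treated_tp])]
    complete = []
    for donor, rows in sub.groupby("donor_id"):
        if set(rows["timepoint"]) >= {baseline_tp, treated_tp}:
            complete.append(donor)
        else:
            warnings.warn(f"donor {donor} lacks a timepoint; excluded from paired design",
                          stacklevel=2)
    sub = sub[sub["donor_id"].isin(complete)]
    donors = sorted(sub["donor_id"].unique())
    cols = {"intercept": np.ones(len(sub))}
    for d in donors[1:]:
        cols[f"donor_{d}"] = (sub["donor_id"] == d).astype(float).to_numpy()
    test_col = f"{treated_tp}_vs_{baseline_tp}"
    cols[test_col] = (sub["timepoint"] == treated_tp).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=sub.index)
    return DesignSpec(X, [test_col], offsets.loc[sub.index])


def offsets_from_factors(nf: NormalizationFactors) -> pd.Series:
    return np.log(nf.effective_library_sizes.astype(float))


def offsets_from_library_sizes(lib: pd.Series) -> pd.Series:
    return np.log(lib.astype(float))


# ---------------------------------------------------------------------------
# likelihoods


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB residual deviance (Poisson limit at phi = 0)."""
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * (np.log(np.maximum(y, 1e-300)) - np.log(mu)), 0.0)
    pois = t1 - (y - mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        nb = t1 - (y + 1.0 / np.maximum(phi, 1e-300)) * (np.log1p(phi * y) - np.log1p(phi * mu))
    unit = np.where(phi <= 1e-12, pois, nb)
    return 2.0 * unit.sum(axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (Poisson limit at phi = 0)."""
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)[:, None]
    pois = y * np.log(mu) - mu - gammaln(y + 1.0)
    r = 1.0 / np.maximum(phi, 1e-300)
    nb = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
          + y * np.log(mu / (r + mu)) + r * np.log(r / (r + mu)))
    ll = np.where(phi <= 1e-12, pois, nb)
    return ll.sum(axis=1)


# ---------------------------------------------------------------------------
# vectorized IRLS


@dataclass
class GLMFit:
    beta: pd.DataFrame       # genes x coefficients (natural-log scale)
    deviance: pd.Series
    fitted: pd.DataFrame     # genes x samples fitted means
    converged: pd.Series
    design: DesignSpec
    dispersions: pd.Series

    def log2fc(self, coefficient: str | None = None) -> pd.Series:
        coefficient = coefficient or self.design.tested[0]
        return self.beta[coefficient] / LN2


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
          max_iter: int = 50, tol: float = 1e-8):
    """IRLS for the NB log-link GLM, batched over genes (shared design)."""
    G, n = y.shape
    p = X.shape[1]
    ridge = 1e-8 * np.eye(p)

    all_zero = y.sum(axis=1) == 0

    eta0 = np.log(np.maximum(y, 0.5))
    XtX = X.T @ X
    beta = np.linalg.solve(XtX + ridge, ((eta0 - offset) @ X).T).T
    eta = np.clip(beta @ X.T + offset, -40.0, 40.0)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, phi)
    converged = np.zeros(G, dtype=bool)

    active = ~all_zero
    for _ in range(max_iter):
        if not active.any():
            break
        ya, mua, etaa = y[active], mu[active], eta[active]
        phia = phi[active]
        W = mua / (1.0 + phia[:, None] * mua)
        W = np.maximum(W, 1e-12)
        z = (etaa - offset) + (ya - mua) / mua
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
        XtWz = np.einsum("ni,gn->gi", X, W * z, optimize=True)
        new_beta = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]

        old_beta = beta[active]
        old_dev = dev[active]
        for _half in range(10):
            eta_new = np.clip(new_beta @ X.T + offset, -40.0, 40.0)
            mu_new = np.exp(eta_new)
            dev_new = nb_deviance(ya, mu_new, phia)
            worse = dev_new > old_dev * (1 + 1e-10) + 1e-10
            if not worse.any():
                break
            new_beta[worse] = 0.5 * (new_beta[worse] + old_beta[worse])
        beta[active] = new_beta
        eta[active], mu[active], dev[active] = eta_new, mu_new, dev_new
        done = np.abs(dev_new - old_dev) < tol * (np.abs(old_dev) + 1.0)
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False

    # all-zero genes: degenerate fit at mu -> 0
    if all_zero.any():
        beta[all_zero] = 0.0
        beta[all_zero, 0] = -40.0
        eta[all_zero] = -40.0
        mu[all_zero] = np.exp(-40.0)
        dev[all_zero] = 0.0
        converged[all_zero] = True
    return beta, mu, dev, converged


def fit_nb_glm(counts: pd.DataFrame, design: DesignSpec,
               dispersions: pd.Series | float,
               max_iter: int = 50, tol: float = 1e-8) -> GLMFit:
    """Maximum-likelihood NB GLM fit for every gene under one design."""
    y = counts[design.X.index].to_numpy(dtype=float)
    X = design.X.to_numpy(dtype=float)
    offset = design.offsets.to_numpy(dtype=float)
    if np.isscalar(dispersions):
        phi = np.full(len(counts), float(dispersions))
    else:
        phi = dispersions.loc[counts.index].to_numpy(dtype=float)
    if (phi < 0).any():
        raise ValueError("dispersions must be nonnegative")
    beta, mu, dev, conv = _irls(y, X, offset, phi, max_iter=max_iter, tol=tol)
    return GLMFit(
        beta=pd.DataFrame(beta, index=counts.index, columns=design.X.columns),
        deviance=pd.Series(dev, index=counts.index),
        fitted=pd.DataFrame(mu, index=counts.index, columns=design.X.index),
        converged=pd.Series(conv, index=counts.index),
        design=design,
        dispersions=pd.Series(phi, index=counts.index),
    )


# ---------------------------------------------------------------------------
# dispersion estimation


def _adjusted_profile_loglik(y, X, offset, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    beta, mu, dev, conv = _irls(y, X, offset, phi, max_iter=30, tol=1e-6)
    ll = nb_loglik(y, mu, phi)
    W = np.maximum(mu / (1.0 + phi[:, None] * mu), 1e-12)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-10 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet


def estimate_dispersions(counts: pd.DataFrame, design: DesignSpec,
                         prior_df: float = 10.0,
                         grid_span: float = 8.0, grid_points: int = 21) -> pd.Series:
    """Tagwise NB dispersions shrunk toward the common Cox-Reid estimate.

    The common dispersion maximizes the summed adjusted profile likelihood;
    tagwise values maximize ``APL_g + prior_n * mean_g(APL)`` on a log2 grid
    around the common value (``prior_n = prior_df / residual_df``), with
    quadratic interpolation at the grid maximum.
    """
    if design.residual_df < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    y = counts[design.X.index].to_numpy(dtype=float)
    X = design.X.to_numpy(dtype=float)
    offset = design.offsets.to_numpy(dtype=float)
    G = y.shape[0]

    zero = y.sum(axis=1) == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero genes assigned the common dispersion",
                      stacklevel=2)

    def common_objective(log10_phi: float) -> float:
        phi = np.full(G, 10.0 ** log10_phi)
        return -float(_adjusted_profile_loglik(y, X, offset, phi)[~zero].sum())

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(common_objective, bounds=(-6.0, 1.5), method="bounded",
                          options={"xatol": 2e-2})
    common = float(10.0 ** res.x)

    grid = common * np.exp2(np.linspace(-grid_span, grid_span, grid_points))
    grid = np.clip(grid, 1e-8, 50.0)
    apl = np.empty((grid_points, G))
    for k, phi_k in enumerate(grid):
        apl[k] = _adjusted_profile_loglik(y, X, offset, np.full(G, phi_k))
    prior_n = prior_df / max(design.residual_df, 1)
    shared = apl[:, ~zero].mean(axis=1, keepdims=True)
    score = apl + prior_n * shared

    best = score.argmax(axis=0)
    log_grid = np.log(grid)
    phi_out = log_grid[best].copy()
    # quadratic interpolation where the max is interior
    interior = (best > 0) & (best < grid_points - 1)
    ii = np.flatnonzero(interior)
    if ii.size:
        b = best[ii]
        y0, y1, y2 = score[b - 1, ii], score[b, ii], score[b + 1, ii]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = log_grid[1] - log_grid[0]
        phi_out[ii] = log_grid[b] + shift * step
    phi = np.exp(phi_out)
    phi[zero] = common
    return pd.Series(phi, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# testing


def lrt_test(full: GLMFit, reduced: GLMFit, neg_tol: float = 1e-6) -> pd.DataFrame:
    """Likelihood-ratio chi-square test between nested fits.

    Returns a DataFrame with columns ``LR``, ``df`` and ``p``.  Genes whose
    full fit failed to converge report p = 1.
    """
    if not set(reduced.design.X.columns) <= set(full.design.X.columns):
        raise ValueError("reduced design must be nested in the full design")
    df = full.design.X.shape[1] - reduced.design.X.shape[1]
    lr = (reduced.deviance - full.deviance).to_numpy(dtype=float)
    scale = np.maximum(np.abs(reduced.deviance.to_numpy()), 1.0)
    if (lr < -neg_tol * scale).any():
        bad = full.deviance.index[lr < -neg_tol * scale].tolist()[:5]
        raise RuntimeError(f"negative LR statistic beyond tolerance (fit failure), e.g. {bad}")
    lr = np.maximum(lr, 0.0)
    # df = 0 (identical designs) is degenerate: LR = 0 and p = 1
    p = np.ones_like(lr) if df == 0 else chi2.sf(lr, df)
    bad_fit = ~(full.converged.to_numpy() & reduced.converged.to_numpy())
    p = np.where(bad_fit, 1.0, p)
    return pd.DataFrame({"LR": lr, "df": df, "p": p}, index=full.deviance.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_lrt_pipeline(counts: pd.DataFrame, design: DesignSpec,
                    dispersions: pd.Series | None = None,
                    prior_df: float = 10.0) -> pd.DataFrame:
    """Dispersion estimation + full/reduced fits + LRT + BH in one call.

    Returns the per-gene table (logFC on the log2 scale, logCPM, dispersion,
    LR, p, q) the DE stages of both analysis branches consume.
    """
    if dispersions is None:
        dispersions = estimate_dispersions(counts, design, prior_df=prior_df)
    full = fit_nb_glm(counts, design, dispersions)
    reduced = fit_nb_glm(counts, design.reduced, dispersions)
    lrt = lrt_test(full, reduced)
    lib = np.exp(design.offsets.to_numpy(dtype=float))
    cpm = counts[design.X.index].to_numpy(dtype=float) / lib[None, :] * 1e6
    out = pd.DataFrame({
        "logFC": full.log2fc(),
        "logCPM": np.log2(cpm.mean(axis=1) + 0.25),
        "dispersion": dispersions.loc[counts.index],
        "LR": lrt["LR"],
        "p": lrt["p"],
        "q": bh_adjust(lrt["p"].to_numpy()),
    }, index=counts.index)
    return out
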