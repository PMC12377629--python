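"""Model-fit and chain diagnostics: DIC, LMPL, Geweke, collinearity.

DIC uses the posterior-mean plug-in: ``DIC = Dbar + p_d`` with
``p_d = Dbar - D(theta_bar)`` where ``D = -2 log L``.  LMPL is the sum of
log conditional predictive ordinates, each CPO the harmonic mean of the
per-draw likelihood of that observation.  The Geweke z-score compares the
mean of the first 10% of a chain with the last 50%, with variances from a
lag-window estimate of the spectral density at frequency zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .carmodel import PosteriorSamples, design_matrix
from .standardize import StudyTable

__all__ = ["model_diagnostics", "geweke_z", "collinearity_checks"]


def model_diagnostics(samples: PosteriorSamples, table: StudyTable) -> dict:
    """DIC, effective parameters p_d and LMPL from stored draws."""
    ll = samples.pointwise_loglik(table)          # (S, K)
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite per-draw log-likelihood encountered")
    dev = -2.0 * ll.sum(axis=1)
    dbar = float(dev.mean())

    # plug-in deviance at posterior means of beta and phi
    X, _ = design_matrix(table, samples.spec.covariates)
    eta_bar = X @ samples.beta.mean(axis=0) + samples.phi.mean(axis=0)
    mu_bar = table.E * np.exp(eta_bar)
    Y = table.Y
    ll_bar = float(np.sum(Y * np.log(mu_bar) - mu_bar - gammaln(Y + 1.0)))
    d_hat = -2.0 * ll_bar
    p_d = dbar - d_hat

    # CPO_k = harmonic mean of per-draw likelihoods, via log-sum-exp
    S = ll.shape[0]
    log_cpo = np.log(S) - logsumexp(-ll, axis=0)
    if np.any(~np.isfinite(log_cpo)):
        warnings.warn("zero-likelihood draws encountered in CPO computation",
                      stacklevel=2)
    lmpl = float(np.sum(log_cpo))

    return {
        "DIC": dbar + p_d,
        "p_d": p_d,
        "LMPL": lmpl,
        "deviance_mean": dbar,
        "deviance_at_mean": d_hat,
        "log_cpo": log_cpo,
    }


def _spectral_var(x: np.ndarray) -> float:
    """Spectral density at frequency zero over segment length (Bartlett window)."""
    n = len(x)
    xc = x - x.mean()
    lag_max = int(np.floor(np.sqrt(n)))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for lag in range(1, lag_max + 1):
        cov = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (lag_max + 1.0)) * cov
    return max(s, 0.0) / n


def geweke_z(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for a single chain.

    Compares the mean of the first ``first`` fraction of the chain against
    the last ``last`` fraction; both means' variances come from spectral
    density estimates at frequency zero, so autocorrelation is accounted
    for.  |z| > 2 suggests the chain has not reached stationarity.
    """
    x = np.asarray(chain, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("chain must have at least 100 draws")
    n1 = int(first * len(x))
    n2 = int(last * len(x))
    seg1, seg2 = x[:n1], x[-n2:]
    if np.ptp(seg1) == 0 or np.ptp(seg2) == 0:
        raise ValueError("constant chain segment; Geweke z undefined")
    v1, v2 = _spectral_var(seg1), _spectral_var(seg2)
    denom = np.sqrt(v1 + v2)
    if denom == 0:
        raise ValueError("zero spectral variance; Geweke z undefined")
    return float((seg1.mean() - seg2.mean()) / denom)


def collinearity_checks(table: StudyTable, samples: PosteriorSamples | None = None,
                        covariates=None) -> dict:
    """Variance inflation factors and posterior correlations of beta.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing covariate j on the others
    (with intercept).  Perfect collinearity yields an infinite VIF with a
    warning.  When posterior samples are supplied, the correlation matrix
    of the beta draws is also returned.
    """
    if covariates is None:
        if samples is not None:
            covariates = [n for n in samples.beta_names if n != "intercept"]
        elif table.covariates is not None:
            covariates = list(table.covariates.columns)
        else:
            covariates = []
    if len(covariates) < 2:
        raise ValueError("VIF requires at least 2 covariates")
    Xc = np.column_stack(
        [table.covariates[c].to_numpy(dtype=float) for c in covariates])
    K, p = Xc.shape
    vif = {}
    for j in range(p):
        yj = Xc[:, j]
        others = np.column_stack([np.ones(K), np.delete(Xc, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss <= 0:
            raise ValueError(f"covariate {covariates[j]!r} has zero variance")
        r2 = 1.0 - float(resid @ resid) / tss
        if r2 >= 1.0 - 1e-12:
            warnings.warn(
                f"covariate {covariates[j]!r} is perfectly collinear",
                stacklevel=2)
            vif[covariates[j]] = np.inf
        else:
            vif[covariates[j]] = 1.0 / (1.0 - r2)

    out = {"vif": vif}
    if samples is not None:
        corr = np.corrcoef(samples.beta.T)
        out["posterior_beta_corr"] = pd.DataFrame(
            corr, index=samples.beta_names, columns=samples.beta_names)
    return out
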