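"""Poisson log-linear disease mapping with a dissimilarity-adjusted
localized CAR prior, fitted by Metropolis-within-Gibbs.

Model
-----
Counts ``Y_k ~ Poisson(E_k * R_k)`` with ``ln R_k = x_k' beta + phi_k``.
The spatial random effects ``phi`` carry a conditional autoregressive
prior whose neighbor weights are attenuated by an edge dissimilarity
``z_ij`` (absolute hardship-decile differences between adjacent units):

    w*_ij(alpha) = w_ij * exp(-alpha * z_ij),

so smoothing is strong between similar neighbors and breaks down across
sharp socioeconomic transitions.  The dissimilarity coefficient ``alpha``
is estimated; an adjacent pair is a *step change* ("social frontier")
when ``w*_ij < 0.5`` at the posterior median of ``alpha``, and the
smallest ``alpha`` at which any pair can be flagged is
``alpha_min = ln(2) / max(z)``.

The joint prior for ``phi`` is Gaussian with precision
``tau^-2 (diag(W* 1) - W* + eps I)``; the small ridge ``eps`` makes the
otherwise intrinsic prior proper so its normalizing constant (needed for
the ``alpha`` update) is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.sparse.linalg import splu

from .graph import AreaGraph
from .hardship import DissimilaritySet
from .standardize import StudyTable

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "FrontierSet",
    "build_wstar",
    "alpha_min",
    "boundary_relative_risk",
    "car_precision",
    "car_full_conditional",
    "car_log_density",
    "sample_car_prior",
    "design_matrix",
    "fit_model",
    "identify_boundaries",
]

LN2 = float(np.log(2.0))


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ModelSpec:
    """Model formula, priors and MCMC settings.

    ``covariates`` names columns of the study table's covariate frame; the
    intercept is always included.  Priors: ``beta ~ N(0, beta_prior_var)``
    elementwise, ``tau2 ~ InvGamma(tau2_shape, tau2_scale)``,
    ``alpha ~ Uniform(0, alpha_upper)``.
    """

    covariates: tuple = ()
    beta_prior_var: float = 1e5
    tau2_shape: float = 1.0
    tau2_scale: float = 0.01
    alpha_upper: float = 50.0
    n_burn: int = 20000
    n_keep: int = 10000
    thin: int = 2
    seed: int = 0
    eps: float = 1e-3
    adapt_interval: int = 50
    target_accept_scalar: float = 0.40
    target_accept_block: float = 0.25

    def __post_init__(self) -> None:
        if self.n_keep <= 0 or self.thin <= 0:
            raise ValueError("n_keep and thin must be positive")
        if self.eps <= 0:
            raise ValueError("propriety jitter eps must be positive")
        if self.alpha_upper <= 0:
            raise ValueError("alpha_upper must be positive")


@dataclass
class PosteriorSamples:
    """Stored MCMC draws with chain metadata."""

    beta: np.ndarray            # (S, p)
    beta_names: tuple
    phi: np.ndarray             # (S, K)
    tau2: np.ndarray            # (S,)
    alpha: np.ndarray           # (S,)
    accept_rates: dict
    spec: ModelSpec
    unit_ids: tuple

    def __post_init__(self) -> None:
        if np.any(self.tau2 <= 0):
            raise ValueError("all tau2 draws must be positive")
        if np.any(self.alpha <= 0) or np.any(self.alpha >= self.spec.alpha_upper):
            raise ValueError("alpha draws must lie in (0, alpha_upper)")
        if len(self.tau2) != self.spec.n_keep:
            raise ValueError("stored draw count must equal n_keep")

    @property
    def n_draws(self) -> int:
        return len(self.tau2)

    def linear_predictor(self, table: StudyTable) -> np.ndarray:
        """Per-draw linear predictor eta = X beta' + phi, shape (S, K)."""
        X, _ = design_matrix(table, self.spec.covariates)
        return self.beta @ X.T + self.phi

    def pointwise_loglik(self, table: StudyTable) -> np.ndarray:
        """Per-draw, per-unit Poisson log-likelihood, shape (S, K)."""
        from scipy.special import gammaln

        eta = self.linear_predictor(table)
        mu = table.E * np.exp(eta)
        Y = table.Y
        return Y * np.log(mu) - mu - gammaln(Y + 1.0)

    def summary(self) -> pd.DataFrame:
        """Posterior medians, 95% credible intervals and Geweke z-scores."""
        from .diagnostics import geweke_z

        rows = {}
        chains = {name: self.beta[:, j] for j, name in enumerate(self.beta_names)}
        chains["tau2"] = self.tau2
        chains["alpha"] = self.alpha
        for name, ch in chains.items():
            try:
                gz = geweke_z(ch)
            except ValueError:
                gz = np.nan
            rows[name] = {
                "median": np.median(ch),
                "lo95": np.quantile(ch, 0.025),
                "hi95": np.quantile(ch, 0.975),
                "mean": ch.mean(),
                "sd": ch.std(ddof=1),
                "geweke_z": gz,
            }
        return pd.DataFrame(rows).T


@dataclass
class FrontierSet:
    """Edges flagged as step changes, with posterior boundary probabilities."""

    edges: tuple                      # index pairs
    edge_ids: tuple                   # unit-id pairs, canonical order
    probability: np.ndarray           # P(w*_ij < 0.5) per edge
    flagged: np.ndarray               # bool per edge (at posterior median alpha)
    alpha_median: float
    alpha_min: float

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if np.any(self.probability < 0) or np.any(self.probability > 1):
            raise ValueError("boundary probabilities must lie in [0, 1]")

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / max(len(self.edges), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id_i": [a for a, _ in self.edge_ids],
            "id_j": [b for _, b in self.edge_ids],
            "boundary_prob": self.probability,
            "step_change": self.flagged.astype(int),
        })

    def to_geojson(self, graph: AreaGraph, path) -> None:
        """Write flagged edges as a LineString layer joining unit centroids."""
        import json

        if graph.centroids is None:
            raise ValueError("graph has no centroids; cannot draw frontier lines")
        feats = []
        for m, (i, j) in enumerate(self.edges):
            if not self.flagged[m]:
                continue
            ci, cj = graph.centroids[i], graph.centroids[j]
            feats.append({
                "type": "Feature",
                "properties": {
                    "id_i": str(self.edge_ids[m][0]),
                    "id_j": str(self.edge_ids[m][1]),
                    "boundary_prob": float(self.probability[m]),
                },
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(ci[0]), float(ci[1])],
                                    [float(cj[0]), float(cj[1])]],
                },
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ----------------------------------------------------------------------
def build_wstar(graph: AreaGraph, Z: DissimilaritySet, alpha: float) -> np.ndarray:
    """Modified edge weights ``w*_ij = exp(-alpha * z_ij)`` per edge."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    z = np.asarray(Z.values, dtype=float)
    if np.any(z < 0):
        raise ValueError("dissimilarities must be nonnegative")
    if len(z) != len(graph.edges):
        raise ValueError("dissimilarity set does not match the graph's edges")
    return np.exp(-alpha * z)


def alpha_min(Z: DissimilaritySet) -> float:
    """Smallest alpha at which the most dissimilar adjacent pair is a boundary.

    Under the rule ``w* = exp(-alpha z) < 0.5``, the first pair that can be
    flagged is the one with maximal z, at ``alpha_min = ln(2) / max(z)``.
    """
    zmax = Z.z_max
    if zmax <= 0:
        raise ValueError("all dissimilarities are zero; no boundary detectable")
    return LN2 / zmax


def boundary_relative_risk(log_coefficient: float) -> float:
    """Relative-risk reading of a log-scale coefficient: ``exp(coef)``."""
    return float(np.exp(log_coefficient))


def _wstar_matrix(graph: AreaGraph, w: np.ndarray, as_sparse: bool):
    ei, ej = graph.edge_arrays
    if as_sparse:
        data = np.concatenate([w, w])
        return sparse.coo_matrix(
            (data, (np.concatenate([ei, ej]), np.concatenate([ej, ei]))),
            shape=(graph.K, graph.K),
        ).tocsr()
    W = np.zeros((graph.K, graph.K))
    W[ei, ej] = w
    W[ej, ei] = w
    return W


def car_precision(graph: AreaGraph, Z: DissimilaritySet, alpha: float,
                  eps: float = 1e-3, as_sparse: bool = False):
    """Unit-scale CAR precision ``Q = diag(W* 1) - W* + eps I``.

    The full prior precision of ``phi`` is ``Q / tau2``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    w = build_wstar(graph, Z, alpha)
    ei, ej = graph.edge_arrays
    rs = (np.bincount(ei, weights=w, minlength=graph.K)
          + np.bincount(ej, weights=w, minlength=graph.K))
    W = _wstar_matrix(graph, w, as_sparse)
    if as_sparse:
        return sparse.diags(rs + eps) - W
    return np.diag(rs + eps) - W


def car_full_conditional(phi, k: int, wstar, tau2: float,
                         eps: float = 1e-3) -> tuple[float, float]:
    """Full-conditional mean and variance of ``phi_k`` given the rest.

    ``wstar`` is the K x K modified adjacency (dense or sparse).  An
    isolated unit (zero row) shrinks to the prior center with variance
    ``tau2 / eps``.
    """
    if tau2 <= 0 or eps <= 0:
        raise ValueError("tau2 and eps must be positive")
    phi = np.asarray(phi, dtype=float)
    if sparse.issparse(wstar):
        row = np.asarray(wstar.getrow(k).todense()).ravel()
    else:
        row = np.asarray(wstar, dtype=float)[k]
    denom = row.sum() + eps
    mean = float(row @ phi) / denom
    var = tau2 / denom
    return mean, var


def car_log_density(phi, graph: AreaGraph, Z: DissimilaritySet, alpha: float,
                    tau2: float, eps: float = 1e-3) -> float:
    """Joint log density of ``phi`` under the proper localized CAR prior."""
    phi = np.asarray(phi, dtype=float)
    Q = car_precision(graph, Z, alpha, eps)
    L = np.linalg.cholesky(Q)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    K = graph.K
    quad = float(phi @ Q @ phi)
    return 0.5 * (logdet - K * np.log(tau2)) - quad / (2.0 * tau2) \
        - 0.5 * K * np.log(2.0 * np.pi)


def sample_car_prior(graph: AreaGraph, Z: DissimilaritySet, alpha: float,
                     tau2: float, eps: float = 1e-3, rng=None) -> np.ndarray:
    """Draw ``phi ~ N(0, tau2 * Q^{-1})`` from the proper localized CAR prior."""
    rng = np.random.default_rng(rng)
    Q = car_precision(graph, Z, alpha, eps)
    L = np.linalg.cholesky(Q)
    zdraw = rng.standard_normal(graph.K)
    x = solve_triangular(L.T, zdraw, lower=False)
    return np.sqrt(tau2) * x


def design_matrix(table: StudyTable, covariates=()) -> tuple[np.ndarray, tuple]:
    """Design matrix with leading intercept column and the named covariates."""
    cols = [np.ones(table.K)]
    names = ["intercept"]
    for name in covariates:
        if table.covariates is None or name not in table.covariates.columns:
            raise ValueError(f"covariate {name!r} not present in study table")
        col = table.covariates[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            raise ValueError(f"covariate {name!r} contains missing values")
        cols.append(col)
        names.append(name)
    return np.column_stack(cols), tuple(names)


# ----------------------------------------------------------------------
def _graph_coloring(graph: AreaGraph) -> list:
    """Partition units into independent sets for vectorized phi updates."""
    G = nx.Graph()
    G.add_nodes_from(range(graph.K))
    G.add_edges_from(graph.edges)
    coloring = nx.greedy_color(G, strategy="largest_first")
    n_colors = max(coloring.values()) + 1
    return [np.array(sorted(k for k, c in coloring.items() if c == col), dtype=int)
            for col in range(n_colors)]


def _logdet_Q(graph: AreaGraph, w: np.ndarray, rs: np.ndarray, eps: float) -> float:
    K = graph.K
    if K <= 2000:
        ei, ej = graph.edge_arrays
        Q = np.zeros((K, K))
        Q[ei, ej] = -w
        Q[ej, ei] = -w
        Q[np.diag_indices(K)] = rs + eps
        try:
            L = np.linalg.cholesky(Q)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "CAR precision not positive definite; increase the propriety "
                "jitter eps"
            ) from exc
        return 2.0 * float(np.sum(np.log(np.diag(L))))
    Qs = sparse.diags(rs + eps) - _wstar_matrix(graph, w, True)
    lu = splu(Qs.tocsc())
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _glm_init(X: np.ndarray, Y: np.ndarray, logE: np.ndarray):
    """Poisson GLM starting values and proposal covariance Cholesky."""
    import statsmodels.api as sm

    p = X.shape[1]
    try:
        res = sm.GLM(Y, X, family=sm.families.Poisson(), offset=logE).fit()
        beta0 = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if not (np.all(np.isfinite(beta0)) and np.all(np.isfinite(cov))):
            raise ValueError
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(p))
    except Exception:
        beta0 = np.zeros(p)
        L = 0.1 * np.eye(p)
    return beta0, L


def fit_model(table: StudyTable, graph: AreaGraph, Z: DissimilaritySet,
              spec: ModelSpec) -> PosteriorSamples:
    """Fit the localized-CAR Poisson model by Metropolis-within-Gibbs.

    Updates per sweep: a blocked random-walk Metropolis step for ``beta``;
    independent-set ("colored") random-walk Metropolis steps for each
    ``phi_k`` against its Poisson likelihood times CAR full conditional;
    a conjugate inverse-gamma Gibbs draw for ``tau2``; a log-scale
    random-walk Metropolis step for ``alpha`` against the joint CAR density
    (including the log-determinant of the precision).  ``phi`` is
    re-centered each sweep with its mean absorbed into the intercept.
    Proposal scales adapt during burn-in only.  Fully reproducible for a
    fixed seed.
    """
    if table.E is None:
        raise ValueError("study table has no expected counts; run standardization")
    Y = np.asarray(table.Y, dtype=float)
    E = np.asarray(table.E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive for a finite likelihood")
    if abs(E.sum() - Y.sum()) > 1e-6 * max(Y.sum(), 1.0):
        warnings.warn(
            "sum(E) != sum(Y): expected counts are not internally standardized",
            stacklevel=2,
        )
    X, names = design_matrix(table, spec.covariates)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    z = np.asarray(Z.values, dtype=float)
    ei, ej = graph.edge_arrays
    if len(z) != len(ei):
        raise ValueError("dissimilarity set does not match the graph's edges")
    K = graph.K
    eps = spec.eps
    a_tau, b_tau = spec.tau2_shape, spec.tau2_scale
    Vb = spec.beta_prior_var

    rng = np.random.default_rng(spec.seed)
    colors = _graph_coloring(graph)
    beta, Lprop = _glm_init(X, Y, np.log(E))
    # start phi at the centered residual log risk so tau2 opens at a
    # realistic scale (a cold phi=0 start collapses the first tau2 draw)
    phi = np.log((Y + 0.5) / E) - X @ beta
    phi -= phi.mean()
    tau2 = max(float(phi.var()), 1e-3)
    alpha = min(1.0, spec.alpha_upper / 2.0)

    w = np.exp(-alpha * z)
    rs = (np.bincount(ei, weights=w, minlength=K)
          + np.bincount(ej, weights=w, minlength=K))
    logdet = _logdet_Q(graph, w, rs, eps)
    xb = X @ beta

    s_beta, s_alpha = 1.0, 0.5
    s_phi = np.full(len(colors), 0.5)

    n_iter = spec.n_burn + spec.n_keep * spec.thin
    out_beta = np.empty((spec.n_keep, p))
    out_phi = np.empty((spec.n_keep, K))
    out_tau2 = np.empty(spec.n_keep)
    out_alpha = np.empty(spec.n_keep)

    # acceptance bookkeeping: (accepted, attempted) per component
    tot = {"beta": [0, 0], "alpha": [0, 0], "phi": [0, 0]}
    bat = {"beta": [0, 0], "alpha": [0, 0]}
    bat_phi = np.zeros((len(colors), 2))

    stored = 0
    for it in range(n_iter):
        burn = it < spec.n_burn

        # ---- beta: blocked random-walk Metropolis
        prop = beta + s_beta * (Lprop @ rng.standard_normal(p))
        xbp = X @ prop
        logr = (Y @ (xbp - xb)
                - (E * np.exp(phi)) @ (np.exp(xbp) - np.exp(xb))
                - (prop @ prop - beta @ beta) / (2.0 * Vb))
        bat["beta"][1] += 1
        tot["beta"][1] += 1
        if np.log(rng.uniform()) < logr:
            beta, xb = prop, xbp
            bat["beta"][0] += 1
            tot["beta"][0] += 1

        # ---- phi: independent-set random-walk Metropolis
        Eexb = E * np.exp(xb)
        for c, idx in enumerate(colors):
            sphi = (np.bincount(ei, weights=w * phi[ej], minlength=K)
                    + np.bincount(ej, weights=w * phi[ei], minlength=K))
            denom = rs[idx] + eps
            m = sphi[idx] / denom
            prec = denom / tau2
            cur = phi[idx]
            cand = cur + s_phi[c] * rng.standard_normal(len(idx))
            dll = (Y[idx] * (cand - cur)
                   - Eexb[idx] * (np.exp(cand) - np.exp(cur)))
            dpr = -0.5 * prec * ((cand - m) ** 2 - (cur - m) ** 2)
            acc = np.log(rng.uniform(size=len(idx))) < dll + dpr
            phi[idx[acc]] = cand[acc]
            bat_phi[c] += (acc.sum(), len(idx))
            tot["phi"][0] += int(acc.sum())
            tot["phi"][1] += len(idx)

        # ---- identifiability: center phi, shift mean into intercept
        mu = phi.mean()
        phi -= mu
        beta = beta.copy()
        beta[0] += mu
        xb = xb + mu

        # ---- tau2: conjugate inverse-gamma Gibbs draw
        dphi = phi[ei] - phi[ej]
        quad = eps * float(phi @ phi) + float(w @ (dphi * dphi))
        tau2 = 1.0 / rng.gamma(a_tau + 0.5 * K, 1.0 / (b_tau + 0.5 * quad))

        # ---- alpha: log-scale random-walk Metropolis against CAR density
        theta = np.log(alpha)
        theta_p = theta + s_alpha * rng.standard_normal()
        alpha_p = np.exp(theta_p)
        bat["alpha"][1] += 1
        tot["alpha"][1] += 1
        if alpha_p < spec.alpha_upper:
            w_p = np.exp(-alpha_p * z)
            rs_p = (np.bincount(ei, weights=w_p, minlength=K)
                    + np.bincount(ej, weights=w_p, minlength=K))
            logdet_p = _logdet_Q(graph, w_p, rs_p, eps)
            quad_p = eps * float(phi @ phi) + float(w_p @ (dphi * dphi))
            logr = (0.5 * (logdet_p - logdet)
                    - (quad_p - quad) / (2.0 * tau2)
                    + (theta_p - theta))      # Jacobian of the log transform
            if np.log(rng.uniform()) < logr:
                alpha, w, rs, logdet = alpha_p, w_p, rs_p, logdet_p
                bat["alpha"][0] += 1
                tot["alpha"][0] += 1

        # ---- proposal adaptation, burn-in only
        if burn and (it + 1) % spec.adapt_interval == 0:
            accd, att = bat["beta"]
            if att:
                s_beta = float(np.clip(
                    s_beta * np.exp(accd / att - spec.target_accept_block),
                    1e-6, 100.0))
            accd, att = bat["alpha"]
            if att:
                s_alpha = float(np.clip(
                    s_alpha * np.exp(accd / att - spec.target_accept_scalar),
                    1e-6, 100.0))
            bat = {"beta": [0, 0], "alpha": [0, 0]}
            for c in range(len(colors)):
                accd, att = bat_phi[c]
                if att:
                    rate = accd / att
                    s_phi[c] = float(np.clip(
                        s_phi[c] * np.exp(rate - spec.target_accept_scalar),
                        1e-6, 100.0))
            bat_phi[:] = 0.0

        # ---- storage
        if not burn and (it - spec.n_burn + 1) % spec.thin == 0:
            out_beta[stored] = beta
            out_phi[stored] = phi
            out_tau2[stored] = tau2
            out_alpha[stored] = alpha
            stored += 1

    assert stored == spec.n_keep
    rates = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in tot.items()}
    return PosteriorSamples(
        beta=out_beta, beta_names=names, phi=out_phi, tau2=out_tau2,
        alpha=out_alpha, accept_rates=rates, spec=spec,
        unit_ids=graph.unit_ids,
    )


def identify_boundaries(samples: PosteriorSamples, graph: AreaGraph,
                        Z: DissimilaritySet) -> FrontierSet:
    """Flag step changes and compute posterior boundary probabilities.

    An edge's boundary probability is the fraction of posterior draws with
    ``exp(-alpha z_ij) < 0.5``; the binary step-change flag applies that
    rule at the posterior median of ``alpha``.
    """
    if samples.alpha is None or len(samples.alpha) == 0:
        raise ValueError("posterior samples contain no alpha draws")
    z = np.asarray(Z.values, dtype=float)
    if len(z) != len(graph.edges):
        raise ValueError("dissimilarity set does not match the graph's edges")
    alpha_draws = samples.alpha
    # exp(-alpha z) < 0.5  <=>  alpha * z > ln 2
    prob = (alpha_draws[:, None] * z[None, :] > LN2).mean(axis=0)
    a_med = float(np.median(alpha_draws))
    flagged = a_med * z > LN2
    try:
        amin = alpha_min(Z)
    except ValueError:
        amin = np.nan
    return FrontierSet(
        edges=graph.edges,
        edge_ids=tuple(graph.edge_ids()),
        probability=prob,
        flagged=flagged,
        alpha_median=a_med,
        alpha_min=amin,
    )
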