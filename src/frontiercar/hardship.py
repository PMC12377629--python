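"""Hardship scoring and edge dissimilarity metrics.

Implements the covariate-side primitives of the boundary-detection
pipeline: empirical decile scores of a deprivation index, absolute decile
differences on adjacent pairs (the dissimilarity metric that drives the
localized CAR prior), a Monte Carlo randomization test for whether
neighbors are more similar than chance, the Hirschman–Herfindahl
concentration index, and a generic first-principal-component composite
index builder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graph import AreaGraph

__all__ = [
    "DissimilaritySet",
    "decile_scores",
    "dissimilarity_matrix",
    "NeighborDifferenceResult",
    "neighbor_difference_test",
    "hhi",
    "composite_index",
]


@dataclass
class DissimilaritySet:
    """Nonnegative per-edge dissimilarity values on an AreaGraph's edges.

    ``values[m]`` is z_ij for the graph's m-th canonical edge.  ``units``
    records the scale: ``"decile"`` for integer absolute decile differences
    in [0, 9], ``"normalized"`` for values scaled to [0, 1] by the maximum
    observed difference.
    """

    edges: tuple
    values: np.ndarray
    K: int
    units: str = "decile"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.edges),):
            raise ValueError("one dissimilarity value per edge required")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be nonnegative")
        if self.units == "decile":
            if np.any(self.values > 9) or np.any(self.values != np.round(self.values)):
                raise ValueError("decile-unit dissimilarities must be integers in [0, 9]")
        elif self.units == "normalized":
            if np.any(self.values > 1):
                raise ValueError("normalized dissimilarities must lie in [0, 1]")
        else:
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def z_max(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric K x K matrix with z on edges, 0 elsewhere."""
        Z = np.zeros((self.K, self.K))
        for (i, j), z in zip(self.edges, self.values):
            Z[i, j] = z
            Z[j, i] = z
        return Z

    def to_frame(self, graph: AreaGraph | None = None) -> pd.DataFrame:
        ids = graph.edge_ids() if graph is not None else list(self.edges)
        return pd.DataFrame(
            {"id_i": [a for a, _ in ids], "id_j": [b for _, b in ids],
             "z": self.values}
        )


def decile_scores(values) -> np.ndarray:
    """Empirical decile score (1..10) per unit.

    Units are ranked (ties receive their average rank) and ranks are binned
    into ten equal-frequency groups, so with distinct values each decile
    holds floor(K/10) or ceil(K/10) units and tied units always share a
    decile.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be a 1-d vector")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing values not allowed")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; deciles undefined")
    ranks = stats.rankdata(values, method="average")
    d = np.ceil(ranks * 10.0 / len(values)).astype(int)
    return np.clip(d, 1, 10)


def dissimilarity_matrix(graph: AreaGraph, deciles,
                         normalize: bool = False) -> DissimilaritySet:
    """Absolute decile difference |d_i - d_j| on each adjacent pair.

    With ``normalize=True`` values are divided by the maximum observed
    difference (all-zero sets are left unchanged).
    """
    d = np.asarray(deciles)
    if d.shape != (graph.K,):
        raise ValueError(f"deciles must have length K={graph.K}")
    if np.any(d < 1) or np.any(d > 10):
        raise ValueError("deciles must lie in 1..10")
    ei, ej = graph.edge_arrays
    z = np.abs(d[ei] - d[ej]).astype(float)
    if normalize:
        zmax = z.max() if len(z) else 0.0
        if zmax > 0:
            z = z / zmax
        return DissimilaritySet(graph.edges, z, graph.K, units="normalized")
    return DissimilaritySet(graph.edges, z, graph.K, units="decile")


@dataclass
class NeighborDifferenceResult:
    """Output of the neighbor-difference randomization test."""

    statistic: float                 # observed mean absolute neighbor difference
    pseudo_p: float                  # lower-tail: neighbors more similar than chance
    observed_diffs: np.ndarray       # |x_i - x_j| per edge
    null_stats: np.ndarray           # permuted mean |diff| values
    null_diffs_sample: np.ndarray    # pooled permuted |diff| values (for histograms)
    n_perm: int
    seed: int | None


def neighbor_difference_test(graph: AreaGraph, values, n_perm: int = 999,
                             seed: int | None = None) -> NeighborDifferenceResult:
    """Monte Carlo randomization test for neighbor similarity.

    Unit values are randomly reassigned to units; the mean absolute
    difference over the fixed edge set forms the null distribution.  The
    lower-tail pseudo p-value ``(1 + #{null <= observed}) / (1 + n_perm)``
    is small when adjacent units are more similar than expected under
    spatial randomness.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = np.asarray(values, dtype=float)
    if x.shape != (graph.K,):
        raise ValueError(f"values must have length K={graph.K}")
    if np.ptp(x) == 0:
        raise ValueError(
            "values are constant; neighbor differences are degenerate under "
            "any permutation"
        )
    ei, ej = graph.edge_arrays
    if len(ei) == 0:
        raise ValueError("graph has no edges")
    obs_diffs = np.abs(x[ei] - x[ej])
    obs = float(obs_diffs.mean())

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    null_diffs = np.abs(perms[:, ei] - perms[:, ej])
    null_stats = null_diffs.mean(axis=1)
    p = (1.0 + int(np.sum(null_stats <= obs))) / (1.0 + n_perm)
    return NeighborDifferenceResult(
        statistic=obs,
        pseudo_p=p,
        observed_diffs=obs_diffs,
        null_stats=null_stats,
        null_diffs_sample=null_diffs.ravel(),
        n_perm=n_perm,
        seed=seed,
    )


def hhi(proportions) -> float:
    """Hirschman–Herfindahl index: sum of squared group shares.

    Ranges from 1/G (G equal groups, maximal diversity) to 1 (a single
    group).  Shares must be nonnegative and sum to 1 within 1e-6; otherwise
    they are renormalized with a warning.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("at least one group share required")
    if np.any(p < 0):
        raise ValueError("group shares must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("group shares sum to zero")
    if abs(total - 1.0) > 1e-6:
        warnings.warn(f"shares sum to {total:.6g}; renormalizing", stacklevel=2)
        p = p / total
    return float(np.sum(p ** 2))


def composite_index(items, loadings=None, names=None) -> np.ndarray:
    """Standardized composite index from a per-unit item matrix.

    Items are z-scored internally.  With ``loadings`` the index is the
    standardized weighted sum; otherwise it is the first principal-component
    score of the standardized items, sign-aligned so the first item loads
    positively.  The returned index has zero mean and unit variance.
    """
    if isinstance(items, pd.DataFrame):
        if names is None:
            names = list(items.columns)
        items = items.to_numpy(dtype=float)
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("items must be a 2-d matrix with at least 2 columns")
    if names is None:
        names = [f"item{j + 1}" for j in range(items.shape[1])]
    sd = items.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s <= 0:
            raise ValueError(f"item {names[j]!r} has zero variance")
    Zm = (items - items.mean(axis=0)) / sd

    if loadings is not None:
        w = np.asarray(loadings, dtype=float)
        if w.shape != (items.shape[1],):
            raise ValueError("one loading per item required")
        idx = Zm @ w
    else:
        _, _, vt = np.linalg.svd(Zm, full_matrices=False)
        pc1 = vt[0]
        if pc1[0] < 0:
            pc1 = -pc1
        idx = Zm @ pc1
    s = idx.std(ddof=0)
    if s <= 0:
        raise ValueError("composite index is degenerate (zero variance)")
    return (idx - idx.mean()) / s
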