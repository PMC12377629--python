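"""Internal indirect standardization: expected counts and SMRs.

Expected counts E_k allocate the study-wide event total to units in
proportion to population at risk (optionally within strata), so that
sum(E) = sum(Y) exactly and the standardized mortality ratio SMR_k =
Y_k / E_k averages to 1 when weighted by E.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["StudyTable", "expected_counts", "smr"]

RESERVED_COLUMNS = ("unit_id", "Y", "n", "E", "SMR", "ehi", "decile")


def expected_counts(Y, n, strata=None) -> np.ndarray:
    """Expected counts by internal indirect standardization.

    ``E_k = n_k * (sum Y / sum n)`` within each stratum (a single stratum by
    default), so the expected counts inherit the study-wide rate and
    ``sum(E) == sum(Y)`` exactly.
    """
    Y = np.asarray(Y, dtype=float)
    n = np.asarray(n, dtype=float)
    if Y.shape != n.shape or Y.ndim != 1:
        raise ValueError("Y and n must be 1-d vectors of equal length")
    if np.any(Y < 0) or np.any(Y != np.round(Y)):
        raise ValueError("Y must contain nonnegative integers")
    if np.any(n <= 0):
        bad = int(np.argmax(n <= 0))
        raise ValueError(f"population must be positive (unit index {bad})")
    if strata is None:
        strata = np.zeros(len(Y), dtype=int)
    strata = np.asarray(strata)
    E = np.empty_like(Y)
    for s in np.unique(strata):
        m = strata == s
        ytot = Y[m].sum()
        if ytot <= 0:
            raise ValueError(f"stratum {s!r} has zero events; rate undefined")
        E[m] = n[m] * (ytot / n[m].sum())
    return E


def smr(Y, E) -> np.ndarray:
    """Standardized mortality ratio ``Y_k / E_k`` per unit."""
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    if Y.shape != E.shape:
        raise ValueError("Y and E must have equal length")
    if np.any(E <= 0):
        bad = int(np.argmax(E <= 0))
        raise ValueError(f"expected count must be positive (unit index {bad})")
    return Y / E


@dataclass
class StudyTable:
    """Per-unit study data: counts, population, expected counts, covariates.

    ``covariates`` is a DataFrame (one row per unit) holding any model
    covariates, including spatial lags.  ``ehi`` and ``decile`` carry the
    hardship score and its decile when available.
    """

    unit_ids: tuple
    Y: np.ndarray
    n: np.ndarray
    E: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    ehi: np.ndarray | None = None
    decile: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unit_ids = tuple(self.unit_ids)
        K = len(self.unit_ids)
        self.Y = np.asarray(self.Y, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.Y.shape != (K,) or self.n.shape != (K,):
            raise ValueError("Y and n must have one entry per unit")
        if np.any(self.Y < 0) or np.any(self.Y != np.round(self.Y)):
            raise ValueError("Y must contain nonnegative integers")
        if np.any(self.n <= 0):
            raise ValueError("population n must be positive")
        if self.E is not None:
            self.E = np.asarray(self.E, dtype=float)
            if self.E.shape != (K,):
                raise ValueError("E must have one entry per unit")
            if np.any(self.E <= 0):
                raise ValueError("expected counts must be positive")
        if self.covariates is not None and len(self.covariates) != K:
            raise ValueError("covariates must have one row per unit")
        for arr_name in ("ehi", "decile"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (K,):
                    raise ValueError(f"{arr_name} must have one entry per unit")
                setattr(self, arr_name, arr)

    @property
    def K(self) -> int:
        return len(self.unit_ids)

    def with_expected(self, strata=None) -> "StudyTable":
        """Return a copy with E filled by internal standardization."""
        return replace(self, E=expected_counts(self.Y, self.n, strata=strata))

    @property
    def smr(self) -> np.ndarray:
        if self.E is None:
            raise ValueError("expected counts not computed; call with_expected()")
        return smr(self.Y, self.E)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"unit_id": list(self.unit_ids), "Y": self.Y.astype(int),
                           "n": self.n})
        if self.E is not None:
            df["E"] = self.E
            df["SMR"] = self.smr
        if self.ehi is not None:
            df["ehi"] = self.ehi
        if self.decile is not None:
            df["decile"] = self.decile.astype(int)
        if self.covariates is not None:
            for c in self.covariates.columns:
                df[c] = np.asarray(self.covariates[c])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyTable":
        missing = {"unit_id", "Y", "n"} - set(df.columns)
        if missing:
            raise ValueError(f"study table missing columns: {sorted(missing)}")
        cov_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
        return cls(
            unit_ids=tuple(df["unit_id"]),
            Y=df["Y"].to_numpy(),
            n=df["n"].to_numpy(),
            E=df["E"].to_numpy() if "E" in df else None,
            covariates=df[cov_cols].reset_index(drop=True) if cov_cols else None,
            ehi=df["ehi"].to_numpy() if "ehi" in df else None,
            decile=df["decile"].to_numpy() if "decile" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "StudyTable":
        return cls.from_frame(pd.read_csv(path))
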