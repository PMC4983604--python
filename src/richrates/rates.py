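"""Brownian-motion rate (sigma^2) estimation and PCA utilities.

The evolutionary rate of a continuous trait is the variance it accrues
per million years under Brownian motion. With tip values ``x`` and the
phylogenetic covariance ``C`` the maximum-likelihood estimates are

    mu_hat     = (1' C^-1 1)^-1  1' C^-1 x          (ancestral state)
    sigma2_hat = (x - mu_hat)' C^-1 (x - mu_hat) / n

with the REML variant dividing by ``n - 1`` instead. Multi-trait rates
(e.g. a single number for several principal components) are combined by
summing the per-trait rates: under a shared tree the multi-rate
Brownian log-likelihood separates by trait, so the summed rate is the
natural scalar summary. The arithmetic mean is available as an option.

PCA here is a thin eigendecomposition wrapper with an explicit
covariance-vs-correlation scaling switch, since trait tables routinely
mix variables on different scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .phylo import PhyloCovariance

__all__ = [
    "PCAResult",
    "RateEstimate",
    "pca",
    "bm_rate",
    "combine_rates",
    "read_trait_table",
]


# --------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # observations x components
    loadings: np.ndarray  # variables x components, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None  # per-variable SDs when correlation-scaled
    variable_labels: tuple[str, ...] | None = None


def pca(
    data: np.ndarray | pd.DataFrame,
    scaling: Literal["covariance", "correlation"] = "covariance",
) -> PCAResult:
    """Principal components of an observations-by-variables table.

    ``scaling="correlation"`` standardizes each variable to unit SD
    first (appropriate when variables are on incommensurable scales,
    e.g. temperature and precipitation); ``"covariance"`` analyzes the
    centered data as-is. Components are ordered by decreasing
    eigenvalue and the variance-explained ratios sum to one.
    """
    labels = tuple(map(str, data.columns)) if isinstance(data, pd.DataFrame) else None
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    if np.isnan(X).any():
        raise ValueError("missing values in trait table")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if scaling == "correlation":
        scale = Xc.std(axis=0, ddof=1)
        if np.any(scale == 0):
            zero = np.flatnonzero(scale == 0)
            raise ValueError(f"constant variables cannot be correlation-scaled: columns {zero.tolist()}")
        Xc = Xc / scale
    elif scaling != "covariance":
        raise ValueError(f"unknown scaling: {scaling!r}")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (X.shape[0] - 1)
    ratio = ev / ev.sum() if ev.sum() > 0 else ev
    return PCAResult(
        scores=Xc @ Vt.T,
        loadings=Vt.T,
        explained_variance=ev,
        explained_variance_ratio=ratio,
        mean=mean,
        scale=scale,
        variable_labels=labels,
    )


# --------------------------------------------------------------------
# sigma^2 estimation
# --------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    """Per-trait and combined Brownian rates with their ancestral states."""

    sigma2_per_trait: np.ndarray  # squared trait units per My
    mu: np.ndarray  # ML ancestral state per trait
    n_species: int
    method: str  # "ml" (divide by n) or "reml" (n - 1)
    combine_mode: str  # "sum" or "mean"

    @property
    def sigma2_combined(self) -> float:
        return combine_rates(self.sigma2_per_trait, mode=self.combine_mode)

    @property
    def sigma2(self) -> float:
        """The single rate: per-trait value if univariate, else combined."""
        if len(self.sigma2_per_trait) == 1:
            return float(self.sigma2_per_trait[0])
        return self.sigma2_combined


def bm_rate(
    x: np.ndarray | pd.Series | pd.DataFrame,
    C: PhyloCovariance | np.ndarray,
    method: Literal["ml", "reml"] = "ml",
    combine: Literal["sum", "mean"] = "sum",
) -> RateEstimate:
    """Maximum-likelihood Brownian rate(s) for one or more traits.

    ``x`` may be a vector (one trait) or a species-by-traits matrix
    aligned to the tip order of ``C``. When ``x`` carries an index and
    ``C`` carries taxa, the rows of ``x`` are aligned to ``C`` by label.
    """
    if isinstance(C, PhyloCovariance):
        taxa = C.taxa
        V = C.matrix
    else:
        taxa = None
        V = np.asarray(C, dtype=float)
    if isinstance(x, (pd.Series, pd.DataFrame)) and taxa is not None:
        missing = [t for t in taxa if t not in x.index]
        if missing:
            raise KeyError(f"tips absent from trait data: {missing}")
        x = x.loc[list(taxa)]
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if V.shape != (n, n):
        raise ValueError(f"covariance is {V.shape}, trait data has {n} species")
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "phylogenetic covariance is singular (coincident tips or "
            "zero-length terminal branches); add a small branch-length jitter"
        ) from exc
    one = np.ones(n)
    Vi1 = cho_solve(cf, one)
    denom = float(one @ Vi1)
    mu = (Vi1 @ X) / denom
    R = X - mu[None, :]
    quad = np.einsum("ij,ij->j", R, cho_solve(cf, R))
    dof = n if method == "ml" else n - 1
    if method not in {"ml", "reml"}:
        raise ValueError(f"unknown method: {method!r}")
    sigma2 = quad / dof
    sigma2[np.abs(sigma2) < 1e-300] = 0.0
    return RateEstimate(
        sigma2_per_trait=np.maximum(sigma2, 0.0),
        mu=mu,
        n_species=n,
        method=method,
        combine_mode=combine,
    )


def combine_rates(per_trait: Sequence[float] | np.ndarray, mode: str = "sum") -> float:
    """Collapse per-trait rates to one number (sum by default, or mean)."""
    rates = np.asarray(per_trait, dtype=float)
    if rates.size == 0:
        raise ValueError("cannot combine an empty list of rates")
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    if mode == "sum":
        return float(rates.sum())
    if mode == "mean":
        return float(rates.mean())
    raise ValueError(f"unknown combine mode: {mode!r}")


def read_trait_table(
    source,
    species_column: str | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a species-by-variables table from delimited text.

    The species key column (default: first column) becomes the index;
    remaining columns must be numeric.
    """
    df = pd.read_csv(source, sep=sep, engine="python")
    key = species_column or df.columns[0]
    if key not in df.columns:
        raise KeyError(f"species column {key!r} not found")
    df = df.set_index(key)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric trait columns: {non_numeric}")
    return df
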