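"""Pybus–Harvey gamma statistic for diversification slowdown.

Given the internode intervals ``g_k`` of an ultrametric tree (``g_k`` is
the time during which the reconstructed phylogeny had exactly ``k``
lineages, ``k = 2..n``), the statistic is

    T   = sum_{k=2}^{n} k * g_k
    T_i = sum_{k=2}^{i} k * g_k
    gamma = [ (1/(n-2)) * sum_{i=2}^{n-1} T_i  -  T/2 ]
            / [ T * sqrt(1 / (12 (n-2))) ]

Under a constant-rate pure-birth (Yule) process gamma is asymptotically
standard normal; negative values indicate branching concentrated toward
the root, read as diversification slowing through time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import BranchingTimes, Phylogeny

__all__ = ["GammaResult", "gamma_stat"]


@dataclass(frozen=True)
class GammaResult:
    """Gamma with the internode bookkeeping it was computed from."""

    gamma: float
    n_tips: int
    total_weighted_time: float  # T = sum k * g_k, in My
    intervals: np.ndarray  # g_k for k = 2..n

    def __float__(self) -> float:
        return self.gamma


def gamma_stat(bt: BranchingTimes | Phylogeny) -> GammaResult:
    """Compute gamma from branching times (or directly from a tree).

    Requires at least 3 tips and a positive total weighted time. Gamma is
    invariant to uniform rescaling of all branch lengths.
    """
    if isinstance(bt, Phylogeny):
        bt = bt.branching_times()
    n = bt.n_tips
    if n < 3:
        raise ValueError(f"gamma requires >= 3 tips, got {n}")
    g = bt.intervals
    if np.any(g < -1e-12):
        raise ValueError("negative internode interval")
    k = np.arange(2, n + 1, dtype=float)
    weighted = k * g
    T = float(weighted.sum())
    if T <= 0:
        raise ValueError("total weighted time is zero: degenerate tree")
    # partial sums T_i for i = 2..n-1 (exclude the final, full sum)
    partial = np.cumsum(weighted)[:-1]
    num = partial.mean() - T / 2.0
    den = T * np.sqrt(1.0 / (12.0 * (n - 2)))
    return GammaResult(float(num / den), n, T, g)
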