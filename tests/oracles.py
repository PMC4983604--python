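"""Independent brute-force oracles used to cross-check the implementation.

These deliberately recompute quantities by a different route than the
package (edge-set intersection instead of postorder accumulation,
reverse instead of forward cumulative sums, explicit matrix inversion
instead of Cholesky solves).
"""

from __future__ import annotations

import numpy as np

from richrates.phylo import Phylogeny


def vcv_path_intersection(tree: Phylogeny) -> np.ndarray:
    """Tip covariance by intersecting root-to-tip edge sets."""
    n_nodes = len(tree.parent)
    paths = {}
    for k, tip in enumerate(tree._tip_idx):
        edges = []
        i = int(tip)
        while tree.parent[i] >= 0:
            edges.append(i)
            i = tree.parent[i]
        paths[k] = set(edges)
    n = tree.n_tips
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = paths[i] & paths[j]
            C[i, j] = sum(tree.branch_lengths[e] for e in shared)
    return C


def gamma_reverse(intervals: np.ndarray) -> float:
    """Pybus-Harvey gamma with the partial sums accumulated tip-to-root."""
    g = np.asarray(intervals, dtype=float)
    n = len(g) + 1
    k = np.arange(2, n + 1, dtype=float)
    w = k * g
    T = w.sum()
    # T_i = T - sum_{j>i} w_j, accumulated from the present backwards
    tail = np.cumsum(w[::-1])[::-1]
    partial = T - np.concatenate([tail[1:], [0.0]])
    num = partial[:-1].mean() - T / 2.0
    return float(num / (T * np.sqrt(1.0 / (12.0 * (n - 2)))))


def gls_beta_explicit(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """(X' V^-1 X)^-1 X' V^-1 y by explicit inversion."""
    Vi = np.linalg.inv(V)
    return np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
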