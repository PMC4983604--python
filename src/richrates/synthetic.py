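"""Synthetic trees, traits and clade tables for testing the analysis.

Every generator is a pure function of its parameters and a seed: the
same seed reproduces the same output bit-for-bit, and each call draws
from a single root-seeded :class:`numpy.random.Generator` consumed in
documented traversal order.

The clade-table generator emulates the statistical structure the
comparative analysis assumes: a Yule backbone tree over clades,
per-clade evolutionary rates drawn from a lognormal, and log species
richness generated as a linear function of one rate plus residuals that
are Brownian on the backbone (phylogenetically correlated, with tunable
Pagel's lambda). Its defaults mirror the real 15-clade salamander
table: 15 clades, a pure-birth rate that yields ~15 lineages in 61 My,
intercept 2.33 and slope 4.76 on the climate rate (the OLS fit of the
shipped table), residual SD 0.6 on the log scale, and clade rates
centered near 0.1 per My.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import PhyloCovariance, Phylogeny

__all__ = [
    "SyntheticCladeSpec",
    "simulate_yule",
    "simulate_bm",
    "generate_clade_dataset",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_yule(n_tips: int, rate: float, seed) -> Phylogeny:
    """Simulate a crown pure-birth (Yule) tree with ``n_tips`` tips.

    Starting from the crown split (two lineages at the root), the
    waiting time while ``k`` lineages exist is Exponential(k * rate);
    at each event a uniformly chosen extant lineage splits. The final
    interval (with ``n_tips`` lineages, ending at the present) is drawn
    from the same law, so internode intervals g_k ~ Exp(k * rate)
    independently for k = 2..n — the null under which the gamma
    statistic is asymptotically standard normal.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed)
    # node bookkeeping: parent pointer, birth time; root = 0 at time 0
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = float(rng.exponential(1.0 / (2 * rate)))
    for k in range(2, n_tips):
        i = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            parent.append(i)
            birth.append(t)
            active.append(len(parent) - 1)
        t += float(rng.exponential(1.0 / ((k + 1) * rate)))
    present = t
    blen = [0.0] * len(parent)
    # branch length: child's birth (or present for tips) minus parent's birth
    is_tip = np.ones(len(parent), bool)
    for p in parent[1:]:
        is_tip[p] = False
    end_time = [present if is_tip[i] else None for i in range(len(parent))]
    # an internal node's end time is its children's birth time
    for i in range(1, len(parent)):
        if end_time[parent[i]] is None:
            end_time[parent[i]] = birth[i]
    end_time[0] = end_time[0] if end_time[0] is not None else present
    for i in range(1, len(parent)):
        blen[i] = end_time[i] - birth[i]
    labels: list[str | None] = [None] * len(parent)
    tip_no = 1
    for i in range(len(parent)):
        if is_tip[i]:
            labels[i] = f"t{tip_no}"
            tip_no += 1
    order = _preorder(parent)
    return _reindex(parent, blen, labels, order)


def _preorder(parent: Sequence[int]) -> list[int]:
    children: list[list[int]] = [[] for _ in parent]
    for i in range(1, len(parent)):
        children[parent[i]].append(i)
    order, stack = [], [0]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children[i]))
    return order


def _reindex(parent, blen, labels, order) -> Phylogeny:
    pos = {old: new for new, old in enumerate(order)}
    return Phylogeny(
        parent=[-1 if parent[i] < 0 else pos[parent[i]] for i in order],
        branch_lengths=[blen[i] for i in order],
        labels=[labels[i] for i in order],
    )


def simulate_bm(
    tree: Phylogeny | PhyloCovariance,
    sigma2: float,
    seed,
    lam: float = 1.0,
    mean: float = 0.0,
    n_traits: int = 1,
) -> pd.DataFrame:
    """Draw tip traits from N(mean, sigma2 * C_lambda) on a tree.

    Returns a tips-by-traits DataFrame indexed by tip label. With
    ``sigma2 = 0`` all tips equal the root state.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    rng = _rng(seed)
    C = tree.vcv() if isinstance(tree, Phylogeny) else tree
    V = sigma2 * C.lambda_transform(lam).matrix
    n = V.shape[0]
    if sigma2 == 0:
        X = np.full((n, n_traits), mean)
    else:
        # small jitter keeps the Cholesky stable for zero-length cherries
        L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / n * np.eye(n))
        X = mean + L @ rng.standard_normal((n, n_traits))
    cols = [f"trait_{j + 1}" for j in range(n_traits)]
    return pd.DataFrame(X, index=list(C.taxa), columns=cols)


@dataclass(frozen=True)
class SyntheticCladeSpec:
    """Parameters of the clade-table generator (defaults emulate the real data)."""

    seed: int = 0
    n_clades: int = 15
    birth_rate: float = 0.033  # events/My; ~15 clades in 61 My
    beta: tuple[float, float] = (2.33, 4.76)  # intercept, slope on the driving rate
    driver: str = "climate_rate"  # which rate generates richness
    lam: float = 1.0  # Pagel's lambda of the residuals
    noise_sd: float = 0.6  # residual SD of ln richness at the tips
    rate_log_mean: float = float(np.log(0.09))  # lognormal location of clade rates
    rate_log_sd: float = 0.8
    gamma_mean: float = -1.8  # per-clade slowdown statistic (drawn, not derived)
    gamma_sd: float = 0.7

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_clade_dataset(
    spec: SyntheticCladeSpec,
) -> tuple[pd.DataFrame, Phylogeny, dict]:
    """Generate a clade table, its backbone tree, and the generating truth.

    Draw order from the single seeded stream: (1) the Yule backbone,
    (2) climate/size/shape rates per clade, (3) crown ages, (4) the
    Brownian residuals of ln richness, (5) per-clade gamma values,
    (6) sampled-species counts. Ln richness is
    ``beta0 + beta1 * driver_rate + residual``; integer richness is
    ``round(exp(ln_richness))`` (floored at 1).
    """
    rng = _rng(spec.seed)
    tree = simulate_yule(spec.n_clades, spec.birth_rate, rng)
    n = spec.n_clades
    taxa = tree.tip_labels

    rates = {
        "climate_rate": rng.lognormal(spec.rate_log_mean, spec.rate_log_sd, n),
        "size_rate": rng.lognormal(np.log(0.02), 0.8, n),
        "shape_rate": rng.lognormal(np.log(0.0008), 0.8, n),
    }
    crown_age = rng.uniform(13.0, 37.0, n)

    C = tree.vcv()
    depth = float(np.mean(np.diag(C.matrix)))
    sigma2_resid = spec.noise_sd**2 / depth  # per-My residual rate
    resid = simulate_bm(C, sigma2_resid, rng, lam=spec.lam).iloc[:, 0]
    beta0, beta1 = spec.beta
    ln_richness = beta0 + beta1 * rates[spec.driver] + resid.loc[taxa].to_numpy()
    richness = np.maximum(np.rint(np.exp(ln_richness)), 1).astype(int)
    # regenerate ln on the attainable grid so the table is self-consistent
    ln_richness = np.log(richness)

    gamma = rng.normal(spec.gamma_mean, spec.gamma_sd, n)
    n_morph = np.clip(rng.binomial(richness, 0.55), 2, richness)
    n_climate = np.clip(rng.binomial(richness, 0.65), 2, richness)

    table = pd.DataFrame(
        {
            "clade": taxa,
            "ln_richness": ln_richness,
            "n_sampled_morph": n_morph,
            "n_sampled_climate": n_climate,
            "crown_age": crown_age,
            "climate_rate": rates["climate_rate"],
            "size_rate": rates["size_rate"],
            "shape_rate": rates["shape_rate"],
            "gamma": gamma,
        }
    ).set_index("clade")
    truth = {
        "beta": spec.beta,
        "driver": spec.driver,
        "lambda": spec.lam,
        "sigma2_resid": sigma2_resid,
        "noise_sd": spec.noise_sd,
        "residuals": resid,
    }
    return table, tree, truth
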