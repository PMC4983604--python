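"""Packaged data: the 15-clade salamander table and a stand-in backbone tree.

The clade table is the printed per-clade dataset: natural-log species
richness, numbers of species sampled for the morphological and climatic
rate estimates, crown age (My), Brownian rates of climatic-niche, body
size and body shape evolution, and the per-clade gamma (diversification
slowdown) statistic.

The backbone tree shipped here is a SYNTHETIC stand-in: its topology
follows published plethodontid relationships but its node ages are
invented (61-My root), because the original time-calibrated backbone is
not redistributable with this package. Analyses on it exercise the full
machinery without replicating published tree-dependent estimates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .phylo import Phylogeny, read_tree

__all__ = [
    "load_clade_table_path",
    "load_plethodontid_clades",
    "load_backbone_tree",
    "load_display_names",
]


def _data_path(name: str):
    return resources.files("richrates.data").joinpath(name)


def load_clade_table_path() -> str:
    return str(_data_path("plethodontid_clades.csv"))


def load_plethodontid_clades() -> pd.DataFrame:
    """The 15-clade table, indexed by clade (tip) label."""
    return pd.read_csv(load_clade_table_path()).set_index("clade")


def load_backbone_tree() -> Phylogeny:
    """The synthetic stand-in backbone phylogeny of the 15 clades."""
    return read_tree(str(_data_path("plethodontid_backbone_synthetic.nex")), format="nexus")


def load_display_names() -> pd.Series:
    """Tip label -> human-readable clade name."""
    df = pd.read_csv(_data_path("clade_display_names.csv"))
    return df.set_index("tip_label")["display_name"]
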