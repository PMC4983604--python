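"""End-to-end analysis: clade table + backbone tree -> model comparison table.

This orchestrates the full comparative analysis: load and validate the
per-clade dataset, align it to the backbone phylogeny, check the
sample-size associations, fit the full grid of PGLS models (richness vs.
evolutionary rates, rate vs. rate, and gamma vs. age-by-rate niche
filling models), rank them by AIC, and draw the diagnostic scatter
plots.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pgls import PGLS, ModelComparison, PGLSResults, compare_models
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "MODEL_GRID",
    "CladeTable",
    "load_clade_table",
    "pearson_r2",
    "sample_size_associations",
    "RichnessModelResults",
    "run_richness_models",
    "make_scatter_figures",
    "replicate",
]

REQUIRED_COLUMNS = (
    "ln_richness",
    "n_sampled_morph",
    "n_sampled_climate",
    "crown_age",
    "climate_rate",
    "size_rate",
    "shape_rate",
    "gamma",
)

#: The full model grid: 7 richness models, 2 rate-vs-rate models, 3
#: age-by-rate interaction (niche filling) models, 3 single-rate slowdown
#: models. Labels mirror the analysis write-up.
MODEL_GRID: tuple[str, ...] = (
    "ln_richness ~ size_rate",
    "ln_richness ~ shape_rate",
    "ln_richness ~ climate_rate",
    "ln_richness ~ shape_rate + size_rate",
    "ln_richness ~ climate_rate + shape_rate + size_rate",
    "ln_richness ~ climate_rate + shape_rate",
    "ln_richness ~ climate_rate + size_rate",
    "size_rate ~ climate_rate",
    "shape_rate ~ climate_rate",
    "gamma ~ crown_age:shape_rate + crown_age + shape_rate",
    "gamma ~ crown_age:size_rate + crown_age + size_rate",
    "gamma ~ crown_age:climate_rate + crown_age + climate_rate",
    "gamma ~ size_rate",
    "gamma ~ shape_rate",
    "gamma ~ climate_rate",
)


# --------------------------------------------------------------------
# the clade table
# --------------------------------------------------------------------

class CladeTable:
    """Validated per-clade dataset, aligned (or alignable) to a tree.

    Wraps a DataFrame indexed by clade label with the per-clade fields:
    ln richness, sampled-species counts, crown age, the three
    evolutionary rates, and gamma.
    """

    def __init__(self, data: pd.DataFrame, provenance: str = "unspecified"):
        self.data = data.copy()
        self.provenance = provenance
        self._validate()

    def _validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clade table missing columns: {missing}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate clade names: {dupes}")
        for col in REQUIRED_COLUMNS:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric value in column {col!r}, rows {df.index[bad].tolist()}"
                )
            if df[col].isna().any():
                raise ValueError(f"missing values in column {col!r}")
        rich = self.richness
        if (rich <= 0).any():
            raise ValueError("richness must round to a positive integer")
        for col in ("n_sampled_morph", "n_sampled_climate"):
            over = df.index[df[col] > rich].tolist()
            if over:
                raise ValueError(f"{col} exceeds richness for clades {over}")
        if (df["crown_age"] <= 0).any():
            raise ValueError("crown ages must be positive")
        if (df[["climate_rate", "size_rate", "shape_rate"]] < 0).to_numpy().any():
            raise ValueError("evolutionary rates must be nonnegative")

    @classmethod
    def from_csv(cls, source, clade_column: str = "clade", provenance: str | None = None) -> "CladeTable":
        df = pd.read_csv(source)
        if clade_column not in df.columns:
            raise ValueError(f"clade table missing key column {clade_column!r}")
        return cls(df.set_index(clade_column), provenance=provenance or str(source))

    @property
    def n_clades(self) -> int:
        return len(self.data)

    @property
    def richness(self) -> pd.Series:
        """Integer species richness recovered as round(exp(ln_richness))."""
        return np.exp(self.data["ln_richness"]).round().astype(int)

    def align_to_tree(
        self, tree: Phylogeny, mapping: pd.Series | dict | None = None
    ) -> tuple["CladeTable", Phylogeny]:
        """Match clade names to tip labels; order rows by the tree's tips.

        ``mapping`` optionally renames table rows (table name -> tip
        label) before matching. Tips without a table row are dropped
        from the tree with a warning; table rows without a tip raise.
        """
        df = self.data
        if mapping is not None:
            mapping = dict(mapping)
            df = df.rename(index=mapping)
        tips = tree.tip_labels
        unmatched = [c for c in df.index if c not in tips]
        if unmatched:
            raise ValueError(f"clades not found among tree tips: {unmatched}")
        extra = [t for t in tips if t not in df.index]
        if extra:
            logger.warning("dropping %d tree tips without clade data: %s", len(extra), extra)
            tree = tree.drop_tips(extra)
        ordered = df.loc[tree.tip_labels]
        return CladeTable(ordered, provenance=self.provenance), tree


def load_clade_table(source, clade_column: str = "clade") -> CladeTable:
    """Read a clade table from delimited text (header row required)."""
    return CladeTable.from_csv(source, clade_column=clade_column)


# --------------------------------------------------------------------
# sample-size associations
# --------------------------------------------------------------------

class CorrelationResult(NamedTuple):
    r2: float
    r: float
    p: float
    n: int


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Squared Pearson correlation (with r and its two-sided P)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r * r), float(r), float(p), len(x))


def sample_size_associations(table: CladeTable) -> pd.DataFrame:
    """The three sampling-effort checks on raw counts and integer richness.

    Rows: morphology vs. climate sample sizes; each sample size vs.
    species richness (richness recovered as round(exp(ln richness))).
    """
    df = table.data
    rich = table.richness
    rows = {
        "morph_vs_climate_counts": pearson_r2(df["n_sampled_morph"], df["n_sampled_climate"]),
        "morph_counts_vs_richness": pearson_r2(df["n_sampled_morph"], rich),
        "climate_counts_vs_richness": pearson_r2(df["n_sampled_climate"], rich),
    }
    return pd.DataFrame(rows).T.rename(columns=dict(enumerate(CorrelationResult._fields)))


# --------------------------------------------------------------------
# the model grid
# --------------------------------------------------------------------

@dataclass
class RichnessModelResults:
    """All fitted models of the grid with their AIC bookkeeping."""

    fits: dict[str, PGLSResults]
    table: pd.DataFrame

    def comparison(self, response: str) -> ModelComparison:
        """AIC comparison restricted to models sharing ``response``."""
        group = {
            lbl: f for lbl, f in self.fits.items()
            if f.model.design.response_name == response
        }
        if not group:
            raise KeyError(f"no fitted models with response {response!r}")
        return compare_models(list(group.values()), list(group))

    def to_json(self) -> str:
        return json.dumps({lbl: f.to_dict() for lbl, f in self.fits.items()}, indent=2)


def run_richness_models(
    table: CladeTable,
    tree: Phylogeny,
    models: Iterable[str] = MODEL_GRID,
    lam: float | str = "ml",
    count_lambda_in_k: bool = True,
    mapping: pd.Series | dict | None = None,
) -> RichnessModelResults:
    """Fit the PGLS model grid on a clade table aligned to a tree.

    Each model is refit with its own ML lambda (or the fixed value
    given); within each response group the AIC difference to the best
    model is reported, with differences of >= 4 flagged as substantial.
    """
    aligned, tree = table.align_to_tree(tree, mapping=mapping)
    logger.info("aligned %d clades to tree", aligned.n_clades)
    C = tree.vcv()
    fits: dict[str, PGLSResults] = {}
    for formula in models:
        fit = PGLS.from_formula(formula, aligned.data, C).fit(
            lam=lam, count_lambda_in_k=count_lambda_in_k
        )
        fits[formula] = fit
        logger.info(
            "fit %-55s lambda=%.4f%s r2=%.4f AIC=%.4f",
            formula, fit.lambda_,
            "*" if fit.lambda_flags else "", fit.rsquared, fit.aic,
        )
    rows = []
    for lbl, f in fits.items():
        rows.append(
            {
                "model": lbl,
                "response": f.model.design.response_name,
                "r2": f.rsquared,
                "P": f.f_pvalue,
                "AIC": f.aic,
                "lambda": f.lambda_,
                "lambda_flags": ",".join(sorted(f.lambda_flags)),
            }
        )
    out = pd.DataFrame(rows).set_index("model")
    out["dAIC"] = out.groupby("response")["AIC"].transform(lambda a: a - a.min())
    out["substantially_worse"] = out["dAIC"] >= 4.0
    return RichnessModelResults(fits=fits, table=out)


# --------------------------------------------------------------------
# figures
# --------------------------------------------------------------------

AXIS_LABELS = {
    "ln_richness": "ln(species richness)",
    "climate_rate": "climatic-niche rate, $\\sigma^2$ (PC units$^2$/My)",
    "size_rate": "body-size rate, $\\sigma^2$ (PC1 units$^2$/My)",
    "shape_rate": "body-shape rate, $\\sigma^2$ (PC2-7 units$^2$/My)",
    "gamma": "gamma (diversification slowdown)",
    "crown_age": "crown age (My)",
}


def make_scatter_figures(
    table: CladeTable,
    pairs: Sequence[tuple[str, str]],
    outdir,
    fmt: str = "png",
) -> list[Path]:
    """One scatter per (predictor, response) pair with an OLS guide line.

    The line is ordinary least squares, drawn for orientation only; the
    inferential results come from the PGLS fits.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for xcol, ycol in pairs:
        if xcol not in table.data.columns or ycol not in table.data.columns:
            raise KeyError(f"unknown columns for figure: {(xcol, ycol)}")
        x = table.data[xcol].to_numpy(float)
        y = table.data[ycol].to_numpy(float)
        fig, ax = plt.subplots(figsize=(4.2, 3.4))
        ax.scatter(x, y, s=32, color="#2a6f97", zorder=3)
        slope, intercept = np.polyfit(x, y, 1)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, intercept + slope * grid, lw=1, color="0.4",
                label="OLS guide line")
        ax.set_xlabel(AXIS_LABELS.get(xcol, xcol))
        ax.set_ylabel(AXIS_LABELS.get(ycol, ycol))
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = outdir / f"{ycol}_vs_{xcol}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths


DEFAULT_FIGURE_PAIRS = (
    ("size_rate", "ln_richness"),
    ("shape_rate", "ln_richness"),
    ("climate_rate", "ln_richness"),
    ("size_rate", "gamma"),
    ("shape_rate", "gamma"),
    ("climate_rate", "gamma"),
)


def replicate(
    outdir,
    table: CladeTable | None = None,
    tree: Phylogeny | None = None,
    lam: float | str = "ml",
    count_lambda_in_k: bool = True,
    figures: bool = True,
) -> RichnessModelResults:
    """Run the packaged analysis end to end and write result artifacts.

    Writes ``models.csv`` (the grid with r2, P, AIC, dAIC, lambda),
    ``fits.json`` (per-model coefficients), ``sample_size_checks.csv``
    and the six diagnostic scatter plots to ``outdir``.
    """
    from . import datasets

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = CladeTable(datasets.load_plethodontid_clades(), provenance="packaged")
    if tree is None:
        tree = datasets.load_backbone_tree()
    logger.info("loaded %d clades (%s)", table.n_clades, table.provenance)
    checks = sample_size_associations(table)
    checks.to_csv(outdir / "sample_size_checks.csv")
    results = run_richness_models(
        table, tree, lam=lam, count_lambda_in_k=count_lambda_in_k
    )
    results.table.to_csv(outdir / "models.csv")
    (outdir / "fits.json").write_text(results.to_json())
    if figures:
        make_scatter_figures(table, DEFAULT_FIGURE_PAIRS, outdir / "figures")
    return results
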