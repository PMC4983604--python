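"""Phylogenetic generalized least squares with ML estimation of Pagel's lambda.

The model is ``y = X b + e`` with ``e ~ N(0, s^2 * C_lambda)`` where
``C_lambda`` is the Brownian-motion tip covariance with off-diagonal
entries scaled by lambda in [0, 1]. For a fixed lambda the GLS
estimates are closed-form,

    b_hat  = (X' C^-1 X)^-1 X' C^-1 y
    s2_hat = e' C^-1 e / n                       (ML)
    logL   = -(n/2) log 2 pi - (n/2) log s2_hat - (1/2) log|C| - n/2,

and lambda itself is estimated by maximizing this profile likelihood
with a bounded scalar search (multistarted Brent). The coefficient of
determination uses the GLS-weighted mean,

    r^2 = 1 - RSS_gls / TSS_gls,
    TSS_gls = (y - mu_gls 1)' C^-1 (y - mu_gls 1),

and the whole-model P value is the GLS F test with (p - 1, n - p)
degrees of freedom. AIC = -2 logL + 2k, where k counts the regression
coefficients, the residual variance, and (by default) lambda when it
was estimated rather than fixed.

Usage follows the statsmodels pattern::

    model = PGLS.from_formula("ln_richness ~ climate_rate", data, cov)
    res = model.fit()            # ML lambda
    res = model.fit(lam=0.0)     # fixed lambda -> ordinary least squares
    print(res.summary())
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .phylo import PhyloCovariance, Phylogeny

__all__ = [
    "DesignMatrix",
    "PGLS",
    "PGLSResults",
    "ModelComparison",
    "build_design",
    "parse_formula",
    "compare_models",
    "SUBSTANTIAL_DELTA_AIC",
]

#: AIC difference treated as substantially better fit (Burnham–Anderson style
#: rule of thumb used throughout the richness analysis; boundary inclusive).
SUBSTANTIAL_DELTA_AIC = 4.0


# --------------------------------------------------------------------
# design matrices and formulas
# --------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """Response vector and predictor matrix aligned to a taxon order."""

    y: np.ndarray
    X: np.ndarray  # first column all ones
    term_names: tuple[str, ...]  # includes "Intercept"
    response_name: str
    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("y and X must have matching row counts")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient; dependent columns among {self.term_names}"
            )


def build_design(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
) -> DesignMatrix:
    """Assemble y and X from named columns of a clade table.

    Interaction columns are elementwise products of two distinct main
    effects; the main effects are always included alongside their
    interaction. Row index labels become the taxon order.
    """
    cols = [response, *terms, *(c for pair in interactions for c in pair)]
    missing = [c for c in dict.fromkeys(cols) if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    terms = list(dict.fromkeys(terms))
    for a, b in interactions:
        if a == b:
            raise ValueError(f"interaction of {a!r} with itself is degenerate")
        for c in (a, b):
            if c not in terms:
                terms.append(c)
    sub = data[[response, *terms]]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns: {bad}")
    y = sub[response].to_numpy(dtype=float)
    columns = [np.ones(len(sub))]
    names = ["Intercept"]
    for t in terms:
        columns.append(sub[t].to_numpy(dtype=float))
        names.append(t)
    for a, b in interactions:
        columns.append(sub[a].to_numpy(dtype=float) * sub[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    X = np.column_stack(columns)
    return DesignMatrix(
        y=y,
        X=X,
        term_names=tuple(names),
        response_name=response,
        taxa=tuple(map(str, sub.index)),
    )


def parse_formula(formula: str) -> tuple[str, list[str], list[tuple[str, str]]]:
    """Parse ``"y ~ a + b + a:b"`` into (response, terms, interactions).

    ``a*b`` expands to ``a + b + a:b``; ``a:b`` likewise pulls in both
    main effects (full-factorial convention). ``y ~ 1`` is the
    intercept-only model.
    """
    if formula.count("~") != 1:
        raise ValueError(f"formula must contain exactly one '~': {formula!r}")
    lhs, rhs = (s.strip() for s in formula.split("~"))
    if not lhs:
        raise ValueError("formula has no response")
    terms: list[str] = []
    interactions: list[tuple[str, str]] = []
    for raw in rhs.split("+"):
        tok = raw.strip()
        if tok in {"", "1"}:
            continue
        m = re.fullmatch(r"(\w+)\s*[:*]\s*(\w+)", tok)
        if m:
            interactions.append((m.group(1), m.group(2)))
        elif re.fullmatch(r"\w+", tok):
            terms.append(tok)
        else:
            raise ValueError(f"cannot parse formula term: {tok!r}")
    return lhs, terms, interactions


# --------------------------------------------------------------------
# the model
# --------------------------------------------------------------------

class PGLS:
    """Generalized least squares under a phylogenetic covariance.

    Parameters
    ----------
    design
        Response and predictors aligned to a taxon order.
    cov
        Phylogenetic covariance (or a tree, whose Brownian covariance is
        taken). Its taxa are reordered to match the design.
    """

    def __init__(self, design: DesignMatrix, cov: PhyloCovariance | Phylogeny | np.ndarray):
        if isinstance(cov, Phylogeny):
            cov = cov.vcv()
        if isinstance(cov, PhyloCovariance):
            cov = cov.reorder(design.taxa)
            V = cov.matrix
        else:
            V = np.asarray(cov, dtype=float)
        n, p = design.X.shape
        if V.shape != (n, n):
            raise ValueError(f"covariance is {V.shape} but design has {n} rows")
        if n <= p:
            raise ValueError(f"insufficient data: n={n} <= parameters p={p}")
        self.design = design
        self.C = V
        self.nobs = n
        self.k_exog = p

    # -- constructors -------------------------------------------------

    @classmethod
    def from_formula(
        cls,
        formula: str,
        data: pd.DataFrame,
        cov: PhyloCovariance | Phylogeny | np.ndarray,
    ) -> "PGLS":
        response, terms, inter = parse_formula(formula)
        return cls(build_design(data, response, terms, inter), cov)

    @classmethod
    def from_arrays(
        cls,
        y: np.ndarray,
        X: np.ndarray,
        cov,
        term_names: Sequence[str] | None = None,
        taxa: Sequence[str] | None = None,
        response_name: str = "y",
    ) -> "PGLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        names = tuple(term_names) if term_names else (
            ("Intercept",) + tuple(f"x{i}" for i in range(1, X.shape[1]))
        )
        taxa = tuple(taxa) if taxa is not None else tuple(f"t{i}" for i in range(len(y)))
        return cls(DesignMatrix(y, X, names, response_name, taxa), cov)

    # -- likelihood ---------------------------------------------------

    def _V(self, lam: float) -> np.ndarray:
        V = self.C * lam
        np.fill_diagonal(V, np.diag(self.C))
        return V

    def _profile(self, lam: float) -> dict:
        """GLS fit at fixed lambda; everything needed downstream."""
        y, X = self.design.y, self.design.X
        n, p = X.shape
        V = self._V(lam)
        try:
            cf = cho_factor(V)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"lambda-transformed covariance singular at lambda={lam}"
            ) from exc
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        ViX = cho_solve(cf, X)
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, ViX.T @ y)
        resid = y - X @ beta
        rss = float(resid @ cho_solve(cf, resid))
        # GLS-weighted mean of y for the total sum of squares
        Vi1 = cho_solve(cf, np.ones(n))
        mu = float(Vi1 @ y) / float(Vi1.sum())
        dev = y - mu
        tss = float(dev @ cho_solve(cf, dev))
        sigma2_ml = rss / n
        with np.errstate(divide="ignore"):  # exact fits have rss = 0
            llf = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2_ml) + logdet + n)
        return {
            "lam": lam,
            "beta": beta,
            "resid": resid,
            "rss": rss,
            "tss": tss,
            "sigma2_ml": sigma2_ml,
            "llf": llf,
            "XtViX": XtViX,
            "logdet": logdet,
        }

    def loglike(self, lam: float) -> float:
        """Profile log-likelihood of lambda (beta and s^2 maximized out)."""
        return self._profile(lam)["llf"]

    def _optimize_lambda(
        self,
        bounds: tuple[float, float],
        multistart: Sequence[float],
        xtol: float,
    ) -> tuple[float, set[str]]:
        lo, hi = bounds
        flags: set[str] = set()
        offdiag = self.C - np.diag(np.diag(self.C))
        scale = np.abs(np.diag(self.C)).max()
        if np.abs(offdiag).max() <= 1e-12 * max(scale, 1.0):
            # star phylogeny: lambda has no effect on the likelihood
            return lo, {"uninformative"}
        best_x, best_f = None, np.inf
        starts = sorted({min(max(s, lo), hi) for s in multistart})
        windows = [lo, *starts, hi]
        for i in range(1, len(windows) - 1):
            a, b = windows[i - 1], windows[i + 1]
            res = optimize.minimize_scalar(
                lambda l: -self.loglike(l),
                bounds=(a, b),
                method="bounded",
                options={"xatol": xtol},
            )
            if res.fun < best_f:
                best_x, best_f = float(res.x), float(res.fun)
        # compare against the boundaries themselves (Brent never lands there)
        for edge in (lo, hi):
            f = -self.loglike(edge)
            if f < best_f - 1e-12:
                best_x, best_f = edge, f
        if best_x <= lo + 10 * xtol or best_x >= hi - 10 * xtol:
            best_x = lo if best_x <= lo + 10 * xtol else hi
            flags.add("boundary")
        return best_x, flags

    # -- fitting ------------------------------------------------------

    def fit(
        self,
        lam: float | str = "ml",
        bounds: tuple[float, float] = (1e-7, 1.0),
        multistart: Sequence[float] = (0.1, 0.5, 0.9),
        xtol: float = 1e-8,
        count_lambda_in_k: bool = True,
    ) -> "PGLSResults":
        """Fit the model, estimating lambda by ML unless a value is given.

        ``count_lambda_in_k`` controls whether an ML-estimated lambda is
        counted as a free parameter in AIC's k (default: yes).
        """
        if isinstance(lam, str):
            if lam.lower() != "ml":
                raise ValueError(f"lam must be a number or 'ml', got {lam!r}")
            lam_hat, flags = self._optimize_lambda(bounds, multistart, xtol)
            estimated = True
        else:
            lam_hat = float(lam)
            if not (0.0 <= lam_hat <= max(1.0, bounds[1])):
                raise ValueError(f"lambda={lam_hat} outside [0, {max(1.0, bounds[1])}]")
            flags = set()
            estimated = False
        prof = self._profile(lam_hat)
        k = self.k_exog + 1 + (1 if (estimated and count_lambda_in_k) else 0)
        return PGLSResults(self, prof, lam_hat, estimated, flags, k)


class PGLSResults:
    """Fitted PGLS model: coefficients, fit statistics, lambda, AIC."""

    def __init__(self, model: PGLS, prof: dict, lam: float, lam_estimated: bool,
                 lam_flags: set[str], k_params: int):
        self.model = model
        self.nobs = model.nobs
        self.df_model = model.k_exog - 1
        self.df_resid = model.nobs - model.k_exog
        self.lambda_ = lam
        self.lambda_estimated = lam_estimated
        self.lambda_flags = frozenset(lam_flags)
        self.k_params = k_params
        names = list(model.design.term_names)
        self.params = pd.Series(prof["beta"], index=names, name="coef")
        self.llf = float(prof["llf"])
        self.aic = -2.0 * self.llf + 2.0 * k_params
        self.scale = prof["rss"] / self.df_resid  # unbiased residual variance
        self.sigma2_ml = prof["sigma2_ml"]
        self.resid = prof["resid"]
        cov_params = self.scale * np.linalg.inv(prof["XtViX"])
        self.cov_params = pd.DataFrame(cov_params, index=names, columns=names)
        self.bse = pd.Series(np.sqrt(np.diag(cov_params)), index=names, name="se")
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid), index=names, name="P>|t|"
        )
        rss, tss = prof["rss"], prof["tss"]
        self.rsquared = 1.0 - rss / tss if tss > 0 else np.nan
        if self.df_model > 0 and rss > 0:
            self.fvalue = ((tss - rss) / self.df_model) / (rss / self.df_resid)
            self.f_pvalue = float(stats.f.sf(self.fvalue, self.df_model, self.df_resid))
        elif self.df_model > 0:
            self.fvalue, self.f_pvalue = np.inf, 0.0  # exact fit
        else:
            self.fvalue, self.f_pvalue = np.nan, np.nan  # intercept-only

    @property
    def formula(self) -> str:
        terms = [t for t in self.model.design.term_names if t != "Intercept"]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.model.design.response_name} ~ {rhs}"

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def to_dict(self) -> dict:
        return {
            "model": self.formula,
            "n": int(self.nobs),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "lambda": float(self.lambda_),
            "lambda_estimated": self.lambda_estimated,
            "lambda_flags": sorted(self.lambda_flags),
            "r2": float(self.rsquared),
            "F": float(self.fvalue),
            "P": float(self.f_pvalue),
            "logLik": self.llf,
            "AIC": self.aic,
            "k": self.k_params,
        }

    def summary(self) -> str:
        lam_note = "ML" if self.lambda_estimated else "fixed"
        if self.lambda_flags:
            lam_note += " (" + ", ".join(sorted(self.lambda_flags)) + ")"
        lines = [
            "Phylogenetic GLS regression",
            "=" * 64,
            f"Model:    {self.formula}",
            f"n obs:    {self.nobs:<8d}  lambda: {self.lambda_:.6f} [{lam_note}]",
            f"r2:       {self.rsquared:<8.4f}  F({self.df_model},{self.df_resid}): "
            f"{self.fvalue:.4f}  P: {self.f_pvalue:.4g}",
            f"logLik:   {self.llf:<10.4f} AIC: {self.aic:.4f} (k={self.k_params})",
            "-" * 64,
            f"{'term':<24}{'coef':>10}{'se':>10}{'t':>8}{'P>|t|':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<24}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>10.4g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


# --------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------

class ModelComparison:
    """AIC ranking of PGLS fits sharing one response and taxon set."""

    def __init__(self, fits: Sequence[PGLSResults], labels: Sequence[str] | None = None):
        fits = list(fits)
        if not fits:
            raise ValueError("no fits to compare")
        responses = {f.model.design.response_name for f in fits}
        if len(responses) > 1:
            raise ValueError(f"fits have mixed responses: {sorted(responses)}")
        taxa = {f.model.design.taxa for f in fits}
        if len(taxa) > 1:
            raise ValueError("fits were estimated on different taxon sets")
        labels = list(labels) if labels is not None else [f.formula for f in fits]
        if len(labels) != len(fits):
            raise ValueError("labels and fits differ in length")
        self.fits = dict(zip(labels, fits))
        aic = np.array([f.aic for f in fits])
        delta = aic - aic.min()
        self.table = pd.DataFrame(
            {
                "model": labels,
                "r2": [f.rsquared for f in fits],
                "P": [f.f_pvalue for f in fits],
                "AIC": aic,
                "dAIC": delta,
                "lambda": [f.lambda_ for f in fits],
                "substantially_worse": delta >= SUBSTANTIAL_DELTA_AIC,
            }
        ).set_index("model")

    @property
    def best(self) -> str:
        return str(self.table["AIC"].idxmin())

    def delta(self, a: str, b: str) -> float:
        """AIC(a) - AIC(b)."""
        return float(self.table.loc[a, "AIC"] - self.table.loc[b, "AIC"])

    def substantially_better(self, a: str, b: str) -> bool:
        """True iff model ``a`` beats ``b`` by at least 4 AIC units."""
        return self.delta(a, b) <= -SUBSTANTIAL_DELTA_AIC

    def __repr__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def compare_models(
    fits: Sequence[PGLSResults], labels: Sequence[str] | None = None
) -> ModelComparison:
    """Rank fitted models by AIC; flag differences of 4 or more as substantial."""
    return ModelComparison(fits, labels)
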