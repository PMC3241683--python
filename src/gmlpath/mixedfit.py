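"""Structural-equation fitting: mixed models with nested random intercepts.

Every equation of a multi-level path model — and every d-separation test —
is a linear or binomial-logit mixed model.  Gaussian equations are fitted
by REML, binomial ones by a Laplace approximation to the marginal
likelihood.  Denominator degrees of freedom follow the containment
(inner–outer) rule used by the classic nlme software: a term that is
constant within the groups of a nesting level is tested against the number
of groups at that level, so nest-level covariates get nest-level df while
observation-level covariates get residual df.

Variables entering a path analysis are standardized to mean 0, SD 1 first,
so coefficients are standardized partial regression coefficients.  Squared
terms square the standardized column and are not re-standardized.
Two-way interactions are entered as Lance-residualized cross products:
the product of two standardized variables is regressed on both main
effects and the OLS residuals, rescaled to SD 1, form the interaction
column — exactly orthogonal to both main effects by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glmm import (
    RandomDesign,
    SeparationError,
    fit_binomial,
    fit_gaussian,
)

__all__ = [
    "LinearTerm", "QuadraticTerm", "CategoricalTerm", "InteractionTerm",
    "ModelSpec", "CoefficientEstimate", "RandomEffectSD", "FitResult",
    "StandardizationParams", "ZeroVarianceError", "SeparationError",
    "standardize", "residualized_interaction", "fit_mixed",
    "collinearity_check", "variance_explained", "random_effect_ci",
]


class ZeroVarianceError(ValueError):
    """A column required to vary is constant."""


# ---------------------------------------------------------------------------
# fixed-effect terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearTerm:
    name: str

    def labels(self):
        return [self.name]


@dataclass(frozen=True)
class QuadraticTerm:
    """Linear plus squared term, entered together."""

    name: str

    def labels(self):
        return [self.name, f"{self.name}^2"]


@dataclass(frozen=True)
class CategoricalTerm:
    """Dummy coding with a named reference level (default: smallest level)."""

    name: str
    reference: str | None = None

    def labels(self):  # resolved against data at build time
        return [self.name]


@dataclass(frozen=True)
class InteractionTerm:
    """Lance-residualized two-way interaction between standardized columns."""

    a: str
    b: str

    @property
    def label(self):
        return f"{self.a}:{self.b}"

    def labels(self):
        return [self.label]


def as_term(t):
    if isinstance(t, str):
        return LinearTerm(t)
    return t


@dataclass
class ModelSpec:
    """One structural (or d-separation) equation."""

    response: str
    fixed_terms: list = field(default_factory=list)
    family: str = "gaussian"  # or "binomial-logit"
    random_nesting: tuple[str, ...] = ()

    def __post_init__(self):
        self.fixed_terms = [as_term(t) for t in self.fixed_terms]
        self.random_nesting = tuple(self.random_nesting)
        if len(set(self.random_nesting)) != len(self.random_nesting):
            raise ValueError("random_nesting has repeated levels")
        names = [t.name if hasattr(t, "name") else t.label for t in self.fixed_terms]
        if self.response in names:
            raise ValueError("response may not appear among fixed terms")
        if self.family not in ("gaussian", "binomial-logit"):
            raise ValueError(f"unknown family {self.family!r}")

    def data_columns(self):
        cols = {self.response}
        for t in self.fixed_terms:
            if isinstance(t, InteractionTerm):
                cols.update((t.a, t.b))
            else:
                cols.add(t.name)
        cols.update(self.random_nesting)
        return cols


@dataclass
class CoefficientEstimate:
    term: str
    beta: float
    se: float
    df: float
    stat: float
    p: float


@dataclass
class RandomEffectSD:
    level: str
    sd: float
    ci_low: float
    ci_high: float
    boundary: bool = False

    def supported(self, tol: float) -> bool:
        return (not self.boundary) and self.ci_low > tol


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: list[CoefficientEstimate]
    random_sd: list[RandomEffectSD]
    sigma_resid: float | None
    loglik: float
    fitted: np.ndarray             # response scale
    fitted_marginal: np.ndarray    # fixed effects only, response scale
    linear_predictor: np.ndarray
    cov_fixed: np.ndarray
    converged: bool
    n_obs: int
    n_dropped: int
    reml: bool

    def coefficient(self, term: str) -> CoefficientEstimate:
        for c in self.coefficients:
            if c.term == term:
                return c
        raise KeyError(f"no coefficient for term {term!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": c.term, "beta": c.beta, "se": c.se, "df": c.df,
                 "stat": c.stat, "p": c.p}
                for c in self.coefficients
            ]
        )


# ---------------------------------------------------------------------------
# standardization and residualized interactions
# ---------------------------------------------------------------------------


@dataclass
class StandardizationParams:
    """Per-variable mean and sample SD used for z-scoring."""

    params: dict[str, tuple[float, float]]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name, (mean, sd) in self.params.items():
            if name in out:
                out[name] = (out[name] - mean) / sd
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name, (mean, sd) in self.params.items():
            if name in out:
                out[name] = out[name] * sd + mean
        return out


def standardize(table: pd.DataFrame, variables) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score the listed columns (sample SD); other columns untouched."""
    out = table.copy()
    params = {}
    for name in variables:
        col = pd.to_numeric(out[name], errors="raise").astype(float)
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise ZeroVarianceError(f"column {name!r} has zero variance")
        out[name] = (col - mean) / sd
        params[name] = (mean, sd)
    return out, StandardizationParams(params)


def residualized_interaction(table: pd.DataFrame, a: str, b: str) -> pd.Series:
    """Standardized residuals of a*b regressed on a and b (with intercept).

    The returned column has sample correlation zero with both main effects
    and SD 1; it carries the interaction information free of overlap with
    the main effects.
    """
    va = np.asarray(table[a], float)
    vb = np.asarray(table[b], float)
    prod = va * vb
    design = np.column_stack([np.ones_like(va), va, vb])
    coef, *_ = np.linalg.lstsq(design, prod, rcond=None)
    resid = prod - design @ coef
    sd = float(np.std(resid, ddof=1))
    if sd < 1e-12:
        raise ZeroVarianceError(f"product {a}*{b} is collinear with its main effects")
    return pd.Series(resid / sd, index=table.index, name=f"{a}:{b}")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(spec: ModelSpec, table: pd.DataFrame):
    """Design matrix, labels, and response from a prepared table.

    Rows with missing values in any model column are dropped (count
    reported).  Categorical terms expand to dummies against their
    reference level; interaction terms are residualized on the retained
    rows.
    """
    cols = spec.data_columns()
    missing = cols - set(table.columns)
    if missing:
        raise KeyError(f"table lacks required columns: {sorted(missing)}")
    sub = table[sorted(cols)].copy()
    keep = ~sub.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    sub = table.loc[keep]

    pieces = [np.ones(len(sub))]
    labels = ["(Intercept)"]
    for term in spec.fixed_terms:
        if isinstance(term, LinearTerm):
            pieces.append(np.asarray(sub[term.name], float))
            labels.append(term.name)
        elif isinstance(term, QuadraticTerm):
            v = np.asarray(sub[term.name], float)
            pieces.extend([v, v * v])
            labels.extend([term.name, f"{term.name}^2"])
        elif isinstance(term, CategoricalTerm):
            levels = sorted(pd.unique(sub[term.name].astype(str)))
            ref = str(term.reference) if term.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} absent from {term.name!r}"
                )
            for lev in levels:
                if lev == ref:
                    continue
                pieces.append((sub[term.name].astype(str) == lev).astype(float).to_numpy())
                labels.append(f"{term.name}[{lev}]")
        elif isinstance(term, InteractionTerm):
            pieces.append(np.asarray(residualized_interaction(sub, term.a, term.b), float))
            labels.append(term.label)
        else:
            raise TypeError(f"unknown term type {type(term)!r}")
    x = np.column_stack(pieces)
    y = np.asarray(sub[spec.response], float)
    groups = []
    comp = None
    for col in spec.random_nesting:
        codes, uniques = pd.factorize(sub[col], sort=True)
        comp = codes if comp is None else comp * len(uniques) + codes
        groups.append(comp)
    x, y, groups, idx = _collapse_replicated(x, y, groups, sub.index.to_numpy())
    return x, y, labels, groups, idx, n_dropped


def _collapse_replicated(x, y, groups, index):
    """Deduplicate rows when the whole model lives at a grouping level.

    If the response and every design column are constant within the groups
    of some nesting level, the inner replicate rows carry no information
    and make the REML profile degenerate (the within-group variance is
    exactly zero, pushing the variance ratio to infinity and shrinking the
    standard errors).  Collapse to one row per group at the outermost such
    level; that level's intercept becomes the residual and deeper levels
    are dropped.
    """
    all_cols = np.column_stack([x, y])
    for k, g in enumerate(groups):
        codes, inv = np.unique(g, return_inverse=True)
        const = True
        order = np.argsort(inv, kind="stable")
        sorted_cols = all_cols[order]
        boundaries = np.flatnonzero(np.diff(inv[order])) + 1
        blocks = np.split(np.arange(len(inv)), boundaries)
        for block in blocks:
            rows = sorted_cols[block]
            if not np.all(rows == rows[0]):
                const = False
                break
        if const:
            first = order[np.r_[0, boundaries]]
            keep = np.sort(first)
            return x[keep], y[keep], [g[keep] for g in groups[:k]], index[keep]
    return x, y, groups, index


def containment_df(x, labels, groups, n):
    """nlme-style containment denominator df per design column.

    Each column is assigned to the outermost nesting level within whose
    groups it is constant (observation level if it varies within the
    innermost groups); df at a level is the number of groups there minus
    the groups one level out minus the number of columns assigned there.
    The intercept is accounted for at the population level (the "1"
    outside all groupings) and reported with the observation-level df, as
    in nlme; with no random levels this reduces to the OLS residual df.
    """
    n_levels = len(groups)
    m = [1] + [len(np.unique(g)) for g in groups] + [n]

    # constant-within-group check for all columns at once, per level
    const_at = np.zeros((n_levels, x.shape[1]), dtype=bool)
    xr = np.round(x, 12)
    for lvl in range(n_levels):
        _, inv = np.unique(groups[lvl], return_inverse=True)
        order = np.argsort(inv, kind="stable")
        sorted_x = xr[order]
        same_group = np.diff(inv[order]) == 0
        within_change = (np.diff(sorted_x, axis=0) != 0) & same_group[:, None]
        const_at[lvl] = ~within_change.any(axis=0)

    assigned = []
    for j, lab in enumerate(labels):
        if lab == "(Intercept)":
            assigned.append(0)  # population level; reported at obs level
            continue
        lvl = n_levels + 1
        for k in range(n_levels):
            if const_at[k, j]:
                lvl = k + 1
                break
        assigned.append(lvl)
    p_at = {lvl: assigned.count(lvl) for lvl in set(assigned) if lvl > 0}
    dfs = []
    for lvl in assigned:
        report_lvl = n_levels + 1 if lvl == 0 else lvl
        df = m[report_lvl] - m[report_lvl - 1] - p_at.get(report_lvl, 0)
        dfs.append(max(df, 1))
    return dfs


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_mixed(
    spec: ModelSpec, table: pd.DataFrame, reml: bool = True, sd_ci: bool = True
) -> FitResult:
    """Fit one structural or d-separation equation.

    Gaussian responses by REML (ML when ``reml=False``, as needed for
    likelihood-ratio comparisons); binomial-logit responses by Laplace
    maximum likelihood.  Two-sided p-values use t statistics with
    containment df.
    """
    x, y, labels, groups, index, n_dropped = build_design(spec, table)
    n = len(y)
    for g in groups:
        if len(np.unique(g)) < 2:
            warnings.warn(
                f"random level with a single group in {spec.response!r} model; "
                "its variance is not identifiable", stacklevel=2
            )
    design = RandomDesign.from_labels(groups, n=n)
    dfs = containment_df(x, labels, groups, n)

    if spec.family == "gaussian":
        core = fit_gaussian(x, y, design, reml=reml, sd_ci=sd_ci)
        sigma_resid = core.sigma_resid
        fitted = core.fitted_conditional
        fitted_marg = core.fitted_marginal
        linpred = core.fitted_conditional
    else:
        core = fit_binomial(x, y, design)
        sigma_resid = None
        fitted = core.fitted_conditional
        fitted_marg = core.fitted_marginal
        linpred = core.linear_predictor

    se = np.sqrt(np.maximum(np.diag(core.cov_beta), 0.0))
    coeffs = []
    for j, lab in enumerate(labels):
        sej = se[j]
        tstat = core.beta[j] / sej if sej > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(tstat), dfs[j]) if np.isfinite(tstat) else np.nan
        coeffs.append(
            CoefficientEstimate(term=lab, beta=float(core.beta[j]), se=float(sej),
                                df=float(dfs[j]), stat=float(tstat), p=float(p))
        )

    random_sd = []
    # inner levels may have been collapsed away as degenerate replicates
    for lvl_idx, lvl_name in enumerate(spec.random_nesting[: design.n_levels]):
        sd = float(core.sigma_levels[lvl_idx])
        se_log = float(core.sigma_se_log[lvl_idx])
        boundary = bool(core.boundary[lvl_idx])
        if boundary or not np.isfinite(se_log):
            lo, hi = 0.0, np.inf if not np.isfinite(se_log) else sd
            if boundary:
                lo, hi = 0.0, sd
                warnings.warn(
                    f"random-effect SD for {lvl_name!r} at boundary (≈0)",
                    stacklevel=2,
                )
        else:
            lo = sd * np.exp(-1.959963984540054 * se_log)
            hi = sd * np.exp(1.959963984540054 * se_log)
        random_sd.append(RandomEffectSD(lvl_name, sd, lo, hi, boundary))

    if not core.converged:
        warnings.warn(f"model for {spec.response!r} did not converge", stacklevel=2)

    return FitResult(
        spec=spec, coefficients=coeffs, random_sd=random_sd,
        sigma_resid=sigma_resid, loglik=core.loglik,
        fitted=np.asarray(fitted), fitted_marginal=np.asarray(fitted_marg),
        linear_predictor=np.asarray(linpred), cov_fixed=core.cov_beta,
        converged=core.converged, n_obs=n, n_dropped=n_dropped, reml=reml,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    singular: bool = False

    @property
    def ok(self):
        return not self.flagged and not self.singular


def collinearity_check(fit: FitResult, threshold: float = 0.7) -> CollinearityReport:
    """Pairwise correlations of coefficient estimates from the fixed-effects
    variance-covariance matrix; pairs with |r| >= threshold are flagged."""
    labels = [c.term for c in fit.coefficients]
    keep = [i for i, lab in enumerate(labels) if lab != "(Intercept)"]
    cov = fit.cov_fixed[np.ix_(keep, keep)]
    names = [labels[i] for i in keep]
    d = np.sqrt(np.diag(cov))
    singular = bool(np.any(d <= 1e-12) or not np.all(np.isfinite(d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(d, d)
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if not np.isfinite(r) or abs(r) >= threshold:
                flagged.append((names[i], names[j], float(r)))
    frame = pd.DataFrame(corr, index=names, columns=names)
    return CollinearityReport(frame, flagged, singular)


def variance_explained(spec: ModelSpec, table: pd.DataFrame) -> float:
    """Approximate proportion of variation accounted for by the fixed effects.

    Gaussian: squared correlation of observed and fitted values from the
    fixed-effects-only refit.  Binomial: R² of the ordinary regression of
    the fixed-effects-only model's logit on the observed 0/1 response.
    """
    bare = ModelSpec(
        response=spec.response, fixed_terms=list(spec.fixed_terms),
        family=spec.family, random_nesting=(),
    )
    x, y, labels, groups, index, _ = build_design(bare, table)
    if spec.family == "gaussian":
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ coef
        if np.std(fitted) < 1e-12 or np.std(y) < 1e-12:
            warnings.warn("zero-variance fitted values; R^2 set to 0", stacklevel=2)
            return 0.0
        r = np.corrcoef(y, fitted)[0, 1]
        return float(r * r)
    core = fit_binomial(x, y, RandomDesign.from_labels([], n=len(y)))
    logit = x @ core.beta
    if np.std(logit) < 1e-12 or np.std(y) < 1e-12:
        warnings.warn("zero-variance fitted values; R^2 set to 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(y, logit)[0, 1]
    return float(r * r)


def random_effect_ci(fit: FitResult, tol_ratio: float = 0.01):
    """95% intervals for random-intercept SDs with a support call.

    Intervals are Wald intervals on the log-SD scale.  A level is called
    "supported" when its lower bound clears a small tolerance (default 1%
    of the residual SD for gaussian fits, 0.01 absolute for binomial) and
    the estimate is not at the zero boundary.
    """
    base = fit.sigma_resid if fit.sigma_resid is not None else 1.0
    tol = tol_ratio * base
    return [
        {
            "level": r.level,
            "sd": r.sd,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "boundary": r.boundary,
            "supported": r.supported(tol),
        }
        for r in fit.random_sd
    ]
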