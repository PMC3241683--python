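"""d-separation tests and the Fisher's C model-fit statistic.

Each basis-set claim ``x ⟂ y | Z`` becomes a mixed-model regression of the
claim's response (the later of the pair in causal order) on the other
member plus the conditioning set, with the response's own random-intercept
nesting.  The claim's p-value is the two-sided p of the tested term (a
likelihood-ratio test when the tested variable is categorical with more
than two levels).  The K p-values combine into

    C = -2 * sum(ln p_i),

which under the model is chi-square with 2K degrees of freedom; a small
combined p indicates the path structure is inconsistent with the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dag import (
    BINOMIAL,
    CATEGORICAL,
    GAUSSIAN,
    ORDINAL,
    IndependenceClaim,
    PathDAG,
    basis_set,
)
from .mixedfit import (
    CategoricalTerm,
    InteractionTerm,
    LinearTerm,
    ModelSpec,
    QuadraticTerm,
    fit_mixed,
)

P_FLOOR = 1e-300


@dataclass
class ClaimTestResult:
    claim: IndependenceClaim
    beta: float
    p: float
    df: float
    stat: float
    converged: bool
    method: str  # "t" or "lrt"


@dataclass
class CStatResult:
    C: float
    K: int
    df: int
    p: float
    claims: list[ClaimTestResult] = field(default_factory=list)
    C_converged_only: float | None = None
    p_converged_only: float | None = None

    def claim_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x": r.claim.x,
                    "y": r.claim.y,
                    "conditioning": ";".join(sorted(r.claim.conditioning)),
                    "response": r.claim.response,
                    "beta": r.beta,
                    "stat": r.stat,
                    "df": r.df,
                    "p": r.p,
                    "method": r.method,
                    "converged": r.converged,
                }
                for r in self.claims
            ]
        )


def resolve_table(dag: PathDAG, response: str, data) -> pd.DataFrame:
    """Pick the study table a response's model is fitted on.

    ``data`` may be a single DataFrame (used for everything) or a mapping
    of table name → DataFrame, in which case the response node's declared
    ``table`` selects the right one.
    """
    if isinstance(data, pd.DataFrame):
        return data
    node = dag.node(response)
    if node.table is not None:
        try:
            return data[node.table]
        except KeyError:
            raise KeyError(
                f"node {response!r} declares table {node.table!r}, "
                f"which is not among {sorted(data)}"
            ) from None
    if len(data) == 1:
        return next(iter(data.values()))
    raise KeyError(
        f"node {response!r} declares no table and several tables were given"
    )


def _response_family(dag: PathDAG, name: str) -> str:
    fam = dag.node(name).family
    if fam == CATEGORICAL:
        raise ValueError(f"categorical node {name!r} cannot be a response")
    if fam in (GAUSSIAN, ORDINAL):
        return "gaussian"
    if fam == BINOMIAL:
        return "binomial-logit"
    raise ValueError(fam)


def _term_for(dag: PathDAG, var: str, response: str, structural: bool):
    """Fixed-effect term for ``var`` in a model for ``response``.

    Conditioning variables take the functional form of the response's own
    structural equation (quadratic edges expand to linear + squared,
    categorical variables to dummies).  Tested variables enter linearly
    (or as dummies when categorical); ordinal moult-type scores are kept
    linear in d-sep probes.
    """
    node = dag.node(var)
    if node.family == CATEGORICAL:
        return CategoricalTerm(var)
    if structural:
        edge = dag.direct_edge(var, response)
        if edge is not None and edge.form == "quadratic":
            return QuadraticTerm(var)
    return LinearTerm(var)


def claim_to_model(claim: IndependenceClaim, dag: PathDAG) -> ModelSpec:
    """Regression specification testing one independence claim."""
    response = claim.response
    node = dag.node(response)
    terms = [_term_for(dag, claim.predictor, response, structural=False)]
    for var in sorted(claim.conditioning):
        terms.append(_term_for(dag, var, response, structural=True))
    parents_in_cond = set(claim.conditioning)
    for edge in dag.interaction_edges(response):
        if {edge.source, edge.partner} <= parents_in_cond:
            terms.append(InteractionTerm(edge.source, edge.partner))
    return ModelSpec(
        response=response,
        fixed_terms=terms,
        family=_response_family(dag, response),
        random_nesting=node.grouping,
    )


def _swap_if_coarser(claim: IndependenceClaim, dag: PathDAG, table: pd.DataFrame):
    """Regress the finer-varying member of the pair on the coarser one.

    When the declared response is constant within its innermost grouping
    while the tested variable varies inside those groups, the replicated
    rows make the response's mixed model degenerate; the independence test
    is symmetric, so the regression is turned around instead.
    """
    resp = dag.node(claim.response)
    pred = dag.node(claim.predictor)
    if not resp.grouping or pred.family == CATEGORICAL:
        return claim
    cols = [c for c in resp.grouping if c in table.columns]
    if len(cols) != len(resp.grouping) or claim.predictor not in table.columns:
        return claim
    comp = None
    for col in cols:
        codes, uniques = pd.factorize(table[col], sort=True)
        comp = codes if comp is None else comp * len(uniques) + codes
    order = np.argsort(comp, kind="stable")
    same = np.diff(comp[order]) == 0

    def varies(column):
        vals = np.asarray(table[column], float)[order]
        return bool(((np.diff(vals) != 0) & same).any())

    if varies(claim.response) or not varies(claim.predictor):
        return claim
    return IndependenceClaim(
        x=claim.x, y=claim.y, conditioning=claim.conditioning, response=claim.predictor
    )


def test_claim(claim: IndependenceClaim, dag: PathDAG, table) -> ClaimTestResult:
    """Fit the claim's model and return the null probability of the tested term."""
    if claim.predictor in claim.conditioning:
        raise ValueError(
            f"tested variable {claim.predictor!r} also appears in the conditioning set"
        )
    resolved = resolve_table(dag, claim.response, table)
    swapped = _swap_if_coarser(claim, dag, resolved)
    if swapped is not claim:
        claim = swapped
        resolved = resolve_table(dag, claim.response, table)
    table = resolved
    spec = claim_to_model(claim, dag)
    pred_node = dag.node(claim.predictor)

    if pred_node.family == CATEGORICAL:
        levels = pd.unique(table[claim.predictor].dropna().astype(str))
        if len(levels) > 2:
            return _lrt_claim(claim, spec, table)

    fit = fit_mixed(spec, table, sd_ci=False)
    if pred_node.family == CATEGORICAL:
        # two levels: single dummy, use its t test
        label = next(
            c.term for c in fit.coefficients if c.term.startswith(f"{claim.predictor}[")
        )
    else:
        label = claim.predictor
    coef = fit.coefficient(label)
    p = coef.p
    if p <= 0:
        warnings.warn("claim p-value underflowed; floored at 1e-300", stacklevel=2)
        p = P_FLOOR
    return ClaimTestResult(
        claim=claim, beta=coef.beta, p=float(p), df=coef.df, stat=coef.stat,
        converged=fit.converged, method="t",
    )


def _lrt_claim(claim, spec, table) -> ClaimTestResult:
    """Likelihood-ratio test for a multi-level categorical tested variable."""
    reduced_terms = [
        t for t in spec.fixed_terms
        if getattr(t, "name", getattr(t, "label", None)) != claim.predictor
    ]
    reduced = ModelSpec(
        response=spec.response, fixed_terms=reduced_terms,
        family=spec.family, random_nesting=spec.random_nesting,
    )
    reml = False  # fixed-effect LR comparisons require ML
    full_fit = fit_mixed(spec, table, reml=reml, sd_ci=False)
    red_fit = fit_mixed(reduced, table, reml=reml, sd_ci=False)
    n_levels = table[claim.predictor].dropna().astype(str).nunique()
    df = n_levels - 1
    lr = max(2.0 * (full_fit.loglik - red_fit.loglik), 0.0)
    p = float(stats.chi2.sf(lr, df))
    if p <= 0:
        p = P_FLOOR
    return ClaimTestResult(
        claim=claim, beta=np.nan, p=p, df=float(df), stat=float(lr),
        converged=full_fit.converged and red_fit.converged, method="lrt",
    )


def fishers_c(pvalues) -> CStatResult:
    """Combine independent null probabilities into Fisher's C.

    C = -2 sum ln(p); under joint truth of the K claims C ~ chi-square
    with 2K df, and the combined p is the upper-tail probability.
    """
    pvalues = list(pvalues)
    if not pvalues:
        raise ValueError("no p-values to combine")
    arr = np.asarray(pvalues, float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    c = float(-2.0 * np.sum(np.log(arr)))
    k = len(arr)
    p = float(stats.chi2.sf(c, 2 * k))
    return CStatResult(C=c, K=k, df=2 * k, p=p)


def test_model_fit(dag: PathDAG, table) -> CStatResult:
    """Full d-sep goodness-of-fit: basis set → claim tests → Fisher's C."""
    claims = basis_set(dag)
    results = [test_claim(c, dag, table) for c in claims]
    combined = fishers_c([r.p for r in results])
    combined.claims = results
    bad = [r for r in results if not r.converged]
    if bad:
        ok_p = [r.p for r in results if r.converged]
        if ok_p:
            sub = fishers_c(ok_p)
            combined.C_converged_only = sub.C
            combined.p_converged_only = float(stats.chi2.sf(sub.C, 2 * len(ok_p)))
        warnings.warn(
            f"{len(bad)} claim model(s) did not converge; C reported with and "
            "without the flagged claims", stacklevel=2,
        )
    return combined
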