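"""End-to-end study pipeline: the four analyses on synthetic or user data.

The four analyses mirror the study design:

1. brood experiment — raw-scale mixed model of nestling mass on the
   manipulation arm (reduced / control / enlarged four-egg broods);
2. first-year survival — binomial-logit GLMM of survival on nestling
   mass, timing of nesting and (curvilinear) tarsus, with nest nested in
   mother nested in year;
3. & 4. the breeding-period and pre-migratory path analyses, run from one
   combined DAG: standardize, residualize declared interactions, test the
   basis set (Fisher's C), parameterize the structural equations and
   decompose effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bodycomp import fat_index, total_body_water_table, validate_moult
from .dag import CATEGORICAL, PathDAG
from .dsep import CStatResult, resolve_table, test_model_fit
from .effects import (
    EffectDecomposition,
    PathCoefficients,
    fit_structural_equations,
    structural_model,
    total_effect,
)
from .mixedfit import (
    CategoricalTerm,
    FitResult,
    LinearTerm,
    ModelSpec,
    QuadraticTerm,
    SeparationError,
    collinearity_check,
    fit_mixed,
    standardize,
    variance_explained,
)

log = logging.getLogger("gmlpath")

DEFAULT_EFFECT_PAIRS = [
    ("timing", "fat"),
    ("timing", "tbw"),
    ("fledglings", "nestling_mass"),
    ("nestling_mass", "fat"),
]


@dataclass
class AnalysisReport:
    name: str
    model_specs: list[str] = field(default_factory=list)
    coefficients: pd.DataFrame | None = None
    cstat: CStatResult | None = None
    effects: list[EffectDecomposition] = field(default_factory=list)
    variance_explained: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = [f"# {self.name}", ""]
        for spec in self.model_specs:
            lines.append(f"- model: `{spec}`")
        if self.cstat is not None:
            lines.append(
                f"\nFisher's C = {self.cstat.C:.2f}, K = {self.cstat.K}, "
                f"df = {self.cstat.df}, P = {self.cstat.p:.3f}"
            )
        if self.coefficients is not None and len(self.coefficients):
            lines.append("\n## Coefficients\n")
            lines.append(self.coefficients.round(3).to_markdown(index=False))
        for eff in self.effects:
            r = eff.rounded()
            lines.append(
                f"\nTotal effect {eff.source} -> {eff.target}: direct {r['direct']}, "
                f"indirect {r['indirect']}, total {r['total']}"
            )
        for k, v in self.variance_explained.items():
            lines.append(f"\nVariance explained ({k}): {100 * v:.0f}%")
        for note in self.notes:
            lines.append(f"\n> {note}")
        return "\n".join(lines) + "\n"


def _describe(spec: ModelSpec) -> str:
    terms = []
    for t in spec.fixed_terms:
        if isinstance(t, QuadraticTerm):
            terms.append(f"{t.name} + {t.name}^2")
        elif isinstance(t, CategoricalTerm):
            terms.append(f"C({t.name})")
        elif isinstance(t, LinearTerm):
            terms.append(t.name)
        else:
            terms.append(t.label)
    rhs = " + ".join(terms) or "1"
    nesting = "/".join(spec.random_nesting) or "none"
    return f"{spec.response} ~ {rhs} [{spec.family}; random: {nesting}]"


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

NESTLING_COLUMNS = {
    "individual", "nest", "mother", "year", "timing_day",
    "fledglings", "tarsus_mm", "mass_g",
}
CAPTURE_COLUMNS = {
    "individual", "nest", "year", "date", "time", "mass_g", "tarsus_mm",
    "moult", "W_g", "E_inj", "E_bkg", "E_plat",
}
SURVIVAL_COLUMNS = {"individual", "survived"}

SCHEMAS = {
    "nestlings": NESTLING_COLUMNS,
    "captures": CAPTURE_COLUMNS,
    "survival": SURVIVAL_COLUMNS,
}


class SchemaError(ValueError):
    pass


def load_tables(paths: dict[str, str], schemas: dict[str, set] | None = None):
    """Read and validate the study CSVs.

    ``paths`` maps table name (nestlings / captures / survival) to a CSV
    path.  Required columns are checked, moult scores validated against
    the 1-4 ordinal scale, and rows with missing required values dropped
    with a logged count.
    """
    schemas = schemas or SCHEMAS
    tables = {}
    for name, path in paths.items():
        df = pd.read_csv(path)
        required = schemas.get(name, set())
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"{name}: missing required columns {sorted(missing)}")
        before = len(df)
        df = df.dropna(subset=sorted(required))
        dropped = before - len(df)
        if dropped:
            log.info("%s: dropped %d rows with missing required values", name, dropped)
        if "moult" in df.columns:
            validate_moult(df["moult"])
        tables[name] = df.reset_index(drop=True)
    return tables


# ---------------------------------------------------------------------------
# path-analysis data preparation
# ---------------------------------------------------------------------------


def prepare_path_tables(
    nestlings: pd.DataFrame,
    captures: pd.DataFrame,
    exchange_k: float = 1.04,
    exclude_manipulated: bool = False,
) -> dict[str, pd.DataFrame]:
    """Node-named analysis tables for the combined path model.

    Derives total body water from the isotope enrichments and the fat
    index from the repeated-measures residual model, merges nest-level
    covariates onto the capture rows, and renames columns to the path
    model's node names.  Values are left on their raw scales; the path
    analysis standardizes them.
    """
    nest_tab = nestlings.copy()
    if exclude_manipulated and "treatment" in nest_tab.columns:
        nest_tab = nest_tab[nest_tab["treatment"].fillna("control") == "control"]
    nest_out = pd.DataFrame(
        {
            "individual": nest_tab["individual"],
            "nest": nest_tab["nest"],
            "year": nest_tab["year"].astype(str),
            "timing": nest_tab["timing_day"].astype(float),
            "fledglings": nest_tab["fledglings"].astype(float),
            "tarsus_nest": nest_tab["tarsus_mm"].astype(float),
            "nestling_mass": nest_tab["mass_g"].astype(float),
        }
    ).reset_index(drop=True)

    cap = captures.copy()
    validate_moult(cap["moult"])
    cap["tbw_g"] = total_body_water_table(cap, k=exchange_k)
    breeding_cols = nestlings.set_index("individual")[
        ["timing_day", "fledglings", "tarsus_mm", "mass_g"]
    ].rename(
        columns={
            "timing_day": "timing", "fledglings": "fledglings",
            "tarsus_mm": "tarsus_nest", "mass_g": "nestling_mass",
        }
    )
    cap = cap.join(breeding_cols, on="individual", rsuffix="_nest")
    # slopes for the index are estimated controlling for the condition
    # covariates, so fat variation correlated with lean mass does not
    # bias the lean-mass slope
    cap["fat_index"] = fat_index(
        cap,
        controls=["date", "time", "moult", CategoricalTerm("year"),
                  "timing", "nestling_mass"],
    )
    cap_out = pd.DataFrame(
        {
            "individual": cap["individual"],
            "nest": cap["nest"],
            "year": cap["year"].astype(str),
            "timing": cap["timing"].astype(float),
            "fledglings": cap["fledglings"].astype(float),
            "tarsus_nest": cap["tarsus_nest"].astype(float),
            "nestling_mass": cap["nestling_mass"].astype(float),
            "date": cap["date"].astype(float),
            "time_captured": cap["time"].astype(float),
            "tarsus_adult": cap["tarsus_mm"].astype(float),
            "moult": cap["moult"].astype(float),
            "tbw": cap["tbw_g"].astype(float),
            "fat": cap["fat_index"].astype(float),
        }
    ).reset_index(drop=True)
    return {"nestlings": nest_out, "captures": cap_out}


def standardize_path_tables(dag: PathDAG, tables: dict[str, pd.DataFrame]):
    """Standardize every non-categorical node column in each table."""
    out = {}
    params = {}
    for name, df in tables.items():
        cols = [
            n for n, node in dag.nodes.items()
            if node.family != CATEGORICAL and n in df.columns
        ]
        std, p = standardize(df, cols)
        out[name] = std
        params[name] = p
    return out, params


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------


def run_brood_experiment(nestlings: pd.DataFrame) -> AnalysisReport:
    """Mixed model for the brood-manipulation experiment, raw scale.

    Restricted to four-egg clutches (the manipulated stratum and its
    controls): nestling mass ~ treatment + tarsus + timing + year with a
    random intercept per natal nest.
    """
    data = nestlings[nestlings["clutch"] == 4].copy() if "clutch" in nestlings else nestlings.copy()
    arms = sorted(data["treatment"].astype(str).unique())
    report = AnalysisReport(name="brood experiment")
    if "control" not in arms:
        report.notes.append("no control arm present; contrasts are degenerate")
    for arm in ("reduced", "enlarged"):
        if arm not in arms:
            report.notes.append(f"missing arm {arm!r}; its contrast is not estimable")
    n_per_arm = data.groupby(data["treatment"].astype(str)).size().to_dict()
    report.diagnostics["n_per_arm"] = n_per_arm

    n_years = data["year"].astype(str).nunique()
    terms = [CategoricalTerm("treatment", reference="control"),
             LinearTerm("tarsus_mm"), LinearTerm("timing_day")]
    if n_years > 1:
        terms.append(CategoricalTerm("year"))
    spec = ModelSpec(
        response="mass_g", fixed_terms=terms,
        family="gaussian", random_nesting=("nest",),
    )
    fit = fit_mixed(spec, data)
    report.model_specs.append(_describe(spec))
    report.coefficients = fit.to_frame()
    report.variance_explained["mass_g"] = variance_explained(spec, data)
    report.diagnostics["collinearity"] = collinearity_check(fit)
    report.diagnostics["converged"] = fit.converged
    report.diagnostics["n_dropped"] = fit.n_dropped
    report.diagnostics["fit"] = fit
    return report


def run_survival_analysis(
    nestlings: pd.DataFrame, survival: pd.DataFrame, curvilinear_tarsus: bool = True
) -> AnalysisReport:
    """Binomial GLMM of first-year survival on nestling traits.

    Covariates are centred at their sample means (slopes are unchanged);
    tarsus enters with a squared term by default, matching the convex
    mass-tarsus relationship seen in long-term data.
    """
    data = nestlings.merge(survival[["individual", "survived"]], on="individual")
    for col, cen in (("mass_g", None), ("timing_day", None), ("tarsus_mm", None)):
        data[f"{col}_c"] = data[col].astype(float) - data[col].astype(float).mean()
    terms = [LinearTerm("mass_g_c"), LinearTerm("timing_day_c")]
    terms.append(QuadraticTerm("tarsus_mm_c") if curvilinear_tarsus else LinearTerm("tarsus_mm_c"))
    spec = ModelSpec(
        response="survived", fixed_terms=terms,
        family="binomial-logit", random_nesting=("year", "mother", "nest"),
    )
    report = AnalysisReport(name="first-year survival")
    try:
        fit = fit_mixed(spec, data)
    except SeparationError as err:
        raise SeparationError(
            f"{err}; check for an outcome that is constant overall or within a "
            "predictor stratum, and consider pooling sparse strata"
        ) from err
    report.model_specs.append(_describe(spec))
    report.coefficients = fit.to_frame()
    report.variance_explained["survived"] = variance_explained(spec, data)
    report.diagnostics["survival_rate"] = float(data["survived"].mean())
    report.diagnostics["converged"] = fit.converged
    report.diagnostics["fit"] = fit
    return report


def screen_interactions(dag: PathDAG, tables) -> tuple[PathDAG, dict]:
    """Test each declared two-way interaction one at a time; keep the
    significant ones (cross-product term added to the response's
    structural equation without the other interactions)."""
    from .dag import PathDAG as _DAG

    pvals = {}
    keep = []
    for edge in dag.edges:
        if edge.form != "interaction":
            keep.append(edge)
            continue
        spec = structural_model(dag, edge.target)
        spec.fixed_terms = [
            t for t in spec.fixed_terms
            if not (hasattr(t, "a") and {t.a, t.b} != {edge.source, edge.partner})
        ]
        fit = fit_mixed(spec, resolve_table(dag, edge.target, tables))
        p = fit.coefficient(f"{edge.source}:{edge.partner}").p
        pvals[(edge.source, edge.partner, edge.target)] = p
        if p < 0.05:
            keep.append(edge)
    slim = _DAG(list(dag.nodes.values()), keep, dag.free_covariance)
    return slim, pvals


def run_path_analysis(
    dag: PathDAG,
    tables,
    effect_pairs=None,
    significant_only: bool = False,
    screen: bool = False,
) -> AnalysisReport:
    """Full generalized multi-level path analysis.

    Standardizes the node columns, optionally screens declared two-way
    interactions one at a time, runs the d-sep basis-set test (Fisher's
    C), parameterizes the structural equations, and decomposes the
    requested source → target effects.
    """
    if isinstance(tables, pd.DataFrame):
        tables = {"data": tables}
    std_tables, _ = standardize_path_tables(dag, tables)
    report = AnalysisReport(name="path analysis")
    if screen:
        dag, pvals = screen_interactions(dag, std_tables)
        report.diagnostics["interaction_screen"] = pvals

    cstat = test_model_fit(dag, std_tables)
    report.cstat = cstat
    report.diagnostics["claims"] = cstat.claim_table()

    coeffs = fit_structural_equations(dag, std_tables)
    report.coefficients = coeffs.to_frame()
    report.diagnostics["path_coefficients"] = coeffs
    for resp, fit in coeffs.fits.items():
        report.model_specs.append(_describe(fit.spec))
        report.diagnostics.setdefault("collinearity", {})[resp] = collinearity_check(fit)
        tab = resolve_table(dag, resp, std_tables)
        report.variance_explained[resp] = variance_explained(fit.spec, tab)
    report.diagnostics["fit_errors"] = {k: str(v) for k, v in coeffs.errors.items()}

    for source, target in (effect_pairs or DEFAULT_EFFECT_PAIRS):
        if source in dag.nodes and target in dag.nodes:
            report.effects.append(
                total_effect(source, target, dag, coeffs, significant_only=significant_only)
            )
    return report


# ---------------------------------------------------------------------------
# full reproduction
# ---------------------------------------------------------------------------


def reproduce(seed: int, config=None, out_dir=None):
    """Simulate a study and run all four analyses.

    Returns ``(study, reports)``; when ``out_dir`` is given, writes the
    simulated CSVs, coefficient tables and markdown reports there.
    """
    from .simulate import SimulationConfig, simulate_study, sparrow_dag

    config = config or SimulationConfig(seed=seed)
    study = simulate_study(config)
    dag = sparrow_dag(config)

    reports = {
        "brood_experiment": run_brood_experiment(study.nestlings),
        "survival": run_survival_analysis(study.nestlings, study.survival),
    }
    tables = prepare_path_tables(
        study.nestlings, study.captures, exchange_k=config.exchange_k
    )
    reports["path_analysis"] = run_path_analysis(dag, tables)

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        study.nestlings.to_csv(out / "nestlings.csv", index=False)
        study.captures.to_csv(out / "captures.csv", index=False)
        study.survival.to_csv(out / "survival.csv", index=False)
        study.truth_breeding.to_csv(out / "truth" / "breeding.csv", index=False)
        study.truth_captures.to_csv(out / "truth" / "captures.csv", index=False)
        for name, rep in reports.items():
            (out / f"{name}.md").write_text(rep.to_markdown())
            if rep.coefficients is not None:
                rep.coefficients.to_csv(out / f"{name}_coefficients.csv", index=False)
            if rep.cstat is not None:
                rep.cstat.claim_table().to_csv(out / f"{name}_claims.csv", index=False)
        log.info("wrote reproduction outputs to %s", out)
    return study, reports
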