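"""Body-condition metrics: heavy-water dilution and the residual fat index.

Total body water (TBW), a surrogate for lean tissue mass, is estimated by
deuterium (D2O) dilution: a known dose of labelled water is injected,
allowed to equilibrate, and the plateau enrichment measured in blood
water.  With dose mass W, injectate enrichment E_inj, pre-dose background
E_bkg and plateau E_plat (all as D2O fractions), the dilution space is

    N = W * (E_inj - E_plat) / (E_plat - E_bkg)

and TBW = N / k, where k >= 1 corrects for exchange of heavy hydrogen
with non-aqueous molecules (default 1.04, the conventional hydrogen
exchange correction).

Fat mass is indexed by the conditional residuals of a repeated-measures
mixed model of body mass on TBW and tarsus length with a random intercept
per individual: mass unexplained by lean tissue and skeletal size is
mostly fat.  The index is returned in standardized residual units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedfit import ModelSpec, QuadraticTerm, fit_mixed

DEFAULT_EXCHANGE_K = 1.04
MOULT_SCORES = (1, 2, 3, 4)  # quartile bins of body-moult completeness


class DilutionError(ValueError):
    """Isotope enrichments inconsistent with a reached plateau."""


@dataclass(frozen=True)
class DilutionSample:
    """One capture with an isotope-dilution measurement (units: g, fractions)."""

    individual: str
    body_mass: float
    dose_mass: float                 # g of injectate, W
    e_injectate: float               # D2O fraction of the dose
    e_background: float              # pre-dose body-water enrichment
    e_plateau: float                 # post-equilibration enrichment
    tarsus: float | None = None
    capture_time: float | None = None
    exchange_k: float = DEFAULT_EXCHANGE_K

    def __post_init__(self):
        if self.dose_mass <= 0 or self.body_mass <= 0:
            raise ValueError("dose mass and body mass must be positive")
        if self.exchange_k < 1.0:
            raise ValueError("exchange correction k must be >= 1")
        if not (self.e_injectate > self.e_plateau >= 0 and self.e_background >= 0):
            raise DilutionError(
                "enrichments must satisfy E_inj > E_plat and E_bkg >= 0"
            )


def total_body_water(sample: DilutionSample) -> float:
    """Total body water (g) from the plateau mass-balance equation."""
    if sample.e_plateau <= sample.e_background:
        raise DilutionError(
            "plateau enrichment does not exceed background: no plateau reached"
        )
    dilution_space = (
        sample.dose_mass
        * (sample.e_injectate - sample.e_plateau)
        / (sample.e_plateau - sample.e_background)
    )
    return dilution_space / sample.exchange_k


def plateau_from_tbw(tbw: float, dose_mass: float, e_injectate: float,
                     e_background: float = 0.0, exchange_k: float = DEFAULT_EXCHANGE_K) -> float:
    """Inverse of :func:`total_body_water`: the plateau enrichment a bird
    with the given TBW would show.  Used by the synthetic study generator."""
    n = tbw * exchange_k
    return (dose_mass * e_injectate + n * e_background) / (n + dose_mass)


def total_body_water_table(table: pd.DataFrame, k: float = DEFAULT_EXCHANGE_K) -> pd.Series:
    """Vectorized TBW for a capture table with columns
    ``W_g, E_inj, E_bkg, E_plat`` (fractions)."""
    e_plat = np.asarray(table["E_plat"], float)
    e_bkg = np.asarray(table["E_bkg"], float)
    if np.any(e_plat <= e_bkg):
        raise DilutionError("some samples have E_plat <= E_bkg: no plateau reached")
    n = np.asarray(table["W_g"], float) * (np.asarray(table["E_inj"], float) - e_plat) / (
        e_plat - e_bkg
    )
    return pd.Series(n / k, index=table.index, name="tbw_g")


def fat_index(
    table: pd.DataFrame,
    mass_col: str = "mass_g",
    tbw_col: str = "tbw_g",
    tarsus_col: str = "tarsus_mm",
    individual_col: str = "individual",
    level: str = "marginal",
    controls=(),
) -> pd.Series:
    """Repeated-measures residual fat index.

    Fits ``body mass ~ TBW + tarsus [+ controls] + (1 | individual)`` and
    returns ``mass - b_tbw * TBW``, centred and rescaled to SD 1: the mass
    variation not accounted for by lean tissue, with tarsus length (and
    any further controls) held fixed when the lean-mass slope is
    estimated.  Positive values mean heavier than lean tissue predicts —
    i.e. relatively fat.

    ``controls`` are covariates that drive fat itself (capture date, time
    of day, moult, year, nestling traits).  Including them when
    *estimating* the lean-mass slope prevents fat variation correlated
    with total body water from biasing that slope (which would leave a
    spurious TBW component in the index); neither their contributions nor
    the tarsus one are subtracted, so condition- and size-related fat
    variation stays in the index.

    The random intercept weights the regression correctly for repeated
    captures.  ``level="conditional"`` additionally subtracts the
    individual BLUPs, leaving only within-individual fat fluctuation.
    """
    if len(table) < 2:
        raise ValueError("need at least two observations")
    if level not in ("marginal", "conditional"):
        raise ValueError("level must be 'marginal' or 'conditional'")
    spec = ModelSpec(
        response=mass_col,
        fixed_terms=[tbw_col, tarsus_col, *controls],
        family="gaussian",
        random_nesting=(individual_col,),
    )
    fit = fit_mixed(spec, table)
    cols = sorted(spec.data_columns())
    used = table.dropna(subset=[c for c in cols if c in table.columns])
    b_tbw = fit.coefficient(tbw_col).beta
    resid = (
        np.asarray(used[mass_col], float)
        - b_tbw * np.asarray(used[tbw_col], float)
    )
    if level == "conditional":
        resid = resid - (fit.fitted - fit.fitted_marginal)  # subtract Z b
    resid = resid - resid.mean()
    sd = float(np.std(resid, ddof=1))
    if sd < 1e-10:
        values = np.zeros_like(resid)
    else:
        values = resid / sd
    return pd.Series(values, index=used.index, name="fat_index")


def nestling_condition_terms(curvilinear: bool = False, tarsus_col: str = "tarsus_mm"):
    """Size-control covariates for nestling condition models.

    The long-term survival dataset shows a slightly convex mass–tarsus
    relationship, so its models carry a squared tarsus term; elsewhere the
    relationship is linear.
    """
    if curvilinear:
        return [QuadraticTerm(tarsus_col)]
    return [tarsus_col]


def validate_moult(scores) -> pd.Series:
    """Check moult scores are in the ordinal 1-4 scale."""
    s = pd.Series(scores)
    bad = ~s.dropna().isin(MOULT_SCORES)
    if bad.any():
        raise ValueError(
            f"moult scores outside {MOULT_SCORES}: {sorted(s.dropna()[bad].unique())}"
        )
    return s
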