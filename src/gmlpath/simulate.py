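"""Synthetic migratory-songbird study generator.

Emulates the structure of a multi-year island study of Savannah sparrows:
~60 nests across 3 breeding seasons, a brood-manipulation experiment on
four-egg clutches, repeated pre-migratory captures (2-11 per juvenile)
with heavy-water dilution measurements, and binary first-year survival.

The generator works on the standardized scale: every structural equation
uses the published standardized path coefficients as ground truth, nested
random intercepts are added per level, and the residual SD of each
endogenous variable is topped up so its marginal variance is ~1 (so a
re-standardized refit recovers the configured coefficients).  Observables
are then mapped to plausible raw units (grams, millimetres, ordinal days);
the raw-unit anchors are invented scaffolding and documented as such.

Two discretization effects are compensated so the configured coefficient
remains the estimand after rounding:

* fledgling counts are ``round(4.17 + 0.62 * latent)``, which inflates the
  response SD by a known factor; latent coefficients are pre-scaled by it;
* moult is an ordinal 1-4 score cut at the quartiles of a unit-normal
  latent; the score-latent correlation (≈0.925) attenuates coefficients
  into the score, so latent coefficients are divided by it.  Downstream
  equations consume the observed standardized score directly, so no
  compensation is needed on the predictor side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .bodycomp import plateau_from_tbw
from .dag import BINOMIAL, CATEGORICAL, GAUSSIAN, ORDINAL, PathDAG, PathEdge, PathNode

# standardized path coefficients used as simulation truth; values match the
# published pre-migratory sparrow analysis, except the small unreported
# main effects marked "qualitative" below
DEFAULT_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("timing", "fledglings"): -0.49,
    ("fledglings", "nestling_mass"): -0.33,
    ("timing", "nestling_mass"): -0.36,
    ("tarsus_nest", "nestling_mass"): 0.67,
    ("fledglings", "tarsus_nest"): 0.25,
    ("timing", "tarsus_nest"): -0.08,
    ("tarsus_nest", "tarsus_adult"): 0.58,
    ("timing", "moult"): -0.35,
    ("date", "moult"): 0.42,
    ("nestling_mass", "tbw"): 0.16,
    ("moult", "tbw"): -0.27,
    ("moult^2", "tbw"): -0.22,
    ("timing", "tbw"): -0.05,        # hypothesized, qualitative magnitude
    ("date", "tbw"): -0.10,          # qualitative
    ("time_captured", "tbw"): 0.07,
    ("tarsus_adult", "tbw"): 0.12,
    ("date:timing", "tbw"): 0.13,
    ("nestling_mass", "fat"): 0.24,
    ("timing", "fat"): -0.08,
    ("moult", "fat"): 0.13,
    ("date", "fat"): 0.32,
    ("time_captured", "fat"): 0.19,
    ("tarsus_adult", "fat"): -0.11,
}

# year contrasts (2009, 2010 vs reference 2008), standardized scale
DEFAULT_YEAR_EFFECTS: dict[str, tuple[float, float]] = {
    "timing": (0.90, 0.22),
    "fledglings": (0.01, 0.35),
    "nestling_mass": (0.34, 0.43),
    "tarsus_nest": (0.66, 0.61),
    "moult": (0.26, 1.03),
    "tbw": (1.23, -0.21),
    "fat": (-0.68, -0.38),
}

# correlation between the quartile-binned standardized moult score and its
# unit-normal latent: E[score * z] / sd(score) with quartile cuts
_PHI = stats.norm.pdf
_CUTS = (-0.6744897501960817, 0.0, 0.6744897501960817)
MOULT_ATTENUATION = (
    1.0 * (0.0 - _PHI(_CUTS[0]))
    + 2.0 * (_PHI(_CUTS[0]) - _PHI(0.0))
    + 3.0 * (_PHI(0.0) - _PHI(_CUTS[2]))
    + 4.0 * (_PHI(_CUTS[2]) - 0.0)
) / np.sqrt(1.25)


@dataclass
class SimulationConfig:
    """Ground truth and sampling design for the synthetic study."""

    seed: int
    n_years: int = 3
    nests_per_year: int = 20
    first_year: int = 2008
    clutch_mean: float = 4.17
    clutch_sd: float = 0.62
    # brood manipulation on four-egg clutches
    arm_probs: dict[str, float] = field(
        default_factory=lambda: {"control": 0.5, "reduced": 0.25, "enlarged": 0.25}
    )
    arm_brood: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "reduced": 3, "enlarged": 5}
    )
    brood_reduction_effect_g: float = 1.2   # causal mass gain, reduced vs control
    brood_enlargement_effect_g: float = -0.3
    coefficients: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    year_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_YEAR_EFFECTS)
    )
    # random-intercept SDs, standardized scale (not published; convention)
    sd_nest: float = 0.3
    sd_individual: float = 0.3
    sd_mother_survival: float = 0.3
    sd_nest_survival: float = 0.3
    sd_year_survival: float = 0.3
    min_resid_var: float = 0.05
    residual_scale: float = 1.0  # diagnostic dial: 0 silences all top-up noise
    # capture process
    capture_prob: float = 0.45
    capture_mean: float = 4.0
    capture_min: int = 2
    capture_max: int = 11
    mother_return_prob: float = 0.5
    # survival model, raw-unit scale, covariates centred at their anchors
    survival_intercept: float = -0.3
    survival_slope_mass: float = 0.13       # per gram of nestling mass
    survival_slope_timing: float = -0.01    # per day of season
    survival_slope_tarsus: float = 0.3      # per mm
    survival_slope_tarsus2: float = -0.06   # per mm^2
    # raw-unit anchors (invented scaffolding for realism)
    timing_day_mean: float = 160.0
    timing_day_sd: float = 12.0
    nestling_mass_g_mean: float = 18.5
    nestling_mass_g_sd: float = 1.6
    tarsus_nest_mm_mean: float = 20.5
    tarsus_nest_mm_sd: float = 0.8
    tarsus_adult_mm_mean: float = 20.8
    tarsus_adult_mm_sd: float = 0.75
    capture_day_mean: float = 244.0
    capture_day_sd: float = 18.0
    capture_hour_mean: float = 12.0
    capture_hour_sd: float = 2.2
    tbw_g_mean: float = 12.0
    tbw_g_sd: float = 1.2
    fat_g_mean: float = 1.8
    fat_g_sd: float = 0.6
    water_fraction_lean: float = 0.70
    mass_noise_g: float = 0.12
    # isotope dilution
    dose_mass_g: float = 0.3
    e_injectate: float = 0.999
    e_background: float = 0.00015
    exchange_k: float = 1.04
    plateau_noise_rel: float = 0.005

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.arm_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("arm probabilities must sum to 1")
        for name in ("sd_nest", "sd_individual", "clutch_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def years(self) -> list[str]:
        return [str(self.first_year + i) for i in range(self.n_years)]

    def year_effect(self, node: str, year_index: int) -> float:
        if year_index == 0:
            return 0.0
        eff = self.year_effects.get(node)
        if eff is None:
            return 0.0
        return eff[min(year_index - 1, len(eff) - 1)]

    def beta(self, source: str, target: str) -> float:
        return self.coefficients.get((source, target), 0.0)

    def with_coefficients(self, updates: dict[tuple[str, str], float]):
        coeffs = dict(self.coefficients)
        coeffs.update(updates)
        return replace(self, coefficients=coeffs)


def sparrow_dag(config: SimulationConfig | None = None) -> PathDAG:
    """The shipped sparrow path model matching the generator's structure."""
    nodes = [
        PathNode("year", CATEGORICAL, (), "nestlings"),
        PathNode("timing", GAUSSIAN, ("nest",), "nestlings"),
        PathNode("fledglings", GAUSSIAN, ("nest",), "nestlings"),
        PathNode("tarsus_nest", GAUSSIAN, ("nest",), "nestlings"),
        PathNode("nestling_mass", GAUSSIAN, ("nest",), "nestlings"),
        PathNode("date", GAUSSIAN, ("nest", "individual"), "captures"),
        PathNode("time_captured", GAUSSIAN, ("nest", "individual"), "captures"),
        PathNode("tarsus_adult", GAUSSIAN, ("nest", "individual"), "captures"),
        PathNode("moult", ORDINAL, ("nest", "individual"), "captures"),
        PathNode("tbw", GAUSSIAN, ("nest", "individual"), "captures"),
        PathNode("fat", GAUSSIAN, ("nest", "individual"), "captures"),
    ]
    coeffs = (config or SimulationConfig(seed=0)).coefficients
    year_eff = (config or SimulationConfig(seed=0)).year_effects
    edges = []
    for (src, tgt) in coeffs:
        if src.endswith("^2"):
            continue  # folded into the quadratic edge below
        if ":" in src:
            a, b = src.split(":")
            edges.append(PathEdge(a, tgt, "interaction", partner=b))
            continue
        form = "quadratic" if (f"{src}^2", tgt) in coeffs else "linear"
        edges.append(PathEdge(src, tgt, form))
    for tgt in year_eff:
        edges.append(PathEdge("year", tgt, "linear"))
    # fat is a residual index constructed orthogonal to total body water,
    # so the fat-tbw independence claim is uninformative by construction;
    # the pair is treated as a free (error) covariance
    dag = PathDAG(nodes, edges, free_covariance=[("fat", "tbw")])
    dag.require_valid()
    return dag


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _topped_noise(rng, systematic, re_var, min_var, label, scale=1.0):
    """Residual draws sized so the total variance is ~1."""
    var_sys = float(np.var(systematic)) if len(systematic) > 1 else 0.0
    resid_var = 1.0 - var_sys - re_var
    if resid_var < min_var:
        warnings.warn(
            f"{label}: systematic + random-effect variance exceeds 1 "
            f"(residual clipped to {min_var})", stacklevel=3,
        )
        resid_var = min_var
    return scale * rng.normal(0.0, np.sqrt(resid_var), size=len(systematic))


def _zscore(values) -> np.ndarray:
    arr = np.asarray(values, float)
    return (arr - arr.mean()) / arr.std(ddof=1)


# fledgling counts: round(clutch_mean + clutch_sd * latent) adds ~uniform
# rounding noise, and the brood manipulation adds +-1 moves on four-egg
# clutches; both inflate sd(count) over clutch_sd.  Latent coefficients are
# pre-scaled by the total inflation so the standardized observed count
# carries the configured coefficient.
def _count_inflation(config: "SimulationConfig") -> float:
    """sd(brood) / cov(latent, brood) from a large reference sample.

    Rounding adds variance but also covaries (sawtooth) with the latent,
    and the manipulation adds independent +-1 moves; a closed form is
    awkward, so both are measured on a fixed large standalone draw.
    """
    rng = np.random.default_rng(987654321)
    z = rng.normal(size=200_000)
    count = np.clip(np.round(config.clutch_mean + config.clutch_sd * z), 1, 8)
    arm_names = list(config.arm_probs)
    arm_p = np.array([config.arm_probs[a] for a in arm_names])
    four = count == 4
    arms = rng.choice(len(arm_names), size=int(four.sum()), p=arm_p)
    delta = np.array([config.arm_brood[arm_names[a]] - 4 for a in arms], float)
    brood = count.copy()
    brood[four] += delta
    cov = float(np.cov(z, brood)[0, 1])
    return float(np.std(brood, ddof=1) / cov)


# ---------------------------------------------------------------------------
# breeding season
# ---------------------------------------------------------------------------


def simulate_breeding(config: SimulationConfig):
    """Nestling table (one row per nestling) plus a hidden truth table."""
    rng = _rng(config, 1)
    years = config.years()
    rows = []
    truth_rows = []
    mothers_pool: list[str] = []
    mother_counter = 0

    nest_records = []
    for yi, year in enumerate(years):
        returning = [m for m in mothers_pool if rng.random() < config.mother_return_prob]
        needed = config.nests_per_year - len(returning)
        new = []
        for _ in range(max(needed, 0)):
            mother_counter += 1
            new.append(f"f{mother_counter:03d}")
        mothers = (returning + new)[: config.nests_per_year]
        mothers_pool = sorted(set(mothers_pool) | set(new))
        for ni, mother in enumerate(mothers):
            nest_records.append(
                {"nest": f"{year}-n{ni + 1:02d}", "mother": mother, "year": year,
                 "year_index": yi}
            )

    n_nests = len(nest_records)
    yi_arr = np.array([r["year_index"] for r in nest_records])

    # timing of nesting (one value per nest)
    sys_t = np.array([config.year_effect("timing", yi) for yi in yi_arr])
    timing_z = sys_t + _topped_noise(rng, sys_t, 0.0, config.min_resid_var, "timing", config.residual_scale)
    timing_day = np.round(config.timing_day_mean + config.timing_day_sd * timing_z)

    # fledgling count via a rounded latent; latent coefficients pre-scaled
    # so the standardized count carries the configured coefficient
    infl = _count_inflation(config)
    sys_f = infl * (
        config.beta("timing", "fledglings") * timing_z
        + np.array([config.year_effect("fledglings", yi) for yi in yi_arr])
    )
    latent_f = sys_f + _topped_noise(rng, sys_f, 0.0, config.min_resid_var, "fledglings", config.residual_scale)
    clutch = np.clip(
        np.round(config.clutch_mean + config.clutch_sd * latent_f), 1, 8
    ).astype(int)

    # brood manipulation among four-egg clutches
    arms = np.array(["control"] * n_nests, dtype=object)
    arm_names = list(config.arm_probs)
    arm_p = np.array([config.arm_probs[a] for a in arm_names])
    four = np.where(clutch == 4)[0]
    draws = rng.choice(len(arm_names), size=len(four), p=arm_p)
    arms[four] = [arm_names[d] for d in draws]
    brood = clutch.copy()
    for idx in four:
        brood[idx] = config.arm_brood[arms[idx]]
    manipulated = np.array([a != "control" for a in arms]) & (clutch == 4)

    # standardized observed count drives the downstream equations
    brood_z = _zscore(brood)

    # extra per-arm mass effect (grams) so the total causal contrast vs
    # control equals the configured experimental effect; the brood-size
    # path itself already moves mass by beta per standardized nestling
    sd_count = float(np.std(brood, ddof=1))
    per_nestling_g = (
        -config.beta("fledglings", "nestling_mass") / sd_count
    ) * config.nestling_mass_g_sd
    extra_g = {
        "control": 0.0,
        "reduced": config.brood_reduction_effect_g - per_nestling_g,
        "enlarged": config.brood_enlargement_effect_g + per_nestling_g,
    }

    u_nest_tar = rng.normal(0.0, config.sd_nest, n_nests)
    u_nest_mass = rng.normal(0.0, config.sd_nest, n_nests)

    nestling_rows = []
    for j, rec in enumerate(nest_records):
        for c in range(brood[j]):
            nestling_rows.append((j, f"{rec['nest']}-c{c + 1}"))
    nest_of = np.array([j for j, _ in nestling_rows])

    # per-nestling tarsus
    sys_tar = (
        config.beta("fledglings", "tarsus_nest") * brood_z[nest_of]
        + config.beta("timing", "tarsus_nest") * timing_z[nest_of]
        + np.array([config.year_effect("tarsus_nest", yi) for yi in yi_arr[nest_of]])
        + u_nest_tar[nest_of]
    )
    tarsus_z = sys_tar + _topped_noise(
        rng, sys_tar, 0.0, config.min_resid_var, "tarsus_nest", config.residual_scale
    )
    tarsus_mm = np.round(
        config.tarsus_nest_mm_mean + config.tarsus_nest_mm_sd * tarsus_z, 1
    )

    sys_m = (
        config.beta("fledglings", "nestling_mass") * brood_z[nest_of]
        + config.beta("timing", "nestling_mass") * timing_z[nest_of]
        + config.beta("tarsus_nest", "nestling_mass") * tarsus_z
        + np.array([config.year_effect("nestling_mass", yi) for yi in yi_arr[nest_of]])
        + u_nest_mass[nest_of]
    )
    mass_z = sys_m + _topped_noise(
        rng, sys_m, 0.0, config.min_resid_var, "nestling_mass", config.residual_scale
    )
    mass_g = config.nestling_mass_g_mean + config.nestling_mass_g_sd * mass_z
    mass_g = mass_g + np.array(
        [extra_g[arms[j]] if manipulated[j] else 0.0 for j in nest_of]
    )
    mass_g = np.round(mass_g, 1)

    for i, (j, nid) in enumerate(nestling_rows):
        rec = nest_records[j]
        rows.append(
            {
                "individual": nid,
                "nest": rec["nest"],
                "mother": rec["mother"],
                "year": rec["year"],
                "timing_day": timing_day[j],
                "clutch": clutch[j],
                "fledglings": brood[j],
                "treatment": arms[j],
                "tarsus_mm": tarsus_mm[i],
                "mass_g": mass_g[i],
            }
        )
        truth_rows.append(
            {
                "individual": nid,
                "nest": rec["nest"],
                "timing_z": timing_z[j],
                "fledglings_z": brood_z[j],
                "tarsus_nest_z": tarsus_z[i],
                "nestling_mass_z": mass_z[i],
                "manipulated": bool(manipulated[j]),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# pre-migratory captures
# ---------------------------------------------------------------------------


def simulate_premigratory(config: SimulationConfig, nestlings: pd.DataFrame):
    """Capture table (repeated rows per captured juvenile) + truth table.

    Breeding-stage standardized values are recomputed from the observed
    nestling table, matching what the analysis pipeline sees.
    """
    rng = _rng(config, 2)
    years = config.years()
    year_index = {y: i for i, y in enumerate(years)}

    captured = rng.random(len(nestlings)) < config.capture_prob
    idx = np.where(captured)[0]
    if len(idx) < 5:
        raise ValueError("capture probability too low: almost no juveniles captured")

    n_caps = np.clip(
        config.capture_min + rng.poisson(
            max(config.capture_mean - config.capture_min, 0.0), size=len(idx)
        ),
        config.capture_min,
        config.capture_max,
    )

    # per-individual quantities
    u_nest = {}
    rows_ind = []
    for k, i in enumerate(idx):
        rec = nestlings.iloc[i]
        nest = rec["nest"]
        if nest not in u_nest:
            u_nest[nest] = rng.normal(0.0, config.sd_nest, size=4)  # ta, moult, tbw, fat
        rows_ind.append(
            {
                "row": i, "individual": rec["individual"], "nest": nest,
                "year": rec["year"], "yi": year_index[rec["year"]],
                "n_cap": n_caps[k],
            }
        )

    u_ind = rng.normal(0.0, config.sd_individual, size=(len(rows_ind), 3))  # moult, tbw, fat

    cap_ind = np.repeat(np.arange(len(rows_ind)), [r["n_cap"] for r in rows_ind])
    n_rows = len(cap_ind)
    date_z = rng.normal(0.0, 1.0, n_rows)
    time_z = rng.normal(0.0, 1.0, n_rows)

    # breeding covariates standardized over the capture rows, matching the
    # scale on which the analysis standardizes the capture table
    nest_row = np.array([rows_ind[k]["row"] for k in cap_ind])
    timing_c = _zscore(nestlings["timing_day"].to_numpy(float)[nest_row])
    mass_c = _zscore(nestlings["mass_g"].to_numpy(float)[nest_row])
    tarsus_nest_c = _zscore(nestlings["tarsus_mm"].to_numpy(float)[nest_row])

    # adult structural size: one value per individual
    first_cap = np.searchsorted(cap_ind, np.arange(len(rows_ind)))
    sys_ta = (
        config.beta("tarsus_nest", "tarsus_adult") * tarsus_nest_c[first_cap]
        + np.array([u_nest[r["nest"]][0] for r in rows_ind])
    )
    ta_z = sys_ta + _topped_noise(rng, sys_ta, 0.0, config.min_resid_var, "tarsus_adult", config.residual_scale)
    ta_mm = np.round(config.tarsus_adult_mm_mean + config.tarsus_adult_mm_sd * ta_z, 1)

    ta_c = ta_z[cap_ind]
    yi_c = np.array([rows_ind[k]["yi"] for k in cap_ind])
    u_nest_c = np.array([u_nest[rows_ind[k]["nest"]] for k in cap_ind])
    u_ind_c = u_ind[cap_ind]

    # moult: unit-variance latent thresholded at its quartiles; latent
    # coefficients inflated by the score-latent attenuation, which is
    # refined empirically (the latent is not exactly normal, so the
    # analytic factor is only the starting point).  The latent is centred
    # so the score is balanced across its bins, and the score is
    # sample-standardized exactly as the analysis will see it.
    eps_mo = rng.normal(0.0, 1.0, n_rows)
    fixed_mo = (
        config.beta("timing", "moult") * timing_c
        + config.beta("date", "moult") * date_z
        + np.array([config.year_effect("moult", yi) for yi in yi_c])
    )
    re_mo = u_nest_c[:, 1] + u_ind_c[:, 0]
    lam = MOULT_ATTENUATION
    for _ in range(3):
        sys_mo = fixed_mo / lam + re_mo
        var_sys = float(np.var(sys_mo))
        resid_var = max(1.0 - var_sys, config.min_resid_var)
        latent_mo = sys_mo + config.residual_scale * np.sqrt(resid_var) * eps_mo
        latent_mo = latent_mo - latent_mo.mean()
        cuts = np.quantile(latent_mo, [0.25, 0.5, 0.75])
        score = 1 + np.searchsorted(cuts, latent_mo)
        moult_s = _zscore(score)
        lam_emp = float(np.cov(latent_mo, moult_s)[0, 1] / np.var(latent_mo))
        if abs(lam_emp - lam) < 1e-4:
            break
        lam = lam_emp
    if resid_var <= config.min_resid_var:
        warnings.warn("moult: systematic variance near 1; residual clipped", stacklevel=2)

    # Lance-residualized date x timing interaction on the capture rows
    prod = date_z * timing_c
    design = np.column_stack([np.ones(n_rows), date_z, timing_c])
    coef, *_ = np.linalg.lstsq(design, prod, rcond=None)
    inter = prod - design @ coef
    sd_inter = np.std(inter, ddof=1)
    inter = inter / sd_inter if sd_inter > 1e-12 else inter

    sys_tbw = (
        config.beta("nestling_mass", "tbw") * mass_c
        + config.beta("timing", "tbw") * timing_c
        + config.beta("moult", "tbw") * moult_s
        + config.beta("moult^2", "tbw") * moult_s**2
        + config.beta("date", "tbw") * date_z
        + config.beta("time_captured", "tbw") * time_z
        + config.beta("tarsus_adult", "tbw") * ta_c
        + config.beta("date:timing", "tbw") * inter
        + np.array([config.year_effect("tbw", yi) for yi in yi_c])
        + u_nest_c[:, 2] + u_ind_c[:, 1]
    )
    tbw_z = sys_tbw + _topped_noise(rng, sys_tbw, 0.0, config.min_resid_var, "tbw", config.residual_scale)
    tbw_g = config.tbw_g_mean + config.tbw_g_sd * tbw_z

    sys_fat = (
        config.beta("nestling_mass", "fat") * mass_c
        + config.beta("timing", "fat") * timing_c
        + config.beta("moult", "fat") * moult_s
        + config.beta("date", "fat") * date_z
        + config.beta("time_captured", "fat") * time_z
        + config.beta("tarsus_adult", "fat") * ta_c
        + np.array([config.year_effect("fat", yi) for yi in yi_c])
        + u_nest_c[:, 3] + u_ind_c[:, 2]
    )
    fat_z = sys_fat + _topped_noise(rng, sys_fat, 0.0, config.min_resid_var, "fat", config.residual_scale)
    fat_g = np.maximum(config.fat_g_mean + config.fat_g_sd * fat_z, 0.05)

    lean_g = tbw_g / config.water_fraction_lean
    mass_obs = np.round(lean_g + fat_g + rng.normal(0.0, config.mass_noise_g, n_rows), 1)

    # isotope enrichments back-computed from true TBW plus plateau noise
    e_plat = np.array(
        [
            plateau_from_tbw(
                t, config.dose_mass_g, config.e_injectate,
                config.e_background, config.exchange_k,
            )
            for t in tbw_g
        ]
    )
    e_plat = e_plat * (1.0 + rng.normal(0.0, config.plateau_noise_rel, n_rows))

    date_day = np.round(config.capture_day_mean + config.capture_day_sd * date_z)
    hour = np.round(
        np.clip(config.capture_hour_mean + config.capture_hour_sd * time_z, 6.0, 19.0), 2
    )

    captures = pd.DataFrame(
        {
            "individual": [rows_ind[k]["individual"] for k in cap_ind],
            "nest": [rows_ind[k]["nest"] for k in cap_ind],
            "year": [rows_ind[k]["year"] for k in cap_ind],
            "date": date_day.astype(int),
            "time": hour,
            "mass_g": mass_obs,
            "tarsus_mm": ta_mm[cap_ind],
            "moult": score.astype(int),
            "W_g": config.dose_mass_g,
            "E_inj": config.e_injectate,
            "E_bkg": config.e_background,
            "E_plat": e_plat,
        }
    )
    truth = pd.DataFrame(
        {
            "individual": captures["individual"],
            "tbw_true_g": tbw_g,
            "fat_true_g": fat_g,
            "lean_true_g": lean_g,
            "tbw_z": tbw_z,
            "fat_z": fat_z,
            "moult_latent": latent_mo,
            "date_z": date_z,
            "time_z": time_z,
            "tarsus_adult_z": ta_c,
        }
    )
    return captures, truth


# ---------------------------------------------------------------------------
# first-year survival
# ---------------------------------------------------------------------------


def simulate_survival(config: SimulationConfig, nestlings: pd.DataFrame) -> pd.DataFrame:
    """Binary first-year survival per nestling from a logit GLMM."""
    rng = _rng(config, 3)
    years = sorted(nestlings["year"].astype(str).unique())
    mothers = sorted(nestlings["mother"].astype(str).unique())
    nests = sorted(nestlings["nest"].astype(str).unique())
    v_year = dict(zip(years, rng.normal(0.0, config.sd_year_survival, len(years))))
    v_mother = dict(zip(mothers, rng.normal(0.0, config.sd_mother_survival, len(mothers))))
    v_nest = dict(zip(nests, rng.normal(0.0, config.sd_nest_survival, len(nests))))

    dm = nestlings["mass_g"].to_numpy(float) - config.nestling_mass_g_mean
    dt = nestlings["timing_day"].to_numpy(float) - config.timing_day_mean
    dta = nestlings["tarsus_mm"].to_numpy(float) - config.tarsus_nest_mm_mean
    eta = (
        config.survival_intercept
        + config.survival_slope_mass * dm
        + config.survival_slope_timing * dt
        + config.survival_slope_tarsus * dta
        + config.survival_slope_tarsus2 * dta**2
        + nestlings["year"].astype(str).map(v_year).to_numpy()
        + nestlings["mother"].astype(str).map(v_mother).to_numpy()
        + nestlings["nest"].astype(str).map(v_nest).to_numpy()
    )
    survived = rng.binomial(1, special.expit(eta))
    return pd.DataFrame(
        {
            "individual": nestlings["individual"],
            "nest": nestlings["nest"],
            "mother": nestlings["mother"],
            "year": nestlings["year"],
            "survived": survived,
        }
    )


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    nestlings: pd.DataFrame
    captures: pd.DataFrame
    survival: pd.DataFrame
    truth_breeding: pd.DataFrame
    truth_captures: pd.DataFrame
    config: SimulationConfig

    def analysis_tables(self) -> dict[str, pd.DataFrame]:
        """Tables as the analysis sees them (no truth columns)."""
        return {
            "nestlings": self.nestlings,
            "captures": self.captures,
            "survival": self.survival,
        }


def simulate_study(config: SimulationConfig) -> StudyData:
    nestlings, truth_b = simulate_breeding(config)
    captures, truth_c = simulate_premigratory(config, nestlings)
    survival = simulate_survival(config, nestlings)
    return StudyData(nestlings, captures, survival, truth_b, truth_c, config)
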