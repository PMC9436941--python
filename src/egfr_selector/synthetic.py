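"""Synthetic CKD cohorts with a planted equation-selection structure.

Covariate marginals default to the study-population profile this package
targets (mean age ~60.6 y, 63.3% male, diabetic-nephropathy prevalence
14.3%, RASi use 31.3%, median measured GFR ~27.7 mL/min/1.73 m^2, BSA
~N(1.7, 0.15), BMI ~N(25, 3.5), right-skewed 24-h urine protein).

Each synthetic patient carries a *hidden* best-equation label determined by
an ordered first-match rule list over the covariates.  Biomarkers are then
manufactured by inverting the monotone estimation equations so that the
planted equation lands close to the measured GFR (small multiplicative
log-normal noise) while the competing candidates are pushed off target
(larger noise).  Under the default configuration the best-match labeling
stage recovers the hidden label for >= 85% of rows, so the full pipeline
(labeling -> tree -> dispatch) is testable end to end without any real
patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Any, Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .equations import (
    CANDIDATE_EQUATIONS,
    EquationId,
    MG_DL_TO_UMOL_L,
    PatientRecord,
    Sex,
    denormalize_gfr,
    du_bois_bsa,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticRecord",
    "PlantedRule",
    "default_rules",
    "sample_covariates",
    "plant_equation_label",
    "invert_equation",
    "generate_cohort",
]

# within-level relative frequencies of the non-diabetic-nephropathy
# pathology categories (13 levels in total incl. diabetic_nephropathy,
# deliberately above the exhaustive-subset cutoff of the tree)
_OTHER_PATHOLOGY = {
    "without_renal_biopsy": 0.730,
    "igan": 0.083,
    "hyperuricemic_nephropathy": 0.043,
    "hypertensive_kidney_injury": 0.036,
    "mspgn": 0.031,
    "mn": 0.015,
    "lupus_nephritis": 0.012,
    "polycystic_kidney": 0.010,
    "fsgs": 0.010,
    "hsp": 0.010,
    "mcd": 0.010,
    "mpgn": 0.010,
}

_DEFAULT_PREVALENCES = {
    "diabetes": 0.317,
    "smoking": 0.193,
    "drinking": 0.139,
    "unilateral_nephrectomy": 0.027,
    "edema": 0.382,
    "gout": 0.127,
    "hyperuricemia": 0.183,
    "cardiovascular_disease": 0.137,
    "cerebral_infarction": 0.071,
    "cerebral_hemorrhage": 0.010,
    "cancer": 0.050,
    "calcium_dobesilate": 0.081,
    "sglt2i": 0.017,
    "beraprost": 0.050,
    "glucocorticoid": 0.085,
    "immunosuppressor": 0.118,
    "diuretic": 0.390,
}

_HTN_GRADES = ("none", "grade1", "grade2", "grade3")
_HTN_PROBS = (0.139, 0.191, 0.203, 0.467)


def _log_params(p25: float, p75: float) -> Tuple[float, float]:
    """Log-normal (mu, sigma) matching a given quartile pair."""
    mu = (math.log(p25) + math.log(p75)) / 2.0
    sigma = (math.log(p75) - math.log(p25)) / (2.0 * 0.6744897501960817)
    return mu, sigma


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the target cohort profile."""

    n: int = 518
    seed: int = 0

    age_mean: float = 60.6
    age_sd: float = 12.0
    age_min: float = 18.0
    age_max: float = 95.0
    male_fraction: float = 0.633

    bsa_mean: float = 1.70
    bsa_sd: float = 0.15
    bsa_min: float = 1.20
    bsa_max: float = 2.40
    bmi_mean: float = 25.0
    bmi_sd: float = 3.5
    bmi_min: float = 15.0
    bmi_max: float = 40.0

    dn_prevalence: float = 0.143
    rasi_prevalence: float = 0.313
    prevalences: Dict[str, float] = dc_field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )

    # 24-h urine protein (mg): log-normal matched to quartiles 224-2782
    urine_protein_p25: float = 224.0
    urine_protein_p75: float = 2782.0
    # 24-h urine volume (L): quartiles 1.2-2.1
    urine_volume_p25: float = 1.2
    urine_volume_p75: float = 2.1
    # urea nitrogen (mmol/L): quartiles 9.1-21.9
    bun_p25: float = 9.1
    bun_p75: float = 21.9
    alb_mean: float = 35.1
    alb_sd: float = 5.0

    # measured GFR on the normalized scale: log-normal, median ~27.7
    sgfr_median: float = 27.7
    sgfr_log_sigma: float = 0.655
    sgfr_min: float = 2.0
    sgfr_max: float = 120.0

    # planted-rule thresholds
    rule_age: float = 65.0
    rule_bsa: float = 1.65
    rule_bmi: float = 22.0

    # multiplicative log-normal noise scales for biomarker targets; the
    # off-target scale must be much larger than the on-target scale because
    # the BIS-2 and CKD-EPI(Cr-CysC) exponent vectors are nearly collinear,
    # which shrinks cross-equation separation by roughly a factor of seven
    noise_planted: float = 0.015
    noise_other: float = 0.60

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("male_fraction", "dn_prevalence", "rasi_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name, v in self.prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence {name!r} must be in [0, 1], got {v!r}")
        if not self.noise_planted > 0 or not self.noise_other > 0:
            raise ValueError("noise scales must be positive")
        if self.noise_planted > self.noise_other:
            raise ValueError("noise_planted must not exceed noise_other")


@dataclass
class SyntheticRecord(PatientRecord):
    """A patient record carrying the planted ground-truth equation."""

    hidden_label: Optional[EquationId] = None


@dataclass(frozen=True)
class PlantedRule:
    name: str
    predicate: Callable[[Mapping[str, Any]], bool]
    equation: EquationId


def default_rules(config: Optional[SyntheticConfig] = None) -> List[PlantedRule]:
    """Ordered, exhaustive first-match rule set planting the selector
    structure: diabetic nephropathy -> BIS-2; elderly RASi users -> Ruijin;
    small body habitus -> CKD-EPI(Cr-CysC); everyone else -> CKD-EPI(CysC)."""
    cfg = config or SyntheticConfig()
    return [
        PlantedRule(
            "diabetic_nephropathy",
            lambda r: bool(r["diabetic_nephropathy"]),
            EquationId.BIS2,
        ),
        PlantedRule(
            "rasi_elderly",
            lambda r: bool(r["rasi"]) and r["age"] > cfg.rule_age,
            EquationId.RUIJIN,
        ),
        PlantedRule(
            "small_body",
            lambda r: r["bsa"] < cfg.rule_bsa or r["bmi"] < cfg.rule_bmi,
            EquationId.CKD_EPI_CR_CYSC,
        ),
        PlantedRule("default", lambda r: True, EquationId.CKD_EPI_CYSC),
    ]


def plant_equation_label(
    covariates: Mapping[str, Any], rules: Sequence[PlantedRule]
) -> EquationId:
    """First matching rule wins; raises if no rule matches."""
    for rule in rules:
        if rule.predicate(covariates):
            return rule.equation
    raise ValueError("rule set is not exhaustive: no rule matched")


# ---------------------------------------------------------------------------
# covariate sampling
# ---------------------------------------------------------------------------

def _trunc_normal(rng, n, mean, sd, lo, hi) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _height_weight_from_bsa_bmi(bsa: np.ndarray, bmi: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    # Du Bois BSA with weight = BMI*(h/100)^2 collapses to a power of height
    height = (bsa * 100.0**0.85 / (0.007184 * bmi**0.425)) ** (1.0 / 1.575)
    weight = bmi * (height / 100.0) ** 2
    return height, weight


def sample_covariates(
    n: int, seed: int, config: Optional[SyntheticConfig] = None
) -> pd.DataFrame:
    """Draw the covariate table (no biomarkers, no measured GFR)."""
    cfg = config or SyntheticConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    age = _trunc_normal(rng, n, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max)
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    bsa = _trunc_normal(rng, n, cfg.bsa_mean, cfg.bsa_sd, cfg.bsa_min, cfg.bsa_max)
    bmi = _trunc_normal(rng, n, cfg.bmi_mean, cfg.bmi_sd, cfg.bmi_min, cfg.bmi_max)
    height, weight = _height_weight_from_bsa_bmi(bsa, bmi)

    frame = pd.DataFrame(
        {
            "patient_id": [f"S{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "height": height,
            "weight": weight,
        }
    )

    # renal pathology: diabetic nephropathy at its configured prevalence,
    # remaining mass split over the other categories
    others = list(_OTHER_PATHOLOGY)
    other_w = np.array([_OTHER_PATHOLOGY[k] for k in others])
    other_w = other_w / other_w.sum()
    is_dn = rng.random(n) < cfg.dn_prevalence
    other_draw = rng.choice(len(others), size=n, p=other_w)
    pathology = np.where(is_dn, "diabetic_nephropathy", np.array(others)[other_draw])
    frame["renal_pathology"] = pathology
    frame["diabetic_nephropathy"] = is_dn.astype(int)

    frame["rasi"] = (rng.random(n) < cfg.rasi_prevalence).astype(int)
    for name, p in cfg.prevalences.items():
        frame[name] = (rng.random(n) < p).astype(int)

    frame["hypertension_grade"] = rng.choice(_HTN_GRADES, size=n, p=_HTN_PROBS)

    mu, sigma = _log_params(cfg.urine_protein_p25, cfg.urine_protein_p75)
    frame["urine_protein_24h"] = rng.lognormal(mu, sigma, n)
    mu, sigma = _log_params(cfg.urine_volume_p25, cfg.urine_volume_p75)
    frame["urine_volume_24h"] = rng.lognormal(mu, sigma, n)
    return frame


# ---------------------------------------------------------------------------
# equation inversion
# ---------------------------------------------------------------------------

def _sex_enum(sex) -> Sex:
    return Sex(sex)


def _power_law_cr(target: float, coeff: float, cr_exp: float) -> float:
    # target = coeff * cr**cr_exp  with cr_exp < 0
    return (target / coeff) ** (1.0 / cr_exp)


def _ckd_epi_piecewise(target: float, c: float, knot: float, a_low: float, a_high: float, age_term: float) -> float:
    """Solve c * (x/knot)**a * age_term = target for x, a branch-dependent."""
    v_knot = c * age_term
    a = a_low if target >= v_knot else a_high
    return knot * (target / v_knot) ** (1.0 / a)


def invert_equation(
    equation: EquationId,
    target_egfr: float,
    *,
    age: float,
    sex,
    cysc: Optional[float] = None,
    scr_mgdl: Optional[float] = None,
) -> float:
    """Biomarker value at which ``equation`` reproduces ``target_egfr``.

    Creatinine-solving equations return creatinine in mg/dL (including
    Xiangya, whose internal umol/L form is converted back); cystatin-
    solving equations return cystatin C in mg/L.  For the two-biomarker
    equations (BIS-2, CKD-EPI(Cr-CysC)) exactly one of ``cysc`` /
    ``scr_mgdl`` must be supplied and the other is solved for.
    """
    equation = EquationId(equation)
    if not target_egfr > 0:
        raise ValueError(f"target eGFR must be positive, got {target_egfr!r}")
    female = _sex_enum(sex) is Sex.FEMALE

    if equation is EquationId.MACISAAC:
        if target_egfr <= -4.2:  # pragma: no cover - guarded by positivity
            raise ValueError("target below the attainable range of MacIsaac")
        return 86.700 / (target_egfr + 4.200)

    if equation is EquationId.RUIJIN:
        coeff = 234.960 * age**-0.280 * (0.828 if female else 1.0)
        return _power_law_cr(target_egfr, coeff, -0.926)

    if equation is EquationId.XIANGYA:
        coeff = 2374.780 * age**-0.25011 * (0.8526126 if female else 1.0)
        cr_umol = _power_law_cr(target_egfr, coeff, -0.54753)
        return cr_umol / MG_DL_TO_UMOL_L

    if equation is EquationId.ABBREV_MDRD:
        coeff = 175.0 * age**-0.203 * (0.742 if female else 1.0)
        return _power_law_cr(target_egfr, coeff, -1.154)

    if equation is EquationId.CN_ABBREV_MDRD:
        coeff = 170.0 * age**-0.176 * 1.202 * (0.762 if female else 1.0)
        return _power_law_cr(target_egfr, coeff, -0.999)

    if equation is EquationId.CKD_EPI_CR:
        c, knot, a_low = (144.0, 0.7, -0.329) if female else (141.0, 0.9, -0.411)
        return _ckd_epi_piecewise(target_egfr, c, knot, a_low, -1.209, 0.993**age)

    if equation is EquationId.ASIAN_CKD_EPI_CR:
        c, knot, a_low = (151.0, 0.7, -0.328) if female else (149.0, 0.9, -0.415)
        return _ckd_epi_piecewise(target_egfr, c, knot, a_low, -1.210, 0.993**age)

    if equation is EquationId.CKD_EPI_CYSC:
        c = 133.0 * (0.932 if female else 1.0)
        return _ckd_epi_piecewise(target_egfr, c, 0.8, -0.499, -1.328, 0.996**age)

    if equation is EquationId.BIS2:
        coeff = 767.0 * age**-0.570 * (0.870 if female else 1.0)
        if (cysc is None) == (scr_mgdl is None):
            raise ValueError("provide exactly one of cysc / scr_mgdl for BIS-2")
        if scr_mgdl is not None:
            return (target_egfr / (coeff * scr_mgdl**-0.400)) ** (1.0 / -0.610)
        return (target_egfr / (coeff * cysc**-0.610)) ** (1.0 / -0.400)

    if equation is EquationId.CKD_EPI_CR_CYSC:
        c, knot, a_low = (130.0, 0.7, -0.248) if female else (135.0, 0.9, -0.207)
        age_term = 0.995**age
        if (cysc is None) == (scr_mgdl is None):
            raise ValueError("provide exactly one of cysc / scr_mgdl for CKD-EPI(Cr-CysC)")
        if scr_mgdl is not None:
            a = a_low if scr_mgdl <= knot else -0.601
            base = c * (scr_mgdl / knot) ** a * age_term
            b = -0.375 if target_egfr >= base else -0.711
            return 0.8 * (target_egfr / base) ** (1.0 / b)
        b = -0.375 if cysc <= 0.8 else -0.711
        base = c * (cysc / 0.8) ** b * age_term
        a = a_low if target_egfr >= base else -0.601
        return knot * (target_egfr / base) ** (1.0 / a)

    raise ValueError(f"no analytic inverse implemented for {equation.value}")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _biomarkers_for_row(
    label: EquationId,
    sgfr_norm: float,
    age: float,
    sex: str,
    eps_small: Tuple[float, float],
    eps_large: Tuple[float, float],
) -> Tuple[float, float]:
    """(creatinine mg/dL, cystatin C mg/L) anchoring the planted equation
    near the measured GFR and the competitors away from it."""
    e_s_cr, e_s_cys = eps_small
    e_l_cr, e_l_cys = eps_large
    if label is EquationId.RUIJIN:
        cr = invert_equation(EquationId.RUIJIN, sgfr_norm * math.exp(e_s_cr), age=age, sex=sex)
        cys = invert_equation(EquationId.CKD_EPI_CYSC, sgfr_norm * math.exp(e_l_cys), age=age, sex=sex)
    elif label is EquationId.CKD_EPI_CYSC:
        cys = invert_equation(EquationId.CKD_EPI_CYSC, sgfr_norm * math.exp(e_s_cys), age=age, sex=sex)
        cr = invert_equation(EquationId.RUIJIN, sgfr_norm * math.exp(e_l_cr), age=age, sex=sex)
    else:
        # two-biomarker targets: creatinine gets a large off-target shift and
        # cystatin C is solved so the planted equation itself stays on target
        cr = invert_equation(EquationId.RUIJIN, sgfr_norm * math.exp(e_l_cr), age=age, sex=sex)
        cys = invert_equation(
            label, sgfr_norm * math.exp(e_s_cys), age=age, sex=sex, scr_mgdl=cr
        )
    return cr, cys


def generate_cohort(
    config: Optional[SyntheticConfig] = None,
    rules: Optional[Sequence[PlantedRule]] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Generate a full synthetic cohort.

    Returns
    -------
    (frame, hidden_labels)
        ``frame`` follows the cohort CSV contract (creatinine stored in
        umol/L) and ``hidden_labels`` holds the planted equation name per
        row, index-aligned with ``frame`` (kept out of the frame so the main
        file matches the real-data contract).
    """
    cfg = config or SyntheticConfig()
    rules = list(rules) if rules is not None else default_rules(cfg)
    rng = np.random.default_rng(cfg.seed)

    frame = sample_covariates(cfg.n, cfg.seed + 1, cfg)
    bsa = np.array([du_bois_bsa(w, h) for w, h in zip(frame["weight"], frame["height"])])
    bmi = frame["weight"] / (frame["height"] / 100.0) ** 2

    mu_g = math.log(cfg.sgfr_median)
    sgfr_norm = np.clip(
        rng.lognormal(mu_g, cfg.sgfr_log_sigma, cfg.n), cfg.sgfr_min, cfg.sgfr_max
    )

    mu_b, sig_b = _log_params(cfg.bun_p25, cfg.bun_p75)
    bun = rng.lognormal(mu_b, sig_b, cfg.n)
    alb = _trunc_normal(rng, cfg.n, cfg.alb_mean, cfg.alb_sd, 15.0, 55.0)

    eps_small = rng.normal(0.0, cfg.noise_planted, size=(cfg.n, 2))
    eps_large = rng.normal(0.0, cfg.noise_other, size=(cfg.n, 2))

    labels: List[str] = []
    scr_umol = np.empty(cfg.n)
    cysc = np.empty(cfg.n)
    for i in range(cfg.n):
        row = {
            "diabetic_nephropathy": frame["diabetic_nephropathy"].iloc[i],
            "rasi": frame["rasi"].iloc[i],
            "age": frame["age"].iloc[i],
            "bsa": bsa[i],
            "bmi": float(bmi.iloc[i]),
        }
        label = plant_equation_label(row, rules)
        labels.append(label.value)
        cr_mgdl, cys = _biomarkers_for_row(
            label,
            float(sgfr_norm[i]),
            float(frame["age"].iloc[i]),
            frame["sex"].iloc[i],
            tuple(eps_small[i]),
            tuple(eps_large[i]),
        )
        scr_umol[i] = cr_mgdl * MG_DL_TO_UMOL_L
        cysc[i] = cys

    frame["scr"] = scr_umol
    frame["scr_unit"] = "umol/L"
    frame["cysc"] = cysc
    frame["bun"] = bun
    frame["alb"] = alb
    frame["sgfr_abs"] = [denormalize_gfr(g, b) for g, b in zip(sgfr_norm, bsa)]

    from .cohort import COHORT_COLUMNS

    ordered = [c for c in COHORT_COLUMNS if c in frame.columns]
    frame = frame[ordered + [c for c in frame.columns if c not in ordered]]
    hidden = pd.Series(labels, name="hidden_label", index=frame.index)
    return frame, hidden


def generate_records(
    config: Optional[SyntheticConfig] = None,
    rules: Optional[Sequence[PlantedRule]] = None,
) -> List[SyntheticRecord]:
    """Like :func:`generate_cohort` but materialized as records carrying
    their hidden label."""
    from .cohort import frame_to_records

    frame, hidden = generate_cohort(config, rules)
    out = []
    for rec, lab in zip(frame_to_records(frame), hidden):
        out.append(
            SyntheticRecord(
                patient_id=rec.patient_id,
                age=rec.age,
                sex=rec.sex,
                height=rec.height,
                weight=rec.weight,
                scr=rec.scr,
                scr_unit=rec.scr_unit,
                cysc=rec.cysc,
                bun=rec.bun,
                alb=rec.alb,
                sgfr_abs=rec.sgfr_abs,
                covariates=rec.covariates,
                hidden_label=EquationId(lab),
            )
        )
    return out
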