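"""Glomerular filtration rate estimation equations.

This module implements thirteen published eGFR equations over a common
:class:`PatientRecord` type, together with the unit conversions they need
(serum creatinine mg/dL <-> umol/L, Du Bois body surface area, and
normalization of absolute GFR to the 1.73 m^2 reference body surface area).

Creatinine is internally converted to mg/dL for every equation except
Xiangya, which consumes umol/L.  Cockcroft-Gault yields mL/min and is
normalized to mL/min/1.73 m^2 through the record's body surface area; all
other equations already report on the normalized scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping, Optional

__all__ = [
    "Sex",
    "EquationId",
    "CANDIDATE_EQUATIONS",
    "PatientRecord",
    "EgfrValue",
    "EquationPanel",
    "MissingInputError",
    "InvalidInputError",
    "convert_creatinine",
    "du_bois_bsa",
    "body_mass_index",
    "normalize_gfr",
    "denormalize_gfr",
    "estimate_egfr",
    "estimate_all",
    "required_inputs",
]

#: 1 mg/dL serum creatinine expressed in umol/L.
MG_DL_TO_UMOL_L = 88.4

#: 1 mmol/L urea nitrogen expressed in mg/dL (used to feed the MDRD family,
#: which was published against conventional units).
BUN_MMOL_L_TO_MG_DL = 2.801

#: Reference body surface area (m^2) for normalized GFR reporting.
REFERENCE_BSA = 1.73

CREATININE_UNITS = ("mg/dL", "umol/L")
_UNIT_ALIASES = {
    "mg/dl": "mg/dL",
    "umol/l": "umol/L",
    "μmol/l": "umol/L",  # μmol/L
    "µmol/l": "umol/L",  # µmol/L
}


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class EquationId(str, enum.Enum):
    """Identifiers for the thirteen estimation equations."""

    COCKCROFT_GAULT = "cockcroft_gault"
    MDRD = "mdrd"
    ABBREV_MDRD = "abbrev_mdrd"
    CN_MDRD = "cn_mdrd"
    CN_ABBREV_MDRD = "cn_abbrev_mdrd"
    CKD_EPI_CR = "ckd_epi_cr"
    CKD_EPI_CYSC = "ckd_epi_cysc"
    CKD_EPI_CR_CYSC = "ckd_epi_cr_cysc"
    ASIAN_CKD_EPI_CR = "asian_ckd_epi_cr"
    BIS2 = "bis2"
    MACISAAC = "macisaac"
    RUIJIN = "ruijin"
    XIANGYA = "xiangya"


#: The four equations the selector chooses among.  The tuple order is also
#: the fixed tie-breaking priority used throughout the package.
CANDIDATE_EQUATIONS = (
    EquationId.BIS2,
    EquationId.CKD_EPI_CYSC,
    EquationId.CKD_EPI_CR_CYSC,
    EquationId.RUIJIN,
)


class MissingInputError(ValueError):
    """A biomarker or demographic field required by an equation is absent."""

    def __init__(self, field_name: str, equation: Optional["EquationId"] = None):
        self.field_name = field_name
        self.equation = equation
        where = f" for {equation.value}" if equation is not None else ""
        super().__init__(f"missing required input '{field_name}'{where}")


class InvalidInputError(ValueError):
    """An input value violates its domain (non-positive biomarker, bad unit)."""


def _canonical_unit(unit: str) -> str:
    u = _UNIT_ALIASES.get(unit.lower(), unit)
    if u not in CREATININE_UNITS:
        raise InvalidInputError(
            f"unknown creatinine unit {unit!r}; expected one of {CREATININE_UNITS}"
        )
    return u


def convert_creatinine(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a serum creatinine concentration between mg/dL and umol/L.

    The exact factor 88.4 umol/L per mg/dL is applied; conversion between
    identical units is the identity.
    """
    if not value > 0:
        raise InvalidInputError(f"creatinine must be positive, got {value!r}")
    src, dst = _canonical_unit(from_unit), _canonical_unit(to_unit)
    if src == dst:
        return value
    if src == "mg/dL":  # -> umol/L
        return value * MG_DL_TO_UMOL_L
    return value / MG_DL_TO_UMOL_L


def du_bois_bsa(weight: float, height: float) -> float:
    """Du Bois body surface area (m^2) from weight (kg) and height (cm)."""
    if not weight > 0:
        raise InvalidInputError(f"weight must be positive, got {weight!r}")
    if not height > 0:
        raise InvalidInputError(f"height must be positive, got {height!r}")
    return weight**0.425 * height**0.725 * 0.007184


def body_mass_index(weight: float, height: float) -> float:
    """BMI (kg/m^2) from weight (kg) and height (cm)."""
    if not weight > 0 or not height > 0:
        raise InvalidInputError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


def normalize_gfr(gfr_abs: float, bsa: float) -> float:
    """Scale an absolute GFR (mL/min) to mL/min per 1.73 m^2."""
    if not bsa > 0:
        raise InvalidInputError(f"body surface area must be positive, got {bsa!r}")
    if gfr_abs < 0:
        raise InvalidInputError(f"GFR must be non-negative, got {gfr_abs!r}")
    return gfr_abs * REFERENCE_BSA / bsa


def denormalize_gfr(gfr_norm: float, bsa: float) -> float:
    """Inverse of :func:`normalize_gfr`."""
    if not bsa > 0:
        raise InvalidInputError(f"body surface area must be positive, got {bsa!r}")
    return gfr_norm * bsa / REFERENCE_BSA


@dataclass
class PatientRecord:
    """One subject: demographics, biomarkers, covariates and measured GFR.

    ``scr`` is stored with its unit (``scr_unit`` in {mg/dL, umol/L});
    ``cysc`` is mg/L, ``bun`` mmol/L, ``alb`` g/L, ``sgfr_abs`` mL/min.
    Clinical covariates (flags, categories, 24-h urine measurements, ...)
    live in the ``covariates`` mapping.
    """

    patient_id: str
    age: float
    sex: Sex
    height: float
    weight: float
    scr: float
    scr_unit: str = "umol/L"
    cysc: Optional[float] = None
    bun: Optional[float] = None
    alb: Optional[float] = None
    sgfr_abs: Optional[float] = None
    covariates: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.scr_unit = _canonical_unit(self.scr_unit)
        if self.age < 18:
            raise InvalidInputError(f"age must be >= 18, got {self.age!r}")
        if not self.height > 0 or not self.weight > 0:
            raise InvalidInputError("height and weight must be positive")
        if not self.scr > 0:
            raise InvalidInputError(f"creatinine must be positive, got {self.scr!r}")
        for name in ("cysc", "bun", "alb", "sgfr_abs"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidInputError(f"{name} must be positive, got {v!r}")

    @property
    def bsa(self) -> float:
        return du_bois_bsa(self.weight, self.height)

    @property
    def bmi(self) -> float:
        return body_mass_index(self.weight, self.height)

    @property
    def scr_mgdl(self) -> float:
        return convert_creatinine(self.scr, self.scr_unit, "mg/dL")

    @property
    def scr_umoll(self) -> float:
        return convert_creatinine(self.scr, self.scr_unit, "umol/L")

    @property
    def sgfr_norm(self) -> Optional[float]:
        """Measured GFR normalized to 1.73 m^2, if measured."""
        if self.sgfr_abs is None:
            return None
        return normalize_gfr(self.sgfr_abs, self.bsa)


@dataclass(frozen=True)
class EgfrValue:
    """An estimated GFR in mL/min per 1.73 m^2, tagged with its equation."""

    value: float
    equation: EquationId


# ---------------------------------------------------------------------------
# the thirteen equations
# ---------------------------------------------------------------------------

_REQUIRED: Dict[EquationId, tuple] = {
    EquationId.COCKCROFT_GAULT: ("scr",),
    EquationId.MDRD: ("scr", "bun", "alb"),
    EquationId.ABBREV_MDRD: ("scr",),
    EquationId.CN_MDRD: ("scr", "bun", "alb"),
    EquationId.CN_ABBREV_MDRD: ("scr",),
    EquationId.CKD_EPI_CR: ("scr",),
    EquationId.CKD_EPI_CYSC: ("cysc",),
    EquationId.CKD_EPI_CR_CYSC: ("scr", "cysc"),
    EquationId.ASIAN_CKD_EPI_CR: ("scr",),
    EquationId.BIS2: ("scr", "cysc"),
    EquationId.MACISAAC: ("cysc",),
    EquationId.RUIJIN: ("scr",),
    EquationId.XIANGYA: ("scr",),
}


def required_inputs(equation: EquationId) -> tuple:
    """Biomarker fields an equation needs beyond age/sex/height/weight."""
    return _REQUIRED[EquationId(equation)]


def _female(record: PatientRecord) -> bool:
    return record.sex is Sex.FEMALE


def _cockcroft_gault(record: PatientRecord, cg_numerator: str) -> float:
    if cg_numerator == "weight":
        mass = record.weight
    elif cg_numerator == "height_as_printed":
        mass = record.height
    else:
        raise InvalidInputError(
            f"cg_numerator must be 'weight' or 'height_as_printed', got {cg_numerator!r}"
        )
    gfr_abs = (140.0 - record.age) * mass / (record.scr_mgdl * 72.0)
    if _female(record):
        gfr_abs *= 0.85
    # computed in mL/min; report on the 1.73 m^2 scale like every other equation
    return normalize_gfr(gfr_abs, record.bsa)


def _mdrd_inputs(record: PatientRecord, si_units: bool) -> tuple:
    bun = record.bun
    alb = record.alb
    if si_units:
        bun = bun * BUN_MMOL_L_TO_MG_DL  # mmol/L -> mg/dL
        alb = alb / 10.0  # g/L -> g/dL
    return bun, alb


def _mdrd(record: PatientRecord, si_units: bool, chinese: bool) -> float:
    bun, alb = _mdrd_inputs(record, si_units)
    v = (
        170.0
        * record.scr_mgdl**-0.999
        * record.age**-0.176
        * bun**-0.170
        * alb**0.318
    )
    if chinese:
        v *= 1.202
    if _female(record):
        v *= 0.762
    return v


def _abbrev_mdrd(record: PatientRecord) -> float:
    v = 175.0 * record.scr_mgdl**-1.154 * record.age**-0.203
    if _female(record):
        v *= 0.742
    return v


def _cn_abbrev_mdrd(record: PatientRecord) -> float:
    # printed without the bun/alb terms of the full Chinese modification
    v = 170.0 * record.scr_mgdl**-0.999 * record.age**-0.176 * 1.202
    if _female(record):
        v *= 0.762
    return v


def _ckd_epi_cr(record: PatientRecord) -> float:
    cr = record.scr_mgdl
    if _female(record):
        c, knot, a_low = 144.0, 0.7, -0.329
    else:
        c, knot, a_low = 141.0, 0.9, -0.411
    a = a_low if cr <= knot else -1.209
    return c * (cr / knot) ** a * 0.993**record.age


def _ckd_epi_cysc(record: PatientRecord) -> float:
    cysc = record.cysc
    a = -0.499 if cysc <= 0.8 else -1.328
    v = 133.0 * (cysc / 0.8) ** a * 0.996**record.age
    if _female(record):
        v *= 0.932
    return v


def _ckd_epi_cr_cysc(record: PatientRecord) -> float:
    cr, cysc = record.scr_mgdl, record.cysc
    if _female(record):
        c, knot, a_low = 130.0, 0.7, -0.248
    else:
        c, knot, a_low = 135.0, 0.9, -0.207
    a = a_low if cr <= knot else -0.601
    b = -0.375 if cysc <= 0.8 else -0.711
    return c * (cr / knot) ** a * (cysc / 0.8) ** b * 0.995**record.age


def _asian_ckd_epi_cr(record: PatientRecord) -> float:
    cr = record.scr_mgdl
    if _female(record):
        c, knot, a_low = 151.0, 0.7, -0.328
    else:
        c, knot, a_low = 149.0, 0.9, -0.415
    a = a_low if cr <= knot else -1.210
    return c * (cr / knot) ** a * 0.993**record.age


def _bis2(record: PatientRecord) -> float:
    v = (
        767.0
        * record.cysc**-0.610
        * record.scr_mgdl**-0.400
        * record.age**-0.570
    )
    if _female(record):
        v *= 0.870
    return v


def _macisaac(record: PatientRecord) -> float:
    return 86.700 / record.cysc - 4.200


def _ruijin(record: PatientRecord) -> float:
    v = 234.960 * record.scr_mgdl**-0.926 * record.age**-0.280
    if _female(record):
        v *= 0.828
    return v


def _xiangya(record: PatientRecord) -> float:
    # the one equation consuming creatinine in umol/L
    v = 2374.780 * record.scr_umoll**-0.54753 * record.age**-0.25011
    if _female(record):
        v *= 0.8526126
    return v


def estimate_egfr(
    equation: EquationId,
    record: PatientRecord,
    *,
    cg_numerator: str = "weight",
    si_units: bool = True,
) -> EgfrValue:
    """Evaluate one estimation equation for one patient.

    Parameters
    ----------
    equation:
        Which of the thirteen equations to apply.
    record:
        The patient.  Creatinine is converted internally to the unit each
        equation expects.
    cg_numerator:
        ``"weight"`` (classical Cockcroft-Gault, default) or
        ``"height_as_printed"`` to reproduce the height-in-numerator variant.
    si_units:
        When True (default) ``bun`` (mmol/L) and ``alb`` (g/L) are converted
        to the conventional units (mg/dL, g/dL) the MDRD family was published
        with; set False to pass them through unconverted.

    Returns
    -------
    EgfrValue
        mL/min per 1.73 m^2, full precision (no clamping or rounding).

    Raises
    ------
    MissingInputError
        If a required biomarker is absent, naming the field.
    """
    equation = EquationId(equation)
    for name in _REQUIRED[equation]:
        if getattr(record, name) is None:
            raise MissingInputError(name, equation)

    if equation is EquationId.COCKCROFT_GAULT:
        value = _cockcroft_gault(record, cg_numerator)
    elif equation is EquationId.MDRD:
        value = _mdrd(record, si_units, chinese=False)
    elif equation is EquationId.CN_MDRD:
        value = _mdrd(record, si_units, chinese=True)
    elif equation is EquationId.ABBREV_MDRD:
        value = _abbrev_mdrd(record)
    elif equation is EquationId.CN_ABBREV_MDRD:
        value = _cn_abbrev_mdrd(record)
    elif equation is EquationId.CKD_EPI_CR:
        value = _ckd_epi_cr(record)
    elif equation is EquationId.CKD_EPI_CYSC:
        value = _ckd_epi_cysc(record)
    elif equation is EquationId.CKD_EPI_CR_CYSC:
        value = _ckd_epi_cr_cysc(record)
    elif equation is EquationId.ASIAN_CKD_EPI_CR:
        value = _asian_ckd_epi_cr(record)
    elif equation is EquationId.BIS2:
        value = _bis2(record)
    elif equation is EquationId.MACISAAC:
        value = _macisaac(record)
    elif equation is EquationId.RUIJIN:
        value = _ruijin(record)
    elif equation is EquationId.XIANGYA:
        value = _xiangya(record)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unhandled equation {equation!r}")
    return EgfrValue(value=value, equation=equation)


@dataclass
class EquationPanel:
    """Result of evaluating every equation whose inputs are available."""

    values: Dict[EquationId, EgfrValue]
    missing: Dict[EquationId, str]


def estimate_all(
    record: PatientRecord,
    *,
    cg_numerator: str = "weight",
    si_units: bool = True,
) -> EquationPanel:
    """Evaluate all thirteen equations; missing-input equations are reported
    as absent with a reason rather than raising."""
    values: Dict[EquationId, EgfrValue] = {}
    missing: Dict[EquationId, str] = {}
    for eq in EquationId:
        try:
            values[eq] = estimate_egfr(
                eq, record, cg_numerator=cg_numerator, si_units=si_units
            )
        except MissingInputError as exc:
            missing[eq] = f"{exc.field_name} missing"
    return EquationPanel(values=values, missing=missing)
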