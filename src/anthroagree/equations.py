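"""The compendium of anthropometric body-composition prediction equations.

Around fifty published equations that estimate body density (BD), fat
percentage (FP, %), fat mass (FM, kg), lean percentage (LP, %) or lean
mass (LM, kg) from skinfolds, girths, bone diameters and demographics,
together with a machine-readable registry of what each equation needs and
how it codes sex and race.

Conventions
-----------
* Skinfolds enter in mm, girths/diameters/height in cm, masses in kg.
  Equations that want height in metres (the Lee RC pair, Poortmans, the
  De Rose bone-mass term) convert internally.
* Each sex-coded equation carries its own numeric coding (they disagree:
  some code men as 1, some as 0, one as 1-vs-2).  Profiles whose ``sex``
  is a male-fraction float are handled linearly: sex *terms* use the
  mixed code, sex-specific *formulas* evaluate both branches and mix.
* Race offsets are only applied where the source publication printed
  them; categories the source did not mention fall back to a printed
  "others" offset when one exists, otherwise raise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

from .profiles import (
    AnthroProfile,
    MissingSiteError,
    PI_PRINTED,
    ValidationError,
    corrected_girth,
    sum_skinfolds,
)

__all__ = [
    "EquationOptions",
    "EquationSpec",
    "EquationResult",
    "DEFAULT_OPTIONS",
    "BD_EQUATIONS",
    "BD_CONVERTERS",
    "estimate",
    "estimate_bd",
    "bd_to_fp",
    "estimate_fp",
    "estimate_fm",
    "estimate_lp",
    "estimate_lm",
    "list_equations",
    "get_spec",
    "registry_json",
]

FAMILIES = ("FP", "FM", "LP", "LM")


@dataclass(frozen=True)
class EquationOptions:
    """Formula-literalism switches.

    The defaults reproduce the arithmetic as printed in the source
    compendium, except where the printed form is nonphysical (the Kerr
    adipose mass and the De Rose bone-mass term; see the methods note).
    """

    full_precision_pi: bool = False
    #: evaluate the Kerr adipose mass and De Rose bone mass literally as
    #: printed (both are dimensionally broken and yield absurd masses);
    #: intended for auditing the printed arithmetic only.
    as_printed: bool = False
    #: O'Connor: square the second-term skinfold sum (0.0005 * S^2)
    #: instead of the printed degenerate linear pair.
    oconnor_squared: bool = False
    #: Heymsfield leading coefficient; printed 0.284, widely published 0.0264.
    heymsfield_coefficient: float = 0.284
    #: Slaughter (male): use the conventional (TR+SS)^2 squared term
    #: instead of the printed (TR+SSP)^2.
    slaughter_ss_squared: bool = False
    #: Kerr adipose Z-score constants (phantom mean and SD of the
    #: height-scaled six-skinfold sum).
    kerr_adipose_c1: float = 116.41
    kerr_adipose_c2: float = 34.79

    @property
    def pi(self) -> float:
        return math.pi if self.full_precision_pi else PI_PRINTED


DEFAULT_OPTIONS = EquationOptions()


@dataclass(frozen=True)
class EquationSpec:
    """Registry entry describing one equation's interface."""

    equation_id: str
    output: str  # one of BD, FP, FM, LP, LM
    required_skinfolds: tuple[str, ...] = ()
    required_circumferences: tuple[str, ...] = ()
    required_diameters: tuple[str, ...] = ()
    required_demographics: tuple[str, ...] = ()  # subset of sex, age, race, BW, H, BMI
    sex_coding: Optional[dict[str, float]] = None
    race_coding: Optional[dict[str, float]] = None
    citation_key: str = ""
    notes: str = ""
    #: False for equations in the registry that the validation study could
    #: not apply (missing axillary/chest folds); excluded from family
    #: counts by default.
    tested_in_study: bool = True

    def as_dict(self) -> dict:
        return {
            "equation_id": self.equation_id,
            "output": self.output,
            "required_skinfolds": list(self.required_skinfolds),
            "required_circumferences": list(self.required_circumferences),
            "required_diameters": list(self.required_diameters),
            "required_demographics": list(self.required_demographics),
            "sex_coding": self.sex_coding,
            "race_coding": self.race_coding,
            "citation_key": self.citation_key,
            "notes": self.notes,
            "tested_in_study": self.tested_in_study,
        }


@dataclass
class EquationResult:
    equation_id: str
    subject_id: str
    value: float
    intermediate: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# coding helpers


def _sex_code(profile: AnthroProfile, coding: dict[str, float], equation_id: str) -> float:
    if isinstance(profile.sex, str):
        return coding[profile.sex]
    # male-fraction profile: linear mix of the two codes
    f = float(profile.sex)
    return coding["male"] * f + coding["female"] * (1.0 - f)


def _by_sex(
    profile: AnthroProfile,
    male_fn: Callable[[], float],
    female_fn: Callable[[], float],
) -> float:
    if isinstance(profile.sex, str):
        return male_fn() if profile.sex == "male" else female_fn()
    f = float(profile.sex)
    return f * male_fn() + (1.0 - f) * female_fn()


def _race_offset(profile: AnthroProfile, coding: dict[str, float], equation_id: str) -> float:
    if profile.race in coding:
        return coding[profile.race]
    if "other" in coding:
        return coding["other"]
    raise ValidationError(
        f"equation {equation_id!r} has no race offset for category {profile.race!r}"
    )


def _bmi(profile: AnthroProfile) -> float:
    return profile.bmi


# --------------------------------------------------------------------------
# Body density equations (all skinfolds in mm; log10 where printed)


def _log10_sum(profile: AnthroProfile, sites: Sequence[str], eq: str) -> float:
    s = sum_skinfolds(profile, sites, eq).value_mm
    if s <= 0:
        raise ValidationError(f"{eq}: skinfold sum must be > 0 for log10, got {s}")
    return math.log10(s)


def _bd_durnin_womersley(p: AnthroProfile, o: EquationOptions) -> float:
    logs = _log10_sum(p, ("BI", "TR", "SS", "SI"), "durnin_womersley")
    return _by_sex(p, lambda: 1.1765 - 0.0744 * logs, lambda: 1.1567 - 0.0717 * logs)


def _bd_forsyth_sinning(p: AnthroProfile, o: EquationOptions) -> float:
    return 1.1103 - 0.00168 * p.skinfold("SS", "forsyth_sinning") - 0.00127 * p.skinfold("AB", "forsyth_sinning")


def _bd_katch_mcardle(p: AnthroProfile, o: EquationOptions) -> float:
    return (
        1.09665
        - 0.00103 * p.skinfold("TR", "katch_mcardle")
        - 0.00056 * p.skinfold("SS", "katch_mcardle")
        - 0.00054 * p.skinfold("AB", "katch_mcardle")
    )


def _bd_nagamine_suzuki(p: AnthroProfile, o: EquationOptions) -> float:
    return 1.0913 - 0.00116 * (p.skinfold("TR", "nagamine_suzuki") + p.skinfold("SS", "nagamine_suzuki"))


def _bd_sloan(p: AnthroProfile, o: EquationOptions) -> float:
    return 1.1043 - 0.001327 * p.skinfold("TH", "sloan") - 0.00131 * p.skinfold("SS", "sloan")


def _bd_wilmore_behnke(p: AnthroProfile, o: EquationOptions) -> float:
    return 1.08543 - 0.000886 * p.skinfold("AB", "wilmore_behnke") - 0.0004 * p.skinfold("TH", "wilmore_behnke")


def _bd_withers(p: AnthroProfile, o: EquationOptions) -> float:
    s = sum_skinfolds(p, ("TR", "SS", "BI", "SI", "AB", "TH", "C"), "withers").value_mm
    if s <= 0:
        raise ValidationError("withers: seven-fold sum must be > 0")
    return 1.0988 - 0.0004 * s


def _bd_white(p: AnthroProfile, o: EquationOptions) -> float:
    return 1.0958 - 0.00088 * p.skinfold("SI", "white") - 0.0006 * p.skinfold("TH", "white")


BD_EQUATIONS: dict[str, Callable[[AnthroProfile, EquationOptions], float]] = {
    "durnin_womersley": _bd_durnin_womersley,
    "forsyth_sinning": _bd_forsyth_sinning,
    "katch_mcardle": _bd_katch_mcardle,
    "nagamine_suzuki": _bd_nagamine_suzuki,
    "sloan": _bd_sloan,
    "wilmore_behnke": _bd_wilmore_behnke,
    "withers": _bd_withers,
    "white": _bd_white,
}

#: Two-compartment BD -> FP converters, FP on the 0-100 percent scale.
BD_CONVERTERS: dict[str, Callable[[float], float]] = {
    "siri": lambda bd: 100.0 * (4.95 / bd - 4.5),
    "brozek": lambda bd: 100.0 * (4.57 / bd - 4.142),
}


def estimate_bd(equation_id: str, profile: AnthroProfile, options: EquationOptions = DEFAULT_OPTIONS) -> float:
    """Body density (~g/ml) from one of the eight BD equations."""
    try:
        fn = BD_EQUATIONS[equation_id]
    except KeyError:
        raise KeyError(f"unknown body-density equation {equation_id!r}") from None
    return fn(profile, options)


def bd_to_fp(converter: str, bd: float) -> float:
    """Convert body density to fat percent via Siri or Brozek."""
    try:
        fn = BD_CONVERTERS[converter]
    except KeyError:
        raise KeyError(f"unknown BD converter {converter!r} (use 'siri' or 'brozek')") from None
    if bd <= 0:
        raise ValidationError(f"body density must be positive, got {bd}")
    if not 0.9 < bd < 1.2:
        warnings.warn(
            f"body density {bd:.4f} outside the physiological range (0.9, 1.2); "
            "fat percent returned anyway",
            stacklevel=2,
        )
    return fn(bd)


# --------------------------------------------------------------------------
# ISAK / Kerr five-way fractionation machinery

_KERR_PHANTOM_H = 170.18


def _kerr_corrected_girths(p: AnthroProfile, o: EquationOptions, eq: str) -> dict[str, float]:
    return {
        "cAC": corrected_girth(p.circumference("Ac", eq), p.skinfold("TR", eq), o.pi),
        "cTHC": corrected_girth(p.circumference("THc", eq), p.skinfold("TH", eq), o.pi),
        "cCC": corrected_girth(p.circumference("Cc", eq), p.skinfold("C", eq), o.pi),
        "cCHC": corrected_girth(p.circumference("CHc", eq), p.skinfold("SS", eq), o.pi),
    }


def _kerr_fm(p: AnthroProfile, o: EquationOptions) -> tuple[float, dict[str, float]]:
    """Kerr adipose mass (kg) with the phantom height scaling.

    The default path standardizes the height-scaled six-skinfold sum into
    an adipose Z-score before applying the phantom adipose model (the
    literal printed arithmetic, available via ``as_printed``, treats the
    raw mm sum as a Z-score and returns several hundred kg).
    """
    s6 = sum_skinfolds(p, ("TR", "SS", "SI", "AB", "TH", "C"), "isak5").value_mm
    if s6 <= 0:
        raise ValidationError("isak5: six-skinfold sum must be > 0")
    scale = (_KERR_PHANTOM_H / p.height_cm) ** 3
    if o.as_printed:
        fm = (s6 * 5.85 + 25.6) / scale
        return fm, {"sum6sk": s6, "scale": scale}
    z_adip = (s6 * (_KERR_PHANTOM_H / p.height_cm) - o.kerr_adipose_c1) / o.kerr_adipose_c2
    fm = (z_adip * 5.85 + 25.6) / scale
    return fm, {"sum6sk": s6, "z_adip": z_adip, "scale": scale}


def _kerr_lm(p: AnthroProfile, o: EquationOptions) -> tuple[float, dict[str, float]]:
    """Kerr muscle mass (kg) from the five corrected girths."""
    cg = _kerr_corrected_girths(p, o, "isak5")
    s5 = cg["cAC"] + p.circumference("FAc", "isak5") + cg["cTHC"] + cg["cCC"] + cg["cCHC"]
    scale = (_KERR_PHANTOM_H / p.height_cm) ** 3
    zmus = (s5 * (_KERR_PHANTOM_H / p.height_cm) - 207.21) / 13.74
    lm = (zmus * 5.4 + 24.5) / scale
    inter = dict(cg)
    inter.update({"sum5corr": s5, "zmus": zmus, "scale": scale})
    return lm, inter


# --------------------------------------------------------------------------
# Direct fat-percentage equations


def _fp_eston(p: AnthroProfile, o: EquationOptions) -> float:
    return (
        0.12 * sum_skinfolds(p, ("BI", "TR", "SS", "SI"), "eston").value_mm
        + 0.36 * (p.skinfold("TH", "eston") + p.skinfold("C", "eston"))
        + 1.61
    )


def _fp_evans(p: AnthroProfile, o: EquationOptions) -> float:
    s3 = p.skinfold("AB", "evans") + p.skinfold("TH", "evans") + p.skinfold("TR", "evans")
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "evans")
    race = _race_offset(p, _RACE_EVANS, "evans")
    return 8.997 + 0.24658 * s3 - 6.343 * sex - 1.998 * race


def _fp_oconnor(p: AnthroProfile, o: EquationOptions) -> float:
    s = p.skinfold("TR", "oconnor") + p.skinfold("SI", "oconnor") + p.skinfold("TH", "oconnor")
    second = 0.0005 * s * s if o.oconnor_squared else 0.0005 * s
    return 0.272 * s - second + 4.972


def _fp_carter(p: AnthroProfile, o: EquationOptions) -> float:
    s6 = sum_skinfolds(p, ("TR", "BI", "SI", "SS", "TH", "C"), "carter").value_mm
    return _by_sex(p, lambda: 2.585 + 0.1051 * s6, lambda: 3.5803 + 0.1548 * s6)


def _fp_faulkner(p: AnthroProfile, o: EquationOptions) -> float:
    s4 = sum_skinfolds(p, ("TR", "SS", "SI", "AB"), "faulkner").value_mm
    return _by_sex(p, lambda: s4 * 0.153 + 5.783, lambda: s4 * 0.213 + 7.9)


def _fp_slaughter(p: AnthroProfile, o: EquationOptions) -> float:
    ts = p.skinfold("TR", "slaughter") + p.skinfold("SS", "slaughter")

    def male() -> float:
        if o.slaughter_ss_squared:
            sq = ts
        else:
            sq = p.skinfold("TR", "slaughter") + p.skinfold("SSP", "slaughter")
        return 1.21 * ts - 0.008 * sq * sq - 3.4

    return _by_sex(p, male, lambda: 1.33 * ts - 0.013 * ts * ts - 2.5)


def _fp_yuhasz(p: AnthroProfile, o: EquationOptions) -> float:
    s6 = sum_skinfolds(p, ("TR", "SS", "SI", "AB", "TH", "C"), "yuhasz").value_mm
    return _by_sex(p, lambda: 0.1051 * s6 + 2.58, lambda: 0.1548 * s6 + 3.58)


def _fp_minematsu(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 2.0}, "minematsu")
    return 10.558 * sex + 0.069 * p.age + 0.667 * _bmi(p) + 0.314 * p.circumference("WC", "minematsu") - 35.881


def _fp_hastuti(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "hastuti")
    return 17.026 + 0.509 * p.skinfold("TR", "hastuti") + 0.342 * p.skinfold("SI", "hastuti") - 5.594 * sex


def _fp_deurenberg(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "deurenberg")
    return 1.2 * _bmi(p) + 0.23 * p.age - 10.8 * sex - 5.4


def _fp_lean_wc(p: AnthroProfile, o: EquationOptions) -> float:
    wc = p.circumference("WC", "lean_wc")
    return _by_sex(
        p,
        lambda: 0.567 * wc + 0.101 * p.age - 31.8,
        lambda: 0.439 * wc + 0.221 * p.age - 9.4,
    )


def _fp_lean_bmi(p: AnthroProfile, o: EquationOptions) -> float:
    bmi = _bmi(p)
    return _by_sex(
        p,
        lambda: 1.33 * bmi + 0.236 * p.age - 20.2,
        lambda: 1.21 * bmi + 0.262 * p.age - 6.7,
    )


def _fp_lean_bmi_tr(p: AnthroProfile, o: EquationOptions) -> float:
    bmi, tr = _bmi(p), p.skinfold("TR", "lean_bmi_tr")
    return _by_sex(
        p,
        lambda: 0.742 * bmi + 0.950 * tr + 0.335 * p.age - 20.0,
        lambda: 0.730 * bmi + 0.548 * tr + 0.270 * p.age - 5.9,
    )


def _fp_lean_log4sk(p: AnthroProfile, o: EquationOptions) -> float:
    logs = _log10_sum(p, ("BI", "TR", "SS", "SI"), "lean_log4sk")
    return _by_sex(
        p,
        lambda: 30.69 * logs + 0.271 * p.age - 39.9,
        lambda: 30.8 * logs + 0.274 * p.age - 31.7,
    )


def _fp_gomez_ambrosi(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 0.0, "female": 1.0}, "gomez_ambrosi")
    bmi = _bmi(p)
    return (
        -44.988
        + 0.503 * p.age
        + 10.689 * sex
        + 3.172 * bmi
        - 0.026 * bmi**2
        + 0.181 * bmi * sex
        - 0.02 * bmi * p.age
        - 0.005 * bmi**2 * sex
        + 0.00021 * bmi**2 * p.age
    )


def _fp_isak5(p: AnthroProfile, o: EquationOptions) -> float:
    fm, _ = _kerr_fm(p, o)
    return fm / p.body_weight_kg * 100.0


_RACE_EVANS = {
    # source prints only Afro descendants = 1 / white = 0; everyone else
    # takes the reference value (see methods note)
    "afro_descendant": 1.0,
    "white": 0.0,
    "hispanic": 0.0,
    "mexican": 0.0,
    "asian": 0.0,
    "other": 0.0,
}

_RACE_LEE_DH_FP_M = {"mexican": 0.53, "hispanic": 0.19, "afro_descendant": -0.79, "other": 0.7}
_RACE_LEE_DH_FP_F = {"mexican": 0.98, "hispanic": 0.23, "afro_descendant": -1.77, "other": 0.08}
_RACE_LEE_DH_FM_M = {"mexican": 0.154, "hispanic": -0.050, "afro_descendant": -0.529, "other": 0.687}
_RACE_LEE_DH_FM_F = {"mexican": 0.357, "hispanic": -0.071, "afro_descendant": -1.345, "other": 0.177}
_RACE_LEE_DH_LM_M = {"mexican": 0.120, "hispanic": 0.097, "afro_descendant": 0.463, "other": -0.661}
_RACE_LEE_DH_LM_F = {"mexican": -0.306, "hispanic": 0.082, "afro_descendant": 1.235, "other": -0.196}
_RACE_LEE_RC_1 = {"asian": -2.0, "afro_descendant": 1.1, "white": 0.0, "hispanic": 0.0}
_RACE_LEE_RC_2 = {"asian": -1.2, "afro_descendant": 1.4, "white": 0.0, "hispanic": 0.0}
_RACE_OLSHVANG_M = {"hispanic": 0.231, "afro_descendant": 0.432, "other": -1.007}
_RACE_OLSHVANG_F = {"hispanic": -0.059, "afro_descendant": 1.085, "other": -0.34}


def _fp_lee_dh(p: AnthroProfile, o: EquationOptions) -> float:
    age, h, bw = p.age, p.height_cm, p.body_weight_kg
    wc = p.circumference("WC", "lee_dh_fp")
    ac = p.circumference("Ac", "lee_dh_fp")
    cc = p.circumference("Cc", "lee_dh_fp")
    thc = p.circumference("THc", "lee_dh_fp")
    tr = p.skinfold("TR", "lee_dh_fp")
    ss = p.skinfold("SS", "lee_dh_fp")

    def male() -> float:
        return (
            2.80 + 0.03 * age - 0.04 * h - 0.08 * bw + 0.35 * wc - 0.18 * ac
            + 0.00 * cc + 0.04 * thc + 0.33 * tr + 0.08 * ss
            + _race_offset(p, _RACE_LEE_DH_FP_M, "lee_dh_fp")
        )

    def female() -> float:
        return (
            32.75 + 0.08 * age - 0.16 * h + 0.10 * bw + 0.12 * wc - 0.05 * ac
            - 0.17 * cc + 0.22 * thc + 0.27 * tr + 0.05 * ss
            + _race_offset(p, _RACE_LEE_DH_FP_F, "lee_dh_fp")
        )

    return _by_sex(p, male, female)


def _fp_giro(p: AnthroProfile, o: EquationOptions) -> float:
    s4 = sum_skinfolds(p, ("TR", "SI", "AB", "TH"), "giro").value_mm
    return -0.620 + 0.159 * s4 + 0.120 * p.circumference("WC", "giro")


def _fp_cavedon1(p: AnthroProfile, o: EquationOptions) -> float:
    return (
        0.241 * p.skinfold("TH", "cavedon1")
        + 0.418 * p.skinfold("AB", "cavedon1")
        + 0.329 * p.skinfold("SS", "cavedon1")
        + 0.259 * p.skinfold("AX", "cavedon1")
        - 1.689
    )


def _fp_cavedon2(p: AnthroProfile, o: EquationOptions) -> float:
    s9 = sum_skinfolds(p, ("BI", "TR", "SS", "AX", "CH", "SI", "AB", "TH", "C"), "cavedon2").value_mm
    return 0.162 * s9 - 0.311


# --------------------------------------------------------------------------
# Fat-mass equations (kg)


def _fm_al_guindan(p: AnthroProfile, o: EquationOptions) -> float:
    bw, h = p.body_weight_kg, p.height_cm
    return _by_sex(
        p,
        lambda: 0.198 * bw + 0.478 * p.circumference("WC", "al_guindan") - 0.147 * h - 12.8,
        lambda: 0.789 * bw + 0.0786 * p.age - 0.342 * h + 24.5,
    )


def _fm_de_rose(p: AnthroProfile, o: EquationOptions) -> float:
    s4 = (
        p.skinfold("SS", "de_rose_fm")
        + p.skinfold("TR", "de_rose_fm")
        + p.skinfold("SSP", "de_rose_fm")
        + p.skinfold("AB", "de_rose_fm")
    )
    return 0.01 * p.body_weight_kg * (s4 * 0.153 + 5.783)


def _fm_isak5(p: AnthroProfile, o: EquationOptions) -> float:
    fm, _ = _kerr_fm(p, o)
    return fm


def _fm_heitmann(p: AnthroProfile, o: EquationOptions) -> float:
    bmi, bw, age = _bmi(p), p.body_weight_kg, p.age
    return _by_sex(
        p,
        lambda: 0.988 * bmi + 0.242 * bw + 0.094 * age - 30.180,
        lambda: 0.988 * bmi + 0.344 * bw + 0.094 * age - 30.180,
    )


def _fm_lee_dh(p: AnthroProfile, o: EquationOptions) -> float:
    age, h, bw = p.age, p.height_cm, p.body_weight_kg
    wc = p.circumference("WC", "lee_dh_fm")
    ac = p.circumference("Ac", "lee_dh_fm")
    cc = p.circumference("Cc", "lee_dh_fm")
    thc = p.circumference("THc", "lee_dh_fm")
    tr = p.skinfold("TR", "lee_dh_fm")
    ss = p.skinfold("SS", "lee_dh_fm")

    def male() -> float:
        return (
            -0.009 + 0.004 * age - 0.108 * h + 0.334 * bw + 0.247 * wc - 0.306 * ac
            - 0.075 * cc - 0.028 * thc + 0.307 * tr + 0.030 * ss
            + _race_offset(p, _RACE_LEE_DH_FM_M, "lee_dh_fm")
        )

    def female() -> float:
        return (
            8.633 + 0.048 * age - 0.166 * h + 0.569 * bw + 0.044 * wc - 0.082 * ac
            - 0.183 * cc + 0.115 * thc + 0.150 * tr + 0.008 * ss
            + _race_offset(p, _RACE_LEE_DH_FM_F, "lee_dh_fm")
        )

    return _by_sex(p, male, female)


def _fm_salamat(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "salamat_fm")
    return -11.938 + 1.606 * _bmi(p) - 8.511 * sex


# --------------------------------------------------------------------------
# Lean-percentage equations (%)


def _lp_lee_rc(p: AnthroProfile, o: EquationOptions) -> float:
    lm = _lm_lee_rc_1(p, o)
    return lm / p.body_weight_kg * 100.0


def _lp_poortmans(p: AnthroProfile, o: EquationOptions) -> float:
    # raw (uncorrected) girths as printed; height in metres (the only
    # physically plausible unit for this girth-squared form)
    h_m = p.height_cm / 100.0
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "poortmans")
    return (
        h_m * (0.0264 * p.circumference("Ac", "poortmans") ** 2)
        + 0.0032 * p.circumference("THc", "poortmans") ** 2
        + 0.0015 * p.circumference("Cc", "poortmans") ** 2
        + 2.56 * sex
        + 0.136 * p.age
    )


def _lp_isak5(p: AnthroProfile, o: EquationOptions) -> float:
    lm, _ = _kerr_lm(p, o)
    return lm / p.body_weight_kg * 100.0


# --------------------------------------------------------------------------
# Lean-mass equations (kg)


def _lm_de_rose(p: AnthroProfile, o: EquationOptions) -> float:
    bw = p.body_weight_kg
    fm = _fm_de_rose(p, o)
    wd = p.diameter("WD", "de_rose_lm")
    fd = p.diameter("FD", "de_rose_lm")
    if o.as_printed:
        core = (p.height_cm**2 / 100.0) * (wd / 100.0) * (fd / 100.0) * 400.0
    else:
        core = (p.height_cm / 100.0) ** 2 * (wd / 100.0) * (fd / 100.0) * 400.0
    bm = 3.02 * core**0.712
    rm = bw * 0.241
    return bw - (fm + bm + rm)


def _lm_heymsfield(p: AnthroProfile, o: EquationOptions) -> float:
    ac = p.circumference("Ac", "heymsfield")
    tr_cm = p.skinfold("TR", "heymsfield") / 10.0
    pi = o.pi
    area = (ac - pi * tr_cm) ** 2 / (4.0 * pi)
    corr = _by_sex(p, lambda: area - 10.0, lambda: area - 6.5)
    return p.height_cm * (o.heymsfield_coefficient + 0.0029 * corr)


def _lee_rc_girth_term(p: AnthroProfile, o: EquationOptions, eq: str) -> float:
    cg = _kerr_corrected_girths(p, o, eq)
    h_m = p.height_cm / 100.0
    return h_m * (0.00744 * cg["cAC"] ** 2 + 0.00088 * cg["cTHC"] ** 2 + 0.00441 * cg["cCC"] ** 2)


def _lm_lee_rc_1(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "lee_rc_1")
    race = _race_offset(p, _RACE_LEE_RC_1, "lee_rc_1")
    return _lee_rc_girth_term(p, o, "lee_rc_1") + 2.4 * sex - 0.048 * p.age + race + 7.8


def _lm_lee_rc_2(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "lee_rc_2")
    race = _race_offset(p, _RACE_LEE_RC_2, "lee_rc_2")
    h_m = p.height_cm / 100.0
    return 0.244 * p.body_weight_kg + 7.8 * h_m + 6.6 * sex - 0.098 * p.age + race - 3.3


def _lm_doupe(p: AnthroProfile, o: EquationOptions) -> float:
    # printed form, height in cm (see methods note on its magnitude)
    cg = _kerr_corrected_girths(p, o, "doupe")
    return p.height_cm * (0.031 * cg["cTHC"] ** 2 + 0.064 * cg["cCC"] ** 2 + 0.089 * cg["cAC"] ** 2) - 3.006


def _lm_isak5(p: AnthroProfile, o: EquationOptions) -> float:
    lm, _ = _kerr_lm(p, o)
    return lm


def _lm_janmahasatian(p: AnthroProfile, o: EquationOptions) -> float:
    bw, bmi = p.body_weight_kg, _bmi(p)
    return _by_sex(
        p,
        lambda: 9270.0 * bw / (8780.0 + 244.0 * bmi),
        lambda: 9270.0 * bw / (6680.0 + 216.0 * bmi),
    )


def _lm_olshvang(p: AnthroProfile, o: EquationOptions) -> float:
    age, h, bw = p.age, p.height_cm, p.body_weight_kg
    wc = p.circumference("WC", "olshvang")
    return _by_sex(
        p,
        lambda: 19.363 + 0.001 * age + 0.064 * h + 0.756 * bw - 0.366 * wc
        + _race_offset(p, _RACE_OLSHVANG_M, "olshvang"),
        lambda: -10.683 - 0.039 * age + 0.186 * h + 0.383 * bw - 0.043 * wc
        + _race_offset(p, _RACE_OLSHVANG_F, "olshvang"),
    )


def _lm_chien(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "chien")
    return (
        27.479
        + 0.726 * p.body_weight_kg
        - 3.383 * sex
        - 0.672 * _bmi(p)
        + 0.514 * p.circumference("FAc", "chien")
        - 0.245 * p.circumference("HC", "chien")
    )


def _lm_lee_dh(p: AnthroProfile, o: EquationOptions) -> float:
    age, h, bw = p.age, p.height_cm, p.body_weight_kg
    wc = p.circumference("WC", "lee_dh_lm")
    ac = p.circumference("Ac", "lee_dh_lm")
    cc = p.circumference("Cc", "lee_dh_lm")
    thc = p.circumference("THc", "lee_dh_lm")
    tr = p.skinfold("TR", "lee_dh_lm")
    ss = p.skinfold("SS", "lee_dh_lm")

    def male() -> float:
        return (
            -1.401 - 0.010 * age + 0.100 * h + 0.632 * bw - 0.225 * wc + 0.315 * ac
            + 0.091 * cc + 0.040 * thc - 0.304 * tr - 0.021 * ss
            + _race_offset(p, _RACE_LEE_DH_LM_M, "lee_dh_lm")
        )

    def female() -> float:
        return (
            -9.193 - 0.045 * age + 0.158 * h + 0.410 * bw - 0.040 * wc + 0.095 * ac
            + 0.193 * cc - 0.105 * thc - 0.152 * tr - 0.004 * ss
            + _race_offset(p, _RACE_LEE_DH_LM_F, "lee_dh_lm")
        )

    return _by_sex(p, male, female)


def _ln_sum(profile: AnthroProfile, sites: Sequence[str], eq: str) -> float:
    s = sum_skinfolds(profile, sites, eq).value_mm
    if s <= 0:
        raise ValidationError(f"{eq}: skinfold sum must be > 0 for log, got {s}")
    return math.log(s)


def _lm_kulkarni3(p: AnthroProfile, o: EquationOptions) -> float:
    # natural log: the base-10 reading over-shoots lean mass by ~11 kg at
    # typical adult inputs, ln reproduces the source's magnitudes
    logs = _ln_sum(p, ("BI", "TR", "SS", "SI"), "kulkarni3")
    age, h, bw = p.age, p.height_cm, p.body_weight_kg
    return _by_sex(
        p,
        lambda: 13.78 - 0.018 * age + 0.064 * h + 0.697 * bw - 5.842 * logs,
        lambda: 1.689 - 0.014 * age + 0.120 * h + 0.499 * bw - 3.315 * logs,
    )


def _lm_kulkarni4(p: AnthroProfile, o: EquationOptions) -> float:
    logs = _ln_sum(p, ("BI", "TR", "SS", "SI"), "kulkarni4")
    age, h, bw = p.age, p.height_cm, p.body_weight_kg
    ac = p.circumference("Ac", "kulkarni4")
    cc = p.circumference("Cc", "kulkarni4")
    hc = p.circumference("HC", "kulkarni4")
    return _by_sex(
        p,
        lambda: 10.385 - 0.005 * age + 0.103 * h + 0.680 * bw + 0.288 * ac + 0.130 * cc - 0.183 * hc - 5.278 * logs,
        lambda: 10.632 - 0.009 * age + 0.102 * h + 0.592 * bw + 0.055 * ac + 0.043 * cc - 0.158 * hc - 3.174 * logs,
    )


def _lm_salamat(p: AnthroProfile, o: EquationOptions) -> float:
    sex = _sex_code(p, {"male": 1.0, "female": 0.0}, "salamat_lm")
    return 14.966 + 0.588 * _bmi(p) + 18.694 * sex + 0.137 * p.circumference("WC", "salamat_lm") - 0.138 * p.age


# --------------------------------------------------------------------------
# Registry

_S = EquationSpec  # brevity in the tables below

_BD_SPECS = [
    _S("durnin_womersley", "BD", ("BI", "TR", "SS", "SI"), required_demographics=("sex",),
       sex_coding=None, citation_key="durnin_womersley_1974"),
    _S("forsyth_sinning", "BD", ("SS", "AB"), citation_key="forsyth_sinning_1973"),
    _S("katch_mcardle", "BD", ("TR", "SS", "AB"), citation_key="katch_mcardle_1973"),
    _S("nagamine_suzuki", "BD", ("TR", "SS"), citation_key="nagamine_suzuki_1964"),
    _S("sloan", "BD", ("TH", "SS"), citation_key="sloan_1967"),
    _S("wilmore_behnke", "BD", ("AB", "TH"), citation_key="wilmore_behnke_1969"),
    _S("withers", "BD", ("TR", "SS", "BI", "SI", "AB", "TH", "C"), citation_key="withers_1987"),
    _S("white", "BD", ("SI", "TH"), citation_key="white_1980"),
]

_FP_DIRECT_SPECS = [
    _S("eston", "FP", ("BI", "TR", "SS", "SI", "TH", "C"), citation_key="eston_2005"),
    _S("evans", "FP", ("AB", "TH", "TR"), required_demographics=("sex", "race"),
       sex_coding={"male": 1, "female": 0}, race_coding=_RACE_EVANS, citation_key="evans_2005"),
    _S("oconnor", "FP", ("TR", "SI", "TH"), citation_key="oconnor_2010",
       notes="printed second term is linear (degenerate with the first); squared variant via options"),
    _S("carter", "FP", ("TR", "BI", "SI", "SS", "TH", "C"), required_demographics=("sex",),
       citation_key="carter_1982"),
    _S("faulkner", "FP", ("TR", "SS", "SI", "AB"), required_demographics=("sex",),
       citation_key="faulkner_1968"),
    _S("slaughter", "FP", ("TR", "SS", "SSP"), required_demographics=("sex",),
       citation_key="slaughter_1988",
       notes="male squared term uses SSP as printed; conventional SS variant via options"),
    _S("yuhasz", "FP", ("TR", "SS", "SI", "AB", "TH", "C"), required_demographics=("sex",),
       citation_key="yuhasz_1974"),
    _S("minematsu", "FP", (), ("WC",), required_demographics=("sex", "age", "BMI"),
       sex_coding={"male": 1, "female": 2}, citation_key="minematsu_2011"),
    _S("hastuti", "FP", ("TR", "SI"), required_demographics=("sex",),
       sex_coding={"male": 1, "female": 0}, citation_key="hastuti_2013"),
    _S("deurenberg", "FP", (), required_demographics=("sex", "age", "BMI"),
       sex_coding={"male": 1, "female": 0}, citation_key="deurenberg_1991"),
    _S("lean_wc", "FP", (), ("WC",), required_demographics=("sex", "age"), citation_key="lean_1996"),
    _S("lean_bmi", "FP", (), required_demographics=("sex", "age", "BMI"), citation_key="lean_1996"),
    _S("lean_bmi_tr", "FP", ("TR",), required_demographics=("sex", "age", "BMI"), citation_key="lean_1996"),
    _S("lean_log4sk", "FP", ("BI", "TR", "SS", "SI"), required_demographics=("sex", "age"),
       citation_key="lean_1996"),
    _S("gomez_ambrosi", "FP", (), required_demographics=("sex", "age", "BMI"),
       sex_coding={"male": 0, "female": 1}, citation_key="gomez_ambrosi_2012"),
    _S("isak5_fp", "FP", ("TR", "SS", "SI", "AB", "TH", "C"), required_demographics=("H", "BW"),
       citation_key="kerr_1988", notes="Kerr adipose mass over body weight, x100"),
    _S("lee_dh_fp", "FP", ("TR", "SS"), ("WC", "Ac", "Cc", "THc"),
       required_demographics=("sex", "age", "race", "BW", "H"),
       race_coding={"male": _RACE_LEE_DH_FP_M, "female": _RACE_LEE_DH_FP_F},  # type: ignore[dict-item]
       citation_key="lee_dh_2017"),
    _S("giro", "FP", ("TR", "SI", "AB", "TH"), ("WC",), citation_key="giro_2023"),
]

_FP_UNTESTED_SPECS = [
    _S("cavedon1", "FP", ("TH", "AB", "SS", "AX"), citation_key="cavedon_2023",
       tested_in_study=False, notes="amputee-specific; axillary fold not collected by the study"),
    _S("cavedon2", "FP", ("BI", "TR", "SS", "AX", "CH", "SI", "AB", "TH", "C"),
       citation_key="cavedon_2023", tested_in_study=False,
       notes="amputee-specific; axillary and chest folds not collected by the study"),
]

_FM_SPECS = [
    _S("al_guindan", "FM", (), ("WC",), required_demographics=("sex", "age", "BW", "H"),
       citation_key="al_guindan_2020"),
    _S("de_rose_fm", "FM", ("SS", "TR", "SSP", "AB"), required_demographics=("BW",),
       citation_key="de_rose_guimaraes_1984"),
    _S("isak5_fm", "FM", ("TR", "SS", "SI", "AB", "TH", "C"), required_demographics=("H",),
       citation_key="kerr_1988"),
    _S("heitmann", "FM", (), required_demographics=("sex", "age", "BW", "BMI"),
       citation_key="heitmann_1990"),
    _S("lee_dh_fm", "FM", ("TR", "SS"), ("WC", "Ac", "Cc", "THc"),
       required_demographics=("sex", "age", "race", "BW", "H"), citation_key="lee_dh_2017"),
    _S("salamat_fm", "FM", (), required_demographics=("sex", "BMI"),
       sex_coding={"male": 1, "female": 0}, citation_key="salamat_2015"),
]

_LP_SPECS = [
    _S("lee_rc_lp", "LP", ("TR", "TH", "C", "SS"), ("Ac", "THc", "Cc", "CHc"),
       required_demographics=("sex", "age", "race", "BW", "H"),
       sex_coding={"male": 1, "female": 0}, race_coding=_RACE_LEE_RC_1,
       citation_key="lee_rc_2000", notes="Lee RC 1 lean mass over body weight, x100"),
    _S("poortmans", "LP", (), ("Ac", "THc", "Cc"), required_demographics=("sex", "age", "H"),
       sex_coding={"male": 1, "female": 0}, citation_key="poortmans_2005"),
    _S("isak5_lp", "LP", ("TR", "TH", "C", "SS"), ("Ac", "FAc", "THc", "Cc", "CHc"),
       required_demographics=("BW", "H"), citation_key="kerr_1988"),
]

_LM_SPECS = [
    _S("de_rose_lm", "LM", ("SS", "TR", "SSP", "AB"), (), ("WD", "FD"),
       required_demographics=("BW", "H"), citation_key="de_rose_guimaraes_1984",
       notes="closure model: LM = BW - (FM + bone + residual)"),
    _S("heymsfield", "LM", ("TR",), ("Ac",), required_demographics=("sex", "H"),
       citation_key="heymsfield_1982",
       notes="leading coefficient 0.284 as printed; 0.0264 variant via options"),
    _S("lee_rc_1", "LM", ("TR", "TH", "C", "SS"), ("Ac", "THc", "Cc", "CHc"),
       required_demographics=("sex", "age", "race", "H"),
       sex_coding={"male": 1, "female": 0}, race_coding=_RACE_LEE_RC_1, citation_key="lee_rc_2000"),
    _S("lee_rc_2", "LM", (), required_demographics=("sex", "age", "race", "BW", "H"),
       sex_coding={"male": 1, "female": 0}, race_coding=_RACE_LEE_RC_2, citation_key="lee_rc_2000",
       notes="height in metres per the printed note"),
    _S("doupe", "LM", ("TR", "TH", "C", "SS"), ("Ac", "THc", "Cc", "CHc"),
       required_demographics=("H",), citation_key="doupe_1997"),
    _S("isak5_lm", "LM", ("TR", "TH", "C", "SS"), ("Ac", "FAc", "THc", "Cc", "CHc"),
       required_demographics=("H",), citation_key="kerr_1988"),
    _S("janmahasatian", "LM", (), required_demographics=("sex", "BW", "BMI"),
       citation_key="janmahasatian_2005"),
    _S("olshvang", "LM", (), ("WC",), required_demographics=("sex", "age", "race", "BW", "H"),
       race_coding={"male": _RACE_OLSHVANG_M, "female": _RACE_OLSHVANG_F},  # type: ignore[dict-item]
       citation_key="olshvang_2024"),
    _S("chien", "LM", (), ("FAc", "HC"), required_demographics=("sex", "BW", "BMI"),
       sex_coding={"male": 1, "female": 0}, citation_key="chien_2008"),
    _S("lee_dh_lm", "LM", ("TR", "SS"), ("WC", "Ac", "Cc", "THc"),
       required_demographics=("sex", "age", "race", "BW", "H"), citation_key="lee_dh_2017"),
    _S("kulkarni3", "LM", ("BI", "TR", "SS", "SI"), required_demographics=("sex", "age", "BW", "H"),
       citation_key="kulkarni_2013"),
    _S("kulkarni4", "LM", ("BI", "TR", "SS", "SI"), ("Ac", "Cc", "HC"),
       required_demographics=("sex", "age", "BW", "H"), citation_key="kulkarni_2013"),
    _S("salamat_lm", "LM", (), ("WC",), required_demographics=("sex", "age", "BMI"),
       sex_coding={"male": 1, "female": 0}, citation_key="salamat_2015"),
]


def _composite_specs() -> list[EquationSpec]:
    out = []
    for bd_spec in _BD_SPECS:
        for conv in ("siri", "brozek"):
            out.append(
                replace(
                    bd_spec,
                    equation_id=f"{bd_spec.equation_id}+{conv}",
                    output="FP",
                    citation_key=f"{bd_spec.citation_key}+{conv}",
                    notes=f"body density per {bd_spec.equation_id}, converted with {conv}",
                )
            )
    return out


#: Registration order is the reporting order: BD, then the FP family in
#: the study's table order (composites first), then FM, LP, LM.
REGISTRY: dict[str, EquationSpec] = {
    s.equation_id: s
    for s in (
        _BD_SPECS
        + _composite_specs()
        + _FP_DIRECT_SPECS
        + _FP_UNTESTED_SPECS
        + _FM_SPECS
        + _LP_SPECS
        + _LM_SPECS
    )
}

_DIRECT_EVALUATORS: dict[str, Callable[[AnthroProfile, EquationOptions], float]] = {
    "eston": _fp_eston,
    "evans": _fp_evans,
    "oconnor": _fp_oconnor,
    "carter": _fp_carter,
    "faulkner": _fp_faulkner,
    "slaughter": _fp_slaughter,
    "yuhasz": _fp_yuhasz,
    "minematsu": _fp_minematsu,
    "hastuti": _fp_hastuti,
    "deurenberg": _fp_deurenberg,
    "lean_wc": _fp_lean_wc,
    "lean_bmi": _fp_lean_bmi,
    "lean_bmi_tr": _fp_lean_bmi_tr,
    "lean_log4sk": _fp_lean_log4sk,
    "gomez_ambrosi": _fp_gomez_ambrosi,
    "isak5_fp": _fp_isak5,
    "lee_dh_fp": _fp_lee_dh,
    "giro": _fp_giro,
    "cavedon1": _fp_cavedon1,
    "cavedon2": _fp_cavedon2,
    "al_guindan": _fm_al_guindan,
    "de_rose_fm": _fm_de_rose,
    "isak5_fm": _fm_isak5,
    "heitmann": _fm_heitmann,
    "lee_dh_fm": _fm_lee_dh,
    "salamat_fm": _fm_salamat,
    "lee_rc_lp": _lp_lee_rc,
    "poortmans": _lp_poortmans,
    "isak5_lp": _lp_isak5,
    "de_rose_lm": _lm_de_rose,
    "heymsfield": _lm_heymsfield,
    "lee_rc_1": _lm_lee_rc_1,
    "lee_rc_2": _lm_lee_rc_2,
    "doupe": _lm_doupe,
    "isak5_lm": _lm_isak5,
    "janmahasatian": _lm_janmahasatian,
    "olshvang": _lm_olshvang,
    "chien": _lm_chien,
    "lee_dh_lm": _lm_lee_dh,
    "kulkarni3": _lm_kulkarni3,
    "kulkarni4": _lm_kulkarni4,
    "salamat_lm": _lm_salamat,
}


def get_spec(equation_id: str) -> EquationSpec:
    try:
        return REGISTRY[equation_id]
    except KeyError:
        raise KeyError(f"unknown equation {equation_id!r}") from None


def list_equations(
    output_filter: Optional[str] = None, include_untested: bool = False
) -> list[EquationSpec]:
    """Registry specs in deterministic (reporting) order.

    With ``output_filter`` set to a family, the counts match the study's
    Bonferroni families: FP 34, FM 6, LP 3, LM 13 (plus BD 8 when asked
    for BD).  ``include_untested`` adds registry entries the study could
    not apply.
    """
    if output_filter is not None and output_filter not in FAMILIES + ("BD",):
        raise ValueError(f"output_filter must be one of {FAMILIES + ('BD',)}, got {output_filter!r}")
    out = []
    for spec in REGISTRY.values():
        if output_filter is not None and spec.output != output_filter:
            continue
        if not include_untested and not spec.tested_in_study:
            continue
        out.append(spec)
    return out


def registry_json() -> list[dict]:
    """JSON-able export of every equation spec."""
    return [s.as_dict() for s in REGISTRY.values()]


# --------------------------------------------------------------------------
# Evaluation entry points


def estimate(
    equation_id: str, profile: AnthroProfile, options: EquationOptions = DEFAULT_OPTIONS
) -> EquationResult:
    """Evaluate any registered equation (or a ``bd+converter`` composite)."""
    spec = get_spec(equation_id)
    intermediate: dict[str, float] = {}
    if "+" in equation_id:
        bd_id, conv = equation_id.split("+", 1)
        bd = estimate_bd(bd_id, profile, options)
        intermediate["BD"] = bd
        value = bd_to_fp(conv, bd)
    elif spec.output == "BD":
        value = estimate_bd(equation_id, profile, options)
    else:
        value = _DIRECT_EVALUATORS[equation_id](profile, options)
        if equation_id in {"isak5_fm", "isak5_fp"}:
            _, intermediate = _kerr_fm(profile, options)
        elif equation_id in {"isak5_lm", "isak5_lp"}:
            _, intermediate = _kerr_lm(profile, options)
        elif equation_id == "de_rose_lm":
            intermediate["FM"] = _fm_de_rose(profile, options)
            intermediate["RM"] = 0.241 * profile.body_weight_kg
            intermediate["BM"] = profile.body_weight_kg - value - intermediate["FM"] - intermediate["RM"]
    return EquationResult(equation_id, profile.subject_id, value, intermediate)


def _family_estimate(
    equation_id: str, profile: AnthroProfile, family: str, options: EquationOptions
) -> float:
    spec = get_spec(equation_id)
    if spec.output != family and not ("+" in equation_id and family == "FP"):
        raise ValueError(f"equation {equation_id!r} estimates {spec.output}, not {family}")
    return estimate(equation_id, profile, options).value


def estimate_fp(equation_id: str, profile: AnthroProfile, options: EquationOptions = DEFAULT_OPTIONS) -> float:
    """Fat percent (0-100 scale) from a direct or composite FP equation."""
    return _family_estimate(equation_id, profile, "FP", options)


def estimate_fm(equation_id: str, profile: AnthroProfile, options: EquationOptions = DEFAULT_OPTIONS) -> float:
    """Fat mass in kg."""
    return _family_estimate(equation_id, profile, "FM", options)


def estimate_lp(equation_id: str, profile: AnthroProfile, options: EquationOptions = DEFAULT_OPTIONS) -> float:
    """Lean percent (0-100 scale)."""
    if profile.body_weight_kg <= 0:
        raise ValidationError("lean percent needs positive body weight")
    return _family_estimate(equation_id, profile, "LP", options)


def estimate_lm(equation_id: str, profile: AnthroProfile, options: EquationOptions = DEFAULT_OPTIONS) -> float:
    """Lean mass in kg."""
    return _family_estimate(equation_id, profile, "LM", options)
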