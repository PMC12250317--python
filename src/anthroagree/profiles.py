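"""Domain types for subjects and their measurements.

One canonical unit system throughout: skinfolds in millimetres,
circumferences/diameters/height in centimetres, masses in kilograms.
Unit conversion, where an equation wants something else (e.g. height in
metres), happens inside the equation evaluator, never on the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "SKINFOLD_SITES",
    "CIRCUMFERENCE_SITES",
    "DIAMETER_SITES",
    "SEXES",
    "RACES",
    "AMPUTATION_LEVELS",
    "AnthroProfile",
    "ReferenceMeasurement",
    "DerivedMeasures",
    "ValidationError",
    "MissingSiteError",
    "compute_bmi",
    "sum_skinfolds",
    "corrected_girth",
    "read_cohort",
    "write_cohort",
]

#: Skinfold site codes (mm). AX (axillary) and CH (chest) are optional —
#: the study protocol did not collect them.
SKINFOLD_SITES = ("BI", "TR", "SS", "SI", "SSP", "AB", "TH", "C", "AX", "CH")

#: Circumference site codes (cm): relaxed arm, forearm, thigh, calf,
#: chest, waist, hip.
CIRCUMFERENCE_SITES = ("Ac", "FAc", "THc", "Cc", "CHc", "WC", "HC")

#: Bone diameter codes (cm): wrist and femur (biepicondylar).
DIAMETER_SITES = ("WD", "FD")

SEXES = ("male", "female")
RACES = ("white", "hispanic", "mexican", "afro_descendant", "asian", "other")
AMPUTATION_LEVELS = ("transtibial", "transfemoral", "hip_disarticulation", "none")

#: The printed value of pi used inside corrected girths; a config switch
#: (``EquationOptions.full_precision_pi``) swaps in ``math.pi``.
PI_PRINTED = 3.141


class ValidationError(ValueError):
    """Raised when a profile or measurement violates its invariants."""


class MissingSiteError(ValidationError):
    """Raised when an equation requests a measurement site that is absent."""

    def __init__(self, site: str, requested_by: str = "") -> None:
        self.site = site
        self.requested_by = requested_by
        suffix = f" (required by {requested_by})" if requested_by else ""
        super().__init__(f"missing measurement site {site!r}{suffix}")


SexLike = Union[str, float]


def _check_sex(sex: SexLike) -> SexLike:
    if isinstance(sex, str):
        if sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {sex!r}")
        return sex
    frac = float(sex)
    if not 0.0 <= frac <= 1.0:
        raise ValidationError(f"sex fraction (male share) must lie in [0, 1], got {frac}")
    return frac


@dataclass
class AnthroProfile:
    """Raw anthropometry and demographics for one subject.

    ``sex`` is normally a category (``"male"``/``"female"``) but may be a
    float in [0, 1] giving the male fraction, which lets a "mean subject"
    built from cohort means be pushed through sex-coded equations.
    """

    subject_id: str
    sex: SexLike
    age: float
    body_weight_kg: float
    height_cm: float
    race: str = "hispanic"
    skinfolds_mm: dict[str, float] = field(default_factory=dict)
    circumferences_cm: dict[str, float] = field(default_factory=dict)
    diameters_cm: dict[str, float] = field(default_factory=dict)
    amputation_level: str = "none"
    measured_side: str = "intact"
    bmi_given: Optional[float] = None  # input-file override, see .bmi

    def __post_init__(self) -> None:
        self.sex = _check_sex(self.sex)
        if self.race not in RACES:
            raise ValidationError(f"race must be one of {RACES}, got {self.race!r}")
        if self.amputation_level not in AMPUTATION_LEVELS:
            raise ValidationError(
                f"amputation_level must be one of {AMPUTATION_LEVELS}, got {self.amputation_level!r}"
            )
        if self.age < 18:
            raise ValidationError(f"age must be >= 18 years, got {self.age}")
        if self.body_weight_kg <= 0:
            raise ValidationError("body weight must be strictly positive")
        if not 100.0 <= self.height_cm <= 230.0:
            raise ValidationError(f"height_cm must lie in [100, 230], got {self.height_cm}")
        for name, table, allowed in (
            ("skinfolds_mm", self.skinfolds_mm, SKINFOLD_SITES),
            ("circumferences_cm", self.circumferences_cm, CIRCUMFERENCE_SITES),
            ("diameters_cm", self.diameters_cm, DIAMETER_SITES),
        ):
            for site, value in table.items():
                if site not in allowed:
                    raise ValidationError(f"unknown {name} site {site!r}")
                if value is None:
                    raise ValidationError(
                        f"{name}[{site!r}] is None; absent sites must be omitted, not stored"
                    )
                if not value > 0:
                    raise ValidationError(f"{name}[{site!r}] must be strictly positive, got {value}")

    @property
    def bmi(self) -> float:
        """BMI in kg/m2: the input-file value if one was given, else recomputed."""
        if self.bmi_given is not None:
            return self.bmi_given
        return compute_bmi(self.body_weight_kg, self.height_cm)

    @property
    def bmi_provenance(self) -> str:
        return "given" if self.bmi_given is not None else "computed"

    def skinfold(self, site: str, requested_by: str = "") -> float:
        try:
            return self.skinfolds_mm[site]
        except KeyError:
            raise MissingSiteError(site, requested_by) from None

    def circumference(self, site: str, requested_by: str = "") -> float:
        try:
            return self.circumferences_cm[site]
        except KeyError:
            raise MissingSiteError(site, requested_by) from None

    def diameter(self, site: str, requested_by: str = "") -> float:
        try:
            return self.diameters_cm[site]
        except KeyError:
            raise MissingSiteError(site, requested_by) from None


@dataclass
class ReferenceMeasurement:
    """DXA-style reference body composition for one subject."""

    fp_percent: float
    fm_kg: float
    lp_percent: float
    lm_kg: float
    bmc_kg: Optional[float] = None
    body_weight_kg: Optional[float] = None  # for the FM/LM < BW invariants

    def __post_init__(self) -> None:
        for name in ("fp_percent", "lp_percent"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValidationError(f"{name} must lie in (0, 100), got {v}")
        if self.fm_kg <= 0 or self.lm_kg <= 0:
            raise ValidationError("fm_kg and lm_kg must be strictly positive")
        if self.body_weight_kg is not None:
            if self.fm_kg >= self.body_weight_kg:
                raise ValidationError("fat mass must be smaller than body weight")
            if self.lm_kg >= self.body_weight_kg:
                raise ValidationError("lean mass must be smaller than body weight")

    def value_for(self, family: str) -> float:
        return {
            "FP": self.fp_percent,
            "FM": self.fm_kg,
            "LP": self.lp_percent,
            "LM": self.lm_kg,
        }[family]


@dataclass
class SkinfoldSum:
    """An arithmetic skinfold sum that remembers the site list it used."""

    value_mm: float
    sites: tuple[str, ...]


@dataclass
class DerivedMeasures:
    bmi_kg_m2: float
    skinfold_sums: dict[str, SkinfoldSum]
    corrected_girths_cm: dict[str, float]


def compute_bmi(body_weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m2."""
    if body_weight_kg <= 0 or height_cm <= 0:
        raise ValidationError("BMI needs strictly positive weight and height")
    return body_weight_kg / (height_cm / 100.0) ** 2


def sum_skinfolds(
    profile: AnthroProfile, sites: Sequence[str], requested_by: str = ""
) -> SkinfoldSum:
    """Sum the named skinfold sites (mm), recording which sites were used.

    Missing sites raise :class:`MissingSiteError` naming the site and the
    requesting equation.
    """
    total = 0.0
    for site in sites:
        total += profile.skinfold(site, requested_by)
    return SkinfoldSum(total, tuple(sites))


def corrected_girth(
    circumference_cm: float, skinfold_mm: float, pi: float = PI_PRINTED
) -> float:
    """Limb girth corrected for the overlying skinfold.

    ``c = girth - skinfold * pi / 10``; the /10 converts mm to cm.  ``pi``
    defaults to the printed 3.141.
    """
    if circumference_cm <= 0 or skinfold_mm < 0:
        raise ValidationError("corrected_girth needs positive girth and non-negative skinfold")
    c = circumference_cm - skinfold_mm * pi / 10.0
    if c <= 0:
        raise ValidationError(
            f"corrected girth {c:.3f} <= 0 for girth {circumference_cm}, skinfold {skinfold_mm}"
        )
    return c


def derived_measures(profile: AnthroProfile, pi: float = PI_PRINTED) -> DerivedMeasures:
    """BMI, the two standard skinfold sums and the four corrected girths.

    Only sums/girths whose inputs are present are reported.
    """
    sums: dict[str, SkinfoldSum] = {}
    for name, sites in (("sum4sk", ("BI", "TR", "SS", "SI")), ("sum6sk", ("TR", "SS", "SI", "AB", "TH", "C"))):
        try:
            sums[name] = sum_skinfolds(profile, sites)
        except MissingSiteError:
            pass
    girths: dict[str, float] = {}
    for name, (girth_site, fold_site) in {
        "cAC": ("Ac", "TR"),
        "cTHC": ("THc", "TH"),
        "cCC": ("Cc", "C"),
        "cCHC": ("CHc", "SS"),
    }.items():
        try:
            girths[name] = corrected_girth(
                profile.circumference(girth_site), profile.skinfold(fold_site), pi
            )
        except MissingSiteError:
            pass
    return DerivedMeasures(profile.bmi, sums, girths)


# --------------------------------------------------------------------------
# Cohort file I/O.  One row per subject; header names are the field/site
# codes above; an empty cell means "missing" (never zero).

_META_COLUMNS = ["subject_id", "sex", "age", "race", "amputation_level", "body_weight_kg", "height_cm", "bmi"]
_REF_COLUMNS = ["fp_percent", "fm_kg", "lp_percent", "lm_kg", "bmc_kg"]
_SITE_COLUMNS = list(SKINFOLD_SITES) + list(CIRCUMFERENCE_SITES) + list(DIAMETER_SITES)
COHORT_COLUMNS = _META_COLUMNS + _SITE_COLUMNS + _REF_COLUMNS


def _row_to_profile(row: Mapping[str, object]) -> AnthroProfile:
    def grab(sites: Iterable[str]) -> dict[str, float]:
        out = {}
        for s in sites:
            v = row.get(s)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                out[s] = float(v)  # type: ignore[arg-type]
        return out

    bmi = row.get("bmi")
    if bmi is not None and isinstance(bmi, float) and math.isnan(bmi):
        bmi = None
    return AnthroProfile(
        subject_id=str(row["subject_id"]),
        sex=row["sex"] if isinstance(row["sex"], str) else float(row["sex"]),  # type: ignore[arg-type]
        age=float(row["age"]),  # type: ignore[arg-type]
        race=str(row.get("race", "hispanic")),
        body_weight_kg=float(row["body_weight_kg"]),  # type: ignore[arg-type]
        height_cm=float(row["height_cm"]),  # type: ignore[arg-type]
        skinfolds_mm=grab(SKINFOLD_SITES),
        circumferences_cm=grab(CIRCUMFERENCE_SITES),
        diameters_cm=grab(DIAMETER_SITES),
        amputation_level=str(row.get("amputation_level", "none")),
        bmi_given=None if bmi is None else float(bmi),  # type: ignore[arg-type]
    )


def read_cohort(path: Union[str, Path]) -> tuple[list[AnthroProfile], list[Optional[ReferenceMeasurement]]]:
    """Read a cohort CSV or XLSX into profiles plus (optional) references."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    profiles: list[AnthroProfile] = []
    references: list[Optional[ReferenceMeasurement]] = []
    for _, row in df.iterrows():
        record = row.to_dict()
        profile = _row_to_profile(record)
        profiles.append(profile)
        ref_vals = {c: record.get(c) for c in _REF_COLUMNS}
        have = {
            k: float(v)
            for k, v in ref_vals.items()
            if v is not None and not (isinstance(v, float) and math.isnan(v))
        }
        if {"fp_percent", "fm_kg", "lp_percent", "lm_kg"} <= set(have):
            references.append(
                ReferenceMeasurement(
                    fp_percent=have["fp_percent"],
                    fm_kg=have["fm_kg"],
                    lp_percent=have["lp_percent"],
                    lm_kg=have["lm_kg"],
                    bmc_kg=have.get("bmc_kg"),
                    body_weight_kg=profile.body_weight_kg,
                )
            )
        else:
            references.append(None)
    return profiles, references


def cohort_frame(
    profiles: Sequence[AnthroProfile],
    references: Optional[Sequence[Optional[ReferenceMeasurement]]] = None,
) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(profiles):
        row: dict[str, object] = {
            "subject_id": p.subject_id,
            "sex": p.sex,
            "age": p.age,
            "race": p.race,
            "amputation_level": p.amputation_level,
            "body_weight_kg": p.body_weight_kg,
            "height_cm": p.height_cm,
            "bmi": p.bmi_given,
        }
        row.update(p.skinfolds_mm)
        row.update(p.circumferences_cm)
        row.update(p.diameters_cm)
        if references is not None and references[i] is not None:
            ref = references[i]
            assert ref is not None
            row.update(
                fp_percent=ref.fp_percent,
                fm_kg=ref.fm_kg,
                lp_percent=ref.lp_percent,
                lm_kg=ref.lm_kg,
                bmc_kg=ref.bmc_kg,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(
    path: Union[str, Path],
    profiles: Sequence[AnthroProfile],
    references: Optional[Sequence[Optional[ReferenceMeasurement]]] = None,
) -> None:
    """Write a cohort in the same schema :func:`read_cohort` reads."""
    path = Path(path)
    df = cohort_frame(profiles, references)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
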