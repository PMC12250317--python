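"""Synthetic cohorts with the statistical structure the validation assumes.

The generator emulates a small cohort of adult para-athletes with
unilateral lower-limb amputation: ~27 subjects, a 22:5 male:female mix,
pooled per-variable means/SDs matching the study sample's descriptive
table, and a correlated structure driven by two latent factors —
*adiposity* (loads on every skinfold and, more weakly, on girths and
weight) and *frame size* (loads on height, girths, weight, diameters).
Skinfolds are drawn log-normally so they stay positive and right-skewed;
girths, height, weight and diameters are Gaussian.

Reference (DXA-style) values are simulated *from a chosen equation*:
``reference = equation(profile) + bias + N(0, noise_sd^2)`` for the
family under test, with the remaining compartments filled in
consistently (FM = FP*BW/100, LM = BW - FM - BMC, ...).  That makes the
true bias and noise of the "reference method" known quantities the
pipeline can be checked against.

Forearm and hip circumferences and the two bone diameters are not part
of the study's descriptive table; their default moments are synthetic,
chosen as realistic adult values, and labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .equations import DEFAULT_OPTIONS, EquationOptions, estimate, get_spec
from .profiles import AnthroProfile, ReferenceMeasurement

__all__ = [
    "TABLE_MOMENTS",
    "SYNTHETIC_MOMENTS",
    "ReferenceModel",
    "CohortConfig",
    "generate_cohort",
    "fixture_cohort",
    "duplicate_measurement_fixture",
]

#: Per-variable pooled (mean, SD) targets from the study's descriptive
#: sample table (n = 27 athletes).
TABLE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (32.85, 7.38),
    "body_weight_kg": (69.52, 13.39),
    "height_cm": (167.63, 6.8),
    "Ac": (32.05, 4.54),
    "THc": (55.59, 4.88),
    "Cc": (36.76, 3.4),
    "CHc": (100.0, 8.6),
    "WC": (95.0, 7.11),
    "TR": (11.8, 5.07),
    "SS": (18.3, 8.3),
    "BI": (7.0, 3.6),
    "SI": (23.07, 8.07),
    "SSP": (15.31, 7.86),
    "AB": (25.45, 9.02),
    "TH": (14.4, 6.0),
    "C": (9.77, 5.26),
    "fp_percent": (27.1, 6.83),
    "fm_kg": (18.32, 6.1),
    "lp_percent": (50.66, 9.24),
    "lm_kg": (49.16, 9.53),
    "bmc_kg": (2.5, 0.42),
}

#: SYNTHETIC moments for variables the study's descriptive table does not
#: report (forearm/hip girth, wrist/femur diameter) — realistic adult
#: values, not taken from any publication.
SYNTHETIC_MOMENTS: dict[str, tuple[float, float]] = {
    "FAc": (26.0, 2.5),
    "HC": (98.0, 6.0),
    "WD": (5.5, 0.35),
    "FD": (9.4, 0.6),
}

_SKINFOLDS = ("BI", "TR", "SS", "SI", "SSP", "AB", "TH", "C")
_GIRTHS = ("Ac", "FAc", "THc", "Cc", "CHc", "WC", "HC")
_DIAMETERS = ("WD", "FD")


@dataclass(frozen=True)
class ReferenceModel:
    """How the simulated reference method relates to a chosen equation."""

    equation_id: str = "hastuti"
    bias: float = 0.7
    noise_sd: float = 4.55


@dataclass
class CohortConfig:
    n_subjects: int = 27
    male_fraction: float = 22.0 / 27.0
    amputation_mix: dict[str, int] = field(
        default_factory=lambda: {"transtibial": 15, "transfemoral": 9, "hip_disarticulation": 3}
    )
    target_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {**TABLE_MOMENTS, **SYNTHETIC_MOMENTS}
    )
    #: latent loadings: skinfolds on adiposity; girths/weight on frame and
    #: adiposity (free parameters — the study reports no correlations)
    adiposity_loading: float = 0.75
    girth_frame_loading: float = 0.55
    girth_adiposity_loading: float = 0.5
    latent_correlation: float = 0.3
    #: mean-centered sex offsets (women vs cohort mean), in each
    #: variable's own units; centering keeps pooled moments on target
    sex_offsets: dict[str, float] = field(
        default_factory=lambda: {"TR": 2.5, "TH": 3.0, "Ac": -2.0, "WC": -4.0, "height_cm": -8.0, "body_weight_kg": -7.0}
    )
    race: str = "hispanic"
    reference_model: ReferenceModel = field(default_factory=ReferenceModel)
    seed: int = 0
    options: EquationOptions = DEFAULT_OPTIONS

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        for name, (m, s) in self.target_moments.items():
            if s <= 0:
                raise ValueError(f"target SD for {name!r} must be > 0")
            if name in _SKINFOLDS + _GIRTHS + _DIAMETERS and m <= 0:
                raise ValueError(f"target mean for {name!r} must be > 0")
        if sum(self.amputation_mix.values()) != self.n_subjects:
            raise ValueError("amputation counts must sum to n_subjects")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_cohort_arrays(cfg: CohortConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = cfg.n_subjects
    rho = cfg.latent_correlation
    adiposity = rng.standard_normal(n)
    frame = rho * adiposity + math.sqrt(1 - rho**2) * rng.standard_normal(n)

    n_male = int(round(n * cfg.male_fraction))
    is_female = np.zeros(n, dtype=bool)
    is_female[n_male:] = True
    rng.shuffle(is_female)

    values: dict[str, np.ndarray] = {"is_female": is_female}

    # age: independent, truncated at adulthood by resampling
    m, s = cfg.target_moments["age"]
    age = m + s * rng.standard_normal(n)
    while np.any(age < 18.0):
        bad = age < 18.0
        age[bad] = m + s * rng.standard_normal(int(bad.sum()))
    values["age"] = age

    w = cfg.adiposity_loading
    for site in _SKINFOLDS:
        m, s = cfg.target_moments[site]
        mu, sigma = _lognormal_params(m, s)
        z = w * adiposity + math.sqrt(1 - w**2) * rng.standard_normal(n)
        values[site] = np.exp(mu + sigma * z)

    wf, wa = cfg.girth_frame_loading, cfg.girth_adiposity_loading
    resid = math.sqrt(max(1e-9, 1.0 - wf**2 - wa**2))
    norm = math.sqrt(wf**2 + wa**2 + 2 * wf * wa * rho + resid**2)
    for name in _GIRTHS + ("body_weight_kg",):
        m, s = cfg.target_moments[name]
        u = (wf * frame + wa * adiposity + resid * rng.standard_normal(n)) / norm
        values[name] = m + s * u

    for name in ("height_cm",) + _DIAMETERS:
        m, s = cfg.target_moments[name]
        u = 0.6 * frame + 0.8 * rng.standard_normal(n)  # var = 0.36 + 0.64 = 1
        values[name] = m + s * u

    # mean-centered sex offsets: women shift by (1 - f_female)*delta,
    # men by -f_female*delta, so the pooled mean stays on target
    f_female = float(np.mean(is_female))
    for name, delta in cfg.sex_offsets.items():
        if name not in values:
            continue
        shift = np.where(is_female, (1.0 - f_female) * delta, -f_female * delta)
        values[name] = values[name] + shift

    # keep physical: positive lengths, height inside the plausible band
    for site in _SKINFOLDS:
        values[site] = np.clip(values[site], 0.5, None)
    for name in _GIRTHS + _DIAMETERS:
        values[name] = np.clip(values[name], 1.0, None)
    values["height_cm"] = np.clip(values["height_cm"], 101.0, 229.0)
    values["body_weight_kg"] = np.clip(values["body_weight_kg"], 30.0, None)
    return values


def _amputation_labels(cfg: CohortConfig, rng: np.random.Generator) -> list[str]:
    labels: list[str] = []
    for level, count in cfg.amputation_mix.items():
        labels.extend([level] * count)
    labels = list(np.array(labels)[rng.permutation(len(labels))])
    return labels


def _profiles_from_arrays(
    values: dict[str, np.ndarray], cfg: CohortConfig, rng: np.random.Generator
) -> list[AnthroProfile]:
    n = cfg.n_subjects
    amputation = _amputation_labels(cfg, rng)
    profiles = []
    for i in range(n):
        profiles.append(
            AnthroProfile(
                subject_id=f"S{i + 1:03d}",
                sex="female" if values["is_female"][i] else "male",
                age=float(values["age"][i]),
                race=cfg.race,
                body_weight_kg=float(values["body_weight_kg"][i]),
                height_cm=float(values["height_cm"][i]),
                skinfolds_mm={s: float(values[s][i]) for s in _SKINFOLDS},
                circumferences_cm={g: float(values[g][i]) for g in _GIRTHS},
                diameters_cm={d: float(values[d][i]) for d in _DIAMETERS},
                amputation_level=amputation[i],
            )
        )
    return profiles


def _simulate_references(
    profiles: Sequence[AnthroProfile], cfg: CohortConfig, rng: np.random.Generator
) -> list[ReferenceMeasurement]:
    model = cfg.reference_model
    family = get_spec(model.equation_id).output
    if family == "BD":
        raise ValueError("reference_model must target FP, FM, LP or LM, not BD")
    bmc_m, bmc_s = cfg.target_moments["bmc_kg"]
    refs = []
    for p in profiles:
        est = estimate(model.equation_id, p, cfg.options).value
        anchor = est + model.bias + rng.normal(0.0, model.noise_sd)
        bw = p.body_weight_kg
        bmc = max(0.5, rng.normal(bmc_m, bmc_s))
        # derive the remaining compartments consistently from the anchored
        # one, clipping the anchor only at physical impossibility
        fm_cap = bw - bmc - 0.2
        if family == "FP":
            fp = min(max(anchor, 0.5), fm_cap / bw * 100.0)
            fm = fp * bw / 100.0
            lm = bw - fm - bmc
        elif family == "FM":
            fm = min(max(anchor, 0.1), fm_cap)
            fp = fm / bw * 100.0
            lm = bw - fm - bmc
        else:  # LM or LP anchor the lean side
            lm = anchor if family == "LM" else anchor * bw / 100.0
            lm = min(max(lm, 0.2), fm_cap)
            fm = bw - lm - bmc
            fp = fm / bw * 100.0
        refs.append(
            ReferenceMeasurement(
                fp_percent=float(fp),
                fm_kg=float(fm),
                lp_percent=float(lm / bw * 100.0),
                lm_kg=float(lm),
                bmc_kg=float(bmc),
                body_weight_kg=bw,
            )
        )
    return refs


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: Optional[int] = None
) -> tuple[list[AnthroProfile], list[ReferenceMeasurement]]:
    """Draw a cohort of profiles plus simulated reference measurements.

    Deterministic for a given config+seed; per-variable sample moments
    converge to the configured targets as n grows.
    """
    cfg = config if config is not None else CohortConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    values = _draw_cohort_arrays(cfg, rng)
    profiles = _profiles_from_arrays(values, cfg, rng)
    references = _simulate_references(profiles, cfg, rng)
    return profiles, references


_FIXTURE_REF_KEYS = ("fp_percent", "fm_kg", "lp_percent", "lm_kg", "bmc_kg")


def fixture_cohort(
    seed: int = 0, config: Optional[CohortConfig] = None
) -> tuple[list[AnthroProfile], list[ReferenceMeasurement]]:
    """A 27-subject cohort moment-matched *exactly* to the descriptive table.

    After drawing a structured cohort, every targeted variable is
    affinely standardized so its sample mean and (ddof=1) SD equal the
    configured targets exactly, preserving the correlation structure.
    Reference values are standardized the same way, so they match the
    printed DXA moments but are no longer an exact function of one
    equation.
    """
    cfg = config if config is not None else CohortConfig()
    cfg = replace(cfg, seed=seed)
    for attempt in range(64):
        rng = np.random.default_rng(cfg.seed + 100_003 * attempt)
        values = _draw_cohort_arrays(cfg, rng)
        ok = True
        for name, (m, s) in cfg.target_moments.items():
            if name in _FIXTURE_REF_KEYS:
                continue
            v = values[name]
            sv = float(np.std(v, ddof=1))
            if sv == 0.0:
                ok = False
                break
            z = (v - float(np.mean(v))) / sv
            new = m + s * z
            if name in _SKINFOLDS + _GIRTHS + _DIAMETERS + ("body_weight_kg",) and np.any(new <= 0):
                ok = False
                break
            if name == "height_cm" and (np.any(new < 100.0) or np.any(new > 230.0)):
                ok = False
                break
            if name == "age" and np.any(new < 18.0):
                ok = False
                break
            values[name] = new
        if not ok:
            continue
        profiles = _profiles_from_arrays(values, cfg, rng)
        raw_refs = _simulate_references(profiles, cfg, rng)
        ref_arrays = {
            k: np.array([getattr(r, k) for r in raw_refs], dtype=float) for k in _FIXTURE_REF_KEYS
        }
        std_ok = True
        for k in _FIXTURE_REF_KEYS:
            m, s = cfg.target_moments[k]
            v = ref_arrays[k]
            sv = float(np.std(v, ddof=1))
            if sv == 0.0:
                std_ok = False
                break
            ref_arrays[k] = m + s * (v - float(np.mean(v))) / sv
        if not std_ok or np.any(ref_arrays["fp_percent"] <= 0) or np.any(ref_arrays["fp_percent"] >= 100):
            continue
        if np.any(ref_arrays["lp_percent"] <= 0) or np.any(ref_arrays["fm_kg"] <= 0) or np.any(ref_arrays["lm_kg"] <= 0):
            continue
        references = [
            ReferenceMeasurement(
                fp_percent=float(ref_arrays["fp_percent"][i]),
                fm_kg=float(ref_arrays["fm_kg"][i]),
                lp_percent=float(ref_arrays["lp_percent"][i]),
                lm_kg=float(ref_arrays["lm_kg"][i]),
                bmc_kg=float(ref_arrays["bmc_kg"][i]),
            )
            for i in range(cfg.n_subjects)
        ]
        return profiles, references
    raise RuntimeError("could not produce a physically valid moment-matched cohort")


def duplicate_measurement_fixture(
    profiles: Sequence[AnthroProfile],
    rel_tem_percent: float = 0.7,
    seed: int = 0,
    sites: Sequence[str] = _SKINFOLDS,
) -> dict[str, np.ndarray]:
    """Simulated duplicate readings with a known relative TEM.

    For each site the second reading is the first plus
    ``N(0, 2 * (rel_tem * mean / 100)^2)``, which makes the expected
    relative TEM equal ``rel_tem_percent``.  Returns ``site -> (n, 2)``.
    """
    if rel_tem_percent < 0:
        raise ValueError("rel_tem_percent must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for site in sites:
        first = np.array([p.skinfold(site, "duplicate_fixture") for p in profiles], dtype=float)
        sd = math.sqrt(2.0) * rel_tem_percent / 100.0 * float(np.mean(first))
        second = first + rng.normal(0.0, sd, size=first.size) if sd > 0 else first.copy()
        out[site] = np.column_stack([first, second])
    return out
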