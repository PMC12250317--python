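"""Orchestration: cohort -> equation estimates -> agreement battery -> reports.

``run_validation`` produces, per family (FP/FM/LP/LM), one agreement
report row per applicable equation plus a descriptive summary (mean +/-
SD per equation and for the reference), mirroring the layout a
method-comparison validation study would report.  ``recommend`` codifies
the study's informal decision narrative as an explicit, configurable
rule cascade.  ``export_outputs`` writes everything as tidy CSV/JSON
with a reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementReport,
    FAMILY_SIZES,
    PairedSample,
    agreement_report,
)
from .equations import (
    DEFAULT_OPTIONS,
    EquationOptions,
    estimate,
    list_equations,
    registry_json,
)
from .profiles import AnthroProfile, MissingSiteError, ReferenceMeasurement, ValidationError
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "RunConfig",
    "FamilyResult",
    "ValidationRun",
    "run_validation",
    "recommend",
    "export_outputs",
]

log = logging.getLogger("anthroagree")

#: Clinically tolerable bias per family: percent-points for FP/LP, kg for
#: FM/LM.  The FP limit follows the study's "bias exceeding 1% is too
#: large" reading; the LP limit mirrors FP.
DEFAULT_CLINICAL_LIMITS = {"FP": 1.0, "FM": 1.0, "LP": 1.0, "LM": 1.5}


@dataclass
class RunConfig:
    families: tuple[str, ...] = ("FP", "FM", "LP", "LM")
    alpha: float = 0.05
    family_sizes: dict[str, int] = field(default_factory=lambda: dict(FAMILY_SIZES))
    clinical_bias_limits: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLINICAL_LIMITS))
    options: EquationOptions = DEFAULT_OPTIONS
    strict: bool = False  # error (instead of skip) on unsatisfiable equations
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("families must be non-empty")
        for fam in self.families:
            if fam not in FAMILY_SIZES:
                raise ValueError(f"unknown family {fam!r}")
        for fam, lim in self.clinical_bias_limits.items():
            if lim <= 0:
                raise ValueError(f"clinical bias limit for {fam} must be > 0")


@dataclass
class FamilyResult:
    family: str
    reports: list[AgreementReport]
    summary: pd.DataFrame  # mean +/- SD per equation, reference row first
    skipped: dict[str, str]  # equation_id -> reason
    recommendations: dict[str, tuple[str, list[str]]]
    samples: dict[str, PairedSample]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append(
                {
                    "equation_id": r.equation_id,
                    "n": r.n,
                    "mean_diff": r.mean_diff,
                    "sd_diff": r.sd_diff,
                    "sed": r.sed,
                    "ci95_lower": r.ci95[0],
                    "ci95_upper": r.ci95[1],
                    "p_value": r.p_value,
                    "test_used": r.test_used,
                    "significant_after_bonferroni": r.significant_after_bonferroni,
                    "icc_absolute": r.icc_absolute,
                    "icc_absolute_ci_lower": r.icc_absolute_ci[0],
                    "icc_absolute_ci_upper": r.icc_absolute_ci[1],
                    "icc_absolute_band": r.icc_absolute_band,
                    "icc_consistency": r.icc_consistency,
                    "icc_consistency_ci_lower": r.icc_consistency_ci[0],
                    "icc_consistency_ci_upper": r.icc_consistency_ci[1],
                    "icc_consistency_band": r.icc_consistency_band,
                    "corr": r.corr,
                    "corr_type": r.corr_type,
                    "corr_band": r.corr_band,
                    "rma_slope": r.rma_slope,
                    "rma_intercept": r.rma_intercept,
                    "loa_lower": r.loa[0],
                    "loa_upper": r.loa[1],
                    "normality_gate": r.gate,
                    "recommendation": self.recommendations.get(r.equation_id, ("", []))[0],
                    "recommendation_reasons": "; ".join(
                        self.recommendations.get(r.equation_id, ("", []))[1]
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ValidationRun:
    config: RunConfig
    families: dict[str, FamilyResult]
    n_subjects: int


def _reference_vector(references: Sequence[ReferenceMeasurement], family: str) -> np.ndarray:
    return np.array([r.value_for(family) for r in references], dtype=float)


def run_validation(
    profiles: Sequence[AnthroProfile],
    references: Sequence[ReferenceMeasurement],
    config: Optional[RunConfig] = None,
) -> ValidationRun:
    """Run the agreement battery for every applicable equation.

    Equations whose inputs a cohort cannot satisfy (missing sites,
    unmapped race offsets) are skipped with a logged reason unless
    ``config.strict``.
    """
    cfg = config if config is not None else RunConfig()
    if len(profiles) != len(references):
        raise ValueError("profiles and references must be aligned")
    if any(r is None for r in references):
        raise ValueError("every subject needs a reference measurement")
    results: dict[str, FamilyResult] = {}
    for family in cfg.families:
        y = _reference_vector(references, family)
        reports: list[AgreementReport] = []
        skipped: dict[str, str] = {}
        recommendations: dict[str, tuple[str, list[str]]] = {}
        samples: dict[str, PairedSample] = {}
        summary_rows = [
            {
                "equation_id": "reference",
                "mean": float(np.mean(y)),
                "sd": float(np.std(y, ddof=1)),
            }
        ]
        for spec in list_equations(family):
            try:
                x = np.array(
                    [estimate(spec.equation_id, p, cfg.options).value for p in profiles],
                    dtype=float,
                )
            except (MissingSiteError, ValidationError) as exc:
                if cfg.strict:
                    raise
                skipped[spec.equation_id] = str(exc)
                log.info("skipping %s: %s", spec.equation_id, exc)
                continue
            sample = PairedSample(x, y, family=family, equation_id=spec.equation_id)
            report = agreement_report(
                sample, alpha=cfg.alpha, family_size=cfg.family_sizes.get(family)
            )
            reports.append(report)
            samples[spec.equation_id] = sample
            recommendations[spec.equation_id] = recommend(report, cfg)
            summary_rows.append(
                {
                    "equation_id": spec.equation_id,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                }
            )
        if not reports:
            raise ValueError(f"family {family}: every equation was skipped")
        results[family] = FamilyResult(
            family=family,
            reports=reports,
            summary=pd.DataFrame(summary_rows),
            skipped=skipped,
            recommendations=recommendations,
            samples=samples,
        )
    return ValidationRun(cfg, results, len(profiles))


def recommend(report: AgreementReport, config: Optional[RunConfig] = None) -> tuple[str, list[str]]:
    """Rule cascade codifying the study's recommendation logic.

    recommended: not significant after Bonferroni AND |bias| within the
    clinical limit AND almost-perfect absolute-agreement ICC.
    acceptable_with_caution: at least substantial ICCa and |bias| within
    twice the limit.  Otherwise not_recommended.  Returns the label and
    the rules that fired.
    """
    cfg = config if config is not None else RunConfig()
    limit = cfg.clinical_bias_limits.get(report.family, 1.0)
    reasons: list[str] = []
    band = report.icc_absolute_band
    bias_ok = abs(report.mean_diff) <= limit
    sig = report.significant_after_bonferroni
    reasons.append(
        f"paired test {'significant' if sig else 'not significant'} after Bonferroni "
        f"(p={report.p_value:.4g})"
    )
    reasons.append(f"|bias| {abs(report.mean_diff):.2f} vs clinical limit {limit:g}")
    reasons.append(f"ICC(absolute) {report.icc_absolute:.2f} ({band})")
    if not sig and bias_ok and band == "almost_perfect":
        return "recommended", reasons
    if band in ("almost_perfect", "substantial") and abs(report.mean_diff) <= 2 * limit:
        return "acceptable_with_caution", reasons
    return "not_recommended", reasons


def export_outputs(
    run: ValidationRun,
    out_dir: Union[str, Path],
    manifest_extra: Optional[dict] = None,
) -> list[Path]:
    """Write per-family report CSV+JSON, Bland-Altman pair CSVs, the
    equation registry and a reproducibility manifest.  Returns the paths
    written."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []

    def _write(path: Path, writer) -> None:
        try:
            writer(path)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        written.append(path)

    for family, res in run.families.items():
        table = res.table
        _write(out / f"report_{family}.csv", lambda p, t=table: t.to_csv(p, index=False))
        _write(
            out / f"report_{family}.json",
            lambda p, t=table: p.write_text(t.to_json(orient="records", indent=2)),
        )
        _write(out / f"summary_{family}.csv", lambda p, r=res: r.summary.to_csv(p, index=False))
        ba_dir = out / "bland_altman"
        ba_dir.mkdir(exist_ok=True)
        for eq_id, sample in res.samples.items():
            pairs = pd.DataFrame(
                {
                    "subject_mean": (sample.x + sample.y) / 2.0,
                    "difference": sample.differences,
                }
            )
            safe = eq_id.replace("+", "_plus_")
            _write(ba_dir / f"{family}_{safe}.csv", lambda p, d=pairs: d.to_csv(p, index=False))
        if res.skipped:
            _write(
                out / f"skipped_{family}.json",
                lambda p, s=res.skipped: p.write_text(json.dumps(s, indent=2)),
            )
    _write(out / "registry.json", lambda p: p.write_text(json.dumps(registry_json(), indent=2)))
    manifest = {
        "package": "anthroagree",
        "version": __version__,
        "seed": run.config.seed,
        "alpha": run.config.alpha,
        "families": list(run.config.families),
        "family_sizes": run.config.family_sizes,
        "clinical_bias_limits": run.config.clinical_bias_limits,
        "options": asdict(run.config.options),
        "n_subjects": run.n_subjects,
        "bias_convention": "mean(reference - estimate); positive = equation underestimates",
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    _write(out / "manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))
    return written


def run_synthetic_validation(
    cohort_config: Optional[CohortConfig] = None,
    run_config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> ValidationRun:
    """Convenience: generate a synthetic cohort and validate it."""
    profiles, references = generate_cohort(cohort_config, seed=seed)
    cfg = run_config if run_config is not None else RunConfig()
    if seed is not None:
        cfg.seed = seed
    return run_validation(profiles, references, cfg)
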