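"""End-to-end orchestration: single measurements and validation studies.

A single measurement runs resample -> absorbance -> least-squares retrieval
-> optional calibration inversion.  Negative retrievals (possible on noisy
input because the estimator is linear) are kept raw internally but clamped
to zero in the reported value, with a quality flag.

The accuracy study mirrors a device-versus-reference comparison (Pearson
correlation plus Bland-Altman agreement over paired measurements); the
screening study mirrors a three-group clinical comparison (group summaries,
one-way ANOVA, and ROC analyses of normal-vs-disease and normal-vs-risk).
Reports embed provenance (a config hash and seed) so identical inputs give
byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationCurve, invert_to_concentration
from .errors import InsufficientDataError, OutOfRangeError, ValidationError
from .spectral import (
    ExtinctionProfile,
    RetrievalSettings,
    Spectrum,
    WavelengthGrid,
    resample_to_integer_grid,
    retrieve_relative_concentration,
)
from .stats import (
    AgreementReport,
    AnovaResult,
    PairedSample,
    ROCReport,
    bland_altman,
    one_way_anova,
    pearson_correlation,
    roc_auc_with_ci,
)

__all__ = [
    "GROUPS",
    "SubjectRecord",
    "MeasurementResult",
    "AccuracyReport",
    "StudyReport",
    "measure_sample",
    "run_accuracy_study",
    "run_screening_study",
    "config_hash",
]

GROUPS = ("normal", "risk", "disease")

NEGATIVE_RETRIEVAL = "negative-retrieval"
CALIBRATION_OUT_OF_RANGE = "calibration-out-of-range"


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: group label, device value, optional reference value."""

    subject_id: str
    group: str
    device_value: float
    reference_value: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if not np.isfinite(self.device_value):
            raise ValidationError("device value must be finite")


@dataclass(frozen=True)
class MeasurementResult:
    """Outcome of a single-sample measurement.

    ``value`` is the reported quantity (clamped at zero, calibrated when a
    curve was supplied); ``raw_concentration`` is the unclamped retrieval.
    """

    value: float
    raw_concentration: float
    residual_norm: float
    calibrated: bool
    flags: tuple[str, ...] = ()


def measure_sample(
    incident: Spectrum,
    transmitted: Spectrum,
    profile: ExtinctionProfile,
    settings: RetrievalSettings | None = None,
    curve: CalibrationCurve | None = None,
    grid: WavelengthGrid | None = None,
) -> MeasurementResult:
    """Full single-sample chain on raw spectra.

    Both spectra (and the extinction profile, if it is on a different grid)
    are resampled to the integer-wavelength grid before retrieval.  When a
    calibration curve is given the retrieved signal is inverted to a
    concentration; a signal outside the curve's invertible interval keeps
    the uncalibrated value and sets a quality flag instead of failing.
    """
    settings = settings or RetrievalSettings()
    grid = grid or WavelengthGrid()
    target = grid.wavelengths()

    inc = resample_to_integer_grid(incident, grid)
    trans = resample_to_integer_grid(transmitted, grid)
    if profile.wavelengths.size != target.size or not np.array_equal(
        profile.wavelengths, target
    ):
        alpha = np.interp(target, profile.wavelengths, profile.alpha)
        profile = ExtinctionProfile(target, alpha)

    result = retrieve_relative_concentration(inc, trans, profile, settings)
    flags: list[str] = []
    raw = result.concentration
    reported = raw
    if raw < 0:
        flags.append(NEGATIVE_RETRIEVAL)
        reported = 0.0

    calibrated = False
    if curve is not None:
        try:
            reported = invert_to_concentration(curve, raw)
            calibrated = True
        except OutOfRangeError:
            flags.append(CALIBRATION_OUT_OF_RANGE)
            reported = max(raw, 0.0)

    return MeasurementResult(
        value=float(reported),
        raw_concentration=float(raw),
        residual_norm=result.residual_norm,
        calibrated=calibrated,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class AccuracyReport:
    """Device-versus-reference agreement over paired measurements."""

    pearson_r: float
    agreement: AgreementReport
    n_used: int
    n_missing: int
    provenance: Mapping | None = None

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "agreement": self.agreement.to_dict(),
            "n_used": self.n_used,
            "n_missing": self.n_missing,
            "provenance": dict(self.provenance) if self.provenance else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


@dataclass(frozen=True)
class StudyReport:
    """Screening-study summary: group stats, ANOVA, and pairwise ROC."""

    group_stats: Mapping[str, Mapping[str, float]]
    anova: AnovaResult
    roc_normal_disease: ROCReport
    roc_normal_risk: ROCReport
    provenance: Mapping | None = None

    def to_dict(self) -> dict:
        return {
            "group_stats": {g: dict(s) for g, s in self.group_stats.items()},
            "anova": self.anova.to_dict(),
            "roc_normal_disease": self.roc_normal_disease.to_dict(),
            "roc_normal_risk": self.roc_normal_risk.to_dict(),
            "provenance": dict(self.provenance) if self.provenance else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def config_hash(config) -> str:
    """SHA-256 of a canonical JSON rendering of a config-like object."""
    if hasattr(config, "__dataclass_fields__"):
        from dataclasses import asdict

        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_accuracy_study(
    records: Sequence[SubjectRecord], provenance: Mapping | None = None
) -> AccuracyReport:
    """Pearson r and Bland-Altman report over device/reference pairs.

    Records without a reference value are excluded and counted; differences
    are device minus reference.
    """
    complete = [r for r in records if r.reference_value is not None]
    n_missing = len(records) - len(complete)
    if len(complete) < 3:
        raise InsufficientDataError(
            f"accuracy study needs >= 3 complete pairs, got {len(complete)}"
        )
    device = np.array([r.device_value for r in complete])
    reference = np.array([r.reference_value for r in complete])
    sample = PairedSample(device, reference)
    return AccuracyReport(
        pearson_r=pearson_correlation(sample),
        agreement=bland_altman(sample, order="a_minus_b"),
        n_used=len(complete),
        n_missing=n_missing,
        provenance=provenance,
    )


def run_screening_study(
    records: Sequence[SubjectRecord], provenance: Mapping | None = None
) -> StudyReport:
    """Three-group comparison: summaries, one-way ANOVA, pairwise ROC.

    The positive class is the elevated-cholesterol group (disease or risk);
    normal is the negative class in both comparisons.
    """
    by_group: dict[str, np.ndarray] = {}
    for g in GROUPS:
        values = np.array([r.device_value for r in records if r.group == g])
        if values.size == 0:
            raise ValidationError(f"screening study requires group {g!r} to be present")
        by_group[g] = values

    group_stats = {
        g: {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        }
        for g, v in by_group.items()
    }
    anova = one_way_anova([by_group[g] for g in GROUPS])

    def _roc(positive_group: str) -> ROCReport:
        scores = np.r_[by_group["normal"], by_group[positive_group]]
        labels = np.r_[
            np.zeros(by_group["normal"].size, dtype=int),
            np.ones(by_group[positive_group].size, dtype=int),
        ]
        return roc_auc_with_ci(scores, labels)

    return StudyReport(
        group_stats=group_stats,
        anova=anova,
        roc_normal_disease=_roc("disease"),
        roc_normal_risk=_roc("risk"),
        provenance=provenance,
    )
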