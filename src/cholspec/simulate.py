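"""Synthetic instrument and study generator.

Stands in for the physical device and the clinical studies: a white-LED
source (two Gaussian emission bands, blue die plus phosphor), a blue
chromogen whose Gaussian absorption band sits inside the 475-780 nm
characteristic window, bounded multiplicative source jitter (the stabilized
LED varies by less than 1% between exposures), a PI-controlled source
start-up transient, 2-fold dilution calibration series, porcine-skin
extraction time courses, CuSO4-style repeatability studies, and three-group
clinical cohorts with a paired noisy linear reference method emulating gas
chromatography.

Every generator is a pure function of its configuration and seed: identical
inputs reproduce identical outputs bit-for-bit.

Cohort design anchors
---------------------
Skin cholesterol is a positive biomarker, modeled log-normal per group.
The elevated groups' median is 1.5x the normal median; the log-scale SD
defaults to 0.27, which places the design normal-vs-disease AUC at
Phi(ln 1.5 / (sigma * sqrt(2))) ~ 0.86.  The reference method reads
device + 72.78 with difference SD 20.03 (arbitrary units), and the
normal-group median of 150 a.u. makes the design device-reference
correlation sigma_d / sqrt(sigma_d^2 + sigma_n^2) ~ 0.906.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import CalibrationPoint
from .errors import ValidationError
from .pipeline import GROUPS, SubjectRecord, measure_sample
from .spectral import (
    ExtinctionProfile,
    RetrievalSettings,
    Spectrum,
    WavelengthGrid,
)

__all__ = [
    "DILUTION_SERIES_UG_ML",
    "LEDModel",
    "ChromogenModel",
    "NoiseModel",
    "ControlLoopConfig",
    "ControlTrajectory",
    "SaturatingResponse",
    "CohortConfig",
    "simulate_source_spectrum",
    "simulate_measurement",
    "simulate_dilution_series",
    "simulate_extraction_timecourse",
    "simulate_control_loop",
    "simulate_repeatability_study",
    "simulate_cohort",
    "simulate_reference_method",
    "simulate_accuracy_pairs",
]

#: 2-fold dilution ladder of the detection reagent (ug/ml).
DILUTION_SERIES_UG_ML = (5.0, 2.5, 1.25, 0.625, 0.3125, 0.15625)


@dataclass(frozen=True)
class LEDModel:
    """White LED emission: blue die + phosphor band, both Gaussian.

    A small broadband pedestal keeps the incident intensity strictly
    positive across the whole processing window.
    """

    blue_center_nm: float = 450.0
    blue_width_nm: float = 18.0
    blue_power: float = 1.0
    phosphor_center_nm: float = 560.0
    phosphor_width_nm: float = 60.0
    phosphor_power: float = 1.8
    pedestal: float = 0.005
    total_power: float = 1.0
    n_samples: int = 2048
    span_nm: tuple[float, float] = (330.0, 850.0)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("LED raw sample count must be >= 2")
        if min(self.blue_power, self.phosphor_power, self.total_power) < 0:
            raise ValidationError("LED powers must be non-negative")
        if self.pedestal < 0:
            raise ValidationError("pedestal must be non-negative")

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.span_nm[0], self.span_nm[1], self.n_samples)

    def nominal_spectrum(self) -> Spectrum:
        w = self.wavelengths()
        blue = self.blue_power * np.exp(
            -0.5 * ((w - self.blue_center_nm) / self.blue_width_nm) ** 2
        )
        phosphor = self.phosphor_power * np.exp(
            -0.5 * ((w - self.phosphor_center_nm) / self.phosphor_width_nm) ** 2
        )
        return Spectrum(w, self.total_power * (self.pedestal + blue + phosphor))


@dataclass(frozen=True)
class ChromogenModel:
    """Blue colored product: one Gaussian absorption band.

    The default band (652 nm, sigma 40 nm) emulates the oxidized-TMB blue
    product; its peak must sit inside the 475-780 nm characteristic band.
    ``peak_alpha_per_mm`` is the extinction at band center per unit relative
    concentration per mm of path.
    """

    center_nm: float = 652.0
    width_nm: float = 40.0
    peak_alpha_per_mm: float = 2.0

    def __post_init__(self) -> None:
        if not (475.0 <= self.center_nm <= 780.0):
            raise ValidationError("chromogen peak must lie inside 475-780 nm")
        if self.width_nm <= 0 or self.peak_alpha_per_mm < 0:
            raise ValidationError("chromogen width must be positive, peak non-negative")

    def profile(self, wavelengths: np.ndarray) -> ExtinctionProfile:
        alpha = self.peak_alpha_per_mm * np.exp(
            -0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2
        )
        return ExtinctionProfile(wavelengths, alpha)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise: bounded source jitter plus optional extras.

    jitter
        Maximum relative deviation of a single exposure's intensity from
        nominal; one uniform multiplicative draw in [1-jitter, 1+jitter]
        per exposure (the stabilized source varies < 1%, so default 0.01).
    detector_sd
        Additive per-sample Gaussian detector noise SD (default off).
    blotting_cv
        Optional multiplicative sample-preparation variability applied to
        the true concentration (operator blotting; default off).
    seed
        Base seed; generators mix it with their own offsets, so identical
        seeds reproduce identical draws.
    """

    jitter: float = 0.01
    detector_sd: float = 0.0
    blotting_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0 or self.detector_sd < 0 or self.blotting_cv < 0:
            raise ValidationError("noise magnitudes must be non-negative")


def _exposure(base: Spectrum, noise: NoiseModel, rng: np.random.Generator) -> Spectrum:
    factor = 1.0 + noise.jitter * rng.uniform(-1.0, 1.0)
    values = base.intensities * factor
    if noise.detector_sd > 0:
        values = values + rng.normal(0.0, noise.detector_sd, size=values.size)
    return Spectrum(base.wavelengths, np.clip(values, 0.0, None))


def simulate_source_spectrum(
    led: LEDModel, noise: NoiseModel, seed_offset: int = 0
) -> Spectrum:
    """One exposure of the source: nominal LED spectrum with jitter applied.

    The total intensity of a realization differs from nominal by at most
    the configured jitter fraction (the draw is bounded, not Gaussian).
    """
    rng = np.random.default_rng([noise.seed, seed_offset])
    return _exposure(led.nominal_spectrum(), noise, rng)


def simulate_measurement(
    true_concentration: float,
    led: LEDModel | None = None,
    chromogen: ChromogenModel | None = None,
    noise: NoiseModel | None = None,
    settings: RetrievalSettings | None = None,
    seed: int = 0,
) -> tuple[Spectrum, Spectrum]:
    """Simulate one (incident, transmitted) exposure pair on the raw grid.

    The transmitted exposure is the Beer-Lambert forward model applied to
    an independently jittered source realization, so incident and
    transmitted carry independent source-intensity errors, as on the real
    instrument where the reference and sample exposures are separate.
    """
    led = led or LEDModel()
    chromogen = chromogen or ChromogenModel()
    noise = noise or NoiseModel()
    settings = settings or RetrievalSettings()
    if true_concentration < 0:
        raise ValidationError("true concentration must be non-negative")

    rng = np.random.default_rng([noise.seed, seed])
    base = led.nominal_spectrum()
    c = true_concentration
    if noise.blotting_cv > 0:
        c = max(c * (1.0 + noise.blotting_cv * rng.normal()), 0.0)

    incident = _exposure(base, noise, rng)
    source_for_sample = _exposure(base, noise, rng)
    alpha = chromogen.profile(base.wavelengths).alpha
    attenuation = np.exp(-alpha * c * settings.path_length_mm)
    transmitted = Spectrum(base.wavelengths, source_for_sample.intensities * attenuation)
    return incident, transmitted


def _measure_value(
    true_concentration: float,
    led: LEDModel,
    chromogen: ChromogenModel,
    noise: NoiseModel,
    settings: RetrievalSettings,
    grid: WavelengthGrid,
    seed: int,
) -> float:
    incident, transmitted = simulate_measurement(
        true_concentration, led, chromogen, noise, settings, seed
    )
    profile = chromogen.profile(grid.wavelengths())
    result = measure_sample(incident, transmitted, profile, settings, grid=grid)
    return result.raw_concentration


@dataclass(frozen=True)
class SaturatingResponse:
    """Hill-type saturation of colored-product formation.

    effective concentration = smax / (1 + (k_ug_ml / c) ** hill)

    which is exactly a four-parameter logistic in log10 concentration with
    lower asymptote 0, upper ``smax``, midpoint log10(k) and slope ``hill``.
    """

    smax: float = 4.0
    k_ug_ml: float = 1.25
    hill: float = 1.2

    def __post_init__(self) -> None:
        if self.smax <= 0 or self.k_ug_ml <= 0 or self.hill <= 0:
            raise ValidationError("saturating-response parameters must be positive")

    def __call__(self, concentration: float) -> float:
        return self.smax / (1.0 + (self.k_ug_ml / concentration) ** self.hill)


def simulate_dilution_series(
    concentrations: Sequence[float] = DILUTION_SERIES_UG_ML,
    led: LEDModel | None = None,
    chromogen: ChromogenModel | None = None,
    noise: NoiseModel | None = None,
    settings: RetrievalSettings | None = None,
    grid: WavelengthGrid | None = None,
    response: SaturatingResponse | None = None,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Measure a calibration dilution ladder through the full pipeline.

    Each reagent concentration maps through a saturating (Hill) response to
    an effective chromogen concentration, which is then measured optically.
    The default ladder is the 2-fold series 5 -> 0.15625 ug/ml.
    """
    led = led or LEDModel()
    chromogen = chromogen or ChromogenModel()
    noise = noise or NoiseModel()
    settings = settings or RetrievalSettings()
    grid = grid or WavelengthGrid()
    response = response or SaturatingResponse()
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValidationError("dilution concentrations must be positive")
    points = []
    for i, c in enumerate(conc):
        signal = _measure_value(
            response(float(c)), led, chromogen, noise, settings, grid, seed=1000 + i
        )
        points.append(CalibrationPoint(concentration=float(c), signal=signal))
    return points


def simulate_extraction_timecourse(
    times_min: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0),
    decay_rate_per_min: float = 0.5,
    baseline_concentration: float = 2.0,
    led: LEDModel | None = None,
    chromogen: ChromogenModel | None = None,
    noise: NoiseModel | None = None,
    settings: RetrievalSettings | None = None,
    grid: WavelengthGrid | None = None,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Ethanol-extraction time course on porcine skin.

    Remaining skin cholesterol decays exponentially with extraction time,
    so measured values decrease monotonically (strictly, when jitter = 0).
    Returns (time_min, measured value) pairs.
    """
    led = led or LEDModel()
    chromogen = chromogen or ChromogenModel()
    noise = noise or NoiseModel()
    settings = settings or RetrievalSettings()
    grid = grid or WavelengthGrid()
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be non-negative")
    if decay_rate_per_min <= 0:
        raise ValidationError("decay rate must be positive")
    if baseline_concentration < 0:
        raise ValidationError("baseline concentration must be non-negative")
    out = []
    for i, ti in enumerate(t):
        true_c = baseline_concentration * np.exp(-decay_rate_per_min * ti)
        value = _measure_value(
            float(true_c), led, chromogen, noise, settings, grid, seed=2000 + i
        )
        out.append((float(ti), value))
    return out


@dataclass(frozen=True)
class ControlLoopConfig:
    """Discrete PI control of source intensity toward a target.

    The default gains (kp=8, ki=16 with dt=0.1 s) give an approximately
    critically damped loop (natural frequency 4 rad/s) that settles within
    1% of target in well under 4 s from any start between 0.5 and 1.5
    times the target.
    """

    target_intensity: float = 1.0
    initial_fraction: float = 1.0
    kp: float = 8.0
    ki: float = 16.0
    sample_period_s: float = 0.1
    settling_tolerance: float = 0.01
    max_time_s: float = 10.0

    def __post_init__(self) -> None:
        if self.target_intensity <= 0:
            raise ValidationError("target intensity must be positive")
        if self.kp < 0 or self.ki < 0:
            raise ValidationError("gains must be non-negative")
        if self.settling_tolerance <= 0:
            raise ValidationError("settling tolerance must be positive")
        if self.sample_period_s <= 0 or self.max_time_s <= 0:
            raise ValidationError("time parameters must be positive")


@dataclass(frozen=True)
class ControlTrajectory:
    """Simulated intensity trajectory with its settling summary.

    ``settling_time_s`` is the first time after which the intensity stays
    within the tolerance band of the target for the rest of the simulation;
    None when the loop never settles (e.g., unstable gains).
    """

    time_s: np.ndarray
    intensity: np.ndarray
    settling_time_s: float | None
    settled: bool


def simulate_control_loop(config: ControlLoopConfig | None = None) -> ControlTrajectory:
    """Integrate the discrete PI loop and report its settling time.

    Plant model: the drive directly integrates intensity,
    I[k+1] = I[k] + dt * (kp * e[k] + ki * integral(e)), e = target - I.
    Divergence (|I| exceeding 10x target) is detected and reported as
    non-settling rather than raising.
    """
    config = config or ControlLoopConfig()
    dt = config.sample_period_s
    n = int(np.floor(config.max_time_s / dt)) + 1
    time = dt * np.arange(n)
    intensity = np.empty(n)
    intensity[0] = config.initial_fraction * config.target_intensity
    integral = 0.0
    diverged = False
    for k in range(n - 1):
        e = config.target_intensity - intensity[k]
        integral += e * dt
        intensity[k + 1] = intensity[k] + dt * (config.kp * e + config.ki * integral)
        if abs(intensity[k + 1]) > 10.0 * config.target_intensity:
            diverged = True
            intensity[k + 2 :] = intensity[k + 1]
            time = time[: k + 2]
            intensity = intensity[: k + 2]
            break

    band = config.settling_tolerance * config.target_intensity
    inside = np.abs(intensity - config.target_intensity) <= band
    if diverged or not inside[-1]:
        return ControlTrajectory(time, intensity, None, False)
    # first index from which the trajectory never leaves the band
    outside = np.where(~inside)[0]
    first_settled = 0 if outside.size == 0 else int(outside[-1]) + 1
    return ControlTrajectory(time, intensity, float(time[first_settled]), True)


def simulate_repeatability_study(
    levels: Sequence[float] = (0.25, 1.0, 4.0),
    replicates: int = 10,
    led: LEDModel | None = None,
    chromogen: ChromogenModel | None = None,
    noise: NoiseModel | None = None,
    settings: RetrievalSettings | None = None,
    grid: WavelengthGrid | None = None,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """Repeatability study at low/medium/high concentration levels.

    Emulates repeated measurement of stable colored solutions (the bench
    study uses CuSO4 because its color does not evolve): ``replicates``
    independent full-pipeline measurements per level, fresh noise each.
    Returns measured values grouped by level, ready for CV computation.
    """
    if replicates < 2:
        raise ValidationError("repeatability needs at least 2 replicates")
    led = led or LEDModel()
    chromogen = chromogen or ChromogenModel()
    noise = noise or NoiseModel()
    settings = settings or RetrievalSettings()
    grid = grid or WavelengthGrid()
    out: dict[float, np.ndarray] = {}
    for li, level in enumerate(levels):
        if level <= 0:
            raise ValidationError("repeatability levels must be positive")
        values = np.array(
            [
                _measure_value(
                    float(level),
                    led,
                    chromogen,
                    noise,
                    settings,
                    grid,
                    seed=seed * 10_000 + li * 100 + r,
                )
                for r in range(replicates)
            ]
        )
        out[float(level)] = values
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Design of the synthetic clinical studies.

    Group sizes default to 115/117/110 (normal/risk/disease); skin
    cholesterol is log-normal per group with the elevated groups' median
    ``disease_ratio`` (default 1.5) times the normal median, and risk drawn
    from the same distribution as disease (the two elevated groups are not
    separable).  The reference method reads device + ``ref_offset`` with
    difference SD ``ref_diff_sd``, so device-minus-reference differences
    center on -ref_offset.  ``n_accuracy`` volunteers (default 73) form the
    paired accuracy study.
    """

    n_normal: int = 115
    n_risk: int = 117
    n_disease: int = 110
    normal_median: float = 150.0
    sigma_log: float = 0.27
    disease_ratio: float = 1.5
    risk_ratio: float | None = None
    ref_offset: float = 72.78
    ref_diff_sd: float = 20.03
    n_accuracy: int = 73
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_risk, self.n_disease, self.n_accuracy) < 1:
            raise ValidationError("group sizes must be >= 1")
        if self.disease_ratio <= 0 or (self.risk_ratio is not None and self.risk_ratio <= 0):
            raise ValidationError("group ratios must be positive")
        if self.sigma_log < 0 or self.ref_diff_sd < 0:
            raise ValidationError("SDs must be non-negative")
        if self.normal_median <= 0:
            raise ValidationError("normal median must be positive")

    @property
    def effective_risk_ratio(self) -> float:
        return self.disease_ratio if self.risk_ratio is None else self.risk_ratio


def simulate_cohort(config: CohortConfig | None = None) -> list[SubjectRecord]:
    """Draw a three-group screening cohort of device values."""
    config = config or CohortConfig()
    rng = np.random.default_rng([config.seed, 1])
    mu_normal = np.log(config.normal_median)
    plan = [
        ("normal", "N", config.n_normal, mu_normal),
        ("risk", "R", config.n_risk, mu_normal + np.log(config.effective_risk_ratio)),
        ("disease", "D", config.n_disease, mu_normal + np.log(config.disease_ratio)),
    ]
    records = []
    for group, prefix, n, mu in plan:
        values = rng.lognormal(mean=mu, sigma=config.sigma_log, size=n)
        records.extend(
            SubjectRecord(subject_id=f"{prefix}{i + 1:03d}", group=group, device_value=float(v))
            for i, v in enumerate(values)
        )
    return records


def simulate_reference_method(
    records: Sequence[SubjectRecord], config: CohortConfig | None = None
) -> list[SubjectRecord]:
    """Attach paired reference-method values (noisy linear reference).

    reference = device + offset + N(0, difference SD), so device-minus-
    reference differences have mean -offset and SD ~ the configured SD.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng([config.seed, 2])
    out = []
    for r in records:
        ref = r.device_value + config.ref_offset + (
            rng.normal(0.0, config.ref_diff_sd) if config.ref_diff_sd > 0 else 0.0
        )
        out.append(replace(r, reference_value=float(ref)))
    return out


def simulate_accuracy_pairs(config: CohortConfig | None = None) -> list[SubjectRecord]:
    """Volunteer cohort for the paired accuracy study.

    ``n_accuracy`` volunteers drawn from the normal-group distribution,
    each with a paired reference measurement.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng([config.seed, 3])
    values = rng.lognormal(
        mean=np.log(config.normal_median), sigma=config.sigma_log, size=config.n_accuracy
    )
    records = [
        SubjectRecord(subject_id=f"V{i + 1:03d}", group="normal", device_value=float(v))
        for i, v in enumerate(values)
    ]
    return simulate_reference_method(records, config)
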