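"""Schema-validated run configuration (YAML).

Every section maps onto one of the package's dataclasses; unknown keys are
rejected with the offending path so a typo in a config file fails loudly
instead of silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

from . import simulate, spectral
from .errors import ValidationError

__all__ = ["RunConfig", "load_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Section):
    start_nm: float = 380.0
    stop_nm: float = 780.0
    step_nm: float = 1.0
    include_endpoint: bool = False


class SettingsSection(_Section):
    path_length_mm: float = 1.0
    band_start_nm: float = 475.0
    band_stop_nm: float = 780.0
    intensity_floor: float = 1e-9


class LEDSection(_Section):
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


class ChromogenSection(_Section):
    center_nm: float = 652.0
    width_nm: float = 40.0
    peak_alpha_per_mm: float = 2.0


class NoiseSection(_Section):
    jitter: float = 0.01
    detector_sd: float = 0.0
    blotting_cv: float = 0.0
    seed: int = 0


class ControlLoopSection(_Section):
    target_intensity: float = 1.0
    initial_fraction: float = 1.0
    kp: float = 8.0
    ki: float = 16.0
    sample_period_s: float = 0.1
    settling_tolerance: float = 0.01
    max_time_s: float = 10.0


class ResponseSection(_Section):
    smax: float = 4.0
    k_ug_ml: float = 1.25
    hill: float = 1.2


class CohortSection(_Section):
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


class RunConfig(_Section):
    """Top-level run configuration; every randomized stage has a seed."""

    seed: int = 0
    grid: GridSection = GridSection()
    settings: SettingsSection = SettingsSection()
    led: LEDSection = LEDSection()
    chromogen: ChromogenSection = ChromogenSection()
    noise: NoiseSection = NoiseSection()
    control_loop: ControlLoopSection = ControlLoopSection()
    response: ResponseSection = ResponseSection()
    cohort: CohortSection = CohortSection()

    def with_seed(self, seed: int | None) -> "RunConfig":
        """Return a copy with every stage seed overridden."""
        if seed is None:
            return self
        data = self.model_dump()
        data["seed"] = seed
        data["noise"]["seed"] = seed
        data["cohort"]["seed"] = seed
        return RunConfig.model_validate(data)

    # ---- conversions to the runtime dataclasses -------------------------
    def grid_obj(self) -> spectral.WavelengthGrid:
        return spectral.WavelengthGrid(**self.grid.model_dump())

    def settings_obj(self) -> spectral.RetrievalSettings:
        return spectral.RetrievalSettings(**self.settings.model_dump())

    def led_obj(self) -> simulate.LEDModel:
        d = self.led.model_dump()
        d["span_nm"] = tuple(d["span_nm"])
        return simulate.LEDModel(**d)

    def chromogen_obj(self) -> simulate.ChromogenModel:
        return simulate.ChromogenModel(**self.chromogen.model_dump())

    def noise_obj(self) -> simulate.NoiseModel:
        return simulate.NoiseModel(**self.noise.model_dump())

    def control_loop_obj(self) -> simulate.ControlLoopConfig:
        return simulate.ControlLoopConfig(**self.control_loop.model_dump())

    def response_obj(self) -> simulate.SaturatingResponse:
        return simulate.SaturatingResponse(**self.response.model_dump())

    def cohort_obj(self) -> simulate.CohortConfig:
        return simulate.CohortConfig(**self.cohort.model_dump())


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when no path)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except PydanticValidationError as exc:
        locations = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ValidationError(f"invalid config {path}: {locations}") from None
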