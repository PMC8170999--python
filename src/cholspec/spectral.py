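"""Beer-Lambert spectral engine.

The instrument records an incident spectrum I0(lambda) and a transmitted
spectrum I1(lambda); a colored product with extinction profile alpha(lambda)
at relative concentration c in a cuvette of path length l attenuates light as

    I1(lambda) = I0(lambda) * exp(-alpha(lambda) * c * l)

so the absorbance A(lambda) = ln[I0(lambda) / I1(lambda)] = alpha(lambda)*c*l
is linear in c.  The relative concentration is retrieved by ordinary least
squares over a characteristic band (default 475-780 nm, where the blue
oxidized-TMB product absorbs), which has the closed form

    c* = sum(alpha*l*A) / sum((alpha*l)**2)

Raw spectrometer output (2048 samples over 330-850 nm) is first resampled by
piecewise-linear interpolation onto an integer-nanometre grid covering the
380-780 nm processing window.  The half-open convention {380, ..., 779}
yields exactly 400 samples; the inclusive alternative (401 points) is
available through :class:`WavelengthGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateDesignError,
    SpanError,
    ValidationError,
)

__all__ = [
    "Spectrum",
    "AbsorbanceSpectrum",
    "WavelengthGrid",
    "ExtinctionProfile",
    "RetrievalSettings",
    "RetrievalResult",
    "resample_to_integer_grid",
    "compute_absorbance",
    "forward_transmission",
    "retrieve_relative_concentration",
]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _check_grid(wavelengths: np.ndarray) -> None:
    if wavelengths.size < 1:
        raise ValidationError("wavelength grid is empty")
    if wavelengths.size > 1 and not np.all(np.diff(wavelengths) > 0):
        raise ValidationError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """An optical spectrum: strictly increasing wavelengths (nm) with
    non-negative intensities."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = _as_float_array(self.wavelengths, "wavelengths")
        i = _as_float_array(self.intensities, "intensities")
        _check_grid(w)
        if w.size != i.size:
            raise ValidationError(
                f"wavelengths ({w.size}) and intensities ({i.size}) differ in length"
            )
        if np.any(i < 0):
            raise ValidationError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def span_nm(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Per-wavelength absorbance A(lambda) = ln(I0/I1).

    Unlike :class:`Spectrum`, values may be negative: on noisy input the
    transmitted intensity can exceed the incident one.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        w = _as_float_array(self.wavelengths, "wavelengths")
        a = _as_float_array(self.absorbance, "absorbance")
        _check_grid(w)
        if w.size != a.size:
            raise ValidationError("wavelengths and absorbance differ in length")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform target grid for resampling.

    The default half-open grid {380, 381, ..., 779} has exactly 400 integer
    wavelengths; set ``include_endpoint=True`` for the inclusive 401-point
    variant.
    """

    start_nm: float = 380.0
    stop_nm: float = 780.0
    step_nm: float = 1.0
    include_endpoint: bool = False

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValidationError("grid start must be below stop")
        if self.step_nm <= 0:
            raise ValidationError("grid step must be positive")

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm))
        if self.include_endpoint:
            return np.linspace(self.start_nm, self.stop_nm, n + 1)
        return self.start_nm + self.step_nm * np.arange(n)


@dataclass(frozen=True)
class ExtinctionProfile:
    """Per-unit-concentration, per-mm extinction coefficient alpha(lambda)."""

    wavelengths: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        w = _as_float_array(self.wavelengths, "wavelengths")
        a = _as_float_array(self.alpha, "alpha")
        _check_grid(w)
        if w.size != a.size:
            raise ValidationError("wavelengths and alpha differ in length")
        if np.any(a < 0):
            raise ValidationError("alpha must be non-negative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "alpha", a)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class RetrievalSettings:
    """Parameters of the retrieval.

    path_length_mm
        Absorber depth l (the instrument's cuvette is 1 mm).
    band_start_nm, band_stop_nm
        Characteristic band over which the least-squares fit runs;
        both endpoints inclusive.
    intensity_floor
        Fraction of the maximum incident intensity below which transmitted
        intensities are floored before taking the logarithm (guards ln(0)).
    """

    path_length_mm: float = 1.0
    band_start_nm: float = 475.0
    band_stop_nm: float = 780.0
    intensity_floor: float = 1e-9

    def __post_init__(self) -> None:
        if self.path_length_mm <= 0:
            raise ValidationError("path_length_mm must be positive")
        if not self.band_start_nm < self.band_stop_nm:
            raise ValidationError("band start must be below band stop")
        if self.intensity_floor <= 0:
            raise ValidationError("intensity_floor must be positive")

    def band_mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.band_start_nm) & (wavelengths <= self.band_stop_nm)


@dataclass(frozen=True)
class RetrievalResult:
    """Outcome of the least-squares retrieval.

    ``concentration`` is in relative units and may be negative on noisy
    input; clamping is the caller's policy (see the pipeline layer).
    """

    concentration: float
    residual_norm: float
    n_wavelengths_used: int

    def __post_init__(self) -> None:
        if self.n_wavelengths_used < 1:
            raise ValidationError("n_wavelengths_used must be >= 1")
        if self.residual_norm < 0:
            raise ValidationError("residual_norm must be non-negative")


def _require_same_grid(w_a: np.ndarray, w_b: np.ndarray, what: str) -> None:
    if w_a.size != w_b.size or not np.array_equal(w_a, w_b):
        raise AlignmentError(f"{what} are not on the same wavelength grid")


def resample_to_integer_grid(
    raw: Spectrum, grid: WavelengthGrid | None = None
) -> Spectrum:
    """Piecewise-linear resampling of ``raw`` onto ``grid``.

    With the default grid this turns a raw spectrometer trace into the
    400-point integer-wavelength spectrum the processing chain operates on.

    Raises
    ------
    SpanError
        If the grid extends beyond the raw spectrum's wavelength span.
    """
    grid = grid or WavelengthGrid()
    if len(raw) < 2:
        raise ValidationError("raw spectrum needs at least 2 points to interpolate")
    target = grid.wavelengths()
    lo, hi = raw.span_nm
    if target[0] < lo or target[-1] > hi:
        raise SpanError(
            f"grid [{target[0]:g}, {target[-1]:g}] nm exceeds raw span [{lo:g}, {hi:g}] nm"
        )
    values = np.interp(target, raw.wavelengths, raw.intensities)
    return Spectrum(target, values)


def compute_absorbance(
    incident: Spectrum,
    transmitted: Spectrum,
    settings: RetrievalSettings | None = None,
) -> AbsorbanceSpectrum:
    """A(lambda) = ln(I0 / max(I1, floor)) on the shared grid.

    The floor is ``settings.intensity_floor`` times the maximum incident
    intensity; it only engages on pathologically dark transmitted samples.
    """
    settings = settings or RetrievalSettings()
    _require_same_grid(incident.wavelengths, transmitted.wavelengths, "spectra")
    i0 = incident.intensities
    if np.any(i0 <= 0):
        raise ValidationError("incident intensities must be strictly positive")
    floor = settings.intensity_floor * float(i0.max())
    i1 = np.maximum(transmitted.intensities, floor)
    return AbsorbanceSpectrum(incident.wavelengths, np.log(i0 / i1))


def forward_transmission(
    incident: Spectrum,
    profile: ExtinctionProfile,
    concentration: float,
    settings: RetrievalSettings | None = None,
) -> Spectrum:
    """Beer-Lambert forward model: I1 = I0 * exp(-alpha * c * l)."""
    settings = settings or RetrievalSettings()
    _require_same_grid(incident.wavelengths, profile.wavelengths, "incident/profile")
    if concentration < 0:
        raise ValidationError("forward model requires concentration >= 0")
    attenuation = np.exp(-profile.alpha * concentration * settings.path_length_mm)
    return Spectrum(incident.wavelengths, incident.intensities * attenuation)


def retrieve_relative_concentration(
    incident: Spectrum,
    transmitted: Spectrum,
    profile: ExtinctionProfile,
    settings: RetrievalSettings | None = None,
) -> RetrievalResult:
    """Least-squares retrieval of the relative concentration over the band.

    Minimizes sum_band (A - alpha*l*c)^2, whose unique minimizer is
    c* = sum(alpha*l*A) / sum((alpha*l)^2).  ``residual_norm`` is the root
    of the minimized sum of squares.
    """
    settings = settings or RetrievalSettings()
    _require_same_grid(incident.wavelengths, profile.wavelengths, "spectra/profile")
    absorbance = compute_absorbance(incident, transmitted, settings)
    mask = settings.band_mask(incident.wavelengths)
    if not mask.any():
        raise DegenerateDesignError("characteristic band contains no wavelengths")
    x = profile.alpha[mask] * settings.path_length_mm
    a = absorbance.absorbance[mask]
    denom = float(x @ x)
    if denom == 0.0:
        raise DegenerateDesignError(
            "extinction profile is identically zero on the characteristic band"
        )
    c = float(x @ a) / denom
    residual = a - x * c
    return RetrievalResult(
        concentration=c,
        residual_norm=float(np.sqrt(residual @ residual)),
        n_wavelengths_used=int(mask.sum()),
    )
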