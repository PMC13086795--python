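"""Rhodopsin absorbance templates and spectral-sensitivity construction.

The alpha band follows the Govardovskii A1 closed form; an optional beta
band adds the UV shoulder. All curves are normalized so that the peak value
is 1, which makes amplitude ratios of template mixtures scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, ParameterError

__all__ = [
    "LAMBDA_MAX_RANGE",
    "SpectralSensitivity",
    "make_grid",
    "validate_grid",
    "alpha_band",
    "beta_band",
    "template_absorbance",
    "compose_sensitivity",
]

#: admissible template peak wavelengths (nm)
LAMBDA_MAX_RANGE = (300.0, 620.0)

#: admissible wavelength-grid extent (nm)
GRID_RANGE = (200.0, 800.0)


def make_grid(start: float = 300.0, stop: float = 700.0, step: float = 5.0) -> np.ndarray:
    """Uniform wavelength grid in nm, inclusive of both endpoints."""
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    return validate_grid(grid)


def validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    """Check grid invariants and return the grid as a float array.

    Raises
    ------
    DataError
        If the grid is not strictly increasing or leaves 200-800 nm.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise DataError("wavelength grid must be a 1-d array with >= 2 points")
    if not np.all(np.diff(wl) > 0):
        raise DataError("wavelength grid must be strictly increasing")
    if wl[0] < GRID_RANGE[0] or wl[-1] > GRID_RANGE[1]:
        raise DataError(
            f"wavelength grid must lie within {GRID_RANGE[0]:.0f}-{GRID_RANGE[1]:.0f} nm"
        )
    return wl


@dataclass
class SpectralSensitivity:
    """Relative spectral sensitivity on a wavelength grid.

    After normalization ``max(values) == 1``. Negative values are only
    admissible for opponent-isolated spectra (``opponent=True``).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)
    opponent: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = validate_grid(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise DataError("sensitivity values must match the wavelength grid")
        if not np.all(np.isfinite(self.values)):
            raise DataError("sensitivity values must be finite")
        if not self.opponent and np.any(self.values < 0):
            raise DataError("negative sensitivities only allowed for opponent spectra")

    def normalized(self) -> "SpectralSensitivity":
        peak = float(np.max(np.abs(self.values)))
        if peak == 0:
            raise DataError("cannot normalize an all-zero sensitivity")
        return SpectralSensitivity(
            self.wavelengths, self.values / peak, dict(self.meta), self.opponent
        )

    def at(self, wavelength: float) -> float:
        """Value at the grid point nearest ``wavelength``."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.values[idx])

    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.values))])

    def to_csv(self, path) -> None:
        """Export as two-column CSV (wavelength_nm, sensitivity)."""
        arr = np.column_stack([self.wavelengths, self.values])
        np.savetxt(path, arr, delimiter=",", header="wavelength_nm,sensitivity", comments="")


def _check_lambda_max(lambda_max: float) -> float:
    lo, hi = LAMBDA_MAX_RANGE
    if not (lo <= lambda_max <= hi):
        raise ParameterError(f"lambda_max={lambda_max} outside [{lo}, {hi}] nm")
    return float(lambda_max)


def alpha_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Unnormalized A1 alpha-band absorbance (Govardovskii closed form)."""
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    with np.errstate(over="ignore"):
        denom = (
            np.exp(69.7 * (a - x))
            + np.exp(28.0 * (0.922 - x))
            + np.exp(-14.9 * (1.104 - x))
            + 0.674
        )
    return 1.0 / denom


def beta_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Unnormalized beta-band (UV shoulder) absorbance."""
    wl = np.asarray(wavelengths, dtype=float)
    lmb = 189.0 + 0.315 * lambda_max
    width = -40.5 + 0.195 * lambda_max
    return 0.26 * np.exp(-(((wl - lmb) / width) ** 2))


def _raw_template(wavelengths: np.ndarray, lambda_max: float, beta: bool) -> np.ndarray:
    s = alpha_band(wavelengths, lambda_max)
    if beta:
        s = s + beta_band(wavelengths, lambda_max)
    return s


def _template_norm(lambda_max: float, beta: bool) -> float:
    # normalize on a fine internal grid so the curve's true peak maps to 1
    fine = np.arange(GRID_RANGE[0], GRID_RANGE[1] + 1.0)
    return float(np.max(_raw_template(fine, lambda_max, beta)))


def template_absorbance(
    lambda_max: float,
    wavelengths: np.ndarray,
    beta: bool = False,
    meta: dict | None = None,
) -> SpectralSensitivity:
    """Evaluate a peak-normalized absorbance template on a wavelength grid.

    Parameters
    ----------
    lambda_max : float
        Peak wavelength in nm, within 300-620.
    wavelengths : array
        Evaluation grid (nm).
    beta : bool
        Include the beta band (UV shoulder). Off by default, matching the
        400-600 nm decomposition window where the beta band is negligible.
    """
    lambda_max = _check_lambda_max(lambda_max)
    wl = validate_grid(wavelengths)
    values = _raw_template(wl, lambda_max, beta) / _template_norm(lambda_max, beta)
    values = np.clip(values, 0.0, 1.0)
    m = {"lambda_max": lambda_max, "beta_band": beta}
    if meta:
        m.update(meta)
    return SpectralSensitivity(wl, values, m)


def compose_sensitivity(
    components: Sequence[tuple[float, float]] | Iterable[tuple[float, float]],
    wavelengths: np.ndarray,
    beta: bool = False,
    meta: dict | None = None,
) -> SpectralSensitivity:
    """Weighted sum of templates, renormalized to peak 1.

    ``components`` is a sequence of ``(lambda_max, amplitude)`` pairs with
    non-negative amplitudes, at least one positive. The true amplitudes (and
    the A445/A545-style ratio of the first two components, when present) are
    recorded in ``meta`` for generator bookkeeping.
    """
    components = list(components)
    if not components:
        raise ParameterError("at least one template component is required")
    amplitudes = np.array([a for _, a in components], dtype=float)
    if np.any(amplitudes < 0):
        raise ParameterError("component amplitudes must be >= 0")
    if not np.any(amplitudes > 0):
        raise ParameterError("all component amplitudes are zero")
    wl = validate_grid(wavelengths)
    total = np.zeros_like(wl)
    for (lam, amp) in components:
        if amp == 0:
            _check_lambda_max(lam)  # still validate
            continue
        total += amp * template_absorbance(lam, wl, beta=beta).values
    peak = float(np.max(total))
    values = total / peak
    m = {
        "components": [(float(lam), float(amp)) for lam, amp in components],
        "beta_band": beta,
    }
    if len(components) >= 2 and components[1][1] > 0:
        m["amplitude_ratio"] = float(components[0][1] / components[1][1])
    if meta:
        m.update(meta)
    return SpectralSensitivity(wl, values, m)
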