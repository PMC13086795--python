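"""Electrophysiology pipeline: Hill fits, reverse-Hill inversion,
polarization typing and opponent-unit isolation.

Voltage responses follow the Naka-Rushton (Hill) saturation
``V = Vmax * I^n / (I^n + K^n)`` with relative intensity ``I = 10^(-OD)``.
Spectral sensitivity is the inverse transform of iso-quantal flash
responses, normalized to peak 1 (the half-saturation constant K cancels
under normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, EmptyOpponentError, FitError, SaturationError
from .templates import SpectralSensitivity

__all__ = [
    "IntensityRun",
    "HillParams",
    "SpectralScan",
    "PolarizationRun",
    "PolarizationResult",
    "hill",
    "fit_hill",
    "reverse_hill",
    "polarization_profile",
    "isolate_opponent_unit",
    "classify_phi_max",
]

#: responses above this fraction of Vmax are treated as saturated
SATURATION_GUARD = 0.98

#: modulation depth below which a polarization profile is called flat
FLAT_MODULATION = 0.05


@dataclass
class IntensityRun:
    """Responses to an attenuation series at a single test wavelength.

    ``attenuation`` is in optical-density units (0 = brightest), strictly
    monotone; ``response`` is the peak depolarization in mV per step.
    """

    attenuation: np.ndarray
    response: np.ndarray
    wavelength: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.attenuation.shape != self.response.shape or self.attenuation.ndim != 1:
            raise DataError("attenuation and response must be matching 1-d arrays")
        d = np.diff(self.attenuation)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DataError("attenuation must be strictly monotone within a run")
        if np.any(self.response < 0):
            raise DataError("intensity-run responses must be >= 0")

    @property
    def intensity(self) -> np.ndarray:
        """Relative intensity on [0, 1]: I = 10^(-OD)."""
        return 10.0 ** (-self.attenuation)


@dataclass
class HillParams:
    """Fitted saturation parameters of the intensity-response function."""

    vmax: float
    n: float
    k: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.n <= 0 or self.k <= 0:
            raise DataError("Hill parameters must be positive")


@dataclass
class SpectralScan:
    """Per-wavelength voltage responses; may contain repeated wavelengths
    from up/down sweeps.

    ``adaptation`` is ``None`` for dark-adapted scans, otherwise a dict
    ``{"wavelengths": [...], "intensity": float}`` describing the steady
    chromatic background.
    """

    wavelengths: np.ndarray
    response: np.ndarray
    sweep: np.ndarray | None = None
    adaptation: dict | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.wavelengths.shape != self.response.shape or self.wavelengths.ndim != 1:
            raise DataError("wavelengths and response must be matching 1-d arrays")
        if self.sweep is None:
            self.sweep = np.array(["up"] * self.wavelengths.size)
        else:
            self.sweep = np.asarray(self.sweep)
            if self.sweep.shape != self.wavelengths.shape:
                raise DataError("sweep tags must match the wavelength array")

    def grid(self) -> np.ndarray:
        return np.unique(self.wavelengths)


@dataclass
class PolarizationRun:
    """Responses versus e-vector angle at a fixed test wavelength.

    0 deg = horizontal, 90 deg = vertical (dorso-ventral) e-vector.
    """

    angle: np.ndarray
    response: np.ndarray
    wavelength: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float) % 360.0
        self.response = np.asarray(self.response, dtype=float)
        if self.angle.shape != self.response.shape or self.angle.ndim != 1:
            raise DataError("angle and response must be matching 1-d arrays")
        if np.unique(self.angle).size < 8:
            raise DataError("polarization run needs >= 8 distinct angles")
        if np.ptp(self.angle) < 180.0 - 1e-9:
            raise DataError("polarization run must cover >= 180 degrees")


@dataclass
class PolarizationResult:
    phi_max: float  # degrees, modulo 180
    ps: float  # polarization sensitivity ratio, >= 1
    microvilli_class: str  # vertical | horizontal | diagonal | indeterminate
    modulation: float = 0.0  # c1/c0 of the cosine fit
    meta: dict = field(default_factory=dict)


def hill(intensity: np.ndarray, vmax: float, n: float, k: float) -> np.ndarray:
    """Naka-Rushton saturation V = Vmax * I^n / (I^n + K^n)."""
    i_n = np.asarray(intensity, dtype=float) ** n
    return vmax * i_n / (i_n + k**n)


def fit_hill(run: IntensityRun) -> HillParams:
    """Least-squares Hill fit of an intensity run.

    Trust-region fit initialized at ``Vmax0 = 1.05 max(V)``, ``n0 = 1`` and
    ``K0 =`` intensity at half-max response, with bounds
    ``Vmax in (max(V), 3 max(V)]``, ``n in [0.5, 3]``, ``K in [1e-6, 1]``.
    """
    if run.response.size < 6:
        raise DataError("Hill fit needs >= 6 points")
    intensity = run.intensity
    v = run.response
    vpeak = float(np.max(v))
    if vpeak <= 0:
        raise DataError("intensity run has no positive responses")

    # initial K: intensity where response crosses half max (log-interpolated)
    order = np.argsort(intensity)
    k0 = float(np.interp(0.5 * vpeak, v[order], intensity[order]))
    k0 = min(max(k0, 1e-6), 1.0)
    x0 = np.array([1.05 * vpeak, 1.0, k0])
    lower = np.array([vpeak * (1.0 + 1e-9), 0.5, 1e-6])
    upper = np.array([3.0 * vpeak, 3.0, 1.0])
    x0 = np.clip(x0, lower, upper)

    def resid(p):
        return hill(intensity, *p) - v

    sol = least_squares(
        resid, x0, bounds=(lower, upper), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitError(f"Hill fit did not converge: {sol.message}")
    vmax, n, k = sol.x
    if vmax >= upper[0] * (1 - 1e-9):
        raise FitError(
            f"Hill fit hit the Vmax bound ({vmax:.3g} mV); "
            "response range likely does not constrain saturation"
        )
    return HillParams(float(vmax), float(n), float(k), rss=float(np.sum(sol.fun**2)))


def _invert_responses(
    responses: np.ndarray, hp: HillParams, wavelengths: np.ndarray
) -> np.ndarray:
    """Reverse-Hill transform of depolarizing responses.

    Returns raw sensitivities ``(r / (Vmax - r))^(1/n)`` with NaN at
    excluded (saturated) points.
    """
    r = np.asarray(responses, dtype=float)
    if np.any(r >= hp.vmax):
        bad = wavelengths[r >= hp.vmax]
        raise SaturationError(
            f"response >= Vmax at wavelength(s) {np.unique(bad).tolist()} nm"
        )
    out = np.full_like(r, np.nan)
    near = r >= SATURATION_GUARD * hp.vmax
    if np.any(near):
        warnings.warn(
            f"{int(near.sum())} response(s) above {SATURATION_GUARD:.0%} of Vmax "
            f"excluded at {np.unique(wavelengths[near]).tolist()} nm",
            stacklevel=3,
        )
    ok = (~near) & (r >= 0)
    out[ok] = (r[ok] / (hp.vmax - r[ok])) ** (1.0 / hp.n)
    return out


def _average_by_wavelength(
    wavelengths: np.ndarray, raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    grid = np.unique(wavelengths)
    avg = np.zeros_like(grid)
    for i, wl in enumerate(grid):
        vals = raw[wavelengths == wl]
        vals = vals[np.isfinite(vals)]
        avg[i] = np.mean(vals) if vals.size else 0.0
    return grid, avg


def reverse_hill(scan: SpectralScan, hp: HillParams) -> SpectralSensitivity:
    """Convert a spectral scan to a peak-normalized spectral sensitivity.

    Up and down sweeps are averaged on the sensitivity scale (the inverse
    transform is nonlinear, so voltage-scale averaging would bias the
    result). Negative responses in a dark-adapted scan are excluded with a
    polarity warning; use :func:`isolate_opponent_unit` for adapted scans
    with hyperpolarizing components.
    """
    r = scan.response.copy().astype(float)
    negative = r < 0
    if np.any(negative):
        warnings.warn(
            f"{int(negative.sum())} hyperpolarizing response(s) excluded "
            "(polarity); use isolate_opponent_unit for opponent spectra",
            stacklevel=2,
        )
        r[negative] = np.nan
    raw = np.full_like(r, np.nan)
    finite = np.isfinite(r)
    raw[finite] = _invert_responses(r[finite], hp, scan.wavelengths[finite])
    grid, avg = _average_by_wavelength(scan.wavelengths, raw)
    peak = float(np.max(avg))
    if peak <= 0:
        raise DataError("scan has no usable depolarizing responses")
    meta = {"cell_id": scan.cell_id, "adaptation": scan.adaptation}
    return SpectralSensitivity(grid, avg / peak, meta)


def classify_phi_max(phi_max: float) -> str:
    """Microvillar-orientation class from the angle of maximal sensitivity.

    Symmetric +/-22.5 deg bins around the three microvillar orientations:
    vertical [67.5, 112.5), horizontal [0, 22.5) u [157.5, 180),
    diagonal otherwise.
    """
    phi = phi_max % 180.0
    if 67.5 <= phi < 112.5:
        return "vertical"
    if phi < 22.5 or phi >= 157.5:
        return "horizontal"
    return "diagonal"


def polarization_profile(run: PolarizationRun, hp: HillParams) -> PolarizationResult:
    """Fit ``s(phi) = c0 + c1 cos(2 (phi - phi_max))`` to reverse-Hill
    sensitivities and report the polarization sensitivity ratio
    ``PS = (c0 + c1) / (c0 - c1)``.
    """
    s = _invert_responses(run.response, hp, run.angle)
    ok = np.isfinite(s)
    if ok.sum() < 8:
        raise DataError("too few usable angles after saturation exclusion")
    phi = np.deg2rad(run.angle[ok])
    design = np.column_stack([np.ones(ok.sum()), np.cos(2 * phi), np.sin(2 * phi)])
    c0, b, c = np.linalg.lstsq(design, s[ok], rcond=None)[0]
    c1 = float(np.hypot(b, c))
    phi_max = float(np.rad2deg(0.5 * np.arctan2(c, b)) % 180.0)
    meta = {"c0": float(c0), "c1": c1}
    if c0 <= 0 or c1 / c0 < FLAT_MODULATION:
        return PolarizationResult(phi_max, 1.0, "indeterminate", c1 / c0 if c0 > 0 else 0.0, meta)
    if c0 <= c1:
        return PolarizationResult(phi_max, float("inf"), "indeterminate", c1 / c0, meta)
    ps = (c0 + c1) / (c0 - c1)
    return PolarizationResult(phi_max, float(ps), classify_phi_max(phi_max), c1 / c0, meta)


def isolate_opponent_unit(
    dark: SpectralSensitivity, adapted: SpectralScan, hp: HillParams
) -> SpectralSensitivity:
    """Extract the opponent unit's sensitivity from a chromatically adapted
    scan.

    Hyperpolarizing (negative) responses are sign-inverted and passed
    through the same reverse-Hill inversion as excitatory responses (the
    host cell's Hill parameters are reused); depolarizing responses carry
    no opponent information and map to zero. The output is normalized to
    peak 1 and flagged ``opponent=True``. Works unchanged for multi-band
    (e.g. green + blue) adaptation.
    """
    if adapted.adaptation is None:
        raise DataError("adapted scan must carry an adaptation descriptor")
    grid = adapted.grid()
    if not np.array_equal(grid, dark.wavelengths):
        raise DataError("dark and adapted scans must share the wavelength grid")
    r = adapted.response
    if not np.any(r < 0):
        raise EmptyOpponentError(
            "no hyperpolarizing responses: cell not opponent or adaptation insufficient"
        )
    inverted = np.where(r < 0, -r, 0.0)
    raw = _invert_responses(inverted, hp, adapted.wavelengths)
    grid, avg = _average_by_wavelength(adapted.wavelengths, raw)
    peak = float(np.max(avg))
    meta = {
        "cell_id": adapted.cell_id,
        "adaptation": adapted.adaptation,
        "source": "opponent-isolation",
    }
    return SpectralSensitivity(grid, avg / peak, meta, opponent=True)
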