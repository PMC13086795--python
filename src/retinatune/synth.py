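"""Synthetic-data generator: electrophysiology, mosaic sections and
eyeshine stacks with known ground truth.

Every generator is seeded and deterministic. Opponency is modelled as
post-nonlinearity subtraction: the response to a spectral flash is the Hill
response of the excitatory unit minus a weighted Hill response of the
inhibitory unit(s); chromatic adaptation divisively reduces each unit's
input gain in proportion to how strongly the unit absorbs the adapting
light (Weber-type). Dorso-ventral gradients are logistic in elevation with
the ventral side high, midpoint inside the equator band.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .ephys import IntensityRun, PolarizationRun, SpectralScan, hill
from .errors import ConfigurationError, ParameterError
from .eyeshine import DEFAULT_WAVELENGTHS, EyeshineStack, R_CHANNEL_WAVELENGTHS
from .templates import SpectralSensitivity, compose_sensitivity, make_grid, template_absorbance

__all__ = [
    "LogisticGradient",
    "GeneratorConfig",
    "CELL_TYPES",
    "SimulatedCell",
    "r9_sensitivity",
    "simulate_cell",
    "simulate_mosaic_section",
    "simulate_eyeshine_stack",
]

CELL_TYPES = ("U+G-", "B+G-", "Bg+R-", "BG+R-", "G+R-", "Y", "G")


@dataclass(frozen=True)
class LogisticGradient:
    """Logistic dorso-ventral gradient p(elevation), ventral-high.

    p(e) = p_min + (p_max - p_min) * expit(-(e - e0)/s); e0 defaults to
    -5 deg (inside the -20..+10 deg equator band), slope 15 deg.
    """

    p_min: float
    p_max: float
    e0: float = -5.0
    s: float = 15.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_min <= self.p_max):
            raise ConfigurationError("need 0 <= p_min <= p_max")
        if self.s <= 0:
            raise ConfigurationError("gradient slope must be > 0")

    def __call__(self, elevation: float | np.ndarray) -> float | np.ndarray:
        val = self.p_min + (self.p_max - self.p_min) * expit(
            -(np.asarray(elevation, dtype=float) - self.e0) / self.s
        )
        return float(val) if np.isscalar(elevation) else val


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators; defaults are placeholders for
    quantities the study does not print (gradients, inhibition weights)."""

    seed: int = 0
    # Hill parameter priors (uniform ranges)
    vmax_range: tuple = (35.0, 45.0)
    n_range: tuple = (0.8, 1.5)
    k_range: tuple = (0.05, 0.2)
    # noise
    response_noise_mv: float = 0.3
    label_noise: float = 0.1
    pixel_noise: float = 0.01
    # A445/A545 ratio versus elevation (dimensionless "probabilities" reused
    # as ratio bounds: high ventral, low dorsal)
    ratio_gradient: LogisticGradient = LogisticGradient(0.3, 1.5)
    # P(BL | L-expressing cell) versus elevation
    bl_gradient: LogisticGradient = LogisticGradient(0.05, 0.8, s=30.0)
    # P(red ommatidium) versus elevation; endpoints match the ~0.1 dorsal /
    # ~0.6 ventral extremes of the eyeshine maps
    red_gradient: LogisticGradient = LogisticGradient(0.1, 0.6, s=15.0)
    p_ul: float = 0.02
    p_u_nonl: float = 0.5
    p_dark: float = 0.05
    # opponency
    w_inhibition: float = 0.3
    w_blue: float = 0.15
    blue_inhibition_above: float = 10.0  # dorsal G+R- cells gain a blue unit
    screening_cuton: float = 600.0
    screening_edge: float = 15.0
    # stimulation
    peak_response_frac: float = 0.7
    adapt_intensity: float = 200.0  # in units of K
    # polarization
    ps_ratio: float = 2.0
    # lattice geometry
    lattice_rows: int = 20
    lattice_cols: int = 20
    lattice_spacing: float = 12.0
    elevation_range: tuple = (-90.0, 90.0)

    def __post_init__(self) -> None:
        if not (0 <= self.w_inhibition < 1) or not (0 <= self.w_blue < 1):
            raise ConfigurationError("inhibitory weights must lie in [0, 1)")
        if not (0 < self.peak_response_frac < 1):
            raise ConfigurationError("peak_response_frac must lie in (0, 1)")
        if self.lattice_rows < 4 or self.lattice_cols < 4:
            raise ConfigurationError("lattice must be at least 4x4")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("ratio_gradient", "bl_gradient", "red_gradient"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = LogisticGradient(**raw[key])
        for key in ("vmax_range", "n_range", "k_range", "elevation_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# electrophysiology


def r9_sensitivity(config: GeneratorConfig, grid: np.ndarray) -> SpectralSensitivity:
    """R9 red-unit sensitivity: 545 nm template long-pass filtered by red
    screening pigment (logistic cut-on), renormalized to peak 1."""
    base = template_absorbance(545.0, grid).values
    longpass = expit((grid - config.screening_cuton) / config.screening_edge)
    v = base * longpass
    return SpectralSensitivity(grid, v / v.max(), {"unit": "R9"})


@dataclass
class SimulatedCell:
    """A simulated recording session plus its ground truth."""

    cell_type: str
    elevation: float
    intensity_run: IntensityRun
    scans: dict  # name -> SpectralScan ("dark", "adapted", ...)
    polarization_run: PolarizationRun
    truth: dict


def _excitatory_sensitivity(
    config: GeneratorConfig, cell_type: str, elevation: float, ratio: float | None
) -> tuple[SpectralSensitivity, float | None]:
    grid = make_grid()
    if cell_type == "U+G-":
        return template_absorbance(355.0, grid, beta=True), None
    if cell_type == "B+G-":
        return template_absorbance(445.0, grid, beta=True), None
    if cell_type in ("Bg+R-", "BG+R-", "G+R-"):
        if ratio is None:
            ratio = float(config.ratio_gradient(elevation))
        return compose_sensitivity([(445.0, ratio), (545.0, 1.0)], grid, beta=True), ratio
    if cell_type == "Y":
        return template_absorbance(565.0, grid), None
    if cell_type == "G":
        return template_absorbance(545.0, grid, beta=True), None
    raise ParameterError(f"unknown cell type {cell_type!r}; valid: {CELL_TYPES}")


def _units(
    config: GeneratorConfig, cell_type: str, elevation: float, ratio: float | None
) -> tuple[SpectralSensitivity, list]:
    """Excitatory sensitivity plus signed inhibitory/excitatory side units
    as (weight, sensitivity) pairs; negative weight = inhibition."""
    grid = make_grid()
    exc, ratio = _excitatory_sensitivity(config, cell_type, elevation, ratio)
    side = []
    w = config.w_inhibition
    if cell_type in ("U+G-", "B+G-"):
        side.append((-w, template_absorbance(545.0, grid, beta=True)))
    elif cell_type in ("Bg+R-", "BG+R-", "G+R-"):
        side.append((-w, r9_sensitivity(config, grid)))
        if elevation > config.blue_inhibition_above and config.w_blue > 0:
            side.append((-config.w_blue, template_absorbance(445.0, grid)))
    elif cell_type == "Y":
        side.append((+w, r9_sensitivity(config, grid)))
    exc.meta["true_ratio"] = ratio
    return exc, side


def _phi_max_for(cell_type: str) -> float:
    if cell_type in ("U+G-", "B+G-", "Bg+R-", "BG+R-", "G+R-"):
        return 90.0  # R1&2: vertical microvilli
    if cell_type == "G":
        return 0.0  # R3&4: horizontal
    return 45.0  # R5-8 / Y: diagonal


def _adaptation_gain(
    unit: SpectralSensitivity, adapt: list[tuple[float, float]] | None, k: float
) -> float:
    """Weber-type divisive gain 1 / (1 + sum_a I_a S_unit(lam_a) / K)."""
    if not adapt:
        return 1.0
    drive = sum(intensity * unit.at(lam) for lam, intensity in adapt)
    return 1.0 / (1.0 + drive / k)


def simulate_cell(
    config: GeneratorConfig,
    cell_type: str,
    elevation: float = 0.0,
    adaptations: list | None = None,
    ratio: float | None = None,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell0",
) -> SimulatedCell:
    """Simulate one intracellular recording session.

    Produces an intensity run at the peak wavelength, a dark-adapted
    spectral scan (up + down sweeps), one adapted scan per entry of
    ``adaptations`` (each a list of ``(wavelength_nm, relative_intensity)``
    pairs, intensity in units of K), and a polarization run, together with
    the ground truth needed to score every pipeline stage.
    """
    if not (-90.0 <= elevation <= 90.0):
        raise ParameterError("elevation must lie in [-90, 90] degrees")
    if rng is None:
        rng = config.rng()
    vmax = float(rng.uniform(*config.vmax_range))
    n = float(rng.uniform(*config.n_range))
    k = float(rng.uniform(*config.k_range))
    exc, side = _units(config, cell_type, elevation, ratio)
    grid = exc.wavelengths
    sigma = config.response_noise_mv

    # iso-quantal flash intensity: peak response at peak_response_frac * Vmax
    f = config.peak_response_frac
    i0 = k * (f / (1.0 - f)) ** (1.0 / n)

    def scan_responses(adapt):
        g_exc = _adaptation_gain(exc, adapt, k)
        r = hill(g_exc * i0 * exc.values, vmax, n, k)
        for w, unit in side:
            g_u = _adaptation_gain(unit, adapt, k)
            r = r + w * hill(g_u * i0 * unit.values, vmax, n, k)
        return r

    def make_scan(adapt, name):
        r_clean = scan_responses(adapt)
        wl = np.concatenate([grid, grid[::-1]])  # up then down sweep
        resp = np.concatenate([r_clean, r_clean[::-1]]) + rng.normal(0, sigma, 2 * grid.size)
        sweep = np.array(["up"] * grid.size + ["down"] * grid.size)
        adaptation = None
        if adapt:
            adaptation = {
                "wavelengths": [lam for lam, _ in adapt],
                "intensity": [inten for _, inten in adapt],
            }
        return SpectralScan(wl, resp, sweep, adaptation, cell_id=cell_id), r_clean

    scans = {}
    scans["dark"], dark_clean = make_scan(None, "dark")
    adapted_truth = {}
    for i, adapt in enumerate(adaptations or []):
        # adapting intensities are given in units of K -> absolute
        adapt_abs = [(lam, inten * k) for lam, inten in adapt]
        name = "adapted_" + "+".join(f"{lam:.0f}" for lam, _ in adapt)
        scans[name], clean = make_scan(adapt_abs, name)
        adapted_truth[name] = clean

    # intensity run at the peak wavelength of the excitatory unit
    od = np.round(np.arange(4.0, -1e-9, -0.2), 10)
    v_run = hill(10.0 ** (-od), vmax, n, k) + rng.normal(0, sigma, od.size)
    run = IntensityRun(od, np.clip(v_run, 0.0, None), exc.peak_wavelength(), cell_id)

    # polarization run at the peak wavelength
    phi_max = _phi_max_for(cell_type)
    angles = np.arange(0.0, 360.0, 15.0)
    ps = config.ps_ratio
    s_phi = (1.0 / ps) + (1.0 - 1.0 / ps) * np.cos(np.deg2rad(angles - phi_max)) ** 2
    p_resp = hill(i0 * s_phi, vmax, n, k) + rng.normal(0, sigma, angles.size)
    pol = PolarizationRun(angles, np.clip(p_resp, 0.0, None), exc.peak_wavelength(), cell_id)

    inhibitory_peaks = [unit.peak_wavelength() for w, unit in side if w < 0]
    truth = {
        "cell_type": cell_type,
        "elevation": elevation,
        "hill": {"vmax": vmax, "n": n, "k": k},
        "ratio": exc.meta.get("true_ratio"),
        "phi_max": phi_max,
        "ps": ps,
        "excitatory": exc,
        "side_units": side,
        "inhibitory_peaks": inhibitory_peaks,
        "dark_clean_response": dark_clean,
        "adapted_clean_responses": adapted_truth,
        "i0": i0,
    }
    return SimulatedCell(cell_type, elevation, run, scans, pol, truth)


# ---------------------------------------------------------------------------
# mosaic sections


def _hex_lattice(rows: int, cols: int, spacing: float) -> np.ndarray:
    """(N, 2) array of (x, y) positions on a hexagonal lattice; y is the
    dorso-ventral axis (larger y = dorsal)."""
    xs, ys = [], []
    for r in range(rows):
        for c in range(cols):
            xs.append((c + 0.5 * (r % 2)) * spacing)
            ys.append(r * spacing * np.sqrt(3) / 2.0)
    return np.column_stack([xs, ys])


def simulate_mosaic_section(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an immunolabelled section as an intensity table.

    Each ommatidium is first assigned L-class membership (red ommatidium)
    from the elevation-dependent red gradient; within the L class each
    R1&2 cell is BL with the elevation-dependent co-expression probability,
    UL at a small constant rate, else L; within the non-L class cells are U
    or B at a fixed ratio. Label intensities are state indicators times
    (1 + noise), with a small non-negative background on off channels.

    Returns ``(table, truth)`` data frames; identical seeds give identical
    tables.
    """
    if rng is None:
        rng = config.rng()
    pos = _hex_lattice(config.lattice_rows, config.lattice_cols, config.lattice_spacing)
    y = pos[:, 1]
    lo, hi = config.elevation_range
    elevation = lo + (hi - lo) * (y - y.min()) / (y.max() - y.min())
    rows, truth_rows = [], []
    for i, ((x, yy), elev) in enumerate(zip(pos, elevation)):
        is_l = rng.random() < config.red_gradient(elev)
        states = []
        for _ in range(2):
            if is_l:
                u = rng.random()
                p_bl = config.bl_gradient(elev)
                if u < p_bl:
                    states.append("BL")
                elif u < p_bl + config.p_ul:
                    states.append("UL")
                else:
                    states.append("L")
            else:
                states.append("U" if rng.random() < config.p_u_nonl else "B")
        row = {"id": f"om{i:04d}", "x_um": float(x), "y_um": float(yy)}
        for cell, state in zip(("r1", "r2"), states):
            for ch in "UBL":
                on = ch in state  # "UL" contains U and L, etc.
                level = (1.0 + config.label_noise * rng.standard_normal()) if on else 0.0
                level = max(level, 0.0) + 0.02 * abs(rng.standard_normal())
                row[f"{cell}_{ch.lower()}"] = level
        rows.append(row)
        truth_rows.append(
            {
                "id": f"om{i:04d}",
                "x_um": float(x),
                "y_um": float(yy),
                "elevation": float(elev),
                "is_l_class": is_l,
                "r1_state": states[0],
                "r2_state": states[1],
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# eyeshine stacks


def simulate_eyeshine_stack(
    config: GeneratorConfig,
    elevation: float,
    rng: np.random.Generator | None = None,
    eye_id: str = "eye0",
    p_red: float | None = None,
) -> tuple[EyeshineStack, pd.DataFrame]:
    """Simulate one hyperspectral eyeshine stack with ground-truth labels.

    Spots sit on a hexagonal lattice. Red spots reflect only in the far-red
    (675/653 nm) frames, non-red spots in all frames, dark spots in none;
    p(red) follows the elevation gradient unless overridden. A smooth
    background (also emitted as the light-adapted background frames) and
    seeded pixel noise are added to every frame.
    """
    if rng is None:
        rng = config.rng()
    spacing = config.lattice_spacing
    pos = _hex_lattice(config.lattice_rows, config.lattice_cols, spacing)
    margin = 2.0 * spacing
    pos = pos + margin
    h = int(np.ceil(pos[:, 1].max() + margin))
    w = int(np.ceil(pos[:, 0].max() + margin))
    if p_red is None:
        p_red = float(config.red_gradient(elevation))

    labels = []
    for _ in range(len(pos)):
        u = rng.random()
        if u < config.p_dark:
            labels.append("dark")
        elif u < config.p_dark + (1 - config.p_dark) * p_red:
            labels.append("red")
        else:
            labels.append("non-red")

    yy, xx = np.mgrid[0:h, 0:w]
    sigma_spot = spacing / 5.0
    # smooth background: broad Gaussian blob + pedestal
    cx, cy = w / 2.0, h / 2.0
    background = 0.05 + 0.3 * np.exp(
        -(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * (0.6 * max(h, w)) ** 2))
    )

    # per-label spot fields (red reflects only far-red; non-red everywhere)
    def spot_field(selected):
        out = np.zeros((h, w))
        for (x, y), label in zip(pos, labels):
            if label in selected:
                out += np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_spot**2)))
        return out

    field_red = spot_field({"red"})
    field_nonred = spot_field({"non-red"})

    frames, backgrounds = {}, {}
    for wl in DEFAULT_WAVELENGTHS:
        signal = field_nonred.copy()
        if wl in R_CHANNEL_WAVELENGTHS:
            signal = signal + field_red
        frame = signal + background + rng.normal(0, config.pixel_noise, (h, w))
        backgrounds[wl] = background + rng.normal(0, config.pixel_noise / 2, (h, w))
        frames[wl] = np.clip(frame, 0.0, None)
    truth = pd.DataFrame(
        {
            "row": pos[:, 1],
            "col": pos[:, 0],
            "label": labels,
            "elevation": elevation,
            "eye_id": eye_id,
        }
    )
    stack = EyeshineStack(
        elevation, frames, backgrounds, eye_id,
        {"p_red": p_red, "p_dark": config.p_dark, "spacing": spacing},
    )
    return stack, truth
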