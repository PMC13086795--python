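"""Two-template spectral decomposition, ratio classification and
dorso-ventral gradient profiling of red-inhibited cells.

A normalized sensitivity is fitted in the 400-600 nm window with a
non-negative linear sum of two fixed absorbance templates peaking at 445
and 545 nm; cells are classified by the amplitude ratio A445/A545
(thresholds 0.9 and 1.1) and the ratio is profiled against elevation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.stats import rankdata, spearmanr

from .errors import CoverageError, DataError, FitError
from .templates import SpectralSensitivity, template_absorbance

__all__ = [
    "TemplateFit",
    "CellRecord",
    "GradientSummary",
    "FIT_WINDOW",
    "PEAKS",
    "RATIO_THRESHOLDS",
    "UV_PEAK_THRESHOLD",
    "DEFAULT_ELEVATION_EDGES",
    "fit_two_templates",
    "classify_ratio",
    "detect_uv_peak",
    "gradient_profile",
]

#: wavelength window (nm) for the two-template fit
FIT_WINDOW = (400.0, 600.0)

#: fixed template peak wavelengths (nm)
PEAKS = (445.0, 545.0)

#: classification thresholds on A445/A545
RATIO_THRESHOLDS = (0.9, 1.1)

#: UV local maximum must reach this fraction of the global peak
UV_PEAK_THRESHOLD = 0.6

#: ventral < -20 deg, equatorial -20..+10 deg, dorsal > +10 deg
DEFAULT_ELEVATION_EDGES = (-90.0, -20.0, 10.0, 90.0)


@dataclass
class TemplateFit:
    """Amplitudes of the 445 + 545 nm template decomposition."""

    a445: float
    a545: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.a445 < 0 or self.a545 < 0:
            raise DataError("template amplitudes must be >= 0")

    @property
    def ratio(self) -> float:
        if self.a545 > 0:
            return self.a445 / self.a545
        return math.inf if self.a445 > 0 else math.nan


@dataclass
class CellRecord:
    """One classified red-inhibited cell."""

    cell_id: str
    elevation: float  # degrees, negative = ventral
    fit: TemplateFit
    class_label: str
    uv_peak: bool = False
    microvilli_class: str = "vertical"


@dataclass
class GradientSummary:
    """Per-elevation-bin ratio statistics plus a monotonic trend test."""

    bin_edges: list
    per_bin: list  # dicts: lo, hi, n, mean_ratio, sd_ratio, majority_class
    rho: float
    p_perm: float
    n_permutations: int
    seed: int
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def fit_two_templates(
    s: SpectralSensitivity, window: tuple[float, float] = FIT_WINDOW
) -> TemplateFit:
    """Non-negative least squares fit of two fixed templates in ``window``.

    Raises
    ------
    DataError
        Fewer than 10 grid points fall inside the window.
    FitError
        Both amplitudes are zero (degenerate fit).
    """
    wl = s.wavelengths
    mask = (wl >= window[0]) & (wl <= window[1])
    if int(mask.sum()) < 10:
        raise DataError(
            f"only {int(mask.sum())} grid points in {window}; need >= 10"
        )
    design = np.column_stack(
        [template_absorbance(p, wl[mask]).values for p in PEAKS]
    )
    target = s.values[mask]
    coeffs, resid = nnls(design, target)
    if coeffs[0] == 0 and coeffs[1] == 0:
        raise FitError("degenerate two-template fit: both amplitudes zero")
    return TemplateFit(
        a445=float(coeffs[0]),
        a545=float(coeffs[1]),
        rss=float(resid**2),
        n_points=int(mask.sum()),
    )


def classify_ratio(fit: TemplateFit | float) -> str:
    """Classify a cell by its A445/A545 ratio.

    ratio > 1.1 -> "Bg+R-", 0.9 <= ratio <= 1.1 -> "BG+R-",
    ratio < 0.9 -> "G+R-". Boundary values (exactly 0.9 or 1.1) fall in the
    middle class, keeping the partition total.
    """
    ratio = fit.ratio if isinstance(fit, TemplateFit) else float(fit)
    if math.isnan(ratio) or ratio < 0:
        raise DataError(f"ratio {ratio} is not classifiable")
    lo, hi = RATIO_THRESHOLDS
    if ratio > hi:
        return "Bg+R-"
    if ratio < lo:
        return "G+R-"
    return "BG+R-"


def detect_uv_peak(
    s: SpectralSensitivity, threshold: float = UV_PEAK_THRESHOLD
) -> bool:
    """True when a local maximum in [300, 400) nm reaches ``threshold`` of
    the global maximum. Flagged cells are excluded from class averages and
    gradient statistics.
    """
    wl = s.wavelengths
    if wl[0] > 300.0 or wl[-1] < 400.0:
        raise CoverageError("grid must cover 300-400 nm for UV-peak detection")
    v = s.values
    global_max = float(np.max(v))
    # interior local maxima (>= both neighbours, > at least one)
    left = np.r_[-np.inf, v[:-1]]
    right = np.r_[v[1:], -np.inf]
    is_max = (v >= left) & (v >= right) & ((v > left) | (v > right))
    uv = is_max & (wl >= 300.0) & (wl < 400.0)
    return bool(np.any(v[uv] >= threshold * global_max))


def _spearman_permutation_p(
    x: np.ndarray, y: np.ndarray, n_permutations: int, seed: int
) -> tuple[float, float]:
    """Spearman rho of (x, y) and a two-sided permutation p-value."""
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx_c = (rx - rx.mean()) / (np.linalg.norm(rx - rx.mean()) or 1.0)
    ry_c = (ry - ry.mean()) / (np.linalg.norm(ry - ry.mean()) or 1.0)
    count = 0
    # permute in blocks to bound memory
    block = 2000
    done = 0
    obs = abs(float(rx_c @ ry_c))
    while done < n_permutations:
        m = min(block, n_permutations - done)
        perms = np.array([rng.permutation(ry_c) for _ in range(m)])
        stats = np.abs(perms @ rx_c)
        count += int(np.sum(stats >= obs - 1e-12))
        done += m
    p = (1 + count) / (1 + n_permutations)
    return rho, p


def gradient_profile(
    cells: Sequence[CellRecord],
    bin_edges: Sequence[float] = DEFAULT_ELEVATION_EDGES,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> GradientSummary:
    """Profile the A445/A545 ratio along the dorso-ventral axis.

    Reports per-bin mean +/- SD of the ratio, the Spearman rank correlation
    of ratio versus elevation, and a two-sided permutation p-value.
    Negative rho means the blue weight decreases dorsally (ventral-high
    gradient). UV-peaking cells are excluded.
    """
    usable = [c for c in cells if not c.uv_peak and math.isfinite(c.fit.ratio)]
    if len(usable) < 3:
        raise DataError("need >= 3 non-UV cells with finite ratios")
    elev = np.array([c.elevation for c in usable])
    ratio = np.array([c.fit.ratio for c in usable])
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 3 or not np.all(np.diff(edges) > 0):
        raise DataError("bin edges must be increasing with >= 2 bins")
    idx = np.clip(np.digitize(elev, edges) - 1, 0, edges.size - 2)
    per_bin = []
    non_empty = 0
    for b in range(edges.size - 1):
        sel = idx == b
        n = int(sel.sum())
        entry = {"lo": float(edges[b]), "hi": float(edges[b + 1]), "n": n}
        if n:
            non_empty += 1
            entry["mean_ratio"] = float(np.mean(ratio[sel]))
            entry["sd_ratio"] = float(np.std(ratio[sel], ddof=1)) if n > 1 else 0.0
            labels = [classify_ratio(r) for r in ratio[sel]]
            entry["majority_class"] = max(set(labels), key=labels.count)
        else:
            entry["mean_ratio"] = None
            entry["sd_ratio"] = None
            entry["majority_class"] = None
        per_bin.append(entry)
    if non_empty < 2:
        raise DataError("all cells fall in one elevation bin; trend undefined")
    if np.ptp(ratio) == 0 or np.ptp(elev) == 0:
        rho, p = 0.0, 1.0  # constant input: no rankable trend
    else:
        rho, p = _spearman_permutation_p(elev, ratio, n_permutations, seed)
    return GradientSummary(
        bin_edges=[float(e) for e in edges],
        per_bin=per_bin,
        rho=rho,
        p_perm=p,
        n_permutations=n_permutations,
        seed=seed,
        meta={"n_cells": len(usable)},
    )
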