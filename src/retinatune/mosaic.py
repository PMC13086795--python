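"""Ommatidial mosaic typing from per-cell immunolabel calls and
strip-density profiles along the dorso-ventral axis.

Each ommatidium is typed by the unordered pair of its two R1&2 expression
states (U, B, L, UL, BL; U&B and U&B&L never occur and are rejected).
Sections are divided into horizontal strips of equal width and per-strip
category fractions (non-L / L / UL / BL) are reported, normalized to the
strip total so the four counts always sum to N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import DataError, InvalidStateError, NoCallError

__all__ = [
    "STATES",
    "CATEGORIES",
    "call_cell_state",
    "type_ommatidium",
    "enumerate_type_space",
    "categorize_ommatidium",
    "OmmatidiumRecord",
    "StripProfile",
    "strip_densities",
    "type_ommatidia_table",
]

#: canonical cell-state order used for unordered type labels
STATES = ("U", "B", "L", "UL", "BL")

CATEGORIES = ("nonL", "L", "UL", "BL")

_STATE_RANK = {s: i for i, s in enumerate(STATES)}


def call_cell_state(
    u_intensity: float,
    b_intensity: float,
    l_intensity: float,
    thresholds: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> str:
    """Call an expression state from per-channel label intensities.

    A channel is positive iff its intensity >= its threshold. The
    combinations {U,B} and {U,B,L} are invalid (never observed) and raise.
    """
    if min(u_intensity, b_intensity, l_intensity) < 0:
        raise DataError("label intensities must be >= 0")
    if min(thresholds) <= 0:
        raise DataError("thresholds must be > 0")
    pos = frozenset(
        name
        for name, val, thr in zip(
            "UBL", (u_intensity, b_intensity, l_intensity), thresholds
        )
        if val >= thr
    )
    mapping = {
        frozenset("U"): "U",
        frozenset("B"): "B",
        frozenset("L"): "L",
        frozenset("UL"): "UL",
        frozenset("BL"): "BL",
    }
    if pos in mapping:
        return mapping[pos]
    if not pos:
        raise NoCallError("no label channel above threshold")
    raise InvalidStateError(f"forbidden co-expression combination {sorted(pos)}")


def _check_state(state: str) -> str:
    if state not in _STATE_RANK:
        raise InvalidStateError(f"unknown cell state {state!r}")
    return state


def type_ommatidium(s1: str, s2: str) -> str:
    """Canonical unordered type label, e.g. (B, U) -> "U/B"."""
    a, b = sorted((_check_state(s1), _check_state(s2)), key=_STATE_RANK.get)
    return f"{a}/{b}"


def enumerate_type_space(states: Sequence[str] = STATES) -> list[str]:
    """All unordered pairs with repetition: k states give k(k+1)/2 types."""
    states = list(states)
    if not states:
        raise DataError("state list must be non-empty")
    if len(set(states)) != len(states):
        raise DataError("states must be distinct")
    ordered = sorted((_check_state(s) for s in states), key=_STATE_RANK.get)
    return [f"{a}/{b}" for a, b in itertools.combinations_with_replacement(ordered, 2)]


def categorize_ommatidium(type_label: str, ul_bl_category: str = "UL") -> str:
    """Map a type label to its Fig-5-style panel category.

    nonL when both cells express only U or B; UL when any cell co-expresses
    U&L and none B&L; BL symmetric; the single mixed UL/BL type goes to
    ``ul_bl_category`` (default UL - the rarer class, so it does not vanish
    into the larger BL panel); everything else is L.
    """
    if ul_bl_category not in ("UL", "BL"):
        raise DataError("ul_bl_category must be 'UL' or 'BL'")
    parts = type_label.split("/")
    if len(parts) != 2:
        raise DataError(f"malformed type label {type_label!r}")
    a, b = (_check_state(p) for p in parts)
    pair = {a, b}
    if pair <= {"U", "B"}:
        return "nonL"
    if "UL" in pair and "BL" in pair:
        return ul_bl_category
    if "UL" in pair:
        return "UL"
    if "BL" in pair:
        return "BL"
    return "L"


@dataclass
class OmmatidiumRecord:
    """One typed ommatidium in section coordinates (y = dorso-ventral,
    larger y = more dorsal)."""

    id: str
    x: float
    y: float
    r1_state: str
    r2_state: str
    type_label: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if not self.type_label:
            self.type_label = type_ommatidium(self.r1_state, self.r2_state)
        if not self.category:
            self.category = categorize_ommatidium(self.type_label)


@dataclass
class StripProfile:
    """Per-strip counts and fractions of the four ommatidial categories.

    Strip 1 is dorsal-most. Fractions are NaN (missing) for empty strips;
    for non-empty strips counts satisfy nonL + L + UL + BL = N and
    fractions sum to 1.
    """

    table: pd.DataFrame
    n_strips: int
    axis_range: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def strip_densities(
    ommatidia: Sequence[OmmatidiumRecord],
    n_strips: int = 10,
    ul_bl_category: str = "UL",
) -> StripProfile:
    """Divide the section into ``n_strips`` horizontal strips of equal
    width spanning its dorso-ventral (y) extent and count categories.

    Per-strip counts are normalized to the strip total; empty strips report
    missing (NaN) fractions rather than zeros.
    """
    if not ommatidia:
        raise DataError("need >= 1 ommatidium")
    y = np.array([o.y for o in ommatidia], dtype=float)
    ymin, ymax = float(y.min()), float(y.max())
    if ymax - ymin <= 0:
        raise DataError("degenerate bounding box along the dorso-ventral axis")
    width = (ymax - ymin) / n_strips
    # strip 1 = dorsal-most (largest y)
    idx = np.clip(((ymax - y) / width).astype(int), 0, n_strips - 1)
    rows = []
    for s in range(n_strips):
        sel = idx == s
        n = int(sel.sum())
        counts = {c: 0 for c in CATEGORIES}
        for o, here in zip(ommatidia, sel):
            if here:
                counts[categorize_ommatidium(o.type_label, ul_bl_category)] += 1
        row = {
            "strip": s + 1,
            "N": n,
            "n_nonL": counts["nonL"],
            "n_L": counts["L"],
            "n_UL": counts["UL"],
            "n_BL": counts["BL"],
        }
        for c in CATEGORIES:
            row[f"f_{c}"] = counts[c] / n if n else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    return StripProfile(
        table=table,
        n_strips=n_strips,
        axis_range=(ymin, ymax),
        meta={"ul_bl_category": ul_bl_category, "total": len(ommatidia)},
    )


def _auto_threshold(values: np.ndarray) -> float:
    """Channel threshold: Otsu split, then the midpoint of the two class
    means (Otsu alone returns the low edge of the background/signal gap,
    which background outliers can cross)."""
    values = np.asarray(values, dtype=float)
    split = float(threshold_otsu(values))
    low, high = values[values <= split], values[values > split]
    if low.size == 0 or high.size == 0:
        return split
    return float(0.5 * (low.mean() + high.mean()))


def type_ommatidia_table(
    df: pd.DataFrame, thresholds: tuple[float, float, float] | None = None
) -> list[OmmatidiumRecord]:
    """Build typed records from an ommatidium table.

    Accepts either pre-called states (columns ``r1_state``, ``r2_state``)
    or raw intensities (``r1_u``, ``r1_b``, ``r1_l``, ``r2_u``, ``r2_b``,
    ``r2_l``). For raw intensities, per-channel thresholds default to Otsu
    over the pooled R1+R2 values of that channel.
    """
    xcol = "x_um" if "x_um" in df.columns else "x"
    ycol = "y_um" if "y_um" in df.columns else "y"
    if "r1_state" in df.columns and "r2_state" in df.columns:
        return [
            OmmatidiumRecord(str(r["id"]), float(r[xcol]), float(r[ycol]),
                             str(r["r1_state"]), str(r["r2_state"]))
            for _, r in df.iterrows()
        ]
    needed = ["r1_u", "r1_b", "r1_l", "r2_u", "r2_b", "r2_l"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"ommatidium table missing columns {missing}")
    if thresholds is None:
        thresholds = tuple(
            _auto_threshold(np.concatenate([df[f"r1_{c}"], df[f"r2_{c}"]]))
            for c in "ubl"
        )
    records = []
    for _, r in df.iterrows():
        s1 = call_cell_state(r["r1_u"], r["r1_b"], r["r1_l"], thresholds)
        s2 = call_cell_state(r["r2_u"], r["r2_b"], r["r2_l"], thresholds)
        records.append(
            OmmatidiumRecord(str(r["id"]), float(r[xcol]), float(r[ycol]), s1, s2)
        )
    return records
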