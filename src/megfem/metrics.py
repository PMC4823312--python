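"""Field-map comparison metrics and equivalent-source characterization.

Two scale-aware measures compare multichannel field maps ``v_r`` (reference)
and ``v_s`` (test):

* the relative difference measure RDM*, the Euclidean distance between the
  two norm-normalized channel vectors -- 0 for identical topographies, 2 for
  sign-inverted ones;
* the relative magnitude difference MAG_rel, the ratio of Euclidean norms
  minus one.

Fitted equivalent sources are characterized against the known physical
sources by Euclidean position error, full-step spacing along the shift
line, orientation angle to the shift direction (folded to [0, 90] degrees,
since the dipole sign is not identifiable), and strength; sources are
grouped by shift eccentricity into *under-defect* (|e| <= 0.5) and
*next-to-defect* (|e| >= a configurable window, default 1.3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fem import Dipole, FieldMap
from .phantom import DefectSpec, ShiftLine, compute_shift_eccentricity


def _values(v) -> np.ndarray:
    if isinstance(v, FieldMap):
        return v.values
    return np.asarray(v, dtype=float)


def rdm_star(v_r, v_s) -> float:
    """Relative difference measure of two maps, in [0, 2]."""
    r = _values(v_r)
    s = _values(v_s)
    if r.shape != s.shape:
        raise ValueError("maps have different channel counts")
    nr = np.linalg.norm(r)
    ns = np.linalg.norm(s)
    if nr == 0.0 or ns == 0.0:
        raise ValueError("RDM* is undefined for a zero-norm map")
    return float(np.linalg.norm(r / nr - s / ns))


def mag_rel(v_r, v_s) -> float:
    """Relative magnitude difference: norm ratio minus one (>= -1)."""
    r = _values(v_r)
    s = _values(v_s)
    if r.shape != s.shape:
        raise ValueError("maps have different channel counts")
    nr = np.linalg.norm(r)
    if nr == 0.0:
        raise ValueError("MAG_rel is undefined for a zero-norm reference")
    return float(np.linalg.norm(s) / nr - 1.0)


@dataclass(frozen=True)
class MapComparison:
    """RDM* and MAG_rel of a test map against a reference map."""

    rdm_star: float
    mag_rel: float
    reference_id: str = ""
    test_id: str = ""


def compare_maps(v_r, v_s, reference_id: str = "",
                 test_id: str = "") -> MapComparison:
    return MapComparison(rdm_star(v_r, v_s), mag_rel(v_r, v_s),
                         reference_id, test_id)


# ---------------------------------------------------------------------------
# equivalent-source characterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceCharacterization:
    """Per-source errors of a fitted equivalent dipole vs the physical one."""

    position_error: float          # mm (ideal 0 - 0.4 mm)
    full_step_spacing: float | None  # mm to the next full-step fit (ideal ~0.7)
    angle_to_shift: float          # degrees in [0, 90] (ideal <= 16)
    strength: float                # uAmm (ideal 100 - 130)
    eccentricity: float
    group: str | None              # "under-defect" | "next-to-defect" | None


def fold_angle(a_deg: float) -> float:
    """Fold an angle between undirected axes into [0, 90] degrees."""
    a = abs(a_deg) % 180.0
    return min(a, 180.0 - a)


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two direction vectors, folded to [0, 90] degrees."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = abs(float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def group_of(eccentricity: float, under_window: float = 0.5,
             next_window: float = 1.3) -> str | None:
    if abs(eccentricity) <= under_window:
        return "under-defect"
    if abs(eccentricity) >= next_window:
        return "next-to-defect"
    return None


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """median, lower and upper quartile (linear interpolation)."""
    v = np.asarray(list(values), dtype=float)
    return (float(np.percentile(v, 50)), float(np.percentile(v, 25)),
            float(np.percentile(v, 75)))


def format_median_iqr(values: Sequence[float], unit: str = "") -> str:
    """Render ``median [lower quartile, upper quartile]``."""
    m, lo, hi = median_iqr(values)
    u = f" {unit}" if unit else ""
    return f"{m:.3g}{u} [{lo:.3g}{u}, {hi:.3g}{u}]"


def characterize_sources(fits: Sequence[Dipole],
                         truths: Sequence[Dipole],
                         line: ShiftLine,
                         defect: DefectSpec,
                         under_window: float = 0.5,
                         next_window: float = 1.3,
                         ) -> list[SourceCharacterization]:
    """Characterize fitted dipoles against aligned physical sources.

    ``fits`` and ``truths`` must be aligned by shift position and ordered
    along the line at full-step spacing; the spacing entry of the last
    source is None.
    """
    if len(fits) != len(truths):
        raise ValueError(
            f"{len(fits)} fits but {len(truths)} physical sources"
        )
    out = []
    for i, (fit, truth) in enumerate(zip(fits, truths)):
        perr = float(np.linalg.norm(fit.pos - truth.pos))
        spacing = (float(np.linalg.norm(fits[i + 1].pos - fit.pos))
                   if i + 1 < len(fits) else None)
        angle = angle_between_deg(fit.mom, line.unit_direction)
        ecc = compute_shift_eccentricity(truth.pos, defect, line)
        out.append(SourceCharacterization(
            position_error=perr,
            full_step_spacing=spacing,
            angle_to_shift=angle,
            strength=fit.strength,
            eccentricity=ecc,
            group=group_of(ecc, under_window, next_window),
        ))
    return out


def characterization_table(chars: Sequence[SourceCharacterization]
                           ) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in chars])


def summarize_characterizations(chars: Sequence[SourceCharacterization]
                                ) -> pd.DataFrame:
    """Median [quartile] summaries per source group and metric."""
    rows = []
    table = characterization_table(chars)
    for group, sub in table.groupby("group", dropna=False):
        for metric in ("position_error", "full_step_spacing",
                       "angle_to_shift", "strength"):
            vals = sub[metric].dropna()
            if len(vals) == 0:
                continue
            m, lo, hi = median_iqr(vals)
            rows.append({"group": group, "metric": metric,
                         "median": m, "lower_quartile": lo,
                         "upper_quartile": hi, "n": len(vals)})
    return pd.DataFrame(rows)
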