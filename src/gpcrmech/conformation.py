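"""Inter-helix marker distances and conformational-state classification.

The receptor conformation is summarized by two Cα–Cα distances:

* ``d36`` — BW 3.50 to 6.34, reporting on the TM6 opening;
* ``d37`` — BW 3.50 to 7.55, reporting on the inward/outward TM7 position.

Three conformational states are assigned from the TM3–TM7 distance
averaged over an analysis window (by default the last 30 ns of a 90 ns
run): pre-active (d37 < 16 Å), non-canonical (16 ≤ d37 < 19 Å) and
atypical (d37 ≥ 19 Å).  Heatmaps use a finer four-color code splitting the
atypical range at 21 Å (green: inactive-like 19–21 Å; yellow: outward TM7
> 21 Å).  All intervals are half-open, closed on the lower edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gpcrmech.structure import BWScheme, MolecularFrame, Trajectory, select_calpha

#: State boundaries on the TM3-TM7 Cα distance (Å).
PREACTIVE_MAX = 16.0
NONCANONICAL_MAX = 19.0
GREEN_MAX = 21.0

STATES = ("pre-active", "non-canonical", "atypical")
BIN_COLORS = ("red", "blue", "green", "yellow")


@dataclass
class DistanceSeries:
    """Per-frame marker distances with condition/replica metadata."""

    times: np.ndarray  # ns
    d36: np.ndarray  # Å
    d37: np.ndarray  # Å
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d36 = np.asarray(self.d36, dtype=float)
        self.d37 = np.asarray(self.d37, dtype=float)
        if not len(self.times) == len(self.d36) == len(self.d37):
            raise ValueError("times, d36 and d37 must have equal length")
        if np.any(self.d36 <= 0) or np.any(self.d37 <= 0):
            raise ValueError("distances must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "d36": self.d36,
                "d37": self.d37,
                "bin": [heatmap_bin(d) for d in self.d37],
            }
        )


def tm_marker_distances(frame: MolecularFrame, scheme: BWScheme) -> tuple[float, float]:
    """(d36, d37) in Å: Cα 3.50–6.34 and Cα 3.50–7.55 distances."""
    markers = ["3.50", "6.34", "7.55"]
    try:
        coords = select_calpha(frame, [scheme.resolve(m) for m in markers])
    except KeyError as exc:
        missing = next(
            (m for m in markers if str(scheme.resolve(m)) in str(exc)), "marker"
        )
        raise KeyError(f"missing marker residue BW {missing}: {exc}") from exc
    d36 = float(np.linalg.norm(coords[1] - coords[0]))
    d37 = float(np.linalg.norm(coords[2] - coords[0]))
    return d36, d37


def distance_series(traj: Trajectory, scheme: BWScheme) -> DistanceSeries:
    """Marker distances for every frame of a trajectory."""
    pairs = [tm_marker_distances(f, scheme) for f in traj]
    return DistanceSeries(
        times=traj.times,
        d36=np.array([p[0] for p in pairs]),
        d37=np.array([p[1] for p in pairs]),
        metadata=dict(traj.metadata),
    )


def window_mean(
    series: DistanceSeries, t_start: float, t_end: float
) -> tuple[float, float]:
    """Mean (d36, d37) over frames with t_start ≤ t ≤ t_end."""
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    mask = (series.times >= t_start) & (series.times <= t_end)
    if not np.any(mask):
        raise ValueError(
            f"window [{t_start}, {t_end}] ns contains no frames "
            f"(series spans [{series.times[0]}, {series.times[-1]}] ns)"
        )
    return float(series.d36[mask].mean()), float(series.d37[mask].mean())


def classify_tm7_state(d37_mean: float) -> str:
    """Three-state label from the windowed TM3-TM7 distance (Å)."""
    if d37_mean <= 0:
        raise ValueError("distance must be positive")
    if d37_mean < PREACTIVE_MAX:
        return "pre-active"
    if d37_mean < NONCANONICAL_MAX:
        return "non-canonical"
    return "atypical"


def heatmap_bin(d37: float) -> str:
    """Four-color heatmap bin: red < 16 ≤ blue < 19 ≤ green < 21 ≤ yellow."""
    if d37 <= 0:
        raise ValueError("distance must be positive")
    if d37 < PREACTIVE_MAX:
        return "red"
    if d37 < NONCANONICAL_MAX:
        return "blue"
    if d37 < GREEN_MAX:
        return "green"
    return "yellow"


def heatmap_bin_index(d37: float) -> int:
    """Integer serialization of :func:`heatmap_bin` (0=red .. 3=yellow)."""
    return BIN_COLORS.index(heatmap_bin(d37))


def collective_variable(d36: float, d37: float) -> float:
    """Gross-conformation collective variable: d36 + d37 (Å)."""
    if d36 <= 0 or d37 <= 0:
        raise ValueError("distances must be positive")
    return d36 + d37
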