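"""Membrane lateral pressure profile pipeline and bilayer property measures.

The lateral pressure at depth z and time t is the difference between the
tangential and normal components of the local pressure tensor,

    π(z, t) = (pxx(z, t) + pyy(z, t)) / 2 − pzz(z, t)   [bar]

recorded per slab of the simulation box (100 slabs by default).  A profile
π(z) is obtained by (1) computing raw π(z, t), (2) correcting each
instantaneous profile for the drift of the bilayer position (tracked by the
barycenter of the lipid phosphorus atoms), (3) averaging over time from a
stabilization cutoff t_min, and (4) smoothing with a 3-point running mean.

Also provided: bilayer thickness (peak-to-peak distance of the phosphorus
z distribution), area per lipid, the C–H order parameter
S_CH = ⟨3cos²θ − 1⟩/2, and the surface-tension relation γ = Lz·(Pz − PT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gpcrmech.units import BAR_ANGSTROM_TO_DYN_PER_CM

DEFAULT_N_SLABS = 100
DEFAULT_TMIN_NS = 20.0  # discard early frames while the box stabilizes
DEFAULT_THICKNESS_BIN = 0.5  # Å


@dataclass
class PressureSlabSeries:
    """Per-slab diagonal pressure tensors over time.

    ``z`` is the regular slab-center grid (Å); ``pxx``, ``pyy``, ``pzz``
    are (n_times, n_slabs) arrays in bar; ``lz`` the cell height (Å) and
    ``z_p`` the phosphorus barycenter (Å) per time point, used as the
    drift reference.
    """

    times: np.ndarray  # ns
    z: np.ndarray  # Å, slab centers
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    lz: np.ndarray  # Å per time
    z_p: np.ndarray  # Å per time
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        for name in ("pxx", "pyy", "pzz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.times), len(self.z)):
                raise ValueError(f"{name} must be (n_times, n_slabs)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite pressures in {name}")
            setattr(self, name, arr)
        dz = np.diff(self.z)
        if len(dz) and not np.allclose(dz, dz[0]):
            raise ValueError("slab grid must be regular")

    @property
    def n_slabs(self) -> int:
        return len(self.z)


@dataclass
class LateralPressureProfile:
    """Drift-corrected, time-averaged lateral pressure π(z)."""

    z: np.ndarray  # Å, bilayer-centered
    pi: np.ndarray  # bar
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.z) != len(self.pi):
            raise ValueError("z and pi must have equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")


def instantaneous_lateral_pressure(pxx, pyy, pzz):
    """π = (pxx + pyy)/2 − pzz, elementwise (bar)."""
    return (np.asarray(pxx) + np.asarray(pyy)) / 2.0 - np.asarray(pzz)


def smooth3(values) -> np.ndarray:
    """3-point running mean; endpoints average the available 2 points."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("expected a non-empty 1-D sequence")
    if len(v) == 1:
        return v.copy()
    out = np.empty_like(v)
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    out[0] = (v[0] + v[1]) / 2.0
    out[-1] = (v[-2] + v[-1]) / 2.0
    return out


def pressure_profile(
    series: PressureSlabSeries,
    t_min: float = DEFAULT_TMIN_NS,
    smooth: bool = True,
    drift_mode: str = "interpolate",
) -> LateralPressureProfile:
    """Reduce a slab series to a drift-corrected, time-averaged π(z).

    Each instantaneous profile is shifted so the phosphorus barycenter
    z_P(t) maps to z = 0, resampled onto the fixed slab grid (linear
    interpolation, or nearest-slab shifting with ``drift_mode="nearest"``),
    averaged over t ≥ t_min, then 3-point smoothed.
    """
    if t_min > series.times[-1]:
        raise ValueError(f"t_min={t_min} ns beyond series end {series.times[-1]} ns")
    if drift_mode not in ("interpolate", "nearest"):
        raise ValueError("drift_mode must be 'interpolate' or 'nearest'")
    box = series.z[-1] - series.z[0]
    if np.any(np.abs(series.z_p) > box):
        raise ValueError("drift shift exceeds the box; grid too coarse")
    mask = series.times >= t_min
    pi_t = instantaneous_lateral_pressure(
        series.pxx[mask], series.pyy[mask], series.pzz[mask]
    )
    shifts = series.z_p[mask]
    dz = series.z[1] - series.z[0] if len(series.z) > 1 else 1.0
    corrected = np.empty_like(pi_t)
    for i, shift in enumerate(shifts):
        if drift_mode == "nearest":
            k = int(round(shift / dz))
            corrected[i] = np.roll(pi_t[i], -k)
        else:
            # value at bilayer-centered z equals raw profile at z + shift
            corrected[i] = np.interp(
                series.z + shift, series.z, pi_t[i], left=pi_t[i, 0], right=pi_t[i, -1]
            )
    mean = corrected.mean(axis=0)
    if smooth:
        mean = smooth3(mean)
    return LateralPressureProfile(
        z=series.z.copy(),
        pi=mean,
        provenance={
            "t_min": t_min,
            "smoothing": smooth,
            "drift_mode": drift_mode,
            "n_times": int(mask.sum()),
        },
    )


def average_profiles(profiles: list[LateralPressureProfile]) -> LateralPressureProfile:
    """Replica average of profiles sharing one grid."""
    z0 = profiles[0].z
    for p in profiles[1:]:
        if not np.array_equal(p.z, z0):
            raise ValueError("profiles must share the same z grid")
    return LateralPressureProfile(
        z=z0.copy(),
        pi=np.mean([p.pi for p in profiles], axis=0),
        provenance={"replicas_averaged": len(profiles)},
    )


def _refined_mode(counts: np.ndarray, centers: np.ndarray) -> float:
    """Histogram mode with parabolic refinement of the top bin."""
    i = int(np.argmax(counts))
    if 0 < i < len(counts) - 1:
        y0, y1, y2 = counts[i - 1], counts[i], counts[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(centers[i] + delta * (centers[1] - centers[0]))
    return float(centers[i])


def bilayer_thickness(
    phosphorus_z, bin_width: float = DEFAULT_THICKNESS_BIN
) -> float:
    """Peak-to-peak distance (Å) of the pooled phosphorus z distribution.

    ``phosphorus_z`` may be a flat array or per-frame lists; values are
    pooled.  Raises if the distribution is unimodal (single leaflet).
    """
    if isinstance(phosphorus_z, (list, tuple)):
        z = np.concatenate([np.ravel(np.asarray(f, dtype=float)) for f in phosphorus_z])
    else:
        z = np.asarray(phosphorus_z, dtype=float).ravel()
    mid = z.mean()
    upper, lower = z[z > mid], z[z <= mid]
    if len(upper) == 0 or len(lower) == 0 or (z.max() - z.min()) < 2 * bin_width:
        raise ValueError("unimodal phosphorus distribution: need two leaflets")
    peaks = []
    for leaflet in (lower, upper):
        nbins = max(int(np.ceil((leaflet.max() - leaflet.min()) / bin_width)), 1)
        counts, edges = np.histogram(leaflet, bins=nbins)
        centers = (edges[:-1] + edges[1:]) / 2.0
        peaks.append(_refined_mode(counts, centers))
    return float(peaks[1] - peaks[0])


def area_per_lipid(
    cell_area: float, protein_cross_section: float, n_lipids_per_leaflet: int
) -> float:
    """(cell area − protein cross-section) / lipids per leaflet (Ų)."""
    if protein_cross_section < 0 or n_lipids_per_leaflet <= 0:
        raise ValueError("cross-section must be >= 0 and lipid count positive")
    free = cell_area - protein_cross_section
    if free <= 0:
        raise ValueError("protein cross-section exceeds the cell area")
    return free / n_lipids_per_leaflet


def order_parameter(ch_vectors) -> float:
    """S_CH = ⟨3cos²θ − 1⟩/2 of C–H bond vectors vs the z axis.

    1 for bonds along the membrane normal, −0.5 in the membrane plane,
    0 for an isotropic orientation distribution.
    """
    v = np.asarray(ch_vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
        raise ValueError("expected a non-empty (n, 3) array of vectors")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length C-H vector")
    cos_theta = v[:, 2] / norms
    return float(np.mean((3.0 * cos_theta**2 - 1.0) / 2.0))


def surface_tension_check(pz: float, pt: float, lz: float) -> float:
    """γ = Lz·(Pz − PT) in dyn/cm (Lz in Å, pressures in bar)."""
    if lz <= 0:
        raise ValueError("cell height must be positive")
    return lz * (pz - pt) * BAR_ANGSTROM_TO_DYN_PER_CM


# ---------------------------------------------------------------------------
# TSV dialects (tab-separated, one header line, '#' comments)

def write_pressure_tsv(path: str, series: PressureSlabSeries) -> None:
    """Write the slab series as (time, slab_index, pxx, pyy, pzz) TSV plus a
    ``<path>.cell`` sidecar with (time, Lz, z_P)."""
    n_t, n_s = len(series.times), series.n_slabs
    df = pd.DataFrame(
        {
            "time": np.repeat(series.times, n_s),
            "slab_index": np.tile(np.arange(n_s), n_t),
            "pxx": series.pxx.ravel(),
            "pyy": series.pyy.ravel(),
            "pzz": series.pzz.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# slab centers (A): {' '.join(f'{z:.4f}' for z in series.z)}\n")
        df.to_csv(fh, sep="\t", index=False)
    side = pd.DataFrame({"time": series.times, "lz": series.lz, "z_p": series.z_p})
    side.to_csv(f"{path}.cell", sep="\t", index=False)


def read_pressure_tsv(path: str) -> PressureSlabSeries:
    """Read the TSV dialect written by :func:`write_pressure_tsv`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# slab centers"):
            raise ValueError(f"{path}: missing slab-center comment header")
        z = np.array([float(x) for x in header.split(":", 1)[1].split()])
        df = pd.read_csv(fh, sep="\t", comment="#")
    times = np.unique(df["time"].to_numpy())
    n_t, n_s = len(times), len(z)
    if len(df) != n_t * n_s:
        raise ValueError(f"{path}: expected {n_t * n_s} rows, found {len(df)}")
    df = df.sort_values(["time", "slab_index"])
    side = pd.read_csv(f"{path}.cell", sep="\t", comment="#")
    side = side.sort_values("time")
    return PressureSlabSeries(
        times=times,
        z=z,
        pxx=df["pxx"].to_numpy().reshape(n_t, n_s),
        pyy=df["pyy"].to_numpy().reshape(n_t, n_s),
        pzz=df["pzz"].to_numpy().reshape(n_t, n_s),
        lz=side["lz"].to_numpy(),
        z_p=side["z_p"].to_numpy(),
    )
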