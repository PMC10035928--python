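"""Geometric core: degree-7 polynomial spinal profiles, 20 mm resampling,
plane-curve curvature and profile-to-profile distance metrics.

A profile is a planar curve v(z) — antero-posterior (sagittal) or lateral
(coronal) value against the cephalo-caudal coordinate z — modelled with a
7th-order polynomial fitted to the projected landmark coordinates.
Profiles are resampled at 20 mm stations anchored at the most cephalad
fitted point, curvature k is computed at each station from the
plane-parametric-curve formula

    k = |x' y'' - y' x''| / (x'^2 + y'^2)^(3/2)

with x the cephalo-caudal and y the in-plane coordinate, derivatives taken
by finite differences over the sampled stations (central in the interior,
one-sided at the endpoints). The root-mean-square distance (RMSD) between
two profiles is computed over matched stations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

DEGREE_DEFAULT = 7
INTERVAL_DEFAULT = 20.0  # mm

Region = Literal["overall", "thoracic", "lumbar"]


# ---------------------------------------------------------------------------
# Profile model
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    """Polynomial profile v(z) with its fit quality against the source points."""

    poly: np.polynomial.Polynomial
    domain: tuple[float, float]  # [z_min, z_max] of the fitted points, mm
    fit_rmse: float  # mm, against the original source coordinates
    plane: str | None = None
    source: str | None = None

    @property
    def degree(self) -> int:
        return self.poly.degree()

    def __call__(self, z) -> np.ndarray:
        return self.poly(np.asarray(z, dtype=float))


def fit_profile(
    z: Sequence[float],
    v: Sequence[float],
    degree: int = DEGREE_DEFAULT,
    plane: str | None = None,
    source: str | None = None,
) -> ProfileModel:
    """Ordinary least-squares polynomial fit of v against z.

    The fit is performed in a centered/scaled variable (numpy's polynomial
    domain mapping to [-1, 1]) for conditioning; ``fit_rmse`` is the
    root-mean-square residual against the input points.
    """
    z = np.asarray(z, dtype=float)
    v = np.asarray(v, dtype=float)
    if z.ndim != 1 or z.shape != v.shape:
        raise ValueError("z and v must be equal-length 1-D arrays")
    if z.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}, got {z.size}")
    if np.unique(z).size != z.size:
        raise ValueError("duplicate z values in profile input")
    poly = np.polynomial.Polynomial.fit(z, v, deg=degree)
    resid = v - poly(z)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ProfileModel(
        poly=poly,
        domain=(float(z.min()), float(z.max())),
        fit_rmse=rmse,
        plane=plane,
        source=source,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@dataclass
class SampledProfile:
    """Profile evaluated at evenly spaced cephalo-caudal stations
    (most cephalad first, stepping caudally)."""

    stations: np.ndarray  # z, mm, strictly decreasing by `interval`
    values: np.ndarray  # v(z), mm
    interval: float
    plane: str | None = None
    source: str | None = None
    curvature: np.ndarray | None = None  # 1/mm, filled by compute_curvature

    def to_frame(self) -> pd.DataFrame:
        data = {"station_mm": self.stations, "value_mm": self.values}
        if self.curvature is not None:
            data["curvature_per_mm"] = self.curvature
        return pd.DataFrame(data)


def sample_profile(
    model: ProfileModel,
    interval: float = INTERVAL_DEFAULT,
    domain: tuple[float, float] | None = None,
) -> SampledProfile:
    """Evaluate a profile at `interval` mm stations anchored at the most
    cephalad end of the domain, stepping caudally while stations remain
    inside the domain."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    z_min, z_max = domain if domain is not None else model.domain
    if z_max - z_min < 2 * interval:
        raise ValueError(
            f"domain [{z_min}, {z_max}] shorter than two {interval} mm intervals"
        )
    n = int(np.floor((z_max - z_min) / interval + 1e-9)) + 1
    stations = z_max - interval * np.arange(n)
    return SampledProfile(
        stations=stations,
        values=model(stations),
        interval=interval,
        plane=model.plane,
        source=model.source,
    )


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def compute_curvature(sampled: SampledProfile) -> np.ndarray:
    """Finite-difference curvature of the sampled plane curve at each station.

    Treats (station, value) as a parametric curve indexed by station number;
    first and second derivatives use central differences in the interior and
    second-order one-sided stencils at the two endpoints. Fills and returns
    ``sampled.curvature``; values are non-negative.
    """
    k = curvature_from_points(sampled.stations, sampled.values)
    sampled.curvature = k
    return k


def _d1(u: np.ndarray) -> np.ndarray:
    """First derivative w.r.t. point index: central interior, second-order
    one-sided at the ends."""
    d = np.empty_like(u)
    d[1:-1] = (u[2:] - u[:-2]) / 2.0
    d[0] = (-3 * u[0] + 4 * u[1] - u[2]) / 2.0
    d[-1] = (3 * u[-1] - 4 * u[-2] + u[-3]) / 2.0
    return d


def _d2(u: np.ndarray) -> np.ndarray:
    """Second derivative w.r.t. point index: three-point stencil, shifted
    one-sided at the ends."""
    d = np.empty_like(u)
    d[1:-1] = u[2:] - 2 * u[1:-1] + u[:-2]
    d[0] = u[0] - 2 * u[1] + u[2]
    d[-1] = u[-1] - 2 * u[-2] + u[-3]
    return d


def curvature_from_points(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 stations for curvature")
    x1, y1 = _d1(x), _d1(y)
    x2, y2 = _d2(x), _d2(y)
    denom = (x1**2 + y1**2) ** 1.5
    return np.abs(x1 * y2 - y1 * x2) / denom


def curvature_analytic(model: ProfileModel, stations: Sequence[float]) -> np.ndarray:
    """Exact curvature of the fitted polynomial curve (z, v(z)) at the given
    stations — the closed-form counterpart of the finite-difference routine,
    useful as an oracle and for truncation-error checks."""
    z = np.asarray(stations, dtype=float)
    d1 = model.poly.deriv(1)(z)
    d2 = model.poly.deriv(2)(z)
    return np.abs(d2) / (1.0 + d1**2) ** 1.5


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSummary:
    """Matched-station distance statistics between two profiles.

    ``rmsd`` is the root-mean-square of the station-wise value differences;
    ``mean_distance`` / ``sd_distance`` summarise the absolute differences.
    The signed lateral statistics (positive = second profile subject-left of
    the first) are populated only for coronal comparisons.
    """

    rmsd: float
    mean_distance: float
    sd_distance: float
    n_stations: int
    region: Region = "overall"
    signed_lateral_mean: float | None = None
    left_lateral_fraction: float | None = None


@dataclass(frozen=True)
class RegionBounds:
    """Cephalo-caudal extent of the thoracic and lumbar regions.

    The thoracic/lumbar boundary sits midway between the T12 and L1 markers,
    so a station at the boundary joins the region whose defining marker is
    nearer.
    """

    thoracic: tuple[float, float]  # (z_low, z_high]
    lumbar: tuple[float, float]

    @classmethod
    def from_vertebral_z(cls, labels: Sequence[str], z: Sequence[float]) -> "RegionBounds":
        zmap = dict(zip(labels, np.asarray(z, dtype=float)))
        for lb in ("T1", "T12", "L1", "L5"):
            if lb not in zmap:
                raise ValueError(f"region bounds need label {lb}")
        mid = (zmap["T12"] + zmap["L1"]) / 2.0
        return cls(thoracic=(mid, zmap["T1"]), lumbar=(zmap["L5"], mid))

    def region_mask(self, stations: np.ndarray, region: Region) -> np.ndarray:
        stations = np.asarray(stations, dtype=float)
        if region == "overall":
            return np.ones_like(stations, dtype=bool)
        if region == "thoracic":
            lo, hi = self.thoracic
            return (stations > lo) & (stations <= hi)
        if region == "lumbar":
            lo, hi = self.lumbar
            return (stations >= lo) & (stations <= hi)
        raise ValueError(f"unknown region {region!r}")


def _matched_stations(a: SampledProfile, b: SampledProfile, tol: float = 1e-6):
    """Indices of stations shared (within tol) by both profiles."""
    ia, ib = [], []
    jb = {round(s / tol): j for j, s in enumerate(b.stations)}
    for i, s in enumerate(a.stations):
        j = jb.get(round(s / tol))
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def profile_rmsd(
    a: SampledProfile,
    b: SampledProfile,
    region: Region = "overall",
    region_bounds: RegionBounds | None = None,
) -> DistanceSummary:
    """RMSD and distance summary between two sampled profiles over their
    matched stations, optionally restricted to the thoracic or lumbar region.

    The distance at a station is the difference of the two in-plane values at
    the same z (matched stations), not a closest-point distance. Signed
    lateral statistics (b - a; positive = b subject-left of a) are attached
    for coronal profiles.
    """
    if region != "overall" and region_bounds is None:
        raise ValueError("regional RMSD requires region_bounds")
    ia, ib = _matched_stations(a, b)
    if region != "overall":
        keep = region_bounds.region_mask(a.stations[ia], region)
        ia, ib = ia[keep], ib[keep]
    if ia.size < 3:
        raise ValueError(
            f"need >= 3 overlapping stations in region {region!r}, got {ia.size}"
        )
    d = b.values[ib] - a.values[ia]
    ad = np.abs(d)
    rmsd = float(np.sqrt(np.mean(d**2)))
    mean = float(ad.mean())
    sd = float(ad.std(ddof=1)) if ia.size > 1 else 0.0
    signed_mean = left_frac = None
    if a.plane == "coronal" and b.plane == "coronal":
        signed_mean = float(d.mean())
        left_frac = float(np.mean(d > 0))  # exact zeros count as not-left
    return DistanceSummary(
        rmsd=rmsd,
        mean_distance=mean,
        sd_distance=sd,
        n_stations=int(ia.size),
        region=region,
        signed_lateral_mean=signed_mean,
        left_lateral_fraction=left_frac,
    )


@dataclass(frozen=True)
class PointwiseLateral:
    """Per-vertebra signed lateral offsets of one marker series relative to
    another (positive = subject-left)."""

    mean: float
    sd: float
    left_fraction: float
    n: int


def marker_pointwise_lateral(spine, fiducials) -> PointwiseLateral:
    """Signed per-level lateral distance fiducial - spine in the coronal
    plane, with the fraction of levels lying subject-left (exact zeros count
    as not-left)."""
    if list(spine.labels) != list(fiducials.labels):
        raise ValueError(
            f"label mismatch: {list(spine.labels)} vs {list(fiducials.labels)}"
        )
    d = np.asarray(fiducials.v, dtype=float) - np.asarray(spine.v, dtype=float)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return PointwiseLateral(
        mean=float(d.mean()),
        sd=sd,
        left_fraction=float(np.mean(d > 0)),
        n=int(d.size),
    )
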