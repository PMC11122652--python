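"""Ellipsoid-zone integrity metrics from segmented macular cubes.

Everything here is per A-scan column first, then aggregated over one of
three fovea-centered regions:

* ``central_subfield`` — 1 mm diameter circle (mean thickness here = CST),
* ``central_macula``  — 2 mm diameter circle (CMT),
* ``panmacular``      — the whole cube footprint.

The core quantity is EZ-RPE thickness (um), the axial distance between the
ellipsoid-zone and RPE surfaces. From it come partial/total EZ attenuation
(percent of regional area with thickness <= 20 um / = 0 um), the
panmacular EZ-RPE volume (mm^3), and — given an intensity cube — the EZ
intensity and the RPE-normalized EZ intensity index
``EZ * (EZ / RPE)``, which cancels per-eye media/gain differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ezquant.cube_model import CubeGeometry, IntensityCube, SurfaceSet
from ezquant.errors import DomainError, ValidationError

RegionName = Literal["central_subfield", "central_macula", "panmacular"]

REGION_DIAMETERS_MM: dict[str, float | None] = {
    "central_subfield": 1.0,
    "central_macula": 2.0,
    "panmacular": None,
}

#: half-width (axial pixels) of the max-pooled intensity sampling window
INTENSITY_WINDOW_PX = 2


@dataclass(frozen=True)
class RegionSpec:
    """A fovea-centered analysis region on the en-face grid."""

    name: str
    center_mm: tuple[float, float] | None = None  # None -> geometric cube center
    diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.name not in REGION_DIAMETERS_MM:
            raise ValidationError(f"unknown region {self.name!r}")
        if self.diameter_mm is not None and self.diameter_mm <= 0:
            raise ValidationError("diameter_mm must be > 0")

    @classmethod
    def standard(cls, name: str, center_mm: tuple[float, float] | None = None
                 ) -> "RegionSpec":
        return cls(name=name, center_mm=center_mm,
                   diameter_mm=REGION_DIAMETERS_MM[name])

    def resolved_center(self, geometry: CubeGeometry) -> tuple[float, float]:
        return self.center_mm if self.center_mm is not None else geometry.center_mm


def standard_regions(center_mm: tuple[float, float] | None = None) -> list[RegionSpec]:
    return [RegionSpec.standard(n, center_mm) for n in REGION_DIAMETERS_MM]


@dataclass(frozen=True)
class AttenuationThresholds:
    """Thickness cutoffs (um) defining partial and total EZ attenuation."""

    partial_um: float = 20.0
    total_um: float = 0.0

    def __post_init__(self) -> None:
        if self.total_um > self.partial_um:
            raise ValidationError("total_um must be <= partial_um")


@dataclass
class ThicknessMap:
    """EZ-RPE thickness (um) per column; absent EZ counts as 0 um."""

    geometry: CubeGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        shape = (self.geometry.n_bscans, self.geometry.n_ascans)
        if arr.shape != shape:
            raise ValidationError(f"thickness map shape {arr.shape} != {shape}")
        if np.isnan(arr).any() or (arr < 0).any():
            raise ValidationError("thickness values must be finite and >= 0")
        self.values = arr


@dataclass
class EyeMetrics:
    """The full per-eye metric vector.

    ``per_region`` maps region name to a dict with keys
    ``partial_attenuation_pct``, ``total_attenuation_pct``,
    ``mean_ez_rpe_um`` and, when an intensity cube was supplied,
    ``ez_intensity`` and ``ez_intensity_index``. Intensity entries are
    None when no cube was available.
    """

    per_region: dict[str, dict[str, float | None]]
    foveal_point_um: float
    ez_rpe_volume_mm3: float

    _SCALAR_FIELDS = ("partial_attenuation_pct", "total_attenuation_pct",
                      "mean_ez_rpe_um", "ez_intensity", "ez_intensity_index")

    def to_row(self) -> dict[str, float | None]:
        """Flatten to one TSV-ready row with documented column names."""
        row: dict[str, float | None] = {}
        for region, vals in self.per_region.items():
            for key in self._SCALAR_FIELDS:
                row[f"{key}_{region}"] = vals.get(key)
        row["foveal_point_thickness_um"] = self.foveal_point_um
        row["ez_rpe_volume_mm3"] = self.ez_rpe_volume_mm3
        return row

    @classmethod
    def from_row(cls, row: dict[str, float | None]) -> "EyeMetrics":
        per_region: dict[str, dict[str, float | None]] = {}
        for region in REGION_DIAMETERS_MM:
            per_region[region] = {
                key: row.get(f"{key}_{region}") for key in cls._SCALAR_FIELDS}
        return cls(per_region=per_region,
                   foveal_point_um=float(row["foveal_point_thickness_um"]),
                   ez_rpe_volume_mm3=float(row["ez_rpe_volume_mm3"]))


# ---------------------------------------------------------------------------
# thickness


def thickness_map(s: SurfaceSet) -> ThicknessMap:
    """EZ-RPE thickness per column: ``max(0, RPE - EZ)``; absent EZ -> 0 um.

    Treating an absent EZ as zero thickness keeps total attenuation
    (thickness = 0) and the absent-EZ intensity convention (intensity = 0)
    mutually consistent.
    """
    with np.errstate(invalid="ignore"):
        t = s.rpe - s.ez
    t = np.where(np.isnan(t), 0.0, np.maximum(t, 0.0))
    return ThicknessMap(geometry=s.geometry, values=t)


def region_mask(region: RegionSpec, geometry: CubeGeometry
                ) -> tuple[np.ndarray, float]:
    """Boolean column mask for a region plus the per-column area (mm^2).

    A column belongs to a circular region iff its footprint *center* lies
    within the circle (no partial-area weighting); ``panmacular`` selects
    every column.
    """
    area = geometry.column_area_mm2
    if region.diameter_mm is None:
        return np.ones((geometry.n_bscans, geometry.n_ascans), dtype=bool), area
    cx, cy = region.resolved_center(geometry)
    r = region.diameter_mm / 2.0
    if not (0 <= cx <= geometry.width_mm and 0 <= cy <= geometry.height_mm):
        raise ValidationError("region center outside the cube footprint")
    if cx - r < 0 or cx + r > geometry.width_mm or cy - r < 0 or cy + r > geometry.height_mm:
        raise ValidationError("region circle extends outside the cube footprint")
    x, y = geometry.column_centers_mm()
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2
    if not mask.any():
        raise DomainError(f"region {region.name!r} selects no columns")
    return mask, area


def mean_region_thickness(t: ThicknessMap, region: RegionSpec) -> float:
    """Unweighted mean thickness (um) over the region's columns.

    Columns all carry equal footprint area, so the unweighted mean equals
    the area-weighted mean.
    """
    mask, _ = region_mask(region, t.geometry)
    return float(t.values[mask].mean())


def foveal_point_thickness(t: ThicknessMap,
                           center_mm: tuple[float, float] | None = None) -> float:
    """Thickness (um) of the single column containing the fovea center."""
    g = t.geometry
    cx, cy = center_mm if center_mm is not None else g.center_mm
    a = min(int(cx / g.dx_mm), g.n_ascans - 1)
    b = min(int(cy / g.dy_mm), g.n_bscans - 1)
    if not (0 <= cx <= g.width_mm and 0 <= cy <= g.height_mm):
        raise DomainError("fovea center outside the cube footprint")
    return float(t.values[b, a])


def attenuation_pct(t: ThicknessMap, region: RegionSpec,
                    thr: AttenuationThresholds = AttenuationThresholds()
                    ) -> tuple[float, float]:
    """Partial and total EZ attenuation (% of regional area).

    Partial counts columns with thickness <= ``thr.partial_um`` (20 um),
    total those with thickness <= ``thr.total_um`` (0 um); total <= partial
    by construction.
    """
    mask, _ = region_mask(region, t.geometry)
    vals = t.values[mask]
    partial = 100.0 * float((vals <= thr.partial_um).mean())
    total = 100.0 * float((vals <= thr.total_um).mean())
    return partial, total


def panmacular_volume(t: ThicknessMap, geometry: CubeGeometry | None = None) -> float:
    """EZ-RPE compartment volume (mm^3) over the whole footprint.

    Sum of thickness (converted to mm) times the column footprint area;
    algebraically equal to mean panmacular thickness (mm) x footprint area.
    """
    g = geometry if geometry is not None else t.geometry
    return float(t.values.sum()) * 1e-3 * g.column_area_mm2


# ---------------------------------------------------------------------------
# intensity


def ez_intensity_profile(cube: IntensityCube, s: SurfaceSet,
                         window_px: int = INTENSITY_WINDOW_PX
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column EZ and RPE intensities (grayscale).

    The intensity at a surface is the maximum voxel value within
    +-``window_px`` axial pixels of the surface depth — max-pooling absorbs
    one-pixel segmentation jitter. Columns with an absent EZ report EZ
    intensity 0.
    """
    if cube.geometry != s.geometry:
        raise ValidationError("intensity cube and surfaces have different geometries")
    g = cube.geometry

    def sample(depth_um: np.ndarray) -> np.ndarray:
        out = np.zeros(depth_um.shape, dtype=np.float64)
        present = ~np.isnan(depth_um)
        idx = np.round(depth_um[present] / g.axial_um_per_px).astype(np.int64)
        idx = np.clip(idx, 0, g.n_depth - 1)
        lo = np.clip(idx - window_px, 0, g.n_depth - 1)
        hi = np.clip(idx + window_px, 0, g.n_depth - 1)
        b_idx, a_idx = np.nonzero(present)
        vals = np.empty(idx.shape, dtype=np.float64)
        for k in range(idx.size):  # bounded window, cheap even at 512x128
            vals[k] = cube.values[b_idx[k], a_idx[k], lo[k]:hi[k] + 1].max()
        out[present] = vals
        return out

    return sample(s.ez), sample(s.rpe)


def ez_intensity_index(ez_i: np.ndarray, rpe_i: np.ndarray, mask: np.ndarray,
                       mode: Literal["per_ascan", "region_mean"] = "per_ascan"
                       ) -> tuple[float, float]:
    """Mean EZ intensity and mean RPE-normalized intensity index in a region.

    The per-column index is ``ez * (ez / rpe)``, defined as 0 where the RPE
    intensity is 0 (shadowed columns carry no normalizable signal). The
    default averages per-column indices over the region; ``region_mean``
    instead forms the index from regional mean intensities.
    """
    if not mask.any():
        raise DomainError("empty region mask")
    ez_m = np.asarray(ez_i, dtype=np.float64)[mask]
    rpe_m = np.asarray(rpe_i, dtype=np.float64)[mask]
    mean_ez = float(ez_m.mean())
    if mode == "region_mean":
        mean_rpe = float(rpe_m.mean())
        index = 0.0 if mean_rpe == 0 else mean_ez * (mean_ez / mean_rpe)
        return mean_ez, index
    with np.errstate(divide="ignore", invalid="ignore"):
        per_col = np.where(rpe_m > 0, ez_m * (ez_m / rpe_m), 0.0)
    return mean_ez, float(per_col.mean())


# ---------------------------------------------------------------------------
# composition


def compute_eye_metrics(s: SurfaceSet, cube: IntensityCube | None = None,
                        fovea_center_mm: tuple[float, float] | None = None,
                        thresholds: AttenuationThresholds = AttenuationThresholds(),
                        ) -> EyeMetrics:
    """Compute every metric for one eye from its surfaces (and optional cube).

    Intensity fields are None when no cube is supplied. The fovea defaults
    to the geometric cube center (cubes are nominally fovea-centered).
    """
    t = thickness_map(s)
    intensities = None
    if cube is not None:
        intensities = ez_intensity_profile(cube, s)
    per_region: dict[str, dict[str, float | None]] = {}
    for region in standard_regions(fovea_center_mm):
        mask, _ = region_mask(region, s.geometry)
        partial, total = attenuation_pct(t, region, thresholds)
        vals: dict[str, float | None] = {
            "partial_attenuation_pct": partial,
            "total_attenuation_pct": total,
            "mean_ez_rpe_um": mean_region_thickness(t, region),
        }
        if intensities is not None:
            ez_i, rpe_i = intensities
            mean_ez, index = ez_intensity_index(ez_i, rpe_i, mask)
            vals["ez_intensity"] = mean_ez
            vals["ez_intensity_index"] = index
        else:
            vals["ez_intensity"] = None
            vals["ez_intensity_index"] = None
        per_region[region.name] = vals
    return EyeMetrics(
        per_region=per_region,
        foveal_point_um=foveal_point_thickness(t, fovea_center_mm),
        ez_rpe_volume_mm3=panmacular_volume(t),
    )
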