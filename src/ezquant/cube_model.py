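"""Data model and file I/O for OCT macular cubes, surfaces and cohort tables.

Conventions
-----------
* Depths are in micrometres, increasing downward from the top of the B-scan.
* Surface grids are ``(n_bscans, n_ascans)`` arrays; grid indices are 0-based.
* Column ``(b, a)`` covers the half-open en-face footprint
  ``[a*dx, (a+1)*dx) x [b*dy, (b+1)*dy)`` in millimetres.
* An absent ellipsoid-zone (EZ) surface at a column is stored as NaN in
  memory and as the sentinel ``NA`` on disk.

Surfaces travel in a TSV dialect: for each layer a one-line JSON header
(``# {...}``) followed by ``n_bscans`` rows of ``n_ascans`` tab-separated
values. Intensity cubes are raw little-endian unsigned 8-bit, C-order
``(bscan, ascan, depth)``, with a JSON sidecar describing the geometry.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ezquant.errors import FormatError, ParseError, ValidationError
from ezquant.va_function import snellen_to_letters

# segmentation jitter this small is clamped instead of rejected (micrometres)
ORDER_CLAMP_TOL_UM = 2.0

LAYER_NAMES = ("ILM", "EZ", "RPE", "BM")

GA_STATUSES = ("none", "foveal", "extrafoveal")
PHAKIC_STATUSES = ("phakic", "pseudophakic")


@dataclass(frozen=True)
class CubeGeometry:
    """Sampling lattice of a macular cube scan.

    Defaults describe the common 6 mm x 6 mm, 512 x 128 A-scan cube with
    1024 axial pixels at 1.955 um/pixel. All regional area and volume
    arithmetic flows from this object.
    """

    width_mm: float = 6.0
    height_mm: float = 6.0
    n_ascans: int = 512
    n_bscans: int = 128
    axial_um_per_px: float = 1.955
    n_depth: int = 1024

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "n_ascans", "n_bscans",
                     "axial_um_per_px", "n_depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"CubeGeometry.{name} must be > 0")

    @property
    def dx_mm(self) -> float:
        """A-scan pitch (mm) along a B-scan."""
        return self.width_mm / self.n_ascans

    @property
    def dy_mm(self) -> float:
        """B-scan pitch (mm)."""
        return self.height_mm / self.n_bscans

    @property
    def column_area_mm2(self) -> float:
        return self.dx_mm * self.dy_mm

    @property
    def footprint_area_mm2(self) -> float:
        return self.width_mm * self.height_mm

    @property
    def depth_um(self) -> float:
        """Total axial extent of the scan in micrometres."""
        return self.n_depth * self.axial_um_per_px

    @property
    def center_mm(self) -> tuple[float, float]:
        return (self.width_mm / 2.0, self.height_mm / 2.0)

    def column_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """En-face centers of every column as ``(x, y)`` grids (mm)."""
        x = (np.arange(self.n_ascans) + 0.5) * self.dx_mm
        y = (np.arange(self.n_bscans) + 0.5) * self.dy_mm
        return np.meshgrid(x, y)


@dataclass
class SurfaceSet:
    """Per-column depths (um) of the four segmented surfaces.

    ``ez`` may contain NaN where the ellipsoid zone is absent. Where all
    four surfaces are present the anatomical ordering ILM <= EZ <= RPE <= BM
    holds; construction clamps violations up to ``ORDER_CLAMP_TOL_UM`` and
    rejects anything larger.
    """

    geometry: CubeGeometry
    ilm: np.ndarray
    ez: np.ndarray
    rpe: np.ndarray
    bm: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.geometry.n_bscans, self.geometry.n_ascans)
        for name in ("ilm", "ez", "rpe", "bm"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise FormatError(
                    f"surface {name!r} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        for name in ("ilm", "rpe", "bm"):
            if np.isnan(getattr(self, name)).any():
                raise ValidationError(f"surface {name!r} contains NaN; only EZ may be absent")
        self._validate_range()
        self._clamp_ordering()

    def _validate_range(self) -> None:
        hi = self.geometry.depth_um
        for name in ("ilm", "ez", "rpe", "bm"):
            arr = getattr(self, name)
            finite = arr[~np.isnan(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > hi):
                raise ValidationError(
                    f"surface {name!r} has depths outside [0, {hi:.1f}] um")

    def _clamp_ordering(self) -> None:
        # enforce ILM <= EZ <= RPE <= BM top-down, tolerating small jitter
        chain = [self.ilm, self.ez, self.rpe, self.bm]
        names = LAYER_NAMES
        for upper, lower, un, ln in zip(chain[:-1], chain[1:], names[:-1], names[1:]):
            with np.errstate(invalid="ignore"):
                excess = upper - lower  # positive where ordering is violated
            bad = np.nan_to_num(excess, nan=0.0)
            if (bad > ORDER_CLAMP_TOL_UM).any():
                worst = float(np.nanmax(excess))
                raise ValidationError(
                    f"surface ordering violated: {un} below {ln} by up to "
                    f"{worst:.2f} um (> {ORDER_CLAMP_TOL_UM} um tolerance)")
            fix = bad > 0
            if fix.any():
                lower[fix] = upper[fix]

    @property
    def ez_absent(self) -> np.ndarray:
        """Boolean mask of columns where the EZ surface is absent."""
        return np.isnan(self.ez)

    @property
    def n_ez_absent(self) -> int:
        return int(self.ez_absent.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurfaceSet):
            return NotImplemented
        return self.geometry == other.geometry and all(
            np.array_equal(getattr(self, n), getattr(other, n), equal_nan=True)
            for n in ("ilm", "ez", "rpe", "bm"))


@dataclass
class IntensityCube:
    """Grayscale OCT voxel cube, ``(n_bscans, n_ascans, n_depth)`` uint8.

    Reflectivity is on a 0-255 scale with 255 = maximum brightness (white);
    the conceptual top of the scale is pure white and 0 marks absent signal.
    """

    geometry: CubeGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        shape = (self.geometry.n_bscans, self.geometry.n_ascans, self.geometry.n_depth)
        if arr.shape != shape:
            raise FormatError(f"cube shape {arr.shape} != geometry {shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError("intensity values outside [0, 255]")
            arr = arr.astype(np.uint8)
        self.values = arr


@dataclass(frozen=True)
class VisitRecord:
    """One clinical visit of one eye."""

    patient_id: str
    eye_id: str
    laterality: str  # "OD" or "OS"
    year: int
    va_letters: int
    ga_status: str  # none | foveal | extrafoveal
    phakic_status: str  # phakic | pseudophakic

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValidationError(f"laterality {self.laterality!r} not OD/OS")
        if not 0 <= self.va_letters <= 100:
            raise ValidationError(f"va_letters {self.va_letters} outside [0, 100]")
        if self.ga_status not in GA_STATUSES:
            raise ValidationError(f"unknown ga_status {self.ga_status!r}")
        if self.phakic_status not in PHAKIC_STATUSES:
            raise ValidationError(f"unknown phakic_status {self.phakic_status!r}")


# ---------------------------------------------------------------------------
# surface TSV I/O


def _geometry_header(geometry: CubeGeometry, layer: str) -> str:
    payload = {
        "layer": layer,
        "width_mm": geometry.width_mm,
        "height_mm": geometry.height_mm,
        "n_ascans": geometry.n_ascans,
        "n_bscans": geometry.n_bscans,
        "axial_um_per_px": geometry.axial_um_per_px,
        "n_depth": geometry.n_depth,
        "units": "um",
    }
    return "# " + json.dumps(payload)


def write_surface_set(s: SurfaceSet, path: str | Path) -> Path:
    """Serialize a :class:`SurfaceSet` to the surface-TSV dialect.

    Values are written with ``repr`` so the read/write round trip is exact.
    """
    path = Path(path)
    arrays = {"ILM": s.ilm, "EZ": s.ez, "RPE": s.rpe, "BM": s.bm}
    lines: list[str] = []
    for layer in LAYER_NAMES:
        lines.append(_geometry_header(s.geometry, layer))
        arr = arrays[layer]
        for row in arr:
            lines.append("\t".join(
                "NA" if np.isnan(v) else repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_surface_set(path: str | Path, geometry: CubeGeometry | None = None) -> SurfaceSet:
    """Parse the surface-TSV dialect back into a validated :class:`SurfaceSet`.

    When ``geometry`` is None it is reconstructed from the file headers.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    tables: dict[str, np.ndarray] = {}
    i = 0
    file_geometry: CubeGeometry | None = None
    while i < len(lines):
        line = lines[i]
        if not line.startswith("# "):
            raise FormatError(f"{path}: expected JSON header at line {i + 1}")
        try:
            header = json.loads(line[2:])
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: bad JSON header at line {i + 1}: {exc}") from exc
        layer = header.get("layer")
        if layer not in LAYER_NAMES:
            raise FormatError(f"{path}: unknown layer {layer!r} at line {i + 1}")
        hdr_geom = CubeGeometry(
            width_mm=header["width_mm"], height_mm=header["height_mm"],
            n_ascans=header["n_ascans"], n_bscans=header["n_bscans"],
            axial_um_per_px=header["axial_um_per_px"], n_depth=header["n_depth"])
        if file_geometry is None:
            file_geometry = hdr_geom
        elif hdr_geom != file_geometry:
            raise FormatError(f"{path}: inconsistent geometry across layer headers")
        i += 1
        rows = []
        while i < len(lines) and not lines[i].startswith("# "):
            if lines[i].strip():
                rows.append(lines[i].split("\t"))
            i += 1
        n_b, n_a = hdr_geom.n_bscans, hdr_geom.n_ascans
        if len(rows) != n_b or any(len(r) != n_a for r in rows):
            got = f"{len(rows)}x{len(rows[0]) if rows else 0}"
            raise FormatError(
                f"{path}: layer {layer}: table is {got}, expected {n_b}x{n_a}")
        arr = np.empty((n_b, n_a), dtype=np.float64)
        for bi, row in enumerate(rows):
            for ai, cell in enumerate(row):
                if cell == "NA":
                    if layer != "EZ":
                        raise ParseError(
                            f"{path}: NA sentinel in non-EZ layer {layer} "
                            f"at row {bi}, col {ai}")
                    arr[bi, ai] = np.nan
                else:
                    try:
                        arr[bi, ai] = float(cell)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: non-numeric cell {cell!r} in layer {layer} "
                            f"at row {bi}, col {ai}") from exc
        tables[layer] = arr
    missing = [l for l in LAYER_NAMES if l not in tables]
    if missing:
        raise FormatError(f"{path}: missing layer tables: {missing}")
    if geometry is not None and file_geometry != geometry:
        raise FormatError(f"{path}: file geometry does not match the requested geometry")
    assert file_geometry is not None
    return SurfaceSet(geometry=file_geometry, ilm=tables["ILM"], ez=tables["EZ"],
                      rpe=tables["RPE"], bm=tables["BM"])


# ---------------------------------------------------------------------------
# intensity cube I/O (raw u8 + JSON sidecar)


def write_intensity_cube(cube: IntensityCube, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(np.ascontiguousarray(cube.values).tobytes())
    g = cube.geometry
    sidecar = {
        "dtype": "uint8", "order": "C", "axes": ["bscan", "ascan", "depth"],
        "width_mm": g.width_mm, "height_mm": g.height_mm,
        "n_ascans": g.n_ascans, "n_bscans": g.n_bscans,
        "axial_um_per_px": g.axial_um_per_px, "n_depth": g.n_depth,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")
    return path


def read_intensity_cube(path: str | Path) -> IntensityCube:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    geometry = CubeGeometry(
        width_mm=sidecar["width_mm"], height_mm=sidecar["height_mm"],
        n_ascans=sidecar["n_ascans"], n_bscans=sidecar["n_bscans"],
        axial_um_per_px=sidecar["axial_um_per_px"], n_depth=sidecar["n_depth"])
    raw = np.frombuffer(path.read_bytes(), dtype=np.uint8)
    expected = geometry.n_bscans * geometry.n_ascans * geometry.n_depth
    if raw.size != expected:
        raise FormatError(f"{path}: {raw.size} voxels on disk, sidecar implies {expected}")
    values = raw.reshape(geometry.n_bscans, geometry.n_ascans, geometry.n_depth)
    return IntensityCube(geometry=geometry, values=values.copy())


# ---------------------------------------------------------------------------
# cohort CSV


COHORT_COLUMNS = ("patient_id", "eye_id", "laterality", "year", "va",
                  "ga_status", "phakic_status")


def read_cohort_table(path: str | Path) -> list[VisitRecord]:
    """Read a cohort CSV into validated :class:`VisitRecord` rows.

    The ``va`` column accepts either an integer ETDRS letter score or a
    Snellen fraction like ``20/40`` (converted via logMAR).
    """
    path = Path(path)
    records: list[VisitRecord] = []
    seen: set[tuple[str, str, int]] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(COHORT_COLUMNS) - set(reader.fieldnames):
            raise FormatError(
                f"{path}: header must contain columns {COHORT_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            va_raw = row["va"].strip()
            try:
                if "/" in va_raw:
                    letters = snellen_to_letters(va_raw)
                else:
                    letters = int(va_raw)
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}: row {lineno}: bad va {va_raw!r}") from exc
            try:
                rec = VisitRecord(
                    patient_id=row["patient_id"].strip(),
                    eye_id=row["eye_id"].strip(),
                    laterality=row["laterality"].strip(),
                    year=int(row["year"]),
                    va_letters=letters,
                    ga_status=row["ga_status"].strip(),
                    phakic_status=row["phakic_status"].strip(),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
            key = (rec.patient_id, rec.eye_id, rec.year)
            if key in seen:
                raise ValidationError(
                    f"{path}: row {lineno}: duplicate (patient, eye, year) {key}")
            seen.add(key)
            records.append(rec)
    return records


def write_cohort_table(records: Iterable[VisitRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow([r.patient_id, r.eye_id, r.laterality, r.year,
                             r.va_letters, r.ga_status, r.phakic_status])
    return path
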