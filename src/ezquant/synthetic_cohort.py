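"""Synthetic OCT cohorts with known ground truth.

The generator emulates the structure of a dry-AMD macular-cube cohort:
every eye carries drusen (local EZ-RPE compressions) on a smooth random
base thickness field; a subset develops a geographic-atrophy (GA) disc in
which EZ-RPE thickness is zero and the EZ surface is absent, mostly
involving the central subfield and growing over follow-up. Intensity
volumes render bright EZ and RPE bands scaled by a per-eye gain (media
clarity, phakic vs pseudophakic), with the bands lost inside GA.

Visual acuity is drawn from a disclosed generating model,

    letters = intercept - a * (central-subfield total attenuation, %)
                        - b * max(0, ref - CST um) + N(0, sd),

so structure-function associations exist by construction and their
recovery by the pipeline is testable. Ground truth (lesion geometry,
analytic regional attenuation fractions, gain, noiseless letters) is
recorded per eye and visit in :class:`SimTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from ezquant.cube_model import (
    CubeGeometry,
    IntensityCube,
    SurfaceSet,
    VisitRecord,
    write_cohort_table,
    write_intensity_cube,
    write_surface_set,
)
from ezquant.ez_metrics import RegionSpec, compute_eye_metrics, region_mask

#: down-scaled lattice used by default for fast, deterministic test runs
TEST_GEOMETRY = CubeGeometry(n_ascans=64, n_bscans=64, n_depth=256)

FULL_GEOMETRY = CubeGeometry()

_RPE_DEPTH_UM = 330.0
_ILM_OFFSET_UM = 180.0
_BM_OFFSET_UM = 15.0
_BACKGROUND_LEVEL = 30.0


@dataclass(frozen=True)
class DrusenConfig:
    count_range: tuple[int, int] = (0, 8)
    radius_range_mm: tuple[float, float] = (0.05, 0.2)
    peak_reduction_um_range: tuple[float, float] = (10.0, 25.0)


@dataclass(frozen=True)
class GAConfig:
    prevalence: float = 0.33
    foveal_involvement_prob: float = 0.84
    radius_range_mm: tuple[float, float] = (0.3, 1.5)
    extrafoveal_radius_range_mm: tuple[float, float] = (0.3, 0.6)
    extrafoveal_offset_range_mm: tuple[float, float] = (1.2, 1.8)
    foveal_offset_max_mm: float = 0.35
    growth_mm_per_year: float = 0.25


@dataclass(frozen=True)
class IntensityConfig:
    ez_level: float = 140.0
    rpe_level: float = 180.0
    noise_sd: float = 8.0
    gain_range: tuple[float, float] = (0.8, 1.2)


@dataclass(frozen=True)
class VAModelConfig:
    intercept: float = 87.0
    attenuation_coef: float = 0.35  # letters per % central-subfield total attenuation
    thickness_coef: float = 0.6     # letters per um of CST deficit below the reference
    thickness_ref_um: float = 25.0
    noise_sd: float = 3.0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort."""

    n_patients: int = 80
    p_both_eyes: float = 0.45
    geometry: CubeGeometry = TEST_GEOMETRY
    base_thickness_um: tuple[float, float] = (33.0, 4.0)  # mean, sd of the field
    drusen: DrusenConfig = DrusenConfig()
    ga: GAConfig = GAConfig()
    intensity: IntensityConfig = IntensityConfig()
    va_model: VAModelConfig = VAModelConfig()
    years: tuple[int, ...] = (0, 5)
    seed: int = 0


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one synthetic eye at one visit."""

    patient_id: str
    eye_id: str
    year: int
    has_ga: bool
    ga_center_mm: tuple[float, float] | None
    ga_radius_mm: float
    ga_foveal: bool
    n_drusen: int
    gain: float
    true_total_attenuation_pct_central_subfield: float
    true_total_attenuation_pct_central_macula: float
    true_total_attenuation_pct_panmacular: float
    true_cst_um: float
    va_letters_noiseless: float
    va_letters: int


@dataclass(frozen=True)
class _EyeParams:
    """Visit-invariant latent state of one synthetic eye."""

    patient_id: str
    eye_id: str
    laterality: str
    phakic_status: str
    gain: float
    field_seed: int
    drusen: tuple[tuple[float, float, float, float], ...]  # (cx, cy, radius, peak)
    has_ga: bool
    ga_center_mm: tuple[float, float] | None
    ga_radius0_mm: float


# ---------------------------------------------------------------------------
# analytic geometry


def circle_overlap_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two circles with center distance ``d``."""
    if r1 <= 0 or r2 <= 0 or d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    # lens formula
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = 0.5 * math.sqrt((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    return a1 + a2 - k


def _true_total_attenuation(params: _EyeParams, config: SimConfig,
                            year: int) -> tuple[float, float, float, float]:
    """Analytic total-attenuation fractions (%) and the GA radius at a visit."""
    g = config.geometry
    if not params.has_ga:
        return 0.0, 0.0, 0.0, 0.0
    cx, cy = params.ga_center_mm
    fx, fy = g.center_mm
    dist = math.hypot(cx - fx, cy - fy)
    r = params.ga_radius0_mm + config.ga.growth_mm_per_year * year
    # keep the disc inside the footprint so circular-overlap truth stays exact
    max_r = min(cx, cy, g.width_mm - cx, g.height_mm - cy) - 0.05
    r = min(r, max_r)
    cs = 100.0 * circle_overlap_area(dist, 0.5, r) / (math.pi * 0.25)
    cm = 100.0 * circle_overlap_area(dist, 1.0, r) / (math.pi * 1.0)
    pan = 100.0 * math.pi * r * r / g.footprint_area_mm2
    return cs, cm, pan, r


# ---------------------------------------------------------------------------
# sampling and rendering


def _sample_eye_params(config: SimConfig, rng: np.random.Generator,
                       patient_id: str, laterality: str) -> _EyeParams:
    g = config.geometry
    fx, fy = g.center_mm
    gain = float(rng.uniform(*config.intensity.gain_range))
    phakic = "phakic" if rng.random() < 0.5 else "pseudophakic"
    n_drusen = int(rng.integers(config.drusen.count_range[0],
                                config.drusen.count_range[1] + 1))
    drusen = tuple(
        (float(rng.uniform(0.5, g.width_mm - 0.5)),
         float(rng.uniform(0.5, g.height_mm - 0.5)),
         float(rng.uniform(*config.drusen.radius_range_mm)),
         float(rng.uniform(*config.drusen.peak_reduction_um_range)))
        for _ in range(n_drusen))
    has_ga = bool(rng.random() < config.ga.prevalence)
    center = None
    radius0 = 0.0
    if has_ga:
        if rng.random() < config.ga.foveal_involvement_prob:
            off = float(rng.uniform(0.0, config.ga.foveal_offset_max_mm))
            radius0 = float(rng.uniform(*config.ga.radius_range_mm))
        else:
            off = float(rng.uniform(*config.ga.extrafoveal_offset_range_mm))
            radius0 = float(rng.uniform(*config.ga.extrafoveal_radius_range_mm))
        theta = float(rng.uniform(0.0, 2.0 * math.pi))
        center = (fx + off * math.cos(theta), fy + off * math.sin(theta))
    return _EyeParams(
        patient_id=patient_id,
        eye_id=f"{patient_id}-{laterality}",
        laterality=laterality,
        phakic_status=phakic,
        gain=gain,
        field_seed=int(rng.integers(0, 2**31 - 1)),
        drusen=drusen,
        has_ga=has_ga,
        ga_center_mm=center,
        ga_radius0_mm=radius0,
    )


def _thickness_grid(params: _EyeParams, config: SimConfig, year: int,
                    ga_radius_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth EZ-RPE thickness grid (um) and the GA column mask."""
    g = config.geometry
    x, y = g.column_centers_mm()
    frng = np.random.default_rng(params.field_seed)
    field_ = np.zeros_like(x)
    for _ in range(6):
        fxc = frng.integers(1, 4)
        fyc = frng.integers(1, 4)
        phase = frng.uniform(0, 2 * math.pi)
        amp = frng.uniform(0.5, 1.0)
        field_ += amp * np.cos(2 * math.pi * (fxc * x / g.width_mm +
                                              fyc * y / g.height_mm) + phase)
    mean, sd = config.base_thickness_um
    s = field_.std()
    if s > 0:
        field_ = field_ * (sd / s)
    t = mean + field_
    for cx, cy, r, peak in params.drusen:
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        t -= peak * np.maximum(0.0, 1.0 - d2 / (r * r))
    t = np.maximum(t, 1.0)  # drusen thin the band but never abolish it
    ga_mask = np.zeros_like(t, dtype=bool)
    if params.has_ga and ga_radius_mm > 0:
        cx, cy = params.ga_center_mm
        ga_mask = (x - cx) ** 2 + (y - cy) ** 2 <= ga_radius_mm ** 2
        t = np.where(ga_mask, 0.0, t)
    return t, ga_mask


def _render_surfaces(t: np.ndarray, ga_mask: np.ndarray,
                     geometry: CubeGeometry) -> SurfaceSet:
    rpe = np.full(t.shape, _RPE_DEPTH_UM)
    ez = rpe - t
    ez = np.where(ga_mask, np.nan, ez)
    ilm = rpe - t - _ILM_OFFSET_UM
    ilm = np.where(ga_mask, rpe - _ILM_OFFSET_UM, ilm)
    bm = rpe + _BM_OFFSET_UM
    return SurfaceSet(geometry=geometry, ilm=ilm, ez=ez, rpe=rpe, bm=bm)


def _render_cube(s: SurfaceSet, gain: float, config: SimConfig,
                 rng: np.random.Generator) -> IntensityCube:
    g = config.geometry
    ic = config.intensity
    base = np.full((g.n_bscans, g.n_ascans, g.n_depth),
                   gain * _BACKGROUND_LEVEL, dtype=np.float32)

    def paint(depth_um: np.ndarray, level: float) -> None:
        present = ~np.isnan(depth_um)
        b_idx, a_idx = np.nonzero(present)
        px = np.round(depth_um[present] / g.axial_um_per_px).astype(np.int64)
        for off in (-1, 0, 1):
            k = np.clip(px + off, 0, g.n_depth - 1)
            base[b_idx, a_idx, k] = gain * level

    paint(s.ez, ic.ez_level)
    paint(s.rpe, ic.rpe_level)
    if ic.noise_sd > 0:
        base = base + rng.normal(0.0, ic.noise_sd, size=base.shape).astype(np.float32)
    values = np.clip(np.round(base), 0, 255).astype(np.uint8)
    return IntensityCube(geometry=g, values=values)


def _render_eye_visit(params: _EyeParams, config: SimConfig, year: int,
                      rng: np.random.Generator
                      ) -> tuple[SurfaceSet, IntensityCube, SimTruth]:
    g = config.geometry
    cs, cm, pan, r_t = _true_total_attenuation(params, config, year)
    t, ga_mask = _thickness_grid(params, config, year, r_t)
    surfaces = _render_surfaces(t, ga_mask, g)
    cube = _render_cube(surfaces, params.gain, config, rng)

    cs_mask, _ = region_mask(RegionSpec.standard("central_subfield"), g)
    true_cst = float(t[cs_mask].mean())
    vm = config.va_model
    clean = (vm.intercept - vm.attenuation_coef * cs
             - vm.thickness_coef * max(0.0, vm.thickness_ref_um - true_cst))
    letters = int(np.clip(round(clean + rng.normal(0.0, vm.noise_sd)), 0, 100))

    fx, fy = g.center_mm
    foveal = False
    if params.has_ga:
        cx, cy = params.ga_center_mm
        foveal = math.hypot(cx - fx, cy - fy) <= r_t + 0.5
    truth = SimTruth(
        patient_id=params.patient_id,
        eye_id=params.eye_id,
        year=year,
        has_ga=params.has_ga,
        ga_center_mm=params.ga_center_mm,
        ga_radius_mm=r_t,
        ga_foveal=foveal,
        n_drusen=len(params.drusen),
        gain=params.gain,
        true_total_attenuation_pct_central_subfield=cs,
        true_total_attenuation_pct_central_macula=cm,
        true_total_attenuation_pct_panmacular=pan,
        true_cst_um=true_cst,
        va_letters_noiseless=clean,
        va_letters=letters,
    )
    return surfaces, cube, truth


def generate_eye(config: SimConfig, rng: np.random.Generator,
                 patient_id: str = "P000", laterality: str = "OD",
                 year: int = 0) -> tuple[SurfaceSet, IntensityCube, SimTruth]:
    """Generate one synthetic eye at one visit from an explicit RNG state."""
    params = _sample_eye_params(config, rng, patient_id, laterality)
    return _render_eye_visit(params, config, year, rng)


def _visit_record(params: _EyeParams, truth: SimTruth) -> VisitRecord:
    ga_status = "none"
    if truth.has_ga:
        ga_status = "foveal" if truth.ga_foveal else "extrafoveal"
    return VisitRecord(
        patient_id=params.patient_id,
        eye_id=params.eye_id,
        laterality=params.laterality,
        year=truth.year,
        va_letters=truth.va_letters,
        ga_status=ga_status,
        phakic_status=params.phakic_status,
    )


def iter_cohort(config: SimConfig
                ) -> Iterator[tuple[VisitRecord, SurfaceSet, IntensityCube, SimTruth]]:
    """Stream every (eye, visit) of the cohort with per-eye RNG substreams.

    The global seed spawns one child stream per eye, so a cohort is
    reproducible independently of generation order or parallelism.
    """
    master = np.random.default_rng(config.seed)
    eye_index = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        lateralities = ["OD"]
        if master.random() < config.p_both_eyes:
            lateralities.append("OS")
        for lat in lateralities:
            eye_rng = np.random.default_rng([config.seed, eye_index])
            params = _sample_eye_params(config, eye_rng, patient_id, lat)
            for year in config.years:
                surfaces, cube, truth = _render_eye_visit(params, config, year, eye_rng)
                yield _visit_record(params, truth), surfaces, cube, truth
            eye_index += 1


def truth_frame(truths: list[SimTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        d = t.__dict__.copy()
        c = d.pop("ga_center_mm")
        d["ga_center_x_mm"] = c[0] if c else np.nan
        d["ga_center_y_mm"] = c[1] if c else np.nan
        rows.append(d)
    return pd.DataFrame(rows)


def generate_cohort(config: SimConfig, out_dir: str | Path | None = None,
                    write_cubes: bool = True
                    ) -> tuple[list[VisitRecord], pd.DataFrame]:
    """Generate the cohort, optionally writing every artifact to ``out_dir``.

    Writes ``cohort.csv``, ``truth.tsv`` and per-(eye, visit) surface TSVs
    under ``surfaces/`` (plus raw intensity cubes under ``cubes/`` when
    ``write_cubes``). Returns the visit records and the ground-truth table.
    """
    records: list[VisitRecord] = []
    truths: list[SimTruth] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "surfaces").mkdir(parents=True, exist_ok=True)
        if write_cubes:
            (out_dir / "cubes").mkdir(parents=True, exist_ok=True)
    for record, surfaces, cube, truth in iter_cohort(config):
        records.append(record)
        truths.append(truth)
        if out_dir is not None:
            stem = f"{record.eye_id}_y{record.year}"
            write_surface_set(surfaces, out_dir / "surfaces" / f"{stem}.tsv")
            if write_cubes:
                write_intensity_cube(cube, out_dir / "cubes" / f"{stem}.u8")
    tf = truth_frame(truths)
    if out_dir is not None:
        write_cohort_table(records, out_dir / "cohort.csv")
        tf.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return records, tf


def simulate_metrics_frame(config: SimConfig, with_intensity: bool = True
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort and measure it in one pass, nothing written.

    Returns the tidy analysis frame (cohort columns + measured metric
    columns, one row per eye-visit) and the ground-truth frame. Cubes are
    discarded as soon as each eye is measured, so memory stays flat.
    """
    rows = []
    truths: list[SimTruth] = []
    for record, surfaces, cube, truth in iter_cohort(config):
        metrics = compute_eye_metrics(surfaces, cube if with_intensity else None)
        row = {
            "patient_id": record.patient_id,
            "eye_id": record.eye_id,
            "laterality": record.laterality,
            "year": record.year,
            "va_letters": record.va_letters,
            "ga_status": record.ga_status,
            "phakic_status": record.phakic_status,
        }
        row.update(metrics.to_row())
        rows.append(row)
        truths.append(truth)
    return pd.DataFrame(rows), truth_frame(truths)
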