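"""Seeded synthetic cohorts: eye images with RPE ROIs, plus assay tables.

The generator emulates the geometry the quantification assumes: a
transverse larval eye section rendered as a filled disc, with the RPE as
a half-annular band running dorsal (image top, 0 angular degrees) to
ventral (image bottom, 180 degrees) around the distal side.  After
photoablation the central band is depigmented (light pixels) and the
recovery fronts — the dorsal and ventral edges of the remaining light
zone — sit at configurable angular positions; knockout cohorts widen or
narrow the light zone relative to controls.  The expected band intensity
at angular position theta is a product of two logistic fronts,

    E(theta) = dark + (light - dark) * sigma((theta - d)/s) * sigma((v - theta)/s)

with ``d``/``v`` the dorsal/ventral front positions and ``s`` a
transition scale in degrees, so effect size (front shift) and front
shape are independently controllable.  A per-image additive illumination
offset and per-pixel Gaussian noise are applied last, then values are
rounded and clipped to the 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .io import write_image, write_manifest, write_roi_imagej, write_roi_json

__all__ = [
    "EyeGeometry",
    "PigmentProfile",
    "CohortSpec",
    "EyeRecord",
    "generate_eye",
    "generate_cohort",
    "generate_assay_tables",
    "write_cohort",
]

BACKGROUND_GRAY = 210  # slide background outside the eye
DISC_GRAY = 190  # retinal tissue inside the eye, outside the RPE band
ROI_VERTEX_STEP_DEG = 2.0


@dataclass(frozen=True)
class EyeGeometry:
    """Placement and size of the synthetic eye and its RPE band (pixels/degrees)."""

    center_row: float = 100.0
    center_col: float = 100.0
    eye_radius: float = 80.0
    band_thickness: float = 18.0
    arc_start_deg: float = 0.0
    arc_end_deg: float = 180.0
    image_height: int = 200
    image_width: int = 200

    def __post_init__(self) -> None:
        if not (self.eye_radius > self.band_thickness > 0):
            raise ValueError("require eye_radius > band_thickness > 0")
        if not (0 <= self.arc_start_deg < self.arc_end_deg <= 180):
            raise ValueError("RPE arc must satisfy 0 <= start < end <= 180 degrees")
        r = self.eye_radius
        if (
            self.center_row - r < 0
            or self.center_col - r < 0
            or self.center_row + r > self.image_height - 1
            or self.center_col + r > self.image_width - 1
        ):
            raise ValueError("eye does not fit inside the image frame")


@dataclass(frozen=True)
class PigmentProfile:
    """Angular pigmentation model of the RPE band after injury.

    ``dark_level`` is pigmented (recovered) RPE, ``light_level`` the
    unpigmented central injury zone; fronts are in angular degrees.
    """

    dark_level: float = 50.0
    light_level: float = 200.0
    dorsal_front_deg: float = 70.0
    ventral_front_deg: float = 110.0
    front_sharpness_deg: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.dark_level < self.light_level <= 255):
            raise ValueError("require 0 <= dark_level < light_level <= 255")
        if self.dorsal_front_deg > self.ventral_front_deg:
            raise ValueError("dorsal front must not exceed ventral front")
        if self.front_sharpness_deg <= 0:
            raise ValueError("front_sharpness_deg must be positive")

    def expected_intensity(self, theta_deg: np.ndarray | float) -> np.ndarray:
        """E(theta): two-logistic-front expected band intensity."""
        t = np.asarray(theta_deg, dtype=np.float64)
        s = self.front_sharpness_deg
        rise = _logistic((t - self.dorsal_front_deg) / s)
        fall = _logistic((self.ventral_front_deg - t) / s)
        return self.dark_level + (self.light_level - self.dark_level) * rise * fall


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one control-vs-knockout experiment.

    Defaults mirror the screen design the pipeline targets: 16 control
    larvae compared against >= 8 knockouts, a 40-degree central injury
    zone, and ``knockout_front_shift_deg`` widening (positive, impaired
    recovery) or narrowing (negative, enhanced recovery) the knockout
    light zone per side.  ``knockout_front_shift_deg = 0`` is a null
    cohort: both groups are draws from one distribution.

    Per-larva nuisance variation has three sources: ``noise_sd``
    (per-pixel Gaussian), ``illumination_offset_sd`` (per-image additive
    offset, removed by the normalization stage), and ``level_jitter_sd``
    (pointwise sd of a smooth per-larva angular pigment-texture field
    added to the band; it survives normalization, as biological
    between-larva variability does in real cohorts, and its ~10-degree
    correlation length keeps distant angular bins nearly independent).
    """

    n_control: int = 16
    n_knockout: int = 8
    base_profile: PigmentProfile = field(default_factory=PigmentProfile)
    knockout_front_shift_deg: float = 0.0
    noise_sd: float = 8.0
    illumination_offset_sd: float = 6.0
    level_jitter_sd: float = 6.0
    geometry: EyeGeometry = field(default_factory=EyeGeometry)
    geometry_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_knockout < 1:
            raise ValueError("cohort needs >= 1 larva per group")
        if self.noise_sd < 0 or self.illumination_offset_sd < 0 or self.level_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.geometry_jitter < 0:
            raise ValueError("geometry_jitter must be non-negative")


@dataclass(frozen=True)
class EyeRecord:
    """One larva: raster, ROI polygon, and manifest metadata."""

    image: np.ndarray  # uint8
    roi: np.ndarray  # (n, 2) float (row, col) vertices
    group: str
    larva_id: str
    ablated: bool = True


def _logistic(x: np.ndarray | float) -> np.ndarray:
    from scipy.special import expit

    return expit(np.asarray(x, dtype=np.float64))


def _polar_coords(geometry: EyeGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho, theta_deg, dcol) for every pixel center; theta is the unsigned
    angle from the dorsal (row-decreasing) axis about the eye center."""
    rows = np.arange(geometry.image_height, dtype=np.float64)
    cols = np.arange(geometry.image_width, dtype=np.float64)
    dc, dr = np.meshgrid(cols - geometry.center_col, rows - geometry.center_row)
    rho = np.hypot(dr, dc)
    theta = np.degrees(np.arctan2(np.abs(dc), -dr))
    return rho, theta, dc


def band_polygon(geometry: EyeGeometry) -> np.ndarray:
    """ROI polygon tracing the RPE band: outer edge dorsal→ventral along the
    distal (column-increasing) side, then the inner edge back; vertices
    every 2 degrees."""
    g = geometry
    n = max(int(np.ceil((g.arc_end_deg - g.arc_start_deg) / ROI_VERTEX_STEP_DEG)), 1)
    phis = np.radians(np.linspace(g.arc_start_deg, g.arc_end_deg, n + 1))
    # position angle phi from dorsal toward the distal side: (row, col) offset
    dir_row, dir_col = -np.cos(phis), np.sin(phis)
    outer = np.column_stack(
        [g.center_row + g.eye_radius * dir_row, g.center_col + g.eye_radius * dir_col]
    )
    r_in = g.eye_radius - g.band_thickness
    inner = np.column_stack(
        [g.center_row + r_in * dir_row, g.center_col + r_in * dir_col]
    )
    return np.vstack([outer, inner[::-1]])


def generate_eye(
    geometry: EyeGeometry,
    profile: PigmentProfile,
    noise_sd: float = 0.0,
    illumination_offset: float = 0.0,
    seed: int = 0,
    level_offset_field: np.ndarray | None = None,
) -> EyeRecord:
    """Render one synthetic eye image plus its RPE-band ROI polygon.

    Rendering order: background, eye disc, RPE band at E(theta) (plus the
    optional angular level-offset field, sampled at integer degrees 0..180
    and interpolated), then the illumination offset and per-pixel Gaussian
    noise, rounded and clipped to [0, 255].
    """
    g = geometry
    rho, theta, dc = _polar_coords(g)
    img = np.full((g.image_height, g.image_width), float(BACKGROUND_GRAY))
    img[rho <= g.eye_radius] = DISC_GRAY
    # Small half-pixel margins keep every rasterized ROI pixel on band shading.
    band = (
        (rho >= g.eye_radius - g.band_thickness - 0.5)
        & (rho <= g.eye_radius + 0.5)
        & (theta >= g.arc_start_deg - 0.5)
        & (theta <= g.arc_end_deg + 0.5)
        & (dc >= -0.5)
    )
    img[band] = profile.expected_intensity(theta[band])
    if level_offset_field is not None:
        if level_offset_field.shape != (181,):
            raise ValueError("level_offset_field must sample degrees 0..180")
        img[band] += np.interp(theta[band], np.arange(181.0), level_offset_field)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = img + illumination_offset
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return EyeRecord(image=img, roi=band_polygon(g), group="", larva_id="", ablated=True)


def _larva_seed(cohort_seed: int, index: int) -> int:
    """Stable per-larva seed: independent of every other larva's presence."""
    return int(np.random.SeedSequence(cohort_seed, spawn_key=(index,)).generate_state(1)[0])


def _jittered_geometry(g: EyeGeometry, jitter: float, rng: np.random.Generator) -> EyeGeometry:
    if jitter == 0:
        return g
    radius = g.eye_radius * (1.0 + jitter * rng.standard_normal())
    radius = float(np.clip(radius, g.band_thickness + 1.0, None))
    dr, dc = jitter * g.eye_radius * rng.standard_normal(2)
    row = float(np.clip(g.center_row + dr, radius, g.image_height - 1 - radius))
    col = float(np.clip(g.center_col + dc, radius, g.image_width - 1 - radius))
    return replace(g, eye_radius=radius, center_row=row, center_col=col)


def _iter_cohort(spec: CohortSpec) -> Iterator[EyeRecord]:
    ko_profile = replace(
        spec.base_profile,
        dorsal_front_deg=spec.base_profile.dorsal_front_deg - spec.knockout_front_shift_deg,
        ventral_front_deg=spec.base_profile.ventral_front_deg + spec.knockout_front_shift_deg,
    )
    for i in range(spec.n_control + spec.n_knockout):
        is_ko = i >= spec.n_control
        group = "knockout" if is_ko else "control"
        larva_seed = _larva_seed(spec.seed, i)
        rng = np.random.default_rng(larva_seed)
        geom = _jittered_geometry(spec.geometry, spec.geometry_jitter, rng)
        offset = (
            spec.illumination_offset_sd * rng.standard_normal()
            if spec.illumination_offset_sd > 0
            else 0.0
        )
        profile = ko_profile if is_ko else spec.base_profile
        field = (
            _texture_field(spec.level_jitter_sd, rng)
            if spec.level_jitter_sd > 0
            else None
        )
        noise_seed = int(rng.integers(0, 2**31))
        rec = generate_eye(
            geom,
            profile,
            noise_sd=spec.noise_sd,
            illumination_offset=offset,
            seed=noise_seed,
            level_offset_field=field,
        )
        yield replace(rec, group=group, larva_id=f"{group}_{i:03d}")


_TEXTURE_HARMONICS = 18  # angular correlation length ~ 180/18 = 10 degrees


def _texture_field(sd: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-larva pigment-texture field over 0..180 degrees.

    A random harmonic series with pointwise variance sd^2; its ~10-degree
    correlation length makes distant angular bins nearly independent
    between larvae while keeping texture smooth within a larva.
    """
    theta = np.arange(181.0)
    coeffs = rng.standard_normal((2, _TEXTURE_HARMONICS)) * (
        sd / np.sqrt(_TEXTURE_HARMONICS)
    )
    k = np.arange(1, _TEXTURE_HARMONICS + 1)
    phase = np.pi * np.outer(theta, k) / 180.0
    return np.cos(phase) @ coeffs[0] + np.sin(phase) @ coeffs[1]


def generate_cohort(spec: CohortSpec) -> list[EyeRecord]:
    """Generate ``n_control + n_knockout`` eye records; knockouts carry the
    front shift.  Bit-identical for identical (spec, seed)."""
    return list(_iter_cohort(spec))


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a cohort to disk (TIFF + .roi + .json ROI + manifest.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in generate_cohort(spec):
        img_name = f"{rec.larva_id}.tif"
        roi_name = f"{rec.larva_id}.json"
        write_image(out / img_name, rec.image)
        write_roi_json(out / roi_name, rec.roi)
        write_roi_imagej(out / f"{rec.larva_id}.roi", rec.roi)
        rows.append(
            {
                "image": img_name,
                "roi": roi_name,
                "group": rec.group,
                "larva_id": rec.larva_id,
                "ablated": rec.ablated,
            }
        )
    manifest = pd.DataFrame(rows)
    write_manifest(out / "manifest.csv", manifest)
    return manifest


# ---------------------------------------------------------------------------
# Assay-table generators (fixtures for the scalar screen arithmetic)


def generate_assay_tables(
    seed: int,
    n_embryos: int = 10,
    mutagenesis_rate: float = 0.8,
    gene: str = "goi",
    true_fold_change: float = 1.0,
    control_target_ct: float = 20.0,
    housekeeping_ct: float = 15.0,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    n_larvae: int = 6,
    count_lambda_brdu: float = 5.0,
    count_lambda_tunel: float = 2.0,
    n_sections: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Seeded (band-call, Ct, count) tables with known ground truth.

    Band calls are per-embryo Bernoulli(``mutagenesis_rate``) headloop
    positives among standard-PCR positives; Ct values are Normal around
    means chosen so the Livak estimate of knockout/control expression is
    ``true_fold_change`` when ``ct_noise_sd = 0``; section counts are
    Poisson.
    """
    rng = np.random.default_rng(seed)
    band = pd.DataFrame(
        {
            "embryo_id": [f"e{i + 1:02d}" for i in range(n_embryos)],
            "gene": gene,
            "headloop_positive": rng.random(n_embryos) < mutagenesis_rate,
            "standard_positive": True,
        }
    )
    # 2^-ddCt = fold  =>  knockout target Ct = control target Ct - log2(fold)
    ko_target = control_target_ct - float(np.log2(true_fold_change))
    ct_rows = []
    for grp, target in (("control", control_target_ct), ("knockout", ko_target)):
        for rep in range(1, n_replicates + 1):
            ct_rows.append(
                {
                    "sample_group": grp,
                    "replicate_id": rep,
                    "target_ct": target + ct_noise_sd * rng.standard_normal(),
                    "housekeeping_ct": housekeeping_ct
                    + ct_noise_sd * rng.standard_normal(),
                }
            )
    ct = pd.DataFrame(ct_rows)
    count_rows = []
    for i in range(n_larvae):
        for sec in range(1, n_sections + 1):
            count_rows.append(
                {
                    "larva_id": f"larva_{i + 1:02d}",
                    "section_index": sec,
                    "count": int(rng.poisson(count_lambda_brdu)),
                    "assay": "BrdU",
                }
            )
            count_rows.append(
                {
                    "larva_id": f"larva_{i + 1:02d}",
                    "section_index": sec,
                    "count": int(rng.poisson(count_lambda_tunel)),
                    "assay": "TUNEL",
                }
            )
    counts = pd.DataFrame(count_rows)
    return band, ct, counts
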