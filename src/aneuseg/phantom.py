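"""Synthetic head-CTA-like phantoms with ground-truth aneurysm and vessel masks.

The generator emulates the gross intensity structure a head CTA pipeline
relies on: bright tubular vessels on darker parenchyma, saccular aneurysm
protrusions attached to a vessel wall, a high-intensity skull shell,
optional hemorrhage regions of intermediate intensity, anisotropic voxel
spacing and additive Gaussian noise. Intensities are arbitrary "HU-like"
units; only their ordering (parenchyma < hemorrhage < vessel ≈ aneurysm <
skull) matters downstream.

Vessels are cubic-interpolated polylines rasterized by distance-to-centerline
thresholding. Aneurysms are ellipsoids attached tangent to the vessel wall so
they overlap the lumen by well under 20% of their volume; ground truth
excludes the lumen, and the ellipsoid is re-scaled after rasterization so the
voxelized volume tracks the requested mm³.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .volume import Volume3D, write_nifti

__all__ = [
    "VesselSegment",
    "AneurysmSpec",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "make_cohort",
    "example_spec",
    "save_case",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VesselSegment:
    """A tubular vessel: centerline control points (mm), radius (mm), intensity."""

    points_mm: list[tuple[float, float, float]]
    radius_mm: float
    intensity: float = 250.0


@dataclass
class AneurysmSpec:
    """A saccular aneurysm request.

    ``attach_mm`` is a world point near the parent vessel; the generator
    snaps it to the closest vessel wall and grows the sac outward along the
    local surface normal. ``eccentricity`` is the polar/equatorial semi-axis
    ratio (1 = sphere; < 1 = oblate along the neck direction).
    """

    attach_mm: tuple[float, float, float]
    volume_mm3: float
    eccentricity: float = 1.0
    intensity: float = 250.0


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (0.75, 0.75, 1.0)
    vessel_segments: list[VesselSegment] = field(default_factory=list)
    aneurysms: list[AneurysmSpec] = field(default_factory=list)
    skull: tuple[float, float] | None = (2.0, 1000.0)  # (thickness mm, intensity)
    hemorrhage_regions: list[tuple[tuple[float, float, float], float, float]] = field(
        default_factory=list
    )  # (center mm, radius mm, intensity)
    parenchyma_intensity: float = 40.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        sp = np.asarray(self.spacing_mm, dtype=float)
        if sp.shape != (3,) or np.any(sp < 0.3) or np.any(sp > 2.0):
            raise ValueError(f"spacing components must lie in [0.3, 2.0] mm, got {self.spacing_mm}")
        for seg in self.vessel_segments:
            if seg.radius_mm <= 0:
                raise ValueError("vessel radius must be > 0")
            if len(seg.points_mm) < 2:
                raise ValueError("a vessel segment needs at least 2 control points")
            if seg.intensity <= self.parenchyma_intensity:
                raise ValueError("vessel intensity must exceed parenchyma intensity")
        voxel_vol = float(np.prod(sp))
        for an in self.aneurysms:
            if an.volume_mm3 <= 0:
                raise ValueError("aneurysm target volume must be > 0")
            if an.volume_mm3 < voxel_vol:
                raise ValueError(
                    f"aneurysm target volume {an.volume_mm3} mm³ is smaller than one "
                    f"voxel ({voxel_vol:.3f} mm³) and cannot be rasterized"
                )
            if an.eccentricity <= 0:
                raise ValueError("aneurysm eccentricity must be > 0")
            if an.intensity <= self.parenchyma_intensity:
                raise ValueError("aneurysm intensity must exceed parenchyma intensity")
        if self.skull is not None:
            thickness, skull_int = self.skull
            if thickness <= 0:
                raise ValueError("skull thickness must be > 0")
            vessel_ints = [s.intensity for s in self.vessel_segments] or [self.parenchyma_intensity]
            if skull_int <= max(vessel_ints):
                raise ValueError("skull intensity must exceed vessel intensity")
        for _, radius, hem_int in self.hemorrhage_regions:
            if radius <= 0:
                raise ValueError("hemorrhage radius must be > 0")
            vessel_ints = [s.intensity for s in self.vessel_segments]
            hi = min(vessel_ints) if vessel_ints else np.inf
            if not (self.parenchyma_intensity < hem_int < hi):
                raise ValueError(
                    "hemorrhage intensity must lie strictly between parenchyma and vessel intensity"
                )


@dataclass
class PhantomCase:
    """A generated phantom: image plus voxel-wise reference standard."""

    image: Volume3D
    aneurysm_mask: Volume3D
    vessel_mask: Volume3D
    aneurysm_truth: list[tuple[int, float]]  # (component id, true volume mm³)
    case_id: str = "case"

    def __post_init__(self) -> None:
        self.image.require_same_grid(self.aneurysm_mask, "image/aneurysm_mask")
        self.image.require_same_grid(self.vessel_mask, "image/vessel_mask")


def _world_coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _densify_centerline(points_mm: np.ndarray, step_mm: float = 0.2) -> np.ndarray:
    """Cubic-interpolate a polyline and resample it at ~step_mm arc spacing."""
    pts = np.asarray(points_mm, dtype=float)
    if len(pts) == 2:
        n = max(int(np.linalg.norm(pts[1] - pts[0]) / step_mm), 2)
        t = np.linspace(0, 1, n)
        return pts[0] + t[:, None] * (pts[1] - pts[0])
    chord = np.r_[0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    spline = CubicSpline(chord, pts, axis=0)
    dense_t = np.linspace(0, chord[-1], max(int(chord[-1] / step_mm), 2))
    return spline(dense_t)


def _rasterize_tubes(shape, spacing, segments: list[VesselSegment]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if not segments:
        return mask
    spacing = np.asarray(spacing)
    for seg in segments:
        dense = _densify_centerline(np.asarray(seg.points_mm))
        lo = dense.min(axis=0) - seg.radius_mm - spacing
        hi = dense.max(axis=0) + seg.radius_mm + spacing
        i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        sub_axes = [np.arange(i0[d], i1[d]) * spacing[d] for d in range(3)]
        grid = np.stack(np.meshgrid(*sub_axes, indexing="ij"), axis=-1)
        tree = cKDTree(dense)
        dist, _ = tree.query(grid.reshape(-1, 3), workers=-1)
        sub = dist.reshape(grid.shape[:3]) <= seg.radius_mm
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= sub
    return mask


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is the unit ``direction``."""
    ez = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(ez[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    ex = np.cross(helper, ez)
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    return np.stack([ex, ey, ez], axis=1)


def _rasterize_ellipsoid(shape, spacing, center, semi_axes, rot) -> np.ndarray:
    spacing = np.asarray(spacing)
    rad = max(semi_axes)
    i0 = np.maximum(np.floor((center - rad - spacing) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((center + rad + spacing) / spacing).astype(int) + 1, shape)
    mask = np.zeros(shape, dtype=bool)
    if np.any(i0 >= i1):
        return mask
    sub_axes = [np.arange(i0[d], i1[d]) * spacing[d] for d in range(3)]
    grid = np.stack(np.meshgrid(*sub_axes, indexing="ij"), axis=-1) - center
    local = grid @ rot  # world -> ellipsoid frame
    rho = np.sum((local / np.asarray(semi_axes)) ** 2, axis=-1)
    mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = rho <= 1.0
    return mask


def _head_ellipsoid(shape, spacing):
    extent = np.asarray(shape) * np.asarray(spacing)
    center = extent / 2.0
    semi = 0.47 * extent
    return center, semi


def _aneurysm_mask_for(
    spec: PhantomSpec,
    an: AneurysmSpec,
    vessel_mask: np.ndarray,
    centerlines: list[tuple[np.ndarray, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    shape, spacing = spec.grid_shape, np.asarray(spec.spacing_mm)
    attach = np.asarray(an.attach_mm, dtype=float)

    if centerlines:
        all_pts = np.concatenate([c for c, _ in centerlines])
        radii = np.concatenate([np.full(len(c), r) for c, r in centerlines])
        d = np.linalg.norm(all_pts - attach, axis=1)
        k = int(np.argmin(d))
        p0, r_vessel = all_pts[k], radii[k]
        n = attach - p0
        if np.linalg.norm(n) < 1e-6:
            # attachment point on the centerline: pick a perpendicular direction
            tangent = all_pts[min(k + 1, len(all_pts) - 1)] - all_pts[max(k - 1, 0)]
            n = np.cross(tangent, rng.standard_normal(3))
        n = n / np.linalg.norm(n)
    else:
        p0, r_vessel, n = attach, 0.0, np.array([0.0, 0.0, 1.0])

    ecc = an.eccentricity
    rot = _rotation_to(n)
    target_voxels = an.volume_mm3 / float(np.prod(spacing))

    # semi-axes (a, a, c) with c = ecc * a aligned to the neck direction
    volume = an.volume_mm3
    mask = np.zeros(shape, dtype=bool)
    for _ in range(6):
        a = (3.0 * volume / (4.0 * np.pi * ecc)) ** (1.0 / 3.0)
        c = ecc * a
        center = p0 + n * (r_vessel + 0.85 * c)
        ellipsoid = _rasterize_ellipsoid(shape, spacing, center, (a, a, c), rot)
        mask = ellipsoid & ~vessel_mask
        # keep the largest 26-connected piece so each request is one component
        labels, n_comp = ndimage.label(mask, structure=_CONN26)
        if n_comp > 1:
            counts = np.bincount(labels.ravel())[1:]
            mask = labels == (int(np.argmax(counts)) + 1)
        achieved = int(mask.sum())
        if achieved == 0:
            volume *= 1.3
            continue
        err = achieved / target_voxels
        if abs(err - 1.0) < 0.02:
            break
        volume /= err
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render a phantom case from its specification.

    Deterministic given ``spec.seed``. Each requested aneurysm yields exactly
    one ground-truth connected component whose voxelized volume lies within
    15% of the requested mm³ (typically within 2–3%).
    """
    spec.validate()
    shape, spacing = tuple(spec.grid_shape), np.asarray(spec.spacing_mm, dtype=float)
    rng = np.random.default_rng(spec.seed)

    head_center, head_semi = _head_ellipsoid(shape, spacing)
    coords = np.stack(_world_coords(shape, spacing), axis=-1)
    rho_outer = np.sum(((coords - head_center) / head_semi) ** 2, axis=-1)
    head = rho_outer <= 1.0
    if spec.skull is not None:
        thickness, skull_int = spec.skull
        inner_semi = head_semi - thickness
        rho_inner = np.sum(((coords - head_center) / inner_semi) ** 2, axis=-1)
        interior = rho_inner <= 1.0
        skull_shell = head & ~interior
    else:
        interior = head
        skull_shell = np.zeros(shape, dtype=bool)

    image = np.zeros(shape, dtype=np.float32)
    image[interior] = spec.parenchyma_intensity

    for center_mm, radius, hem_int in spec.hemorrhage_regions:
        sphere = (
            np.sum((coords - np.asarray(center_mm)) ** 2, axis=-1) <= radius**2
        ) & interior
        image[sphere] = hem_int

    vessel_mask = _rasterize_tubes(shape, spacing, spec.vessel_segments) & interior
    if spec.vessel_segments:
        vessel_int = float(np.mean([s.intensity for s in spec.vessel_segments]))
        image[vessel_mask] = vessel_int
    if spec.aneurysms and not vessel_mask.any() and spec.vessel_segments:
        raise ValueError("vessel segments produced an empty mask; cannot attach aneurysms")

    centerlines = [
        (_densify_centerline(np.asarray(s.points_mm)), s.radius_mm)
        for s in spec.vessel_segments
    ]
    aneurysm_mask = np.zeros(shape, dtype=bool)
    truth: list[tuple[int, float]] = []
    per_masks = []
    for idx, an in enumerate(spec.aneurysms, start=1):
        m = _aneurysm_mask_for(spec, an, vessel_mask, centerlines, rng) & interior
        if m.sum() == 0:
            raise ValueError(
                f"aneurysm {idx} at {an.attach_mm} rasterized to zero voxels "
                "(attachment outside the head interior?)"
            )
        for j, prev in enumerate(per_masks, start=1):
            if (m & prev).any():
                raise ValueError(f"aneurysm definitions {j} and {idx} overlap; reject spec")
        per_masks.append(m)
        image[m] = an.intensity
        aneurysm_mask |= m
        truth.append((idx, float(m.sum()) * float(np.prod(spacing))))

    if spec.skull is not None:
        image[skull_shell] = spec.skull[1]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    sp = tuple(spacing)
    return PhantomCase(
        image=Volume3D(image.astype(np.float32), sp),
        aneurysm_mask=Volume3D(aneurysm_mask.astype(np.uint8), sp),
        vessel_mask=Volume3D(vessel_mask.astype(np.uint8), sp),
        aneurysm_truth=truth,
    )


def example_spec(
    grid_shape=(64, 64, 48),
    spacing_mm=(0.75, 0.75, 1.0),
    noise_sd: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """A base head phantom: skull shell plus three curved vessels, no aneurysms."""
    extent = np.asarray(grid_shape) * np.asarray(spacing_mm)
    cx, cy, cz = extent / 2.0

    def pts(raw):
        return [tuple(p) for p in raw]

    vessels = [
        VesselSegment(
            pts(
                [
                    (cx - 0.30 * extent[0], cy, cz - 0.15 * extent[2]),
                    (cx - 0.10 * extent[0], cy + 0.10 * extent[1], cz),
                    (cx + 0.10 * extent[0], cy - 0.08 * extent[1], cz + 0.05 * extent[2]),
                    (cx + 0.30 * extent[0], cy, cz + 0.15 * extent[2]),
                ]
            ),
            radius_mm=1.6,
        ),
        VesselSegment(
            pts(
                [
                    (cx, cy - 0.30 * extent[1], cz + 0.10 * extent[2]),
                    (cx + 0.08 * extent[0], cy, cz - 0.05 * extent[2]),
                    (cx, cy + 0.30 * extent[1], cz + 0.10 * extent[2]),
                ]
            ),
            radius_mm=1.3,
        ),
        VesselSegment(
            pts(
                [
                    (cx - 0.18 * extent[0], cy - 0.22 * extent[1], cz - 0.1 * extent[2]),
                    (cx - 0.22 * extent[0], cy + 0.05 * extent[1], cz + 0.06 * extent[2]),
                    (cx - 0.12 * extent[0], cy + 0.24 * extent[1], cz + 0.1 * extent[2]),
                ]
            ),
            radius_mm=1.1,
        ),
    ]
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        spacing_mm=tuple(spacing_mm),
        vessel_segments=vessels,
        aneurysms=[],
        noise_sd=noise_sd,
        seed=seed,
    )


def _sample_attachment(
    base: PhantomSpec, rng: np.random.Generator
) -> tuple[tuple[float, float, float], int]:
    seg_idx = int(rng.integers(len(base.vessel_segments)))
    seg = base.vessel_segments[seg_idx]
    dense = _densify_centerline(np.asarray(seg.points_mm))
    # avoid endpoints so the sac sits on the vessel body
    k = int(rng.integers(int(0.15 * len(dense)), int(0.85 * len(dense))))
    tangent = dense[min(k + 1, len(dense) - 1)] - dense[max(k - 1, 0)]
    perp = np.cross(tangent, rng.standard_normal(3))
    perp /= np.linalg.norm(perp)
    attach = dense[k] + perp * (seg.radius_mm + 0.2)
    return tuple(float(v) for v in attach), seg_idx


def make_cohort(
    n: int,
    base_spec: PhantomSpec,
    volume_range: tuple[float, float],
    seed: int,
    multiplicity_prob: float = 0.16,
) -> list[PhantomCase]:
    """Generate ``n`` phantom cases with aneurysm volumes uniform in ``volume_range``.

    A case carries a second aneurysm with probability ``multiplicity_prob``
    (default matches a cohort of ~1.16 aneurysms per patient). Per-case seeds
    are derived deterministically from the master ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vmin, vmax = volume_range
    if vmin > vmax:
        raise ValueError(f"volume_range min {vmin} > max {vmax}")
    if not base_spec.vessel_segments:
        raise ValueError("base_spec must define vessel segments to attach aneurysms")

    master = np.random.SeedSequence(seed)
    cases = []
    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        case_seed = int(rng.integers(0, 2**31 - 1))
        n_an = 2 if rng.random() < multiplicity_prob else 1
        aneurysms = []
        for _ in range(40):  # rejection-sample non-overlapping attachments
            if len(aneurysms) == n_an:
                break
            attach, _ = _sample_attachment(base_spec, rng)
            vol = float(rng.uniform(vmin, vmax))
            ecc = float(rng.uniform(0.75, 1.0))
            radius_est = (3 * vol / (4 * np.pi)) ** (1 / 3)
            too_close = any(
                np.linalg.norm(np.asarray(attach) - np.asarray(a.attach_mm))
                < 2.5 * (radius_est + (3 * a.volume_mm3 / (4 * np.pi)) ** (1 / 3))
                for a in aneurysms
            )
            if too_close:
                continue
            aneurysms.append(AneurysmSpec(attach_mm=attach, volume_mm3=vol, eccentricity=ecc))
        spec = dataclasses.replace(base_spec, aneurysms=aneurysms, seed=case_seed)
        case = generate_phantom(spec)
        case.case_id = f"case{i:03d}"
        cases.append(case)
    return cases


def save_case(case: PhantomCase, outdir: str | Path) -> Path:
    """Write image/masks as NIfTI-1 and the reference volumes as CSV."""
    outdir = Path(outdir) / case.case_id
    outdir.mkdir(parents=True, exist_ok=True)
    write_nifti(case.image, outdir / "image.nii.gz")
    write_nifti(case.aneurysm_mask, outdir / "aneurysm_mask.nii.gz")
    write_nifti(case.vessel_mask, outdir / "vessel_mask.nii.gz")
    pd.DataFrame(case.aneurysm_truth, columns=["component_id", "volume_mm3"]).to_csv(
        outdir / "aneurysm_truth.csv", index=False
    )
    return outdir
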