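"""CTA preprocessing: brain masking, multi-scale vesselness, resampling, normalization.

The chain mirrors a standard aneurysm-segmentation front end:

1. brain mask by intensity-band thresholding + morphology (an atlas-free
   surrogate for registration-based brain extraction);
2. two Hessian-eigenvalue vessel-enhancement maps at complementary scale
   ranges (0.5–5 and 5–15 voxels) that together separate normal-calibre
   vessels from larger saccular structures;
3. resampling of all channels to 0.5 mm isotropic;
4. percentile normalization of the CTA channel, z-scoring of the vesselness
   channels.

Vesselness scales are Gaussian sigmas in voxel units of the native
(pre-resampling) grid, matching how scale ranges are quoted for clinical
CTA; the enhancement is computed before resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "VesselnessParams",
    "ChannelStack",
    "compute_brain_mask",
    "vesselness",
    "vesselness_response",
    "resample_isotropic",
    "normalize_cta",
    "normalize_zscore",
    "build_stack",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: scale ranges (voxels) of the two vessel-enhanced channels
SMALL_SCALE_RANGE = (0.5, 5.0)
LARGE_SCALE_RANGE = (5.0, 15.0)


@dataclass
class VesselnessParams:
    """Multi-scale Hessian vesselness configuration (bright tubes on dark)."""

    scale_range_voxels: tuple[float, float] = SMALL_SCALE_RANGE
    n_scales: int = 5
    alpha: float = 0.5
    beta: float = 0.5
    c: float | str = "auto"  # "auto": half the max Frobenius Hessian norm over all scales
    polarity: str = "bright"

    def __post_init__(self) -> None:
        lo, hi = self.scale_range_voxels
        if not (0 < lo < hi):
            raise ValueError(f"scale range must satisfy 0 < min < max, got {self.scale_range_voxels}")
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")

    def scales(self) -> np.ndarray:
        lo, hi = self.scale_range_voxels
        return np.geomspace(lo, hi, self.n_scales)


@dataclass
class ChannelStack:
    """Co-registered normalized channels forming the network input."""

    channels: list[Volume3D]
    variant_tag: str  # Orig | Vess | LDim
    mask: Volume3D | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        first = self.channels[0]
        for ch in self.channels[1:]:
            first.require_same_grid(ch, "stack channels")
        if self.mask is not None:
            first.require_same_grid(self.mask, "stack/mask")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    def as_array(self) -> np.ndarray:
        """(C, X, Y, Z) float32 view of the channels."""
        return np.stack([c.values.astype(np.float32) for c in self.channels])


def compute_brain_mask(
    vol: Volume3D,
    air_max: float = 20.0,
    bone_min: float = 300.0,
    closing_mm: float = 1.5,
) -> Volume3D:
    """Soft-tissue brain mask by intensity banding and morphology.

    Keeps voxels in the band ``(air_max, bone_min)``, closes and hole-fills,
    and returns the largest connected component. The skull shell (above
    ``bone_min``) is excluded; intracranial vessels (below it) are retained.
    """
    values = vol.values
    band = (values > air_max) & (values < bone_min)
    if not band.any():
        raise ValueError(
            f"no brain tissue found: no voxels in intensity band ({air_max}, {bone_min})"
        )
    radius = tuple(max(int(round(closing_mm / s)), 1) for s in vol.spacing_mm)
    structure = np.ones(tuple(2 * r + 1 for r in radius), dtype=bool)
    closed = ndimage.binary_closing(band, structure=structure)
    # closing may bleed into the skull shell: re-exclude bone
    closed &= values < bone_min
    labels, n = ndimage.label(closed, structure=_CONN26)
    if n == 0:
        raise ValueError(
            f"no brain tissue found after morphology with band ({air_max}, {bone_min})"
        )
    counts = np.bincount(labels.ravel())[1:]
    largest = labels == (int(np.argmax(counts)) + 1)
    filled = ndimage.binary_fill_holes(largest)
    filled &= values < bone_min
    # hole filling can split the bone-excluded set; keep one component
    labels, n = ndimage.label(filled, structure=_CONN26)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        filled = labels == (int(np.argmax(counts)) + 1)
    return vol.with_values(filled.astype(np.uint8))


def _hessian_eigenvalues(smoothed: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized Hessian eigenvalues, sorted by ascending magnitude."""
    grads = np.gradient(smoothed)
    H = np.empty(smoothed.shape + (3, 3), dtype=np.float32)
    for i in range(3):
        second = np.gradient(grads[i])
        for j in range(3):
            H[..., i, j] = second[j]
    H *= sigma**2  # gamma-normalization, gamma = 2
    eig = np.linalg.eigvalsh(H.reshape(-1, 3, 3)).reshape(smoothed.shape + (3,))
    order = np.argsort(np.abs(eig), axis=-1)
    return np.take_along_axis(eig, order, axis=-1)


def _geometry_and_structureness(
    vol_values: np.ndarray, sigma: float, params: VesselnessParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel geometric line factor and squared Frobenius norm at one scale."""
    smoothed = ndimage.gaussian_filter(vol_values.astype(np.float32), sigma, mode="nearest")
    lam = _hessian_eigenvalues(smoothed, sigma)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    eps = np.finfo(np.float32).tiny
    ra = np.abs(l2) / (np.abs(l3) + eps)  # plate vs line
    rb = np.abs(l1) / (np.sqrt(np.abs(l2 * l3)) + eps)  # blob vs line
    s2 = l1**2 + l2**2 + l3**2  # structureness (Frobenius norm squared)
    geo = (1.0 - np.exp(-(ra**2) / (2 * params.alpha**2))) * np.exp(
        -(rb**2) / (2 * params.beta**2)
    )
    # bright-on-dark polarity: the two principal curvatures must be negative
    geo[(l2 >= 0) | (l3 >= 0)] = 0.0
    return geo.astype(np.float32), s2.astype(np.float32)


def vesselness_response(
    vol: Volume3D, params: VesselnessParams
) -> tuple[Volume3D, Volume3D]:
    """Multi-scale vesselness plus the per-voxel scale attaining the maximum.

    Returns ``(response, argmax_scale)`` where ``argmax_scale`` holds the
    sigma (in voxels) at which each voxel's response peaked (0 where the
    response is 0 everywhere).
    """
    scales = params.scales()
    min_extent = min(vol.shape)
    if scales[-1] * 3 > min_extent / 2:
        raise ValueError(
            f"max scale {scales[-1]:.1f} voxels has filter support larger than the "
            f"image (min extent {min_extent} voxels)"
        )
    per_scale = [
        _geometry_and_structureness(vol.values, float(sigma), params) for sigma in scales
    ]
    if params.c == "auto":
        # shared across scales so the multi-scale maximum reflects which scale
        # is in focus, not each scale's own normalization
        max_s2 = max(float(s2.max()) for _, s2 in per_scale)
        c = 0.5 * float(np.sqrt(max_s2)) if max_s2 > 0 else 1.0
    else:
        c = float(params.c)
    best = np.zeros(vol.shape, dtype=np.float32)
    best_scale = np.zeros(vol.shape, dtype=np.float32)
    for sigma, (geo, s2) in zip(scales, per_scale):
        resp = geo * (1.0 - np.exp(-s2 / (2 * c**2)))
        better = resp > best
        best_scale[better] = sigma
        np.maximum(best, resp, out=best)
    np.clip(best, 0.0, 1.0, out=best)
    return vol.with_values(best), vol.with_values(best_scale)


def vesselness(vol: Volume3D, params: VesselnessParams) -> Volume3D:
    """Per-voxel maximum over log-spaced scales of the tubular-structure response."""
    response, _ = vesselness_response(vol, params)
    return response


def resample_isotropic(
    vol: Volume3D, target_mm: float = 0.5, mode: str = "continuous"
) -> Volume3D:
    """Resample to isotropic ``target_mm`` spacing.

    ``continuous`` uses trilinear interpolation; ``label`` nearest-neighbour
    (masks stay binary). World extent is preserved within one voxel.
    """
    if target_mm <= 0:
        raise ValueError(f"target spacing must be > 0, got {target_mm}")
    if mode not in ("continuous", "label"):
        raise ValueError(f"mode must be 'continuous' or 'label', got {mode!r}")
    values = vol.values
    was_int = values.dtype.kind in "biu"
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.astype(np.float32)))
    # numpy (i,j,k) -> sitk (z,y,x): reverse spacing/origin
    img.SetSpacing(tuple(reversed(vol.spacing_mm)))
    img.SetOrigin(tuple(reversed(vol.origin_mm)))
    new_size = [
        max(int(round(n * s / target_mm)), 1) for n, s in zip(vol.shape, vol.spacing_mm)
    ]
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing((target_mm,) * 3)
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    resampler.SetSize(list(reversed(new_size)))
    resampler.SetInterpolator(
        sitk.sitkLinear if mode == "continuous" else sitk.sitkNearestNeighbor
    )
    resampler.SetDefaultPixelValue(0.0)
    out = sitk.GetArrayFromImage(resampler.Execute(img))
    if mode == "label" or was_int:
        out = np.rint(out).astype(values.dtype if was_int else np.uint8)
    return Volume3D(np.ascontiguousarray(out), (target_mm,) * 3, vol.origin_mm)


def normalize_cta(vol: Volume3D, mask: Volume3D | None = None) -> Volume3D:
    """Map the masked 5th..95th intensity percentiles linearly to [0, 1], clipped."""
    values = vol.values.astype(np.float32)
    sel = mask.values.astype(bool) if mask is not None else np.ones(vol.shape, dtype=bool)
    inside = values[sel]
    if inside.size == 0:
        raise ValueError("normalization mask is empty")
    p5, p95 = np.percentile(inside, [5.0, 95.0])
    if p95 <= p5:
        log.warning("constant masked region: percentile window degenerate, output all zeros")
        return vol.with_values(np.zeros(vol.shape, dtype=np.float32))
    out = np.clip((values - p5) / (p95 - p5), 0.0, 1.0).astype(np.float32)
    out[~sel] = 0.0
    return vol.with_values(out)


def normalize_zscore(vol: Volume3D, mask: Volume3D | None = None) -> Volume3D:
    """Standardize to zero mean / unit SD over the masked voxels."""
    values = vol.values.astype(np.float32)
    sel = mask.values.astype(bool) if mask is not None else np.ones(vol.shape, dtype=bool)
    inside = values[sel]
    mu, sd = float(inside.mean()), float(inside.std())
    if sd == 0:
        log.warning("zero-variance region in z-score normalization, output all zeros")
        return vol.with_values(np.zeros(vol.shape, dtype=np.float32))
    out = ((values - mu) / sd).astype(np.float32)
    out[~sel] = 0.0
    return vol.with_values(out)


def build_stack(
    vol: Volume3D,
    variant: str,
    target_mm: float = 0.5,
    small_scales: tuple[float, float] = SMALL_SCALE_RANGE,
    large_scales: tuple[float, float] = LARGE_SCALE_RANGE,
) -> ChannelStack:
    """Full preprocessing chain for one input-configuration variant.

    ``Orig`` and ``LDim`` yield a single normalized CTA channel; ``Vess``
    adds the two z-scored vessel-enhanced channels. All channels end on a
    common ``target_mm`` isotropic grid; pipeline order is fixed:
    mask → enhance → resample → normalize.
    """
    variant = variant.capitalize() if variant.lower() in ("orig", "vess", "ldim") else variant
    if variant == "Ldim":
        variant = "LDim"
    if variant not in ("Orig", "Vess", "LDim"):
        raise ValueError(f"variant must be one of Orig, Vess, LDim; got {variant!r}")

    mask = compute_brain_mask(vol)
    masked = vol.with_values(vol.values * mask.values)

    raw_channels: list[Volume3D] = [masked]
    if variant == "Vess":
        # cap the large range so the filter support fits small desk-scale grids
        max_allowed = min(vol.shape) / 6.0 - 1e-6
        lo, hi = large_scales
        large = (lo, min(hi, max_allowed)) if hi > max_allowed else large_scales
        for rng in (small_scales, large):
            params = VesselnessParams(scale_range_voxels=rng)
            raw_channels.append(vesselness(masked, params))

    mask_iso = resample_isotropic(mask, target_mm, mode="label")
    channels_iso = [resample_isotropic(ch, target_mm, mode="continuous") for ch in raw_channels]

    out_channels = [normalize_cta(channels_iso[0], mask_iso)]
    for ch in channels_iso[1:]:
        out_channels.append(normalize_zscore(ch, mask_iso))
    return ChannelStack(
        channels=out_channels,
        variant_tag=variant,
        mask=mask_iso,
        meta={
            "target_mm": target_mm,
            "small_scale_range_voxels": tuple(small_scales),
            "large_scale_range_voxels": tuple(large_scales),
            "vesselness_computed_before_resampling": True,
        },
    )
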