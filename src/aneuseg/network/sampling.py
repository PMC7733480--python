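"""Patch extraction for training and inference.

A training example is a pair of 3D segments centered at the same world
location: the high-resolution segment read directly from the image, and a
context segment sampled at stride ``r`` (the downsample factor, 3) from a
``r³``-box-smoothed copy of the image. For an output window of ``w`` voxels
starting at voxel ``o``, the high-resolution input covers ``[o-8, o+w+8)``
and the context input covers ``ceil(w/r)+16`` smoothed voxels starting at
``o - 8r + (r-1)//2`` with stride ``r``; after the context pathway's eight
convolutions, ×r upsampling and cropping, context feature ``j`` sits under
output voxel ``o+j`` to within half the stride. Because the context grid
shifts with ``o`` only modulo ``r``, predictions are identical for any
tiling whose offsets are congruent mod ``r``.

Half of the training segments are centered on foreground voxels and half on
background voxels inside the brain mask; out-of-bounds regions are
zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..preprocess import ChannelStack
from ..volume import Volume3D
from .model import NetworkConfig

__all__ = ["PatchPair", "PreparedCase", "prepare_case", "extract_pair", "sample_patches", "augment_flips"]


@dataclass
class PatchPair:
    """Aligned (image, context, label) segments for one training example."""

    image_segment: np.ndarray  # (C, s, s, s)
    context_segment: np.ndarray  # (C, cs, cs, cs)
    label_segment: np.ndarray  # (w, w, w) binary

    def __post_init__(self) -> None:
        assert self.image_segment.ndim == 4 and self.context_segment.ndim == 4


@dataclass
class PreparedCase:
    """Zero-padded image and smoothed-context arrays ready for extraction."""

    img: np.ndarray  # (C, X+2P, Y+2P, Z+2P)
    ctx_src: np.ndarray  # box-smoothed copy, same shape
    pad: int
    shape: tuple[int, int, int]  # original spatial shape
    out_window: int
    factor: int


def prepare_case(stack_arr: np.ndarray, out_window: int, factor: int = 3) -> PreparedCase:
    """Pad the channel array and precompute the smoothed context source."""
    pad = out_window + 8 * factor + 4
    img = np.pad(stack_arr, ((0, 0),) + ((pad, pad),) * 3)
    ctx_src = ndimage.uniform_filter(img, size=(1, factor, factor, factor))
    return PreparedCase(
        img=img,
        ctx_src=ctx_src,
        pad=pad,
        shape=stack_arr.shape[1:],
        out_window=out_window,
        factor=factor,
    )


def _windows_for(prep: PreparedCase, o: np.ndarray, w: int):
    """High-res and context input windows for output start ``o`` (unpadded)."""
    r, P = prep.factor, prep.pad
    hi_start = o + P - 8
    hi_size = w + 16
    K = -(-w // r) + 16
    g = o + P - 8 * r + (r - 1) // 2
    hi = prep.img[
        :,
        hi_start[0] : hi_start[0] + hi_size,
        hi_start[1] : hi_start[1] + hi_size,
        hi_start[2] : hi_start[2] + hi_size,
    ]
    idx = [g[d] + r * np.arange(K) for d in range(3)]
    ctx = prep.ctx_src[:, idx[0]][:, :, idx[1]][:, :, :, idx[2]]
    return hi, ctx


def extract_pair(
    prep: PreparedCase, center: tuple[int, int, int], labels: np.ndarray | None
) -> PatchPair:
    """Extract the segment pair whose output window is centered at ``center``."""
    w = prep.out_window
    o = np.asarray(center) - w // 2
    hi, ctx = _windows_for(prep, o, w)
    if labels is not None:
        lab = np.zeros((w, w, w), dtype=np.uint8)
        lo_clip = np.maximum(o, 0)
        hi_clip = np.minimum(o + w, prep.shape)
        if np.all(hi_clip > lo_clip):
            src = labels[
                lo_clip[0] : hi_clip[0], lo_clip[1] : hi_clip[1], lo_clip[2] : hi_clip[2]
            ]
            off = lo_clip - o
            lab[
                off[0] : off[0] + src.shape[0],
                off[1] : off[1] + src.shape[1],
                off[2] : off[2] + src.shape[2],
            ] = src
    else:
        lab = np.zeros((w, w, w), dtype=np.uint8)
    return PatchPair(
        image_segment=np.ascontiguousarray(hi),
        context_segment=np.ascontiguousarray(ctx),
        label_segment=lab,
    )


def sample_patches(
    stack: ChannelStack,
    labels: Volume3D,
    config: NetworkConfig,
    n: int,
    seed: int,
    prep: PreparedCase | None = None,
) -> list[PatchPair]:
    """Draw ``n`` segment pairs, half centered on foreground voxels and half
    on background voxels inside the brain mask; deterministic given ``seed``."""
    stack.channels[0].require_same_grid(labels, "stack/labels")
    lab = labels.values.astype(bool)
    if stack.mask is not None:
        brain = stack.mask.values.astype(bool)
    else:
        brain = np.any(stack.as_array() != 0, axis=0)
    bg = brain & ~lab

    n_fg = int(round(n * config.foreground_fraction))
    fg_idx = np.argwhere(lab)
    bg_idx = np.argwhere(bg)
    if n_fg > 0 and len(fg_idx) == 0:
        raise ValueError("no foreground voxels to sample from, but foreground fraction > 0")
    if len(bg_idx) == 0:
        bg_idx = np.argwhere(~lab)

    rng = np.random.default_rng(seed)
    if prep is None:
        prep = prepare_case(stack.as_array(), config.out_window, config.downsample_factor)
    pairs = []
    for _ in range(n_fg):
        c = fg_idx[rng.integers(len(fg_idx))]
        pairs.append(extract_pair(prep, tuple(c), lab))
    for _ in range(n - n_fg):
        c = bg_idx[rng.integers(len(bg_idx))]
        pairs.append(extract_pair(prep, tuple(c), lab))
    return pairs


def augment_flips(pair: PatchPair, seed: int) -> PatchPair:
    """Independently flip each spatial axis with probability 0.5.

    Image, context and label flip together; applying the same flip pattern
    twice restores the original pair.
    """
    rng = np.random.default_rng(seed)
    flips = rng.random(3) < 0.5
    img, ctx, lab = pair.image_segment, pair.context_segment, pair.label_segment
    for ax, do_flip in enumerate(flips):
        if do_flip:
            img = np.flip(img, axis=ax + 1)
            ctx = np.flip(ctx, axis=ax + 1)
            lab = np.flip(lab, axis=ax)
    return PatchPair(
        image_segment=np.ascontiguousarray(img),
        context_segment=np.ascontiguousarray(ctx),
        label_segment=np.ascontiguousarray(lab),
    )
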