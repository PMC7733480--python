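"""Dense volume inference by tiling the patch network, and binarization.

The network is fully convolutional, so a whole volume is processed as
non-overlapping output tiles whose input windows overlap by the receptive
field. Tile offsets are multiples of the tile size, which is a multiple of
the downsample factor — this keeps the context-pathway grid congruent
across tiles, so a tiled prediction is exactly the prediction of a single
whole-volume pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import ChannelStack
from ..volume import Volume3D
from .model import DualPathwayNet
from .sampling import _windows_for, prepare_case

__all__ = ["ProbabilityMap", "predict_volume", "binarize"]


@dataclass
class ProbabilityMap:
    """Voxel-wise foreground confidence on a Volume3D grid."""

    volume: Volume3D
    provenance: tuple[str, str] = ("", "")  # (variant_tag, fold id or "fused")

    @property
    def values(self) -> np.ndarray:
        return self.volume.values


def predict_volume(
    model: DualPathwayNet,
    stack: ChannelStack,
    tile: int | None = None,
    apply_mask: bool = True,
    provenance: tuple[str, str] | None = None,
) -> ProbabilityMap:
    """Foreground probability for every voxel of ``stack``.

    ``tile`` is the output-window edge length (rounded up to a multiple of
    the downsample factor); ``None`` picks a batch-friendly default. With
    ``apply_mask`` the probabilities outside the brain mask are zeroed.
    """
    cfg = model.config
    arr = stack.as_array()
    if arr.shape[0] != cfg.channels_in:
        raise ValueError(
            f"channel mismatch: model expects {cfg.channels_in} channels, "
            f"stack has {arr.shape[0]}"
        )
    r = cfg.downsample_factor
    if tile is None:
        tile = 6 * r
    tile = max(r * (-(-tile // r)), r)  # round up to a multiple of the factor

    shape = np.array(arr.shape[1:])
    n_tiles = -(-shape // tile)
    prep = prepare_case(arr, out_window=tile, factor=r)
    canvas = np.zeros(tuple(n_tiles * tile), dtype=np.float32)

    offsets = [
        (i * tile, j * tile, k * tile)
        for i in range(n_tiles[0])
        for j in range(n_tiles[1])
        for k in range(n_tiles[2])
    ]
    batch = 32
    for start in range(0, len(offsets), batch):
        group = offsets[start : start + batch]
        his, ctxs = [], []
        for o in group:
            hi, ctx = _windows_for(prep, np.asarray(o), tile)
            his.append(np.ascontiguousarray(hi))
            ctxs.append(np.ascontiguousarray(ctx))
        probs = model.predict_proba(np.stack(his), np.stack(ctxs))
        for o, p in zip(group, probs):
            canvas[o[0] : o[0] + tile, o[1] : o[1] + tile, o[2] : o[2] + tile] = p
    out = canvas[: shape[0], : shape[1], : shape[2]]
    if apply_mask and stack.mask is not None:
        out = out * stack.mask.values.astype(np.float32)
    vol = stack.channels[0].with_values(out.astype(np.float32))
    return ProbabilityMap(
        volume=vol, provenance=provenance or (stack.variant_tag, "")
    )


def binarize(p: ProbabilityMap | Volume3D, threshold: float = 0.5) -> Volume3D:
    """Threshold a probability map into a segmentation mask (``p >= t``)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    vol = p.volume if isinstance(p, ProbabilityMap) else p
    return vol.with_values((vol.values >= threshold).astype(np.uint8))
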