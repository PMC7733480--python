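"""Dual-pathway 3D patch segmentation network (DeepMedic-style).

Two identical convolutional pathways process a 3D image segment at native
resolution and at one-third resolution, centered at the same location.
Layers 1–8 are 3³ valid convolutions per pathway with residual connections
at layers 4, 6 and 8; the low-resolution features are upsampled and fused
with the high-resolution ones; layers 9 and 10 are 1×1×1 ("fully
connected") convolutions with a residual spanning the block; layer 11 is
the two-class classification layer. Batch normalization and PReLU follow
every convolution except the classifier.

The output window is ``segment − 16`` voxels per axis (eight 3³ valid
convolutions); the context pathway consumes ``ceil(out/3) + 16`` voxels of
the downsampled image so that, after ×3 nearest-neighbour upsampling and
cropping, the two feature blocks are congruent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = ["NetworkConfig", "DualPathwayNet", "build_model", "N_CONV_LAYERS", "RECEPTIVE_FIELD"]

N_CONV_LAYERS = 8  # 3³ conv layers per pathway
RECEPTIVE_FIELD = 2 * N_CONV_LAYERS + 1  # 17 voxels


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters.

    ``pathway_widths`` (feature maps of conv layers 1–8) defaults to a
    reduced profile suitable for CPU-scale runs; widths are configurable up
    to literature scale.
    """

    segment_size: int = 25
    channels_in: int = 1
    pathway_widths: tuple[int, ...] = (4, 4, 8, 8, 8, 8, 16, 16)
    fc_width: int = 24
    n_layers: int = 11
    kernel: int = 3
    residual_layers: tuple[int, ...] = (4, 6, 8, 10)
    downsample_factor: int = 3
    batch_size: int = 15
    epochs: int = 30
    batches_per_epoch: int = 10
    activation: str = "prelu"
    batch_norm: bool = True
    loss: str = "dice"
    dice_smooth: float = 1.0
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 0.0
    foreground_fraction: float = 0.5
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.segment_size % 2 == 0 or self.segment_size < RECEPTIVE_FIELD:
            raise ValueError(
                f"segment_size must be odd and >= the receptive field of the normal "
                f"pathway ({RECEPTIVE_FIELD} voxels); got {self.segment_size}"
            )
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if len(self.pathway_widths) != N_CONV_LAYERS:
            raise ValueError(f"pathway_widths must have {N_CONV_LAYERS} entries")

    @property
    def out_window(self) -> int:
        return self.segment_size - (RECEPTIVE_FIELD - 1)

    @property
    def context_out_window(self) -> int:
        return -(-self.out_window // self.downsample_factor)  # ceil

    @property
    def context_segment_size(self) -> int:
        return self.context_out_window + (RECEPTIVE_FIELD - 1)

    def np_dtype(self):
        return np.float64 if self.dtype == "float64" else np.float32


def _he_init(rng: np.random.Generator, shape, fan_in, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class _ConvBlock:
    """conv (+ BN + PReLU) with its parameters and running statistics."""

    def __init__(self, rng, c_in, c_out, k, dtype, with_bn_act=True):
        fan_in = c_in * k**3
        self.w = Parameter(_he_init(rng, (c_out, c_in, k, k, k), fan_in, dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self.with_bn_act = with_bn_act
        if with_bn_act:
            self.gamma = Parameter(np.ones(c_out, dtype=dtype))
            self.beta = Parameter(np.zeros(c_out, dtype=dtype))
            self.prelu_a = Parameter(np.full(c_out, 0.25, dtype=dtype))
            self.running_mean = np.zeros(c_out, dtype=dtype)
            self.running_var = np.ones(c_out, dtype=dtype)

    def __call__(self, x: Tensor, training: bool, use_bn: bool) -> Tensor:
        h = ag.conv3d(x, self.w, self.b)
        if self.with_bn_act:
            if use_bn:
                h = ag.batchnorm(
                    h, self.gamma, self.beta, self.running_mean, self.running_var, training
                )
            h = ag.prelu(h, self.prelu_a)
        return h

    def parameters(self):
        params = [self.w, self.b]
        if self.with_bn_act:
            params += [self.gamma, self.beta, self.prelu_a]
        return params

    def state(self):
        d = {"w": self.w.data, "b": self.b.data}
        if self.with_bn_act:
            d.update(
                gamma=self.gamma.data,
                beta=self.beta.data,
                prelu_a=self.prelu_a.data,
                running_mean=self.running_mean,
                running_var=self.running_var,
            )
        return d

    def load_state(self, d):
        self.w.data = d["w"]
        self.b.data = d["b"]
        if self.with_bn_act:
            self.gamma.data = d["gamma"]
            self.beta.data = d["beta"]
            self.prelu_a.data = d["prelu_a"]
            self.running_mean = d["running_mean"]
            self.running_var = d["running_var"]


class DualPathwayNet:
    """The two-pathway patch network; see module docstring for the layout."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        dtype = config.np_dtype()
        rng = np.random.default_rng(config.seed)
        widths = config.pathway_widths
        k = config.kernel

        def make_pathway():
            blocks = []
            c_prev = config.channels_in
            for w_out in widths:
                blocks.append(_ConvBlock(rng, c_prev, w_out, k, dtype))
                c_prev = w_out
            return blocks

        self.path_hi = make_pathway()
        self.path_lo = make_pathway()
        c_cat = 2 * widths[-1]
        self.fc9 = _ConvBlock(rng, c_cat, config.fc_width, 1, dtype)
        self.fc10 = _ConvBlock(rng, config.fc_width, config.fc_width, 1, dtype)
        self.classifier = _ConvBlock(rng, config.fc_width, 2, 1, dtype, with_bn_act=False)
        self.loss_log: list[float] = []

    # -- forward ----------------------------------------------------------

    def _run_pathway(self, blocks, x: Tensor, training: bool) -> Tensor:
        cfg = self.config
        inputs: dict[int, Tensor] = {}
        h = x
        for layer_idx, block in enumerate(blocks, start=1):
            inputs[layer_idx] = h
            h = block(h, training, cfg.batch_norm)
            if layer_idx in cfg.residual_layers and layer_idx <= N_CONV_LAYERS:
                skip = inputs[layer_idx - 1]
                skip = ag.crop_center(skip, h.shape[2:])
                skip = ag.pad_channels(skip, h.shape[1])
                h = h + skip
        return h

    def forward(self, x_hi: np.ndarray, x_lo: np.ndarray, training: bool = False) -> Tensor:
        """Logits (N, 2, w, w, w) for high-res segments and their context.

        ``x_hi``: (N, C, s, s, s); ``x_lo``: (N, C, cs, cs, cs) with
        ``cs = config.context_segment_size``. The high-res output window may
        be any size ≥ 1 (fully convolutional); the context input must cover
        ``ceil(w/3) + 16`` low-res voxels for an output window of ``w``.
        """
        cfg = self.config
        if x_hi.shape[1] != cfg.channels_in:
            raise ValueError(
                f"channel mismatch: model expects {cfg.channels_in}, got {x_hi.shape[1]}"
            )
        dtype = cfg.np_dtype()
        hi = self._run_pathway(self.path_hi, Tensor(x_hi.astype(dtype)), training)
        lo = self._run_pathway(self.path_lo, Tensor(x_lo.astype(dtype)), training)
        lo_up = ag.upsample_repeat(lo, cfg.downsample_factor)
        lo_up = ag.crop_offset(lo_up, (0, 0, 0), hi.shape[2:])
        cat = ag.concat_channels(hi, lo_up)
        h = self.fc9(cat, training, cfg.batch_norm)
        h = self.fc10(h, training, cfg.batch_norm)
        if 10 in cfg.residual_layers:  # residual spanning the 1×1×1 block
            h = h + ag.pad_channels(cat, h.shape[1])
        return self.classifier(h, training, cfg.batch_norm)

    def predict_proba(self, x_hi: np.ndarray, x_lo: np.ndarray) -> np.ndarray:
        """Foreground probabilities (N, w, w, w) in inference mode."""
        return ag.foreground_prob(self.forward(x_hi, x_lo, training=False)).data

    # -- bookkeeping ------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for block in self.path_hi + self.path_lo + [self.fc9, self.fc10, self.classifier]:
            params += block.parameters()
        return params

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- checkpointing ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint weights, BN statistics and the embedded config (npz)."""
        arrays = {}
        for name, block in self._named_blocks():
            for key, arr in block.state().items():
                arrays[f"{name}.{key}"] = arr
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    def _named_blocks(self):
        for i, b in enumerate(self.path_hi, start=1):
            yield f"hi{i}", b
        for i, b in enumerate(self.path_lo, start=1):
            yield f"lo{i}", b
        yield "fc9", self.fc9
        yield "fc10", self.fc10
        yield "classifier", self.classifier

    @classmethod
    def load(cls, path: str | Path) -> "DualPathwayNet":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["config_json"].tobytes()).decode())
            for key in ("pathway_widths", "residual_layers"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(NetworkConfig(**cfg_dict))
            for name, block in model._named_blocks():
                block.load_state(
                    {k.split(".", 1)[1]: data[k] for k in data.files if k.startswith(name + ".")}
                )
        return model


def build_model(config: NetworkConfig) -> DualPathwayNet:
    """Construct the network; parameter count is deterministic from config."""
    return DualPathwayNet(config)
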