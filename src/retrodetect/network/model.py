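"""The residual 1D convolutional detector.

Six stages: a wide stem convolution reading the 4-row one-hot input, four
residual blocks that downsample the length by factors 5, 2, 5 and 2 (their
product equals the 100-bp cell size, so the output length is the number of
grid cells) while doubling the channel count, and a 1x1 output convolution
to 22 channels followed by the bounded detection-head activations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .. import schema as S
from .layers import Conv1d, DetectionHead, ResidualBlock, Sequential

_DTYPES = {"float32": np.float32, "float64": np.float64}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture settings; defaults are the full-scale detector."""

    window_len: int = S.DEFAULT_WINDOW_LEN
    cell_size: int = S.DEFAULT_CELL_SIZE
    stem_channels: int = 16
    stem_kernel: int = 50
    block_factors: tuple[int, ...] = (5, 2, 5, 2)
    block_kernel: int = 9
    channel_growth: int = 2
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.window_len % self.cell_size != 0:
            raise ValueError(
                f"window_len {self.window_len} not divisible by cell_size {self.cell_size}"
            )
        if math.prod(self.block_factors) != self.cell_size:
            raise ValueError(
                "product of block downsampling factors "
                f"{self.block_factors} must equal the cell size {self.cell_size}"
            )
        if self.dtype not in _DTYPES:
            raise ValueError(f"dtype must be one of {sorted(_DTYPES)}")

    @property
    def n_cells(self) -> int:
        return self.window_len // self.cell_size

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_factors"] = list(self.block_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["block_factors"] = tuple(d["block_factors"])
        return cls(**d)


class Detector:
    """Callable detector: one-hot batches ``(B, 4, window_len)`` to
    prediction grids ``(B, n_cells, 22)`` with presence/start/length in
    [0, 1] and softmax class groups."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dtype = _DTYPES[config.dtype]
        layers = [
            Conv1d(4, config.stem_channels, config.stem_kernel, stride=1,
                   rng=rng, dtype=dtype, name="stem"),
        ]
        cin = config.stem_channels
        for b, factor in enumerate(config.block_factors):
            cout = cin * config.channel_growth
            layers.append(
                ResidualBlock(cin, cout, factor, kernel_size=config.block_kernel,
                              rng=rng, dtype=dtype, name=f"block{b + 1}")
            )
            cin = cout
        layers.append(Conv1d(cin, S.N_COORDS, 1, stride=1, rng=rng, dtype=dtype, name="out"))
        layers.append(DetectionHead(S.N_TYPES, S.N_LINEAGES))
        self.net = Sequential(*layers)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPES[self.config.dtype])
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != 4 or x.shape[2] != self.config.window_len:
            raise ValueError(
                f"expected input (B, 4, {self.config.window_len}), got {x.shape}"
            )
        return self.net.forward(x, train=train)

    __call__ = forward

    def backward(self, dpred: np.ndarray) -> np.ndarray:
        return self.net.backward(dpred)

    def parameters(self):
        return self.net.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def predict(self, features: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Inference in batches (batch-norm in running-stats mode)."""
        features = np.asarray(features)
        if features.ndim == 2:
            features = features[None]
        out = [
            self.forward(features[i : i + batch_size], train=False)
            for i in range(0, features.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights as ``<path>.npz`` with a JSON config side-car
        ``<path>.json``."""
        path = Path(path)
        arrays = {p.name: p.value for p in self.parameters()}
        for i, layer in enumerate(self._batchnorms()):
            arrays[f"__running_mean_{i}"] = layer.running_mean
            arrays[f"__running_var_{i}"] = layer.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.config.to_dict(), indent=2) + "\n")

    def _batchnorms(self):
        from .layers import BatchNorm1d

        out = []
        def walk(layer):
            if isinstance(layer, BatchNorm1d):
                out.append(layer)
            for attr in ("layers",):
                for sub in getattr(layer, attr, []):
                    walk(sub)
            for attr in ("main", "shortcut"):
                sub = getattr(layer, attr, None)
                if sub is not None:
                    walk(sub)
        walk(self.net)
        return out

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "Detector":
        path = Path(path)
        config = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = cls(config, seed=seed)
        with np.load(path.with_suffix(".npz")) as data:
            for p in model.parameters():
                p.value[...] = data[p.name]
            for i, layer in enumerate(model._batchnorms()):
                layer.running_mean[...] = data[f"__running_mean_{i}"]
                layer.running_var[...] = data[f"__running_var_{i}"]
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> Detector:
    """Construct the detector for a configuration (defaults: 50 kb windows,
    500 cells x 22 outputs)."""
    return Detector(config or ModelConfig(), seed=seed)
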