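"""The 3D residual CNN: construction, forward/backward, checkpoints."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import NetworkConfig
from .layers import BatchNorm3D, Conv3D, ReLU


class ResidualCNN3D:
    """Stack of 'same' 3D convolutions with a global input-to-output skip.

    Layers 1..N-1 carry ``n_feature_maps`` maps, each followed by batch
    normalization and ReLU; the final convolution has a single map and no
    normalization or activation; the network input is added elementwise to
    the final convolution output, so a network whose final layer is zero
    computes the identity map exactly.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | int | None = None) -> None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        w = cfg.n_feature_maps
        self.blocks: list[list] = []
        c_in = 1
        for _ in range(cfg.n_conv_layers - 1):
            block = [Conv3D(c_in, w, rng)]
            if cfg.use_batchnorm:
                block.append(BatchNorm3D(w))
            block.append(ReLU())
            self.blocks.append(block)
            c_in = w
        self.final = Conv3D(c_in, cfg.final_maps, rng)
        self.final.W *= cfg.final_init_scale

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, D, H, W) or (N, D, H, W, 1) float32; output matches input shape."""
        squeeze = x.ndim == 4
        if squeeze:
            x = x[..., None]
        x = np.ascontiguousarray(x, np.float32)
        h = x
        for block in self.blocks:
            for layer in block:
                h = layer.forward(h, training)
        h = self.final.forward(h, training)
        out = h + x if self.cfg.residual_add else h
        return out[..., 0] if squeeze else out

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients; dy matches the forward output shape."""
        if dy.ndim == 4:
            dy = dy[..., None]
        dy = np.ascontiguousarray(dy, np.float32)
        # the skip path contributes no parameter gradients
        d = self.final.backward(dy, need_dx=len(self.blocks) > 0)
        for bi in range(len(self.blocks) - 1, -1, -1):
            for li in range(len(self.blocks[bi]) - 1, -1, -1):
                layer = self.blocks[bi][li]
                if isinstance(layer, Conv3D):
                    d = layer.backward(d, need_dx=bi > 0)
                else:
                    d = layer.backward(d)

    # -- parameters --------------------------------------------------------

    def _layers(self):
        for block in self.blocks:
            yield from block
        yield self.final

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def zero_final_layer(self) -> None:
        """Force the final convolution to zero: the network becomes identity."""
        self.final.W[:] = 0.0
        self.final.b[:] = 0.0

    # -- checkpoints -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        for bi, block in enumerate(self.blocks):
            for layer in block:
                if isinstance(layer, BatchNorm3D):
                    arrays[f"rm{bi}"] = layer.running_mean
                    arrays[f"rv{bi}"] = layer.running_var
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ResidualCNN3D":
        with np.load(Path(path)) as data:
            cfg = NetworkConfig(**json.loads(bytes(data["config_json"]).decode()))
            net = cls(cfg, rng=0)
            for i, p in enumerate(net.params):
                p[:] = data[f"p{i}"]
            for bi, block in enumerate(net.blocks):
                for layer in block:
                    if isinstance(layer, BatchNorm3D):
                        layer.running_mean = data[f"rm{bi}"].copy()
                        layer.running_var = data[f"rv{bi}"].copy()
        return net


def build_network(cfg: NetworkConfig, rng_seed: int = 0) -> ResidualCNN3D:
    """Construct the residual CNN with MSRA-initialized weights."""
    return ResidualCNN3D(cfg, rng=np.random.default_rng(rng_seed))
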