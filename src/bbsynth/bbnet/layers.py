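"""NumPy building blocks: 3D convolution, batch norm, ReLU, with backprop.

Convolutions use a shift-and-GEMM scheme: for each of the 27 kernel taps the
padded input is sliced at that offset and multiplied against the tap's
(C_in x C_out) weight slice with one BLAS GEMM, accumulating into the
output.  This avoids materializing the (voxels x 27*C_in) im2col matrix and
is memory-bandwidth friendly on a single CPU core.

Data layout is channels-last: (N, D, H, W, C), float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3D", "BatchNorm3D", "ReLU"]


def _conv3d(x: np.ndarray, W: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """'Same' 3D convolution. x (N,D,H,Wd,C); W (3,3,3,C,K); b (K,)."""
    N, D, H, Wd, C = x.shape
    K = W.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    y = np.empty((N, D, H, Wd, K), np.float32)
    y[:] = 0.0 if b is None else b
    acc = y.reshape(-1, K)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                xs = xp[:, i : i + D, j : j + H, k : k + Wd, :].reshape(-1, C)
                acc += xs @ W[i, j, k]
    return y


def _conv3d_dw(xp: np.ndarray, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weight/bias gradients. xp is the padded forward input."""
    N, D, H, Wd, K = dy.shape
    C = xp.shape[-1]
    dy2 = dy.reshape(-1, K)
    dW = np.empty((3, 3, 3, C, K), np.float32)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                xs = xp[:, i : i + D, j : j + H, k : k + Wd, :].reshape(-1, C)
                dW[i, j, k] = xs.T @ dy2
    return dW, dy2.sum(axis=0)


class Conv3D:
    """3x3x3 'same' convolution with one-voxel zero padding on every face."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 weight_init: str = "msra") -> None:
        fan_in = 27 * c_in
        if weight_init == "msra":
            std = np.sqrt(2.0 / fan_in)
        elif weight_init == "zeros":
            std = 0.0
        else:
            raise ValueError(f"unknown weight init {weight_init!r}")
        self.W = (rng.standard_normal((3, 3, 3, c_in, c_out)) * std).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        return _conv3d(x, self.W, self.b)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        assert self._xp is not None, "backward before forward(training=True)"
        self.dW, self.db = _conv3d_dw(self._xp, dy)
        self._xp = None
        if not need_dx:
            return None
        # dx = conv of dy with the spatially flipped, channel-transposed kernel
        Wrot = np.ascontiguousarray(self.W[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3))
        return _conv3d(dy, Wrot, None)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class BatchNorm3D:
    """Per-channel batch normalization over (N, D, H, W).

    Training uses batch statistics and updates exponential running averages;
    evaluation uses the accumulated running statistics only.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = np.ones(c, np.float32)
        self.beta = np.zeros(c, np.float32)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * invstd
        if training:
            self._xhat, self._invstd = xhat, invstd
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        axes = (0, 1, 2, 3)
        m = float(np.prod([dy.shape[a] for a in axes]))
        self.dgamma = (dy * xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (invstd / m) * (m * dxhat - dxhat.sum(axis=axes)
                             - xhat * (dxhat * xhat).sum(axis=axes))
        self._xhat = self._invstd = None
        return dx.astype(np.float32)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    params: list = []
    grads: list = []
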