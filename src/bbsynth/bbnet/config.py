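"""Architecture and optimization configuration for the 3D residual CNN."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class NetworkConfig:
    """3D residual CNN architecture.

    The reference architecture is 25 convolution layers of 64 feature maps
    with 3x3x3 kernels, batch normalization + ReLU after every convolution
    except the last, one output map, one-voxel zero padding on every face so
    shapes are preserved, and an elementwise addition of the network input
    to the final convolution output (residual learning).

    ``desk_scale`` returns a reduced configuration (depth 5, width 16) that
    trains in minutes on one CPU while keeping every structural property.
    """

    n_conv_layers: int = 25
    kernel_size: tuple[int, int, int] = (3, 3, 3)
    n_feature_maps: int = 64
    final_maps: int = 1
    use_batchnorm: bool = True
    activation: str = "relu"
    residual_add: bool = True
    padding_vox: int = 1
    # scale on the MSRA std of the final conv; 0 starts the network at the
    # exact identity map (zero residual branch), which shortens short
    # CPU-budget runs without changing what is learnable
    final_init_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_conv_layers < 2:
            raise ValueError("n_conv_layers must be >= 2")
        self.kernel_size = tuple(int(k) for k in self.kernel_size)
        if self.kernel_size != (3, 3, 3):
            raise ValueError("only 3x3x3 kernels are supported")
        if self.final_maps != 1:
            raise ValueError("the final convolution layer must have exactly 1 map")
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")
        if self.padding_vox != 1:
            raise ValueError("padding must be 1 voxel per face for shape preservation")

    @classmethod
    def desk_scale(cls) -> "NetworkConfig":
        return cls(n_conv_layers=5, n_feature_maps=16, final_init_scale=0.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The reference schedule: Adam at an initial learning rate of 1e-5 decayed
    by a factor of 10 every 10 epochs, gradients clipped to global norm 1,
    batch size 10, MSE loss, 31x31x31 co-located patches, MSRA
    (variance-scaled rectifier) weight initialization, 30 training epochs
    with early stopping when the validation loss saturates.

    ``desk_scale`` raises the learning rate to 1e-3 and shrinks the patch
    budget so that a depth-5/width-16 network converges within a CPU-minute
    budget on phantom data; everything else is unchanged.
    """

    learning_rate: float = 1e-5
    lr_decay_factor: float = 10.0
    lr_decay_every_epochs: int = 10
    grad_clip: float = 1.0
    batch_size: int = 10
    loss: str = "mse"
    n_epochs: int = 30
    patch_size: int = 31
    patches_per_volume: int = 500
    fg_min_fraction: float = 0.5
    optimizer: str = "adam"
    weight_init: str = "msra"
    patience: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "lr_decay_factor", "lr_decay_every_epochs",
                     "grad_clip", "batch_size", "n_epochs", "patch_size",
                     "patches_per_volume", "patience"):
            if getattr(self, name) < 0 or (name not in ("n_epochs",) and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.loss != "mse":
            raise ValueError("only MSE loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if not 0.0 <= self.fg_min_fraction <= 1.0:
            raise ValueError("fg_min_fraction must lie in [0, 1]")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        kw = dict(learning_rate=1e-3, patches_per_volume=75, patch_size=19,
                  n_epochs=30, patience=3, lr_decay_every_epochs=15)
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate in effect during 0-based ``epoch`` under the step decay."""
    return cfg.learning_rate / (cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every_epochs))


@dataclass
class TrainLog:
    """Per-epoch history of one optimization run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float | None] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = "max_epochs"  # or "validation_saturation"

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"epoch": range(len(self.train_loss)), "train_loss": self.train_loss,
             "val_loss": self.val_loss, "lr": self.lr}
        ).to_csv(path, index=False)
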