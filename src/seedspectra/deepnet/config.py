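"""Configuration objects for the deep spectral classifiers."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ..errors import ValidationError

__all__ = ["DeepConfig", "EcaSpec", "eca_kernel_size"]


def eca_kernel_size(channels: int, gamma: float = 2.0, b_coef: float = 1.0) -> int:
    """Adaptive ECA kernel width: nearest odd integer to |log2(C)/gamma + b/gamma|.

    Follows the ECA-Net mapping ``k = |psi(C)|_odd``: truncate to an integer
    and bump even values up to the next odd number, with a floor of 1.
    """
    if channels < 1:
        raise ValidationError("channels must be >= 1")
    t = abs(math.log2(channels) / gamma + b_coef / gamma)
    k = int(t)
    if k % 2 == 0:
        k += 1
    return max(k, 1)


@dataclass(frozen=True)
class EcaSpec:
    """Efficient channel attention: GAP -> 1-D conv of width k -> sigmoid gate."""

    channels: int
    gamma: float = 2.0
    b_coef: float = 1.0

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ValidationError("channels must be >= 1")

    @property
    def kernel_k(self) -> int:
        return eca_kernel_size(self.channels, self.gamma, self.b_coef)


@dataclass(frozen=True)
class DeepConfig:
    """Architecture and training regime for the 1DCNN family.

    ``use_lstm/use_attention/use_eca`` select the ablation variant:
    (F,F,F) is the plain 1DCNN baseline, (T,T,T) the full
    CNN-LSTM-attention-ECA model.  Conv kernel/stride/padding default to
    3/1/1 and the pooling is max of width 2; learning rate 1e-3, batch 16.
    """

    conv_channels: int = 64
    kernel_size: int = 3
    stride: int = 1
    padding: int = 1
    pool_width: int = 2
    lstm_layers: int = 3
    lstm_hidden: int = 64
    attn_heads: int = 8
    use_lstm: bool = True
    use_attention: bool = True
    use_eca: bool = True
    n_classes: int = 30
    n_bands: int = 512
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 200
    rng_seed: int = 0
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if min(self.conv_channels, self.n_classes, self.n_bands, self.batch_size, self.epochs) < 1:
            raise ValidationError("counts must be >= 1")
        if self.stride != 1:
            raise ValidationError("only stride 1 is implemented")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValidationError("kernel_size must be odd and >= 1")
        if self.pool_width < 1:
            raise ValidationError("pool_width must be >= 1")
        if self.use_lstm and (self.lstm_layers < 1 or self.lstm_hidden < 1):
            raise ValidationError("lstm_layers and lstm_hidden must be >= 1")
        if self.use_attention:
            d_model = self.lstm_hidden if self.use_lstm else self.conv_channels
            if d_model % self.attn_heads != 0:
                raise ValidationError(
                    f"model width {d_model} not divisible by attn_heads {self.attn_heads}"
                )
        if self.dtype not in ("float32", "float64"):
            raise ValidationError("dtype must be float32 or float64")

    @property
    def d_model(self) -> int:
        """Feature width of the sequence entering attention / ECA / the head."""
        return self.lstm_hidden if self.use_lstm else self.conv_channels

    def ablation_name(self) -> str:
        if not self.use_lstm:
            return "1DCNN"
        if not self.use_attention:
            return "1DCNN-LSTM"
        if not self.use_eca:
            return "1DCNN-LSTM-ATTENTION"
        return "CLA-CA"
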