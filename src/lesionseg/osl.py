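"""Order Statistics Layer (OSL).

At the network bottleneck, lesion cores and borders carry extreme feature
activations.  The OSL summarizes each pixel's channel vector by the mean of
its k smallest and k largest entries, normalizes both by the large statistic
(to damp outliers and gain scale invariance), and concatenates the two
resulting maps onto the feature tensor, growing C channels to C+2.

The layer has no learnable parameters.  It expects nonnegative input (its
contract is to sit immediately after a ReLU), which keeps the normalized
statistics in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

__all__ = ["OSLParams", "channel_order_stats", "normalize_orders",
           "osl_forward", "osl_layer"]


@dataclass(frozen=True)
class OSLParams:
    """k: number of extreme channels averaged; eps: division guard."""
    k: int = 1
    eps: float = 1e-7

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")


def _check_nonneg(values):
    if np.any(values < 0):
        raise ValueError("OSL input must be nonnegative (post-ReLU contract)")


def channel_order_stats(x: np.ndarray, k: int):
    """Per-pixel mean of the k smallest / largest channel values.

    Parameters
    ----------
    x : (H, W, C) array, nonnegative.
    k : int in [1, C].

    Returns
    -------
    (small_order, large_order) : two (H, W, 1) arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected H x W x C tensor, got shape {x.shape}")
    c = x.shape[-1]
    if not 1 <= k <= c:
        raise ValueError(f"k={k} outside [1, C={c}]")
    srt = np.sort(x, axis=-1)
    small = srt[..., :k].mean(axis=-1, keepdims=True)
    large = srt[..., c - k:].mean(axis=-1, keepdims=True)
    return small, large


def normalize_orders(small: np.ndarray, large: np.ndarray, eps: float = 1e-7):
    """Divide both order statistics by (large + eps); outputs lie in [0, 1)."""
    small = np.asarray(small, dtype=np.float64)
    large = np.asarray(large, dtype=np.float64)
    _check_nonneg(small)
    _check_nonneg(large)
    if np.any(small > large + 1e-12):
        raise ValueError("small order statistic exceeds large: invalid input")
    denom = large + eps
    return small / denom, large / denom


def osl_forward(x: np.ndarray, params: OSLParams = OSLParams()) -> np.ndarray:
    """NumPy reference forward: concat(x, small_norm, large_norm) -> H x W x (C+2)."""
    x = np.asarray(x)
    _check_nonneg(x)
    small, large = channel_order_stats(x, params.k)
    small_n, large_n = normalize_orders(small, large, params.eps)
    return np.concatenate(
        [x, small_n.astype(x.dtype), large_n.astype(x.dtype)], axis=-1)


def osl_layer(x: "ad.Tensor", params: OSLParams = OSLParams()) -> "ad.Tensor":
    """Differentiable OSL on an NCHW autodiff tensor: C -> C+2 channels."""
    _check_nonneg(x.data)
    small, large = ad.channel_extremes(x, params.k)
    denom = ad.add(large, ad.Tensor(np.float32(params.eps)))
    small_n = ad.div(small, denom)
    large_n = ad.div(large, denom)
    return ad.concat([x, small_n, large_n], axis=-1)
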