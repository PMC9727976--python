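"""Retinex enhancement for fundus photographs: SSR, MSR and MSRCR.

Single-scale Retinex (SSR) compares each pixel to a Gaussian surround in log
space, ``log(I + eps) - log(G_sigma * I + eps)``; the multi-scale variant
(MSR) averages SSR maps over several surround widths; MSRCR adds a per-channel
colour-restoration factor so that the dynamic-range compression does not wash
out colour.  The defaults follow the classic Jobson-Rahman-Woodell
formulation: surround scales (15, 80, 250) px with equal weights, alpha=125,
beta=46, and a (1, 99) percentile stretch to 8-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RetinexParams",
    "single_scale_retinex",
    "multi_scale_retinex",
    "msrcr",
    "MSRCREnhancer",
]


@dataclass
class RetinexParams:
    """Parameters of the MSRCR enhancement.

    scales are Gaussian surround standard deviations in pixels; weights are
    normalised to sum to one.  ``alpha`` and ``beta`` control the
    colour-restoration factor, ``gain``/``offset`` the linear output map, and
    ``clip_low``/``clip_high`` the percentile stretch of the final image.
    """

    scales: tuple = (15.0, 80.0, 250.0)
    scale_weights: tuple | None = None
    alpha: float = 125.0
    beta: float = 46.0
    gain: float = 1.0
    offset: float = 0.0
    clip_low: float = 1.0
    clip_high: float = 99.0
    epsilon: float = 1.0

    def __post_init__(self):
        self.scales = tuple(float(s) for s in self.scales)
        if any(s <= 0 for s in self.scales):
            raise ValueError("all Retinex scales must be positive")
        if self.scale_weights is None:
            self.scale_weights = tuple([1.0 / len(self.scales)] *
                                       len(self.scales))
        else:
            w = np.asarray(self.scale_weights, dtype=float)
            if len(w) != len(self.scales):
                raise ValueError(
                    f"{len(w)} weights for {len(self.scales)} scales")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("scale weights must be nonnegative with a "
                                 "positive sum")
            self.scale_weights = tuple(w / w.sum())
        if not 0 <= self.clip_low < self.clip_high <= 100:
            raise ValueError("require 0 <= clip_low < clip_high <= 100")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _surround(channel: np.ndarray, sigma: float) -> np.ndarray:
    # Separable Gaussian, reflect padding, kernel truncated at 3 sigma.
    return gaussian_filter(channel, sigma, mode="reflect", truncate=3.0)


def single_scale_retinex(image_channel, sigma: float,
                         epsilon: float = 1.0) -> np.ndarray:
    """SSR of a single nonnegative channel: signed, unbounded output."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    channel = np.asarray(image_channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("empty image channel")
    return np.log(channel + epsilon) - np.log(_surround(channel, sigma) +
                                              epsilon)


def multi_scale_retinex(image_channel, params: RetinexParams) -> np.ndarray:
    """Weighted sum of SSR maps over ``params.scales``."""
    channel = np.asarray(image_channel, dtype=np.float64)
    out = np.zeros_like(channel)
    for sigma, w in zip(params.scales, params.scale_weights):
        out += w * single_scale_retinex(channel, sigma, params.epsilon)
    return out


def msrcr(image, params: RetinexParams | None = None) -> np.ndarray:
    """Multi-scale Retinex with colour restoration of an RGB image.

    Per channel i:  out_i = gain * (C_i * MSR_i + offset)  with colour factor
    C_i = beta * (log(alpha * I_i + eps) - log(I_R + I_G + I_B + eps)),
    followed by a per-channel percentile clip and a linear rescale to
    [0, 255].  Output shape and dtype match the input.
    """
    params = params or RetinexParams()
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("msrcr requires an H x W x 3 colour image")
    img = arr.astype(np.float64)
    eps = params.epsilon
    intensity_sum = img.sum(axis=2)
    out = np.empty_like(img)
    for i in range(3):
        msr_i = multi_scale_retinex(img[:, :, i], params)
        c_i = params.beta * (np.log(params.alpha * img[:, :, i] + eps) -
                             np.log(intensity_sum + eps))
        out[:, :, i] = params.gain * (c_i * msr_i + params.offset)
    for i in range(3):
        lo, hi = np.percentile(out[:, :, i],
                               [params.clip_low, params.clip_high])
        if hi - lo < 1e-12:
            out[:, :, i] = 127.5  # constant channel: mid-range by convention
        else:
            out[:, :, i] = np.clip(
                (out[:, :, i] - lo) / (hi - lo), 0.0, 1.0) * 255.0
    if np.issubdtype(arr.dtype, np.integer):
        out = np.rint(out)
    return out.astype(arr.dtype)


class MSRCREnhancer(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer applying MSRCR per image.

    ``transform`` accepts a single H x W x 3 image or a sequence/stack of
    them and returns the enhanced image(s) with dtype preserved.
    """

    def __init__(self, scales=(15.0, 80.0, 250.0), scale_weights=None,
                 alpha=125.0, beta=46.0, gain=1.0, offset=0.0, clip_low=1.0,
                 clip_high=99.0, epsilon=1.0):
        self.scales = scales
        self.scale_weights = scale_weights
        self.alpha = alpha
        self.beta = beta
        self.gain = gain
        self.offset = offset
        self.clip_low = clip_low
        self.clip_high = clip_high
        self.epsilon = epsilon

    def _params(self) -> RetinexParams:
        return RetinexParams(scales=self.scales,
                             scale_weights=self.scale_weights,
                             alpha=self.alpha, beta=self.beta, gain=self.gain,
                             offset=self.offset, clip_low=self.clip_low,
                             clip_high=self.clip_high, epsilon=self.epsilon)

    def fit(self, X, y=None):
        self._params()  # validate
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        params = self._params()
        arr = np.asarray(X)
        if arr.ndim == 3:
            return msrcr(arr, params)
        if arr.ndim == 4:
            return np.stack([msrcr(im, params) for im in arr])
        raise ValueError("expected one H x W x 3 image or a stack of them")
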