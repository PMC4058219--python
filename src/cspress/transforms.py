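"""Sparse transform and measurement operators.

Wraps PyWavelets' multilevel separable 2D DWT behind the coefficient-set
container the reconstruction loop manipulates, and provides the undersampled
Fourier operator ``F_u`` (centered unitary FFT followed by mask projection)
and its adjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .phantom import from_kspace, to_kspace
from .sampling import SamplingMask

__all__ = [
    "WaveletSpec",
    "CoefficientSet",
    "wavelet_analysis",
    "wavelet_synthesis",
    "masked_ft",
    "masked_ft_adjoint",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family and decomposition depth (e.g. haar/3, bior4.4/6)."""

    family: str = "haar"
    levels: int = 3
    #: boundary extension; symmetric (half-sample) is the common imaging choice
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("decomposition depth must be >= 1")
        if self.family not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet family {self.family!r}")

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.family)


@dataclass
class CoefficientSet:
    """Multilevel 2D wavelet coefficients.

    ``coeffs`` follows the PyWavelets layout: ``[cA_n, (cH_n, cV_n, cD_n),
    ..., (cH_1, cV_1, cD_1)]`` with the approximation band first. Complex
    images are handled natively (real and imaginary channels transformed
    with the same filters).
    """

    coeffs: list
    spec: WaveletSpec
    image_shape: tuple[int, int]

    def map_details(self, fn) -> "CoefficientSet":
        """Apply ``fn`` to every detail band, leaving the approximation band."""
        new = [self.coeffs[0]] + [
            tuple(fn(band) for band in level) for level in self.coeffs[1:]
        ]
        return CoefficientSet(new, self.spec, self.image_shape)

    def map_all(self, fn) -> "CoefficientSet":
        new = [fn(self.coeffs[0])] + [
            tuple(fn(band) for band in level) for level in self.coeffs[1:]
        ]
        return CoefficientSet(new, self.spec, self.image_shape)

    def detail_magnitudes(self) -> np.ndarray:
        return np.concatenate(
            [np.abs(band).ravel() for level in self.coeffs[1:] for band in level]
        )

    def energy(self) -> float:
        tot = float(np.sum(np.abs(self.coeffs[0]) ** 2))
        for level in self.coeffs[1:]:
            for band in level:
                tot += float(np.sum(np.abs(band) ** 2))
        return tot

    def l1(self) -> float:
        tot = float(np.sum(np.abs(self.coeffs[0])))
        for level in self.coeffs[1:]:
            for band in level:
                tot += float(np.sum(np.abs(band)))
        return tot


def wavelet_analysis(img: np.ndarray, spec: WaveletSpec) -> CoefficientSet:
    """Multilevel 2D wavelet decomposition of a (possibly complex) image."""
    with warnings.catch_warnings():
        # depths beyond pywt's boundary-safe maximum are legitimate here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(img, spec.wavelet, mode=spec.mode, level=spec.levels)
    return CoefficientSet(list(coeffs), spec, tuple(np.shape(img)))


def wavelet_synthesis(c: CoefficientSet, spec: WaveletSpec | None = None) -> np.ndarray:
    """Inverse multilevel 2D wavelet transform; exact round trip with analysis."""
    spec = c.spec if spec is None else spec
    img = pywt.waverec2(c.coeffs, spec.wavelet, mode=spec.mode)
    # waverec2 may pad odd dimensions by one sample; crop to the original grid
    return img[: c.image_shape[0], : c.image_shape[1]]


def masked_ft(img: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Undersampled Fourier operator F_u: centered unitary FFT then projection."""
    if np.shape(img) != mask.shape:
        raise ValueError("image and mask shapes differ")
    return to_kspace(img) * mask.values


def masked_ft_adjoint(k: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Adjoint F_u*: projection then centered unitary inverse FFT."""
    if np.shape(k) != mask.shape:
        raise ValueError("k-space and mask shapes differ")
    return from_kspace(k * mask.values)
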