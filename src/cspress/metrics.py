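"""Reconstruction-quality metrics.

The error indicators are *median* absolute error (MAE) and *median* square
error (MSE) over pixels — medians, not means, so a small fraction of badly
reconstructed pixels (edges, ringing) does not dominate the score. Mean
variants are available behind the ``statistic`` flag. By default both
images are affinely rescaled to an 8-bit 0–255 intensity range (using the
reference image's min/max) before comparison, which puts the reported
numbers on the familiar display scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .sampling import SamplingMask, correlation_2d, epr, ProbabilityMap

__all__ = ["EvalReport", "mae", "mse", "evaluate"]

Scale = Literal["none", "0-255"]
Statistic = Literal["median", "mean"]


@dataclass
class EvalReport:
    mae: float
    mse: float
    epr: float
    corr2d: float
    sampling_ratio: float
    method: str = ""

    def __post_init__(self) -> None:
        if self.mae < 0 or self.mse < 0 or not 0 <= self.epr <= 1:
            raise ValueError("inconsistent evaluation report")

    def as_dict(self) -> dict:
        return asdict(self)


def _prepare(x: np.ndarray, ref: np.ndarray, scale: Scale) -> tuple[np.ndarray, np.ndarray]:
    if np.shape(x) != np.shape(ref):
        raise ValueError("image shapes differ")
    a, b = np.abs(x).astype(float), np.abs(ref).astype(float)
    if scale == "0-255":
        lo, hi = b.min(), b.max()
        span = hi - lo if hi > lo else 1.0
        a = (a - lo) / span * 255.0
        b = (b - lo) / span * 255.0
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    return a, b


def mae(
    x: np.ndarray,
    ref: np.ndarray,
    scale: Scale = "none",
    statistic: Statistic = "median",
) -> float:
    """Median (or mean) absolute pixel error between magnitude images."""
    a, b = _prepare(x, ref, scale)
    d = np.abs(a - b)
    return float(np.median(d) if statistic == "median" else np.mean(d))


def mse(
    x: np.ndarray,
    ref: np.ndarray,
    scale: Scale = "none",
    statistic: Statistic = "median",
) -> float:
    """Median (or mean) squared pixel error between magnitude images."""
    a, b = _prepare(x, ref, scale)
    d = (a - b) ** 2
    return float(np.median(d) if statistic == "median" else np.mean(d))


def evaluate(
    recon: np.ndarray,
    truth: np.ndarray,
    mask: SamplingMask,
    k_full: np.ndarray,
    pmap: ProbabilityMap | None = None,
    scale: Scale = "0-255",
    method: str = "",
) -> EvalReport:
    """Bundle the standard indicators for one reconstruction run."""
    corr = correlation_2d(pmap, k_full) if pmap is not None else float("nan")
    return EvalReport(
        mae=mae(recon, truth, scale=scale),
        mse=mse(recon, truth, scale=scale),
        epr=epr(mask, k_full),
        corr2d=corr,
        sampling_ratio=mask.ratio,
        method=method,
    )
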