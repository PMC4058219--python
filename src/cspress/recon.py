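"""Image reconstruction from undersampled k-space.

Two solvers for the wavelet-sparsity cost function are provided.

*Iterative thresholding algorithm (ITA)* solves the improved cost function

    min ||Ψx||_1   s.t.   F_u P x = y  and  x = S x,

where ``P`` is a unit-modulus phase-correction matrix estimated from the
symmetric central rows of k-space (so the corrected object is approximately
real, as in partial-Fourier homodyne processing) and ``S`` is a binary
region-of-support projector that suppresses background. Each iteration
hard-thresholds the wavelet coefficients at a linearly decreasing threshold,
restores exact data consistency by overwriting the sampled k-space
positions with the measurements, and projects onto the support.

*FISTA* is the accelerated proximal-gradient baseline for the conventional
cost function ``min λ||Ψx||_1 + ½||F_u x − y||²`` (soft thresholding, unit
step — valid since the centered FFT is unitary); the monotone variant is
used, which keeps the best-objective iterate so the objective never
increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .phantom import from_kspace, to_kspace
from .sampling import SamplingMask, central_rows
from .transforms import (
    CoefficientSet,
    WaveletSpec,
    wavelet_analysis,
    wavelet_synthesis,
)

__all__ = [
    "ThresholdSchedule",
    "ReconConfig",
    "ReconResult",
    "estimate_phase",
    "estimate_support",
    "hard_threshold",
    "soft_threshold",
    "data_consistency",
    "ita_reconstruct",
    "fista_reconstruct",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSchedule:
    """Linearly decreasing threshold series T(1)=Ti ... T(MaxITER)=Tf."""

    Ti: float
    Tf: float
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def value(self, k: int) -> float:
        """Threshold at iteration ``k`` (1-based)."""
        if not 1 <= k <= self.max_iter:
            raise ValueError(f"iteration {k} outside 1..{self.max_iter}")
        if self.max_iter == 1:
            return self.Ti
        if k == self.max_iter:
            return self.Tf  # exact endpoint, no accumulated round-off
        return self.Ti - (self.Ti - self.Tf) / (self.max_iter - 1) * (k - 1)


@dataclass
class ReconConfig:
    """Solver parameters shared by ITA and the FISTA baseline.

    ``Ti``/``Tf`` default to 0.5x and 0.001x the largest detail-coefficient
    magnitude of the zero-filled initial image (resolved at run time when
    left as None). ``stall_tol`` (F) and ``patience`` (I) implement the
    stagnation stop: terminate once the iterate changes by at most F, in
    Frobenius norm, for I consecutive iterations. F defaults to 0 (stop
    only when the iterate is exactly stationary): with a decreasing
    threshold schedule the iterate sits still on plateaus between threshold
    crossings, so any sizeable positive F cuts the schedule short and
    degrades the reconstruction; set F > 0 deliberately when iteration
    budget matters more than the last fraction of quality. ``epsilon`` records the
    fidelity bound of the constrained formulation; ITA enforces exact
    consistency (epsilon = 0) and FISTA's ``lam`` plays its Lagrangian role.
    """

    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    Ti: float | None = None
    Tf: float | None = None
    max_iter: int = 200
    stall_tol: float | None = None  # F; default 0.0 (exact stationarity)
    patience: int = 5  # I
    epsilon: float = 0.0
    use_phase: bool = False
    use_support: bool = False
    n_central: int = 4
    support_frac: float = 0.05
    threshold_approx: bool = False  # coarsest approximation band exempt
    lam: float | None = None  # FISTA l1 weight; default 0.01 * max |Ψ(x0)|

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.patience < 1:
            raise ValueError("max_iter and patience must be >= 1")
        if self.stall_tol is not None and self.stall_tol < 0:
            raise ValueError("stall tolerance must be nonnegative")


@dataclass
class ReconResult:
    image: np.ndarray
    iterations_run: int
    stop_reason: Literal["budget", "stalled"]
    change_norms: list[float]
    objective: list[float] = field(default_factory=list)


# --------------------------------------------------------------------------
# improved-cost-function ingredients
# --------------------------------------------------------------------------

def _central_kspace(y: np.ndarray, mask: SamplingMask, n_central: int) -> np.ndarray:
    rows = central_rows(y.shape[0], n_central)
    if not mask.values[rows].all():
        raise ValueError(
            f"the {n_central} central rows must be fully sampled for "
            "low-frequency phase/support estimation"
        )
    ks = np.zeros_like(y)
    ks[rows] = y[rows]
    return ks


def estimate_phase(
    y: np.ndarray, mask: SamplingMask, n_central: int = 4
) -> np.ndarray:
    """Unit-modulus phase map from the symmetric central k-space rows.

    Keeps the ``n_central`` fully sampled rows around DC, zero-fills the
    rest, inverse-transforms to a low-resolution image ``Is`` and returns
    ``P = exp(-i angle(Is))``; multiplying the object by ``P`` removes its
    smooth phase, making it approximately real.
    """
    Is = from_kspace(_central_kspace(y, mask, n_central))
    return np.exp(-1j * np.angle(Is))


def estimate_support(
    y: np.ndarray,
    mask: SamplingMask,
    frac: float = 0.05,
    n_central: int = 4,
) -> np.ndarray:
    """Binary region-of-support from a low-resolution central-row image.

    Thresholds the low-resolution magnitude at ``frac`` of its maximum,
    then applies binary closing and hole filling to obtain a solid object
    support. ``frac = 0`` yields the all-ones (no-op) projector. In practice
    the support would come from a coarse prescan; this derives the same
    information from the already-acquired central rows.
    """
    if frac < 0:
        raise ValueError("threshold fraction must be nonnegative")
    if frac == 0:
        return np.ones(y.shape, dtype=bool)
    mag = np.abs(from_kspace(_central_kspace(y, mask, n_central)))
    s = mag >= frac * mag.max()
    s = ndimage.binary_closing(s, structure=np.ones((3, 3)))
    return ndimage.binary_fill_holes(s)


def hard_threshold(c: CoefficientSet, T: float) -> CoefficientSet:
    """Keep coefficients with complex magnitude > T unchanged; zero the rest.

    The coarsest approximation band is exempt: it carries the DC content of
    the image, which the decreasing threshold schedule could not recover
    once zeroed.
    """
    if T < 0:
        raise ValueError("threshold must be nonnegative")
    return c.map_details(lambda band: np.where(np.abs(band) > T, band, 0))


def soft_threshold(c: CoefficientSet, T: float, include_approx: bool = False) -> CoefficientSet:
    """Complex soft thresholding (magnitude shrinkage, phase preserved)."""

    def shrink(band):
        mag = np.abs(band)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(mag > 0, np.maximum(mag - T, 0.0) / np.where(mag > 0, mag, 1.0), 0.0)
        return band * scale

    return c.map_all(shrink) if include_approx else c.map_details(shrink)


def data_consistency(
    x: np.ndarray,
    y: np.ndarray,
    mask: SamplingMask,
    P: np.ndarray | None = None,
) -> np.ndarray:
    """Exact k-space fidelity: overwrite sampled positions with measurements.

    Transforms the phase-corrected estimate ``P x`` to k-space, replaces the
    sampled entries with the acquired data ``y``, and transforms back,
    undoing the phase correction with ``conj(P)`` (valid since |P| = 1).
    Afterwards ``to_kspace(P x')`` equals ``y`` exactly on the mask.
    """
    if np.shape(x) != mask.shape or np.shape(y) != mask.shape:
        raise ValueError("image, data and mask shapes differ")
    if P is None:
        k = to_kspace(x)
        k[mask.values] = y[mask.values]
        return from_kspace(k)
    k = to_kspace(P * x)
    k[mask.values] = y[mask.values]
    return np.conj(P) * from_kspace(k)


# --------------------------------------------------------------------------
# solvers
# --------------------------------------------------------------------------

def _resolve_thresholds(cfg: ReconConfig, x0: np.ndarray) -> ThresholdSchedule:
    if cfg.Ti is not None and cfg.Tf is not None:
        return ThresholdSchedule(cfg.Ti, cfg.Tf, cfg.max_iter)
    peak = wavelet_analysis(x0, cfg.wavelet).detail_magnitudes().max()
    Ti = cfg.Ti if cfg.Ti is not None else 0.5 * peak
    Tf = cfg.Tf if cfg.Tf is not None else 0.001 * peak
    return ThresholdSchedule(Ti, Tf, cfg.max_iter)


def ita_reconstruct(
    y: np.ndarray,
    mask: SamplingMask,
    cfg: ReconConfig | None = None,
    support: np.ndarray | None = None,
) -> ReconResult:
    """Iterative thresholding reconstruction of the improved cost function.

    Starting from the zero-filled inverse ``x0 = IDFT(y)``, each iteration
    (1) hard-thresholds the wavelet coefficients at the scheduled threshold
    T(k), (2) restores exact consistency with the acquired samples, and
    (3) projects onto the region of support. Stops when the iterate changes
    by at most F for I consecutive iterations, or at the iteration budget.
    """
    cfg = cfg or ReconConfig()
    if np.shape(y) != mask.shape:
        raise ValueError("data and mask shapes differ")
    # estimate_phase returns the corrector exp(-i*phi_hat); the solver's
    # state is the corrected object (approximately real, hence sparser),
    # so data_consistency gets the restorer conj(corrector) = exp(+i*phi_hat)
    P = None
    x = from_kspace(y)
    if cfg.use_phase:
        corrector = estimate_phase(y, mask, cfg.n_central)
        P = np.conj(corrector)
        x = corrector * x
    sched = _resolve_thresholds(cfg, x)
    F = cfg.stall_tol if cfg.stall_tol is not None else 0.0
    S: np.ndarray | None = None
    if cfg.use_support:
        S = (
            support.astype(bool)
            if support is not None
            else estimate_support(y, mask, cfg.support_frac, cfg.n_central)
        )
    changes: list[float] = []
    stop_reason: Literal["budget", "stalled"] = "budget"
    stalled = 0
    k = 0
    for k in range(1, cfg.max_iter + 1):
        c = wavelet_analysis(x, cfg.wavelet)
        c = hard_threshold(c, sched.value(k))
        x_new = wavelet_synthesis(c)
        x_new = data_consistency(x_new, y, mask, P)
        if S is not None:
            x_new = np.where(S, x_new, 0)
        change = float(np.linalg.norm(x_new - x))
        changes.append(change)
        x = x_new
        stalled = stalled + 1 if change <= F else 0
        if stalled >= cfg.patience:
            stop_reason = "stalled"
            break
    return ReconResult(x, k, stop_reason, changes)


def _objective(x, y, mask, cfg, lam) -> float:
    resid = to_kspace(x) * mask.values - y * mask.values
    return lam * wavelet_analysis(x, cfg.wavelet).l1() + 0.5 * float(
        np.sum(np.abs(resid) ** 2)
    )


def fista_reconstruct(
    y: np.ndarray,
    mask: SamplingMask,
    cfg: ReconConfig | None = None,
) -> ReconResult:
    """Monotone FISTA baseline for the conventional cost function.

    Accelerated proximal-gradient iteration on
    ``λ||Ψx||_1 + ½||F_u x − y||²`` with unit step (the forward operator is
    non-expansive: unitary centered FFT composed with a binary projection)
    and wavelet-domain soft thresholding as the proximal map. Keeps the
    best-objective iterate so the recorded objective is non-increasing.
    """
    cfg = cfg or ReconConfig()
    if np.shape(y) != mask.shape:
        raise ValueError("data and mask shapes differ")
    x = from_kspace(y * mask.values)
    lam = (
        cfg.lam
        if cfg.lam is not None
        else 0.01 * float(np.max(np.abs(wavelet_analysis(x, cfg.wavelet).detail_magnitudes())))
    )
    F = cfg.stall_tol if cfg.stall_tol is not None else 0.0
    z = x.copy()
    t = 1.0
    best = x
    best_obj = _objective(x, y, mask, cfg, lam)
    objectives = [best_obj]
    changes: list[float] = []
    stop_reason: Literal["budget", "stalled"] = "budget"
    stalled = 0
    k = 0
    for k in range(1, cfg.max_iter + 1):
        grad = from_kspace((to_kspace(z) - y) * mask.values)
        u = z - grad
        if lam > 0:
            c = soft_threshold(wavelet_analysis(u, cfg.wavelet), lam, include_approx=True)
            u = wavelet_synthesis(c)
        obj = _objective(u, y, mask, cfg, lam)
        x_prev = best
        if obj <= best_obj:
            best, best_obj = u, obj
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = u + (t - 1.0) / t_next * (u - x)
        x, t = u, t_next
        objectives.append(best_obj)
        change = float(np.linalg.norm(best - x_prev))
        changes.append(change)
        stalled = stalled + 1 if change <= F else 0
        if stalled >= cfg.patience:
            stop_reason = "stalled"
            break
    return ReconResult(best, k, stop_reason, changes, objectives)
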