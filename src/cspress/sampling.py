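"""Sampling-pattern design for Cartesian compressed-sensing MRI.

Implements the energy-preserving sampling design (ePRESS) — build a
probability map from the k-space magnitudes of reference scans, reweight it
with a hamming window, and deterministically select the highest-probability
points — alongside the standard comparators: the polynomial variable-density
(VD) probability map, PDF-driven random sampling (used both to realize VD
masks and the reference-power-spectrum "power" method), and plain
low-resolution (central k-space) sampling. Also provides the evaluation
diagnostics: the energy-preserving ratio (EPR) and 2D / row-wise Pearson
correlations between a probability map and a test k-space.

Masks come in two flavors: ``point`` mode selects individual k-space points
(the 2-PE-axis setting of a 3D scan, applied per slice) and ``line`` mode
selects whole rows, i.e. full readout lines (the single-PE-axis 2D setting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .phantom import to_kspace

__all__ = [
    "ProbabilityMap",
    "SamplingMask",
    "central_rows",
    "build_ipdf",
    "hamming2d",
    "apply_window",
    "select_mask",
    "vd_pdf",
    "pdf_random_mask",
    "lowres_mask",
    "epress_mask",
    "epr",
    "correlation_2d",
    "rowwise_correlation",
]

Mode = Literal["point", "line"]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityMap:
    """A nonnegative 2D grid over k-space that sums to one."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("probability map must be 2D")
        if np.any(v < 0):
            raise ValueError("probability map has negative entries")
        s = v.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("probability map must have positive finite mass")
        object.__setattr__(self, "values", v / s)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SamplingMask:
    """Binary k-space selection pattern."""

    values: np.ndarray
    mode: Mode = "point"
    always_sampled_center: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        object.__setattr__(self, "values", v.astype(bool))
        if self.mode == "line":
            rows = self.values.any(axis=1)
            if not (self.values[rows].all() and ~self.values[~rows].any()):
                raise ValueError("line-mode mask must select whole rows")
        if self.always_sampled_center:
            rows = central_rows(self.values.shape[0], self.always_sampled_center)
            if not self.values[rows].all():
                raise ValueError("declared central rows are not all sampled")

    @property
    def n_points(self) -> int:
        return int(self.values.sum())

    @property
    def ratio(self) -> float:
        return self.n_points / self.values.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def central_rows(N: int, n: int) -> slice:
    """The ``n`` central rows (containing the DC row at index ``N // 2``)."""
    if n < 0 or n > N:
        raise ValueError(f"invalid central row count {n} for {N} rows")
    start = N // 2 - n // 2
    return slice(start, start + n)


# --------------------------------------------------------------------------
# probability maps
# --------------------------------------------------------------------------

def build_ipdf(
    references: Sequence[np.ndarray], mode: Mode = "point"
) -> ProbabilityMap:
    """Initial probability map (iPDF) from reference k-spaces.

    Sums the k-space magnitudes over all references and normalizes to unit
    mass. In ``line`` mode the sum is additionally collapsed along the
    readout (column) axis into a per-row profile, broadcast back across the
    grid, so whole readout lines share one probability.
    """
    if len(references) == 0:
        raise ValueError("need at least one reference k-space")
    shapes = {np.shape(r) for r in references}
    if len(shapes) != 1:
        raise ValueError(f"reference k-spaces have mixed shapes: {shapes}")
    acc = np.zeros(shapes.pop())
    for r in references:
        acc += np.abs(r)
    if mode == "line":
        profile = acc.sum(axis=1, keepdims=True)
        acc = np.broadcast_to(profile, acc.shape).copy()
    elif mode != "point":
        raise ValueError(f"unknown mask mode {mode!r}")
    return ProbabilityMap(acc)


def build_power_pdf(references: Sequence[np.ndarray]) -> ProbabilityMap:
    """Reference power-spectrum map: like the iPDF but with |K|^2 weights."""
    if len(references) == 0:
        raise ValueError("need at least one reference k-space")
    acc = np.zeros(np.shape(references[0]))
    for r in references:
        acc += np.abs(r) ** 2
    return ProbabilityMap(acc)


def hamming2d(N: int, M: int | None = None) -> np.ndarray:
    """Separable 2D hamming window with its peak (value 1) at the DC bin.

    Each axis uses the factor ``0.54 - 0.46 cos(2 pi m / N)`` evaluated at
    ``m = 0 .. N-1``, so the corners take the hamming endpoint value 0.08
    per axis and the window is symmetric about the DC bin at ``N // 2``
    (``w[(N - m) % N] == w[m]``). Strictly positive everywhere.
    """
    M = N if M is None else M
    if N < 2 or M < 2:
        raise ValueError("window needs at least 2 samples per axis")
    wr = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(N) / N)
    wc = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(M) / M)
    return np.outer(wr, wc)


def apply_window(
    ipdf: ProbabilityMap,
    alpha: float,
    operator: Literal["multiply", "divide"] = "multiply",
) -> ProbabilityMap:
    """Windowed probability map wPDF ∝ iPDF · ω^α, renormalized.

    The hamming window smooths the selection surface and regularizes the
    ranking of mid-frequency points; ``α`` controls how strongly it acts.
    With ``operator="divide"`` the window is divided out instead
    (wPDF ∝ iPDF / ω^α), which pushes sampling probability toward the
    outer, high-frequency portion of k-space at the price of captured
    energy — useful when edge recovery matters more than SNR. The default
    multiplicative form is the one that keeps the energy-preserving
    property: its masks capture at least as much k-space energy as
    variable-density or power-spectrum random masks at any matched ratio.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    w = hamming2d(*ipdf.shape)
    if operator == "multiply":
        return ProbabilityMap(ipdf.values * w**alpha)
    if operator == "divide":
        return ProbabilityMap(ipdf.values / w**alpha)
    raise ValueError(f"unknown window operator {operator!r}")


def vd_pdf(N: int, M: int | None = None, p: float = 10.0) -> ProbabilityMap:
    """Variable-density polynomial map ``(1 - r)^p``.

    ``r`` is the distance from the k-space center, normalized so the most
    distant grid corner has ``r = 1``; negative bases are clipped to zero.
    ``p = 0`` gives a uniform map; larger ``p`` concentrates mass at the
    center.
    """
    M = N if M is None else M
    if p < 0:
        raise ValueError("p must be nonnegative")
    rows = np.arange(N) - N // 2
    cols = np.arange(M) - M // 2
    R = np.hypot(*np.meshgrid(rows, cols, indexing="ij"))
    r = R / R.max()
    return ProbabilityMap(np.clip(1.0 - r, 0.0, None) ** p)


# --------------------------------------------------------------------------
# mask construction
# --------------------------------------------------------------------------

def _topk_bool(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest entries; ties broken by (row, col)."""
    flat = values.ravel()
    rows, cols = np.unravel_index(np.arange(flat.size), values.shape)
    order = np.lexsort((cols, rows, -flat))  # primary: value descending
    out = np.zeros(flat.size, dtype=bool)
    out[order[:k]] = True
    return out.reshape(values.shape)


def select_mask(
    wpdf: ProbabilityMap,
    n_points: int,
    mode: Mode = "point",
    center_rows: int = 4,
) -> SamplingMask:
    """Deterministic threshold selection of the highest-probability points.

    Equivalent to lowering a threshold level on the wPDF until exactly the
    requested number of points (or readout lines, in ``line`` mode) lies
    above it; realized as an exact top-k sort with (row, col) lexicographic
    tie-breaking. The ``center_rows`` central rows are always included and
    counted against the budget, guaranteeing the symmetric low-frequency
    data needed for phase estimation. Masks are nested in ``n_points``.
    """
    N, M = wpdf.shape
    v = wpdf.values
    if mode == "line":
        if not 0 < n_points <= N:
            raise ValueError(f"need 0 < n_lines <= {N}, got {n_points}")
        if center_rows > n_points:
            raise ValueError("forced central rows exceed the line budget")
        row_score = v.sum(axis=1)
        forced = np.zeros(N, dtype=bool)
        forced[central_rows(N, center_rows)] = True
        score = row_score.copy()
        score[forced] = np.inf
        sel = _topk_bool(score[:, None], n_points)[:, 0]
        mask = np.repeat(sel[:, None], M, axis=1)
    elif mode == "point":
        if not 0 < n_points <= N * M:
            raise ValueError(f"need 0 < n_points <= {N * M}, got {n_points}")
        forced = np.zeros((N, M), dtype=bool)
        forced[central_rows(N, center_rows)] = True
        if forced.sum() > n_points:
            raise ValueError(
                f"forced central rows need {int(forced.sum())} points, "
                f"budget is {n_points}"
            )
        score = v.copy()
        score[forced] = np.inf
        mask = _topk_bool(score, n_points)
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    return SamplingMask(mask, mode=mode, always_sampled_center=center_rows)


def epress_mask(
    references: Sequence[np.ndarray],
    n_points: int,
    alpha: float = 0.8,
    mode: Mode = "point",
    center_rows: int = 4,
) -> SamplingMask:
    """Full energy-preserving design: iPDF -> hamming-windowed wPDF -> top-k."""
    ipdf = build_ipdf(references, mode=mode)
    return select_mask(apply_window(ipdf, alpha), n_points, mode, center_rows)


def pdf_random_mask(
    pdf: ProbabilityMap,
    n_points: int,
    seed: int = 0,
    center_rows: int = 0,
) -> SamplingMask:
    """Exact-count weighted random sampling without replacement.

    Draws exactly ``n_points`` distinct k-space points with inclusion
    preference proportional to the probability map; reproducible under a
    fixed seed. Optionally forces the central rows on (counted against the
    budget) so the mask satisfies phase-estimation preconditions.
    """
    N, M = pdf.shape
    if not 0 < n_points <= N * M:
        raise ValueError(f"need 0 < n_points <= {N * M}, got {n_points}")
    if n_points == N * M:
        return SamplingMask(
            np.ones((N, M), dtype=bool), mode="point",
            always_sampled_center=center_rows,
        )
    forced = np.zeros((N, M), dtype=bool)
    forced[central_rows(N, center_rows)] = True
    n_forced = int(forced.sum())
    if n_forced > n_points:
        raise ValueError("forced central rows exceed the point budget")
    p = pdf.values.copy()
    p[forced] = 0.0
    flat = p.ravel()
    n_draw = n_points - n_forced
    if np.count_nonzero(flat) < n_draw:
        raise ValueError(
            "probability map has fewer nonzero entries than requested points"
        )
    mask = forced.copy()
    if n_draw:
        rng = np.random.default_rng(seed)
        idx = rng.choice(flat.size, size=n_draw, replace=False, p=flat / flat.sum())
        mask.ravel()[idx] = True
    return SamplingMask(mask, mode="point", always_sampled_center=center_rows)


def lowres_mask(N: int, M: int | None = None, n_points: int = 0) -> SamplingMask:
    """Central (low-resolution) sampling: the points nearest the k-space center."""
    M = N if M is None else M
    if not 0 < n_points <= N * M:
        raise ValueError(f"need 0 < n_points <= {N * M}, got {n_points}")
    rows = np.arange(N) - N // 2
    cols = np.arange(M) - M // 2
    R = np.hypot(*np.meshgrid(rows, cols, indexing="ij"))
    return SamplingMask(_topk_bool(-R, n_points), mode="point")


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def epr(mask: SamplingMask, k: np.ndarray) -> float:
    """Energy-preserving ratio: fraction of total |k|^2 captured by the mask."""
    if mask.shape != k.shape:
        raise ValueError("mask and k-space shapes differ")
    e = np.abs(k) ** 2
    total = e.sum()
    if total == 0:
        raise ValueError("k-space is identically zero")
    return float(e[mask.values].sum() / total)


def correlation_2d(pmap: ProbabilityMap, k: np.ndarray) -> float:
    """Pearson correlation between a probability map and |k|, flattened."""
    if pmap.shape != np.shape(k):
        raise ValueError("map and k-space shapes differ")
    a = pmap.values.ravel()
    b = np.abs(k).ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def rowwise_correlation(pmap: ProbabilityMap, k: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlations; rows with zero variance yield NaN."""
    if pmap.shape != np.shape(k):
        raise ValueError("map and k-space shapes differ")
    a = pmap.values
    b = np.abs(k)
    out = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        if a[i].std() > 0 and b[i].std() > 0:
            out[i] = np.corrcoef(a[i], b[i])[0, 1]
    return out


def kspace_stack(images: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Convenience: transform a stack of images to centered k-space."""
    return [to_kspace(im) for im in images]
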