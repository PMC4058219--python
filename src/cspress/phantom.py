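"""Randomized Shepp-Logan phantom datasets and simulated k-space acquisition.

The sampling-design method studied by this package builds its probability
maps from *reference scans* — previously acquired images of similar objects.
Since no real scans ship with the package, this module emulates that setting:
it generates families of Shepp-Logan head phantoms whose ellipse parameters
are randomly perturbed, so that every member shares the gross anatomy while
differing in intensity, scale, position and orientation, exactly the regime
in which reference-driven sampling design is supposed to help.

Conventions used throughout the package:

* images are ``(N, M)`` arrays indexed ``[row, col]``, 0-based;
* the field of view is the unit square ``[-1, 1]^2`` sampled at pixel
  centers, with the vertical coordinate decreasing with the row index
  (standard image orientation);
* k-space is centered: the DC component sits at index ``(N//2, M//2)``;
* the image <-> k-space transforms are unitary, so energy (sum of squared
  magnitudes) is identical in both domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EllipseSpec",
    "PhantomDataset",
    "SHEPP_LOGAN_ELLIPSES",
    "DEFAULT_VARIANCES",
    "shepp_logan",
    "perturb_ellipses",
    "make_dataset",
    "to_kspace",
    "from_kspace",
    "synth_phase",
    "save_dataset",
    "load_dataset",
    "save_png",
]


# --------------------------------------------------------------------------
# ellipse parametrization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse of a head phantom.

    Parameters
    ----------
    A : float
        Additive intensity contributed inside the ellipse (dimensionless).
    a, b : float
        Horizontal / vertical semi-axes as fractions of the half field of
        view; must be positive.
    x0, y0 : float
        Center coordinates, fractions of the half field of view, in [-1, 1].
    phi : float
        Rotation angle of the horizontal semi-axis, in degrees,
        counter-clockwise.
    """

    A: float
    a: float
    b: float
    x0: float
    y0: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(
                f"ellipse semi-axes must be positive, got a={self.a}, b={self.b}"
            )
        if abs(self.x0) > 1 or abs(self.y0) > 1:
            raise ValueError(
                f"ellipse center ({self.x0}, {self.y0}) outside the unit FOV"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.a, self.b, self.x0, self.y0, self.phi])


#: The modified Shepp-Logan ellipse set (the Matlab ``phantom`` default),
#: with improved contrast relative to the original 1974 intensities.
SHEPP_LOGAN_ELLIPSES: tuple[EllipseSpec, ...] = (
    EllipseSpec(1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    EllipseSpec(-0.8, 0.6624, 0.874, 0.0, -0.0184, 0.0),
    EllipseSpec(-0.2, 0.11, 0.31, 0.22, 0.0, -18.0),
    EllipseSpec(-0.2, 0.16, 0.41, -0.22, 0.0, 18.0),
    EllipseSpec(0.1, 0.21, 0.25, 0.0, 0.35, 0.0),
    EllipseSpec(0.1, 0.046, 0.046, 0.0, 0.1, 0.0),
    EllipseSpec(0.1, 0.046, 0.046, 0.0, -0.1, 0.0),
    EllipseSpec(0.1, 0.046, 0.023, -0.08, -0.605, 0.0),
    EllipseSpec(0.1, 0.023, 0.023, 0.0, -0.606, 0.0),
    EllipseSpec(0.1, 0.023, 0.046, 0.06, -0.605, 0.0),
)

#: Per-parameter perturbation variances (A, a, b, x0, y0, phi[deg]) used for
#: the randomized phantom study.
DEFAULT_VARIANCES: tuple[float, ...] = (0.1, 0.05, 0.05, 0.05, 0.05, 10.0)


@dataclass
class PhantomDataset:
    """A family of randomized phantoms: reference images plus one test image."""

    references: list[np.ndarray]
    test: np.ndarray
    seed: int
    variances: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_VARIANCES)
    )

    def __post_init__(self) -> None:
        shapes = {r.shape for r in self.references} | {self.test.shape}
        if len(shapes) != 1:
            raise ValueError(f"dataset grids have inconsistent shapes: {shapes}")

    @property
    def n_ref(self) -> int:
        return len(self.references)

    @property
    def shape(self) -> tuple[int, int]:
        return self.test.shape


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def _pixel_grid(N: int, M: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates on [-1, 1]^2; y decreases with row index."""
    x = -1.0 + (2.0 * np.arange(M) + 1.0) / M
    y = 1.0 - (2.0 * np.arange(N) + 1.0) / N
    return np.meshgrid(x, y)


def shepp_logan(
    N: int, ellipses: Sequence[EllipseSpec] = SHEPP_LOGAN_ELLIPSES
) -> np.ndarray:
    """Rasterize an analytic ellipse phantom on an ``N x N`` grid.

    Each pixel value is the sum of the additive intensities ``A`` of all
    ellipses whose interior contains the pixel center.
    """
    if N < 16:
        raise ValueError(f"grid size must be >= 16, got {N}")
    if not ellipses:
        raise ValueError("ellipse list must be nonempty")
    X, Y = _pixel_grid(N, N)
    img = np.zeros((N, N))
    for e in ellipses:
        theta = np.deg2rad(e.phi)
        c, s = np.cos(theta), np.sin(theta)
        dx, dy = X - e.x0, Y - e.y0
        u = (dx * c + dy * s) / e.a
        v = (-dx * s + dy * c) / e.b
        img[u * u + v * v <= 1.0] += e.A
    # exact cancellations of the signed intensities leave +-1e-16 dust
    img[np.abs(img) < 1e-12] = 0.0
    return img


# --------------------------------------------------------------------------
# randomized perturbation
# --------------------------------------------------------------------------

def perturb_ellipses(
    base: Sequence[EllipseSpec],
    variances: Sequence[float] = DEFAULT_VARIANCES,
    seed: int | np.random.Generator = 0,
    max_retries: int = 100,
) -> list[EllipseSpec]:
    """Add independent zero-mean Gaussian noise to every ellipse parameter.

    The six entries of ``variances`` are the noise *variances* of
    ``(A, a, b, x0, y0, phi)`` in that order. An ellipse whose perturbed
    semi-axes come out nonpositive (or whose center leaves the FOV) is
    redrawn, up to ``max_retries`` times.
    """
    variances = np.asarray(variances, dtype=float)
    if variances.shape != (6,):
        raise ValueError("variances must be a 6-vector (A, a, b, x0, y0, phi)")
    if np.any(variances < 0):
        raise ValueError("variances must be nonnegative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sd = np.sqrt(variances)
    out: list[EllipseSpec] = []
    for e in base:
        params = e.as_array()
        for attempt in range(max_retries + 1):
            cand = params + rng.standard_normal(6) * sd
            a, b = cand[1], cand[2]
            if a > 0 and b > 0 and abs(cand[3]) <= 1 and abs(cand[4]) <= 1:
                out.append(EllipseSpec(*cand))
                break
        else:
            raise RuntimeError(
                f"could not draw a valid perturbation of {e} in "
                f"{max_retries} retries; variances too large for its geometry"
            )
    return out


def make_dataset(
    N: int = 128,
    n_ref: int = 20,
    variances: Sequence[float] = DEFAULT_VARIANCES,
    seed: int = 0,
    base: Sequence[EllipseSpec] = SHEPP_LOGAN_ELLIPSES,
) -> PhantomDataset:
    """Generate ``n_ref`` randomized reference phantoms plus one test phantom.

    Every image comes from an independently perturbed copy of the base
    ellipse set; the whole dataset is a pure function of
    ``(N, n_ref, variances, seed, base)``.
    """
    if n_ref < 1:
        raise ValueError("need at least one reference image")
    rng = np.random.default_rng(seed)
    images = [
        shepp_logan(N, perturb_ellipses(base, variances, rng))
        for _ in range(n_ref + 1)
    ]
    return PhantomDataset(
        references=images[:n_ref],
        test=images[n_ref],
        seed=seed if isinstance(seed, int) else -1,
        variances=np.asarray(variances, dtype=float),
    )


# --------------------------------------------------------------------------
# simulated acquisition: centered unitary Fourier transforms
# --------------------------------------------------------------------------

def to_kspace(img: np.ndarray) -> np.ndarray:
    """Centered unitary 2D DFT: image -> k-space with DC at (N//2, M//2)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img), norm="ortho")
    )


def from_kspace(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_kspace` (exact up to floating-point round-off)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k), norm="ortho")
    )


def synth_phase(
    img: np.ndarray, strength: float, seed: int = 0
) -> np.ndarray:
    """Impose a smooth synthetic phase on a magnitude image.

    Real MR images carry slowly varying phase from field inhomogeneity and
    receive-chain delays; this emulates it with a random second-order 2D
    polynomial field, recentred and scaled so its range is exactly
    ``[-strength, strength]`` radians. The output magnitude equals the input
    magnitude everywhere.
    """
    if strength < 0:
        raise ValueError("phase strength must be nonnegative")
    if strength == 0:
        return np.asarray(img, dtype=complex)
    N, M = img.shape
    X, Y = _pixel_grid(N, M)
    rng = np.random.default_rng(seed)
    c = rng.standard_normal(5)
    phi = c[0] * X + c[1] * Y + c[2] * X * X + c[3] * X * Y + c[4] * Y * Y
    lo, hi = phi.min(), phi.max()
    if hi - lo < 1e-12:  # degenerate draw: fall back to a plane
        phi = X
        lo, hi = phi.min(), phi.max()
    phi = (phi - 0.5 * (lo + hi)) * (2.0 * strength / (hi - lo))
    return np.abs(img) * np.exp(1j * phi)


# --------------------------------------------------------------------------
# dataset I/O
# --------------------------------------------------------------------------

def save_dataset(ds: PhantomDataset, path) -> None:
    """Write a dataset to HDF5 (groups /references/<i> and /test)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("references")
        for i, r in enumerate(ds.references):
            g.create_dataset(str(i), data=r)
        f.create_dataset("test", data=ds.test)
        f.attrs["seed"] = ds.seed
        f.attrs["variances"] = ds.variances


def load_dataset(path) -> PhantomDataset:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["references"]
        refs = [g[str(i)][()] for i in range(len(g))]
        return PhantomDataset(
            references=refs,
            test=f["test"][()],
            seed=int(f.attrs.get("seed", -1)),
            variances=np.asarray(f.attrs.get("variances", DEFAULT_VARIANCES)),
        )


def save_png(img: np.ndarray, path) -> None:
    """Write an 8-bit grayscale preview of a (possibly complex) image."""
    from PIL import Image

    mag = np.abs(img).astype(float)
    rng_ = mag.max() - mag.min()
    scaled = (mag - mag.min()) / rng_ * 255.0 if rng_ > 0 else np.zeros_like(mag)
    Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)


# re-exported for callers that construct perturbed sets directly
def with_params(e: EllipseSpec, **kw) -> EllipseSpec:
    return replace(e, **kw)
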