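"""Isophote-curvature center voting over a difference-of-Gaussians pyramid.

Isophotes are curves of constant intensity.  Around a circular structure such
as a pupil they are concentric circles, and the curvature of an isophote is
the reciprocal of the radius of its osculating circle:

    kappa = -(Ly^2 Lxx - 2 Lx Ly Lxy + Lx^2 Lyy) / (Lx^2 + Ly^2)^(3/2)

with L* the Gaussian first/second derivatives of the luminance.  Inverting the
curvature and orienting it along the gradient gives, at every pixel, a
displacement vector pointing to the estimated center of the local osculating
circle:

    D = -(Lx, Ly) (Lx^2 + Ly^2) / (Ly^2 Lxx - 2 Lx Ly Lxy + Lx^2 Lyy)

Each pixel deposits a vote at p + D(p) in an accumulator; pixels on a circle
boundary all vote for its center.  To cover a range of pupil scales, the
voting runs on every level of a difference-of-Gaussians pyramid and the
per-level accumulators are upsampled to the base resolution and summed.

Votes are weighted by curvedness sqrt(Lxx^2 + 2 Lxy^2 + Lyy^2) by default so
strong curved structure outvotes flat noise; unit weights are available as an
option, as is restricting votes to dark-centered isophotes (pupils are dark).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .roi import DegenerateInputError

logger = logging.getLogger("pupilloc")


@dataclass(frozen=True)
class DerivativeSet:
    """First- and second-order Gaussian derivatives of one image at scale ``sigma``."""

    Lx: np.ndarray
    Ly: np.ndarray
    Lxx: np.ndarray
    Lyy: np.ndarray
    Lxy: np.ndarray
    sigma: float


@dataclass(frozen=True)
class CurvatureField:
    kappa: np.ndarray        # 1/pixels; only meaningful where valid
    valid_mask: np.ndarray   # False where the gradient is below the floor


@dataclass(frozen=True)
class DisplacementField:
    dx: np.ndarray
    dy: np.ndarray
    weight: np.ndarray       # nonnegative vote mass per pixel
    valid_mask: np.ndarray


@dataclass(frozen=True)
class PyramidConfig:
    """Difference-of-Gaussians pyramid and voting thresholds.

    ``max_displacement=None`` defaults to half the patch diagonal at vote
    time.  ``deriv_sigma`` is the scale of the Gaussian-derivative filters
    applied to each pyramid level.
    """

    n_octaves: int = 3
    n_intervals: int = 2
    base_sigma: float = 1.6
    deriv_sigma: float = 1.0
    max_displacement: float | None = None
    gradient_floor: float = 1e-4
    numerator_floor: float = 1e-6
    curvedness_weight: bool = True
    dark_only: bool = False

    def __post_init__(self) -> None:
        if self.n_octaves < 1 or self.n_intervals < 1:
            raise ValueError("n_octaves and n_intervals must be >= 1")
        if self.base_sigma <= 0 or self.deriv_sigma <= 0:
            raise ValueError("sigmas must be positive")


_MIN_OCTAVE_SIZE = 16


def _deriv_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative kernel with corrected discrete moments.

    The raw sampled kernels leave small nonzero moments (e.g. the second
    derivative responds ~1e-5 to a constant), which corrupts the curvature
    formula on nearly flat structures; enforcing sum = 0 and unit response to
    the matching monomial makes the filters exact on low-order polynomials.
    """
    radius = max(1, int(round(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    if order == 0:
        return g / g.sum()
    if order == 1:
        k = x * g
        return k / (k @ x)          # response to a unit ramp = 1
    if order == 2:
        k = (x**2 - (x**2 * g).sum() / g.sum()) * g   # sum(k) = 0
        return k / ((k @ x**2) / 2.0)                 # response to x^2 = 2
    raise ValueError("order must be 0, 1 or 2")


def gaussian_derivatives(image: np.ndarray, sigma: float) -> DerivativeSet:
    """Gaussian first/second derivative responses, reflect borders.

    Exact on polynomials of matching degree (away from the border region),
    which the closed-form curvature tests rely on.
    """
    image = np.asarray(image, dtype=np.float64)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if min(image.shape) <= 2 * sigma:
        raise DegenerateInputError(
            f"image {image.shape} smaller than the sigma={sigma} kernel support"
        )

    def g(oy: int, ox: int) -> np.ndarray:
        out = ndimage.correlate1d(image, _deriv_kernel(sigma, oy), axis=0,
                                  mode="reflect")
        return ndimage.correlate1d(out, _deriv_kernel(sigma, ox), axis=1,
                                   mode="reflect")

    return DerivativeSet(
        Lx=g(0, 1), Ly=g(1, 0), Lxx=g(0, 2), Lyy=g(2, 0), Lxy=g(1, 1), sigma=sigma,
    )


def _curvature_numerator(d: DerivativeSet) -> np.ndarray:
    return d.Ly**2 * d.Lxx - 2.0 * d.Lx * d.Ly * d.Lxy + d.Lx**2 * d.Lyy


def isophote_curvature(derivs: DerivativeSet, gradient_floor: float = 1e-4) -> CurvatureField:
    """Signed isophote curvature; masked where the gradient magnitude is negligible."""
    g2 = derivs.Lx**2 + derivs.Ly**2
    valid = np.sqrt(g2) >= gradient_floor
    kappa = np.zeros_like(g2)
    np.divide(-_curvature_numerator(derivs), g2**1.5, out=kappa, where=valid)
    return CurvatureField(kappa=kappa, valid_mask=valid)


def displacement_vectors(
    derivs: DerivativeSet,
    curvature: CurvatureField,
    max_displacement: float,
    numerator_floor: float = 1e-6,
    curvedness_weight: bool = True,
    dark_only: bool = False,
) -> DisplacementField:
    """Per-pixel vector to the center of the local osculating circle.

    Valid where the curvature denominator is above ``numerator_floor`` and the
    displacement magnitude does not exceed ``max_displacement``.  With
    ``dark_only`` set, only pixels whose isophote bends around a center darker
    than its surround keep their vote.
    """
    T = _curvature_numerator(derivs)
    g2 = derivs.Lx**2 + derivs.Ly**2
    valid = curvature.valid_mask & (np.abs(T) >= numerator_floor)
    scale = np.zeros_like(T)
    np.divide(-g2, T, out=scale, where=valid)
    dx = derivs.Lx * scale
    dy = derivs.Ly * scale
    mag = np.hypot(dx, dy)
    valid = valid & (mag <= max_displacement)
    if dark_only:
        valid = valid & (T > 0)
    if curvedness_weight:
        weight = np.sqrt(derivs.Lxx**2 + 2.0 * derivs.Lxy**2 + derivs.Lyy**2)
    else:
        weight = np.ones_like(T)
    weight = np.where(valid, weight, 0.0)
    dx = np.where(valid, dx, 0.0)
    dy = np.where(valid, dy, 0.0)
    return DisplacementField(dx=dx, dy=dy, weight=weight, valid_mask=valid)


def accumulate_votes(field: DisplacementField, extent: tuple[int, int]) -> np.ndarray:
    """Bilinearly splat each valid pixel's weight at its displaced position.

    ``extent`` is (height, width).  Vote mass falling outside the extent is
    dropped; everything else is conserved exactly.
    """
    h, w = extent
    if field.dx.shape != (h, w):
        raise ValueError("extent must equal the displacement field extent")
    votes = np.zeros((h, w))
    ys, xs = np.nonzero(field.valid_mask)
    if ys.size == 0:
        return votes
    tx = xs + field.dx[ys, xs]
    ty = ys + field.dy[ys, xs]
    wgt = field.weight[ys, xs]
    x0 = np.floor(tx).astype(np.int64)
    y0 = np.floor(ty).astype(np.int64)
    fx = tx - x0
    fy = ty - y0
    for dyc, dxc, frac in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yy = y0 + dyc
        xx = x0 + dxc
        inside = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        np.add.at(votes, (yy[inside], xx[inside]), wgt[inside] * frac[inside])
    return votes


def dog_pyramid(image: np.ndarray, config: PyramidConfig) -> list[tuple[np.ndarray, int]]:
    """Difference-of-Gaussians levels paired with their octave scale factor.

    Within octave ``o`` (image downsampled by 2^o), Gaussian blurs at
    sigma = base_sigma * 2^(i/n_intervals), i = 0..n_intervals, are differenced
    into n_intervals DoG levels, each normalized to zero mean and unit maximum
    absolute value.  Octaves stop early (with a warning) once the next image
    would fall below 16 pixels on a side.
    """
    image = np.asarray(image, dtype=np.float64)
    levels: list[tuple[np.ndarray, int]] = []
    current = image
    rel_sigmas = [config.base_sigma * 2.0 ** (i / config.n_intervals)
                  for i in range(config.n_intervals + 1)]
    for o in range(config.n_octaves):
        if min(current.shape) < _MIN_OCTAVE_SIZE:
            logger.warning(
                "stopping pyramid at %d octave(s): next level %s is below %d px",
                o, current.shape, _MIN_OCTAVE_SIZE,
            )
            break
        blurs = [ndimage.gaussian_filter(current, s, mode="reflect") for s in rel_sigmas]
        for i in range(config.n_intervals):
            dog = blurs[i + 1] - blurs[i]
            dog = dog - dog.mean()
            peak = np.abs(dog).max()
            if peak > 0:
                dog = dog / peak
            levels.append((dog, 2**o))
        current = blurs[-1][::2, ::2]
    if not levels:
        raise DegenerateInputError(
            f"image {image.shape} too small for even one {_MIN_OCTAVE_SIZE}-px octave"
        )
    return levels


def vote_space_for_level(level: np.ndarray, scale: int, config: PyramidConfig,
                         max_displacement: float) -> np.ndarray:
    """Derivative -> curvature -> displacement -> accumulate, on one pyramid level."""
    derivs = gaussian_derivatives(level, config.deriv_sigma)
    curv = isophote_curvature(derivs, config.gradient_floor)
    field = displacement_vectors(
        derivs, curv,
        max_displacement=max_displacement / scale,
        numerator_floor=config.numerator_floor,
        curvedness_weight=config.curvedness_weight,
        dark_only=config.dark_only,
    )
    return accumulate_votes(field, level.shape)


def multiscale_vote_space(patch: np.ndarray, config: PyramidConfig = PyramidConfig()) -> np.ndarray:
    """Sum of per-level vote accumulators, upsampled to the patch resolution."""
    patch = np.asarray(patch, dtype=np.float64)
    H, W = patch.shape
    max_disp = config.max_displacement
    if max_disp is None:
        max_disp = 0.5 * float(np.hypot(H, W))
    total = np.zeros((H, W))
    ys, xs = np.mgrid[0:H, 0:W].astype(np.float64)
    for level, scale in dog_pyramid(patch, config):
        acc = vote_space_for_level(level, scale, config, max_disp)
        if acc.shape != (H, W):
            # decimation keeps every 2^o-th pixel, so level pixel i sits at base
            # coordinate i*scale; upsample on that grid to avoid a half-pixel shift
            acc = ndimage.map_coordinates(acc, [ys / scale, xs / scale],
                                          order=1, mode="nearest")
        total += acc
    return total
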