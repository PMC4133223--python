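"""Multi-scale radial self-similarity map.

A region is radially self-similar when its intensities are (linearly) preserved
under reflections about mirror lines through its center.  At each pixel the
strength of that relationship is measured by the normalized (Pearson)
correlation between the intensities sampled on a circular neighborhood and the
intensities of the reflected sample set.  Averaging the coefficient over M
mirror-line orientations phi_m = k*pi/M gives the radial similarity score at
one radius; averaging again over a set of radii gives the multi-scale map.
The pupil — a dark disk, nearly invariant under every reflection through its
center — scores close to 1 at its center.

Sampling uses a regular polar grid (n_angular angles x n_radial rings), which
is exactly closed under the reflection group whenever n_angular is a multiple
of 2M, so reflected samples land on sampled locations and no resampling
asymmetry is introduced.  Intensities are read by cubic B-spline interpolation
(bilinear sampling is visibly anisotropic at the one-pixel ring and erodes the
score a radially symmetric field should reach at its center).
Both correlation vectors share a single mean: the average intensity of the
untransformed sample set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .roi import DegenerateInputError

#: Score assigned where a sample vector has zero variance (flat region): a
#: constant neighborhood carries no evidence of radial structure.
DEGENERATE_SCORE = 0.0

_VAR_EPS = 1e-18


@dataclass(frozen=True)
class DiskSampleSet:
    """Polar sample grid on a disk of radius ``r`` (offsets from the center)."""

    r: float
    rho: np.ndarray  # (S,) radial distances, in (0, r]
    phi: np.ndarray  # (S,) angles in [0, 2*pi)

    @property
    def dx(self) -> np.ndarray:
        return self.rho * np.cos(self.phi)

    @property
    def dy(self) -> np.ndarray:
        return self.rho * np.sin(self.phi)

    def __len__(self) -> int:
        return self.rho.size


@dataclass(frozen=True)
class SelfSimConfig:
    """Parameters of the self-similarity stage.

    ``n_radial=None`` uses one ring per pixel of radius (n_radial = r).
    ``margin`` must cover the largest radius so every sample stays in-image;
    the map is only computed for pixels at least ``margin`` away from every
    border.
    """

    n_orientations: int = 8
    radii: tuple[float, ...] = (2, 3, 4, 5, 6, 7, 8)
    margin: int = 10
    n_angular: int = 16
    n_radial: int | None = None

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("need at least 2 mirror-line orientations")
        if len(self.radii) < 1 or any(r <= 0 for r in self.radii):
            raise ValueError("radii must be a non-empty list of positive values")
        if list(self.radii) != sorted(self.radii):
            raise ValueError("radii must be strictly increasing")
        if self.margin < max(self.radii):
            raise ValueError("margin must be >= the largest radius")
        if self.n_angular < 4 or self.n_angular % 4:
            raise ValueError("n_angular must be a multiple of 4 and >= 4")
        if self.n_angular % (2 * self.n_orientations):
            raise ValueError(
                "n_angular must be a multiple of 2*n_orientations so the polar "
                "grid is closed under every mirror reflection"
            )

    @property
    def mirror_angles(self) -> np.ndarray:
        M = self.n_orientations
        return np.arange(M) * (np.pi / M)

    def rings_for(self, r: float) -> int:
        return self.n_radial if self.n_radial is not None else max(1, int(round(r)))


def build_disk_samples(r: float, n_angular: int, n_radial: int) -> DiskSampleSet:
    """Regular polar grid: rho_j = j*r/n_radial (j=1..n_radial), phi_i = i*2pi/n_angular."""
    if r <= 0:
        raise ValueError("radius must be positive")
    if n_angular < 4 or n_angular % 4:
        raise ValueError("n_angular must be a multiple of 4 and >= 4")
    if n_radial < 1:
        raise ValueError("n_radial must be >= 1")
    rho = np.repeat(np.arange(1, n_radial + 1) * (r / n_radial), n_angular)
    phi = np.tile(np.arange(n_angular) * (2 * np.pi / n_angular), n_radial)
    return DiskSampleSet(r=float(r), rho=rho, phi=phi)


def reflect(rho: np.ndarray, phi: np.ndarray, phi_m: float):
    """Reflect polar offsets about the mirror line at orientation ``phi_m``.

    (rho, phi) -> (rho, 2*phi_m - phi) mod 2pi; distances are preserved.
    """
    return rho, np.mod(2.0 * phi_m - phi, 2.0 * np.pi)


def rotate(rho: np.ndarray, phi: np.ndarray, theta: float):
    """Rotate polar offsets by ``theta`` about the disk center."""
    return rho, np.mod(phi + theta, 2.0 * np.pi)


#: Spline order for off-grid intensity lookups.  Cubic keeps the interpolant's
#: radial fidelity ~1e-8 on smooth radially symmetric fields, where bilinear
#: anisotropy alone costs ~1e-3 of correlation at the symmetry center.
SPLINE_ORDER = 3


def _sample(image: np.ndarray, cx: float, cy: float, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    coords = np.vstack([cy + dy, cx + dx])  # map_coordinates is (row, col)
    return ndimage.map_coordinates(np.asarray(image, dtype=np.float64), coords,
                                   order=SPLINE_ORDER, mode="mirror")


def _pearson_shared_mean(v0: np.ndarray, vt: np.ndarray) -> float:
    """Correlation with the mean taken over the untransformed sample set."""
    m = v0.mean()
    a, b = v0 - m, vt - m
    sa, sb = float(a @ a), float(b @ b)
    if sa <= _VAR_EPS or sb <= _VAR_EPS:
        return DEGENERATE_SCORE
    return float(np.clip((a @ b) / np.sqrt(sa * sb), -1.0, 1.0))


def _check_center(image: np.ndarray, center: tuple[float, float], r: float) -> None:
    H, W = image.shape
    cx, cy = center
    if not (cx >= r and cy >= r and cx <= W - 1 - r and cy <= H - 1 - r):
        raise ValueError(
            f"center {center} is closer than the sampling radius {r} to a border"
        )


def selfsim_coefficient(image: np.ndarray, center: tuple[float, float],
                        samples: DiskSampleSet, phi_m: float) -> float:
    """Self-similarity score at one center under one mirror-line orientation."""
    _check_center(image, center, samples.r)
    cx, cy = center
    v0 = _sample(image, cx, cy, samples.dx, samples.dy)
    rho_r, phi_r = reflect(samples.rho, samples.phi, phi_m)
    vt = _sample(image, cx, cy, rho_r * np.cos(phi_r), rho_r * np.sin(phi_r))
    return _pearson_shared_mean(v0, vt)


def rotation_coefficient(image: np.ndarray, center: tuple[float, float],
                         samples: DiskSampleSet, theta: float) -> float:
    """Self-similarity score under a rotation by ``theta``.

    On sample grids closed under both transform families this equals the
    reflection coefficient at phi_m = theta/2.
    """
    _check_center(image, center, samples.r)
    cx, cy = center
    v0 = _sample(image, cx, cy, samples.dx, samples.dy)
    rho_r, phi_r = rotate(samples.rho, samples.phi, theta)
    vt = _sample(image, cx, cy, rho_r * np.cos(phi_r), rho_r * np.sin(phi_r))
    return _pearson_shared_mean(v0, vt)


def radial_similarity(image: np.ndarray, center: tuple[float, float], r: float,
                      config: SelfSimConfig, transform: str = "reflection") -> float:
    """Mean self-similarity coefficient over all mirror-line orientations.

    With ``transform="rotation"`` the average runs over the rotation angles
    2*phi_m instead.  The two averages are mathematically identical on sample
    grids closed under both families (the individual coefficients are not).
    """
    samples = build_disk_samples(r, config.n_angular, config.rings_for(r))
    if transform == "reflection":
        coeffs = [selfsim_coefficient(image, center, samples, phi_m)
                  for phi_m in config.mirror_angles]
    elif transform == "rotation":
        coeffs = [rotation_coefficient(image, center, samples, 2.0 * phi_m)
                  for phi_m in config.mirror_angles]
    else:
        raise ValueError(f"unknown transform family: {transform!r}")
    return float(np.mean(coeffs))


@dataclass(frozen=True)
class SimilarityMap:
    """Per-pixel multi-scale self-similarity scores over the margin-trimmed interior."""

    values: np.ndarray
    offset: int  # position of values[0, 0] inside the patch, both axes


def multiscale_selfsim_map(patch: np.ndarray, config: SelfSimConfig = SelfSimConfig()) -> SimilarityMap:
    """Radial similarity averaged over the configured radii, at every interior pixel.

    The outermost ``margin`` pixels are discarded in each direction; the map's
    (0, 0) therefore sits at patch coordinate (margin, margin).
    """
    patch = np.asarray(patch, dtype=np.float64)
    H, W = patch.shape
    mg = config.margin
    if H <= 2 * mg or W <= 2 * mg:
        raise DegenerateInputError(
            f"patch {W}x{H} too small for a {mg}-pixel margin on every side"
        )
    h, w = H - 2 * mg, W - 2 * mg
    ys, xs = np.mgrid[mg:mg + h, mg:mg + w]
    coeffs = ndimage.spline_filter(patch, order=SPLINE_ORDER, mode="mirror")
    mirror = config.mirror_angles
    M = mirror.size

    acc = np.zeros((h, w))
    for r in config.radii:
        samples = build_disk_samples(r, config.n_angular, config.rings_for(r))
        S = len(samples)
        # offsets for the original grid and each reflected copy: ((1+M)*S,)
        dxs = [samples.dx]
        dys = [samples.dy]
        for phi_m in mirror:
            rho_r, phi_r = reflect(samples.rho, samples.phi, phi_m)
            dxs.append(rho_r * np.cos(phi_r))
            dys.append(rho_r * np.sin(phi_r))
        dx = np.concatenate(dxs)
        dy = np.concatenate(dys)
        coords = np.empty((2, dx.size, h, w))
        coords[0] = ys[None] + dy[:, None, None]
        coords[1] = xs[None] + dx[:, None, None]
        vals = ndimage.map_coordinates(coeffs, coords.reshape(2, -1),
                                       order=SPLINE_ORDER, mode="mirror",
                                       prefilter=False).reshape(dx.size, h, w)
        v0 = vals[:S]
        mean = v0.mean(axis=0)
        a = v0 - mean
        sa = np.einsum("shw,shw->hw", a, a)
        score_r = np.zeros((h, w))
        for k in range(M):
            b = vals[(k + 1) * S:(k + 2) * S] - mean
            sb = np.einsum("shw,shw->hw", b, b)
            num = np.einsum("shw,shw->hw", a, b)
            ok = (sa > _VAR_EPS) & (sb > _VAR_EPS)
            coeff = np.full((h, w), DEGENERATE_SCORE)
            np.divide(num, np.sqrt(sa * sb), out=coeff, where=ok)
            score_r += np.clip(coeff, -1.0, 1.0)
        acc += score_r / M
    return SimilarityMap(values=acc / len(config.radii), offset=mg)
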