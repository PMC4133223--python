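"""Independent brute-force oracles used by the test suite.

The transform geometry, sample enumeration and all statistics here are plain
Python loops with math.fsum accumulation, sharing no code path with the
vectorized package implementation.  Off-grid intensity lookup goes through
scipy's spline interpolation (a shared standard primitive, not part of the
statistic under test) so both routes read identical sample values.
"""

from __future__ import annotations

import math

from scipy import ndimage


def lookup(img, x: float, y: float) -> float:
    """Cubic-spline intensity lookup at real coordinates (x = column, y = row)."""
    return float(ndimage.map_coordinates(img, [[y], [x]], order=3, mode="mirror")[0])


def polar_grid(r: float, n_angular: int, n_radial: int):
    """[(rho, phi), ...] on the regular polar grid."""
    return [(j * r / n_radial, i * 2.0 * math.pi / n_angular)
            for j in range(1, n_radial + 1) for i in range(n_angular)]


def selfsim_coefficient(img, cx: float, cy: float, r: float, n_angular: int,
                        n_radial: int, phi_m: float) -> float:
    """Normalized correlation between a disk sample set and its mirror image."""
    grid = polar_grid(r, n_angular, n_radial)
    v0 = [lookup(img, cx + rho * math.cos(phi), cy + rho * math.sin(phi))
          for rho, phi in grid]
    vt = []
    for rho, phi in grid:
        phi_r = 2.0 * phi_m - phi
        vt.append(lookup(img, cx + rho * math.cos(phi_r), cy + rho * math.sin(phi_r)))
    mean = math.fsum(v0) / len(v0)
    a = [v - mean for v in v0]
    b = [v - mean for v in vt]
    sa = math.fsum(x * x for x in a)
    sb = math.fsum(x * x for x in b)
    if sa <= 1e-18 or sb <= 1e-18:
        return 0.0
    c = math.fsum(x * y for x, y in zip(a, b)) / math.sqrt(sa * sb)
    return max(-1.0, min(1.0, c))


def radial_similarity(img, cx, cy, r, n_angular, n_radial, n_orientations) -> float:
    coeffs = [selfsim_coefficient(img, cx, cy, r, n_angular, n_radial,
                                  k * math.pi / n_orientations)
              for k in range(n_orientations)]
    return math.fsum(coeffs) / len(coeffs)


def multiscale_map(img, radii, n_angular, n_orientations, margin):
    """Per-pixel mean radial similarity over radii (n_radial = round(r) rings)."""
    h, w = len(img), len(img[0])
    out = []
    for y in range(margin, h - margin):
        row = []
        for x in range(margin, w - margin):
            vals = [radial_similarity(img, x, y, r, n_angular, max(1, round(r)),
                                      n_orientations) for r in radii]
            row.append(math.fsum(vals) / len(vals))
        out.append(row)
    return out


def splat_votes(dx, dy, weight, valid, h: int, w: int):
    """Pure-Python bilinear vote splatting; returns (votes, dropped_mass)."""
    votes = [[0.0] * w for _ in range(h)]
    dropped = 0.0
    for y in range(len(valid)):
        for x in range(len(valid[0])):
            if not valid[y][x]:
                continue
            tx = x + dx[y][x]
            ty = y + dy[y][x]
            wt = weight[y][x]
            x0 = math.floor(tx)
            y0 = math.floor(ty)
            fx = tx - x0
            fy = ty - y0
            for oy, ox, frac in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                                 (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
                yy, xx = y0 + oy, x0 + ox
                if 0 <= yy < h and 0 <= xx < w:
                    votes[yy][xx] += wt * frac
                else:
                    dropped += wt * frac
    return votes, dropped
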