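"""Synthetic periocular patches with exact ground truth.

The generator renders the gross photometric structure of an eye region —
bright sclera, mid-gray iris disk, dark pupil disk — plus the nuisances that
make real pupil localization hard: eyelid occlusion from above, a specular
highlight on the cornea, a linear illumination gradient, and additive Gaussian
pixel noise.  Disk boundaries are anti-aliased by 4x4 subpixel area sampling
so gradients at the edges are smooth rather than staircased.  Every scene is
reproducible bit-for-bit from its parameter set and seed (NumPy PCG64).

Analytic fields (paraboloid, ramp, radially symmetric profile, constant) are
provided as closed-form oracles for the curvature and self-similarity stages.

For end-to-end runs through the face-cropping path, ``render_face_scene``
composes a left and a right patch onto a face-sized canvas at exactly the
anthropometric crop positions, so a face box covering the canvas crops back
the rendered patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import roi

_SUPERSAMPLE = 4
EYELID_DROP = 0.1  # eyelid level = sclera_level - EYELID_DROP (skin-like)


@dataclass(frozen=True)
class EyeSceneParams:
    """Full description of one synthetic periocular scene."""

    patch_w: int = 64
    patch_h: int = 48
    center: tuple[float, float] = (32.0, 24.0)  # (x, y), real pixels
    pupil_radius: float = 5.0
    iris_radius: float = 11.0
    sclera_level: float = 0.85
    iris_level: float = 0.45
    pupil_level: float = 0.08
    eyelid_coverage: float = 0.0  # fraction of iris height occluded from above
    highlight: tuple[tuple[float, float], float, float] | None = None  # (offset, radius, level)
    illum_gradient: tuple[float, float] = (0.0, 0.0)  # intensity per pixel (gx, gy)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pupil_radius < self.iris_radius):
            raise ValueError("need 0 < pupil_radius < iris_radius")
        if self.iris_radius >= min(self.patch_w, self.patch_h) / 2:
            raise ValueError("iris_radius must be below half the patch extent")
        if not (0 <= self.pupil_level < self.iris_level < self.sclera_level <= 1):
            raise ValueError("need pupil_level < iris_level < sclera_level in [0,1]")
        if not (0 <= self.eyelid_coverage < 1):
            raise ValueError("eyelid_coverage must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class LabeledPatch:
    image: np.ndarray
    truth_center: tuple[float, float]
    params: EyeSceneParams


def render_eye(params: EyeSceneParams) -> LabeledPatch:
    """Render one periocular patch; identical params give bit-identical images."""
    s = _SUPERSAMPLE
    w, h = params.patch_w, params.patch_h
    cx, cy = params.center
    # subpixel centers: pixel i covers [i-0.5, i+0.5); s samples per axis
    sub = (np.arange(s) + 0.5) / s - 0.5
    xs = (np.arange(w)[:, None] + sub[None, :]).ravel()  # (w*s,)
    ys = (np.arange(h)[:, None] + sub[None, :]).ravel()  # (h*s,)
    dist = np.hypot(xs[None, :] - cx, ys[:, None] - cy)  # (h*s, w*s)

    img = np.full(dist.shape, params.sclera_level)
    img[dist <= params.iris_radius] = params.iris_level
    img[dist <= params.pupil_radius] = params.pupil_level
    if params.highlight is not None:
        (ox, oy), hr, hl = params.highlight
        hdist = np.hypot(xs[None, :] - (cx + ox), ys[:, None] - (cy + oy))
        img[(hdist <= hr) & (dist <= params.iris_radius)] = hl
    if params.eyelid_coverage > 0:
        y_lid = cy + params.iris_radius * (2 * params.eyelid_coverage - 1)
        img[ys < y_lid, :] = params.sclera_level - EYELID_DROP
    # 4x4 area average back to pixel resolution
    img = img.reshape(h, s, w, s).mean(axis=(1, 3))

    gx, gy = params.illum_gradient
    if gx or gy:
        px = np.arange(w) - (w - 1) / 2
        py = np.arange(h) - (h - 1) / 2
        img = img + gx * px[None, :] + gy * py[:, None]
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return LabeledPatch(image=np.clip(img, 0.0, 1.0),
                        truth_center=params.center, params=params)


@dataclass(frozen=True)
class SceneRanges:
    """Uniform parameter ranges for dataset generation.

    Defaults span plausible pupil scales for a ~25 %-of-face-width patch and
    the nuisance magnitudes the detector is expected to withstand; centers are
    drawn at least ``center_margin`` pixels from every border so the truth
    stays inside the self-similarity map's interior.
    """

    patch_w: int = 64
    patch_h: int = 48
    pupil_radius: tuple[float, float] = (3.0, 8.0)
    iris_gap: tuple[float, float] = (4.0, 8.0)  # iris_radius - pupil_radius
    sclera_level: tuple[float, float] = (0.75, 0.95)
    iris_level: tuple[float, float] = (0.35, 0.55)
    pupil_level: tuple[float, float] = (0.02, 0.15)
    eyelid_coverage: tuple[float, float] = (0.0, 0.4)
    highlight_prob: float = 0.5
    highlight_radius: tuple[float, float] = (1.0, 2.0)
    highlight_level: float = 0.95
    illum_gradient: tuple[float, float] = (-0.002, 0.002)  # per component
    noise_sigma: tuple[float, float] = (0.0, 0.05)
    center_margin: int = 16

    def __post_init__(self) -> None:
        for name in ("pupil_radius", "iris_gap", "sclera_level", "iris_level",
                     "pupil_level", "eyelid_coverage", "highlight_radius",
                     "illum_gradient", "noise_sigma"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        if self.center_margin * 2 >= min(self.patch_w, self.patch_h):
            raise ValueError("center_margin leaves no interior for the eye center")


def draw_params(ranges: SceneRanges, rng: np.random.Generator, seed: int) -> EyeSceneParams:
    """Draw one scene's parameters from the given ranges."""
    u = lambda pair: float(rng.uniform(*pair))
    pr = u(ranges.pupil_radius)
    ir = pr + u(ranges.iris_gap)
    m = ranges.center_margin
    center = (float(rng.uniform(m, ranges.patch_w - 1 - m)),
              float(rng.uniform(m, ranges.patch_h - 1 - m)))
    # keep the intensity ordering even if the configured ranges touch
    sclera = u(ranges.sclera_level)
    iris = min(u(ranges.iris_level), sclera - 0.05)
    pupil = min(u(ranges.pupil_level), iris - 0.05)
    highlight = None
    if rng.uniform() < ranges.highlight_prob:
        hr = u(ranges.highlight_radius)
        highlight = ((float(rng.uniform(-pr, pr)), float(rng.uniform(-pr, pr))),
                     hr, ranges.highlight_level)
    return EyeSceneParams(
        patch_w=ranges.patch_w, patch_h=ranges.patch_h, center=center,
        pupil_radius=pr, iris_radius=ir,
        sclera_level=sclera, iris_level=iris, pupil_level=max(pupil, 0.0),
        eyelid_coverage=u(ranges.eyelid_coverage),
        highlight=highlight,
        illum_gradient=(u(ranges.illum_gradient), u(ranges.illum_gradient)),
        noise_sigma=u(ranges.noise_sigma),
        seed=seed,
    )


def render_dataset(n: int, ranges: SceneRanges = SceneRanges(),
                   master_seed: int = 0) -> list[LabeledPatch]:
    """Render ``n`` scenes with parameters drawn from ``ranges``, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(master_seed)
    patches = []
    for _ in range(n):
        seed = int(rng.integers(0, 2**31 - 1))
        patches.append(render_eye(draw_params(ranges, rng, seed)))
    return patches


@dataclass(frozen=True)
class AnalyticField:
    """Closed-form test image, min-max rescaled to [0, 1].

    ``raw_lo``/``raw_hi`` are the pre-rescale extrema, so raw values can be
    recovered as raw = lo + value * (hi - lo).
    """

    image: np.ndarray
    raw_lo: float
    raw_hi: float
    center: tuple[float, float]


def render_analytic(kind: str, size: int, center: tuple[float, float] | None = None,
                    profile=None) -> AnalyticField:
    """Evaluate a named closed-form field on a size x size pixel grid.

    Kinds: ``paraboloid`` ((x-cx)^2 + (y-cy)^2), ``ramp`` (I proportional to y),
    ``radial`` (profile(rho), default cos(rho/4)), ``constant``.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    if center is None:
        center = ((size - 1) / 2, (size - 1) / 2)
    cx, cy = center
    x = np.arange(size)[None, :] - cx
    y = np.arange(size)[:, None] - cy
    if kind == "paraboloid":
        raw = x**2 + y**2 + np.zeros((size, size))
    elif kind == "ramp":
        raw = np.broadcast_to(np.arange(size, dtype=float)[:, None], (size, size)).copy()
    elif kind == "radial":
        rho = np.hypot(x, y)
        raw = (profile or (lambda r: np.cos(r / 4.0)))(rho)
    elif kind == "constant":
        raw = np.full((size, size), 0.5)
    else:
        raise ValueError(f"unknown analytic field kind: {kind!r}")
    lo, hi = float(raw.min()), float(raw.max())
    image = np.full_like(raw, 0.5) if hi == lo else (raw - lo) / (hi - lo)
    return AnalyticField(image=image, raw_lo=lo, raw_hi=hi, center=center)


# ---------------------------------------------------------------------------
# Face-canvas composition: places a left and right patch exactly where the
# anthropometric crop rule will recover them, enabling end-to-end runs through
# the cropping path with known truth in canvas (source) coordinates.

SKIN_LEVEL = 0.75


@dataclass(frozen=True)
class FaceScene:
    canvas: np.ndarray
    box: roi.FaceBox
    left_truth: tuple[float, float]   # canvas coordinates
    right_truth: tuple[float, float]


def render_face_scene(left: LabeledPatch, right: LabeledPatch) -> FaceScene:
    """Paste two rendered patches onto a face-sized canvas.

    The canvas is sized so a face box covering it crops patches of exactly the
    rendered size at the standard anthropometric positions.
    """
    if left.params.patch_w != right.params.patch_w or left.params.patch_h != right.params.patch_h:
        raise ValueError("left and right patches must share dimensions")
    pw, ph = left.params.patch_w, left.params.patch_h
    fw = round(pw / roi.LEFT_EYE_FRACTIONS[2])
    fh = round(ph / roi.LEFT_EYE_FRACTIONS[3])
    canvas = np.full((fh, fw), SKIN_LEVEL)
    box = roi.FaceBox(0, 0, fw, fh)
    truths = {}
    for side, patch in (("left", left), ("right", right)):
        probe = roi.crop_periocular(canvas, box, side)
        ox, oy = probe.offset_x, probe.offset_y
        canvas[oy:oy + ph, ox:ox + pw] = patch.image
        truths[side] = (patch.truth_center[0] + ox, patch.truth_center[1] + oy)
    return FaceScene(canvas=canvas, box=box,
                     left_truth=truths["left"], right_truth=truths["right"])
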