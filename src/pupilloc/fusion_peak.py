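"""Fusion of the two evidence maps and peak selection.

The self-similarity map and the vote accumulator are each min-max normalized
to [0, 1], pointwise summed over the margin-trimmed region, smoothed with a
Gaussian kernel (so broad coherent hills beat isolated noise spikes), and the
peak of the smoothed joint space is reported as the pupil center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .isophote_voting import PyramidConfig, multiscale_vote_space
from .self_similarity import SelfSimConfig, SimilarityMap, multiscale_selfsim_map

logger = logging.getLogger("pupilloc")

DEFAULT_SMOOTHING_SIGMA = 3.0


@dataclass(frozen=True)
class JointSpace:
    values: np.ndarray
    offset: int  # margin inherited from the similarity map
    smoothing_sigma: float = 0.0


@dataclass(frozen=True)
class PupilEstimate:
    """Located eye center in patch coordinates (x = column, y = row)."""

    x: int
    y: int
    score: float
    side: str = "unknown"
    low_confidence: bool = False


def normalize01(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant map becomes all zeros.

    Zeros (not 0.5) keep a signal-free stage neutral in the pointwise sum.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def fuse(ss: SimilarityMap, votes: np.ndarray,
         w_selfsim: float = 1.0, w_votes: float = 1.0) -> JointSpace:
    """Pointwise sum of the normalized maps over the similarity map's extent."""
    votes = np.asarray(votes, dtype=np.float64)
    h, w = ss.values.shape
    off = ss.offset
    if votes.shape[0] < off + h or votes.shape[1] < off + w:
        raise ValueError(
            f"vote accumulator {votes.shape} does not cover the similarity "
            f"map extent {h}x{w} at offset {off}"
        )
    cropped = votes[off:off + h, off:off + w]
    joint = w_selfsim * normalize01(ss.values) + w_votes * normalize01(cropped)
    return JointSpace(values=joint, offset=off)


def smooth(space: JointSpace, sigma: float = DEFAULT_SMOOTHING_SIGMA) -> JointSpace:
    """Gaussian smoothing with reflect borders; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    values = space.values if sigma == 0 else ndimage.gaussian_filter(
        space.values, sigma, mode="reflect")
    return JointSpace(values=values, offset=space.offset, smoothing_sigma=sigma)


def locate_peak(space: JointSpace, side: str = "unknown") -> PupilEstimate:
    """Argmax of the joint space, ties broken by smallest row then column."""
    if space.values.size == 0:
        raise ValueError("empty joint space")
    iy, ix = np.unravel_index(int(np.argmax(space.values)), space.values.shape)
    score = float(space.values[iy, ix])
    low = score <= 0.0
    if low:
        logger.warning("joint space has no positive peak; low-confidence estimate")
    return PupilEstimate(x=int(ix) + space.offset, y=int(iy) + space.offset,
                         score=score, side=side, low_confidence=low)


def detect_pupil(
    patch: np.ndarray,
    ss_config: SelfSimConfig = SelfSimConfig(),
    pyr_config: PyramidConfig = PyramidConfig(),
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
    w_selfsim: float = 1.0,
    w_votes: float = 1.0,
    side: str = "unknown",
) -> PupilEstimate:
    """End-to-end pupil localization on one periocular patch.

    ``w_selfsim`` / ``w_votes`` weight the two normalized evidence maps in the
    joint sum (1:1 by default); setting one to zero evaluates the other map
    alone under the same smoothing and peak rule.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if w_selfsim != 0.0:
        ss = multiscale_selfsim_map(patch, ss_config)
    else:  # zero map with the right extent, so the offset bookkeeping is uniform
        mg = ss_config.margin
        ss = SimilarityMap(
            values=np.zeros((patch.shape[0] - 2 * mg, patch.shape[1] - 2 * mg)),
            offset=mg,
        )
    if w_votes != 0.0:
        votes = multiscale_vote_space(patch, pyr_config)
    else:
        votes = np.zeros_like(patch)
    joint = fuse(ss, votes, w_selfsim=w_selfsim, w_votes=w_votes)
    return locate_peak(smooth(joint, smoothing_sigma), side=side)
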