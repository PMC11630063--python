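"""Heart-candidate segmentation from temporal intensity change.

After per-frame brightness normalization, pixels that change strongly over
time are found by a rolling absolute difference (default window: 2
frames) of Gaussian-blurred frames. The temporal mean of those differences
is a per-pixel motion score; triangle thresholding splits it into
static/moving, morphological opening removes specks, and connected
components of substantial size become the initial regions of interest —
the candidate heart regions handed to the spectral stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_triangle
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening

from .config import DiffConfig, MaskConfig
from .errors import NoCallError
from .video_io import FrameStack

logger = logging.getLogger(__name__)

#: frames narrower than this intensity spread are treated as constant.
_CONST_EPS = 1e-12


@dataclass
class MaskComponent:
    label: int
    area: int
    coords: np.ndarray  # (area, 2) pixel coordinates


@dataclass
class MotionMask:
    """Boolean mask of moving pixels with its connected components."""

    mask: np.ndarray
    components: list[MaskComponent] = field(default_factory=list)
    window_size: int = 2
    score: np.ndarray | None = None  # per-pixel motion score (diagnostics)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def normalize_brightness(stack: FrameStack) -> FrameStack:
    """Affinely rescale each frame to a common brightness and contrast.

    Each frame is mapped so its 1st–99th percentile spread becomes 0.9
    (i.e. spans [0.05, 0.95]) and its median becomes 0.5. Pure per-frame
    gain changes (illumination flicker) are removed exactly, pixel order
    within a frame is preserved, and the map is idempotent. The location
    anchor is the median, not the mean: the mean of a frame contains the
    heart's own intensity modulation, and subtracting it would inject an
    antiphase copy of the beat into every static pixel. Constant frames
    are left unchanged and logged.
    """
    frames = stack.frames
    p1, med, p99 = np.percentile(frames, [1, 50, 99], axis=(1, 2))
    spread = p99 - p1
    degenerate = spread <= _CONST_EPS
    if degenerate.any():
        logger.warning(
            "normalize_brightness: %d constant frame(s) left unchanged",
            int(degenerate.sum()),
        )
    scale = np.where(degenerate, 1.0, 0.9 / np.maximum(spread, _CONST_EPS))
    offset = np.where(degenerate, 0.0, 0.5 - scale * med)
    out = frames * scale[:, None, None] + offset[:, None, None]
    return stack.with_frames(out)


def rolling_abs_difference(
    stack: FrameStack,
    window: int = 2,
    blur_sigma: float = 2.0,
) -> np.ndarray:
    """Absolute rolling difference of Gaussian-blurred frames.

    ``out[t] = |blur(frames[t + window - 1]) - blur(frames[t])|`` for
    ``t = 0 .. n_frames - window``, so the output holds
    ``n_frames - window + 1`` difference frames.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = stack.n_frames
    if window > n:
        raise ValueError(f"window {window} exceeds frame count {n}")
    blurred = ndimage.gaussian_filter(stack.frames, sigma=(0.0, blur_sigma, blur_sigma))
    return np.abs(blurred[window - 1 :] - blurred[: n - window + 1])


def triangle_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Triangle-algorithm threshold of a 1-D intensity sample.

    Builds the histogram, draws the line from its peak to the farthest
    nonzero tail bin, and returns the bin maximizing the perpendicular
    distance to that line — well suited to the heavily skewed motion-score
    histograms this pipeline produces (most pixels are static).
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    if values.max() - values.min() <= _CONST_EPS:
        raise ValueError("constant sample has no threshold")
    return float(threshold_triangle(values, nbins=nbins))


def build_motion_mask(
    diff: np.ndarray,
    min_object_px: int = 50,
    opening_radius: int = 2,
    window_size: int = 2,
) -> MotionMask:
    """Threshold the temporal-mean motion score into cleaned components.

    The rolling differences are aggregated by temporal mean (robust to
    single-frame glitches), triangle-thresholded, opened with a disc of
    ``opening_radius``, and components below ``min_object_px`` pixels are
    dropped. Components use 8-connectivity.

    Raises
    ------
    NoCallError
        ``no_motion`` when nothing survives the cleaning.
    """
    diff = np.asarray(diff)
    if diff.ndim != 3 or diff.shape[0] == 0:
        raise ValueError(f"expected a (time, h, w) difference array, got {diff.shape}")
    score = diff.mean(axis=0)
    if score.max() - score.min() <= _CONST_EPS:
        raise NoCallError("no_motion", "motion score is constant (static video)")
    thr = triangle_threshold(score.ravel())
    mask = score > thr
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius)).astype(bool)
    labels = label(mask, connectivity=2)
    components = []
    keep = np.zeros_like(mask)
    for prop in regionprops(labels):
        if prop.area >= min_object_px:
            components.append(
                MaskComponent(label=prop.label, area=int(prop.area), coords=prop.coords)
            )
            keep[labels == prop.label] = True
    if not components:
        raise NoCallError("no_motion", "no moving region of substantial size")
    components.sort(key=lambda c: c.area, reverse=True)
    return MotionMask(mask=keep, components=components, window_size=window_size, score=score)


def motion_mask_from_stack(stack: FrameStack, diff_cfg: DiffConfig | None = None,
                           mask_cfg: MaskConfig | None = None) -> MotionMask:
    """Convenience: normalization is assumed done; diff + threshold + clean."""
    diff_cfg = diff_cfg or DiffConfig()
    mask_cfg = mask_cfg or MaskConfig()
    diff = rolling_abs_difference(stack, diff_cfg.window, diff_cfg.blur_sigma)
    return build_motion_mask(
        diff,
        min_object_px=mask_cfg.min_object_px,
        opening_radius=mask_cfg.opening_radius,
        window_size=diff_cfg.window,
    )
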