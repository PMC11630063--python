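"""Embryo localization and cropping.

The embryo is the one large, roughly circular object in the well. Each
sampled frame contributes one candidate circle (Canny edges followed by a
circular Hough transform); the detected location is the most common circle
across frames after quantizing centers to 8-px and radii to 4-px cells,
which makes "most common" well defined on continuous outputs. The stack is
then cropped to the circle's bounding box plus a margin, so the expensive
per-pixel spectral analysis never sees well-background pixels.

Corrupted acquisitions show up as runs of all-black frames; a stack is
rejected outright when the empty-frame fraction reaches 5%.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.filters import sobel, threshold_otsu
from skimage.transform import downscale_local_mean, hough_circle, hough_circle_peaks

from .config import CropConfig, HoughConfig
from .errors import NoCallError
from .video_io import FrameStack

logger = logging.getLogger(__name__)

_CENTER_BIN_PX = 8
_RADIUS_BIN_PX = 4


@dataclass
class EmbryoRegion:
    """A detected embryo circle and the crop window derived from it."""

    center: tuple[float, float]  # (row, col) px
    radius: float  # px
    crop_window: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max), half-open
    n_frames_voting: int

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        r0, r1, c0, c1 = self.crop_window
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"degenerate crop window {self.crop_window}")


def count_empty_frames(stack: FrameStack, empty_threshold: float = 0.01) -> int:
    """Number of frames whose mean intensity is below ``empty_threshold``."""
    means = stack.frames.mean(axis=(1, 2))
    return int((means < empty_threshold).sum())


def gate_empty_fraction(
    stack: FrameStack,
    max_fraction: float = 0.05,
    empty_threshold: float = 0.01,
) -> bool:
    """True (pass) iff the empty-frame fraction is below ``max_fraction``.

    The boundary is rejecting: a stack with exactly 5% empty frames fails.
    """
    n_empty = count_empty_frames(stack, empty_threshold)
    return n_empty / stack.n_frames < max_fraction


def fill_empty_frames(stack: FrameStack, empty_threshold: float = 0.01) -> FrameStack:
    """Replace surviving black frames with the nearest preceding good frame.

    Applied only after the empty-frame gate passed, so at most a few
    frames change; holding the last good frame keeps the temporal grid
    (and hence the frequency resolution) intact. Leading black frames
    take the first good frame.
    """
    means = stack.frames.mean(axis=(1, 2))
    empty = means < empty_threshold
    if not empty.any():
        return stack
    good = np.flatnonzero(~empty)
    if good.size == 0:
        raise NoCallError("corrupted_video", "every frame is empty")
    frames = stack.frames.copy()
    # index of the latest good frame at or before t (first good one for leaders)
    idx = np.maximum.accumulate(np.where(~empty, np.arange(stack.n_frames), -1))
    idx[idx < 0] = good[0]
    frames[empty] = frames[idx[empty]]
    return stack.with_frames(frames)


def _frame_circle(frame: np.ndarray, radii: np.ndarray) -> tuple[float, float, float] | None:
    """Best Hough circle of one frame as (row, col, radius), or None."""
    grad = sobel(frame)
    if grad.max() <= 0:
        return None
    high = threshold_otsu(grad)
    edges = canny(frame, sigma=2.0, low_threshold=0.5 * high, high_threshold=high)
    if not edges.any():
        return None
    accum = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] <= 0:
        return None
    return float(cy[0]), float(cx[0]), float(rad[0])


def locate_embryo(
    stack: FrameStack,
    radius_range: tuple[float, float] | None = None,
    hough: HoughConfig | None = None,
    crop: CropConfig | None = None,
    empty_threshold: float = 0.01,
) -> EmbryoRegion:
    """Detect the embryo circle by modal vote across sampled frames.

    ``radius_range`` is in pixels; when omitted it is derived from the
    configured fractions of the short image side. Every ``frame_stride``-th
    non-empty frame votes; candidate circles are binned (8-px centers,
    4-px radii) and the members of the modal bin are averaged. Ties pick
    the lexicographically smallest (row, col, radius) bin for determinism.

    Raises
    ------
    NoCallError
        ``no_embryo`` when no frame yields a circle.
    """
    hough = hough or HoughConfig()
    crop = crop or CropConfig()
    h, w = stack.frame_shape
    if radius_range is None:
        short = min(h, w)
        radius_range = (hough.radius_range[0] * short, hough.radius_range[1] * short)
    ds = max(1, int(hough.downscale))
    r_lo = max(3, int(round(radius_range[0] / ds)))
    r_hi = max(r_lo + 1, int(round(radius_range[1] / ds)))
    radii = np.arange(r_lo, r_hi + 1, max(1, hough.radius_step // ds))

    means = stack.frames.mean(axis=(1, 2))
    candidates = np.flatnonzero(means >= empty_threshold)
    if candidates.size == 0:
        raise NoCallError("no_embryo", "no non-empty frame to vote on")
    voting = candidates[:: hough.frame_stride]

    circles: list[tuple[float, float, float]] = []
    for t in voting:
        frame = stack.frames[t]
        if ds > 1:
            frame = downscale_local_mean(frame, (ds, ds))
        found = _frame_circle(frame, radii)
        if found is not None:
            # map the reduced-resolution circle back to full coordinates
            circles.append(
                (
                    found[0] * ds + (ds - 1) / 2.0,
                    found[1] * ds + (ds - 1) / 2.0,
                    found[2] * ds,
                )
            )
    if not circles:
        raise NoCallError("no_embryo", "Hough transform found no circle in any frame")

    bins = Counter(
        (
            int(r // _CENTER_BIN_PX),
            int(c // _CENTER_BIN_PX),
            int(rad // _RADIUS_BIN_PX),
        )
        for r, c, rad in circles
    )
    top = max(bins.values())
    modal_bin = min(b for b, n in bins.items() if n == top)
    members = [
        circ
        for circ in circles
        if (
            int(circ[0] // _CENTER_BIN_PX),
            int(circ[1] // _CENTER_BIN_PX),
            int(circ[2] // _RADIUS_BIN_PX),
        )
        == modal_bin
    ]
    row, col, radius = (float(np.mean(v)) for v in zip(*members))

    margin = crop.margin_fraction * radius
    r0 = int(np.clip(np.floor(row - radius - margin), 0, h - 1))
    r1 = int(np.clip(np.ceil(row + radius + margin) + 1, r0 + 1, h))
    c0 = int(np.clip(np.floor(col - radius - margin), 0, w - 1))
    c1 = int(np.clip(np.ceil(col + radius + margin) + 1, c0 + 1, w))
    logger.debug(
        "embryo at (%.1f, %.1f) r=%.1f from %d/%d voting frames",
        row, col, radius, len(members), len(voting),
    )
    return EmbryoRegion(
        center=(row, col),
        radius=radius,
        crop_window=(r0, r1, c0, c1),
        n_frames_voting=len(voting),
    )


def crop_stack(stack: FrameStack, region: EmbryoRegion) -> FrameStack:
    """Restrict every frame to the region's crop window."""
    r0, r1, c0, c1 = region.crop_window
    h, w = stack.frame_shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"crop window {region.crop_window} outside frame {(h, w)}")
    return stack.with_frames(stack.frames[:, r0:r1, c0:c1])
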