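"""Post-hoc quality control.

The dominant error mode of the spectral estimate is the second harmonic:
an axial view registers both chamber contractions per beat, so one of two
technical replicates ("loops") of the same embryo can read twice the other.
When the lower reading also agrees with the cohort's typical rate, the
doubled one is halved and the pair averaged; concordant pairs are simply
averaged; anything else is a discordant no-call. A configurable minimum
rate (default 70 bpm) discards physiologically implausible calls, and
whole-embryo movement early in the movie voids the measurement (later
movement truncates the analysis window instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .config import QcConfig
from .spectral import HeartbeatEstimate
from .video_io import FrameStack

logger = logging.getLogger(__name__)


@dataclass
class LoopPair:
    """All loops of one well plus the cohort reference rate."""

    well_id: str
    estimates: list[HeartbeatEstimate]
    group_reference_bpm: float | None = None


@dataclass
class Correction:
    bpm: float | None
    flag: str  # halved | averaged | both_halved | discordant | single_loop


def compute_group_reference(bpms: list[float], min_group: int = 3) -> float | None:
    """Robust cohort-typical rate: the (lower) median of called bpms.

    The median resists contamination by uncorrected doubles; with an even
    count the lower middle value is taken, for determinism. Groups smaller
    than ``min_group`` get no reference (the harmonic check then falls back
    to the ratio test alone).
    """
    called = sorted(b for b in bpms if b is not None and np.isfinite(b))
    if len(called) < min_group:
        return None
    return float(called[(len(called) - 1) // 2])


def harmonic_correct(
    pair: LoopPair,
    ratio_tol: float = 0.15,
    group_tol: float = 0.20,
) -> Correction:
    """Resolve the two-loop second-harmonic artifact for one well.

    With called loops (lo <= hi) and group reference g:

    - ``halved``: hi is about twice lo and lo agrees with g
      -> (hi/2 + lo)/2
    - ``averaged``: both agree with g -> (hi + lo)/2
    - ``both_halved``: both are about twice g -> (hi/2 + lo/2)/2
    - ``discordant``: anything else -> no-call

    "About twice" means |hi/lo - 2| <= ratio_tol, generous enough to absorb
    FFT bin discretization; agreement with g means a relative gap of at
    most group_tol. Without a reference (small cohorts) only the ratio
    tests run: a pair near ratio 2 is halved, near ratio 1 averaged.
    A single called loop passes through as ``single_loop``.
    """
    called = [e.bpm for e in pair.estimates if e.called]
    if len(called) == 0:
        return Correction(bpm=None, flag="discordant")
    if len(called) == 1:
        return Correction(bpm=float(called[0]), flag="single_loop")
    if len(called) > 2:
        raise ValueError("harmonic correction is defined for at most two loops")
    lo, hi = sorted(called)
    g = pair.group_reference_bpm
    ratio_is_double = abs(hi / lo - 2.0) <= ratio_tol
    if g is not None:
        lo_in_group = abs(lo - g) / g <= group_tol
        hi_in_group = abs(hi - g) / g <= group_tol
        lo_is_double = abs(lo / 2.0 - g) / g <= group_tol
        hi_is_double = abs(hi / 2.0 - g) / g <= group_tol
        if ratio_is_double and lo_in_group:
            return Correction(bpm=(hi / 2.0 + lo) / 2.0, flag="halved")
        if lo_in_group and hi_in_group:
            return Correction(bpm=(hi + lo) / 2.0, flag="averaged")
        if lo_is_double and hi_is_double:
            return Correction(bpm=(hi / 2.0 + lo / 2.0) / 2.0, flag="both_halved")
        return Correction(bpm=None, flag="discordant")
    logger.info("well %s: no group reference, ratio test only", pair.well_id)
    if ratio_is_double:
        return Correction(bpm=(hi / 2.0 + lo) / 2.0, flag="halved")
    if abs(hi / lo - 1.0) <= ratio_tol:
        return Correction(bpm=(hi + lo) / 2.0, flag="averaged")
    return Correction(bpm=None, flag="discordant")


def apply_bpm_floor(estimate: HeartbeatEstimate, floor_bpm: float = 70.0) -> HeartbeatEstimate:
    """Discard calls below the experiment's plausibility floor.

    The boundary is inclusive: a call exactly at the floor is retained.
    """
    if not estimate.called or estimate.bpm >= floor_bpm:
        return estimate
    return replace(
        estimate,
        bpm=None,
        freq_hz=None,
        error_code="below_floor",
        qc_flags=estimate.qc_flags | {"below_floor"},
    )


def detect_movement(
    stack: FrameStack,
    displacement_fraction: float = 0.05,
) -> int | None:
    """First frame index at which the whole field jumps, or None.

    Consecutive frames are registered by FFT cross-correlation (the
    translation maximizing the circular cross-correlation, computed for
    all frame pairs in one batch); a shift larger than
    ``displacement_fraction`` of the crop width flags a whole-embryo
    movement. Heartbeat motion itself is local and produces near-zero
    global shifts.
    """
    frames = stack.frames - stack.frames.mean(axis=(1, 2), keepdims=True)
    n, h, w = frames.shape
    threshold = displacement_fraction * w
    spectra = np.fft.rfft2(frames)
    cross = np.fft.irfft2(spectra[:-1] * np.conj(spectra[1:]), s=(h, w))
    flat = cross.reshape(n - 1, -1).argmax(axis=1)
    dr, dc = np.unravel_index(flat, (h, w))
    # wrap circular shifts into the symmetric range
    dr = np.where(dr > h // 2, dr - h, dr)
    dc = np.where(dc > w // 2, dc - w, dc)
    moved = np.flatnonzero(np.hypot(dr, dc) > threshold)
    return int(moved[0]) + 1 if moved.size else None


@dataclass
class MovementDecision:
    flag: str | None  # None | early_movement | late_movement
    event_frame: int | None
    truncate_at: int | None  # analyze frames[:truncate_at] when late


def movement_qc(
    stack: FrameStack,
    qc_cfg: QcConfig | None = None,
) -> MovementDecision:
    """Classify embryo movement against the minimum stable window.

    Movement before ``min_stable_seconds`` (default 5 s) leaves too short a
    frequency profile and voids the measurement; later movement truncates
    the analysis to the stable prefix (at the cost of coarser frequency
    resolution).
    """
    qc_cfg = qc_cfg or QcConfig()
    event = detect_movement(stack, qc_cfg.movement_px_fraction)
    if event is None:
        return MovementDecision(flag=None, event_frame=None, truncate_at=None)
    if event / stack.fps < qc_cfg.min_stable_seconds:
        return MovementDecision(flag="early_movement", event_frame=event, truncate_at=None)
    return MovementDecision(flag="late_movement", event_frame=event, truncate_at=event)
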