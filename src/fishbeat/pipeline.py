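"""End-to-end plate processing.

``analyze_stack`` runs one well/loop movie through the full chain:
empty-frame gate -> embryo localization and crop -> movement QC ->
brightness normalization -> motion mask -> per-pixel FFT -> periodic
region -> KDE heart-rate estimate -> phase clustering. ``run_plate``
batches this over a discovered plate, applies the cross-loop harmonic
correction and the bpm floor, and writes the single results CSV. A failed
well never aborts the plate; it becomes a no-call row with an error code.
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace

import numpy as np

from . import embryo, motion, qc, spectral, video_io
from .config import PipelineConfig
from .errors import NoCallError
from .spectral import HeartbeatEstimate
from .video_io import DEFAULT_LAYOUT_PATTERN, FrameStack, PlateResult

logger = logging.getLogger(__name__)


def analyze_stack(stack: FrameStack, config: PipelineConfig | None = None) -> HeartbeatEstimate:
    """Estimate the heart rate of one well/loop movie.

    Raises
    ------
    NoCallError
        With the stage-specific error code (``corrupted_video``,
        ``no_embryo``, ``early_movement``, ``no_motion``,
        ``no_periodic_region``) when the movie cannot be called.
    """
    config = config or PipelineConfig()
    if not embryo.gate_empty_fraction(
        stack, config.max_empty_fraction, config.empty_threshold
    ):
        raise NoCallError("corrupted_video", "too many empty frames")
    stack = embryo.fill_empty_frames(stack, config.empty_threshold)

    region = embryo.locate_embryo(
        stack,
        hough=config.hough,
        crop=config.crop,
        empty_threshold=config.empty_threshold,
    )
    cropped = embryo.crop_stack(stack, region)

    movement = qc.movement_qc(cropped, config.qc)
    flags: set[str] = set()
    if movement.flag == "early_movement":
        raise NoCallError("early_movement", f"embryo moved at frame {movement.event_frame}")
    if movement.flag == "late_movement":
        flags.add("late_movement")
        cropped = cropped.with_frames(cropped.frames[: movement.truncate_at])

    normalized = motion.normalize_brightness(cropped)
    mmask = motion.motion_mask_from_stack(normalized, config.diff, config.mask)
    spec = spectral.pixel_spectra(normalized, mmask)
    snr_max = config.ft.snr_max if config.ft.snr_max is not None else np.inf
    pmask = spectral.periodic_mask(spec, config.ft.band_hz, (config.ft.snr_min, snr_max))
    estimate = spectral.estimate_heart_rate(
        spec,
        pmask,
        config.kde.bandwidth_hz,
        config.kde.grid_points,
        amplitude_weighted=config.kde.amplitude_weighted,
    )
    if estimate.n_pixels >= config.phase.min_pixels:
        clusters, spread = spectral.phase_map(spec, pmask, config.phase.max_clusters)
        estimate = replace(estimate, phase_clusters=clusters, phase_spread_rad=spread)
    estimate.qc_flags |= flags
    return estimate


def _no_call(code: str) -> HeartbeatEstimate:
    return HeartbeatEstimate(bpm=None, error_code=code)


def run_plate(
    input_dir,
    fps: float,
    output_path=None,
    config: PipelineConfig | None = None,
    plate_id: str = "plate",
    layout_pattern: str = DEFAULT_LAYOUT_PATTERN,
    apply_harmonic_correction: bool = True,
) -> PlateResult:
    """Process every discovered well/loop of a plate into one results table.

    The harmonic correction runs after all loops complete, using the
    cohort median of called rates as the group reference; the bpm floor is
    applied last. When ``output_path`` is given the CSV is also written.
    """
    config = config or PipelineConfig()
    groups = video_io.discover_plate(input_dir, layout_pattern)
    estimates: dict[tuple[str, int], HeartbeatEstimate] = {}
    for (well_id, loop_id), paths in groups.items():
        t0 = time.perf_counter()
        try:
            stack = video_io.load_frame_stack(paths, fps, well_id, loop_id)
            est = analyze_stack(stack, config)
        except NoCallError as exc:
            est = _no_call(exc.error_code)
        estimates[(well_id, loop_id)] = est
        logger.info(
            "well %s loop %d: bpm=%s roi=%d snr=%.3g (%.2f s)",
            well_id,
            loop_id,
            f"{est.bpm:.1f}" if est.called else f"no-call:{est.error_code}",
            est.n_pixels,
            est.snr_median or 0.0,
            time.perf_counter() - t0,
        )

    wells = sorted({w for w, _ in estimates})
    n_loops = max(sum(1 for k in estimates if k[0] == w) for w in wells)
    corrections: dict[str, qc.Correction] = {}
    if apply_harmonic_correction and n_loops > 1:
        reference = qc.compute_group_reference(
            [e.bpm for e in estimates.values() if e.called]
        )
        for well_id in wells:
            loop_ests = [estimates[k] for k in sorted(estimates) if k[0] == well_id]
            if sum(e.called for e in loop_ests) == 0:
                continue
            if sum(e.called for e in loop_ests) > 2:
                logger.warning("well %s: >2 called loops, correction skipped", well_id)
                continue
            corrections[well_id] = qc.harmonic_correct(
                qc.LoopPair(well_id, loop_ests, reference),
                config.qc.ratio_tol,
                config.qc.group_tol,
            )

    result = PlateResult(plate_id=plate_id)
    for (well_id, loop_id), est in sorted(estimates.items()):
        bpm = est.bpm
        status = "ok"
        error_code = est.error_code
        if est.called and well_id in corrections:
            corr = corrections[well_id]
            bpm = corr.bpm
            status = corr.flag
            if corr.bpm is None:
                error_code = "discordant"
        elif est.called and "late_movement" in est.qc_flags:
            status = "late_movement"
        elif not est.called:
            status = est.error_code

        if bpm is not None and bpm < config.qc.floor_bpm:
            bpm = None
            status = "below_floor"
            error_code = "below_floor"

        result.add_row(
            well_id=well_id,
            loop_id=loop_id,
            bpm=bpm,
            qc_status=status,
            snr=est.snr_median,
            n_roi_pixels=est.n_pixels if est.called else None,
            n_phase_clusters=len(est.phase_clusters) if est.phase_clusters else None,
            phase_spread_rad=est.phase_spread_rad,
            error_code=error_code,
        )

    if output_path is not None:
        video_io.write_results(result, output_path)
    return result
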