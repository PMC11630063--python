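"""Seedable synthetic well videos with known ground truth.

The generator emulates the signal structure of a bright-field well-plate
acquisition of a transparent fish embryo: a roughly circular embryo darker
than the well background, one or two spatially compact chambers whose
pixel intensities pulse sinusoidally at a shared beat frequency (distinct
phases), aperiodic distractor regions (random-walk intensity, mimicking
blood flow), frame-to-frame illumination flicker, occasional all-black
corrupted frames, and an optional whole-embryo displacement event.

Intensity is modelled as additive sinusoidal modulation rather than a
deforming boundary; this keeps the ground-truth spectrum analytic while
exercising every pipeline stage. Frames are quantized to the uint16 grid
so a written TIFF round-trips bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .video_io import FrameStack

DEFAULT_TEMPLATE = "{well}_L{loop:02d}_T{frame:04d}.tif"

_BACKGROUND = 0.78
_EMBRYO_LEVEL = 0.45
_TEXTURE_AMPLITUDE = 0.05


@dataclass
class Chamber:
    """One pulsing heart chamber: a disc with a smooth radial falloff."""

    center: tuple[float, float]  # (row, col) px
    radius_px: float
    freq_hz: float
    phase_rad: float = 0.0
    amplitude: float = 0.15


@dataclass
class Distractor:
    """An aperiodic motion region whose intensity follows a random walk."""

    center: tuple[float, float]
    radius_px: float
    step_sigma: float = 0.03


@dataclass
class SceneSpec:
    """Full description of one synthetic well video."""

    image_size: tuple[int, int] = (512, 512)
    fps: float = 13.0
    duration_s: float = 10.0
    embryo_center: tuple[float, float] | None = None  # None = image center
    embryo_radius: float | None = None  # None = 30% of short side
    chambers: list[Chamber] = field(default_factory=list)
    distractors: list[Distractor] = field(default_factory=list)
    flicker_amplitude: float = 0.0
    n_black_frames: int = 0
    movement_event: tuple[float, float] | None = None  # (time_s, displacement_px)
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.embryo_center is not None:
            return self.embryo_center
        return (self.image_size[0] / 2.0, self.image_size[1] / 2.0)

    def resolved_radius(self) -> float:
        if self.embryo_radius is not None:
            return float(self.embryo_radius)
        return 0.30 * min(self.image_size)

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    def validate(self) -> None:
        er = self.resolved_radius()
        ec = np.asarray(self.resolved_center())
        for ch in self.chambers:
            d = np.hypot(*(np.asarray(ch.center) - ec))
            if d + ch.radius_px > er:
                raise ValueError(
                    f"chamber at {ch.center} (r={ch.radius_px}) lies outside "
                    f"the embryo disc (center {tuple(ec)}, r={er:.1f})"
                )
        freqs = {ch.freq_hz for ch in self.chambers}
        if len(freqs) > 1:
            # permitted (negative tests) but never silent
            import warnings

            warnings.warn("chambers do not share one frequency", stacklevel=2)


def _disc_weight(shape: tuple[int, int], center, radius: float) -> np.ndarray:
    """Tukey-style radial falloff: flat core, raised-cosine rolloff at the rim.

    The flat core (60% of the radius) keeps most of the region at full
    modulation depth — as in a contracting chamber — with a smooth edge so
    the rendered frames have no spatial discontinuity.
    """
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r = np.hypot(rr - center[0], cc - center[1])
    core = 0.6 * radius
    rim = np.clip((r - core) / (radius - core), 0.0, 1.0)
    return np.where(r <= radius, 0.5 * (1.0 + np.cos(np.pi * rim)), 0.0)


def _quantize16(frames: np.ndarray) -> np.ndarray:
    return np.round(np.clip(frames, 0.0, 1.0) * 65535.0) / 65535.0


def render_scene(spec: SceneSpec) -> tuple[FrameStack, dict]:
    """Render one well video and its ground-truth manifest.

    Identical specs (including the seed) produce bit-identical frames.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    n = spec.n_frames
    center = spec.resolved_center()
    radius = spec.resolved_radius()

    # static scene: well background, darker embryo disc, smooth texture
    rr, cc = np.ogrid[:h, :w]
    inside = np.hypot(rr - center[0], cc - center[1]) <= radius
    base = np.full((h, w), _BACKGROUND)
    base[inside] = _EMBRYO_LEVEL
    from scipy.ndimage import gaussian_filter

    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=4.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    base = base + _TEXTURE_AMPLITUDE * texture * inside

    t = np.arange(n) / spec.fps
    frames = np.repeat(base[None, :, :], n, axis=0)

    for ch in spec.chambers:
        wgt = _disc_weight((h, w), ch.center, ch.radius_px)
        signal = ch.amplitude * np.sin(2 * np.pi * ch.freq_hz * t + ch.phase_rad)
        frames += signal[:, None, None] * wgt[None, :, :]

    for dis in spec.distractors:
        wgt = _disc_weight((h, w), dis.center, dis.radius_px)
        # aperiodic drift: a random walk smoothed to a ~1 s timescale, so
        # its spectrum concentrates below the physiologic band the way
        # slow blood-flow or gut motion does
        walk = np.cumsum(rng.normal(0.0, dis.step_sigma, size=n))
        from scipy.ndimage import gaussian_filter1d

        walk = gaussian_filter1d(walk, sigma=spec.fps, mode="nearest")
        walk = np.clip(walk, -0.25, 0.25)
        frames += walk[:, None, None] * wgt[None, :, :]

    if spec.flicker_amplitude > 0:
        gain = 1.0 + spec.flicker_amplitude * rng.uniform(-1.0, 1.0, size=n)
        frames *= gain[:, None, None]

    movement_frame = None
    if spec.movement_event is not None:
        time_s, displacement = spec.movement_event
        movement_frame = int(round(time_s * spec.fps))
        if 0 < movement_frame < n:
            shift = int(round(displacement))
            frames[movement_frame:] = np.roll(
                frames[movement_frame:], shift=(shift, 0), axis=(1, 2)
            )

    black_idx: list[int] = []
    if spec.n_black_frames > 0:
        black_idx = sorted(
            rng.choice(n, size=spec.n_black_frames, replace=False).tolist()
        )
        frames[black_idx] = 0.0

    frames = _quantize16(frames)
    stack = FrameStack(frames=frames, fps=spec.fps)

    freqs = sorted({ch.freq_hz for ch in spec.chambers})
    manifest = {
        "image_size": list(spec.image_size),
        "fps": spec.fps,
        "n_frames": n,
        "embryo_center": list(center),
        "embryo_radius": radius,
        "true_freq_hz": freqs[0] if len(freqs) == 1 else freqs,
        "true_bpm": 60.0 * freqs[0] if len(freqs) == 1 else [60.0 * f for f in freqs],
        "chamber_phases_rad": [ch.phase_rad for ch in spec.chambers],
        "chamber_centers": [list(ch.center) for ch in spec.chambers],
        "chamber_radii_px": [ch.radius_px for ch in spec.chambers],
        "black_frame_indices": black_idx,
        "movement_frame": movement_frame,
        "seed": spec.seed,
    }
    if not spec.chambers:
        manifest["true_freq_hz"] = None
        manifest["true_bpm"] = None
    return stack, manifest


def default_scene(
    seed: int = 0,
    freq_hz: float = 2.0,
    image_size: tuple[int, int] = (512, 512),
    fps: float = 13.0,
    duration_s: float = 10.0,
    two_chambers: bool = False,
    chamber_phases: tuple[float, float] = (0.0, np.pi),
    amplitude: float = 0.15,
    with_distractor: bool = False,
    flicker_amplitude: float = 0.0,
    **kwargs,
) -> SceneSpec:
    """A realistic scene with geometry scaled to the image size.

    The embryo disc fills 30% of the short side; chambers sit near the
    embryo center with radii of ~16% of the embryo radius, adjacent when
    two chambers are requested; the optional distractor emulates blood
    flow in a peripheral vessel.
    """
    h, w = image_size
    ec = (h / 2.0, w / 2.0)
    er = 0.30 * min(image_size)
    cr = max(6.0, 0.16 * er)
    if two_chambers:
        # two chambers joined by an atrioventricular boundary region whose
        # phase sits halfway between them (in quadrature with both, so the
        # junction never cancels and the heart region stays connected)
        off = cr * 1.4
        mid_phase = chamber_phases[0] + 0.5 * np.angle(
            np.exp(1j * (chamber_phases[1] - chamber_phases[0]))
        )
        chambers = [
            Chamber((ec[0] - off, ec[1]), cr, freq_hz, chamber_phases[0], amplitude),
            Chamber((ec[0] + off, ec[1]), cr, freq_hz, chamber_phases[1], amplitude),
            Chamber((ec[0], ec[1]), 0.55 * cr, freq_hz, mid_phase, 0.5 * amplitude),
        ]
    else:
        chambers = [Chamber(ec, cr, freq_hz, chamber_phases[0], amplitude)]
    distractors = []
    if with_distractor:
        distractors = [Distractor((ec[0], ec[1] + 0.65 * er), max(5.0, 0.12 * er))]
    return SceneSpec(
        image_size=image_size,
        fps=fps,
        duration_s=duration_s,
        embryo_center=ec,
        embryo_radius=er,
        chambers=chambers,
        distractors=distractors,
        flicker_amplitude=flicker_amplitude,
        seed=seed,
        **kwargs,
    )


def _well_ids(n: int) -> list[str]:
    ids = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
    return ids[:n]


def choose_doubled_loop(spec: SceneSpec, loops: int) -> int:
    """Seeded choice of which loop of a harmonic well reads doubled."""
    well_rng = np.random.default_rng([spec.seed, 0xB5])
    return int(well_rng.integers(loops))


def loop_scene_spec(spec: SceneSpec, loop: int, doubled: bool = False) -> SceneSpec:
    """The scene spec actually rendered for one loop of one well.

    Loops share the well's geometry and rate but have loop-specific noise
    seeds (replicates differ in noise, not in biology). A doubled loop
    beats at twice the frequency with chambers of half the area — the
    axial-view second-harmonic artifact.
    """
    out = dataclasses.replace(
        spec,
        chambers=[dataclasses.replace(ch) for ch in spec.chambers],
        seed=int(np.random.SeedSequence([spec.seed, loop]).generate_state(1)[0] % (2**31)),
    )
    if doubled:
        for ch in out.chambers:
            ch.freq_hz *= 2.0
            ch.radius_px /= np.sqrt(2.0)  # halved spatial extent (area)
    return out


def render_plate(
    specs: dict[str, SceneSpec],
    loops: int,
    out_dir: str | Path,
    harmonic_wells: set[str] | frozenset[str] = frozenset(),
    template: str = DEFAULT_TEMPLATE,
    overwrite: bool = False,
) -> dict:
    """Write a whole synthetic plate as TIFF sequences plus manifest.json.

    Every well is rendered ``loops`` times with loop-specific noise seeds.
    For wells in ``harmonic_wells`` exactly one loop (seeded choice) beats
    at twice the true frequency with chambers of halved radius — the
    second-harmonic artifact an axial view of a two-chambered heart
    produces. The manifest records which loop was doubled.
    """
    if not specs:
        raise ValueError("specs map is empty")
    unknown = set(harmonic_wells) - set(specs)
    if unknown:
        raise ValueError(f"harmonic_wells not in specs: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"template": template, "loops": loops, "wells": {}}
    for well_id, spec in specs.items():
        doubled_loop = (
            choose_doubled_loop(spec, loops)
            if well_id in harmonic_wells and loops > 0
            else None
        )
        base_freqs = sorted({ch.freq_hz for ch in spec.chambers})
        well_entry: dict = {
            "doubled_loop": doubled_loop,
            # the well's physiologic rate, independent of any doubled loop
            "true_bpm": 60.0 * base_freqs[0] if len(base_freqs) == 1 else None,
            "loops": {},
        }
        for loop in range(loops):
            loop_spec = loop_scene_spec(spec, loop, doubled=loop == doubled_loop)
            stack, scene_manifest = render_scene(loop_spec)
            frames16 = np.round(stack.frames * 65535.0).astype(np.uint16)
            for idx in range(frames16.shape[0]):
                path = out_dir / template.format(well=well_id, loop=loop, frame=idx)
                if path.exists() and not overwrite:
                    raise FileExistsError(f"refusing to overwrite {path}")
                tifffile.imwrite(path, frames16[idx])
            scene_manifest["doubled"] = loop == doubled_loop
            well_entry["loops"][str(loop)] = scene_manifest
        manifest["wells"][well_id] = well_entry

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def default_plate_specs(
    n_wells: int = 96,
    seed: int = 17,
    bpm_range: tuple[float, float] = (70.0, 286.0),
    image_size: tuple[int, int] = (512, 512),
    fps: float = 13.0,
    duration_s: float = 10.0,
    **scene_kwargs,
) -> dict[str, SceneSpec]:
    """Per-well scene specs with true rates uniform over ``bpm_range``.

    One master seed fans out to independent per-well substreams, so single
    wells are reproducible regardless of plate size.
    """
    specs: dict[str, SceneSpec] = {}
    for i, well_id in enumerate(_well_ids(n_wells)):
        ss = np.random.SeedSequence([seed, i])
        sub = np.random.default_rng(ss)
        bpm = sub.uniform(*bpm_range)
        specs[well_id] = default_scene(
            seed=int(ss.generate_state(1)[0] % (2**31)),
            freq_hz=bpm / 60.0,
            image_size=image_size,
            fps=fps,
            duration_s=duration_s,
            **scene_kwargs,
        )
    return specs
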