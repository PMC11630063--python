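"""Reading per-well TIFF frame sequences and writing the results table.

One well of a plate acquisition is a short bright-field movie (10 s at 13
or 24 fps, i.e. 130 or 240 frames) stored either as one TIFF file per
frame or as a single multi-page TIFF. Frames are promoted to float64 on
[0, 1] at load time (divide by the dtype maximum) so every downstream
threshold is dtype-independent; RGB input is collapsed to luminance.

The batch output is a single CSV with one row per (well, loop); wells
without a heart-rate call carry ``NA`` in the bpm column and a
machine-readable ``error_code``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import FishbeatError

#: default filename template: <well>_L<loop>_T<frame>.tif, e.g. A01_L01_T0007.tif
DEFAULT_LAYOUT_PATTERN = (
    r"(?P<well>[A-H]\d{2})_L(?P<loop>\d+)_T(?P<frame>\d+)\.tiff?$"
)

#: rendering of a no-call bpm in the results CSV.
NO_CALL = "NA"

RESULT_COLUMNS = [
    "plate_id",
    "well_id",
    "loop_id",
    "bpm",
    "qc_status",
    "snr",
    "n_roi_pixels",
    "n_phase_clusters",
    "phase_spread_rad",
    "error_code",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """One well's ordered grayscale frames plus acquisition metadata.

    ``frames`` is (time, height, width) float64 on [0, 1].
    """

    frames: np.ndarray
    fps: float
    well_id: str = ""
    loop_id: int = 0
    source_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError(
                f"frames must be (time, height, width) with >= 2 frames, "
                f"got shape {self.frames.shape}"
            )
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """A copy of this stack with the pixel data replaced."""
        return FrameStack(
            frames=frames,
            fps=self.fps,
            well_id=self.well_id,
            loop_id=self.loop_id,
            source_paths=list(self.source_paths),
        )


@dataclass
class PlateResult:
    """The results table for one plate: one row per (well, loop)."""

    rows: list[dict] = field(default_factory=list)
    plate_id: str = "plate"

    def add_row(self, **kwargs) -> None:
        row = {col: kwargs.get(col) for col in RESULT_COLUMNS if col != "plate_id"}
        key = (row["well_id"], row["loop_id"])
        if any((r["well_id"], r["loop_id"]) == key for r in self.rows):
            raise ValueError(f"duplicate result row for well/loop {key}")
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=[c for c in RESULT_COLUMNS if c != "plate_id"])
        df.insert(0, "plate_id", self.plate_id)
        return df.sort_values(["well_id", "loop_id"], kind="stable").reset_index(drop=True)


def _to_float01(img: np.ndarray) -> np.ndarray:
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / np.iinfo(img.dtype).max
    else:
        img = img.astype(np.float64)
    if img.ndim == 3:
        if img.shape[-1] not in (3, 4):
            raise FishbeatError(f"cannot interpret image of shape {img.shape}")
        img = img[..., :3] @ _LUMA
    if img.ndim != 2:
        raise FishbeatError(f"expected a 2-D frame, got shape {img.shape}")
    return img


def load_frame_stack(
    paths: Iterable[str | Path],
    fps: float,
    well_id: str = "",
    loop_id: int = 0,
) -> FrameStack:
    """Load an ordered TIFF frame sequence into a :class:`FrameStack`.

    ``paths`` may be many single-image files (one per frame, in acquisition
    order) or a single multi-page TIFF holding the whole movie. RGB frames
    are converted to grayscale with the standard luminance weights.

    Raises
    ------
    FishbeatError
        If any file is unreadable or the frames disagree in shape.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise FishbeatError("no input paths given")
    frames: list[np.ndarray] = []
    for p in paths:
        try:
            data = tifffile.imread(p)
        except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
            raise FishbeatError(f"unreadable TIFF file: {p}") from exc
        if data.ndim >= 3 and len(paths) == 1 and data.shape[-1] not in (3, 4):
            frames.extend(_to_float01(page) for page in data)  # multi-page movie
        else:
            frames.append(_to_float01(data))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FishbeatError(f"frames have mismatched dimensions: {sorted(shapes)}")
    return FrameStack(
        frames=np.stack(frames),
        fps=fps,
        well_id=well_id,
        loop_id=loop_id,
        source_paths=[str(p) for p in paths],
    )


def discover_plate(
    root: str | Path,
    layout_pattern: str = DEFAULT_LAYOUT_PATTERN,
) -> dict[tuple[str, int], list[Path]]:
    """Group the frame files under ``root`` by (well_id, loop_id).

    ``layout_pattern`` is a regex with named groups ``well``, ``loop`` and
    ``frame``; files that do not match are ignored. Each group's list is
    sorted by the integer frame index.

    Raises
    ------
    FishbeatError
        If ``root`` does not exist or no file matches the pattern.
    """
    root = Path(root)
    if not root.is_dir():
        raise FishbeatError(f"input directory does not exist: {root}")
    rx = re.compile(layout_pattern)
    groups: dict[tuple[str, int], list[tuple[int, Path]]] = {}
    for path in sorted(root.rglob("*")):
        if not path.is_file():
            continue
        m = rx.search(path.name)
        if m is None:
            continue
        key = (m.group("well"), int(m.group("loop")))
        groups.setdefault(key, []).append((int(m.group("frame")), path))
    if not groups:
        raise FishbeatError(
            f"no frame files under {root} match the layout pattern {layout_pattern!r}"
        )
    return {
        key: [p for _, p in sorted(items)] for key, items in sorted(groups.items())
    }


def write_results(result: PlateResult, destination: str | Path) -> None:
    """Write the plate results as CSV with a stable column order.

    No-call bpm values are rendered as the fixed marker ``NA``; re-reading
    with :func:`read_results` reproduces the table.
    """
    df = result.to_frame()
    try:
        df.to_csv(destination, index=False, na_rep=NO_CALL, float_format="%.6g")
    except OSError as exc:
        raise FishbeatError(f"cannot write results to {destination}") from exc


def read_results(source: str | Path) -> PlateResult:
    """Parse a results CSV written by :func:`write_results`."""
    df = pd.read_csv(source, na_values=[NO_CALL], keep_default_na=False)
    plate_ids = df["plate_id"].unique().tolist() if len(df) else ["plate"]
    result = PlateResult(plate_id=plate_ids[0] if plate_ids else "plate")
    for _, row in df.iterrows():
        d = row.to_dict()
        d.pop("plate_id", None)
        d = {k: (None if pd.isna(v) else v) for k, v in d.items()}
        if d.get("loop_id") is not None:
            d["loop_id"] = int(d["loop_id"])
        if d.get("n_roi_pixels") is not None:
            d["n_roi_pixels"] = int(d["n_roi_pixels"])
        if d.get("n_phase_clusters") is not None:
            d["n_phase_clusters"] = int(d["n_phase_clusters"])
        result.add_row(**d)
    return result


def results_equal(a: PlateResult, b: PlateResult, rtol: float = 1e-5) -> bool:
    """Whether two result tables agree (numeric columns within ``rtol``)."""
    fa, fb = a.to_frame(), b.to_frame()
    if list(fa.columns) != list(fb.columns) or len(fa) != len(fb):
        return False
    for col in fa.columns:
        xa, xb = fa[col], fb[col]
        if xa.dtype.kind in "fc" or xb.dtype.kind in "fc":
            ok = np.isclose(
                pd.to_numeric(xa, errors="coerce"),
                pd.to_numeric(xb, errors="coerce"),
                rtol=rtol,
                equal_nan=True,
            )
            if not ok.all():
                return False
        elif not (xa.fillna("") == xb.fillna("")).all():
            return False
    return True
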