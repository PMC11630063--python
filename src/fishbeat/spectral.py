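"""Per-pixel Fourier analysis of the motion mask.

Each candidate pixel's mean-removed intensity series is transformed with a
real FFT (rectangular window; the frequency resolution is fps / n_frames
Hz). A pixel is "periodic" when its dominant nonzero-frequency bin falls
in the physiologic band (default 0.5–5 Hz, i.e. 30–300 bpm) and the
peak-to-background SNR is high enough; the largest connected region of
periodic pixels is taken to be the heart. The heart rate is the mode of
that region's dominant frequencies, found with a Gaussian kernel density
estimate, times 60 to convert Hz to beats per minute.

The Fourier phase at the dominant bin separates the two heart chambers:
they share the beat frequency but counter-beat roughly pi radians apart,
so clustering pixel phases on the unit circle recovers the chamber
structure without any segmentation of the chambers themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import NoCallError
from .motion import MotionMask
from .video_io import FrameStack

_MIN_FRAMES = 16


@dataclass
class PixelSpectrum:
    """Per-pixel FFT results over the motion-mask pixels."""

    freqs: np.ndarray  # (n_bins,) Hz, nonnegative rfft bins
    amplitude: np.ndarray  # (n_pixels, n_bins)
    phase: np.ndarray  # (n_pixels,) radians at the dominant bin, (-pi, pi]
    dominant_bin: np.ndarray  # (n_pixels,) int index into freqs
    dominant_freq: np.ndarray  # (n_pixels,) Hz
    snr: np.ndarray  # (n_pixels,)
    coords: np.ndarray  # (n_pixels, 2) (row, col) in the cropped frame
    frame_shape: tuple[int, int]
    fps: float
    n_frames: int

    @property
    def bin_width_hz(self) -> float:
        return self.fps / self.n_frames


@dataclass
class PeriodicMask:
    """The largest connected region of periodic pixels."""

    mask: np.ndarray  # boolean (h, w)
    region_area: int
    band: tuple[float, float]
    snr_range: tuple[float, float]
    pixel_index: np.ndarray  # indices into the PixelSpectrum arrays


@dataclass
class HeartbeatEstimate:
    """One well/loop's heart-rate call with QC annotations."""

    bpm: float | None
    freq_hz: float | None = None
    snr_median: float | None = None
    n_pixels: int = 0
    phase_clusters: list[tuple[float, int]] = field(default_factory=list)
    phase_spread_rad: float | None = None
    qc_flags: set[str] = field(default_factory=set)
    error_code: str | None = None

    @property
    def called(self) -> bool:
        return self.bpm is not None


def pixel_spectra(stack: FrameStack, mask: MotionMask, detrend: bool = True) -> PixelSpectrum:
    """Real FFT of every masked pixel's intensity time series.

    Detrending is mean removal only; no window function is applied (the
    KDE across many pixels suppresses leakage-driven outliers).
    """
    n = stack.n_frames
    if n < _MIN_FRAMES:
        raise ValueError(f"need at least {_MIN_FRAMES} frames, got {n}")
    coords = np.argwhere(mask.mask)
    if coords.shape[0] == 0:
        raise ValueError("motion mask is empty")
    series = stack.frames[:, coords[:, 0], coords[:, 1]].T  # (n_pixels, n)
    if detrend:
        series = series - series.mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(series, axis=1)
    amplitude = np.abs(spectrum)
    freqs = np.fft.rfftfreq(n, d=1.0 / stack.fps)

    nonzero = amplitude[:, 1:]
    dominant_bin = 1 + np.argmax(nonzero, axis=1)
    rows = np.arange(coords.shape[0])
    peak_amp = amplitude[rows, dominant_bin]
    # an effectively constant series leaves only roundoff in the spectrum;
    # treat its peak as zero so the pixel gets SNR 0, not noise/noise
    peak_amp = np.where(peak_amp < n * 1e-12, 0.0, peak_amp)
    n_other = nonzero.shape[1] - 1
    other_mean = (nonzero.sum(axis=1) - peak_amp) / max(n_other, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(peak_amp > 0, peak_amp / np.where(other_mean > 0, other_mean, np.inf), 0.0)
    snr = np.where((peak_amp > 0) & (other_mean <= 0), np.inf, snr)
    phase = np.angle(spectrum[rows, dominant_bin])
    # map -pi to pi so phases live in (-pi, pi]
    phase = np.where(phase <= -np.pi, np.pi, phase)
    return PixelSpectrum(
        freqs=freqs,
        amplitude=amplitude,
        phase=phase,
        dominant_bin=dominant_bin,
        dominant_freq=freqs[dominant_bin],
        snr=snr,
        coords=coords,
        frame_shape=mask.mask.shape,
        fps=stack.fps,
        n_frames=n,
    )


def snr_of_peak(amplitude_row: np.ndarray, peak_bin: int) -> float:
    """Peak amplitude over the mean of all other nonzero-frequency bins.

    The DC bin and the peak itself are excluded from the denominator; an
    all-zero spectrum has SNR 0 by definition, and a noiseless tone has
    infinite SNR.
    """
    amp = np.asarray(amplitude_row, dtype=float)
    if amp.shape[0] < 4:
        raise ValueError("need at least 3 nonzero-frequency bins")
    if peak_bin < 1 or peak_bin >= amp.shape[0]:
        raise ValueError(f"peak_bin {peak_bin} is not a nonzero-frequency bin")
    peak = amp[peak_bin]
    others = np.delete(amp[1:], peak_bin - 1)
    denom = others.mean()
    if peak <= 0:
        return 0.0
    if denom <= 0:
        return np.inf
    return float(peak / denom)


def periodic_mask(
    spec: PixelSpectrum,
    band_hz: tuple[float, float] = (0.5, 5.0),
    snr_range: tuple[float, float] = (2.0, np.inf),
) -> PeriodicMask:
    """Keep in-band, high-SNR pixels and select the largest connected region.

    Raises
    ------
    NoCallError
        ``no_periodic_region`` when no pixel survives the filters.
    """
    lo, hi = band_hz
    nyquist = spec.fps / 2.0
    if not 0 < lo < hi <= nyquist + 1e-9:
        raise ValueError(f"band {band_hz} invalid for Nyquist {nyquist}")
    s_lo, s_hi = snr_range
    keep = (
        (spec.dominant_freq >= lo)
        & (spec.dominant_freq <= hi)
        & (spec.snr >= s_lo)
        & (spec.snr <= s_hi)
    )
    if not keep.any():
        raise NoCallError("no_periodic_region", "no pixel passes band + SNR filters")
    kept2d = np.zeros(spec.frame_shape, dtype=bool)
    kc = spec.coords[keep]
    kept2d[kc[:, 0], kc[:, 1]] = True
    labels = label(kept2d, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best = int(np.argmax(areas))
    region = labels == best
    in_region = region[spec.coords[:, 0], spec.coords[:, 1]] & keep
    return PeriodicMask(
        mask=region,
        region_area=int(region.sum()),
        band=(lo, hi),
        snr_range=(s_lo, s_hi),
        pixel_index=np.flatnonzero(in_region),
    )


def _kde_mode(values: np.ndarray, bandwidth: float, band: tuple[float, float],
              grid_points: int = 512, weights: np.ndarray | None = None) -> float:
    """Argmax of a fixed-bandwidth Gaussian KDE over ``values``.

    The evaluation grid is the band grid plus the observed atoms, so a
    strongly modal atom (the usual case: many pixels share one FFT bin)
    is returned exactly.
    """
    unique = np.unique(values)
    if unique.size == 1:
        return float(unique[0])
    if weights is None:
        weights = np.ones_like(values)
    grid = np.union1d(np.linspace(band[0], band[1], grid_points), unique)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = (weights[None, :] * np.exp(-0.5 * z**2)).sum(axis=1)
    return float(grid[np.argmax(density)])


def estimate_heart_rate(
    spec: PixelSpectrum,
    pmask: PeriodicMask,
    kde_bandwidth: float | None = None,
    grid_points: int = 512,
    amplitude_weighted: bool = False,
) -> HeartbeatEstimate:
    """Modal dominant frequency of the heart region, as beats per minute.

    ``kde_bandwidth`` defaults to one frequency-bin width (fps/n_frames Hz).
    By default every pixel votes once; with ``amplitude_weighted`` each
    vote is weighted by the pixel's peak amplitude (pixels with stronger
    periodic signal count more).
    """
    idx = pmask.pixel_index
    if idx.size == 0:
        raise ValueError("periodic mask is empty")
    bandwidth = kde_bandwidth if kde_bandwidth is not None else spec.bin_width_hz
    weights = None
    if amplitude_weighted:
        rows = np.arange(spec.amplitude.shape[0])
        weights = spec.amplitude[rows, spec.dominant_bin][idx]
    freq = _kde_mode(
        spec.dominant_freq[idx], bandwidth, pmask.band, grid_points, weights
    )
    snr_finite = spec.snr[idx]
    snr_median = float(np.median(np.where(np.isfinite(snr_finite), snr_finite, 1e9)))
    return HeartbeatEstimate(
        bpm=60.0 * freq,
        freq_hz=freq,
        snr_median=snr_median,
        n_pixels=int(idx.size),
    )


def _circular_mean(phases: np.ndarray) -> float:
    return float(np.arctan2(np.sin(phases).mean(), np.cos(phases).mean()))


def circular_distance(a: float, b: float) -> float:
    """Shortest angular distance between two phases, in [0, pi]."""
    d = np.angle(np.exp(1j * (a - b)))
    return float(abs(d))


def phase_map(
    spec: PixelSpectrum,
    pmask: PeriodicMask,
    n_clusters_max: int = 3,
    random_state: int = 0,
) -> tuple[list[tuple[float, int]], float]:
    """Cluster heart-region pixel phases on the unit circle.

    Only pixels whose dominant bin equals the region's modal bin enter, so
    phases are comparable. k-means runs on (cos phi, sin phi); k is chosen
    from 1..n_clusters_max — a single cluster when the phases are nearly
    concentrated (resultant length > 0.95) or when no k >= 2 reaches a
    silhouette of 0.4, otherwise the silhouette-best k. Returns clusters
    as (circular mean phase, pixel count) sorted by count descending, plus
    the circular distance between the two most separated cluster means
    (0.0 for a single cluster).
    """
    idx = pmask.pixel_index
    if idx.size == 0:
        return [], 0.0
    bins = spec.dominant_bin[idx]
    modal_bin = np.bincount(bins).argmax()
    phases = spec.phase[idx[bins == modal_bin]]
    n = phases.size
    if n == 0:
        return [], 0.0

    resultant = np.hypot(np.sin(phases).mean(), np.cos(phases).mean())
    points = np.column_stack([np.cos(phases), np.sin(phases)])
    n_unique = np.unique(np.round(points, 9), axis=0).shape[0]
    best_k, best_labels = 1, np.zeros(n, dtype=int)
    if resultant <= 0.95 and n_unique >= 2:
        best_score = 0.4  # silhouette floor below which one cluster wins
        for k in range(2, min(n_clusters_max, n_unique) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(points)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(points, km.labels_)
            if score > best_score:
                best_score, best_k, best_labels = score, k, km.labels_

    clusters = []
    for lab in range(best_k):
        member = phases[best_labels == lab]
        if member.size:
            clusters.append((_circular_mean(member), int(member.size)))
    clusters.sort(key=lambda c: c[1], reverse=True)
    spread = 0.0
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            spread = max(spread, circular_distance(clusters[i][0], clusters[j][0]))
    return clusters, spread
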