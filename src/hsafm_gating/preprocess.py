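"""Frame flattening, drift correction, particle detection/tracking and
morphometric summaries of calibrated height movies.

All heights are nm; all positions are 0-based (row, col) pixels unless a
function documents nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .io import Movie

__all__ = [
    "ParticleTrack",
    "plane_flatten",
    "drift_correct",
    "detect_particles",
    "track_particles",
    "nfold_average",
    "cross_section",
    "height_histogram",
]


@dataclass
class ParticleTrack:
    """Per-molecule center trajectory; NaN rows mark frames without a fix."""

    molecule_id: int
    positions: np.ndarray  # (n_frames, 2) float px, NaN where missing

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.positions[:, 0])

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


# --------------------------------------------------------------------------
# flattening
# --------------------------------------------------------------------------


def plane_flatten(
    frame: np.ndarray,
    mask: np.ndarray | None = None,
    auto_mask: bool = True,
) -> np.ndarray:
    """Subtract the least-squares background plane a + b·col + c·row.

    ``mask`` marks pixels to *exclude* from the fit (protein).  With
    ``auto_mask`` and no explicit mask, pixels above the Otsu threshold are
    excluded so that protruding particles do not tilt the fit; the plane is
    subtracted from every pixel either way.  Idempotent to numerical
    precision.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    if mask is None and auto_mask and np.ptp(frame) > 0:
        mask = frame > threshold_otsu(frame)
    if mask is None:
        mask = np.zeros(frame.shape, dtype=bool)
    keep = ~np.asarray(mask, dtype=bool)
    if not keep.any():
        raise ValueError("all pixels are masked: cannot fit a plane")
    rr, cc = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    A = np.column_stack([np.ones(keep.sum()), cc[keep], rr[keep]])
    coef, *_ = np.linalg.lstsq(A, frame[keep], rcond=None)
    plane = coef[0] + coef[1] * cc + coef[2] * rr
    return frame - plane


# --------------------------------------------------------------------------
# drift correction
# --------------------------------------------------------------------------


def drift_correct(
    movie: Movie,
    reference: str = "previous",
    upsample_factor: int = 20,
    max_step_px: float | None = None,
) -> tuple[Movie, np.ndarray]:
    """Estimate and remove lateral scanner drift by subpixel cross-correlation.

    Frame-to-frame shifts come from the upsampled-DFT cross-correlation peak
    (``reference='previous'`` accumulates pairwise shifts; ``'first'``
    registers every frame to frame 0).  Frames are resampled (bilinear) so
    the static background is stationary.  Returns the corrected movie and
    the per-frame cumulative (d_row, d_col) shifts in px that were removed.
    A pairwise estimate larger than ``max_step_px`` is treated as a failed
    correlation and replaced by the previous step (shift propagated).
    """
    if movie.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    if reference not in ("previous", "first"):
        raise ValueError("reference must be 'previous' or 'first'")
    frames = movie.frames.astype(float)
    shifts = np.zeros((movie.n_frames, 2))
    prev_step = np.zeros(2)
    for f in range(1, movie.n_frames):
        ref = frames[f - 1] if reference == "previous" else frames[0]
        # classical (unnormalized) cross-correlation: phase normalization is
        # biased on smooth, sparsely structured height images
        step, _, _ = phase_cross_correlation(
            ref, frames[f], upsample_factor=upsample_factor, normalization=None
        )
        if max_step_px is not None and np.abs(step).max() > max_step_px:
            step = prev_step  # flagged frame: propagate neighboring shift
        else:
            prev_step = step
        shifts[f] = shifts[f - 1] + step if reference == "previous" else step
    corrected = np.empty_like(frames)
    corrected[0] = frames[0]
    for f in range(1, movie.n_frames):
        corrected[f] = ndimage.shift(frames[f], shifts[f], order=1, mode="nearest")
    out = Movie(
        frames=corrected,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        line_time=movie.line_time,
        t0=movie.t0,
    )
    return out, shifts


# --------------------------------------------------------------------------
# detection and tracking
# --------------------------------------------------------------------------


def detect_particles(
    frame: np.ndarray,
    pixel_size: float,
    min_height: float = 3.0,
    min_separation: float = 8.0,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Subpixel particle centers in a flattened frame.

    The frame is smoothed at roughly half the particle radius so that each
    multi-lobed particle collapses into one round blob whose maximum sits at
    the molecule center whatever the conformation; local maxima above
    ``min_height`` (nm) are non-maximum-suppressed at ``min_separation``
    (nm) and refined to subpixel by a quadratic fit to the 3×3 peak
    neighborhood.  Returns (n, 2) float px.
    """
    sm = ndimage.gaussian_filter(np.asarray(frame, dtype=float), smooth_sigma / pixel_size)
    min_dist = max(int(round(min_separation / pixel_size)), 1)
    peaks = peak_local_max(
        sm, min_distance=min_dist, threshold_abs=min_height, exclude_border=False
    )
    centers = []
    for r, c in peaks:
        pr, pc = float(r), float(c)
        if 0 < r < sm.shape[0] - 1:
            denom = sm[r - 1, c] - 2 * sm[r, c] + sm[r + 1, c]
            if denom < 0:
                pr += 0.5 * (sm[r - 1, c] - sm[r + 1, c]) / denom
        if 0 < c < sm.shape[1] - 1:
            denom = sm[r, c - 1] - 2 * sm[r, c] + sm[r, c + 1]
            if denom < 0:
                pc += 0.5 * (sm[r, c - 1] - sm[r, c + 1]) / denom
        centers.append((pr, pc))
    return np.array(centers).reshape(-1, 2)


def track_particles(
    detections: list[np.ndarray],
    max_link_distance: float,
    pixel_size: float = 1.0,
    max_gap: int = 3,
) -> list[ParticleTrack]:
    """Greedy nearest-neighbor frame-to-frame linking of detections.

    ``detections`` holds one (n_i, 2) px array per frame.  Links are made in
    ascending-distance order under ``max_link_distance`` (nm); unlinked
    detections start new tracks; a track not seen for more than ``max_gap``
    frames is closed.  Greedy linking is adequate for the quasi-static,
    well-separated packing this pipeline targets.
    """
    max_link_px = max_link_distance / pixel_size
    n_frames = len(detections)
    tracks: list[dict] = []  # {'pos': (F,2), 'last': frame, 'id': int}
    for f, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        active = [t for t in tracks if f - t["last"] <= max_gap]
        pairs = []
        for ti, t in enumerate(active):
            last_pos = t["pos"][t["last"]]
            d = np.sqrt(((dets - last_pos) ** 2).sum(axis=1))
            for di in range(len(dets)):
                if d[di] <= max_link_px:
                    pairs.append((d[di], ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti]["pos"][f] = dets[di]
            active[ti]["last"] = f
        for di in range(len(dets)):
            if di not in used_d:
                pos = np.full((n_frames, 2), np.nan)
                pos[f] = dets[di]
                tracks.append({"pos": pos, "last": f})
    return [ParticleTrack(molecule_id=i, positions=t["pos"]) for i, t in enumerate(tracks)]


# --------------------------------------------------------------------------
# morphometrics
# --------------------------------------------------------------------------


def _rotate_about(patch: np.ndarray, center: tuple[float, float], angle: float) -> np.ndarray:
    """Bilinear rotation of ``patch`` by ``angle`` (rad) about ``center`` (px)."""
    rr, cc = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    src_r = center[0] + ca * dr - sa * dc
    src_c = center[1] + sa * dr + ca * dc
    return ndimage.map_coordinates(patch, [src_r, src_c], order=1, mode="nearest")


def nfold_average(
    particle_patch: np.ndarray, n: int, center: tuple[float, float] | None = None
) -> np.ndarray:
    """n-fold rotational symmetrization: mean over k·360°/n rotations.

    Acts as a projection onto the n-fold symmetric subspace (up to bilinear
    interpolation error).  ``center`` defaults to the patch center.
    """
    patch = np.asarray(particle_patch, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if center is None:
        center = ((patch.shape[0] - 1) / 2.0, (patch.shape[1] - 1) / 2.0)
    if not (0 <= center[0] < patch.shape[0] and 0 <= center[1] < patch.shape[1]):
        raise ValueError("center outside patch")
    if n == 1:
        return patch.copy()
    acc = np.zeros_like(patch)
    for k in range(n):
        acc += _rotate_about(patch, center, 2 * np.pi * k / n)
    return acc / n


@dataclass
class SectionProfile:
    distance: np.ndarray  # nm along the section
    height: np.ndarray  # nm
    peak_to_peak: float  # nm
    periodicity: float | None  # nm, None when undefined


def cross_section(
    frame: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    pixel_size: float,
) -> SectionProfile:
    """Bilinear height profile between two (row, col) px points.

    Samples at ``pixel_size`` steps; reports the peak-to-peak height and the
    dominant periodicity as the first off-zero local maximum of the
    autocorrelation of the mean-subtracted profile (robust for the short
    profiles typical of lattice-spacing measurements).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    seg = np.linalg.norm(p1 - p0)
    if seg < 1:
        raise ValueError("degenerate segment")
    n = int(np.ceil(seg)) + 1
    rows = np.linspace(p0[0], p1[0], n)
    cols = np.linspace(p0[1], p1[1], n)
    h = ndimage.map_coordinates(np.asarray(frame, dtype=float), [rows, cols], order=1)
    dist = np.linspace(0, seg * pixel_size, n)
    x = h - h.mean()
    period = None
    if np.ptp(x) > 0:
        ac = np.correlate(x, x, mode="full")[n - 1 :]
        # first local maximum after the zero-lag peak has decayed
        for i in range(1, len(ac) - 1):
            if ac[i] >= ac[i - 1] and ac[i] > ac[i + 1] and ac[i] > 0:
                period = dist[i]
                break
    return SectionProfile(
        distance=dist, height=h, peak_to_peak=float(h.max() - h.min()), periodicity=period
    )


@dataclass
class HeightHistogram:
    bin_centers: np.ndarray  # nm
    counts: np.ndarray
    modes: np.ndarray  # nm, detected peak positions
    mode_separations: np.ndarray  # nm, pairwise |mode_i − mode_j|


def height_histogram(
    data: np.ndarray, bin_width: float = 0.2, smooth_bins: float = 2.0
) -> HeightHistogram:
    """All-pixel height histogram with smoothed local-maximum mode detection."""
    values = np.asarray(data, dtype=float).ravel()
    if values.size < 1000:
        raise ValueError("need at least 1000 height values")
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width:  # constant image: single mode
        return HeightHistogram(
            bin_centers=np.array([values.mean()]),
            counts=np.array([values.size]),
            modes=np.array([values.mean()]),
            mode_separations=np.array([]),
        )
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sm = ndimage.gaussian_filter1d(counts.astype(float), smooth_bins)
    peaks = [
        i
        for i in range(1, len(sm) - 1)
        if sm[i] >= sm[i - 1] and sm[i] > sm[i + 1] and sm[i] > 0.05 * sm.max()
    ]
    modes = centers[peaks]
    seps = np.abs(modes[:, None] - modes[None, :])[np.triu_indices(len(modes), 1)]
    return HeightHistogram(
        bin_centers=centers, counts=counts, modes=modes, mode_separations=seps
    )
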