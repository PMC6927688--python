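"""Per-molecule observables: ΔHeight/time traces and section kymographs.

ΔHeight is the standard scalar observable for single-channel gating in
height movies: the maximum minus the minimum height inside a small window
(default 5 × 5 nm) centered on the tracked molecule.  A symmetric ring with
a central pore dip gives ΔHeight ≈ ring relief + dip depth (~1 nm); a
conformation with an elevated subunit raises the window maximum and hence
ΔHeight.  Being a difference, ΔHeight is exactly invariant under any
constant height offset of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Movie
from .preprocess import ParticleTrack

__all__ = ["HeightTrace", "Kymograph", "delta_height_trace", "kymograph"]


@dataclass
class HeightTrace:
    molecule_id: int
    times: np.ndarray  # s, one entry per valid tracked frame
    delta_height: np.ndarray  # nm
    frames: np.ndarray  # frame indices the values come from
    window_size: float  # nm


@dataclass
class Kymograph:
    molecule_id: int
    data: np.ndarray  # (n_frames, n_samples) nm; NaN rows where untracked
    distance: np.ndarray  # nm along the section
    times: np.ndarray  # s per row
    angle: float  # rad


def _window_bounds(center: float, half_px: int, size: int) -> tuple[int, int]:
    c = int(round(center))
    return c - half_px, c + half_px + 1


def delta_height_trace(
    movie: Movie,
    track: ParticleTrack,
    window: float = 5.0,
    follow_track: bool = True,
) -> HeightTrace:
    """ΔHeight(t) = max − min over the window×window nm box on the center.

    The box is axis-aligned and rounded to whole pixels (10×10 px at
    0.5 nm px⁻¹ defaults).  Frames where the track has no fix yield gaps
    (never interpolated values); frames whose window would cross the frame
    edge are skipped.  With ``follow_track=False`` the box stays at the
    track's median position (fixed-window mode).  Time stamps refer to the
    scan line through the molecule center when the movie carries a line
    time.
    """
    if track.n_valid < 1:
        raise ValueError("track has no valid frames")
    half_px = max(int(round(window / movie.pixel_size)) // 2, 1)
    fixed = np.nanmedian(track.positions, axis=0)
    times, values, frames = [], [], []
    for f in range(movie.n_frames):
        if not track.valid[f]:
            continue
        pos = track.positions[f] if follow_track else fixed
        r0, r1 = _window_bounds(pos[0], half_px, movie.frames.shape[1])
        c0, c1 = _window_bounds(pos[1], half_px, movie.frames.shape[2])
        if r0 < 0 or c0 < 0 or r1 > movie.frames.shape[1] or c1 > movie.frames.shape[2]:
            continue  # window out of bounds: flagged by absence
        box = movie.frames[f, r0:r1, c0:c1]
        values.append(float(box.max() - box.min()))
        times.append(movie.line_time_of(f, pos[0]) if movie.line_time else movie.frame_times[f])
        frames.append(f)
    return HeightTrace(
        molecule_id=track.molecule_id,
        times=np.asarray(times),
        delta_height=np.asarray(values),
        frames=np.asarray(frames, dtype=int),
        window_size=2 * half_px * movie.pixel_size,
    )


def kymograph(
    movie: Movie,
    track: ParticleTrack,
    angle: float = 0.0,
    length: float = 12.0,
) -> Kymograph:
    """Fixed-length height section through the per-frame center, one row per frame.

    The section runs through the tracked center at ``angle`` (rad, 0 = along
    image columns), sampled bilinearly at pixel_size steps over ``length``
    nm.  Untracked frames produce NaN rows so the time axis stays uniform.
    """
    if track.n_valid < 1:
        raise ValueError("track has no valid frames")
    n = int(round(length / movie.pixel_size)) + 1
    s = np.linspace(-length / 2, length / 2, n) / movie.pixel_size
    dr, dc = s * np.sin(angle), s * np.cos(angle)
    data = np.full((movie.n_frames, n), np.nan)
    for f in range(movie.n_frames):
        if not track.valid[f]:
            continue
        pos = track.positions[f]
        rows, cols = pos[0] + dr, pos[1] + dc
        if rows.min() < 0 or cols.min() < 0 or rows.max() > movie.frames.shape[1] - 1:
            continue
        if cols.max() > movie.frames.shape[2] - 1:
            continue
        data[f] = ndimage.map_coordinates(
            movie.frames[f].astype(float), [rows, cols], order=1
        )
    return Kymograph(
        molecule_id=track.molecule_id,
        data=data,
        distance=s * movie.pixel_size,
        times=movie.frame_times,
        angle=angle,
    )
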