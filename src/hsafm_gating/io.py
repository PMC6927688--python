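"""Movie container and on-disk formats.

A movie is a calibrated stack of height images (nm above the support plane)
with per-frame acquisition times.  On disk it is a multi-page 32-bit float
TIFF plus a JSON sidecar holding the calibration
(``pixel_size_nm``, ``frame_interval_s``, ``line_time_s``, ``t0_s``).
Ground-truth gating logs are JSON lines, one record per state interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Movie", "save_movie", "load_movie", "save_ground_truth", "load_ground_truth"]


@dataclass
class Movie:
    """Height-image stack, heights in nm, 0-based (row, col) pixel coordinates."""

    frames: np.ndarray  # (n_frames, rows, cols) float
    pixel_size: float  # nm per pixel
    frame_interval: float  # s
    line_time: float | None = None  # s per scan line (frame_interval / rows)
    t0: float = 0.0  # acquisition time of frame 0, s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.line_time is None:
            self.line_time = self.frame_interval / self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of the first line of each frame, s."""
        return self.t0 + np.arange(self.n_frames) * self.frame_interval

    def line_time_of(self, frame: int, row: float) -> float:
        """Acquisition time of scan line ``row`` of ``frame``, s."""
        return float(self.frame_times[frame] + row * self.line_time)


def save_movie(movie: Movie, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tif`` (float32 heights) and ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    tif = prefix.with_suffix(".tif")
    meta = prefix.with_suffix(".json")
    tifffile.imwrite(tif, movie.frames.astype(np.float32), photometric="minisblack")
    meta.write_text(
        json.dumps(
            {
                "pixel_size_nm": movie.pixel_size,
                "frame_interval_s": movie.frame_interval,
                "line_time_s": movie.line_time,
                "t0_s": movie.t0,
            },
            indent=2,
        )
    )
    return tif, meta


def load_movie(prefix: str | Path) -> Movie:
    prefix = Path(prefix)
    tif = prefix if prefix.suffix == ".tif" else prefix.with_suffix(".tif")
    meta = json.loads(tif.with_suffix(".json").read_text())
    frames = tifffile.imread(tif)
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(
        frames=frames,
        pixel_size=meta["pixel_size_nm"],
        frame_interval=meta["frame_interval_s"],
        line_time=meta.get("line_time_s"),
        t0=meta.get("t0_s", 0.0),
    )


def save_ground_truth(records: list[dict], path: str | Path) -> None:
    """One JSON object per line: {molecule_id, t_start_s, t_end_s, class}."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def load_ground_truth(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
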