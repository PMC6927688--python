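"""End-to-end analysis chain: movie → flatten → drift-correct → detect →
track → classify → occupancy / transition statistics.

`run_condition` additionally owns the synthesis step for the per-condition
steady-state presets, which is what the population-level recovery analyses
exercise: a 20-molecule patch imaged for ~100 frames per ligand condition,
mirroring the scale of the per-condition movie sections the statistics are
computed from (~20 molecules × ~80–100 frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import (
    ClassifierThresholds,
    classify_snapshot,
    extract_features,
    transition_matrix,
)
from .io import Movie
from .preprocess import (
    ParticleTrack,
    detect_particles,
    drift_correct,
    plane_flatten,
    track_particles,
)
from .synthetic import (
    CONDITION_PRESETS,
    ConditionPreset,
    ImagingConfig,
    make_lattice_patch,
    simulate_movie,
)

__all__ = ["analyze_movie", "classify_movie", "run_condition", "ConditionResult"]


def analyze_movie(
    movie: Movie,
    min_height: float = 3.0,
    min_separation: float = 8.0,
    max_link_distance: float = 4.0,
    min_track_fraction: float = 0.5,
) -> tuple[Movie, list[ParticleTrack]]:
    """Flatten, drift-correct, detect and track; returns (corrected movie, tracks).

    Tracks covering fewer than ``min_track_fraction`` of the frames are
    dropped (spurious detections, edge particles drifting out).
    """
    flat = Movie(
        frames=np.stack([plane_flatten(f) for f in movie.frames]),
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        line_time=movie.line_time,
        t0=movie.t0,
    )
    if movie.n_frames >= 2:
        corrected, _ = drift_correct(flat, reference="previous")
    else:
        corrected = flat
    detections = [
        detect_particles(
            f, corrected.pixel_size, min_height=min_height, min_separation=min_separation
        )
        for f in corrected.frames
    ]
    tracks = track_particles(
        detections, max_link_distance, pixel_size=corrected.pixel_size
    )
    keep = [t for t in tracks if t.n_valid >= min_track_fraction * movie.n_frames]
    for i, t in enumerate(keep):
        t.molecule_id = i
    return corrected, keep


def classify_movie(
    movie: Movie,
    tracks: list[ParticleTrack],
    thresholds: ClassifierThresholds | None = None,
    patch_radius: float = 8.5,
) -> pd.DataFrame:
    """Per-frame class labels for every tracked molecule.

    Extracts a square patch of ``patch_radius`` nm around the tracked
    center in each frame (edge-clipped patches are skipped) and applies the
    decision-list classifier.  Returns a DataFrame with columns
    molecule_id, frame, class.
    """
    thr = thresholds or ClassifierThresholds()
    half = int(round(patch_radius / movie.pixel_size))
    rows = []
    for tr in tracks:
        for f in np.flatnonzero(tr.valid):
            r, c = tr.positions[f]
            r0, c0 = int(round(r)) - half, int(round(c)) - half
            r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
            if r0 < 0 or c0 < 0 or r1 > movie.frames.shape[1] or c1 > movie.frames.shape[2]:
                continue
            patch = movie.frames[f, r0:r1, c0:c1]
            center = (r - r0, c - c0)
            feats = extract_features(patch, center, movie.pixel_size, thr)
            rows.append(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": int(f),
                    "class": classify_snapshot(feats, thr),
                }
            )
    return pd.DataFrame(rows, columns=["molecule_id", "frame", "class"])


@dataclass
class ConditionResult:
    condition: str
    labels: pd.DataFrame  # molecule_id, frame, class (classified)
    truth: pd.DataFrame  # molecule_id, frame, class (generator ground truth)
    occupancy: pd.DataFrame
    transitions: object  # TransitionMatrix
    tracks: list[ParticleTrack] | None = None
    patch_centers: np.ndarray | None = None  # generator centers, nm


def _truth_frame_labels(records: list[dict], frame_interval: float, n_frames: int) -> pd.DataFrame:
    rows = []
    for rec in records:
        f0 = int(round(rec["t_start_s"] / frame_interval))
        f1 = int(round(rec["t_end_s"] / frame_interval))
        for f in range(f0, min(f1, n_frames)):
            rows.append({"molecule_id": rec["molecule_id"], "frame": f, "class": rec["class"]})
    return pd.DataFrame(rows, columns=["molecule_id", "frame", "class"])


def run_condition(
    condition: str | ConditionPreset,
    seed: int,
    n_frames: int = 100,
    lattice: tuple[int, int] = (4, 5),
    pixel_size: float = 0.5,
    frame_interval: float = 0.55,
    thresholds: ClassifierThresholds | None = None,
) -> ConditionResult:
    """Simulate one steady-state condition and run the full analysis chain.

    ``condition`` is a preset name ("10mM", "3mM", "0mM", "readdition") or a
    :class:`ConditionPreset`.  The default 4×5 lattice gives 20 molecules.
    """
    preset = CONDITION_PRESETS[condition] if isinstance(condition, str) else condition
    from .classify import occupancy as occupancy_table

    patch = make_lattice_patch(*lattice)
    extent_r = 10.0 * 2 + (lattice[0] - 1) * patch.lattice_spacing
    extent_c = 10.0 * 2 + (lattice[1] - 1) * patch.lattice_spacing + patch.lattice_spacing / 2
    grid = ImagingConfig(
        pixel_size=pixel_size,
        frame_shape=(int(np.ceil(extent_r / pixel_size)), int(np.ceil(extent_c / pixel_size))),
        frame_interval=frame_interval,
    )
    movie, records = simulate_movie(
        preset, None, patch, grid, duration=n_frames * frame_interval, seed=seed
    )
    corrected, tracks = analyze_movie(movie)
    labels = classify_movie(corrected, tracks, thresholds)
    occ = occupancy_table(labels, condition=preset.name)
    trans = transition_matrix(labels)
    truth = _truth_frame_labels(records, frame_interval, movie.n_frames)
    return ConditionResult(
        condition=preset.name,
        labels=labels,
        truth=truth,
        occupancy=occ,
        transitions=trans,
        tracks=tracks,
        patch_centers=patch.particle_centers,
    )
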