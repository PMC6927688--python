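"""Flattening, drift correction, detection/tracking, morphometrics."""

import numpy as np
import pytest

from hsafm_gating.io import Movie
from hsafm_gating.preprocess import (
    cross_section,
    detect_particles,
    drift_correct,
    height_histogram,
    nfold_average,
    plane_flatten,
    track_particles,
)
from hsafm_gating.synthetic import (
    ImagingConfig,
    MembranePatch,
    ParticleGeometry,
    make_lattice_patch,
    render_height_map,
    render_state_paths,
    simulate_movie,
    tip_dilate,
    CONDITION_PRESETS,
    StateInterval,
)

PX = 0.5


# ------------------------------------------------------------------ flattening


def test_flatten_pure_plane_gives_zeros():
    rr, cc = np.mgrid[0:40, 0:50]
    frame = 2.0 + 0.01 * cc - 0.02 * rr
    out = plane_flatten(frame, auto_mask=False)
    assert np.abs(out).max() < 1e-10


def test_flatten_recovers_particle_field_when_masked():
    rng = np.random.default_rng(0)
    particles = np.zeros((40, 50))
    particles[10:20, 15:25] = rng.uniform(3, 7, (10, 10))
    rr, cc = np.mgrid[0:40, 0:50]
    plane = 1.5 + 0.03 * cc + 0.01 * rr
    out = plane_flatten(particles + plane, mask=particles > 0)
    assert np.allclose(out, particles, atol=1e-9)


def test_flatten_is_idempotent_and_removes_residual_tilt():
    rng = np.random.default_rng(1)
    frame = rng.normal(0, 0.2, (60, 60)) + np.linspace(0, 3, 60)[None, :]
    once = plane_flatten(frame, auto_mask=False)
    twice = plane_flatten(once, auto_mask=False)
    assert np.allclose(once, twice, atol=1e-9)
    # residual plane coefficients of the output are numerically zero
    rr, cc = np.mgrid[0:60, 0:60]
    A = np.column_stack([np.ones(3600), cc.ravel(), rr.ravel()])
    coef, *_ = np.linalg.lstsq(A, once.ravel(), rcond=None)
    assert abs(coef[1]) < 1e-12 and abs(coef[2]) < 1e-12


def test_flatten_all_masked_errors():
    with pytest.raises(ValueError):
        plane_flatten(np.ones((10, 10)), mask=np.ones((10, 10), dtype=bool))


# ------------------------------------------------------------ drift correction


def _movie_with_drift(drift_nm_s, n_frames=12, noise=0.0):
    from hsafm_gating.synthetic import lattice_frame_shape

    patch = make_lattice_patch(2, 3)
    grid = ImagingConfig(
        frame_shape=lattice_frame_shape(2, 3),
        vertical_noise_sd=noise,
        drift_velocity=drift_nm_s,
        tip_radius=2.0,
    )
    paths = [
        [StateInterval(0.0, 1e9, "closed")] for _ in range(len(patch.particle_centers))
    ]
    frames = render_state_paths(
        paths, patch, grid, n_frames, noise_sd=noise, drift_velocity=drift_nm_s
    )
    return Movie(frames=frames, pixel_size=PX, frame_interval=0.55)


def test_zero_drift_movie_gives_zero_shifts():
    movie = _movie_with_drift((0.0, 0.0))
    _, shifts = drift_correct(movie)
    assert np.abs(shifts).max() < 0.05


def test_known_drift_recovered_within_quarter_pixel():
    drift = (0.2 / 0.55, 0.35 / 0.55)  # nm/s giving (0.2, 0.35) nm per frame
    movie = _movie_with_drift(drift, n_frames=12)
    _, shifts = drift_correct(movie)
    # applied shift per frame f is −drift·t_f in px
    t = np.arange(12) * 0.55
    expected = -np.outer(t, np.asarray(drift)) / PX
    assert np.abs(shifts - expected).max() < 0.25
    # recovered drift velocity within 10%
    vel = (shifts[-1] - shifts[0]) / (11 * 0.55) * PX
    assert np.allclose(-vel, drift, rtol=0.10)


def test_single_frame_movie_rejected():
    movie = _movie_with_drift((0, 0), n_frames=1)
    with pytest.raises(ValueError):
        drift_correct(movie)


# ------------------------------------------------------- detection / tracking


def test_detects_all_lattice_particles_within_one_pixel():
    from hsafm_gating.synthetic import lattice_frame_shape

    patch = make_lattice_patch(4, 5)
    grid = ImagingConfig(frame_shape=lattice_frame_shape(4, 5), vertical_noise_sd=0.0)
    surface = render_height_map(ParticleGeometry.for_class("closed"), patch, grid)
    frame = tip_dilate(surface, 2.0, PX) - 5.0  # membrane-referenced
    centers = detect_particles(frame, PX)
    assert len(centers) == 20
    truth = patch.particle_centers / PX
    for c in centers:
        assert np.min(np.linalg.norm(truth - c, axis=1)) < 1.0


def test_flat_frame_yields_no_detections():
    assert detect_particles(np.zeros((64, 64)), PX).shape == (0, 2)


def test_close_pair_is_suppressed_to_one_detection():
    grid = ImagingConfig(frame_shape=(64, 64), vertical_noise_sd=0.0)
    patch = MembranePatch(particle_centers=np.array([[16.0, 13.0], [16.0, 18.0]]))
    surface = render_height_map(ParticleGeometry.for_class("closed"), patch, grid)
    centers = detect_particles(surface - 5.0, PX, min_separation=8.0)
    assert len(centers) == 1


def test_static_particles_give_full_length_tracks():
    dets = [np.array([[10.0, 10.0], [10.0, 40.0]]) for _ in range(20)]
    tracks = track_particles(dets, max_link_distance=4.0, pixel_size=PX)
    assert len(tracks) == 2
    assert all(t.n_valid == 20 for t in tracks)


def test_disappearing_particle_ends_track_without_spurious_link():
    dets = [np.array([[10.0, 10.0], [10.0, 40.0]]) for _ in range(10)]
    dets += [np.array([[10.0, 40.0]]) for _ in range(10)]
    tracks = track_particles(dets, max_link_distance=4.0, pixel_size=PX)
    lengths = sorted(t.n_valid for t in tracks)
    assert lengths == [10, 20]


def test_identity_preserved_for_separated_crossing_paths():
    # two particles approach but stay > max_link_distance per frame step
    a = [np.array([[10.0, 10.0 + f], [30.0, 30.0 - f]]) for f in range(15)]
    tracks = track_particles(a, max_link_distance=2.0, pixel_size=1.0)
    assert len(tracks) == 2
    assert all(t.n_valid == 15 for t in tracks)
    # each track stays on its own smooth path (no identity swap)
    for t in tracks:
        steps = np.diff(t.positions[:, 1])
        assert np.all(np.abs(steps) <= 1.0 + 1e-9)


# --------------------------------------------------------------- morphometrics


def test_nfold_average_identity_and_projection(class_surfaces):
    c = int(round(12.0 / PX))
    patch = class_surfaces["open2"][c - 14 : c + 15, c - 14 : c + 15]
    assert np.array_equal(nfold_average(patch, 1), patch)
    once = nfold_average(patch, 5)
    twice = nfold_average(once, 5)
    # bilinear interpolation at the steep plateau edge sets the error floor
    assert np.abs(twice - once).max() < 0.2
    assert np.abs(twice - once).mean() < 0.03
    # symmetrized output correlates > 0.999 with its own 72° rotation
    rot = nfold_average(once, 1)  # copy
    from hsafm_gating.preprocess import _rotate_about

    r72 = _rotate_about(once, ((once.shape[0] - 1) / 2,) * 2, 2 * np.pi / 5)
    inner = np.s_[4:-4, 4:-4]
    assert np.corrcoef(once[inner].ravel(), r72[inner].ravel())[0, 1] > 0.999


def test_nfold_average_center_outside_patch_errors():
    with pytest.raises(ValueError):
        nfold_average(np.zeros((11, 11)), 5, center=(20.0, 20.0))


def test_cross_section_step_height_across_membrane_edge():
    # membrane + protein occupies the left half; bare support on the right
    grid = ImagingConfig(frame_shape=(80, 120), vertical_noise_sd=0.0)
    patch = MembranePatch(
        particle_centers=np.array([[20.0, 15.0]]),
        membrane_rect=(0.0, 0.0, 40.0, 30.0),
    )
    surface = render_height_map(ParticleGeometry.for_class("closed"), patch, grid)
    prof = cross_section(surface, (40, 10), (40, 110), PX)
    assert prof.peak_to_peak == pytest.approx(12.0, abs=0.1)


def test_cross_section_recovers_lattice_periodicity():
    patch = make_lattice_patch(1, 6, spacing=14.0)
    grid = ImagingConfig(frame_shape=(44, 200), vertical_noise_sd=0.0)
    surface = render_height_map(ParticleGeometry.for_class("closed"), patch, grid)
    row = int(round(10.0 / PX))
    prof = cross_section(surface, (row, 10), (row, 190), PX)
    assert prof.periodicity == pytest.approx(14.0, abs=0.5)


def test_cross_section_constant_frame_flags_undefined_periodicity():
    prof = cross_section(np.full((40, 40), 3.0), (5, 5), (35, 35), PX)
    assert prof.peak_to_peak == pytest.approx(0.0, abs=1e-9)
    assert prof.periodicity is None
    with pytest.raises(ValueError):
        cross_section(np.zeros((40, 40)), (5, 5), (5, 5), PX)


def test_height_histogram_support_vs_protein_modes():
    grid = ImagingConfig(frame_shape=(100, 100), vertical_noise_sd=0.0)
    patch = MembranePatch(
        particle_centers=np.array([[12.0, 12.0], [12.0, 26.0], [26.0, 12.0], [26.0, 26.0]]),
        membrane_rect=(0.0, 0.0, 38.0, 38.0),
    )
    surface = render_height_map(ParticleGeometry.for_class("closed"), patch, grid)
    imaged = tip_dilate(surface, 2.0, PX)  # tip broadening fills the ring tops
    rng = np.random.default_rng(2)
    hist = height_histogram(imaged + rng.normal(0, 0.15, imaged.shape), bin_width=0.2)
    assert len(hist.modes) >= 2
    # support (0) to protein top (12 nm) separation among the detected modes
    assert np.any(np.abs(hist.mode_separations - 12.0) < 0.8)


def test_height_histogram_stacked_membranes_two_levels():
    rng = np.random.default_rng(3)
    frame = np.zeros((120, 120)) + rng.normal(0, 0.15, (120, 120))
    frame[:, 40:] += 12.0  # first membrane + protein
    frame[:, 80:] += 5.0  # stacked second membrane: 17 nm total
    hist = height_histogram(frame, bin_width=0.2)
    seps = hist.mode_separations
    assert np.any(np.abs(seps - 12.0) < 0.5)
    assert np.any(np.abs(seps - 17.0) < 0.5)


def test_height_histogram_constant_image_single_mode():
    hist = height_histogram(np.full((40, 40), 2.5), bin_width=0.2)
    assert len(hist.modes) == 1
    assert hist.modes[0] == pytest.approx(2.5)
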