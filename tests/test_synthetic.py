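"""Simulator: chelation equilibrium, gating sampling, rendering, tip model."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hsafm_gating.preprocess import nfold_average
from hsafm_gating.synthetic import (
    CLASSES,
    CONDITION_PRESETS,
    ConcentrationSchedule,
    ConditionPreset,
    GatingModel,
    ImagingConfig,
    MembranePatch,
    ParticleGeometry,
    StateInterval,
    free_mg,
    make_lattice_patch,
    render_height_map,
    render_state_paths,
    sample_gating,
    sample_preset_states,
    simulate_movie,
    tip_dilate,
)

from conftest import PX, center_px


# --------------------------------------------------------------------- free_mg


def test_free_mg_no_chelator_is_total():
    assert free_mg(10.0, 0.0, 0.1) == pytest.approx(10.0)


def test_free_mg_stoichiometric_limit():
    assert free_mg(10.0, 10.0, 1e-12) == pytest.approx(0.0, abs=1e-4)


def test_free_mg_matches_bisection_oracle():
    # independent oracle: bisect the mass-balance g(x) = x + E·x/(x+K) − M
    mg, edta, kd = 10.0, 8.0, 0.1

    def mass_balance(x):
        return x + edta * x / (x + kd) - mg

    expected = brentq(mass_balance, 0.0, mg)
    assert free_mg(mg, edta, kd) == pytest.approx(expected, rel=1e-10)


def test_free_mg_rejects_negative_inputs():
    with pytest.raises(ValueError):
        free_mg(-1.0, 0.0, 0.1)


# ----------------------------------------------------------------- gating CTMC


def test_stationary_closed_fraction_matches_analytic_law():
    model = GatingModel(K_d=2.0)
    schedule = ConcentrationSchedule.constant(10.0)
    path = sample_gating(model, schedule, duration=10_000.0, seed=1)[0]
    closed_time = sum(iv.t_end - iv.t_start for iv in path if iv.class_label == "closed")
    frac = closed_time / 10_000.0
    # ~140 closed sojourns in 10^4 s; allow 3 effective-sample-size SEs
    assert frac == pytest.approx(10.0 / 12.0, abs=0.05)


def test_saturating_concentration_stays_closed():
    # open sojourns vanish as c → ∞ (return rate k_on·c); at c = 10^6·K_d the
    # path is closed for all but a ~microsecond fraction of the time
    model = GatingModel(K_d=2.0)
    schedule = ConcentrationSchedule.constant(1e6)
    path = sample_gating(model, schedule, duration=500.0, seed=2)[0]
    closed_time = sum(iv.t_end - iv.t_start for iv in path if iv.class_label == "closed")
    assert closed_time / 500.0 > 0.9999
    assert path[0].class_label == "closed"


def test_sample_gating_is_deterministic_for_fixed_seed():
    model = GatingModel()
    schedule = ConcentrationSchedule(events=[(0.0, 10.0, 0.0), (50.0, 10.0, 30.0)])
    a = sample_gating(model, schedule, 200.0, seed=7, n_molecules=3)
    b = sample_gating(model, schedule, 200.0, seed=7, n_molecules=3)
    assert a == b


def test_gating_intervals_tile_duration():
    path = sample_gating(GatingModel(), ConcentrationSchedule.constant(2.0), 300.0, seed=3)[0]
    assert path[0].t_start == 0.0
    assert path[-1].t_end == pytest.approx(300.0)
    for a, b in zip(path[:-1], path[1:]):
        assert a.t_end == pytest.approx(b.t_start)


# -------------------------------------------------------------------- presets


def test_preset_transition_matrix_invariants():
    for preset in CONDITION_PRESETS.values():
        P = preset.transition_matrix()
        pi = np.asarray(preset.occupancy)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert P.min() >= 0
        assert np.allclose(pi @ P, pi)  # stationary by construction
        assert np.allclose(P[1:, 0], preset.return_prob)


def test_preset_sampling_reaches_stationary_statistics():
    preset = CONDITION_PRESETS["3mM"]
    states = sample_preset_states(preset, 20, 2000, seed=5)
    occ = np.bincount(states.ravel(), minlength=4) / states.size
    assert np.allclose(occ, preset.occupancy, atol=0.02)
    a, b = states[:, :-1].ravel(), states[:, 1:].ravel()
    emp_return = (b[a > 0] == 0).mean()
    assert emp_return == pytest.approx(preset.return_prob, abs=0.02)


def test_infeasible_preset_rejected():
    with pytest.raises(ValueError):
        ConditionPreset("bad", 0.0, (0.02, 0.30, 0.30, 0.38), 0.5)


# ------------------------------------------------------------------- rendering


def test_closed_particle_peak_height_is_membrane_plus_protrusion(class_surfaces):
    # membrane 5 nm + protrusion 7 nm = 12 nm total above the support
    assert class_surfaces["closed"].max() == pytest.approx(12.0, abs=0.05)


def test_closed_render_is_five_fold_symmetric(class_surfaces):
    c = center_px()
    patch = class_surfaces["closed"][c - 14 : c + 15, c - 14 : c + 15]
    sym = nfold_average(patch, 5)
    # bilinear interpolation at the steep plateau edge dominates the error
    assert np.abs(sym - patch).max() < 0.2
    assert np.corrcoef(sym.ravel(), patch.ravel())[0, 1] > 0.9999


def test_open2_center_window_exceeds_closed_by_apex_extra(class_surfaces):
    c = center_px()
    w = slice(c - 5, c + 6)  # 5×5 nm center window
    diff = class_surfaces["open2"][w, w].max() - class_surfaces["closed"][w, w].max()
    assert diff == pytest.approx(1.5, abs=0.05)


def test_geometry_invariants_enforced():
    with pytest.raises(ValueError):
        ParticleGeometry(class_label="closed", apex_extra=1.0)
    with pytest.raises(ValueError):
        ParticleGeometry(ring_diameter=12.0)
    with pytest.raises(ValueError):
        ParticleGeometry(class_label="closed", subunit_offsets=(0, 0, 0, 0, 1))


def test_lattice_patch_enforces_min_spacing():
    with pytest.raises(ValueError):
        make_lattice_patch(2, 2, spacing=6.0)


# ---------------------------------------------------------------- tip dilation


def test_tip_dilate_zero_radius_is_identity(class_surfaces):
    s = class_surfaces["closed"]
    assert np.array_equal(tip_dilate(s, 0.0, PX), s)


def test_tip_dilate_never_lowers_any_pixel(class_surfaces):
    for s in class_surfaces.values():
        assert (tip_dilate(s, 2.0, PX) - s).min() >= 0


def test_tip_dilate_spike_matches_naive_neighborhood_oracle():
    # naive O(N·K) oracle: out[x] = max_u surface[x+u] − cap[u]
    rng = np.random.default_rng(0)
    surface = rng.uniform(0, 1, (20, 20))
    surface[10, 10] = 8.0  # single-pixel spike
    tip_r, px = 1.5, 0.5
    k = int(np.ceil(tip_r / px))
    out = np.full_like(surface, -np.inf)
    for r in range(20):
        for c in range(20):
            for dr in range(-k, k + 1):
                for dc in range(-k, k + 1):
                    rho2 = (dr * px) ** 2 + (dc * px) ** 2
                    if rho2 > tip_r**2:
                        continue
                    rr = min(max(r + dr, 0), 19)  # reflect-ish edge like grey_dilation
                    cc = min(max(c + dc, 0), 19)
                    cap = tip_r - np.sqrt(tip_r**2 - rho2)
                    out[r, c] = max(out[r, c], surface[rr, cc] - cap)
    got = tip_dilate(surface, tip_r, px)
    interior = (slice(k, 20 - k), slice(k, 20 - k))
    assert np.allclose(got[interior], out[interior])
    assert got[10, 10] == pytest.approx(8.0)  # apex height preserved


# ---------------------------------------------------------------------- movies


def _tiny_setup(n_particles=(2, 2)):
    from hsafm_gating.synthetic import lattice_frame_shape

    patch = make_lattice_patch(*n_particles)
    grid = ImagingConfig(
        frame_shape=lattice_frame_shape(*n_particles), vertical_noise_sd=0.0
    )
    return patch, grid


def test_saturating_noiseless_movie_has_identical_frames():
    patch, grid = _tiny_setup()
    model = GatingModel(K_d=2.0)
    movie, records = simulate_movie(
        model, ConcentrationSchedule.constant(1e6), patch, grid, duration=3.0, seed=4
    )
    assert movie.n_frames >= 2
    for f in range(1, movie.n_frames):
        assert np.array_equal(movie.frames[f], movie.frames[0])
    assert all(r["class"] == "closed" for r in records)


def test_same_seed_gives_byte_identical_movie():
    patch, grid = _tiny_setup()
    preset = CONDITION_PRESETS["3mM"]
    m1, g1 = simulate_movie(preset, None, patch, grid, duration=5.0, seed=11)
    m2, g2 = simulate_movie(preset, None, patch, grid, duration=5.0, seed=11)
    assert np.array_equal(m1.frames, m2.frames)
    assert g1 == g2


def test_mid_frame_state_switch_renders_intra_frame_mixture(single_patch, single_grid):
    # scripted path: closed until the scan reaches row 14 (above the particle
    # core), open2 afterwards — the frame's lower part must show the dome
    t_switch = single_grid.frame_interval * (14 / 48)
    paths = [
        [
            StateInterval(0.0, t_switch, "closed"),
            StateInterval(t_switch, 10.0, "open2"),
        ]
    ]
    frames = render_state_paths(paths, single_patch, single_grid, n_frames=1)
    closed_ref = tip_dilate(
        render_height_map(ParticleGeometry.for_class("closed"), single_patch, single_grid),
        single_grid.tip_radius,
        PX,
    )
    open2_ref = tip_dilate(
        render_height_map(ParticleGeometry.for_class("open2"), single_patch, single_grid),
        single_grid.tip_radius,
        PX,
    )
    frame = frames[0]
    # rows clear of the switch line (tip dilation mixes a ~4 px margin)
    assert np.allclose(frame[:10], closed_ref[:10], atol=1e-5)
    assert np.allclose(frame[18:], open2_ref[18:], atol=1e-5)
    # the two conformations genuinely differ in the rendered lower part
    assert np.abs(open2_ref[18:] - closed_ref[18:]).max() > 1.0
    assert not np.allclose(frame, closed_ref, atol=0.5)


def test_ground_truth_closed_fraction_at_kd_is_half():
    patch, grid = _tiny_setup((3, 3))
    model = GatingModel(K_d=2.0)
    _, records = simulate_movie(
        model, ConcentrationSchedule.constant(2.0), patch, grid, duration=400.0, seed=13
    )
    total = sum(r["t_end_s"] - r["t_start_s"] for r in records)
    closed = sum(r["t_end_s"] - r["t_start_s"] for r in records if r["class"] == "closed")
    assert closed / total == pytest.approx(0.5, abs=0.08)


def test_movie_roundtrip_io(tmp_path):
    from hsafm_gating.io import load_movie, save_movie

    patch, grid = _tiny_setup()
    movie, _ = simulate_movie(CONDITION_PRESETS["10mM"], None, patch, grid, 2.0, seed=1)
    save_movie(movie, tmp_path / "m")
    back = load_movie(tmp_path / "m")
    assert np.allclose(back.frames, movie.frames)
    assert back.pixel_size == movie.pixel_size
    assert back.line_time == pytest.approx(movie.line_time)
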