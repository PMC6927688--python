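"""Ground-truthed synthetic HS-AFM movies of membrane-embedded pentameric channels.

The simulator emulates raster-scanned height movies of a crowded membrane
patch of pentameric ion channels whose intracellular face gates between four
conformational classes under ligand (Mg²⁺) control:

``closed``
    5-fold symmetric ring of subunit lobes with a central pore dip.
``open1``
    compact asymmetric form, three elevated protrusions of reduced lateral
    extent.
``open2``
    dome-shaped form, one subunit displaced onto the channel axis and raised.
``openplus``
    everything else — asymmetric per-subunit elevations of all kinds, not
    necessarily taller than the closed ring.

Image formation is physical at the level that matters for the downstream
analyses: particles are drawn as smooth Gaussian-cap subunit lobes on a
plateau, the frame is scanned line by line (so states faster than the frame
time produce intra-frame mixtures), the finite tip is applied as grayscale
dilation with a spherical-cap kernel, and vertical Gaussian noise plus linear
scanner drift are added.

Conventions: pixel coordinates are 0-based (row, col) with origin top-left;
physical position (nm) = pixel × pixel_size; heights are nm above the
support plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Movie

__all__ = [
    "CLASSES",
    "ImagingConfig",
    "ParticleGeometry",
    "GatingModel",
    "ConcentrationSchedule",
    "MembranePatch",
    "ConditionPreset",
    "CONDITION_PRESETS",
    "StateInterval",
    "free_mg",
    "sample_gating",
    "sample_preset_states",
    "render_height_map",
    "render_state_paths",
    "tip_dilate",
    "simulate_movie",
    "make_lattice_patch",
    "lattice_frame_shape",
]

#: Conformational classes, in canonical order.
CLASSES = ("closed", "open1", "open2", "openplus")


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------


@dataclass
class ImagingConfig:
    """Raster-scan imaging parameters."""

    pixel_size: float = 0.5  # nm per pixel
    frame_shape: tuple[int, int] = (128, 128)  # (rows, cols) px
    frame_interval: float = 0.55  # s per frame
    vertical_noise_sd: float = 0.1  # nm
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # (row, col) nm/s
    tip_radius: float = 2.0  # nm

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.vertical_noise_sd < 0:
            raise ValueError("vertical_noise_sd must be >= 0")
        if self.tip_radius < 0:
            raise ValueError("tip_radius must be >= 0")

    @property
    def line_time(self) -> float:
        """Time per scan line, s (frame_interval / rows)."""
        return self.frame_interval / self.frame_shape[0]


@dataclass
class ParticleGeometry:
    """Parametric pentamer surface model.

    The particle is a flat-topped plateau of height ``base_protrusion`` above
    the membrane (super-Gaussian profile), carrying ``subunit_count`` Gaussian
    subunit lobes (sigma = ring_diameter/4) whose apexes reach exactly
    ``base_protrusion`` (+ per-class elevation), and a central pore dip of
    depth ``center_dip_depth`` carved into the plateau.  Lobes and plateau are
    combined by pointwise maximum, so the apex height is exact by
    construction.
    """

    class_label: str = "closed"
    outer_diameter: float = 10.9  # nm
    ring_diameter: float = 5.0  # nm (top-ring of subunit lobes)
    base_protrusion: float = 7.0  # nm above membrane
    apex_extra: float = 0.0  # nm added to elevated lobes (open classes)
    subunit_count: int = 5
    center_dip_depth: float = 0.5  # nm
    ring_relief: float = 0.5  # nm height of lobes above the plateau
    orientation: float = 0.0  # azimuth, radians
    subunit_offsets: tuple[float, ...] | None = None  # nm, openplus only

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not self.ring_diameter < self.outer_diameter:
            raise ValueError("ring_diameter must be < outer_diameter")
        if self.subunit_count != 5:
            raise ValueError("the model is pentameric: subunit_count must be 5")
        if self.class_label == "closed":
            if self.apex_extra != 0:
                raise ValueError("closed geometry has apex_extra = 0")
            if self.subunit_offsets is not None and len(set(self.subunit_offsets)) > 1:
                raise ValueError("closed geometry has all subunit offsets equal")

    @classmethod
    def for_class(
        cls,
        class_label: str,
        orientation: float = 0.0,
        subunit_offsets: tuple[float, ...] | None = None,
        apex_extra: float | None = None,
        **kwargs,
    ) -> "ParticleGeometry":
        if apex_extra is None:
            apex_extra = 0.0 if class_label == "closed" else 1.5
        return cls(
            class_label=class_label,
            apex_extra=apex_extra,
            orientation=orientation,
            subunit_offsets=subunit_offsets,
            **kwargs,
        )

    @property
    def lobe_sigma(self) -> float:
        return self.ring_diameter / 4.0

    def lobe_positions(self) -> list[tuple[float, float, float]]:
        """(d_row, d_col, apex_height_above_membrane) of each subunit lobe."""
        r_ring = self.ring_diameter / 2.0
        base = self.base_protrusion
        out: list[tuple[float, float, float]] = []
        if self.class_label == "closed":
            for k in range(5):
                a = self.orientation + 2 * math.pi * k / 5
                out.append((r_ring * math.sin(a), r_ring * math.cos(a), base))
        elif self.class_label == "open1":
            # compact, three elevated lobes, asymmetric azimuths
            r_in = 0.72 * r_ring
            for deg in (0.0, 75.0, 160.0):
                a = self.orientation + math.radians(deg)
                out.append((r_in * math.sin(a), r_in * math.cos(a), base + self.apex_extra))
        elif self.class_label == "open2":
            for k in range(1, 5):
                a = self.orientation + 2 * math.pi * k / 5
                out.append((r_ring * math.sin(a), r_ring * math.cos(a), base))
            out.append((0.0, 0.0, base + self.apex_extra))
        else:  # openplus
            offsets = self.subunit_offsets or (0.0,) * 5
            for k in range(5):
                a = self.orientation + 2 * math.pi * k / 5
                out.append((r_ring * math.sin(a), r_ring * math.cos(a), base + offsets[k]))
        return out


@dataclass
class GatingModel:
    """Ligand-dependent continuous-time Markov gating model.

    Closed → open at rate ``k_off`` (ligand unbinding); any open class →
    closed at rate ``k_on * [Mg²⁺]_free``, so the stationary closed occupancy
    at constant concentration c is c / (c + K_d) with K_d = k_off / k_on.
    ``q_open`` exchanges the three open classes among themselves; entries into
    the open manifold are distributed by ``open_entry_weights``.  While in
    ``openplus`` the five subunit elevations are resampled at
    ``subunit_flicker_rate`` to emulate sub-frame-time subunit fluctuations.
    """

    K_d: float = 2.0  # mM
    k_off: float = 1.0 / 60.0  # s^-1
    k_on: float | None = None  # mM^-1 s^-1; defaults to k_off / K_d
    q_open: np.ndarray | None = None  # 3x3 rate matrix over (open1, open2, openplus)
    open_entry_weights: tuple[float, float, float] = (0.3, 0.3, 0.4)
    subunit_flicker_rate: float = 2.0  # s^-1
    subunit_flicker_amp: float = 0.8  # nm

    def __post_init__(self) -> None:
        if self.k_on is None:
            self.k_on = self.k_off / self.K_d
        if self.k_off <= 0 or self.k_on <= 0:
            raise ValueError("rates must be > 0")
        if not math.isclose(self.k_off / self.k_on, self.K_d, rel_tol=1e-9):
            raise ValueError("k_off / k_on must equal K_d")
        w = np.asarray(self.open_entry_weights, dtype=float)
        if w.min() < 0 or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("open_entry_weights must be probabilities summing to 1")
        if self.q_open is None:
            q = np.full((3, 3), 0.2)
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            self.q_open = q
        else:
            self.q_open = np.asarray(self.q_open, dtype=float)
            off = self.q_open - np.diag(np.diag(self.q_open))
            if off.min() < 0:
                raise ValueError("off-diagonal open-exchange rates must be >= 0")

    def stationary_closed_fraction(self, c: float) -> float:
        return c / (c + self.K_d) if c > 0 else 0.0


@dataclass
class ConcentrationSchedule:
    """Time-stamped total Mg²⁺ / EDTA amounts; free Mg²⁺ by 1:1 chelation."""

    events: list[tuple[float, float, float]]  # (time s, Mg_total mM, EDTA_total mM)
    kd_edta: float = 0.1  # mM, conditional 1:1 dissociation constant (pH 6)

    def __post_init__(self) -> None:
        times = [e[0] for e in self.events]
        if not self.events:
            raise ValueError("schedule needs at least one event")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(e[1] < 0 or e[2] < 0 for e in self.events):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def constant(cls, mg_mM: float) -> "ConcentrationSchedule":
        return cls(events=[(0.0, mg_mM, 0.0)])

    def totals_at(self, t: float) -> tuple[float, float]:
        mg, edta = self.events[0][1], self.events[0][2]
        for et, emg, eedta in self.events:
            if et <= t:
                mg, edta = emg, eedta
            else:
                break
        return mg, edta

    def free_mg_at(self, t: float) -> float:
        mg, edta = self.totals_at(t)
        return free_mg(mg, edta, self.kd_edta)

    def breakpoints(self) -> list[float]:
        return [e[0] for e in self.events]


@dataclass
class MembranePatch:
    """Particle layout on a supported membrane.

    ``particle_centers`` are (row, col) positions in nm.  The membrane top
    sits ``membrane_top_height`` nm above the support (0 nm reference); an
    optional ``membrane_rect`` (row0, col0, row1, col1, nm) restricts the
    membrane to a sub-rectangle, exposing bare support elsewhere.
    """

    particle_centers: np.ndarray
    membrane_top_height: float = 5.0
    lattice_spacing: float = 14.0
    membrane_rect: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.particle_centers = np.atleast_2d(np.asarray(self.particle_centers, dtype=float))

    def validate_spacing(self, outer_diameter: float = 10.9) -> None:
        c = self.particle_centers
        if len(c) > 1:
            d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.8 * outer_diameter:
                raise ValueError("particles closer than 0.8 x outer_diameter")


def lattice_frame_shape(
    n_rows: int,
    n_cols: int,
    spacing: float = 14.0,
    margin: float = 10.0,
    pixel_size: float = 0.5,
) -> tuple[int, int]:
    """Frame shape (rows, cols) px that holds the lattice with its margin."""
    extent_r = 2 * margin + (n_rows - 1) * spacing
    extent_c = 2 * margin + (n_cols - 1) * spacing + (spacing / 2 if n_rows > 1 else 0.0)
    return (int(math.ceil(extent_r / pixel_size)), int(math.ceil(extent_c / pixel_size)))


def make_lattice_patch(
    n_rows: int,
    n_cols: int,
    spacing: float = 14.0,
    margin: float = 10.0,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> MembranePatch:
    """Quasi-hexagonal particle lattice with a clear margin, full membrane."""
    rng = rng or np.random.default_rng(0)
    centers = []
    for i in range(n_rows):
        for j in range(n_cols):
            r = margin + i * spacing
            c = margin + j * spacing + (spacing / 2 if i % 2 else 0.0)
            if jitter > 0:
                r += rng.uniform(-jitter, jitter)
                c += rng.uniform(-jitter, jitter)
            centers.append((r, c))
    patch = MembranePatch(particle_centers=np.array(centers), lattice_spacing=spacing, **kwargs)
    patch.validate_spacing()
    return patch


# --------------------------------------------------------------------------
# chelation equilibrium
# --------------------------------------------------------------------------


def free_mg(mg_total: float, edta_total: float, kd_edta: float) -> float:
    """Free Mg²⁺ (mM) from totals under 1:1 Mg–EDTA binding mass balance.

    Solves x² + (EDTA − Mg + K)x − K·Mg = 0 for its positive root,
    which always lies in [0, mg_total].
    """
    if mg_total < 0 or edta_total < 0 or kd_edta < 0:
        raise ValueError("concentrations and K_d must be >= 0")
    if kd_edta == 0:
        return max(mg_total - edta_total, 0.0)
    b = edta_total - mg_total + kd_edta
    x = 0.5 * (-b + math.sqrt(b * b + 4.0 * kd_edta * mg_total))
    return min(max(x, 0.0), mg_total)


# --------------------------------------------------------------------------
# gating state sampling
# --------------------------------------------------------------------------


@dataclass
class StateInterval:
    """Constant-conformation interval of one molecule's gating path."""

    t_start: float
    t_end: float
    class_label: str
    orientation: float = 0.0
    subunit_offsets: tuple[float, ...] | None = None


def _draw_flicker_offsets(rng: np.random.Generator, amp: float) -> tuple[float, ...]:
    # enforce genuine asymmetry: resample until the subunit spread is large
    for _ in range(100):
        off = rng.uniform(-amp, amp, size=5)
        if off.max() - off.min() >= 0.6 * amp:
            return tuple(off)
    return tuple(off)


def sample_gating(
    model: GatingModel,
    schedule: ConcentrationSchedule,
    duration: float,
    seed: int | np.random.Generator,
    n_molecules: int = 1,
) -> list[list[StateInterval]]:
    """Gillespie-sample per-molecule gating paths under a concentration schedule.

    The closed→open rate is ``k_off``; the open→closed rate is
    ``k_on · [Mg²⁺]_free(t)`` (piecewise constant between schedule events, so
    waiting times are redrawn at each breakpoint, which is exact for
    exponential clocks).  Returns one list of :class:`StateInterval` per
    molecule; intervals tile [0, duration].
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    open_classes = CLASSES[1:]
    bps = [t for t in schedule.breakpoints() if 0.0 < t < duration]
    paths: list[list[StateInterval]] = []
    for _ in range(n_molecules):
        t = 0.0
        c = schedule.free_mg_at(0.0)
        # stationary initial state at the starting concentration
        if rng.random() < model.stationary_closed_fraction(c):
            state = "closed"
        else:
            state = open_classes[rng.choice(3, p=np.asarray(model.open_entry_weights))]
        orientation = rng.uniform(0.0, 2 * math.pi)
        offsets = (
            _draw_flicker_offsets(rng, model.subunit_flicker_amp) if state == "openplus" else None
        )
        intervals: list[StateInterval] = []
        seg_start = 0.0
        next_bp = iter(bps + [duration])
        bp = next(next_bp)
        while t < duration:
            if state == "closed":
                labels = list(open_classes)
                rates = [model.k_off * w for w in model.open_entry_weights]
            else:
                i = open_classes.index(state)
                labels = ["closed"] + [open_classes[j] for j in range(3) if j != i]
                rates = [model.k_on * c] + [model.q_open[i, j] for j in range(3) if j != i]
                if state == "openplus":
                    labels.append("__flicker__")
                    rates.append(model.subunit_flicker_rate)
            total = float(sum(rates))
            dt = rng.exponential(1.0 / total) if total > 0 else math.inf
            if t + dt >= bp:
                # advance to the breakpoint; the exponential clock is memoryless
                t = bp
                if t >= duration:
                    break
                c = schedule.free_mg_at(t)
                bp = next(next_bp)
                continue
            t += dt
            k = rng.choice(len(rates), p=np.asarray(rates) / total)
            event = labels[k]
            intervals.append(StateInterval(seg_start, t, state, orientation, offsets))
            seg_start = t
            if event == "__flicker__":
                offsets = _draw_flicker_offsets(rng, model.subunit_flicker_amp)
            else:
                prev = state
                state = event
                if state == "closed":
                    offsets = None
                else:
                    if prev == "closed":
                        orientation = rng.uniform(0.0, 2 * math.pi)
                    offsets = (
                        _draw_flicker_offsets(rng, model.subunit_flicker_amp)
                        if state == "openplus"
                        else None
                    )
        intervals.append(StateInterval(seg_start, duration, state, orientation, offsets))
        paths.append(intervals)
    return paths


# --------------------------------------------------------------------------
# per-condition discrete presets (steady-state movie sections)
# --------------------------------------------------------------------------


@dataclass
class ConditionPreset:
    """Per-frame 4-class Markov chain for a steady-state imaging condition.

    ``occupancy`` is the stationary class distribution (order: closed, open1,
    open2, openplus); ``return_prob`` is the aggregate conditional probability
    that a molecule in any open class is back in the closed class one frame
    later.  The frame-to-frame transition matrix is constructed so that the
    chain's stationary law equals ``occupancy`` exactly and every open row has
    closed-return probability ``return_prob``.
    """

    name: str
    mg_mM: float
    occupancy: tuple[float, float, float, float]
    return_prob: float
    noise_sd: float = 0.1  # nm
    drift_velocity: tuple[float, float] = (0.02, 0.03)  # nm/s
    flicker_amp: float = 0.8  # nm, openplus subunit spread

    def __post_init__(self) -> None:
        pi = np.asarray(self.occupancy, dtype=float)
        if pi.min() < 0 or not math.isclose(pi.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("occupancy must be a probability vector")
        pi_c = pi[0]
        if pi_c * 1.0 < (1 - pi_c) * self.return_prob:
            raise ValueError("occupancy/return_prob combination infeasible")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 4×4 frame-to-frame matrix with the preset invariants."""
        pi = np.asarray(self.occupancy, dtype=float)
        pi_c = pi[0]
        mu = pi[1:] / pi[1:].sum()
        r = self.return_prob
        p_cc = 1.0 - (1.0 - pi_c) * r / pi_c
        P = np.zeros((4, 4))
        P[0, 0] = p_cc
        P[0, 1:] = (1.0 - p_cc) * mu
        for i in range(1, 4):
            P[i, 0] = r
            P[i, 1:] = (1.0 - r) * mu
        return P


#: Steady-state condition presets.  The printed anchors are the saturating
#: closed occupancy (~91%), the intermediate open-+ pool (~50%), the partial
#: recovery after re-addition (~35% closed) and the open→closed return
#: probabilities (~14% at 3 mM, ~7% at 0 mM); the remaining cells are chosen
#: to match the qualitative picture (elevated states favored at 0 mM).
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "10mM": ConditionPreset("10mM", 10.0, (0.91, 0.03, 0.03, 0.03), 0.50),
    "3mM": ConditionPreset("3mM", 3.0, (0.15, 0.15, 0.20, 0.50), 0.14),
    "0mM": ConditionPreset("0mM", 0.0, (0.10, 0.25, 0.30, 0.35), 0.07),
    "readdition": ConditionPreset("readdition", 25.0, (0.35, 0.15, 0.20, 0.30), 0.25),
}


def sample_preset_states(
    preset: ConditionPreset,
    n_molecules: int,
    n_frames: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Per-frame class indices (n_molecules, n_frames), stationary start."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = preset.transition_matrix()
    pi = np.asarray(preset.occupancy)
    states = np.empty((n_molecules, n_frames), dtype=np.int64)
    for m in range(n_molecules):
        s = rng.choice(4, p=pi)
        for f in range(n_frames):
            states[m, f] = s
            s = rng.choice(4, p=P[s])
    return states


# --------------------------------------------------------------------------
# image formation
# --------------------------------------------------------------------------

_PEDESTAL_EXP = 8  # super-Gaussian sharpness of the plateau edge


def _particle_relative_height(
    geom: ParticleGeometry, dr: np.ndarray, dc: np.ndarray
) -> np.ndarray:
    """Particle height above the membrane on a grid of offsets (nm) from center."""
    d2 = dr**2 + dc**2
    r_ped = 0.95 * geom.outer_diameter / 2.0
    ped = (geom.base_protrusion - geom.ring_relief) * np.exp(
        -((np.sqrt(d2) / r_ped) ** _PEDESTAL_EXP)
    )
    sig_dip = geom.ring_diameter / 5.0
    ped = ped - geom.center_dip_depth * np.exp(-d2 / (2.0 * sig_dip**2))
    out = ped
    s2 = 2.0 * geom.lobe_sigma**2
    for lr, lc, h in geom.lobe_positions():
        lobe = h * np.exp(-(((dr - lr) ** 2) + ((dc - lc) ** 2)) / s2)
        out = np.maximum(out, lobe)
    return np.clip(out, 0.0, None)


def _membrane_base(patch: MembranePatch, grid: ImagingConfig) -> np.ndarray:
    rows, cols = grid.frame_shape
    base = np.full((rows, cols), patch.membrane_top_height, dtype=float)
    if patch.membrane_rect is not None:
        r0, c0, r1, c1 = (v / grid.pixel_size for v in patch.membrane_rect)
        mask = np.zeros((rows, cols), dtype=bool)
        mask[int(round(r0)) : int(round(r1)), int(round(c0)) : int(round(c1))] = True
        base[~mask] = 0.0
    return base


def _draw_particle(
    surface: np.ndarray,
    grid: ImagingConfig,
    center_nm: np.ndarray,
    geom: ParticleGeometry,
    membrane_top: float,
    row_range: tuple[int, int] | None = None,
) -> None:
    """Max-combine one particle into ``surface`` (restricted to ``row_range``)."""
    px = grid.pixel_size
    extent = geom.outer_diameter / 2.0 + 2.5  # nm beyond which the particle is flat
    r_lo = max(int(math.floor((center_nm[0] - extent) / px)), 0)
    r_hi = min(int(math.ceil((center_nm[0] + extent) / px)) + 1, surface.shape[0])
    c_lo = max(int(math.floor((center_nm[1] - extent) / px)), 0)
    c_hi = min(int(math.ceil((center_nm[1] + extent) / px)) + 1, surface.shape[1])
    if row_range is not None:
        r_lo = max(r_lo, row_range[0])
        r_hi = min(r_hi, row_range[1])
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi) * px - center_nm[0]
    cc = np.arange(c_lo, c_hi) * px - center_nm[1]
    dr, dc = np.meshgrid(rr, cc, indexing="ij")
    h = membrane_top + _particle_relative_height(geom, dr, dc)
    np.maximum(surface[r_lo:r_hi, c_lo:c_hi], h, out=surface[r_lo:r_hi, c_lo:c_hi])


def render_height_map(
    geometry: ParticleGeometry | list[ParticleGeometry],
    patch: MembranePatch,
    grid: ImagingConfig,
) -> np.ndarray:
    """True (pre-tip) surface of the patch, nm above the support plane.

    ``geometry`` is either one :class:`ParticleGeometry` applied to every
    center or a list with one geometry per particle.
    """
    centers = patch.particle_centers
    geoms = [geometry] * len(centers) if isinstance(geometry, ParticleGeometry) else list(geometry)
    if len(geoms) != len(centers):
        raise ValueError("need one geometry per particle center")
    surface = _membrane_base(patch, grid)
    for center, geom in zip(centers, geoms):
        _draw_particle(surface, grid, center, geom, patch.membrane_top_height)
    return surface


def tip_dilate(surface: np.ndarray, tip_radius: float, pixel_size: float) -> np.ndarray:
    """Image the surface with a spherical-cap tip by grayscale dilation.

    The imaged height at x is max_u [surface(x+u) − cap(u)] with
    cap(u) = R − sqrt(R² − |u|²): the lowest position at which a sphere of
    radius R touches the surface.  Output ≥ input everywhere; equality at
    every point the tip apex can touch, tip_radius = 0 is the identity.
    """
    if tip_radius < 0:
        raise ValueError("tip_radius must be >= 0")
    if tip_radius == 0:
        return surface.copy()
    k = int(math.ceil(tip_radius / pixel_size))
    u = np.arange(-k, k + 1) * pixel_size
    du, dv = np.meshgrid(u, u, indexing="ij")
    rho2 = du**2 + dv**2
    inside = rho2 <= tip_radius**2
    cap = np.where(inside, tip_radius - np.sqrt(np.clip(tip_radius**2 - rho2, 0, None)), 0.0)
    struct = np.where(inside, -cap, -1e9)
    return ndimage.grey_dilation(surface, structure=struct)


# --------------------------------------------------------------------------
# movie synthesis
# --------------------------------------------------------------------------


def _geometry_for_interval(iv: StateInterval, flicker_amp: float = 0.8) -> ParticleGeometry:
    return ParticleGeometry.for_class(
        iv.class_label, orientation=iv.orientation, subunit_offsets=iv.subunit_offsets
    )


def _preset_paths(
    preset: ConditionPreset,
    n_molecules: int,
    n_frames: int,
    frame_interval: float,
    rng: np.random.Generator,
) -> list[list[StateInterval]]:
    """Frame-resolved interval paths from the discrete preset chain."""
    states = sample_preset_states(preset, n_molecules, n_frames, rng)
    paths = []
    for m in range(n_molecules):
        orientation = rng.uniform(0, 2 * math.pi)
        ivs = []
        for f in range(n_frames):
            lab = CLASSES[states[m, f]]
            if lab != "closed" and (f == 0 or states[m, f] != states[m, f - 1]):
                orientation = rng.uniform(0, 2 * math.pi)
            offsets = (
                _draw_flicker_offsets(rng, preset.flicker_amp) if lab == "openplus" else None
            )
            ivs.append(
                StateInterval(f * frame_interval, (f + 1) * frame_interval, lab, orientation, offsets)
            )
        paths.append(ivs)
    return paths


def _ground_truth_records(paths: list[list[StateInterval]], duration: float) -> list[dict]:
    records = []
    for m, ivs in enumerate(paths):
        cur = None
        for iv in ivs:
            if iv.t_start >= duration:
                break
            t0, t1 = iv.t_start, min(iv.t_end, duration)
            if cur is not None and cur["class"] == iv.class_label:
                cur["t_end_s"] = t1
            else:
                if cur is not None:
                    records.append(cur)
                cur = {"molecule_id": m, "t_start_s": t0, "t_end_s": t1, "class": iv.class_label}
        if cur is not None:
            records.append(cur)
    return records


def simulate_movie(
    model: GatingModel | ConditionPreset,
    schedule: ConcentrationSchedule | None,
    patch: MembranePatch,
    grid: ImagingConfig,
    duration: float,
    seed: int,
) -> tuple[Movie, list[dict]]:
    """Render a ground-truthed movie of the patch under the gating model.

    Frames are rendered line by line: scan line i of frame f reflects each
    molecule's conformation at time f·frame_interval + i·line_time, so states
    faster than the frame time produce intra-frame mixtures.  Linear scanner
    drift displaces all particle centers; vertical Gaussian noise is added
    last (after tip dilation).  Returns the movie and the ground-truth log,
    one record per constant-class interval per molecule.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n_frames = max(int(round(duration / grid.frame_interval)), 1)
    n_mol = len(patch.particle_centers)
    if isinstance(model, ConditionPreset):
        paths = _preset_paths(model, n_mol, n_frames, grid.frame_interval, rng)
        noise_sd = model.noise_sd
        drift = model.drift_velocity
    else:
        if schedule is None:
            raise ValueError("a ConcentrationSchedule is required with a GatingModel")
        paths = sample_gating(model, schedule, duration, rng, n_molecules=n_mol)
        noise_sd = grid.vertical_noise_sd
        drift = grid.drift_velocity
    frames = render_state_paths(
        paths, patch, grid, n_frames, noise_sd=noise_sd, drift_velocity=drift, rng=rng
    )
    movie = Movie(
        frames=frames,
        pixel_size=grid.pixel_size,
        frame_interval=grid.frame_interval,
        line_time=grid.line_time,
    )
    return movie, _ground_truth_records(paths, duration)


def render_state_paths(
    paths: list[list[StateInterval]],
    patch: MembranePatch,
    grid: ImagingConfig,
    n_frames: int,
    noise_sd: float = 0.0,
    drift_velocity: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Line-by-line render of explicit per-molecule state-interval paths.

    The workhorse behind :func:`simulate_movie`; useful on its own for
    scripted conformational sequences (e.g. a state switch at a chosen time
    inside a frame).
    """
    rng = rng or np.random.default_rng(0)
    drift = np.asarray(drift_velocity, dtype=float)
    n_mol = len(patch.particle_centers)
    base = _membrane_base(patch, grid)
    rows, cols = grid.frame_shape
    lt = grid.line_time
    frames = np.empty((n_frames, rows, cols), dtype=np.float32)
    cursors = [0] * n_mol
    for f in range(n_frames):
        t_f = f * grid.frame_interval
        surface = base.copy()
        offset = drift * t_f
        for m in range(n_mol):
            center = patch.particle_centers[m] + offset
            ivs = paths[m]
            # row band this molecule can touch
            extent = 10.9 / 2.0 + 2.5
            r0 = max(int(math.floor((center[0] - extent) / grid.pixel_size)), 0)
            r1 = min(int(math.ceil((center[0] + extent) / grid.pixel_size)) + 1, rows)
            if r0 >= r1:
                continue
            # advance cursor past intervals that ended before this frame's band
            i = cursors[m]
            while i + 1 < len(ivs) and ivs[i].t_end <= t_f + r0 * lt:
                i += 1
            cursors[m] = i
            r = r0
            while r < r1:
                iv = ivs[i]
                # last row (exclusive) still inside this interval
                if iv.t_end >= t_f + (r1 - 1) * lt or i == len(ivs) - 1:
                    r_stop = r1
                else:
                    r_stop = min(int(math.floor((iv.t_end - t_f) / lt)) + 1, r1)
                    r_stop = max(r_stop, r + 1)
                geom = _geometry_for_interval(iv)
                _draw_particle(
                    surface, grid, center, geom, patch.membrane_top_height, row_range=(r, r_stop)
                )
                r = r_stop
                while i + 1 < len(ivs) and ivs[i].t_end <= t_f + r * lt:
                    i += 1
        imaged = tip_dilate(surface, grid.tip_radius, grid.pixel_size)
        if noise_sd > 0:
            imaged = imaged + rng.normal(0.0, noise_sd, size=imaged.shape)
        frames[f] = imaged
    return frames
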