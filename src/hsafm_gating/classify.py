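"""Four-class conformational classification of per-frame particle snapshots.

Each tracked molecule snapshot is reduced to shape features and assigned by
a fixed decision list to one of the four conformational classes
(``closed`` — 5-fold symmetric ring; ``open2`` — dome with elevated center;
``open1`` — compact, three elevated protrusions; ``openplus`` — any other
asymmetric form).  Features:

``S5``
    mean Pearson correlation between the mean-subtracted core of the patch
    and its 72°·k rotations (k = 1..4), on a disk around the center, so the
    rotationally symmetric membrane surround does not inflate it.
``apex`` / ``apex_offset``
    maximum height above the local membrane (annulus median at 1.2–1.5 ×
    the outer radius) inside the core, and the distance of that maximum
    from the center.
``n_lobes``
    count of suppressed local maxima within 1 nm of the apex.
``eccentricity``
    sqrt(1 − λ_min/λ_max) of the second moments of the near-apex footprint.

The decision list (order matters):
closed if S5 ≥ s_thr and apex < h_thr; open2 if apex ≥ h_thr and
apex_offset ≤ r_core; open1 if apex ≥ h_thr, n_lobes ≤ 3 and
eccentricity ≥ e_thr; else openplus.  Features, and hence the classifier,
are invariant under 72° rotation and any constant height offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max

from .synthetic import CLASSES

__all__ = [
    "SnapshotFeatures",
    "ClassifierThresholds",
    "extract_features",
    "classify_snapshot",
    "occupancy",
    "transition_matrix",
    "return_to_closed_probability",
    "occupancy_test",
    "TransitionMatrix",
]


@dataclass
class SnapshotFeatures:
    s5: float  # 5-fold rotational correlation, in [-1, 1]; NaN when flat
    apex: float  # nm above local membrane
    apex_offset: float  # nm from the tracked center
    n_lobes: int
    eccentricity: float
    local_membrane: float  # nm, reference level used


@dataclass
class ClassifierThresholds:
    """Decision-list thresholds, tuned on noiseless simulator renders only.

    ``h_thr`` sits midway between the closed apex (~7 nm) and the elevated
    open apex (~8.5 nm) above the local membrane.
    """

    s_thr: float = 0.80
    h_thr: float = 7.75  # nm above local membrane
    r_core: float = 1.5  # nm
    e_thr: float = 0.65
    n_lobes_max: int = 3
    outer_diameter: float = 10.9  # nm, sets annulus and core radii


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def extract_features(
    particle_patch: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    thresholds: ClassifierThresholds | None = None,
    smooth_sigma: float = 0.3,
) -> SnapshotFeatures:
    """Shape features of one particle snapshot.

    ``particle_patch`` must span at least the outer diameter around
    ``center`` (px); the local membrane reference is a low percentile of the
    annulus at 1.2–1.5 × the outer radius (in crowded patches the annulus
    median rides on the tip-broadened flanks of the neighbors, while the
    inter-particle gaps still reach the membrane), so the patch should
    extend that far where possible.
    """
    thr = thresholds or ClassifierThresholds()
    patch = np.asarray(particle_patch, dtype=float)
    if min(patch.shape) * pixel_size < thr.outer_diameter:
        raise ValueError("patch smaller than the particle outer diameter")
    sm = ndimage.gaussian_filter(patch, smooth_sigma / pixel_size)
    r_out = thr.outer_diameter / 2.0
    rr, cc = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]]
    d_nm = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2) * pixel_size
    annulus = (d_nm >= 1.2 * r_out) & (d_nm <= 1.5 * r_out)
    local_membrane = (
        float(np.percentile(sm[annulus], 15)) if annulus.any() else float(np.min(sm))
    )

    core = d_nm <= 0.65 * r_out + 1.0  # covers ring lobes incl. lobe width
    core_vals = sm[core] - local_membrane
    apex = float(core_vals.max())
    idx = np.flatnonzero(core.ravel())[int(np.argmax(core_vals))]
    pr, pc = np.unravel_index(idx, patch.shape)
    apex_offset = float(np.hypot(pr - center[0], pc - center[1]) * pixel_size)

    # 5-fold rotational correlation on the core disk; the disk stops short of
    # the (rotationally symmetric) plateau edge, which would otherwise
    # dominate the variance and inflate S5 for asymmetric conformations.
    # A heavier smoothing is used for this feature alone: the symmetry
    # contrast lives at the subunit-lobe scale, so extra noise suppression
    # stabilizes S5 without erasing it.
    sm5 = ndimage.gaussian_filter(patch, 0.6 / pixel_size)
    s5_mask = d_nm <= 0.70 * r_out
    base_vals = sm5[s5_mask]
    if np.ptp(base_vals) == 0:
        s5 = float("nan")
    else:
        corrs = []
        for k in range(1, 5):
            rot = _rotate_about(sm5, center, 2 * np.pi * k / 5)
            corrs.append(np.corrcoef(base_vals, rot[s5_mask])[0, 1])
        s5 = float(np.mean(corrs))

    # lobes within 1 nm of the apex, suppressed at 1.5 nm
    lobe_thr = local_membrane + apex - 1.0
    peaks = peak_local_max(
        np.where(d_nm <= 0.8 * r_out, sm, -np.inf),
        min_distance=max(int(round(1.5 / pixel_size)), 1),
        threshold_abs=lobe_thr,
        exclude_border=False,
    )
    n_lobes = len(peaks)

    # eccentricity of the near-apex footprint
    foot = (sm >= lobe_thr) & (d_nm <= 0.8 * r_out)
    if foot.sum() >= 3:
        pts = np.column_stack(np.nonzero(foot)).astype(float)
        cov = np.cov(pts.T)
        evals = np.sort(np.linalg.eigvalsh(cov))
        ecc = float(np.sqrt(max(1.0 - evals[0] / evals[1], 0.0))) if evals[1] > 0 else 0.0
    else:
        ecc = 0.0
    return SnapshotFeatures(
        s5=s5,
        apex=apex,
        apex_offset=apex_offset,
        n_lobes=n_lobes,
        eccentricity=ecc,
        local_membrane=local_membrane,
    )


def _rotate_about(patch: np.ndarray, center: tuple[float, float], angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    return ndimage.map_coordinates(
        patch, [center[0] + ca * dr - sa * dc, center[1] + sa * dr + ca * dc], order=1,
        mode="nearest",
    )


def classify_snapshot(
    features: SnapshotFeatures, thresholds: ClassifierThresholds | None = None
) -> str:
    """Decision-list class assignment; see the module docstring for the rules."""
    thr = thresholds or ClassifierThresholds()
    f = features
    if np.isnan(f.s5):
        return "openplus"
    if f.s5 >= thr.s_thr and f.apex < thr.h_thr:
        return "closed"
    if f.apex >= thr.h_thr and f.apex_offset <= thr.r_core and f.eccentricity < thr.e_thr:
        return "open2"
    if f.apex >= thr.h_thr and f.n_lobes <= thr.n_lobes_max and f.eccentricity >= thr.e_thr:
        return "open1"
    return "openplus"


# --------------------------------------------------------------------------
# population statistics
# --------------------------------------------------------------------------


def occupancy(labels: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Mean class occupancy (%) with s.e.m. across molecules.

    ``labels`` needs columns molecule_id, frame, class.  Per-molecule class
    fractions are computed first; the table reports their mean and standard
    error across molecules (matching error bars computed across molecules,
    not pooled frames).
    """
    mols = labels["molecule_id"].unique()
    if len(mols) < 2:
        raise ValueError("occupancy needs >= 2 molecules")
    frac = np.zeros((len(mols), len(CLASSES)))
    for i, m in enumerate(mols):
        sub = labels.loc[labels["molecule_id"] == m, "class"]
        for j, cls in enumerate(CLASSES):
            frac[i, j] = (sub == cls).mean()
    mean = 100.0 * frac.mean(axis=0)
    sem = 100.0 * frac.std(axis=0, ddof=1) / np.sqrt(len(mols))
    out = pd.DataFrame(
        {
            "class": CLASSES,
            "mean_pct": mean,
            "sem_pct": sem,
            "n_molecules": len(mols),
            "n_frames": len(labels),
        }
    )
    if condition is not None:
        out.insert(0, "condition", condition)
    return out


@dataclass
class TransitionMatrix:
    """Frame(n)→frame(n+1) class transitions.

    ``percentages`` are row-normalized (per origin state), the convention
    under which an aggregate open→closed entry reads as a conditional
    return probability.  Block sums cover the elevated ({open2, open1}²)
    and elongated ({open1, openplus}²) 2×2 blocks.
    """

    counts: np.ndarray  # 4×4 ints, rows = frame n, cols = frame n+1
    percentages: np.ndarray  # row-normalized, NaN rows where no counts
    elevated_block_sum: float  # % of all transitions
    elongated_block_sum: float

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


def transition_matrix(labels: pd.DataFrame) -> TransitionMatrix:
    """Count consecutive same-molecule frame pairs and row-normalize."""
    idx = {c: i for i, c in enumerate(CLASSES)}
    counts = np.zeros((4, 4), dtype=int)
    for _, sub in labels.sort_values("frame").groupby("molecule_id"):
        cl = sub["class"].map(idx).to_numpy()
        fr = sub["frame"].to_numpy()
        consec = np.diff(fr) == 1
        np.add.at(counts, (cl[:-1][consec], cl[1:][consec]), 1)
    if counts.sum() < 1:
        raise ValueError("need at least 2 frames of labels")
    with np.errstate(invalid="ignore"):
        pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    total = counts.sum()
    elev = [idx["open2"], idx["open1"]]
    elon = [idx["open1"], idx["openplus"]]
    elevated = 100.0 * counts[np.ix_(elev, elev)].sum() / total
    elongated = 100.0 * counts[np.ix_(elon, elon)].sum() / total
    return TransitionMatrix(
        counts=counts,
        percentages=pct,
        elevated_block_sum=float(elevated),
        elongated_block_sum=float(elongated),
    )


def return_to_closed_probability(matrix: TransitionMatrix) -> float:
    """Aggregate conditional probability (%) that any open class returns to closed."""
    open_rows = matrix.counts[1:, :]
    total = open_rows.sum()
    if total == 0:
        raise ValueError("no transitions out of open classes")
    return float(100.0 * open_rows[:, 0].sum() / total)


def occupancy_test(
    fractions_a: np.ndarray, fractions_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample two-tailed Welch t test on per-molecule class fractions."""
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 molecules per condition")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples: p undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
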