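# Methods

`hsafm-gating` reimplements, as a tested pipeline, the single-molecule
analysis used to characterize Mg²⁺-dependent gating of a pentameric ion
channel (CorA-type Mg²⁺ channels) in high-speed AFM (HS-AFM) height movies:
ΔHeight trace extraction, STaSI state idealization, dwell/transition
statistics, four-class conformational classification, titration K_d
estimation, and an elastic-rod treatment of the long TM1 helix.  Because no
raw movies are deposited for this kind of experiment, the package includes a
first-class synthetic movie generator that emulates the experimental conditions;
every downstream stage is validated against the generator's ground truth.

## Synthetic HS-AFM movies

**Particle model.**  A channel seen from its intracellular face is drawn as
a flat-topped plateau (super-Gaussian of exponent 8, radius 0.95 × the
5.45 nm outer radius) of height `base_protrusion` = 7 nm above the membrane,
carrying five Gaussian subunit lobes (σ = ring_diameter/4 = 1.25 nm) on a
ring of diameter 5.0 nm, and a central pore dip of 0.5 nm carved into the
plateau.  Plateau and lobes combine by pointwise maximum, so the apex height
is exact by construction: the closed particle peaks at
membrane (5 nm) + 7 nm = 12 nm above the support, and its 5 × 5 nm
center-window ΔHeight is ring relief (0.5) + dip (0.5) ≈ 1 nm.  The four
conformational classes are parametric variants:

- **closed** — exactly 72°-rotation-symmetric ring;
- **open-I** — three lobes elevated by `apex_extra` = 1.5 nm at 0.72 × the
  ring radius, asymmetric azimuths (0°, 75°, 160°): compact, elongated,
  eccentric footprint;
- **open-II** — one lobe displaced onto the axis and raised by 1.5 nm
  (dome), four ring lobes retained;
- **open-+** — per-subunit elevation offsets drawn uniformly in ±0.8 nm,
  redrawn until the spread (max − min) exceeds 0.6 × the amplitude, because
  the class denotes *genuinely asymmetric* molecules; offsets resample at
  the subunit flicker rate (2 s⁻¹) or every frame in the per-condition
  presets, emulating sub-frame-time subunit fluctuations.

The default dimensions follow the measured morphometrics of the CorA
intracellular face under HS-AFM (top-ring 5.0 nm, outer diameter 10.9 nm,
~7 nm intracellular protrusion, membrane+protein ≈ 12 nm, lattice
periodicity ≈ 14 nm).  Ring relief and
dip depth (0.5 nm each) are set so the closed-state window ΔHeight is the
reported ~1 nm.

**Image formation.**  Frames are raster-scanned line by line: scan line *i*
of frame *f* reflects each molecule's conformation at time
`f·frame_interval + i·line_time`, so gating faster than the frame time
produces intra-frame chimeras, as in real HS-AFM.  The finite tip is a
spherical cap of radius 2 nm applied as grayscale dilation
(`imaged(x) = max_u [surface(x+u) − cap(u)]`), which never lowers a pixel
and preserves apex heights at touchable peaks.  Defaults: 0.5 nm px⁻¹,
0.55 s per frame, vertical Gaussian noise σ = 0.1 nm, linear scanner drift.
Cantilever dynamics, feedback artifacts and parachuting are out of scope.

**Gating models.**  Two interchangeable state processes drive the movies:

1. `GatingModel` — a continuous-time Markov chain over
   {closed, open-I, open-II, open-+}.  Closed → open at `k_off` (ligand
   unbinding, default 1/60 s⁻¹); open → closed at `k_on · [Mg²⁺]_free(t)`
   with `k_off/k_on = K_d` = 2 mM, giving stationary closed occupancy
   c/(c + K_d); a symmetric 0.2 s⁻¹ exchange among the open classes.  Free
   Mg²⁺ follows 1:1 Mg–EDTA mass balance (conditional K_d 0.1 mM at pH 6)
   under a time-stamped concentration schedule; Gillespie sampling redraws
   waiting times at schedule breakpoints (exact for exponential clocks).
2. `ConditionPreset` — a per-frame 4-class chain for steady-state movie
   sections at fixed Mg²⁺.  Given a target stationary occupancy π and an
   aggregate open→closed return probability r, the transition matrix is
   built as: closed row stays with `p_cc = 1 − (1−π_c)·r/π_c`, every open
   row returns with r, and all remaining mass is distributed over the open
   classes proportionally to π — a construction whose stationary law equals
   π exactly.

**Preset calibration.**  The per-condition anchors are the reported
population statistics for CorA at these conditions: closed ≈ 91% at 10 mM, open-+ ≈ 50% at 3 mM,
closed ≈ 35% after re-addition of 25 mM, and return probabilities ≈ 14%
(3 mM) and ≈ 7% (0 mM).  The cells not reported anywhere were fixed once at
values consistent with the qualitative description (asymmetric classes
dominate at low Mg²⁺; the elevated open-II class is favored at 0 mM):

| condition  | closed | open-I | open-II | open-+ | return r |
|-----------|-------:|-------:|--------:|-------:|---------:|
| 10 mM     |   0.91 |   0.03 |    0.03 |   0.03 |     0.50 |
| 3 mM      |   0.15 |   0.15 |    0.20 |   0.50 |     0.14 |
| 0 mM      |   0.10 |   0.25 |    0.30 |   0.35 |     0.07 |
| re-add 25 |   0.35 |   0.15 |    0.20 |   0.30 |     0.25 |

These presets are the definition of the simulated experimental conditions, not
tuning knobs.

**What the generator does not emulate.**  Real data additionally contain
scan-line noise and scars, nonlinear/piezo-creep drift, tip changes and
double-tip artifacts, molecular diffusion and exchange, neighbor-contact
deformation, and conformations outside the four parametric classes.
Passing recovery tests therefore demonstrates that the analysis chain is
correct and unbiased on data obeying its assumptions — not that the
classifier would reach the same accuracy on microscope data, where
published analyses have relied on manual assignment.

## Preprocessing

Flattening fits and subtracts a least-squares plane, excluding protein
pixels via an Otsu mask by default (configurable off); contrast adjustment
is considered display-only and never touches analyzed heights.  Drift
correction estimates frame-to-frame shifts by upsampled-DFT
cross-correlation using the *classical* (unnormalized) correlation —
measured on synthetic movies, the phase-normalized variant is biased by up
to ~0.2 px per step on these smooth, sparsely structured height images,
while the classical form recovers scripted drift to < 0.05 px; frames are
resampled bilinearly.  Detection smooths the frame at σ = 2 nm (about half
the particle radius) so that any conformation collapses into a single round
blob whose maximum sits at the molecule center, then applies non-maximum
suppression at the lattice half-spacing and 3×3 quadratic subpixel
refinement; this choice (rather than a footprint centroid) keeps the
tracked center within ~0.5 px of the true center for *all* conformations,
which the rotational-symmetry feature below depends on.  Tracking is greedy
nearest-neighbor linking — adequate at the quasi-static packing densities
simulated here, and a documented limitation for mobile samples.
Morphometrics (height histograms with smoothed mode detection,
cross-sections with autocorrelation periodicity, n-fold symmetrized
averages) follow the standard definitions; periodicity uses the first
off-zero autocorrelation maximum rather than an FFT because the measured
profiles are short.

## ΔHeight traces and idealization

ΔHeight(t) is the maximum minus minimum height in a 5 × 5 nm axis-aligned,
whole-pixel window centered on the tracked molecule (10 × 10 px at
defaults); missing frames yield gaps, never interpolation, and the
statistic is offset-invariant by construction.  Traces are idealized with a
STaSI-style three-stage procedure:

1. **Noise**: σ̂ = median|x_{i+1} − x_i| / (0.6745·√2) — robust to steps.
2. **Steps**: recursive binary segmentation at the split maximizing the
   two-sample t statistic, accepted while t > 5.0 with ≥ 2-point children.
3. **Grouping and MDL**: nearest-mean agglomeration of segment means
   (duration-weighted centroids) to k levels, k chosen by minimum
   description length

   DL(k) = (N/2)·ln(RSS_k/N) + ((m + 3k)/2)·ln N,

   with m the retained change points.  The per-level cost is weighted ×3
   over the plain BIC count: after step detection, segment means scatter
   around the true levels and an extra level can always absorb part of that
   scatter, so the unit-cost penalty over-selects k on long traces
   (measured: 79/100 correct two-level selections at Δ = 1.5 nm,
   σ = 0.2 nm, N = 500).  With the weighted cost the same benchmark gives
   98/100, pure noise selects k = 1 in 100/100, and genuinely three-level
   traces still select k = 3 in 46/50.  The pipeline default forces k = 2
   (`force_k=2`), mirroring the two-ΔHeight-state analysis.

Dwell statistics exclude censored (first/last) dwells from means, apply no
missed-event correction for the finite frame time, and keep one-frame
dwells flagged.  The equilibrium energy difference is
ΔG = −ln(τ_low/τ_high) k_BT.

## Classification

Each snapshot patch (8.5 nm half-width) is reduced to five features.  The
local membrane reference is the 15th percentile of the annulus at 1.2–1.5 ×
the outer radius — in crowded lattices the annulus *median* rides on the
tip-broadened flanks of the neighbors (~+0.9 nm), while the inter-particle
gaps still reach the membrane.  The 5-fold correlation S5 (mean Pearson
correlation with the 72°·k rotations, k = 1..4) is evaluated on a disk of
0.70 × the outer radius: a larger disk includes the rotationally symmetric
plateau edge, which dominates the variance and inflates S5 for asymmetric
conformations (openplus S5 ≈ 0.7 at 0.92 × r_out vs ≈ 0.2 at 0.70 × r_out).
The apex uses light smoothing (σ = 0.3 nm); S5 uses heavier smoothing
(σ = 0.6 nm) because its contrast lives at the subunit-lobe scale.
Decision list, in order: closed (S5 ≥ 0.80 and apex < 7.75 nm), open-II
(apex ≥ 7.75 nm, offset ≤ 1.5 nm, eccentricity < 0.65), open-I
(apex ≥ 7.75 nm, ≤ 3 near-apex lobes, eccentricity ≥ 0.65), else open-+.
All thresholds were calibrated on simulator renders only; on mixed
four-class movies at σ_noise = 0.1 nm the confusion matrix is ≥ 99% correct
for closed/open-+ and ≥ 95% overall (open-I↔open-II confusion does not
enter any reported statistic).  Occupancies are averaged per molecule first
(s.e.m. across molecules); transition matrices are row-normalized, the only
convention under which the aggregate open→closed entry reads as a
conditional return probability.

## Titration and rod mechanics

The asymmetric fraction (a particle is "dynamically asymmetric" when
non-closed in ≥ 50% of its frames) is fitted by weighted least squares to
f(c) = 1 − cⁿ/(cⁿ + K_dⁿ) with the Hill coefficient fixed at 1 by default
(the experiment reports a single apparent K_d; freeing n on a handful of
binomial points mostly fits noise); confidence intervals come from a
parametric bootstrap over particles.

TM1 is treated as a semiflexible rod (persistence length 100 nm, contour
length 11 nm, stiffness K_S = L_p·k_BT) restricted to circular arcs, so
E(r) = L_p·L/(2r²) in k_BT; at 1 k_BT, r = √550 ≈ 23 nm.  Both end-movement
conventions are provided — arc drop r(1 − cos L/r) ≈ 2.53 nm (default) and
small-angle L²/(2r) ≈ 2.58 nm — agreeing within 5% at L/r ≈ 0.47 and both
rounding to the ~2–3 nm scale quoted for such motions.

## Problem sizes and numerics

The per-condition recovery analyses use 20 molecules (4 × 5 lattice,
14 nm spacing) × 110 frames — matching the scale of typical per-condition HS-AFM movie
sections (~20 molecules × ~80–100 frames) and giving ≥ 2,000 frame pairs per transition matrix.  Dwell
recovery uses 25 molecules × 1,220 frames at 0.55 s.  Degenerate inputs
(flat patches, all-masked frames, zero-variance t tests, empty transition
rows) raise or flag rather than silently producing numbers; RSS = 0 in the
MDL is floored at machine epsilon; ties in agglomeration resolve to the
lowest-index pair deterministically.  All randomness flows through
`numpy.random.Generator` seeds, and a fixed seed reproduces movies
byte-identically.

## Known limitations

Greedy tracking will swap identities for fast-moving crossing particles;
the classifier thresholds are specific to the parametric geometry and the
0.5 nm px⁻¹ / 2 nm tip regime; no missed-event correction means dwell means
are biased long when true dwells approach the frame time; the EDTA model is
a single conditional 1:1 constant; drift is linear.  The elastic-rod model
ignores anchoring compliance and treats bending modes independently.
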