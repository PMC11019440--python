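# Methods

This note documents the models and numerical choices behind `casatrack`:
what each stage assumes, which knobs matter, what the simulator does and
does not emulate, and the known limitations.

## Acquisition model and units

The pipeline is written for single-channel brightfield video at constant
frame rate, by default 100 fps for 10 s (1000 frames), recorded through a
20× objective onto a camera with 6.5 µm physical pixels. All image
processing runs in pixels; all distances that carry biological meaning
(linking gates, velocities, radii) are in **sample-plane micrometres**,
obtained as pixel distance × γ with γ = 6.5/20 = 0.325 µm/pixel. The config
field `um_per_pixel` is therefore the sample-plane scale; a config may
instead give `camera_pixel_um` and `magnification` and the ratio is used.
Velocities in camera-plane units would be 20× too large, which is why the
sample-plane convention is fixed here and documented rather than left
implicit.

Default analysis parameters (all configurable via YAML/TOML):

| parameter | default | unit | role |
|---|---|---|---|
| `frame_rate` (FR) | 100 | frames/s | time base of all velocities |
| `um_per_pixel` (γ) | 0.325 | µm/px | sample-plane scale |
| `sensitivity` (S) | 0.6 | — | detector acceptance threshold 1−S |
| `max_link_distance` (D) | 4.2 | µm | frame-to-frame linking gate |
| `gap_max_frames` (G) | 5 | frames | gap-closing frame budget |
| `gap_max_distance` | 8.5 | µm | gap-closing distance budget |
| `min_track_length` | 100 | points | tracking-noise filter |
| `min_vsl` | 2 | µm/s | tracking-noise filter |
| `min_lin` | 10 | % | immotile/out-of-focus cut |
| `split_factor` | 5 | — | anomalous-jump split multiple |
| `head_radius_range` | (2, 6) | px | matched-filter template radii |
| `gaussian_sigma` / `opening_radius` / `wiener_window` | 1 / 2 / 5 | px | filter chain |

The filter-chain sizes and the head-radius range are engineering defaults
chosen for heads a few pixels wide (a 4–5 µm head at γ = 0.325 spans
roughly 12–15 px in diameter, but its bright core after filtering is much
smaller); they are required config, not constants.

## Detection

Each frame passes through Gaussian smoothing, grey-scale morphological
opening (disk), global mean subtraction and an adaptive Wiener filter, in
that order, which leaves heads as bright blobs on a zero-mean background.
The Wiener step is the standard local mean/variance shrinkage estimator,
written with a guarded division so that locally constant neighbourhoods
pass through unchanged (the textbook form is 0/0 there).

Head candidates are peaks of a circular matched-filter accumulator: the
normalised cross-correlation of the filtered frame against zero-mean,
soft-edged disk templates spanning `head_radius_range`, maximised over
radius. A peak is accepted when its accumulator response exceeds 1 − S, so
raising the sensitivity S can only add detections (the count is monotone
non-decreasing in S on any fixed frame), and when its filtered intensity
clears an absolute noise floor of `noise_floor_k` (default 5) robust
standard deviations (1.4826·MAD of the frame). The floor is independent of
S and exists because normalised correlation is scale-free: without it,
noise patches that happen to be disk-shaped would be accepted at any
sensitivity. Accepted peaks are refined by the intensity-weighted centroid
of the positive filtered signal inside the matched disk; on noise-free
rendered heads the localization error is ≈0.25 px RMS, well below the 1 px
target, and recall/precision both exceed 0.95 at the default rendering
noise.

## Linking

Frame-to-frame correspondence is a linear assignment problem: among
assignments that pair as many detections as possible at distances ≤ D, the
one minimising the total paired distance is chosen. It is solved with the
Jonker–Volgenant/Hungarian solver on an augmented (n+m)×(n+m) cost matrix
in which infeasible pairs (distance > D) carry a prohibitive cost and
"leave unmatched" carries a large-but-smaller cost, so matching is always
preferred when feasible. Tests verify agreement with an independent
exhaustive-enumeration oracle on hundreds of random instances.

Gap closing repairs fragments produced by missed detections: an end→start
pair with 1…G missing frames in between and end distance ≤ `gap_max_distance`
is merged. Candidates are consumed greedily, closest pair first (ties:
smaller frame gap, then fragment order), repeated until stable; because a
merge never creates a new candidate endpoint, one sorted pass realises the
fixed point exactly, making the result independent of detection order.
Gap closing runs over all link chains *including* isolated single
detections, so two fragments bridged by a lone surviving detection inside
a noisy stretch are still reunited; chains shorter than two points are
discarded afterwards. Missing frames of merged tracks are filled by linear
interpolation and flagged; interpolated points participate in kinematics
like real ones.

Finally, a track whose consecutive-step distance somewhere exceeds
`split_factor` × its mean step is split at the first such step and both
halves re-examined recursively (the mean is recomputed per half). The
operation is idempotent and never splits constant-step tracks. The mean
used for the threshold is the track's own pre-split mean — the simplest
deterministic reading of the rule; which mean the original routine used is
not documented anywhere we could check.

## Kinematics, filters and classes

VSL, VCL and LIN follow the standard CASA definitions given in the README.
Tracks must be frame-consecutive (interpolation first) and have N ≥ 2.
A track with zero path length has undefined LIN; it is reported as 0 and
the record left unclassified. Filters run in the order length → VSL → LIN,
and a rejected track reports only the first failed criterion: length and
VSL are tracking-noise cuts, while the LIN ≥ 10% floor removes immotile
cells and out-of-focus objects. Classification uses half-open VCL bands —
slow [25, 80), medium [80, 150), rapid [150, ∞) µm/s — closing the
measure-zero boundary cases that strict inequalities would leave
unassigned; VCL < 25 µm/s is "unclassified" and excluded from the
three-class percentages. VAP, BCF and ALH are deliberately not computed:
they depend on an average-path construction with no standard definition.

## Pratt circle fit

Circular swimming is quantified by fitting a(x²+y²)+bx+cy+d = 0 under the
Pratt normalisation b²+c²−4ad = 1, i.e. the generalised eigenproblem
Mv = ηBv with M the scatter matrix of [x²+y², x, y, 1] and B the constraint
matrix; the solution is the eigenvector of the smallest non-negative
eigenvalue. Data are centred and scaled to unit RMS radius before the solve
for conditioning, making the fit exactly translation/rotation invariant and
scale equivariant. Fewer than 3 points, coincident points or collinear data
(|a| < 1e-12 after scaling) raise a degenerate-fit error. Reported per fit:
centre, radius R, RMS orthogonal residual, and the signed total turning
angle — the sum of wrapped consecutive angular increments about the fitted
centre, so a drifting circle accumulates beyond 2π.

A track counts as circular when rms/R ≤ 0.15, |turning| ≥ 2π and
R ≤ 100 µm. These three thresholds are this package's own reproducible
criterion (the quantity was historically scored by eye); they are config
fields, and the defaults are stated as engineering choices. A straight
track fails on all three (huge fitted radius, tiny turning).

## Population statistics

Class percentages are over motile (classified) tracks only. The
redistribution of a class between time-steps t₁ → t₂ is the signed relative
change (%T_t₂ − %T_t₁)/%T_t₁ · 100, defined only when the starting share is
positive. Distribution shifts of VSL/VCL/LIN within a class are tested with
the tie-corrected Kruskal–Wallis H (χ² reference, k−1 df), applied pairwise
to every pair of time-steps within one condition; with three steps that is
exactly three comparisons per class per parameter. Identical values across
both groups are a well-defined no-effect case (H = 0, p = 1). Conditions
prepared from different source samples are never compared against each
other — the report carries an explanatory note instead. Stars follow the
common convention (*** p<0.001, ** p<0.01, * p<0.05); no multiple-testing
correction is applied by default, a Bonferroni option exists. Replicate
recordings of the same time-step are pooled.

## Synthetic ground truth

The simulator emulates the default acquisition (10 s, 100 fps, 512×512 px
at γ = 0.325 → a 166×166 µm field) with three motion kinds in 2-D:

* **straight_wobble** — constant drift plus a transverse sinusoid (the
  projected head yaw). The drift speed is calibrated by root finding so the
  *sampled* path length per second equals the programmed VCL to machine
  precision; the programmed VCL is thus the discrete-path ground truth.
* **circular** — constant angular rate on a circle, with the rate set so
  the sampled chord speed equals the programmed VCL.
* **immotile** — iid Gaussian jitter (σ = 0.3 µm) about a fixed point.
  Tracked, such a cell shows non-trivial apparent VCL but near-zero VSL and
  LIN, which is exactly what the VSL/LIN filters are for.

Population draws: speeds uniform within the class bands (slow 25–80,
medium 80–150, rapid 150–250 µm/s), wobble frequency uniform in 8–15 Hz,
wobble amplitude 0.1·VCL/f so the lateral oscillation contributes ≈40% of
the path speed, circle radii 15–60 µm. The default desk-scale scenario is
30 swimmers: 9 slow + 9 medium + 7 rapid straight, 3 circular, 2 immotile.
Heads are rendered as Gaussian spots (σ = 2 px, amplitude 1) on a constant
background (0.1) with additive pixel noise (σ = 0.05, i.e. 5% of the head
peak); everything is deterministic per seed.

Straight swimmers are kept inside the field by *reflective folding* at a
margin: the unbounded path is mapped through a triangle wave, which
preserves per-step path length and therefore VCL and the class label. Real
recordings instead lose fast swimmers over the field edge within a second
or two at this field size. Consequences: simulated VSL and LIN of long
tracks are lower than for a truly unbounded swimmer (the path turns back),
and passing recovery tests say nothing about edge-exit losses in real data.
Other realism gaps, accepted deliberately: no flagellum (only the head is
rendered), no hydrodynamic wall interactions, no chemotaxis, no
z-excursions or defocus blur, no illumination drift. Motion is strictly
2-D; the tracker itself only ever sees the 2-D projection.

## Error budgets and problem sizes

Test and verification scenarios are sized for a desk machine: the full
default scenario (1000 frames, 512², 30 swimmers) runs simulate → detect →
track → analyze in a few minutes on one CPU; oracle-based checks use
hundreds of randomized small instances.

Two measurement-physics facts shape what recovery accuracy is achievable
and are worth stating explicitly:

* **VCL is sampling-rate dependent.** The discrete path length grows with
  frame rate for any non-straight path; comparisons across frame rates are
  only meaningful at fixed FR. The simulator defines programmed VCL at the
  sampled rate, so noise-free recovery is exact to <1% (the only residual
  error comes from fold corners).
* **Localization noise inflates VCL with a floor that does not average
  out.** For iid localization error σ per coordinate, each measured step
  acquires an additive random component of RMS 2σ, contributing roughly
  √(VCL² + (FR·γ·2σ·√(π)/2·…)²) ≈ √(VCL² + c²) with c ≈ 29 µm/s at
  σ = 0.5 px, FR = 100, γ = 0.325. Slow swimmers (VCL 25–50 µm/s) are
  therefore overestimated by tens of percent under that noise level, while
  rapid swimmers are barely affected. Track smoothing would trade this bias
  for attenuation of the genuine wobble path (≈−6% at a 3-frame window) and
  is deliberately not applied: the estimator stays the plain
  sum-of-segments formula, and class accuracy — which tolerates the floor
  except within a few µm/s of the band edges — is the robust quantity under
  noise. Detection-derived tracks from the bundled renderer have ≈0.25 px
  localization error, for which the floor is ≈14 µm/s in quadrature, small
  for all but the slowest cells.

## Known limitations

* No appearance model: two swimmers that physically cross can exchange
  identities; both resulting tracks keep valid kinematics but belong to a
  chimera of the two cells. Probabilistic (Kalman/MHT) tracking is out of
  scope.
* The circular-swimmer criterion thresholds are package defaults, not
  field-calibrated constants.
* 3-D motion, morphology, flagellar beat parameters and average-path
  quantities (VAP/BCF/ALH) are out of scope.
* Gap closing cannot recover breaks whose end distance exceeds the distance
  budget, which for rapid cells (≥ ~210 µm/s) already happens at 3 missing
  frames; such tracks are split and may then fail the length filter.
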