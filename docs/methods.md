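# Methods

## Measurement model

The camera looks straight down (nadir) from altitude `H` onto a flat ground
plane and translates with the aircraft. Under these assumptions two frames
of the ground are related exactly by a plane homography; for a purely
translating camera it degenerates to a translation, but the full 8-dof model
is fitted by default so small attitude wobble is absorbed. Everything the
method computes rests on three identities:

- footprint diameter `d = 2·H·tan(FOV/2)`, split by the pixel aspect ratio
  into length `L` and width `W`, giving the ground sampling distance `L/M`
  (metres per pixel, `M` = long-side pixel count). `L² + W² = d²` is
  enforced as a test invariant.
- ground-referenced displacement `S₂ = X₂ − H(X₁)`. The vector form is
  deliberate: a scalar "panning minus image distance" subtraction loses the
  sign whenever the pedestrian's image motion reverses (drone overtaking),
  while the vector form reduces to it for collinear motion.
- relief displacement `δ = r·h/H`, where `r` is the image distance of the
  *elevated* point's projection from the image centre. With that reading the
  identity is exact under central projection, not a small-`h` approximation:
  a head at elevation `h` over a ground point imaged at radius `r_g` appears
  at `r_g·H/(H−h)`, and the offset `r_g·h/(H−h)` equals `r_head·h/H`
  identically. The simulator and the correction share this geometry, which
  is what makes the simulator a fair oracle.

## The correction and its sign

Differencing `δ` across a stride gives the spurious speed contribution
`v_c = (r₂−r₁)·h·fps·L·cosθ/(n·H·M)`; the corrected speed is `v_m − v_c`,
clamped at zero (clamping is flagged, not an error: it occurs only when
noise exceeds the true speed of a near-stationary pedestrian).

Two refinements matter in practice:

- `θ` is computed from the *walking direction* — the angle between the
  flight axis and `S₂` — not from the pedestrian's position vector. The
  position-based formula (available as `heading_angle`) agrees only for
  pedestrians walking through the image centre and under-corrects laterally
  offset ones.
- `(r₂−r₁)` is projected onto the walking direction: when `S₂` points
  against the flight axis (the usual case when the drone is faster than the
  pedestrian) the sign of the term flips. Because the reported raw speed is
  a magnitude `‖S₂‖`, omitting the flip would *add* the bias instead of
  removing it for every overtaken pedestrian. With both refinements the
  corrected speed is exact (to solver precision) for straight-line motion in
  the noise-free geometry, in either direction — verified end to end in the
  tests.

A consequence worth stating: with head-tracking under exact central
projection, the signed bias of the *raw* speed for a walker moving **with**
the camera is negative once the camera is faster
(`v_raw = (v_p·H − V·h)/(H−h)`), and positive, growing with camera speed `V`,
for walkers moving **against** it (`+(v_p+V)·h/(H−h)`) and for standing
pedestrians (`+V·h/(H−h)`, the magnitude folding the sign). The
monotone-bias sweep used in the acceptance tests therefore runs its walkers
against the flight direction — the configuration in which the
"bias grows with drone speed, correction removes the trend" pattern is
geometrically well defined.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `fov_deg` | 84° | diagonal field of view of the sensor |
| image size | 1920×1080 | decoded frame, long side = `M` |
| `fps` | 30 | decoded frame rate |
| `altitude_m` | 40 | flight height `H`; the survey height at which pedestrian detection was most reliable |
| `pedestrian_height_m` | 1.7 | assumed head height `h`; per-person heights are unknown, so one population value is used |
| `frame_interval` | `fps` (1 s) | stride `n`; longer strides trade time resolution for noise averaging |
| `flight_axis` | `up` | image axis the flight direction maps to (sign included) |
| RANSAC `min_fit_points` | 50 | minimum input correspondences (minimal samples are 4 points) |
| RANSAC `max_iterations` | 5000 | iteration cap |
| RANSAC `residual_threshold` | 7e3 | squared symmetric transfer error, px² (≈59 px one-way) |
| RANSAC `min_consensus` | 300 | inlier count below which the model is flagged (not failed) |
| RANSAC `confidence` | 0.999 | adaptive early-stop confidence; 1.0 forces the full iteration budget |

The residual threshold is generous by design — its role in this pipeline is
to reject gross mismatches, not to trim the noise floor — and its units are
exposed in configuration because reasonable implementations differ on the
metric. Focal length is carried as metadata only: the relief identity
eliminates it.

## Synthetic scenes

The simulator emulates the data-collection conditions: a camera at 40 m
translating at 0–6 m/s along a street (piecewise-constant speed, optional
sinusoidal lateral sway standing in for wind drift), pedestrians of heights
1.5–1.9 m walking straight lines at 0–2 m/s with or against the flight
direction across a 15 m-wide street, start positions covering the central
80% of the initial footprint. Feature matches are true ground points with
Gaussian pixel noise (default σ = 1 px) plus a fraction (default 20%) of
uniform random pixel pairs standing in for false descriptor matches; head
positions get the same σ. Defaults of 500 features per frame pair keep the
expected inlier count above the 300-consensus flag.

What the simulator does **not** model — lens distortion, rolling shutter,
camera tilt, terrain relief, gait oscillation, detector box jitter that is
correlated over time, identity switches — bounds what passing tests show:
they validate the estimation and correction chain against exact projective
geometry with realistic random error, not the detector/tracker front end.
Field accuracy will be limited by those omitted effects, chiefly how well a
detection box centre tracks a fixed anatomical point.

## Numerical choices

- Homography fits use Hartley-normalised DLT via SVD; configurations with a
  near-zero second singular value gap raise a degeneracy error rather than
  returning garbage.
- RANSAC draws 4-point samples uniformly without replacement from a
  PCG64 generator seeded per run (per frame pair the seed is offset by the
  pair index), so whole pipelines are reproducible bit for bit; outputs are
  written with fixed float formats for the same reason.
- Adaptive termination uses the standard `log(1−p)/log(1−w⁴)` bound and is
  capped by `max_iterations`.
- Track aggregation uses the median over strides (robust to single-stride
  glitches from identity switches); strides with missing endpoints or
  missing frame-pair homographies are skipped and logged.
- Stride homographies are composed from consecutive-pair homographies when
  no direct estimate exists; composition error grows as a random walk
  (~0.3 px over 30 noisy pairs at 400–500 features), well under the pixel
  noise itself.
- Negative corrected speeds clamp to zero with a flag.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic scenes:
10-second scenes at 30 fps (300 frame pairs), 50 pedestrians per scene, one
scene per drone speed 0–6 m/s. These sizes give ~330 per-track estimates
per sweep, enough to estimate the within-0.1 m/s fraction to a few percent
while a full sweep stays around half a minute on one CPU.

## Known limitations

- A single assumed pedestrian height: a true height differing by Δh changes
  the correction by the factor Δh/h (≈±12% across 1.5–1.9 m), which at
  drone–pedestrian relative speeds of ≤6 m/s leaves residual errors well
  under 0.05 m/s, as the end-to-end sweep shows.
- The box centre is taken as the head position; in real footage the centre
  of a detection box sits somewhere between head and feet, so the effective
  `h` is smaller and partly self-correcting, but no attempt is made to model
  it.
- Speeds are magnitudes; direction reversals within a stride alias to lower
  speeds.
- The correction's `cosθ` treatment drops the lateral component of the
  relief change; it is second order for near-axis walking but grows for
  strongly diagonal walkers under fast flight.
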