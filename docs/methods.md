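# Methods

This note records the measurement model implemented by `gatelag`, the
simulator it is validated against, the numerical choices, and the known
limitations.

## Measurement model

A phantom carrying a small radio-opaque ball moves at constant velocity
*v* through a gating window of half-width *w* centered at position *c*.
The gating system permits the beam inside the window, so the beam-on
reference position is the window edge the phantom *enters* (`c + w` for
descending motion, `c − w` for ascending) and the beam-off reference is
the edge it *exits*. The reference image is acquired statically at the
relevant reference position and assumed delay-free.

Because the system reacts late, the ball in the motion image sits a
distance Δx past the reference position, further along the motion
direction. The delay is `t = Δx / v`. Positions are measured on the
portal imager and divided by the magnification `M = SID / SAD` to obtain
isocenter-plane millimetres; by similar triangles this makes the result
independent of the imager extension. Displacements along the motion
direction are signed positive; a negative beam-on delay (system gating
early) is reported as negative rather than clamped, since hiding it
would mask a fault.

### Velocity

The traversal velocity is the slope of an ordinary least-squares line
through (time, position) waveform samples restricted to an explicit,
operator-chosen time window covering the linear segment of the stroke.
Auto-segmentation of the waveform is deliberately not attempted; an
explicit window is reproducible. The fit reports R², and the two-sided
slope t-test with n − 2 degrees of freedom. With exactly two samples the
residual degrees of freedom are zero; the p-value is reported as 0.0 for
this exact-line degenerate case.

### Beam-on analysis

The ball is located in reference and snapshot images by profile
analysis: rows transverse to the motion are averaged over a band
centered on the ball (band half-width defaulting to roughly the ball
radius in pixels), attenuation is taken as background (profile median)
minus intensity, and the center is the attenuation-weighted centroid of
the contiguous region above 50% of the attenuation depth, extended by
3 px on each side. The margin matters: with a hard pixel-in/pixel-out
cut at the 50% boundary the centroid jitters by ~0.13 px as the true
center moves sub-pixel; including the antialiased edge tails, whose
weights fall smoothly to zero, reduces the jitter to ~0.003 px,
independent of band width. Detection requires the depth to exceed 6×
the robust (MAD) profile noise; more than one disjoint region above
threshold is reported as ambiguous rather than silently resolved.

### Beam-off analysis

The integrated beam-off image is an elongated blur trace; its
stop-side edge encodes where the beam actually switched off. The
displacement is found by shifting the normalized reference ball profile
along the motion direction and minimizing the sum of squared
differences against the normalized trace profile over a fixed window
from the trace mid-plateau to one reference-FWHM beyond the stop edge.
Because the trace interior is swept, the reference template is extended
to a plateau on its trailing side; on the stop side it is exactly the
static edge shape, which in the simulator's high-contrast limit equals
the trace edge shape — so the objective has a sharp, unbiased minimum.
The grid is 0.25 px coarse, refined to 0.05 px around the minimum; the
search range defaults to 0–15 mm at the isocenter plane, covering
delays up to 625 ms at 24 mm/s with margin. A minimum at the lower
bound (zero displacement, i.e. zero delay) is legitimate; a minimum at
the upper bound raises a search-range error. Independently, the
50%-crossing stop edge minus the reference's own stop-side 50% crossing
(both taken with the same narrow 2-px band, so the two crossings sit at
the same geometric offset) gives an edge-based estimate; disagreement
beyond 2 px emits a quality warning.

### Aggregation conventions

Within a beam mode, repeats (typically five) are summarized by the mean
displacement (MDD, mm), mean delay (ms), and **sample** SD (divisor
n − 1) — the conventional spread estimate for repeated measurements of
one quantity. Across beam modes, the system summary is the mean and
**population** SD (divisor N) of the per-mode mean delays: the modes
measured are the modes of interest, not a sample from a larger
population. The two conventions are deliberately different, are pinned
by a discriminating test, and are recorded in the report metadata.
Printed values are rounded half-up to two decimals.

## The simulator

The simulator renders what the analysis consumes and nothing more: a
uniform-background portal image with the ball as an opaque disk of
diameter `d · M` at the detector, edge-antialiased by area-weighted
sub-pixel coverage (16×16 samples per pixel, giving ≤0.4% area error
per edge pixel and ~10⁻⁴ relative error on total attenuated flux).
Detector noise is additive Gaussian with a seeded generator.

* **Snapshot** (beam-on): the minimal-MU exposure is treated as
  instantaneous; the disk is drawn at
  `reference + sign · v · t_true / 1000`.
* **Trace** (beam-off): the swept region of the moving disk — a stadium
  shape (rectangle with semicircular caps) from the start position to
  the stop position `reference + sign · v · t_true / 1000` — is drawn at
  the full attenuation depth. This is the *saturated high-contrast
  limit* of the time-integrated exposure. A literal dwell-time integral
  would give a stop edge that ramps linearly over a ball diameter
  (crossing 50% at the stop *center*) and an edge shape equal to the
  integral of the ball's edge; the saturated limit instead makes the
  trace's stop-side edge profile identical to the static ball's edge —
  the property the matching algorithm and the 50%-crossing edge
  semantics rely on, and consistent with the high-contrast "ellipse"
  appearance of a metal ball in an MV beam. An optional linear
  intensity ramp over the final `ramp_time` of travel models a soft
  dose-rate cutoff phenomenologically (default 0 = hard cutoff).

Defaults are the reference measurement conditions: SAD 1000 mm, SID
1600 mm (M = 1.6), pixel pitch 0.34 mm, velocity 24 mm/s, gate
half-width 1 mm, descending motion, five repeats per mode. The ball
diameter defaults to 6 mm — a typical Winston-Lutz ball scale, chosen
here because the physical cube's ball size is not specified by its
datasheet-level description; it is configurable and nothing downstream
assumes it. Ball contrast 0.8 on a background of 10⁴ counts; "2% noise"
in the tests means σ = 0.02 × depth = 160 counts. The motion axis is
the image column axis with positions increasing with column index;
descending motion therefore moves the ball toward lower columns. This
fixed convention keeps every test reproducible.

What the simulator does **not** emulate: scatter, penumbra, heel
effect, imager lag/ghosting, WL3 cube edges and setup lines, dose-rate
servo dynamics, or surface-tracking optics. Passing round-trip tests
therefore demonstrates the correctness of the *analysis chain* under
the stated geometry — not robustness to every artifact of clinical
images.

## Numerical choices and problem sizes

* Edge localization: linear interpolation of the 50% crossing between
  bracketing pixels; no Gaussian fitting (adequate at 0.34 mm pitch).
* One detector pixel corresponds to `0.34 / 1.6 / 24 s ≈ 8.85 ms` at
  the default geometry — the natural resolution unit; noise-free
  round-trip errors are required to stay below one pixel-equivalent and
  in practice stay below 0.05 px.
* Degenerate inputs: uniform images raise a no-ball error; traces with
  under ~3 ball radii of travel still return edges but warn; a zero
  time-variance waveform raises a degenerate-fit error.
* Test and acceptance problem sizes (chosen to keep the default run in
  seconds while exercising every path): 192×512-pixel images; delay
  grid {50, 100, 150, 300, 500} ms noise-free for both phases; 100
  seeded repeats at 2% noise; 20 randomized scenes for the centroid
  oracle; brute-force matching oracle at 0.01 px; end-to-end CLI run
  with 2 modes × 3 repeats.

## Known limitations

* Only the end-to-end latency is measured; optical, processing, and
  beam-servo contributions are not separable by this method.
* Constant-velocity traversal is assumed; irregular breathing patterns
  and amplitude- vs phase-gating differences are out of scope.
* The beam-off matcher assumes the trace is long enough to present a
  plateau; very short beams degrade the normalization.
* Real trace edges with a slow dose-rate ramp-down are softer than the
  saturated model; the optional ramp parameter exists to probe this
  sensitivity but no calibrated ramp shape is claimed.
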