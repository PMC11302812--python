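# gatelag

EPID-based quality assurance of **beam-on and beam-off time delays** for
respiratory-gated radiotherapy.

## The problem

Respiratory gating switches the treatment beam on and off as the
patient's surface moves through a position window. The gating chain —
optical surface tracking (e.g. Catalyst™ or AlignRT™), its processing,
and the linac's beam servo — has an end-to-end latency: the beam turns on
and off *late* relative to the phantom crossing the gate boundary. That
latency shifts dose in time and therefore in space, and guidelines such
as AAPM TG-142 call for it to be measured routinely. `gatelag` gives
medical physicists the analysis side of a simple measurement: drive a
metal-ball phantom at constant velocity through the gate, image it with
the portal imager (EPID), and read the latency off the ball's position.

## The method

With the phantom moving at constant velocity *v* (nominally 24 mm/s from
a least-squares fit of the waveform), the time delay is

```
t = Δx / v,        Δx = (P_meas − P_ref) · SAD / SID
```

where `P_meas` and `P_ref` are the sub-pixel ball positions in the motion
and static reference images, measured at the detector plane and
back-projected to the isocenter plane through the similar-triangles
magnification `M = SID / SAD` (1.6 for SAD 1000 mm, SID 1600 mm; the EPID
extension therefore does not affect the result).

* **Beam-on:** a minimal-MU plan produces a snapshot of the ball;
  `P_meas` is its attenuation-weighted sub-pixel centroid.
* **Beam-off:** the integrated image shows an elongated blur trace, so no
  single ball position exists. The static reference ball profile is
  *intentionally displaced* along the motion direction and matched (sum of
  squared differences, coarse-to-fine grid down to 0.05 px) against the
  trace's stop-side edge; the best-matching displacement is Δx. An
  independent 50%-crossing edge estimate cross-checks the match.

Per beam mode (energy + dose rate), repeats are aggregated into the mean
distance discrepancy (MDD, mean Δx), mean delay, and sample SD; per
system, the cross-energy summary is the mean ± population SD of the
per-mode mean delays.

A synthetic portal-image simulator (`gatelag.simulate`) renders
reference, snapshot, and trace images with known ground-truth delays,
geometry, and noise, so the entire pipeline is testable without a linac.

## Worked example

```python
from gatelag import (BeamGeometry, SimScenario, render_pair,
                     beam_on_delay, beam_off_delay, aggregate_repeats)

geometry = BeamGeometry()          # SAD 1000 mm, SID 1600 mm, pitch 0.34 mm
velocity = 24.0                    # mm/s, from the waveform fit

# five repeats of a beam-on measurement with 2% detector noise
repeats = []
for seed in range(5):
    scenario = SimScenario(true_delay=300.0, phase="beam_on",
                           noise_sigma=160.0, seed=seed)
    reference, snapshot = render_pair(scenario)
    repeats.append(beam_on_delay(reference, snapshot, geometry, velocity,
                                 repeat_index=seed, beam_mode="6xFFF, 1200"))

result = aggregate_repeats(repeats)
print(f"{result.beam_mode}: MDD {result.mdd:.2f} mm, "
      f"delay {result.mean_delay:.2f} +/- {result.sd:.2f} ms "
      f"(n={result.n_repeats})")

# one beam-off repeat: stop-edge matching on the blur trace
scenario = SimScenario(true_delay=97.69, phase="beam_off")
reference, trace = render_pair(scenario)
m = beam_off_delay(reference, trace, geometry, velocity)
print(f"beam-off: delta_x {m.delta_x:.2f} mm -> delay {m.delay:.2f} ms")
```

prints

```
6xFFF, 1200: MDD 7.20 mm, delay 300.00 +/- 0.06 ms (n=5)
beam-off: delta_x 2.34 mm -> delay 97.62 ms
```

The simulated 300 ms beam-on latency is recovered exactly at this noise
level (a ground-truth delay of 300 ms at 24 mm/s is a 7.20 mm
displacement), and the 97.69 ms beam-off latency is recovered to within
a tenth of a detector pixel (one pixel ≙ 8.85 ms at this geometry and
velocity).

The same workflows are available from the shell:

```
gatelag simulate --phase on --delay-ms 300 --seed 1 --out sim/
gatelag analyze-on --ref sim/reference.png --motion sim/motion.png --out results/
gatelag report --manifest manifest.csv --tolerance-ms 100 --out report/
```

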