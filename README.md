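# pulsekit

Derivative-based signal processing for impedance flow cytometry (IFC).

In an IFC device, a particle crossing the two sensing regions of a
differential electrode pair produces a characteristic bipolar pulse in the
demodulated impedance magnitude: one positive peak as it enters, one negative
peak as it exits.  Detecting these events and extracting their biophysical
features — peak-to-peak amplitude ΔV (which scales with particle volume) and
transit time Δt (set by the electrode pitch and flow velocity) — is the core
of every IFC analysis pipeline, and must often run in real time on long,
drifting, noisy recordings.

`pulsekit` is for people building or evaluating such pipelines.  It provides:

- **`pulsekit.sim`** — a synthetic stream generator with exact ground truth:
  bipolar Gaussian pulses with Poisson arrivals and diameter-dependent
  amplitude (A = c·d³, 5 % CV on diameter), additive white noise shaped by an
  n-stage first-order low-pass cascade, and optional baseline drift.
- **`pulsekit.detect`** — the derivative detector.  Model the record as
  s(t) = e(t) + b(t) + n(t) (events, slow baseline, noise); then
  s′(t) = e′(t) + b′(t) + n′(t) with b′ ≈ 0, so differentiation suppresses
  drift while emphasising each pulse's steep ingress/egress slopes.  The
  detector computes s′ by finite differences (central in the interior,
  one-sided at the boundaries), thresholds |s′|, pairs the resulting
  positive/negative slope lobes, and reads all landmarks — raw-signal peaks
  and event boundaries — off the zero crossings of s′.  One linear pass,
  no template, no training.
- **`pulsekit.recon`** — feature extraction (ΔV, Δt) from the landmarks and
  an optional bi-Gaussian recovery,
  ŝ(t) = A·exp(−(t−t₀+δ/2)²/2σ²) − A·exp(−(t−t₀−δ/2)²/2σ²),
  for lightweight visual verification of detected events.
- **`pulsekit.baseline`** — the conventional comparator: moving-median
  detrend, two-sided amplitude threshold, run pairing (each stage
  toggleable), plus balanced-threshold tuning used to compare methods fairly.
- **`pulsekit.evaluate`** — tolerance-based one-to-one matching against
  ground truth; precision, recall, F1, FDR, and relative peak-position and
  peak-to-peak errors; a paired benchmark sweep over flow-rate/bandwidth
  conditions.
- **`pulsekit.classify`** — a portable decision tree on (ΔV, Δt) for particle
  sizing, with chunked streaming classification.
- **`pulsekit.studies`** — the reproducible end-to-end study protocols.

## Worked example

```python
import pulsekit as pk

# 5-second stream of 4 um beads at standard acquisition settings
cfg = pk.SimulationConfig(D_um=4.0, duration_s=5.0)
stream = pk.synthesize_stream(cfg, seed=7)
kin = pk.derive_kinematics(cfg)
print(f"velocity {kin.v_um_s:.0f} um/s, peak separation {kin.delta_s*1e3:.2f} ms, "
      f"lobe width {kin.sigma_s*1e3:.2f} ms")
print(f"{stream.trace.n} samples, {len(stream.truth)} true events")

det_cfg = pk.DetectorConfig.from_kinematics(kin.delta_s, kin.sigma_s,
                                            cfg.fs_Sa_s, auto_k=5.0)
events = pk.run_pipeline(stream.trace, det_cfg)
metrics = pk.evaluate_stream(events, stream.truth, tol_s=kin.delta_s / 2)
print(f"detected {len(events)} events: precision {metrics.precision:.3f}, "
      f"recall {metrics.recall:.3f}, FDR {metrics.fdr:.3f}")
print(f"peak-position error {metrics.peak_pos_err_pct:.2f}%, "
      f"peak-to-peak error {metrics.p2p_err_pct:.2f}%")

ev = events[0]
print(f"first event: dV = {ev.features.dV_V*1e6:.2f} uV, "
      f"dt = {ev.features.dt_s*1e3:.3f} ms")
fit = pk.fit_bigaussian(ev, stream.trace)
print(f"bi-Gaussian fit: A = {fit.A_V*1e6:.2f} uV, "
      f"sigma = {fit.sigma_s*1e3:.3f} ms, delta = {fit.delta_s*1e3:.3f} ms")
```

prints

```
velocity 37037 um/s, peak separation 1.08 ms, lobe width 0.27 ms
575500 samples, 171 true events
detected 165 events: precision 1.000, recall 0.965, FDR 0.000
peak-position error 1.31%, peak-to-peak error 4.77%
first event: dV = 5.65 uV, dt = 1.095 ms
bi-Gaussian fit: A = 2.85 uV, sigma = 0.264 ms, delta = 1.083 ms
```

At 2 µL/min through a 30 µm square channel, particles move at ≈ 37 mm/s, so
the 40 µm electrode pitch yields a ≈ 1.08 ms transit between the two peaks.
With an automatic threshold at five robust noise standard deviations of s′,
all detections are genuine (FDR 0) and the handful of missed events are
coincident transits that overlap within one pulse width.  The fitted
bi-Gaussian parameters recover the generator's pulse shape (σ = 0.27 ms,
δ = 1.08 ms) to a few percent; ΔV ≈ 2A as expected for well-separated lobes.

The same pipeline is available from the shell:

```sh
pulsekit simulate --config sim.yaml --seed 7 --out stream.h5 --truth-csv truth.csv
pulsekit detect --in stream.h5 --threshold auto:5 --out events.csv
pulsekit evaluate --events events.csv --truth truth.csv --tol 0.54e-3 --out metrics.json
pulsekit recover --in stream.h5 --out recon.h5
pulsekit benchmark --seeds 10 --out sweep.csv
pulsekit train --streams streams/ --out model.json
pulsekit classify --in stream.h5 --model model.json --out labeled.csv
```

Every subcommand writes a JSON manifest next to its output with the resolved
configuration and seeds, sufficient to re-execute the run bit-identically.

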