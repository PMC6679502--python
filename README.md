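# lodlamp

A desk-scale digital twin of a lab-on-a-disc isothermal-amplification (LAMP)
instrument. The package simulates every computational subsystem of the
device end to end:

- **`lodlamp.thermal`** — first-order lumped-capacitance model of the
  laser-heated amplification chamber (PWM heating, passive cooling), with a
  calibration routine anchored to the 70 °C steady state at 1:1 duty.
- **`lodlamp.tocs`** — thermochromic-sheet optics: logistic intensity-vs-
  temperature curves with heating/cooling hysteresis, curve inversion for
  temperature estimation, raw-intensity normalization, and a noisy camera
  observation model. The heating branch crosses 50 % of maximum at 60 °C.
- **`lodlamp.control`** — the two-phase controller: heat at fixed 1:1 duty
  until the sheet intensity plateaus (auto-calibration of the maximum), set
  the target to 50 % of that maximum, then PD control of the PWM duty ratio
  for the 40-minute hold; steady-state MSE reporting after transient
  detection.
- **`lodlamp.protocol`** — the seven-step disc driving sequence (sample
  injection, spins, valve actuations, heating) as a validated state machine
  with a timestamped event log.
- **`lodlamp.imaging`** — synthetic labeled 30×30 RGB ROI patches emulating
  the indigo (negative) vs sky-blue (positive) HNB color change, with
  ambiguity mixing, hue jitter, illumination gradients, and pixel noise.
- **`lodlamp.classify`** — colorimetric endpoint caller: circular-hue/HSV/RGB
  color features plus a regularized logistic model (a lightweight, CPU-only
  stand-in for a CNN), with JSON model serialization.
- **`lodlamp.pipeline` / `lodlamp.cli`** — configuration loading, seed
  fan-out, and the end-to-end virtual assay producing a reproducible report
  bundle (trace.csv, events.csv, images + manifest.csv, model.json,
  metrics.json, report.json).

## CLI

```bash
# full virtual assay (protocol -> temperature control -> images -> calls)
lodlamp run --seed 1 --out outdir/

# individual stages
lodlamp simulate-control --seed 1 --out trace.csv --report report.json
lodlamp generate-images --n-train 100 --n-test 30 --seed 1 --out images/
lodlamp train --manifest images/manifest.csv --out model.json
lodlamp classify --model model.json --image images/test_0000_negative.png
lodlamp evaluate --model model.json --manifest images/manifest.csv --report metrics.json
```

All commands accept `--config cfg.yaml` where applicable; the YAML mirrors
the nested config blocks (`plant`, `tocs`, `controller`, `imaging`,
`setpoint`, `include_calibration_in_heating`). Every run is deterministic
for a fixed seed: one global seed fans out into independent per-stage
streams.

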