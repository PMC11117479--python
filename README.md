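# gradchip

A digital twin of a multi-drug concentration-gradient microfluidic chip.
The package models the chip's chamber-cascade dilution process, designs the
combinatorial valve multiplexer that addresses its inlet channels, plans
per-chamber drug-combination dose matrices from path-directed gradients,
and summarizes cell-response readouts.

The reference device holds 40 culture chambers (8 arrays x 5 chambers),
each array fed by 3 independently controllable channels, for 24 liquid
inlets addressed by 7 control valves in a three-control-one arrangement.
A 4 s pulse at 5 mm/s replaces a calibrated fraction
(0.2248, 0.2003, 0.1716, 0.1387, 0.1128) of each chamber's liquid from the
pulse-entry side, so flow direction ("path-1" vs "path-2") selects which
end of an array receives the highest dose.

## Modules

- `gradchip.layout` — chip structure (arrays x chambers x channels),
  chamber geometry, capacity counts.
- `gradchip.mux` — k-control-1 valve multiplexer: minimum valve count,
  lexicographic address assignment, actuation patterns, exhaustive
  isolation verification.
- `gradchip.transport` — calibrated replacement-fraction profile, pulse
  events and schedules, the per-pulse mixing recurrence and its closed
  form.
- `gradchip.solver` — de-novo finite-volume advection-diffusion model:
  Hele-Shaw (potential) flow on a channel-plus-chambers domain, explicit
  upwind advection + central diffusion with a CFL-limited step.
- `gradchip.planner` — per-chamber dose gradients, reported values
  (rounded to the nearest 1% of inlet), combination dose matrices and
  combo codes ("1 + 5 + 5" = high + low + low), array/condition planning.
- `gradchip.response` — stemness fractions from per-cell reporter tables,
  per-condition summaries over repeats, synthetic cohorts from a logistic
  dose-response model, and its maximum-likelihood fit.

## CLI

```bash
gradchip layout summary examples/layout.yaml      # {"chambers": 40, "inlets": 24, "arrays": 8}
gradchip layout validate examples/layout.yaml
gradchip mux design --channels 24 --k 3 --out mux.csv --json mux.json
gradchip simulate --schedule examples/schedule.yaml --out trajectory.csv
gradchip plan --config examples/plan.yaml --out dose_matrix.csv
gradchip synth --plan examples/plan.yaml --model examples/model.yaml --out cells.csv
gradchip analyze --cells cells.csv --out summary.csv
```

Config documents are YAML; see `examples/` for each document shape. Tables
are CSV.

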