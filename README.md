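# dualscale

Simulation and analysis pipeline for persistent adaptation in a bursting
model neuron regulated on two timescales.

A single-compartment conductance-based neuron with seven voltage-gated
currents (Na, CaT, CaS, H, Kd, KCa, A) plus leak is driven by
calcium-sensor feedback that adjusts

* the **maximal conductances** slowly (τg = 600 s, mimicking channel
  expression), and
* the **half-(in)activation voltages** of all 11 gating curves quickly
  (τhalf = 6 s, mimicking posttranslational modification), with a soft
  penalty that discourages large shifts.

The package reproduces an in-silico experimental program around repeated
high-extracellular-potassium perturbations: the potassium and leak reversal
potentials are stepped from (−80, −50) mV to (−55, −32) mV for three
30-minute perturbations separated by 30-minute washes.  The naive model
enters depolarization block on first exposure and recovers only after the
slow process reshapes its conductances; on re-exposure it resumes spiking
almost immediately, while baseline bursting is preserved in every wash —
the latent trace of the first perturbation is stored in the channel
densities.

## Layout

| module | contents |
| --- | --- |
| `dualscale.channels` | channel definitions, gating curves/time constants, lookup tables |
| `dualscale.model` | integrator (numba kernel + pure-Python reference step), state types |
| `dualscale.sensing` | three-band calcium decomposition, setpoints, calibration |
| `dualscale.regulation` | dual-timescale update laws, weight profiles, named variants |
| `dualscale.protocol` | perturbation schedules and environment lookup |
| `dualscale.ensemble` | seeded generation of degenerate bursting models |
| `dualscale.burst` | spike detection, burst-onset latency, activity classification |
| `dualscale.geometry` | trajectory snapshots, displacement norms, bounding spheres, angles |
| `dualscale.stats` | Kruskal–Wallis + Dunn/Bonferroni comparisons |
| `dualscale.experiments` | experiment orchestration, reconfiguration, reports |
| `dualscale.cli` | `dualscale` command-line entry point |

## CLI

```sh
dualscale generate-ensemble --n 20 --seed 1 --out bundle.h5
dualscale run --ensemble bundle.h5 --variant full --profile full --out run/
dualscale analyze --run run/ --out report/
```

Variants: `full`, `half_only`, `gmax_only`, `reversed`, `half_disabled`.
Profiles: `full` (220-min protocol) and `ci` (5-min epochs).

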