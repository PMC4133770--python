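# cerebarm

Closed-loop simulation of cerebellar motor learning in a robot manipulation
task. A rate-based cerebellar micro-circuit — granular-layer state generator,
Purkinje cells (PC), mossy-fiber (MF) baseline, deep cerebellar nuclei (DCN)
output — delivers corrective torques to a simulated 3-link arm tracking a
fast "eight-shape" trajectory while carrying unexpected payloads or resisting
a sinusoidal force field. Four synaptic sites learn simultaneously:

* **PF-PC** (cortical): `dw = LTP/(IO+1)^a - LTD*IO` on the active
  parallel fiber — state-specific error-driven learning under the
  inferior-olive (IO) teaching signal;
* **MF-DCN** and **PC-DCN**: slow gain control of the nuclear output;
* **IO-DCN**: `dw = MTP*IO - MTD/(IO+1)^a` with MTP/MTD orders of magnitude
  larger than LTP/LTD — a fast self-adaptive excitatory connection from the
  olive onto the nuclei that acts as a built-in feedback controller during
  the early, otherwise open-loop, phase of learning.

The package is for computational neuroscientists and neurorobotics
researchers who want a desk-scale, fully deterministic testbed for
distributed cerebellar plasticity: every experiment is a few seconds to a
few minutes of CPU.

## Worked example

```python
import numpy as np
from cerebarm import preset, run_experiment, LearningCurve, convergence_samples

# distributed DCN plasticity alone (no IO-DCN), 2 kg payload
noio = run_experiment(preset("fig3_2kg", n_trials=1000))
# same task with the self-adaptive IO-DCN connection
adapt = run_experiment(preset("fig5_adaptive", n_trials=1000))

for name, res in [("no IO-DCN", noio), ("adaptive IO-DCN", adapt)]:
    print(f"{name:16s} trial-1 MAE {res.mae[0]:.3f} rad, "
          f"trial-10 {res.mae[9]:.3f}, final {res.mae[-100:].mean():.4f}")
print("IO-DCN drive share, first vs last decile: "
      f"{adapt.io_share[:100].mean():.2f} vs {adapt.io_share[-100:].mean():.2f}")
```

prints

```
no IO-DCN        trial-1 MAE 0.272 rad, trial-10 0.189, final 0.0117
adaptive IO-DCN  trial-1 MAE 0.058 rad, trial-10 0.053, final 0.0194
IO-DCN drive share, first vs last decile: 0.68 vs 0.03
```

Without the IO-DCN connection the circuit is effectively open-loop for
hundreds of trials (trial-10 error is still 70% of trial-1) before the slow
DCN gain adaptation completes. With the adaptive IO-DCN connection the error
is cut ~5x on the very first trial; as the cortical pathways converge, the
olivary contribution to the nuclear drive fades from ~70% to ~3% — the
transfer of control the model predicts.

The same machinery is available from the shell:

```bash
cerebarm list-scenarios
cerebarm run --scenario fig5_adaptive --trials 1000 --out runs/adaptive --plot
cerebarm sweep --trials 400 --out runs/sweep.json
cerebarm compare fig3_2kg fig5_adaptive --trials 1000
```

Each run directory contains the per-trial MAE and weight-series CSV files,
the final weight tables, the resolved YAML configuration and a JSON summary.

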