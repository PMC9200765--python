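# crabloom

Analysis toolkit for escape decisions of crabs facing one or two
simultaneously approaching looming stimuli — and for the
looming-sensitive lobula giant neurons thought to drive those
decisions.

When two threats approach at once, an animal can attend *selectively*
(respond to one threat, suppress the other: escape directions form a
bimodal distribution, one mode directly away from each stimulus) or
*divide* attention (integrate both: a single mode in the direction that
maximises distance from both).  Analogously, a looming-sensitive neuron
confronted with two stimuli can respond like the stronger single
stimulus (a max / select-stronger rule) or blend the two (sum or
average).  `crabloom` implements the full analysis chain that
discriminates these hypotheses, plus a synthetic-data generator that
emulates both the treadmill escape experiments and the intracellular
recordings, so every stage is testable end to end without access to
the original recordings.

The core pieces:

- **Stimulus kinematics** — a disk of diameter D approaching at speed v
  subtends `theta(tau) = 2 arctan(R / (v tau))` at time-to-collision
  tau (capped at 180° when it fills the screen), with analytic
  expansion rate `2Rv / (d² + R²)`; Weber contrast and display
  linearization included.
- **Circular statistics** — vector summaries, Rayleigh test, Rao
  homogeneity (dispersion) test, bootstrap confidence arcs, the
  multimodal transform (angles ×4 mod 360 for 90°-separated stimuli,
  ×2 for axial/180°) that maps selective escape modes onto 0° and the
  divided mode onto 180°, the green/white/red sector protocol, and 90°
  body-orientation binning.
- **Spike-train analysis** — instantaneous firing rate by Gaussian-kernel
  smoothing (FWHM 200 ms) normalized to conserve the spike count,
  spontaneous baseline statistics, response onset at mean + 2 SD with a
  sustained-crossing requirement, peak and average rate during the
  response.
- **Attention inference** — decision procedures returning
  selective / divided (behaviour) and select_stronger / sum / average
  (neurons) verdicts with their supporting statistics, plus
  subject-stratified permutation tests for timing contrasts with Holm
  adjustment.
- **Synthetic data** — Latin-square treatment orders, von Mises escape
  directions with body-orientation and contrast choice biases, and
  inhomogeneous-Poisson spike trains driven by stimulus expansion rate
  under a configurable integration rule.

## Worked example

```python
import crabloom as cl

params = cl.BehaviorGenParams(attention_mode="selective", seed=42)
trials = cl.gen_escape_trials(params, cl.experiment1_treatments(), 50, 1)
report = cl.behavioral_decision(trials, cl.AnalysisConfig(seed=0))
print("verdict:", report.behavioral_verdict)
for name, entry in report.statistics["treatments"].items():
    print(f"{name}: n={entry['n_responding']}, "
          f"transformed mean={entry['mean_transformed']:.1f} deg, "
          f"rho={entry['rho_transformed']:.2f}, "
          f"Rayleigh p={entry['rayleigh_transformed']['p']:.2g}")
```

prints

```
verdict: selective
Paired90: n=39, transformed mean=4.6 deg, rho=0.26, Rayleigh p=0.068
Paired180: n=32, transformed mean=2.5 deg, rho=0.79, Rayleigh p=2.9e-09
```

Fifty simulated crabs saw each treatment once; 39 and 32 responded to
the paired treatments.  After the multimodal transform both paired
distributions have mean directions near 0° — the signature of selective
attention (a divided strategy would put them near 180°).  The ×2
transform of the axial Paired 180 data is far more concentrated
(rho 0.79) than the ×4 transform of Paired 90 (rho 0.26), so here the
180° treatment carries the statistical weight of the verdict.

The same pipeline is available from the shell:

```sh
crabloom stimulus-trace            # collision in 25.00 s; initial subtense 0.34 deg
crabloom run-all --seed 7 --out results/
```

`run-all` simulates a behavioural experiment and a neuron population,
analyses both, and writes `trials.csv`, `spikes.csv`, `spike_meta.csv`
and a provenance-stamped `report.json` (byte-identical across reruns
with the same config and seed).

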