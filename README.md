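# refuge-phage

Tools for studying how ephemeral spatial refuges change the outcome of
lytic phage predation on bacteria.  In a well-mixed culture, phage attack
selects hard for heritable genetic resistance; inside the dead-end
micro-channels of a mother-machine device the encounter rate between phage
and bacteria is far lower and survival is dominated by *phenotypic*
resistance — chiefly cell-to-cell variation in surface-receptor expression.
This package implements the computational machinery needed to dissect that
contrast:

- **`refuge_phage.abm`** — a generation-discrete agent-based infection
  model.  Each bacterium carries a receptor-expression level ρ ∈ [0.5, 1]
  (its per-attempt infection probability) and a binary genetic-resistance
  flag γ.  Infected cells convert, on average, R·N<sub>sus</sub>/(N<sub>sus</sub>+N<sub>inf</sub>)
  uninfected cells per generation (attempt counts are Poisson), then lyse;
  uninfected cells double up to the carrying capacity — globally in the
  unstructured environment, per 20-cell channel in the structured one.
  Daughters inherit γ exactly and ρ with N(ρ, 0.1) perturbation.
- **`refuge_phage.flow` / `refuge_phage.transport`** — steady no-slip flow
  in the 25 × 100 μm main channel (rectangular-duct series or sparse
  Poisson solve, rescaled to an exact volumetric rate) and Brownian
  point-particle phage transport (D = 4 μm²/s, 5 ms steps, specular wall
  reflection, periodic along the flow axis), with per-refuge entry/exit
  event logs, arrival rates, residence times and phage-free-fraction
  curves.
- **`refuge_phage.encounter`** — the diffusion-limited capture-rate
  constant k = 2πDl / ln(2l/w) for a rod-shaped cell and the encounter
  rate E = C_B·C_P·k, with unit handling (μm³/s ↔ ml/min).
- **`refuge_phage.trajectory`** — single-cell analysis of per-channel
  time series: fate classification (lysed / survived growing /
  survived non-growing / filamented / flushed), probabilistic imputation
  of flushed cells, division-count distributions before death,
  population curves with SEM, t = 2–7 h linear extrapolation to the
  predicted eradication time, and killed-vs-survivor receptor-reporter
  comparisons (Shapiro–Wilk gated t / rank tests).
- **`refuge_phage.synthetic`** — a ground-truthed generator of
  mother-machine-like datasets (continuous-time division, Poisson phage
  arrival at 1.2 per channel per hour, fluorescence-dependent infection,
  25-min lysis delay, filamentation episodes, capacity flushing) so every
  analysis stage is testable without any external data.

## Worked example

Contrast the two environments at the study conditions (K = 10⁶ well-mixed
vs 2000 × 20-cell channels; 10⁴ founders, 200 initially infected, R = 20,
background genetic-resistance frequency 5 × 10⁻⁴):

```python
import numpy as np
from refuge_phage.abm import ABMConfig, run

for kind in ("unstructured", "structured"):
    res = run(ABMConfig(environment_kind=kind, n_generations=25,
                        n_replicates=5, seed=1))
    finals = [r[-1].fraction_genetic_resistant for r in res.records]
    totals = [r[-1].n_total for r in res.records]
    print(f"{kind:13s} median final resistant fraction: "
          f"{np.median(finals):.2e}  median population: {np.median(totals):.0f}")
```

prints

```
unstructured  median final resistant fraction: 1.00e+00  median population: 1000000
structured    median final resistant fraction: 8.05e-04  median population: 36040
```

Well-mixed, the susceptible population collapses within ~3 generations and
the handful of genetically resistant founders sweeps to fixation.  In the
channelised environment the same background frequency stays near 8 × 10⁻⁴:
resistant clones cannot spread beyond their 20-cell refuge, while
genetically sensitive, low-ρ cells survive — at 25 generations, sampled
infection attempts kill cells with systematically higher receptor levels
than the cells they spare.

The encounter-rate calculator gives the well-mixed baseline:

```
$ refuge-phage encounter --D 4 --l 3 --w 0.8 --cb 1e7 --cp 1e7
{
  "k_ml_per_min": 2.2452164570937015e-09,
  "encounter_rate_per_ml_per_h": 13471298.742562208,
  "per_cell_rate_per_h": 1.347129874256221,
  ...
}
```

i.e. k ≈ 2.2 × 10⁻⁹ ml/min, and at 10⁷ bacteria and phage per ml each
bacterium meets more than one phage per hour.

The same functionality is scriptable through the CLI:
`refuge-phage {abm,transport,encounter,analyze,synth} --config FILE --out DIR`;
every run writes a `manifest.json` (config, seeds, version) and reruns with
the same config are bit-identical.

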