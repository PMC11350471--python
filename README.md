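# chargeladder

Analysis of protein **charge ladders** measured by capillary electrophoresis
(CE): estimate a protein's net charge *Z*, the change in net charge upon
metal-site reduction (ΔZ_ET), percent charge regulation, and whether an
electron-transfer event is uncoupled ET, proton-coupled (PCET) or
two-proton-coupled (2PCET).

Intended for protein biophysical chemists who measure metalloprotein
electrostatics with lysine-acetylation charge ladders — and for anyone who
wants a tested, seeded synthetic-electropherogram generator to validate such
an analysis end to end.

## The method

A lysine charge ladder is a set of derivatives of one protein with
N = 0, 1, 2, … acetylations, each removing one positive lysine charge
(net effect ΔZ_Ac < 0 per acetylation). In CE against a neutral
electroosmotic-flow (EOF) marker such as DMF, the effective mobility of
rung N is linear in N:

    μ = (L_d·L_t/V)·(1/t − 1/t_eof),      μ_N = c·(Z + N·ΔZ_Ac)

so an ordinary least-squares line of μ on N has x-intercept −Z/ΔZ_Ac and

    Z = ΔZ_Ac · intercept/slope

independently of the unknown hydrodynamic coefficient *c* — the ladder is
its own calibration. Comparing oxidized and reduced forms gives
ΔZ = Z_red − Z_ox, and per transferred electron:

| ΔZ per electron | protons per electron | label |
|---|---|---|
| −1 | 0 | ET |
| 0 | 1 | PCET |
| +1 | 2 | 2PCET |

with percent charge regulation 100·(1 − |ΔZ/e|). See `docs/methods.md` for
the full model, defaults and numerical choices.

## Worked example

Simulate a paired oxidized/reduced experiment for a dimer with true
Z_ox = −6.35 and Z_red = −6.44 (four Cu²⁺ → Cu¹⁺, near-complete charge
regulation), six ladder rungs, six technical replicates per state, realistic
replicate jitter and detector noise — then run the full analysis:

```python
from chargeladder import (CapillaryConfig, SyntheticTruth, analyze_experiment,
                          report, simulate_experiment)
from chargeladder.synthetic import NoiseSpec

truth = SyntheticTruth()          # Z_ox=-6.35, Z_red=-6.44, 6 rungs
exp = simulate_experiment(truth, NoiseSpec(), CapillaryConfig(),
                          n_replicates=6, base_seed=17, pH=7.4)
comparison = analyze_experiment(exp, n_electrons=4)
print(f"Z_ox  = {comparison.z_ox.z_mean:+.2f} +/- {comparison.z_ox.z_sd:.2f}")
print(f"Z_red = {comparison.z_red.z_mean:+.2f} +/- {comparison.z_red.z_sd:.2f}")
print(f"dZ_4ET = {comparison.delta_z:+.2f}, per electron {comparison.delta_z_per_e:+.2f}")
print(f"charge regulation {comparison.cr_percent:.0f}%  ->  {comparison.coupling_label}")
```

prints

```
Z_ox  = -6.35 +/- 0.08
Z_red = -6.47 +/- 0.06
dZ_4ET = -0.12, per electron -0.03
charge regulation 97%  ->  PCET
```

Each replicate's electropherogram was peak-picked, its rungs assigned
relative to its own EOF marker, converted to mobilities, and regressed; the
per-replicate Z values average to within the replicate scatter (±0.08) of
the true −6.35. The four-electron reduction changes the dimer's charge by
only ≈ −0.1 instead of −4: ~97 % of the added charge is absorbed by proton
uptake, the signature of PCET at every copper site.
`report([comparison])` renders the same numbers as a publication-style
two-row table, and `chargeladder simulate / analyze / redox` expose the
same steps as a command-line workflow on trace CSV files.

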