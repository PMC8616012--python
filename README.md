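# polarcyte

A toolkit for single-particle optical cytometry that combines **polarized
light scattering** with **chlorophyll fluorescence**.  It targets instruments
that focus a polarized laser into a stirred aquatic suspension, let particles
transit the focal volume one at a time, and record five synchronized
photodetector voltages: four polarization-analyzer channels and one
fluorescence channel.  The goal is to classify suspended particles —
microplastics, mineral grains, microalgae down to ~1 μm cyanobacteria — from
their per-particle optical signatures, without microscopy or flow-cytometer
plumbing.

## The measurement model

The polarization state of a beam is the Stokes vector
`S = [I, Q, U, V]ᵀ`; the per-particle polarization features are

```
q = Q/I,  u = U/I,  v = V/I,        DOP = sqrt(q² + u² + v²)
```

A division-of-amplitude polarization-state analyzer (PSA) splits the
collected light into four channels (two 30:70 and one 50:50 non-polarizing
splitters), each analyzed by its own element chain — a 135° quarter-wave
plate + 90° polarizer (left-circular channel), and 0°, 90° and 45°
polarizers.  The four voltages are linear in the incident Stokes vector:

```
IPSA = [IL, I0, I90, I135]ᵀ = A_PSA · S        ⇒        S = A_PSA⁻¹ · IPSA
```

`A_PSA` is either built from the ideal-element forward model or **calibrated**
by probing the analyzer with known Stokes states and solving the stacked
equations by least squares.  A particle's transit produces a pulse on every
channel; integrating each channel over the pulse, inverting `A_PSA`, and
normalizing the fluorescence integral by the recovered intensity gives the
six-feature record per particle:

```
[I, q, u, v, DOP, F],        F = Fm / I
```

`F = Fm/I` cancels the transit-position amplitude factor common to all
channels.  An LDA/SVM stage then classifies particles, and comparing the
five-feature (`pol5`) against the six-feature (`pol5+F`) classifier
quantifies what simultaneous fluorescence measurement adds.

A bundled instrument simulator generates labeled synthetic experiments
(Poisson transits, class-specific scattering Mueller matrices and
fluorescence ratios, Gaussian channel noise) so the whole chain is testable
without hardware.

## Worked example

Simulate the four-algae benchmark, then compare classification with and
without fluorescence:

```python
from polarcyte import make_benchmark_suite, svm_train_eval

bench = make_benchmark_suite("algae4", seed=1, n_per_class=400)
labels = bench.features["label"]
r5 = svm_train_eval(bench.features, labels, feature_set="pol5",   seed=1)
r6 = svm_train_eval(bench.features, labels, feature_set="pol5+F", seed=1)
print(f"pol5   accuracy: {r5.accuracy:.1%}  per-class {r5.per_class_accuracy}")
print(f"pol5+F accuracy: {r6.accuracy:.1%}  per-class {r6.per_class_accuracy}")
```

prints

```
pol5   accuracy: 76.5%  per-class {'D.S.': 1.0, 'M.A.': 0.467, 'P.G.': 0.608, 'P.T.': 0.983}
pol5+F accuracy: 94.8%  per-class {'D.S.': 0.992, 'M.A.': 0.925, 'P.G.': 0.883, 'P.T.': 0.992}
```

(per-class values shown to three decimals).  The two spherical
bloom-forming classes (`P.G.`, `M.A.`) share a scattering signature, so
polarization alone confuses them (47–61% per-class accuracy);
their distinct fluorescence distributions resolve the pair once `F` joins
the feature vector.

The same works from the shell:

```
polarcyte simulate --preset ps10-family --seed 5 --mode traces --out-prefix bench
polarcyte extract  --traces bench.traces.tsv --out features.csv
polarcyte train    --features features.csv --feature-set pol5+F
```

and the fluorescence physics chain is available as a table, e.g.

```
$ polarcyte physics --par 1e9 --chla 5 --a-star 0.02 --qa-star 0.6 --phi-f 0.03
yield_umol_m3_s      1.8e+06
emitted_flux_umol_s  1.8e-05
total_power_nw       3143.47
collection_fraction  0.00111408
collected_power_nw   3.50209
voltage_v            17.5105
```

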