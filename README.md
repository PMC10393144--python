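# esport-erp

Analysis pipeline for oddball-paradigm EEG and cognitive-test data that asks
whether task expertise (professional vs novice esports players) leaves
measurable neurophysiological and behavioural signatures. The package
implements the full chain from epoched multi-channel EEG to publishable
result tables — and, because the underlying study's raw recordings are not
publicly deposited, ships a synthetic-data generator that emulates the
study's two-group statistical structure so every stage is testable end to
end.

## What it computes

Given epoched EEG (32-channel 10–20 montage, 250 Hz) from four oddball
blocks — a simple blue/red-ball oddball (B/RB) and three game-scene blocks
with decreasing target size (BT, MT, ST) — plus trial logs from reaction-time
and visual-search tests:

- **Preprocessing** — Kaiser-windowed sinc FIR band filters (0.5–30 Hz)
  applied zero-phase, epoching with a 100 ms pre-stimulus baseline,
  peak-to-peak amplitude rejection at 500 µV, and robust-z channel screening
  (z > 3 with SD taken as 0.7413 × IQR) with inverse-distance interpolation.
- **ERP components** — per-subject target-locked averages; P200/N200/P300
  measured as the mean within ±10 ms of the windowed extremum (amplitude)
  and the 50 % fractional-area latency:
  `lat = min{ t : ∫ᵗ [s(τ)·polarity]₊ dτ = ½ ∫ [s(τ)·polarity]₊ dτ }`,
  integrating over the component search window.
- **Time–frequency** — single-trial variational mode decomposition (ADMM
  with Wiener-filter mode updates and power-centroid frequency updates) into
  K = 6 band-limited modes, Hilbert–Huang spectrograms on a 101-point
  0–30 Hz grid, and group comparison of subject-mean spectrograms.
- **Tensor decomposition** — order-3 (channel × time × trial) and order-4
  (channel × frequency × time × trial) tensors over pooled target trials,
  approximated by rank-5 CPD fitted with alternating least squares under an
  orthonormality constraint on the spatial factor; per-subject component
  power = signed sum of the subject's trial coefficients, compared across
  groups with the Mann–Whitney U test.
- **Statistics** — Welch's unequal-variance t (raw data or printed
  summaries), label-permutation tests (exact enumeration for tiny samples),
  Hedges' g with the exact Γ-function small-sample correction,
  threshold-free cluster enhancement
  `TFCE(p) = Σ_h e(p,h)^E · h^H · dh` (E = 0.5, H = 2) over 1-D ERP curves,
  2-D spectrograms and the electrode adjacency graph, with max-statistic
  permutation p-values, and channel-wise Spearman correlation maps.
- **Cognitive metrics** — reaction-time cleaning (physiological thresholds,
  then a per-subject 1.5-IQR fence), correct rates, visual-search final
  score (+1/−1), signed target-count error, and comparison rows in the
  published table format.

## Worked example

```python
from esport_erp import synthetic, erp, stats
from esport_erp.synthetic import SimulationConfig
from esport_erp.profiles import default_profiles

profiles = default_profiles()               # published group summaries
cfg = SimulationConfig(seed=1)
epochs = synthetic.generate_epochs(cfg, "ST", profiles,
                                   n_targets=32, n_nontargets=8)
measures = erp.measure_components(epochs)   # tidy per-subject table
p300 = measures[measures.component == "P300"]
pro = p300[p300.group == "PRO"]
nov = p300[p300.group == "NOVICE"]
t, df, p = stats.permutation_test(pro.amplitude_uV, nov.amplitude_uV,
                                  n_perm=2000, seed=0)
print(f"t = {t:.1f}, p = {p:.4f}")
```

prints

```
t = 6.5, p = 0.0005
```

i.e. with the study-calibrated group profiles (small-target P300 amplitude
15.87 ± 5.40 µV for professionals vs 7.75 ± 3.16 µV for novices) a
10-vs-10-subject permutation test flags the amplitude difference decisively.
Worked-example statistics computable from printed summaries alone reproduce
the published table: the visual-search final-score row
(16.90 ± 6.05 vs 19.10 ± 6.37, n = 10 each) gives Welch t(18) = −0.8 and
Hedges g = 0.34, exactly as printed.

A full synthetic run (all four paradigms through every stage, with report
CSVs) is one call:

```bash
esport-erp run-all --seed 1 --out run_output --scale-targets 12
```

## Layout

```
src/esport_erp/
  synthetic.py      two-group EEG + cognitive-log generator
  preprocessing.py  FIR filters, epoching, rejection, channel repair
  erp.py            ERP averaging and component measurement
  vmd.py            variational mode decomposition, Hilbert spectrograms
  tensor.py         trial tensors, orthogonality-constrained CPD
  stats.py          permutation tests, effect sizes, TFCE, Spearman maps
  cognitive.py      reaction-time/visual-search metrics and filtering
  features.py       per-subject feature tables and correlation analyses
  pipeline.py       end-to-end orchestration and report tables
  cli.py            thin command-line wrapper (esport-erp)
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
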