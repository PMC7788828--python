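# brainshift

Quantitative MRI analysis of cerebral compartment shifts for paired
two-condition small-animal studies — for example, how two anesthetic regimens
redistribute volume between cerebrospinal fluid (CSF) and brain parenchyma
and shift tissue T2\*.  The package bundles four estimator families behind a
single pipeline, and a digital brain phantom that generates every input with
known ground truth, so the whole analysis is testable without scanner data.

* **Morphometry** — proton-density-weighted (PDW) volumes are bias-corrected,
  segmented into GM/WM/CSF posteriors by a prior-weighted Gaussian-mixture EM
  with a partial-volume (mixel) refinement, and summarized as probabilistic
  compartment volumes (posterior mass × voxel volume).
* **Relaxometry** — per-voxel T2\* from multi-gradient-echo series by
  log-linear least squares on S(TE) = S0·e^(−TE/T2\*), with 0.1–99%
  percentile-trimmed compartment means.
* **Diffusion** — three orthogonal DWI directions combined by geometric mean;
  Stejskal–Tanner ADC maps fitted separately in low (20–205), mid (235–1016)
  and high (1117–2518 s/mm²) b-value windows from
  S(b) = S0·e^(−b·ADC); and for b ≥ 235 s/mm² the simplified kurtosis model

      S(b) = S0 · exp(−b·ADC₀ + (b·ADC₀)²·K/6)

  fitted per voxel by bounded trust-region nonlinear least squares
  (K initialized at 0.623; box constraints 0.5–2.0× the mid-window S0 and
  ADC, 0 < K < 2).
* **Voxel statistics** — voxel-wise paired t-tests with Benjamini–Hochberg
  FDR correction, paired tests on compartment totals, and ROI tables.

## Worked example

Simulate a 12-subject paired cohort in which condition A carries a ~6%
larger CSF compartment (190 vs 180 mm³, exchanged with parenchyma so total
intracranial volume is conserved) and condition B a +1.8 ms global T2\*
shift, then run the full analysis:

```bash
brainshift run-all --seed 17 --out results/run1/
```

which prints the group-level paired tests, e.g.

```json
{
  "csf_mm3": {
    "metric": "csf_mm3",
    "n_pairs": 12,
    "mean_a": 191.94,
    "mean_b": 182.09,
    "mean_difference": 9.85,
    "t": 17.56,
    "p": 2.1e-09,
    "pct_difference": 5.41
  },
  "parenchyma_t2star_ms": { "mean_a": 28.52, "mean_b": 30.27, "...": "..." }
}
```

Read: across the 12 pairs the segmentation recovered a CSF volume of
191.9 mm³ in condition A versus 182.1 mm³ in condition B — a 9.9 mm³ (5.4%)
paired difference, hugely significant (t = 17.6) and matching the planted
190 : 180 contrast at the cohort's jittered anatomy — while TIV shows no
difference (t = 1.59, p = 0.14) and the T2\* means sit ~1.75 ms apart.  `results/run1/` also holds
per-subject `volumes.csv`, `t2star.csv`, `adc_rois.csv` (ADC in μm²/s per
b-window plus kurtosis per ROI), voxel-wise t/p/q/significance maps as
NIfTI, the protocol files (bval/bvec + YAML), and `summary.json` with the
configuration hash.

The kurtosis sensitivity experiment runs standalone in seconds:

```bash
brainshift simulate-kurtosis-effect --reductions 0.2,0.4
#  kurtosis_reduction  k_value  adc_fit_mm2_s  adc_pct_change
#                 0.2      0.8       0.000386        9.000000
#                 0.4      0.6       0.000418       17.960671
```

i.e. with the reference calibrated so a 20% kurtosis reduction inflates the
high-b mono-exponential ADC by 9%, a 40% reduction inflates it by ~18% —
reduced non-Gaussian diffusion masquerades as faster diffusion when ADC is
read from high b-values alone.

Every subcommand is also available individually (`simulate`, `segment`,
`volumes`, `fit-t2star`, `fit-adc`, `fit-kurtosis`, `vbm`, `roi-stats`), and
the same functionality is importable:

```python
import brainshift as bs

protocol = bs.DiffusionProtocol.default()          # 57 b-values, 20-2518 s/mm^2
table = bs.simulate_dmso(protocol, adc=6.8e-4)     # mono-exponential control
fit = bs.fit_adc_range(table["signal"].to_numpy(), protocol, "high")
print(fit.adc_map * 1e6)                           # -> 680.0 um^2/s
```

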