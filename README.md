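# neuroraman

Raman spectral analysis of brain tissue for discriminating traumatic brain
injury (TBI) from healthy controls: probe-spectrum preprocessing, hexagonal
self-organizing-map classification with a per-class discriminant index
(SKiNET/SOMDI), and non-negative least-squares (NNLS) unmixing of brain-lipid
components.

## The problem

Intracranial Raman probes measure inelastic light scattering from cortical
tissue. The fingerprint region (600–1800 cm⁻¹) carries the biochemistry:
after brain injury, mitochondrial cardiolipin is released and oxidised, which
depresses the unsaturated-lipid bands at 1266 cm⁻¹ (=C–H in-plane bending)
and 1660 cm⁻¹ (C=C stretch) while the shared CH₂/CH₃ bending band at
1447 cm⁻¹ is comparatively stable — so the 1447/1660 peak-height ratio rises
with injury severity. Raw probe spectra, however, are dominated by a broad
fluorescence background, detector noise and cosmic-ray spikes, and the
injury signal in a single short-acquisition spectrum is subtle. This package
implements the full chain from raw accumulation stacks to class calls and
lipid quantification, together with a synthetic-acquisition generator that
makes every stage testable against known ground truth.

## Methods at a glance

- **Synthetic cohorts** — each sample is a non-negative mixture
  `y = Σᵢ cᵢ Kᵢ(ν) + b(ν)` of pseudo-Voigt component spectra
  (cardiolipin, ganglioside, hemoglobin, cholesterol, protein) over a
  fluorescence background `b`, emitted as 15 noisy accumulations with
  Poisson-count cosmic-ray spikes. Class structure: cardiolipin mean
  coefficient at 50 % in the TBI class.
- **Preprocessing** — spikes are detected per channel against the median of
  the other accumulations (robust z > 8) and replaced by that neighbour
  median; the baseline is an 11-node cubic spline fitted by iteratively
  re-weighted penalised least squares that tracks the lower envelope;
  resampling is linear and never extrapolates.
- **SKiNET** — a hexagonal Kohonen map (default 10×10) whose neurons carry a
  spectral weight vector and a co-trained class-label vector. Classification
  is the label argmax of the best-matching unit (BMU). The SOM discriminant
  index for class c is `Σₙ (Lₙ,c − mean_{c'≠c} Lₙ,c') Wₙ`, normalised by
  total weight mass: its positive peaks are the wavenumbers that drive
  activation toward class c.
- **Unmixing** — `min_{c ≥ 0} ‖y − Σᵢ cᵢ Kᵢ − c₀·1‖₂` per sample average
  spectrum (peak-normalised components, optional constant offset), followed
  by per-component one-way ANOVA across injury groups.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohort (40 samples, seeded). From the repository root:

```
$ python analysis/01_simulate_cohort.py
wrote 40 samples (15 accumulations each) to scratch/cohort
  true cardiolipin coefficient, control: 1.004 +/- 0.102
  true cardiolipin coefficient, TBI: 0.471 +/- 0.058

$ python analysis/02_preprocess.py
preprocessed 40 samples into scratch/preprocessed
  1447/1660 ratio, TBI: 1.689 +/- 0.111
  1447/1660 ratio, control: 1.301 +/- 0.107
ratio elevated in TBI: True

$ python analysis/03_train_som.py
trained 10x10 SOM on 28 spectra; held-out accuracy 1.00 on 12
  top SOMDI bands, TBI: 1266, 1661, 1337, 1449, 753 cm-1

$ python analysis/04_unmix.py
mean |coefficient error| relative to component means: 4.7%
  cardiolipin  control 0.946  TBI 0.420  F=394.1  p=1.2e-21
  ganglioside  control 0.764  TBI 0.835  F=2.7  p=0.11
  ...
```

Reading the output: the injury ratio 1447/1660 is clearly elevated in the
TBI group (1.69 vs 1.30); the SOM separates held-out TBI from control
spectra perfectly at this effect size; the discriminant concentrates on the
diagnostic bands (1266, 1660, 1337, 1447/1449, 1003 cm⁻¹); and NNLS recovers
the programmed cardiolipin depletion (fitted 0.42 vs 0.95, true 0.47 vs
1.00) with cardiolipin the only strongly significant group difference.
Summary tables land in `results/`, bulky per-sample intermediates in
`scratch/`.

The same pipeline is scriptable in one step (`neuroraman run --config
config.yaml --out results/run`) and exposed as a library
(`neuroraman.generate_cohort`, `preprocess_stack`, `train_som`,
`compute_somdi`, `nnls_fit`, `group_compare`, ...).

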