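# aquaspec

Chemometric characterization of water–polymer interactions in near-infrared
(NIR) spectra.

When water is dispersed in a polymer matrix, its two major NIR bands — the
"overtone" band (ν<sub>s</sub> + ν<sub>as</sub>, ~6900 cm⁻¹) and the
combination band (ν<sub>as</sub> + δ, ~5200 cm⁻¹) — shift, broaden and grow
shoulders depending on how strongly the matrix binds water. Hydrophobic
matrices (PTFE, PP, PS) promote self-associated, bulk-like water domains
visible as broad red shoulders; hydrophilic biopolymers (chitin, cellulose)
bind water so strongly that bulk-like domains barely form. `aquaspec`
packages the full analysis workflow used to study these effects on
diffuse-reflectance FT-NIR spectra of polymer–water mixtures
(10,000–4000 cm⁻¹, 0–10 % w/w water), together with a synthetic spectra
generator that emulates the reported spectral structure so every stage is
testable without instrument data.

## What is in the box

* **Preprocessing** — reflectance→absorbance (A = log₁₀ 1/R), linear offset
  correction (per-spectrum minimum subtraction), SNV, averaging per
  concentration level; wide-CSV and JCAMP-DX I/O.
* **Synthetic generator** — Gaussian band models per polymer with water-band
  center trajectories, bulk-water shoulders, residual bound water, polymer
  band–water coupling, per-preparation baselines and additive noise, for a
  bundled library of nine matrices ordered by hydrophilicity
  (PTFE < PP < PS < PVC < POM < PA < lignin < chitin < cellulose).
* **Difference spectroscopy** — resolve the water (or polymer) component by
  subtracting the pure reference spectrum scaled at an anchor wavenumber:
  f = A<sub>mix</sub>(ν₀)/A<sub>ref</sub>(ν₀), component = mix − f·ref;
  plus water-band peak tracking over the concentration series.
* **Chemometrics** — NIPALS PCA, PLS1 regression of water fraction with full
  leave-one-out cross-validation and residual-based outlier flagging,
  median-linkage (WPGMC) hierarchical clustering on squared Euclidean
  distances, and MCR-ALS (X ≈ C·S with non-negative C and S solved by
  alternating active-set NNLS).
* **2D correlation spectroscopy** — synchronous Φ = X̃ᵀX̃/(m−1) and
  asynchronous Ψ = X̃ᵀNX̃/(m−1) maps (N the discrete Hilbert–Noda matrix)
  with water concentration as the perturbation.
* **Two-band aquagrams** — standardized absorbance
  An<sub>λ</sub> = (A<sub>λ</sub> − µ<sub>λ</sub>)/σ<sub>λ</sub> at selected
  wavenumbers of both water regions, rendered as radar charts.
* **CLI** — `aquaspec simulate | preprocess | diffspec | pca | cluster |
  plsr | mcr | cos2d | aquagram | run | demo`.

## Worked example

```sh
aquaspec demo --out demo_run --seed 1
```

simulates the full design (6 concentration levels × 6 preparations ×
3 measurements) for a hydrophobic (PP) and a hydrophilic (cellulose)
matrix and runs every stage. From `demo_run/summary.json`:

```json
"diffspec": {
 "PP":        {"overtone_shift": [6798.0, 6834.0],
               "combination_shift": [5178.0, 5182.0]},
 "cellulose": {"overtone_shift": [7094.0, 7118.0],
               "combination_shift": [5180.0, 5170.0]}
},
"plsr": {
 "PP":        {"r2_cv": 0.9999986, "rmsecv": 4.02e-05},
 "cellulose": {"r2_cv": 0.9999984, "rmsecv": 4.36e-05}
}
```

Reading: in the PP matrix the resolved water overtone band blueshifts from
~6798 to ~6834 cm⁻¹ as water rises from 1 % to 10 % (water becoming more
bulk-like), while its combination band stays at ~5180 cm⁻¹; cellulose's
overtone band sits far higher (~7100 cm⁻¹, weakly bound water). The
leave-one-out R²<sub>cv</sub> ≈ 1 confirms the spectral variation tracks the
nominal water content. The 2D-COS block of the same summary shows the
asynchronous cross-peak between the two water bands changing sign between
the hydrophobic and hydrophilic matrices — the overtone band responds
*faster* than the combination band in weakly hydrophilic matrices and
*slower* in strongly hydrophilic ones.

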