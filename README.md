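# kfluoro

Monte Carlo model of iodine K-fluorescence imaging in a layered breast
phantom, for physicists studying contrast-enhanced, photon-counting breast
imaging. An iodinated contrast agent accumulates preferentially in tumor
tissue; X-ray photons above the iodine K edge (33.18 keV) create K-shell
vacancies whose characteristic Kα (28.46 keV) and Kβ₁ (33.29 keV) photons
can escape the breast and be counted by a silicon converter. The
tumor-to-fibrous ratio of counted K photons is a functional contrast signal
that complements conventional attenuation imaging.

## Model

A broad beam sampled from a filtered tungsten spectrum (40 or 50 kV, 1.6 mm
Al + 0.3 mm Gd) enters a slab phantom: fat *d₁* / internal tissue *d₂*
(fibrous or tumor, uniformly loaded with iodine) / fat *d₃*. For each
history:

1. free path in fat `S₁ = −ln R / μ_fat(E)`; histories interacting in fat
   terminate;
2. the surviving remainder is converted into the contrast layer with the
   effective iodine coefficient `μ_eff(E) = (μ/ρ)_I(E)·d_CA·pd_CA`, where
   `d_CA = 300 mg/mL` and the packing density `pd_CA` is 0.14 (fibrous) or
   0.56 (tumor);
3. an interaction is photoelectric with probability `μ_pe/μ_att` of iodine
   and creates a K vacancy with probability `σ_K/(σ_K+σ_L)` above the edge;
4. the vacancy radiates Kα with probability `ξ_KL·ω_Kα = 0.690` or Kβ₁ with
   `(1−ξ_KL)·ω_Kβ = 0.162`, isotropically;
5. the K photon gets one sampled free path against the host tissue
   (iodine excluded), converted into fat at the layer boundary; it is
   *emitted* if it leaves through the bottom plane within the lateral
   bounds, and *counted* if it then photoelectrically absorbs within the
   700 µm silicon converter.

The incident photon budget is normalized to an entrance surface air kerma
of 10 mGy (4 cm total fat) or 15 mGy (8 cm). Tallies are accumulated in
independent batches for mean ± SD.

## Worked example

```
kfluoro sweep --thicknesses 0.2,1.0,2.5 --tissues fibrous,tumor \
              --kv 40 --fat 4 --n-photons 8000000 --seed 1 --out demo/
```

prints

```
d2=0.2 mm: Kalpha ratio 3.67 +/- 0.15
d2=1.0 mm: Kalpha ratio 3.26 +/- 0.05
d2=2.5 mm: Kalpha ratio 2.66 +/- 0.03
```

Each line is the tumor/fibrous ratio of counted Kα photons for one internal
layer thickness at 40 kV with 4 cm of fat, from paired 8×10⁶-photon runs.
The ratio starts near the packing-density ratio (0.56/0.14 = 4) for thin
layers and falls with thickness as the iodine-loaded layer saturates —
thin lesions are the easiest to discriminate. `demo/tallies.csv` holds the
per-run produced/emitted/counted tallies with their batch SDs (e.g. the
fibrous 0.2 mm run yields 38 463 Kα produced, 4 487 emitted, 926 counted),
`demo/ratios.csv` the ratios, and `demo/manifest.json` the seed and full
configuration for exact re-runs.

The same can be done from Python:

```python
from kfluoro import RunConfig, run_simulation, tumor_fibrous_ratio

tallies = {
    t: run_simulation(RunConfig(tube_kv=40, tissue=t, d2_mm=1.0,
                                total_fat_cm=4, n_photons=8_000_000), seed=1)
    for t in ("fibrous", "tumor")
}
print(tumor_fibrous_ratio(tallies["tumor"], tallies["fibrous"]))
```

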