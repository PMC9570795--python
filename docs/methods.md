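# Methods

## Model overview and assumptions

The package implements an analog Monte Carlo model of iodine K-fluorescence
production, escape and counting in a three-slab breast phantom. The model is
deliberately minimal and mirrors a fixed set of governing relations rather
than a general-purpose transport code:

* **Incident transport is attenuation-only.** A photon either survives the
  upper fat layer (Beer–Lambert free path) or its history ends; coherent and
  incoherent scattering act solely as terminal competing channels, never as
  direction-changing events. Only the survivor stream reaches the contrast
  layer.
* **The contrast layer interacts through its iodine load alone.** The
  interaction depth inside the layer is governed by
  `μ_eff(E) = (μ/ρ)_I(E)·d_CA·pd_CA`; the host tissue's own attenuation is
  excluded from this step. Conversely, escaping K photons see only the host
  tissue (fibrous/tumor) and fat — iodine's effect on tissue attenuation is
  ignored.
* **Only K vacancies produce tracked photons.** Photoelectric events below
  the K edge (L-shell) and scattering terminate silently. A K vacancy
  radiates Kα with probability ξ_KL·ω_Kα = 0.820×0.841, Kβ₁ with
  (1−ξ_KL)·ω_Kβ = 0.180×0.900, and otherwise nothing is followed
  (non-radiative relaxation).
* **K-photon escape uses one survival decision per layer.** A free path is
  sampled against the host tissue; if it crosses the layer's lower boundary
  the unspent path is converted into fat by the ratio of attenuation
  coefficients and the photon is advanced from the boundary crossing.
  Emission requires exit through the bottom plane; upward-going photons are
  terminated (no backscatter or top-surface tallying). Lateral containment
  is evaluated where the trajectory pierces the exit plane — checking the
  free-path endpoint instead would reject escapes based on the arbitrary
  overshoot beyond the phantom (mean 1/μ_fat ≈ 4 cm at 28.46 keV) and, with
  a 10×10 cm face, would suppress roughly half of all bottom-plane escapes,
  which is inconsistent with the emitted/produced fractions the model is
  meant to reproduce (≈0.19 for a thin fibrous layer under the 40 kV
  spectrum).
* **The detector is a bare 700 µm silicon slab.** A photon is counted iff a
  sampled free path against total silicon attenuation ends inside the
  thickness *and* the interaction is photoelectric. By default the path is
  compared to the slab thickness regardless of incidence angle (the literal
  recipe); `DetectorConfig(angled_paths=True)` divides the thickness by
  |cos θ| for sensitivity analysis. The phantom–detector air gap is ignored.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d_CA` | 0.300 g/cm³ | nominal iodine concentration of the agent |
| `pd_CA` | 0.14 / 0.56 | packing density, fibrous / tumor (tracer-distribution volume), giving 42 / 168 mg/mL effective iodine |
| `d2` | 0.02–0.25 cm | internal layer thickness |
| total fat | 4 or 8 cm | split equally above and below the layer |
| ESAK | 10 / 15 mGy | entrance air kerma pairing for 4 / 8 cm fat; sets the photon budget |
| filters | 1.6 mm Al + 0.3 mm Gd | intrinsic and additional filtration, both tube voltages |
| K edge, Kα, Kβ₁ | 33.18, 28.46, 33.29 keV | iodine energies |
| ω_Kα, ω_Kβ, ξ_KL | 0.841, 0.900, 0.820 | fluorescent yields and KL-relaxation probability |
| detector | 700 µm Si, ρ = 2.33 g/cm³ | converter layer |
| lateral face | 10×10 cm | beam uniform over the face; edge losses are small but nonzero (grazing exits) |
| batches | 10 | independent RNG substreams; SD of batch totals scaled by √batches |

## Spectra and kerma normalization

`generate_w_spectrum` is a deterministic semi-empirical fixture: a Kramers
photon-number shape `N(E) ∝ (E0−E)/E` on a uniform 0.5 keV grid (default
10.5 keV to the tube voltage). Tungsten characteristic K lines lie above
59 keV and are omitted; anode self-filtration is not modeled. Runs aiming at
a specific measured tube should load an externally computed spectrum CSV
instead (`spectrum_path`). After filtration the entrance air kerma is
`Σ C·N(Eᵢ)·Eᵢ·(μ_en/ρ)_air(Eᵢ)` with the standard conversion
`C = 1.602e-5 µGy·mm²·g/(keV·cm²)`; the photon budget is the spectrum scaled
to the target kerma. With the default fixture the 40 kV/10 mGy budget is
≈1.55×10⁸ photons/mm² and the 50 kV:40 kV budget ratio ≈1.29. Because
below-edge photons cannot contribute to any tally, an optional importance
mode (`importance_sampling=True`) simulates only the above-edge fluence
with a proportionally reduced budget; it is unbiased for every tally and
off by default.

## Attenuation data

All coefficients live in versioned CSVs under `src/kfluoro/data`,
regenerated by `tools/generate_attenuation_tables.py`:

* **Elements and air** (iodine, silicon, aluminum, gadolinium, air):
  hand-entered anchor grids at standard reference magnitudes (NIST
  XCOM / Hubbell–Seltzer scale), stored as linear coefficients at
  conventional densities. Absorption edges are encoded as adjacent grid
  rows. The gadolinium below-K-edge anchors follow the universal
  photoelectric shape σ/g ∝ Z⁵/A·f(E/E_K) scaled from the tungsten and
  barium grids, which agree to a few percent.
* **Breast tissues** (fat, fibrous, tumor): a *synthetic* reconstruction
  (files suffixed `_synthetic`) — the underlying experimental measurements
  are published only graphically, so the tables come from a smooth
  photoelectric-plus-scatter parameterization pinned to widely published
  breast-tissue magnitudes (fat 0.456, fibrous 0.802, carcinoma 0.844 cm⁻¹
  at 20 keV).
* **K/L split**: the iodine K-shell share of photoelectric absorption is a
  precomputed jump-ratio-derived table (≈0.87, weakly energy dependent),
  zero below the edge by contract.

Interpolation is log-linear (ln μ linear in E), exact at grid nodes.
Tissue coefficients at the K-line energies are extracted by the
single-exponential fit `a·e^{−bE}` over the sparse measured-style points
(14–30 keV), a log-space least-squares fit — this mirrors the extraction
procedure the model prescribes and slightly underestimates the true
coefficients at 33.29 keV where the Compton floor flattens the curve.
Incident-beam transport uses the full tabulated curves instead.

## What the synthetic data do and do not show

The bundled tissue tables and the spectrum fixture emulate the *shape* of
real breast attenuation and filtered tungsten spectra, not any specific
measured dataset. Quantities that divide out common factors — the
tumor/fibrous counted ratios, the 40→50 kV relative advantage, the
produced→emitted→counted orderings — are robust to the residual data
uncertainty, and the test suite checks them against closed-form oracles and
published-scale reference values. Absolute tallies (photon budgets, counted
photons per mGy) inherit the uncertainty of the spectrum model and the
reference tables and should be read as order-of-magnitude estimates.

## Numerical choices

* Free paths use `−log1p(−U)/μ` with `U ∈ [0,1)`, avoiding `log(0)`.
* RNG: one `numpy` PCG64 generator per batch, spawned from
  `SeedSequence(seed)`; runs are bit-reproducible for a fixed seed and all
  functions draw only from the generator passed in.
* Batch totals give `SD(total) = √B·std(batch totals, ddof=1)`; the
  replication scheme behind published SDs is unknown, so SDs are reported
  but not compared.
* Energies are sampled per bin (inverse CDF) with uniform jitter inside the
  bin; the default grid starts at 10.5 keV so jittered energies stay inside
  the tissue tables.
* Degenerate inputs: zero-photon runs return all-zero tallies; a zero
  fibrous counted count makes the ratio NaN with a diagnostic note rather
  than infinity; kerma normalization of a zero spectrum is a validation
  error.
* Acceptance-scale runs use 1.6–4.8×10⁷ histories per simulation (thinner
  layers get more, for comparable counted statistics); the counted ratios
  are invariant to the budget, which only sets the sampling error.

## Known limitations

* No scattered-photon transport, electron transport, Doppler broadening or
  detector charge sharing; no L-fluorescence emission.
* K photons escape only through the bottom plane; top-surface fluorescence
  (relevant to backscatter geometries) is not tallied.
* The Kβ branch is modeled as the single Kβ₁ line at 33.29 keV.
* The spectrum fixture has no anode self-filtration or heel effect, so its
  soft-tail content — and hence absolute kerma-normalized budgets — differs
  from measured tube spectra; equal-kerma *comparisons* between the two
  fixture spectra remain internally consistent.
* Slab phantoms only; no anthropomorphic or voxelized geometry.
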