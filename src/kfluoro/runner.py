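"""End-to-end simulation runs: spectrum -> phantom -> transport -> detector.

A run samples a photon budget (set by a target entrance surface air kerma,
or overridden directly), transports every history through the slab phantom,
and tallies iodine K photons at three stages per line (Kalpha / Kbeta1):

* produced — K vacancies that radiated a tracked K photon;
* emitted — K photons escaping the phantom through the bottom plane;
* counted — emitted photons photoelectrically absorbed in the converter.

Histories are split into equal batches on independent RNG substreams; batch
totals provide the standard-deviation estimates.  Runs are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import materials as mat
from .detector import DetectorConfig, detect
from .phantom import Phantom, REFERENCE_ESAK_MGY, make_breast_phantom
from .spectrum import (
    Spectrum,
    apply_filtration,
    generate_w_spectrum,
    load_spectrum,
    photons_for_esak,
    sample_energy,
)
from .transport import (
    CHANNEL_PHOTOELECTRIC_K,
    LINE_KALPHA,
    LINE_KBETA1,
    advance_to_contrast_layer,
    isotropic_directions,
    sample_interaction_channel,
    sample_k_emission,
    transport_k_photon,
)

__all__ = [
    "RunConfig",
    "Tally",
    "RatioReport",
    "run_simulation",
    "tumor_fibrous_ratio",
    "write_report",
    "load_config",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one simulation run.

    Lengths are cm internally; the constructor arguments carry explicit unit
    suffixes where they deviate.  The reference air-kerma pairing (10 mGy for
    4 cm total fat, 15 mGy for 8 cm) is enforced unless ``force`` is set or
    an explicit ``n_photons`` budget bypasses kerma normalization.
    """

    tube_kv: float = 40.0
    tissue: str = "fibrous"
    d2_mm: float = 1.0
    total_fat_cm: float = 4.0
    target_esak_mGy: float | None = None  # default: reference pairing
    n_photons: int | None = None  # explicit budget override
    batches: int = 10
    bin_width_keV: float = 0.5
    e_min_keV: float = 10.5
    filters: tuple[tuple[str, float], ...] = (
        ("aluminum", 0.16),  # 1.6 mm intrinsic
        ("gadolinium", 0.03),  # 0.3 mm additional
    )
    spectrum_path: str | None = None  # optional externally generated spectrum
    detector_thickness_um: float = 700.0
    dCA_mg_ml: float = 300.0
    packing_density: float | None = None  # default by tissue type
    lateral_cm: float = 10.0
    importance_sampling: bool = False
    force: bool = False

    def __post_init__(self) -> None:
        if self.batches < 1:
            raise ConfigError("batches must be >= 1")
        esak_target = self.target_esak_mGy
        reference = REFERENCE_ESAK_MGY.get(float(self.total_fat_cm))
        if esak_target is None:
            if reference is None:
                raise ConfigError(
                    "no reference ESAK for this fat thickness; set target_esak_mGy"
                )
            object.__setattr__(self, "target_esak_mGy", reference)
        elif (
            self.n_photons is None
            and not self.force
            and reference is not None
            and abs(esak_target - reference) > 1e-9
        ):
            raise ConfigError(
                f"ESAK {esak_target} mGy does not match the reference pairing "
                f"({reference} mGy for {self.total_fat_cm} cm fat); "
                "pass force=True to override"
            )

    def make_phantom(self) -> Phantom:
        return make_breast_phantom(
            self.tissue,
            self.d2_mm,
            self.total_fat_cm,
            concentration_g_cm3=self.dCA_mg_ml / 1000.0,
            packing_density=self.packing_density,
            lateral_cm=self.lateral_cm,
        )

    def echo(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Tally:
    """K-photon tallies (totals over all batches) with batch-derived SDs."""

    produced_kalpha: int
    emitted_kalpha: int
    counted_kalpha: int
    produced_kbeta1: int
    emitted_kbeta1: int
    counted_kbeta1: int
    sd_produced_kalpha: float
    sd_emitted_kalpha: float
    sd_counted_kalpha: float
    sd_produced_kbeta1: float
    sd_emitted_kbeta1: float
    sd_counted_kbeta1: float
    n_incident: int
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for line in ("kalpha", "kbeta1"):
            p = getattr(self, f"produced_{line}")
            e = getattr(self, f"emitted_{line}")
            c = getattr(self, f"counted_{line}")
            if not 0 <= c <= e <= p:
                raise ValueError(
                    f"tally ordering violated for {line}: "
                    f"counted {c} <= emitted {e} <= produced {p} expected"
                )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("config_echo")
        return d


@dataclass(frozen=True)
class RatioReport:
    """Tumor-over-fibrous counted-photon ratios with propagated uncertainty."""

    ratio_counted_kalpha: float
    sd_ratio_counted_kalpha: float
    ratio_counted_kbeta1: float
    sd_ratio_counted_kbeta1: float
    d2_mm: float
    tube_kv: float
    total_fat_cm: float
    note: str = ""


def _build_filtered_spectrum(config: RunConfig) -> Spectrum:
    if config.spectrum_path is not None:
        s = load_spectrum(config.spectrum_path)
    else:
        s = generate_w_spectrum(
            config.tube_kv, config.bin_width_keV, e_min=config.e_min_keV
        )
    for name, thickness_cm in config.filters:
        s = apply_filtration(s, mat.load_material(name), thickness_cm)
    return s


def _batch_sizes(total: int, batches: int) -> list[int]:
    base, extra = divmod(total, batches)
    return [base + (1 if i < extra else 0) for i in range(batches)]


def run_simulation(config: RunConfig, seed: int) -> Tally:
    """Run a full simulation and return the accumulated tallies.

    The photon budget is ``config.n_photons`` if given, else the number of
    photons bringing the filtered spectrum to the target entrance air kerma.
    With ``importance_sampling`` enabled, only the above-K-edge portion of
    the spectrum is simulated (the sub-edge portion cannot contribute to any
    tally), with the budget reduced by the above-edge fluence fraction.
    """
    spectrum = _build_filtered_spectrum(config)
    air = mat.load_material("air")
    phantom = config.make_phantom()
    fat = mat.load_material("fat")
    iodine = mat.load_material("iodine")
    silicon = mat.load_material("silicon")
    params = mat.IODINE_FLUORESCENCE
    det = DetectorConfig(silicon, thickness_cm=config.detector_thickness_um * 1e-4)

    if config.n_photons is not None:
        n_total = int(config.n_photons)
    else:
        n_total, _ = photons_for_esak(
            spectrum, config.target_esak_mGy * 1000.0, air
        )

    sim_spectrum = spectrum
    n_sim = n_total
    if config.importance_sampling:
        above = spectrum.energies >= mat.IODINE_K_EDGE_KEV
        frac = float(spectrum.counts[above].sum() / spectrum.counts.sum())
        sim_spectrum = Spectrum(
            spectrum.energies[above],
            spectrum.counts[above],
            tube_voltage=spectrum.tube_voltage,
            filtration=spectrum.filtration,
        )
        n_sim = int(round(n_total * frac))

    # K-line attenuation coefficients from the exponential extraction fits
    fat_fit = mat.fit_exponential(energies=mat.load_tissue_fit_points("fat")[0],
                                  values=mat.load_tissue_fit_points("fat")[1])
    tis_e, tis_mu = mat.load_tissue_fit_points(phantom.internal_tissue)
    tissue_fit = mat.fit_exponential(energies=tis_e, values=tis_mu)
    line_e = {LINE_KALPHA: mat.KALPHA_KEV, LINE_KBETA1: mat.KBETA1_KEV}
    mu_tissue_line = {k: tissue_fit(v) for k, v in line_e.items()}
    mu_fat_line = {k: fat_fit(v) for k, v in line_e.items()}

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(config.batches)]
    cols = [
        "produced_kalpha", "emitted_kalpha", "counted_kalpha",
        "produced_kbeta1", "emitted_kbeta1", "counted_kbeta1",
    ]
    batch_tallies = np.zeros((config.batches, 6), dtype=np.int64)

    for i, (rng, n_batch) in enumerate(zip(streams, _batch_sizes(n_sim, config.batches))):
        if n_batch == 0:
            continue
        e = sample_energy(sim_spectrum, rng, size=n_batch)
        interacted, depth = advance_to_contrast_layer(e, phantom, fat, iodine, rng)
        e_int = e[interacted]
        depth_int = depth[interacted]
        channel = sample_interaction_channel(e_int, iodine, rng)
        kmask = channel == CHANNEL_PHOTOELECTRIC_K
        n_k = int(kmask.sum())
        lines = sample_k_emission(params, n_k, rng)
        a, b, c = isotropic_directions(n_k, rng)
        depth_k = depth_int[kmask]
        # entrance position is uniform over the face and independent of the
        # rest of the history; sample it for tracked photons only
        x0 = rng.random(n_k) * phantom.x_dimension
        y0 = rng.random(n_k) * phantom.y_dimension

        for j, line in enumerate((LINE_KALPHA, LINE_KBETA1)):
            sel = lines == line
            n_line = int(sel.sum())
            batch_tallies[i, 3 * j + 0] = n_line
            if n_line == 0:
                continue
            escaped = transport_k_photon(
                x0[sel], y0[sel], depth_k[sel], (a[sel], b[sel], c[sel]),
                mu_tissue_line[line], mu_fat_line[line], phantom, rng,
            )
            n_escaped = int(escaped.sum())
            batch_tallies[i, 3 * j + 1] = n_escaped
            if n_escaped == 0:
                continue
            energies_det = np.full(n_escaped, line_e[line])
            counted = detect(energies_det, det, rng, incidence_cosines=c[sel][escaped])
            batch_tallies[i, 3 * j + 2] = int(counted.sum())

    totals = batch_tallies.sum(axis=0)
    if config.batches > 1:
        sds = batch_tallies.std(axis=0, ddof=1) * np.sqrt(config.batches)
    else:
        sds = np.zeros(6)

    kw = {cols[k]: int(totals[k]) for k in range(6)}
    kw.update({f"sd_{cols[k]}": float(sds[k]) for k in range(6)})
    return Tally(n_incident=n_total, config_echo=config.echo(), **kw)


def scaled_equal_esak_budgets(
    kvs: tuple[float, ...],
    total_fat_cm: float,
    esak_mgy: float,
    base_photons: int,
) -> dict[float, int]:
    """Photon budgets for comparing spectra at equal entrance air kerma.

    The full ESAK-normalized budgets are computed per tube voltage and then
    scaled by a common factor so the first voltage runs ``base_photons``
    histories; relative budgets (what equal-kerma comparisons depend on) are
    preserved exactly.
    """
    air = mat.load_material("air")
    full = {}
    for kv in kvs:
        s = _build_filtered_spectrum(RunConfig(
            tube_kv=kv, total_fat_cm=total_fat_cm, force=True,
            target_esak_mGy=esak_mgy,
        ))
        full[kv], _ = photons_for_esak(s, esak_mgy * 1000.0, air)
    scale = base_photons / full[kvs[0]]
    return {kv: int(round(n * scale)) for kv, n in full.items()}


def tumor_fibrous_ratio(t_tumor: Tally, t_fibrous: Tally) -> RatioReport:
    """Elementwise counted-count ratios, tumor over fibrous.

    Both tallies must share geometry, spectrum and kerma normalization.
    Uncertainties are propagated from the batch SDs in quadrature on the
    relative scale.  A zero fibrous count yields a NaN ratio with a
    diagnostic note rather than an infinity.
    """
    ct, cf = t_tumor.config_echo, t_fibrous.config_echo
    for key in ("tube_kv", "d2_mm", "total_fat_cm", "target_esak_mGy"):
        if ct and cf and ct.get(key) != cf.get(key):
            raise ValueError(f"tallies differ in {key}: {ct.get(key)} vs {cf.get(key)}")

    note = ""
    values = {}
    for line in ("kalpha", "kbeta1"):
        num = getattr(t_tumor, f"counted_{line}")
        den = getattr(t_fibrous, f"counted_{line}")
        if den == 0:
            values[line] = (float("nan"), float("nan"))
            note += f"undefined {line} ratio: zero fibrous counted count; "
            continue
        ratio = num / den
        rel = 0.0
        if num > 0:
            rel = np.hypot(
                getattr(t_tumor, f"sd_counted_{line}") / num,
                getattr(t_fibrous, f"sd_counted_{line}") / den,
            )
        values[line] = (ratio, ratio * rel)
    return RatioReport(
        ratio_counted_kalpha=values["kalpha"][0],
        sd_ratio_counted_kalpha=values["kalpha"][1],
        ratio_counted_kbeta1=values["kbeta1"][0],
        sd_ratio_counted_kbeta1=values["kbeta1"][1],
        d2_mm=ct.get("d2_mm", float("nan")),
        tube_kv=ct.get("tube_kv", float("nan")),
        total_fat_cm=ct.get("total_fat_cm", float("nan")),
        note=note.strip(),
    )


def write_report(
    tallies: list[Tally],
    ratios: list[RatioReport],
    out_dir,
    *,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write tally and ratio CSVs plus a JSON run manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for t in tallies:
        row = {
            "tissue": t.config_echo.get("tissue"),
            "d2_mm": t.config_echo.get("d2_mm"),
            "tube_kv": t.config_echo.get("tube_kv"),
            "total_fat_cm": t.config_echo.get("total_fat_cm"),
        }
        row.update(t.as_dict())
        rows.append(row)
    tally_path = out / "tallies.csv"
    pd.DataFrame(rows).to_csv(tally_path, index=False)
    paths["tallies"] = tally_path

    if ratios:
        ratio_path = out / "ratios.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in ratios]).to_csv(
            ratio_path, index=False
        )
        paths["ratios"] = ratio_path

    from . import __version__

    manifest = {
        "seed": seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "configs": [t.config_echo for t in tallies],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = manifest_path
    return paths


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Recognized keys mirror the dataclass fields; ``filters`` entries use
    ``{material, thickness_mm}`` mappings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "filters" in raw:
        raw["filters"] = tuple(
            (f["material"], float(f["thickness_mm"]) / 10.0) for f in raw["filters"]
        )
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
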