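"""Incident X-ray spectra: generation, filtration, air kerma, sampling.

A :class:`Spectrum` is a histogram of photon counts on a uniform energy grid
(bin centers, keV).  Counts are interpreted as photons per mm^2 wherever air
kerma is computed.  The tungsten-anode generator is a deterministic
semi-empirical bremsstrahlung model (Kramers-shaped photon-number spectrum,
characteristic lines negligible below 60 kV); paper-faithful absolute photon
budgets depend on the upstream spectrum model, so externally computed spectra
can be loaded from two-column CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import AttenuationCurve

__all__ = [
    "Spectrum",
    "load_spectrum",
    "save_spectrum",
    "generate_w_spectrum",
    "apply_filtration",
    "energy_fluence",
    "esak",
    "photons_for_esak",
    "sample_energy",
]

#: Fluence-to-air-kerma conversion: uGy per (photon/mm^2 * keV * cm^2/g).
#: 1 keV/g = 1.602176634e-16 J / 1e-3 kg = 1.602e-13 Gy; fluence per mm^2 is
#: 100x the per-cm^2 value; Gy -> uGy is 1e6.  Product: 1.602176634e-5.
KERMA_UGY_PER_FLUENCE = 1.602176634e-5


class SpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """Binned photon-number spectrum on a uniform energy grid."""

    energies: np.ndarray  # bin centers, keV, ascending, uniform width
    counts: np.ndarray  # photons per bin (>= 0)
    tube_voltage: float | None = None  # kV label; counts are 0 above it
    filtration: tuple[tuple[str, float], ...] = ()  # (material, thickness cm)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        n = np.asarray(self.counts, dtype=float)
        if e.ndim != 1 or e.size == 0 or n.shape != e.shape:
            raise SpectrumError("energies and counts must be matching 1-D arrays")
        if e.size > 1:
            widths = np.diff(e)
            if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
                raise SpectrumError("energy grid must be ascending and uniform")
        if np.any(n < 0):
            raise SpectrumError("negative counts")
        if self.tube_voltage is not None and np.any(n[e > self.tube_voltage] > 0):
            raise SpectrumError("nonzero counts above tube voltage")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "counts", n)

    @property
    def bin_width(self) -> float:
        e = self.energies
        return float(e[1] - e[0]) if e.size > 1 else 1.0

    @property
    def e0(self) -> float:
        """Maximum spectral energy with nonzero counts."""
        nz = np.nonzero(self.counts > 0)[0]
        return float(self.energies[nz[-1]]) if nz.size else 0.0

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, counts=self.counts * factor)


def load_spectrum(path) -> Spectrum:
    """Read a two-column ``energy_keV,photons_per_mm2`` CSV."""
    energies, counts = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if lineno == 1 and not _is_number(parts[0]):
                continue  # header
            try:
                e, c = float(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise SpectrumError(f"{path}: parse error on line {lineno}") from exc
            if energies and e <= energies[-1]:
                raise SpectrumError(
                    f"{path}: non-ascending energy on line {lineno}"
                )
            if c < 0:
                raise SpectrumError(f"{path}: negative count on line {lineno}")
            energies.append(e)
            counts.append(c)
    return Spectrum(np.asarray(energies), np.asarray(counts))


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def save_spectrum(s: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("energy_keV,photons_per_mm2\n")
        for e, c in zip(s.energies, s.counts):
            fh.write(f"{float(e)!r},{float(c)!r}\n")


def generate_w_spectrum(
    kv: float, bin_width: float = 0.5, e_min: float = 8.0, total: float = 1e6
) -> Spectrum:
    """Unfiltered tungsten-anode bremsstrahlung-shaped spectrum.

    Kramers photon-number shape ``N(E) dE ~ (E0 - E)/E dE`` on a uniform grid
    of ``bin_width`` keV bins from ``e_min`` to the tube voltage, normalized
    to ``total`` photons.  Deterministic for fixed inputs; tungsten
    characteristic K lines lie above 59 keV and are omitted at these tube
    voltages.
    """
    if not 20.0 <= kv <= 60.0:
        raise SpectrumError(f"tube voltage {kv} kV outside supported range [20, 60]")
    edges = np.arange(e_min, kv + bin_width * 0.5, bin_width)
    centers = edges[:-1] + bin_width / 2 if edges.size > 1 else np.array([e_min])
    counts = np.clip(kv - centers, 0.0, None) / centers
    counts *= total / counts.sum()
    return Spectrum(centers, counts, tube_voltage=float(kv))


def apply_filtration(
    s: Spectrum, material: AttenuationCurve, thickness_cm: float
) -> Spectrum:
    """Attenuate every bin by ``exp(-mu(E) * thickness)``.

    Successive filters commute (pure per-bin multiplication).
    """
    if thickness_cm < 0:
        raise SpectrumError("filter thickness must be >= 0")
    if thickness_cm == 0:
        return s
    trans = np.exp(-material.mu_at(s.energies) * thickness_cm)
    return replace(
        s,
        counts=s.counts * trans,
        filtration=s.filtration + ((material.material, thickness_cm),),
    )


def energy_fluence(s: Spectrum) -> float:
    """Total energy fluence, sum of N(E_i)*E_i (keV per mm^2)."""
    return float(np.sum(s.counts * s.energies))


def esak(s: Spectrum, air: AttenuationCurve) -> float:
    """Entrance surface air kerma in uGy for counts in photons/mm^2.

    Standard fluence-to-kerma sum: ``sum_i C * N(E_i) * E_i * (mu_en/rho)_air``
    with ``C`` = :data:`KERMA_UGY_PER_FLUENCE`.
    """
    if s.counts.sum() == 0:
        return 0.0
    mu_en = air.mu_en_rho_at(s.energies)
    return float(np.sum(KERMA_UGY_PER_FLUENCE * s.counts * s.energies * mu_en))


def photons_for_esak(
    s: Spectrum, target_ugy: float, air: AttenuationCurve
) -> tuple[int, Spectrum]:
    """Scale the spectrum to a target entrance air kerma.

    Returns the integer photon budget of the scaled spectrum together with
    the scaled spectrum itself.
    """
    current = esak(s, air)
    if current <= 0:
        raise SpectrumError("cannot scale a zero-kerma spectrum to a target ESAK")
    scaled = s.scaled(target_ugy / current)
    return int(round(scaled.total_counts)), scaled


def sample_energy(s: Spectrum, rng: np.random.Generator, size: int | None = None):
    """Sample photon energies by inverse-CDF over bins.

    A bin is drawn with probability proportional to its counts and the energy
    is drawn uniformly within the bin, so the histogram of many draws on the
    spectrum's bin edges converges to the normalized counts.
    """
    total = s.counts.sum()
    if total <= 0:
        raise SpectrumError("cannot sample from an empty spectrum")
    n = 1 if size is None else int(size)
    cdf = np.cumsum(s.counts) / total
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    e = s.energies[idx]
    if s.energies.size > 1:
        e = e + (rng.random(n) - 0.5) * s.bin_width
    return float(e[0]) if size is None else e
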