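"""Energy-dependent interaction coefficients for the simulation media.

The package transports photons through breast fat, an iodine-loaded internal
tissue layer (fibrous or tumor), filter metals (Al, Gd), air (for entrance
air-kerma normalization) and a silicon converter.  Each medium is represented
by an :class:`AttenuationCurve` — a tabulated linear attenuation coefficient
on an ascending energy grid, interpolated log-linearly (``ln mu`` linear in
``E``) between nodes.

Two coefficient extractions specific to the model live here as well:

* :func:`fit_exponential` — the single-exponential fit ``a*exp(-b*E)`` used to
  extract tissue attenuation at the iodine K-line energies (28.46 and
  33.29 keV) from sparse measured points.
* :func:`kshell_fraction` — the probability that an iodine photoelectric
  absorption creates a K-shell (rather than L-shell) vacancy, from a bundled
  jump-ratio-derived table; zero below the K edge by contract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AttenuationCurve",
    "ExponentialFit",
    "FluorescenceParams",
    "IODINE_FLUORESCENCE",
    "IODINE_K_EDGE_KEV",
    "KALPHA_KEV",
    "KBETA1_KEV",
    "DENSITY_G_CM3",
    "load_material",
    "load_tissue_fit_points",
    "fit_exponential",
    "iodine_equivalent_mu",
    "photoelectric_fraction",
    "kshell_fraction",
]

#: Iodine K shell binding energy (keV).
IODINE_K_EDGE_KEV = 33.18
#: Iodine K-line energies (keV).
KALPHA_KEV = 28.46
KBETA1_KEV = 33.29

#: Conventional densities (g/cm^3) behind the bundled linear coefficients.
DENSITY_G_CM3 = {
    "iodine": 4.93,
    "silicon": 2.33,
    "aluminum": 2.699,
    "gadolinium": 7.90,
    "air": 1.205e-3,
}

_DATA_FILES = {
    "fat": "fat_synthetic.csv",
    "fibrous": "fibrous_synthetic.csv",
    "tumor": "tumor_synthetic.csv",
    "iodine": "iodine.csv",
    "silicon": "silicon.csv",
    "aluminum": "aluminum.csv",
    "gadolinium": "gadolinium.csv",
    "air": "air.csv",
}


class MaterialRangeError(ValueError):
    """Energy query outside a material's tabulated range."""


class MaterialDataError(ValueError):
    """Missing or inconsistent coefficient data."""


@dataclass(frozen=True)
class AttenuationCurve:
    """Tabulated linear attenuation coefficients for one material.

    Parameters
    ----------
    material
        Registry name (``fat``, ``iodine``, ...).
    energies
        Ascending energy grid in keV.  Absorption edges are represented by
        two closely spaced nodes.
    mu_total
        Total linear attenuation coefficient, per cm, strictly positive.
    mu_pe
        Photoelectric component, per cm (optional; iodine and silicon).
    mu_en_rho
        Mass energy-absorption coefficient, cm^2/g (optional; air).
    """

    material: str
    energies: np.ndarray
    mu_total: np.ndarray
    mu_pe: np.ndarray | None = None
    mu_en_rho: np.ndarray | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.mu_total, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise MaterialDataError(
                f"{self.material}: energy grid must be strictly ascending"
            )
        if mu.shape != e.shape or np.any(mu <= 0):
            raise MaterialDataError(
                f"{self.material}: mu_total must be positive on the grid"
            )
        if self.mu_pe is not None:
            pe = np.asarray(self.mu_pe, dtype=float)
            if pe.shape != e.shape or np.any(pe <= 0):
                raise MaterialDataError(f"{self.material}: invalid mu_pe column")
            if np.any(pe > mu * (1 + 1e-12)):
                raise MaterialDataError(
                    f"{self.material}: mu_pe exceeds mu_total on the grid"
                )
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_total", mu)
        if self.mu_pe is not None:
            object.__setattr__(self, "mu_pe", np.asarray(self.mu_pe, float))
        if self.mu_en_rho is not None:
            object.__setattr__(self, "mu_en_rho", np.asarray(self.mu_en_rho, float))

    # -- queries ------------------------------------------------------------

    def _check_range(self, energy: np.ndarray) -> None:
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(energy < lo) or np.any(energy > hi):
            raise MaterialRangeError(
                f"energy query outside {self.material} table range "
                f"[{lo:g}, {hi:g}] keV"
            )

    def mu_at(self, energy):
        """Total linear attenuation (per cm) at ``energy`` (keV).

        Log-linear interpolation: ``ln mu`` is interpolated linearly in
        energy, so tabulated nodes are reproduced exactly and exponential
        segments are interpolated exactly.
        """
        e = np.asarray(energy, dtype=float)
        self._check_range(e)
        out = np.exp(np.interp(e, self.energies, np.log(self.mu_total)))
        return float(out) if np.isscalar(energy) else out

    def pe_at(self, energy):
        """Photoelectric linear attenuation (per cm) at ``energy`` (keV)."""
        if self.mu_pe is None:
            raise MaterialDataError(
                f"{self.material}: no photoelectric column available"
            )
        e = np.asarray(energy, dtype=float)
        self._check_range(e)
        out = np.exp(np.interp(e, self.energies, np.log(self.mu_pe)))
        return float(out) if np.isscalar(energy) else out

    def mu_en_rho_at(self, energy):
        """Mass energy-absorption coefficient (cm^2/g) at ``energy`` (keV)."""
        if self.mu_en_rho is None:
            raise MaterialDataError(
                f"{self.material}: no energy-absorption column available"
            )
        e = np.asarray(energy, dtype=float)
        self._check_range(e)
        out = np.exp(np.interp(e, self.energies, np.log(self.mu_en_rho)))
        return float(out) if np.isscalar(energy) else out


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of ``mu(E) = amplitude * exp(-decay_rate * E)``.

    The fit is linear in log space (``ln mu`` regressed on ``E``), matching
    how tissue attenuation is extracted at the K-line energies from sparse
    measured points.
    """

    amplitude: float  # per cm
    decay_rate: float  # per keV
    fit_energy_range: tuple[float, float]
    residual: float  # RMS residual of ln(mu)

    def __call__(self, energy):
        e = np.asarray(energy, dtype=float)
        out = self.amplitude * np.exp(-self.decay_rate * e)
        return float(out) if np.isscalar(energy) else out


@dataclass(frozen=True)
class FluorescenceParams:
    """K-fluorescence constants of the contrast element.

    ``xi_KL`` is the probability that the K vacancy is filled from the L
    shell; ``omega_kalpha``/``omega_kbeta`` are the fluorescent yields of the
    two radiative branches.  A K vacancy therefore radiates a Kalpha photon
    with probability ``xi_KL*omega_kalpha`` and a Kbeta1 photon with
    probability ``(1-xi_KL)*omega_kbeta``; otherwise nothing is tracked.
    """

    k_edge: float = IODINE_K_EDGE_KEV
    e_kalpha: float = KALPHA_KEV
    e_kbeta1: float = KBETA1_KEV
    omega_kalpha: float = 0.841
    omega_kbeta: float = 0.900
    xi_KL: float = 0.820

    def __post_init__(self) -> None:
        for name in ("omega_kalpha", "omega_kbeta", "xi_KL"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @property
    def p_kalpha(self) -> float:
        return self.xi_KL * self.omega_kalpha

    @property
    def p_kbeta1(self) -> float:
        return (1.0 - self.xi_KL) * self.omega_kbeta


#: Default iodine parameters (K edge 33.18 keV, Kalpha 28.46, Kbeta1 33.29).
IODINE_FLUORESCENCE = FluorescenceParams()


# ---------------------------------------------------------------------------
# bundled data access
# ---------------------------------------------------------------------------

def _read_csv(filename: str) -> dict[str, np.ndarray]:
    ref = resources.files("kfluoro.data").joinpath(filename)
    with ref.open("r") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [row for row in reader if row]
    cols = np.asarray(rows, dtype=object)
    return {
        name: cols[:, i] for i, name in enumerate(header)
    }


def load_material(name: str) -> AttenuationCurve:
    """Load a bundled material by registry name."""
    if name not in _DATA_FILES:
        raise MaterialDataError(
            f"unknown material {name!r}; known: {sorted(_DATA_FILES)}"
        )
    cols = _read_csv(_DATA_FILES[name])
    e = cols["energy_keV"].astype(float)
    mu = cols["mu_total_per_cm"].astype(float)
    pe = cols["mu_pe_per_cm"].astype(float) if "mu_pe_per_cm" in cols else None
    en = cols["mu_en_rho_cm2_g"].astype(float) if "mu_en_rho_cm2_g" in cols else None
    return AttenuationCurve(name, e, mu, pe, en)


def load_tissue_fit_points(tissue: str) -> tuple[np.ndarray, np.ndarray]:
    """Sparse measured-style (energy, mu) points for the K-line extraction fit."""
    cols = _read_csv("tissue_fit_points_synthetic.csv")
    mask = cols["material"].astype(str) == tissue
    if not mask.any():
        raise MaterialDataError(f"no fit points for tissue {tissue!r}")
    return cols["energy_keV"][mask].astype(float), cols["mu_total_per_cm"][mask].astype(float)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_exponential(
    points: Iterable[tuple[float, float]] | None = None,
    *,
    energies: Sequence[float] | None = None,
    values: Sequence[float] | None = None,
) -> ExponentialFit:
    """Fit ``a*exp(-b*E)`` to (energy, coefficient) points in log space.

    Minimizes squared residuals of ``ln mu`` against a straight line in
    energy.  Requires at least three points with distinct energies and
    strictly positive coefficients.
    """
    if points is not None:
        pts = np.asarray(list(points), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (energy, mu) pairs")
        e, mu = pts[:, 0], pts[:, 1]
    else:
        e = np.asarray(energies, dtype=float)
        mu = np.asarray(values, dtype=float)
    if e.size < 3:
        raise ValueError("exponential fit needs at least 3 points")
    if np.unique(e).size != e.size:
        raise ValueError("fit energies must be distinct")
    if np.any(mu <= 0):
        raise ValueError("fit coefficients must be strictly positive")
    slope, intercept = np.polyfit(e, np.log(mu), 1)
    pred = slope * e + intercept
    residual = float(np.sqrt(np.mean((np.log(mu) - pred) ** 2)))
    return ExponentialFit(
        amplitude=float(np.exp(intercept)),
        decay_rate=float(-slope),
        fit_energy_range=(float(e.min()), float(e.max())),
        residual=residual,
    )


def iodine_equivalent_mu(
    energy,
    concentration_g_cm3: float,
    packing_density: float,
    iodine: AttenuationCurve | None = None,
) -> float | np.ndarray:
    """Effective linear attenuation (per cm) of the iodine-loaded layer.

    ``(mu/rho)_I(E) * d_CA * pd_CA``: the contrast layer attenuates the
    incident beam through its iodine load alone; the host tissue's own
    attenuation is deliberately excluded for this step.
    """
    if concentration_g_cm3 <= 0:
        raise ValueError("contrast concentration must be > 0")
    if not 0 < packing_density <= 1:
        raise ValueError("packing density must be in (0, 1]")
    if iodine is None:
        iodine = load_material("iodine")
    mass_mu = iodine.mu_at(energy) / DENSITY_G_CM3["iodine"]
    return mass_mu * concentration_g_cm3 * packing_density


def photoelectric_fraction(curve: AttenuationCurve, energy):
    """Probability that an interaction in ``curve`` is photoelectric.

    Ratio of the photoelectric to the total linear coefficient; the
    complement covers the (terminal, untracked) Rayleigh+Compton channel.
    """
    return curve.pe_at(energy) / curve.mu_at(energy)


_K_FRACTION_TABLE: tuple[np.ndarray, np.ndarray] | None = None


def _k_fraction_table() -> tuple[np.ndarray, np.ndarray]:
    global _K_FRACTION_TABLE
    if _K_FRACTION_TABLE is None:
        cols = _read_csv("iodine_kshell_fraction.csv")
        _K_FRACTION_TABLE = (
            cols["energy_keV"].astype(float),
            cols["k_shell_fraction"].astype(float),
        )
    return _K_FRACTION_TABLE


def kshell_fraction(energy):
    """K-shell share of iodine photoelectric absorption, sigma_K/(sigma_K+sigma_L).

    Returns 0 below the K edge (33.18 keV), where no K vacancy is possible.
    """
    e_tab, frac = _k_fraction_table()
    e = np.asarray(energy, dtype=float)
    if np.any(e > e_tab[-1]):
        raise MaterialRangeError(
            f"K-shell fraction table ends at {e_tab[-1]:g} keV"
        )
    out = np.where(e < IODINE_K_EDGE_KEV, 0.0, np.interp(e, e_tab, frac))
    return float(out) if np.isscalar(energy) else out
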