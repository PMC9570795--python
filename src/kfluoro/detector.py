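"""Photon-counting detection in a silicon converter layer.

An escaped K photon is counted iff it interacts within the converter
thickness (sampled free path against the total silicon attenuation) *and*
that interaction is photoelectric.  By default the sampled path is compared
to the slab thickness regardless of incidence angle, exactly as the
governing recipe is written; an optional angled-path mode divides the
thickness by |cos(theta)| for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import AttenuationCurve

__all__ = ["DetectorConfig", "detect", "detection_probability"]


@dataclass(frozen=True)
class DetectorConfig:
    """Converter-layer configuration (default: 700 um silicon, 2.33 g/cm^3)."""

    material: AttenuationCurve
    thickness_cm: float = 0.070
    density_g_cm3: float = 2.33
    angled_paths: bool = False

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError("detector thickness must be > 0")


def detect(
    energies: np.ndarray,
    cfg: DetectorConfig,
    rng: np.random.Generator,
    incidence_cosines: np.ndarray | None = None,
) -> np.ndarray:
    """Monte Carlo counting decision for each photon; returns a boolean mask."""
    e = np.asarray(energies, dtype=float)
    mu = cfg.material.mu_at(e)
    mu_pe = cfg.material.pe_at(e)
    u = rng.random(e.shape)
    ks = -np.log1p(-u) / mu
    thickness = cfg.thickness_cm
    if cfg.angled_paths and incidence_cosines is not None:
        thickness = cfg.thickness_cm / np.abs(incidence_cosines)
    interacts = ks <= thickness
    photoelectric = rng.random(e.shape) <= mu_pe / mu
    return interacts & photoelectric


def detection_probability(energy, cfg: DetectorConfig):
    """Closed-form counted fraction ``(1 - exp(-mu*Th)) * mu_pe/mu``."""
    mu = cfg.material.mu_at(energy)
    mu_pe = cfg.material.pe_at(energy)
    return (1.0 - np.exp(-mu * cfg.thickness_cm)) * mu_pe / mu
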