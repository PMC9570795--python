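"""Monte Carlo core: photon transport to the contrast layer, interaction
channel sampling, K-photon emission and K-photon escape transport.

The model is deliberately minimal, mirroring its governing equations:

* Incident photons travel straight down (+z).  A free path is sampled in fat;
  photons interacting within the upper fat layer are terminated (no scatter
  transport).  The surviving remainder of the path is converted into the
  contrast layer using the *iodine* effective attenuation
  ``(mu/rho)_I * d_CA * pd_CA`` alone.
* An interaction in the layer is photoelectric with probability
  ``mu_pe/mu_total`` of iodine, K-shell with probability
  ``sigma_K/(sigma_K+sigma_L)`` above the K edge; every other channel is
  terminal and untracked.
* A K vacancy radiates Kalpha (28.46 keV) with probability
  ``xi_KL*omega_Kalpha`` or Kbeta1 (33.29 keV) with probability
  ``(1-xi_KL)*omega_Kbeta``; emission is isotropic.
* The K photon gets one sampled free path per layer: tissue attenuation
  (iodine excluded) across the remaining layer thickness, then a
  path-length conversion into fat.  It escapes ("is emitted") iff its final
  position leaves the slab through the bottom plane within the lateral
  bounds.

All functions are vectorized over photon arrays and draw randomness only
from the ``numpy`` Generator passed in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import (
    AttenuationCurve,
    FluorescenceParams,
    IODINE_K_EDGE_KEV,
    iodine_equivalent_mu,
    kshell_fraction,
)
from .phantom import Phantom

__all__ = [
    "CHANNEL_NO_INTERACTION",
    "CHANNEL_SCATTERED",
    "CHANNEL_PHOTOELECTRIC_L",
    "CHANNEL_PHOTOELECTRIC_K",
    "LINE_NONE",
    "LINE_KALPHA",
    "LINE_KBETA1",
    "advance_to_contrast_layer",
    "sample_interaction_channel",
    "sample_k_emission",
    "isotropic_directions",
    "transport_k_photon",
]

# interaction channel codes
CHANNEL_NO_INTERACTION = 0  # photon never interacted inside the contrast layer
CHANNEL_SCATTERED = 1  # Rayleigh/Compton: terminal, untracked
CHANNEL_PHOTOELECTRIC_L = 2  # L-shell vacancy: terminal, no tracked photon
CHANNEL_PHOTOELECTRIC_K = 3  # K-shell vacancy: may radiate a K photon

# emission line codes
LINE_NONE = 0
LINE_KALPHA = 1
LINE_KBETA1 = 2


def _exponential_path(rng: np.random.Generator, mu, size=None):
    """Free path -ln(R)/mu with R uniform on (0, 1]."""
    u = rng.random(size if size is not None else np.shape(mu))
    return -np.log1p(-u) / mu


def advance_to_contrast_layer(
    energies: np.ndarray,
    phantom: Phantom,
    fat: AttenuationCurve,
    iodine: AttenuationCurve,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Transport incident photons from the entrance face into the layer.

    Samples the fat free path ``S1``; photons with ``S1 <= d1`` are
    terminated.  Survivors convert the remainder ``S2 = S1 - d1`` into the
    iodine-loaded layer via the effective iodine coefficient; an interaction
    occurs at converted depth ``S2' < d2``.

    Returns ``(interacted, depth)`` where ``interacted`` is a boolean mask
    and ``depth`` holds S2' (cm, valid where ``interacted``; NaN elsewhere).
    """
    e = np.asarray(energies, dtype=float)
    mu_fat = fat.mu_at(e)
    s1 = _exponential_path(rng, mu_fat)
    reached = s1 > phantom.d1
    mu_eff = iodine_equivalent_mu(
        e,
        phantom.contrast_concentration,
        phantom.packing_density,
        iodine=iodine,
    )
    s2prime = (s1 - phantom.d1) * mu_fat / mu_eff
    interacted = reached & (s2prime < phantom.d2)
    depth = np.where(interacted, s2prime, np.nan)
    return interacted, depth


def sample_interaction_channel(
    energies: np.ndarray,
    iodine: AttenuationCurve,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the interaction channel for photons interacting in the layer.

    Channel probabilities use the iodine coefficients only: photoelectric
    with ``mu_pe/mu_total``, then K-shell with the jump-ratio fraction
    (zero below the K edge, so sub-edge photons can only scatter or produce
    untracked L vacancies).
    """
    e = np.asarray(energies, dtype=float)
    p_pe = iodine.pe_at(e) / iodine.mu_at(e)
    p_k = kshell_fraction(e)
    is_pe = rng.random(e.shape) <= p_pe
    is_k = rng.random(e.shape) <= p_k
    channel = np.full(e.shape, CHANNEL_SCATTERED, dtype=np.int8)
    channel[is_pe] = CHANNEL_PHOTOELECTRIC_L
    channel[is_pe & is_k] = CHANNEL_PHOTOELECTRIC_K
    return channel


def isotropic_directions(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit direction cosines (a, b, c) uniform over the sphere."""
    phi = 2.0 * np.pi * rng.random(n)
    c = 1.0 - 2.0 * rng.random(n)  # cos(theta)
    sin_t = np.sqrt(np.clip(1.0 - c * c, 0.0, 1.0))
    return sin_t * np.cos(phi), sin_t * np.sin(phi), c


def sample_k_emission(
    params: FluorescenceParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Radiative outcome of ``n`` K vacancies.

    Kalpha with probability ``xi_KL*omega_Kalpha``, Kbeta1 with
    ``(1-xi_KL)*omega_Kbeta``, otherwise nothing tracked (non-radiative
    relaxation).  Returns line codes; directions are sampled separately with
    :func:`isotropic_directions`.
    """
    r4 = rng.random(n)
    r5 = rng.random(n)
    r6 = rng.random(n)
    lines = np.full(n, LINE_NONE, dtype=np.int8)
    ka = (r4 <= params.xi_KL) & (r5 <= params.omega_kalpha)
    kb = (r4 > params.xi_KL) & (r6 <= params.omega_kbeta)
    lines[ka] = LINE_KALPHA
    lines[kb] = LINE_KBETA1
    return lines


def transport_k_photon(
    x0: np.ndarray,
    y0: np.ndarray,
    depth_in_layer: np.ndarray,
    abc: tuple[np.ndarray, np.ndarray, np.ndarray],
    mu_tissue: float | np.ndarray,
    mu_fat: float | np.ndarray,
    phantom: Phantom,
    rng: np.random.Generator,
) -> np.ndarray:
    """Escape transport of K photons produced inside the contrast layer.

    Production site is ``(x0, y0, d1 + depth_in_layer)``.  One free path is
    sampled against the host-tissue attenuation (iodine excluded).  If it
    carries the photon across the layer's lower boundary, the unspent path is
    converted into fat by the attenuation-coefficient ratio and the photon is
    advanced from the boundary crossing by the converted remainder.  The
    photon counts as emitted iff its final position exits through the bottom
    plane (``z > z_dimension``) within the lateral bounds; upward-going and
    laterally escaping photons are absorbed/terminated.

    Returns a boolean ``escaped`` mask.
    """
    a, b, c = abc
    s2p = np.asarray(depth_in_layer, dtype=float)
    n = s2p.size
    ks1 = _exponential_path(rng, np.broadcast_to(np.asarray(mu_tissue, float), s2p.shape).copy())

    remaining = phantom.d2 - s2p  # tissue thickness below the production site
    with np.errstate(divide="ignore", invalid="ignore"):
        geom_path = remaining / c  # slant path to the lower boundary (c > 0)
    crosses = (c > 0) & (ks1 > geom_path)

    # unspent free path at the boundary, converted for fat
    ks2 = np.where(crosses, ks1 - geom_path, 0.0)
    ks2prime = ks2 * np.asarray(mu_tissue, float) / np.asarray(mu_fat, float)

    # The photon is emitted iff the converted fat step carries it past the
    # bottom plane.  Lateral containment is evaluated where the trajectory
    # pierces that exit plane — the point at which the photon actually
    # leaves the slab — so that the bounds check rejects genuinely
    # out-of-phantom trajectories without penalizing the (arbitrary)
    # free-path overshoot beyond the exit.
    with np.errstate(divide="ignore", invalid="ignore"):
        slant_exit = (phantom.d2 - s2p + phantom.d3) / c  # site -> exit plane
    x_exit = x0 + slant_exit * a
    y_exit = y0 + slant_exit * b

    escaped = (
        crosses
        & (ks2prime * c > phantom.d3)
        & (x_exit > 0)
        & (x_exit <= phantom.x_dimension)
        & (y_exit > 0)
        & (y_exit <= phantom.y_dimension)
    )
    return escaped
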