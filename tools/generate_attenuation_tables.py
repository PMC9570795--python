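"""Regenerate the attenuation tables bundled under ``src/kfluoro/data``.

All coefficients are stored as *linear* attenuation coefficients (per cm) at
the conventional solid/standard densities recorded in
``kfluoro.materials.DENSITY_G_CM3``; air additionally carries the mass
energy-absorption coefficient (cm^2/g) used for air-kerma evaluation.

Provenance
----------
* Elemental curves (iodine, silicon, aluminum, gadolinium) and air are
  hand-entered anchor grids at standard reference magnitudes (NIST
  XCOM / Hubbell & Seltzer scale), with absorption-edge discontinuities
  represented by two closely spaced grid rows.  Between anchors the package
  interpolates, so only the anchors are stored.
* Breast-tissue curves (fat, fibrous, tumor) are a SYNTHETIC reconstruction:
  the experimental measurements the model calls for are published only in
  graphical form, so the files (suffixed ``_synthetic``) are generated from a
  smooth photoelectric + scatter parameterization pinned to widely published
  breast-tissue attenuation magnitudes (e.g. fat 0.456 /cm, fibrous
  0.802 /cm, carcinoma 0.844 /cm at 20 keV).
* The iodine K/L photoelectric split is a jump-ratio-derived table: just
  above the K edge the K-shell share is sigma_K/(sigma_K+sigma_L) with
  sigma_K the edge step of the photoelectric cross-section and sigma_L the
  L-dominated below-edge remainder; the share drifts only weakly with energy.

Run from the repository root:  python tools/generate_attenuation_tables.py
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "kfluoro" / "data"

# Conventional densities used to convert mass -> linear coefficients.
DENSITY = {
    "iodine": 4.93,
    "silicon": 2.33,
    "aluminum": 2.699,
    "gadolinium": 7.90,
    "air": 1.205e-3,
}

# ---------------------------------------------------------------------------
# Elemental anchor grids: energy (keV), mass attenuation total / photoelectric
# (cm^2/g).  K-edge of iodine at 33.18 keV and of gadolinium at ~50.24 keV are
# encoded as adjacent rows.
# ---------------------------------------------------------------------------

IODINE = [
    # E,    mu/rho tot, mu/rho pe
    (8.0, 305.0, 302.0),
    (10.0, 161.9, 159.3),
    (12.0, 95.8, 93.3),
    (15.0, 55.12, 52.9),
    (20.0, 25.43, 23.6),
    (25.0, 13.97, 12.4),
    (30.0, 8.561, 7.35),
    (33.16, 6.553, 5.50),
    (33.18, 35.82, 34.70),
    (35.0, 31.10, 30.10),
    (40.0, 22.10, 21.30),
    (45.0, 16.10, 15.40),
    (50.0, 12.32, 11.70),
    (55.0, 9.71, 9.10),
    (60.0, 7.58, 7.05),
]

SILICON = [
    (8.0, 65.00, 64.30),
    (10.0, 33.89, 33.30),
    (15.0, 10.34, 9.92),
    (20.0, 4.464, 4.13),
    (25.0, 2.435, 2.15),
    (30.0, 1.436, 1.20),
    (35.0, 0.9326, 0.740),
    (40.0, 0.7012, 0.517),
    (45.0, 0.5470, 0.365),
    (50.0, 0.4385, 0.265),
    (55.0, 0.3720, 0.200),
    (60.0, 0.3207, 0.152),
]

ALUMINUM = [
    (8.0, 50.33),
    (10.0, 26.23),
    (15.0, 7.955),
    (20.0, 3.441),
    (25.0, 1.828),
    (30.0, 1.128),
    (35.0, 0.7800),
    (40.0, 0.5685),
    (45.0, 0.4519),
    (50.0, 0.3681),
    (55.0, 0.3178),
    (60.0, 0.2778),
]

# Gadolinium anchors below the K edge follow the universal photoelectric
# shape sigma/g ~ Z^5/A * f(E/E_K) scaled from the tungsten and barium
# grids (both scalings agree to a few percent); K edge at 50.24 keV.
GADOLINIUM = [
    (8.5, 260.0),
    (10.0, 220.0),
    (15.0, 90.0),
    (20.0, 41.5),
    (25.0, 23.2),
    (30.0, 14.5),
    (35.0, 9.70),
    (40.0, 7.10),
    (45.0, 5.06),
    (50.0, 3.75),
    (50.23, 3.73),
    (50.25, 18.5),
    (55.0, 14.5),
    (60.0, 11.5),
]

# air: E, mu/rho total, mu_en/rho  (cm^2/g)
AIR = [
    (8.0, 9.93, 9.446),
    (10.0, 5.120, 4.742),
    (15.0, 1.614, 1.334),
    (20.0, 0.7779, 0.5389),
    (25.0, 0.5040, 0.2700),
    (30.0, 0.3538, 0.1537),
    (35.0, 0.2927, 0.0994),
    (40.0, 0.2485, 0.06833),
    (45.0, 0.2262, 0.05216),
    (50.0, 0.2080, 0.04098),
    (55.0, 0.1970, 0.03506),
    (60.0, 0.1875, 0.03041),
]

# Iodine K-shell share of photoelectric absorption, K vs L shells only,
# jump-ratio derived (see module docstring).  Below the K edge the package
# returns 0 by contract.
IODINE_K_FRACTION = [
    (33.18, 0.865),
    (35.0, 0.866),
    (40.0, 0.868),
    (45.0, 0.869),
    (50.0, 0.870),
    (55.0, 0.871),
    (60.0, 0.872),
]

# ---------------------------------------------------------------------------
# Breast tissues: linear attenuation (per cm) from a photoelectric power law
# plus a slowly varying scatter floor (synthetic reconstruction, see above).
# ---------------------------------------------------------------------------


def _tissue_mu(E: np.ndarray, pe20: float, sc20: float, n: float, scale: float = 1.0):
    """Linear attenuation = scale * (pe20*(20/E)^n + sc20*(E/20)^-0.13)."""
    E = np.asarray(E, dtype=float)
    return scale * (pe20 * (20.0 / E) ** n + sc20 * (E / 20.0) ** -0.13)


TISSUE_PARAMS = {
    # name: (pe20, sc20, n, scale)
    "fat": (0.285, 0.205, 3.10, 0.93),
    "fibrous": (0.575, 0.227, 3.05, 1.00),
    "tumor": (0.612, 0.232, 3.05, 1.00),
}

TISSUE_GRID = [10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30, 33, 36, 40, 45, 50, 55, 60]
# Sparse "measured" grid used for the exponential K-line extraction fits.
FIT_POINT_GRID = [14, 16, 18, 20, 22, 24, 26, 28, 30]


def _write(path: Path, header: list[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([f"{v:.6g}" if isinstance(v, float) else v for v in row])
    print(f"wrote {path}")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    _write(
        OUT / "iodine.csv",
        ["energy_keV", "mu_total_per_cm", "mu_pe_per_cm"],
        [(e, t * DENSITY["iodine"], p * DENSITY["iodine"]) for e, t, p in IODINE],
    )
    _write(
        OUT / "silicon.csv",
        ["energy_keV", "mu_total_per_cm", "mu_pe_per_cm"],
        [(e, t * DENSITY["silicon"], p * DENSITY["silicon"]) for e, t, p in SILICON],
    )
    _write(
        OUT / "aluminum.csv",
        ["energy_keV", "mu_total_per_cm"],
        [(e, t * DENSITY["aluminum"]) for e, t in ALUMINUM],
    )
    _write(
        OUT / "gadolinium.csv",
        ["energy_keV", "mu_total_per_cm"],
        [(e, t * DENSITY["gadolinium"]) for e, t in GADOLINIUM],
    )
    _write(
        OUT / "air.csv",
        ["energy_keV", "mu_total_per_cm", "mu_en_rho_cm2_g"],
        [(e, t * DENSITY["air"], en) for e, t, en in AIR],
    )
    _write(
        OUT / "iodine_kshell_fraction.csv",
        ["energy_keV", "k_shell_fraction"],
        IODINE_K_FRACTION,
    )

    for name, (pe20, sc20, n, scale) in TISSUE_PARAMS.items():
        grid = np.asarray(TISSUE_GRID, dtype=float)
        mu = _tissue_mu(grid, pe20, sc20, n, scale)
        _write(
            OUT / f"{name}_synthetic.csv",
            ["energy_keV", "mu_total_per_cm"],
            list(zip(grid.tolist(), mu.tolist())),
        )

    rows = []
    for name, (pe20, sc20, n, scale) in TISSUE_PARAMS.items():
        grid = np.asarray(FIT_POINT_GRID, dtype=float)
        mu = _tissue_mu(grid, pe20, sc20, n, scale)
        rows.extend((name, e, m) for e, m in zip(grid.tolist(), mu.tolist()))
    _write(
        OUT / "tissue_fit_points_synthetic.csv",
        ["material", "energy_keV", "mu_total_per_cm"],
        rows,
    )


if __name__ == "__main__":
    main()
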