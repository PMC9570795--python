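"""Three-layer breast phantom geometry and contrast-agent loading.

The phantom is a slab sandwich along the beam axis z: an upper fat layer
``d1``, a thin internal layer ``d2`` of fibrous or tumor tissue uniformly
loaded with iodine, and a lower fat layer ``d3`` (``d1 = d3``).  The iodine
load is a nominal concentration ``d_CA`` (g/cm^3) times a packing density
``pd_CA`` representing the tracer-distribution volume of the tissue: 0.14
for normal (fibrous) tissue and 0.56 for tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Phantom", "make_breast_phantom", "REFERENCE_ESAK_MGY"]

#: Reference entrance-air-kerma pairing by total fat thickness (cm -> mGy).
REFERENCE_ESAK_MGY = {4.0: 10.0, 8.0: 15.0}

#: Packing densities of the contrast agent per tissue type.
PACKING_DENSITY = {"fibrous": 0.14, "tumor": 0.56}

#: Nominal contrast-agent concentration (g/cm^3).
DEFAULT_CONCENTRATION = 0.300


@dataclass(frozen=True)
class Phantom:
    """Slab geometry (cm) plus contrast loading of the internal layer."""

    d1: float  # upper fat, cm
    d2: float  # internal layer, cm
    d3: float  # lower fat, cm
    internal_tissue: str  # "fibrous" or "tumor"
    contrast_concentration: float = DEFAULT_CONCENTRATION  # g/cm^3
    packing_density: float = 0.14
    x_dimension: float = 10.0  # cm
    y_dimension: float = 10.0  # cm

    def __post_init__(self) -> None:
        if self.internal_tissue not in ("fibrous", "tumor"):
            raise ValueError(f"unknown internal tissue {self.internal_tissue!r}")
        for name in ("d1", "d2", "d3", "x_dimension", "y_dimension"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.contrast_concentration <= 0:
            raise ValueError("contrast concentration must be > 0")
        if not 0 < self.packing_density <= 1:
            raise ValueError("packing density must be in (0, 1]")

    @property
    def z_dimension(self) -> float:
        """Total slab thickness, exactly d1 + d2 + d3 (cm)."""
        return self.d1 + self.d2 + self.d3

    @property
    def effective_iodine_g_cm3(self) -> float:
        """Actual iodine density in the layer: d_CA * pd_CA (g/cm^3)."""
        return self.contrast_concentration * self.packing_density


def make_breast_phantom(
    tissue: str,
    d2_mm: float,
    total_fat_cm: float,
    *,
    concentration_g_cm3: float = DEFAULT_CONCENTRATION,
    packing_density: float | None = None,
    lateral_cm: float = 10.0,
) -> Phantom:
    """Reference breast phantom with symmetric fat layers.

    ``tissue`` is ``fibrous`` or ``tumor`` (packing density 0.14 / 0.56
    unless overridden); ``d2_mm`` must lie in the modeled 0.2-2.5 mm range
    and ``total_fat_cm`` is 4 (average breast) or 8 cm (large/dense breast),
    split equally above and below the internal layer.
    """
    if tissue not in PACKING_DENSITY:
        raise ValueError(f"tissue must be one of {sorted(PACKING_DENSITY)}")
    if not 0.2 <= d2_mm <= 2.5:
        raise ValueError("internal layer thickness must be within [0.2, 2.5] mm")
    if total_fat_cm not in (4.0, 8.0):
        raise ValueError("total fat thickness must be 4 or 8 cm")
    pd = PACKING_DENSITY[tissue] if packing_density is None else packing_density
    half = total_fat_cm / 2.0
    return Phantom(
        d1=half,
        d2=d2_mm / 10.0,
        d3=half,
        internal_tissue=tissue,
        contrast_concentration=concentration_g_cm3,
        packing_density=pd,
        x_dimension=lateral_cm,
        y_dimension=lateral_cm,
    )
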