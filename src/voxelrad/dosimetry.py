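"""Air-kerma computation from attenuated per-bin fluence.

Each spectrum bin contributes

    D_i = (muen/rho)_air(E_i) * Psi_i * (100 / d_ij)^2 * f_c

where ``Psi_i = phi_att_i * E_i`` is the attenuated energy fluence,
``d_ij`` the source-to-pixel distance in cm (the fluence is normalised at
1 m = 100 cm, hence the inverse-square corrective factor) and ``f_c``
collects the unit conversions from keV/mm^2 times cm^2/g into microgray.

Unit chain: Psi [keV/mm^2] * 1.602e-16 [J/keV] * 1e6 [mm^2/m^2]
            * (muen/rho) [cm^2/g] * 0.1 [(m^2/kg)/(cm^2/g)]
            = Gy;  * 1e6 -> uGy.  Net constant: 1.602e-5 uGy per
            (keV/mm^2 * cm^2/g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialTables, load_material_tables, lookup_muen_air
from .projection import FluenceImage, Geometry

__all__ = ["DoseImage", "bin_dose", "total_dose", "F_C_UGY"]

#: uGy per (photon fluence [mm^-2] * energy [keV] * muen/rho [cm^2/g]);
#: 1.602e-19 J/eV expressed through the unit chain in the module docstring.
F_C_UGY = 1.602e-5


@dataclass
class DoseImage:
    """Per-pixel incident air kerma, uGy."""

    kerma_uGy: np.ndarray
    pitch_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kerma_uGy = np.asarray(self.kerma_uGy, dtype=np.float64)
        if self.kerma_uGy.ndim != 2:
            raise ValueError("kerma map must be 2-D")
        if not np.all(np.isfinite(self.kerma_uGy)) or np.any(self.kerma_uGy < 0):
            raise ValueError("kerma values must be finite and non-negative")
        if self.pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.kerma_uGy.shape  # type: ignore[return-value]

    def write_tiff(self, path) -> None:
        """Debug export as 32-bit float TIFF."""
        import tifffile

        tifffile.imwrite(str(path), self.kerma_uGy.astype(np.float32))


def bin_dose(
    phi_att,
    energy_keV: float,
    distance_cm,
    tables: MaterialTables | None = None,
):
    """Air kerma (uGy) contributed by one energy bin.

    ``(muen/rho)_air(E) * (phi_att * E) * (100/d)^2 * f_c`` — linear in the
    attenuated fluence; the inverse-square factor is exactly 1 at d = 100 cm.
    """
    distance_cm = np.asarray(distance_cm, dtype=float)
    if np.any(distance_cm <= 0):
        raise ValueError("source distance must be positive")
    muen = lookup_muen_air(energy_keV, tables)
    out = muen * np.asarray(phi_att, float) * energy_keV * (100.0 / distance_cm) ** 2 * F_C_UGY
    return float(out) if np.isscalar(phi_att) and distance_cm.ndim == 0 else out


def total_dose(
    fluence_image: FluenceImage,
    geometry: Geometry | None = None,
    tables: MaterialTables | None = None,
) -> DoseImage:
    """Sum the per-bin kerma over the spectrum at every pixel.

    The source distance ``d_ij`` is evaluated per pixel centre, which gives
    the natural inverse-square fall-off towards the field edges.  Exactly
    additive over any partition of the spectrum.
    """
    tables = tables or load_material_tables()
    geometry = geometry or fluence_image.geometry
    energies = fluence_image.energies_keV
    if fluence_image.phi.shape[0] != energies.size:
        raise ValueError("fluence image and spectrum bins are misaligned")
    d_cm = geometry.source_pixel_distances_mm() / 10.0
    muen = np.asarray(tables.interp("muen_over_rho_air", energies))
    # sum_i muen_i * phi_i * E_i, then the shared geometric factor
    spectral = np.tensordot(muen * energies, fluence_image.phi, axes=(0, 0))
    kerma = spectral * (100.0 / d_cm) ** 2 * F_C_UGY
    meta = {
        "kvp_label": getattr(fluence_image.spectrum, "kvp_label", None),
        "sid_cm": geometry.sid_cm,
    }
    return DoseImage(kerma, geometry.pitch_mm, meta)
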