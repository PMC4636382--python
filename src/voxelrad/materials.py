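"""HU-to-attenuation conversion and the air energy-absorption table.

The voxel model carries CT numbers (Hounsfield units).  At the CT's effective
energy of 60 keV the linear attenuation of a voxel is the affine rescaling

    mu_voxel = (HU/1000 + 1) * mu_water(60 keV)

and at any other beam energy E it is corrected by the material's relative
attenuation curve f(E) = mu(E)/mu(60 keV):

    mu(E) = mu_voxel * f(E)

The tables shipped with the package are small transcriptions of standard
reference tabulations (mass attenuation of water, cortical bone and
aluminium; mass energy-absorption of air) on a 20-150 keV grid; values
between grid points are interpolated log-log.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib.resources import as_file, files

import numpy as np

__all__ = [
    "MaterialTables",
    "load_material_tables",
    "hu_to_mu",
    "lookup_muen_air",
    "classify_hu",
    "MATERIAL_CLASSES",
    "MU_WATER_60KEV_PER_MM",
    "WATER_DENSITY_G_CM3",
]

WATER_DENSITY_G_CM3 = 1.0
BONE_DENSITY_G_CM3 = 1.92

#: material-class codes used by the per-voxel f(E) selection
MATERIAL_CLASSES = ("water", "bone")

_TABLE_NAMES = (
    "mu_over_rho_water",
    "mu_over_rho_bone",
    "mu_over_rho_aluminium",
    "muen_over_rho_air",
)


def _read_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    res = files("voxelrad").joinpath(f"data/tables/{name}.csv")
    with as_file(res) as path, open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and r[0] != "energy_keV"]
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class MaterialTables:
    """Reference physics tables with log-log interpolation.

    Attributes
    ----------
    mu_water_60keV : float
        Linear attenuation of water at 60 keV, mm^-1.
    grids : dict
        ``name -> (energies_keV, values)`` for each shipped table.
    """

    grids: dict
    mu_water_60keV: float

    def interp(self, table: str, energy_keV) -> np.ndarray | float:
        """Log-log interpolate a table; raises outside its energy range."""
        e_grid, v_grid = self.grids[table]
        e = np.asarray(energy_keV, dtype=float)
        if np.any(e < e_grid[0]) or np.any(e > e_grid[-1]):
            raise ValueError(
                f"energy outside {table} table range "
                f"[{e_grid[0]:g}, {e_grid[-1]:g}] keV"
            )
        out = np.exp(np.interp(np.log(e), np.log(e_grid), np.log(v_grid)))
        return float(out) if np.isscalar(energy_keV) else out

    def f_of_E(self, energy_keV, material_class: str = "water"):
        """Relative attenuation mu(E)/mu(60 keV) for a material class."""
        table = {
            "water": "mu_over_rho_water",
            "bone": "mu_over_rho_bone",
        }[material_class]
        return self.interp(table, energy_keV) / self.interp(table, 60.0)

    @property
    def energy_range_keV(self) -> tuple[float, float]:
        e, _ = self.grids["mu_over_rho_water"]
        return float(e[0]), float(e[-1])


_CACHED: MaterialTables | None = None


def load_material_tables() -> MaterialTables:
    """Load (and cache) the embedded reference tables."""
    global _CACHED
    if _CACHED is None:
        grids = {name: _read_table(name) for name in _TABLE_NAMES}
        e, v = grids["mu_over_rho_water"]
        mu60 = float(np.interp(60.0, e, v)) * WATER_DENSITY_G_CM3 / 10.0  # mm^-1
        _CACHED = MaterialTables(grids=grids, mu_water_60keV=mu60)
    return _CACHED


#: linear attenuation of water at 60 keV (mm^-1), from the embedded table
MU_WATER_60KEV_PER_MM = load_material_tables().mu_water_60keV


def hu_to_mu(
    hu,
    energy_keV: float,
    tables: MaterialTables | None = None,
    material_class: str = "water",
):
    """Linear attenuation coefficient (mm^-1) of a voxel at a beam energy.

    Implements ``(HU/1000 + 1) * mu_water(60 keV) * f(E)``; results for
    HU < -1000 are clamped to zero (negative attenuation is unphysical).
    Raises for energies outside the table range — no extrapolation.
    """
    tables = tables or load_material_tables()
    f = tables.f_of_E(energy_keV, material_class)
    mu = (np.asarray(hu, dtype=float) / 1000.0 + 1.0) * tables.mu_water_60keV * f
    mu = np.maximum(mu, 0.0)
    return float(mu) if np.isscalar(hu) else mu


def lookup_muen_air(energy_keV, tables: MaterialTables | None = None):
    """Mass energy-absorption coefficient of air (cm^2/g) at an energy.

    Exact at the tabulated grid points, log-log interpolated between them;
    raises for energies outside the 20-150 keV range.
    """
    tables = tables or load_material_tables()
    return tables.interp("muen_over_rho_air", energy_keV)


# HU thresholds for the optional per-voxel material classification
_HU_BONE_THRESHOLD = 300.0


def classify_hu(hu: np.ndarray) -> np.ndarray:
    """Map HU to a material-class index (0 = water-like, 1 = bone).

    Voxels above +300 HU take the bone f(E) curve; everything else
    (air, lung, soft tissue) follows water's energy dependence.
    """
    return (np.asarray(hu) > _HU_BONE_THRESHOLD).astype(np.uint8)
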