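"""Polychromatic X-ray spectra as binned photon fluence.

A :class:`Spectrum` holds the photon fluence per energy bin for one beam
quality, in the representation the simulator consumes everywhere downstream:
bin-centre energies on a uniform grid (default 5 keV wide) and fluence in
photons per mm^2 per mAs, normalised to a source distance of 1 m.

Example spectra shipped with the package are produced by
:func:`kramers_spectrum`, a deliberately simple analytic tungsten-anode model
(Kramers continuum filtered by the inherent aluminium filtration).  They are
physically plausible stand-ins, not measured spectra: every downstream
computation is agnostic to where the binned fluence came from.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "load_spectrum",
    "save_spectrum",
    "rebin_spectrum",
    "scale_fluence",
    "kramers_spectrum",
    "bundled_spectrum",
    "DEFAULT_BIN_WIDTH_KEV",
]

DEFAULT_BIN_WIDTH_KEV = 5.0

CSV_HEADER = ("energy_keV", "fluence_per_mm2_per_mAs_at_1m")


@dataclass(frozen=True)
class Spectrum:
    """Binned photon fluence for one beam quality.

    Parameters
    ----------
    kvp_label : float
        Tube potential in kV; the maximum photon energy.
    energies_keV : ndarray
        Bin-centre energies, strictly increasing, uniformly spaced at
        ``bin_width_keV`` with centres at ``(k + 1/2) * bin_width_keV``.
    fluence : ndarray
        Photon fluence per bin, photons / mm^2 / mAs at 1 m from the source.
    bin_width_keV : float
        Uniform bin width (default 5 keV).
    """

    kvp_label: float
    energies_keV: np.ndarray
    fluence: np.ndarray
    bin_width_keV: float = DEFAULT_BIN_WIDTH_KEV

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "fluence", f)
        if e.ndim != 1 or e.size == 0 or f.shape != e.shape:
            raise ValueError("energies and fluence must be matching 1-D arrays")
        if self.bin_width_keV <= 0:
            raise ValueError("bin width must be positive")
        if e.size > 1:
            d = np.diff(e)
            if np.any(d <= 0):
                raise ValueError("bin energies must be strictly increasing")
            if not np.allclose(d, self.bin_width_keV, rtol=1e-9, atol=1e-9):
                raise ValueError(
                    "bin spacing must equal the uniform bin width "
                    f"({self.bin_width_keV} keV)"
                )
        if np.any(f < 0):
            raise ValueError("fluence values must be non-negative")
        if e[-1] > self.kvp_label:
            raise ValueError(
                f"maximum bin energy {e[-1]:g} keV exceeds tube potential "
                f"{self.kvp_label:g} kV"
            )

    @property
    def n_bins(self) -> int:
        return int(self.energies_keV.size)

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())


def load_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum from its CSV representation.

    The file has a header ``energy_keV,fluence_per_mm2_per_mAs_at_1m``, one
    row per bin and an optional leading comment ``# kvp=<float>`` recording
    the tube potential.  Energies out of order are rejected, never silently
    reordered.
    """
    path = Path(path)
    kvp: float | None = None
    energies: list[float] = []
    fluence: list[float] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            first = row[0].strip()
            if first.startswith("#"):
                text = " ".join(row).lstrip("# ").strip()
                if text.lower().startswith("kvp"):
                    kvp = float(text.split("=", 1)[1])
                continue
            if first == CSV_HEADER[0]:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                e, phi = float(row[0]), float(row[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if e <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive energy {e}")
            energies.append(e)
            fluence.append(phi)
    if not energies:
        raise ValueError(f"{path}: no spectrum rows found")
    e = np.asarray(energies)
    if e.size > 1 and np.any(np.diff(e) <= 0):
        raise ValueError(f"{path}: bin energies are not strictly increasing")
    width = float(e[1] - e[0]) if e.size > 1 else DEFAULT_BIN_WIDTH_KEV
    if kvp is None:
        kvp = float(e[-1] + width / 2)
    return Spectrum(kvp, e, np.asarray(fluence), bin_width_keV=width)


def save_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum in the CSV format :func:`load_spectrum` reads."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# kvp={spectrum.kvp_label:g}\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for e, phi in zip(spectrum.energies_keV, spectrum.fluence):
            writer.writerow([f"{e:.10g}", f"{phi:.10g}"])


def rebin_spectrum(
    raw: list[tuple[float, float]] | np.ndarray,
    bin_width_keV: float = DEFAULT_BIN_WIDTH_KEV,
    kvp_label: float | None = None,
) -> Spectrum:
    """Accumulate an arbitrarily gridded spectrum into uniform bins.

    Each raw ``(energy, fluence)`` point is assigned to the bin
    ``floor(E / w)`` whose centre is ``(k + 1/2) * w``; fluence is summed, so
    the total is conserved exactly.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("raw spectrum is empty")
    arr = arr.reshape(-1, 2)
    e_raw, phi_raw = arr[:, 0], arr[:, 1]
    if np.any(e_raw <= 0):
        raise ValueError("raw energies must be positive")
    if bin_width_keV <= 0:
        raise ValueError("bin width must be positive")
    k = np.floor(e_raw / bin_width_keV).astype(int)
    k_min, k_max = int(k.min()), int(k.max())
    fluence = np.zeros(k_max - k_min + 1)
    np.add.at(fluence, k - k_min, phi_raw)
    centres = (np.arange(k_min, k_max + 1) + 0.5) * bin_width_keV
    if kvp_label is None:
        kvp_label = float(centres[-1] + bin_width_keV / 2)
    return Spectrum(kvp_label, centres, fluence, bin_width_keV=bin_width_keV)


def scale_fluence(spectrum: Spectrum, mAs: float) -> Spectrum:
    """Scale every bin's fluence by the tube current-time product (mAs).

    The stored fluence is per mAs; multiplying by the exposure's mAs yields
    the fluence actually delivered.  Strictly linear: ``scale(a)`` then
    ``scale(b)`` equals ``scale(a*b)``.
    """
    if mAs <= 0:
        raise ValueError(f"mAs must be positive, got {mAs}")
    return Spectrum(
        spectrum.kvp_label,
        spectrum.energies_keV,
        spectrum.fluence * mAs,
        bin_width_keV=spectrum.bin_width_keV,
    )


# ---------------------------------------------------------------------------
# Analytic stand-in spectra

# Nominal free-in-air kerma output per mAs at 1 m used to normalise the
# analytic spectra, approximating a general-purpose tube with ~2.5 mm Al
# inherent filtration: K(kVp) ~ 9e-3 * kVp^2 uGy/mAs (about 58 uGy at 80 kVp).
_OUTPUT_UGY_PER_MAS_COEFF = 9.0e-3
_INHERENT_FILTRATION_MM_AL = 2.5
_AL_DENSITY_G_CM3 = 2.699


def kramers_spectrum(
    kvp: float,
    bin_width_keV: float = DEFAULT_BIN_WIDTH_KEV,
    filtration_mm_al: float = _INHERENT_FILTRATION_MM_AL,
) -> Spectrum:
    """Analytic tungsten-anode bremsstrahlung spectrum.

    Kramers' law (unfiltered fluence proportional to ``(kVp - E) / E``)
    attenuated by ``filtration_mm_al`` of aluminium, binned on the uniform
    grid and normalised so that the free-in-air kerma per mAs at 1 m matches
    the nominal tube output ``9e-3 * kVp^2`` uGy/mAs.  A stand-in for
    measured or catalogue spectra; adequate because downstream physics only
    consumes the binned fluence.
    """
    # local import: materials depends on nothing here, avoid cycle at module load
    from .materials import load_material_tables

    if kvp <= 20:
        raise ValueError("tube potential must exceed 20 kV")
    tables = load_material_tables()
    n_lo = int(math.floor(20.0 / bin_width_keV)) + 1
    n_hi = int(math.ceil(kvp / bin_width_keV))
    centres = (np.arange(n_lo, n_hi) + 0.5) * bin_width_keV
    centres = centres[centres < kvp]
    rel = (kvp - centres) / centres
    mu_al_mm = (
        tables.interp("mu_over_rho_aluminium", centres) * _AL_DENSITY_G_CM3 / 10.0
    )
    rel *= np.exp(-mu_al_mm * filtration_mm_al)
    # kerma per unit fluence-shape, at d = 1 m (inverse-square factor 1)
    muen = tables.interp("muen_over_rho_air", centres)
    kerma = float(np.sum(muen * rel * centres) * 1.602e-5)
    target = _OUTPUT_UGY_PER_MAS_COEFF * kvp**2
    return Spectrum(
        float(kvp), centres, rel * (target / kerma), bin_width_keV=bin_width_keV
    )


def bundled_spectrum(kvp: int | float) -> Spectrum:
    """Load one of the spectra shipped as package data (70/80/90/102/120 kV)."""
    from importlib.resources import as_file, files

    name = f"tungsten_{int(kvp)}kv.csv"
    res = files("voxelrad").joinpath(f"data/spectra/{name}")
    if not res.is_file():
        avail = sorted(
            p.name for p in files("voxelrad").joinpath("data/spectra").iterdir()
            if p.name.endswith(".csv")
        )
        raise FileNotFoundError(f"no bundled spectrum {name}; available: {avail}")
    with as_file(res) as p:
        return load_spectrum(p)
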