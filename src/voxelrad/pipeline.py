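"""End-to-end radiograph simulation.

Stage order: project -> dose -> scatter -> grid -> noise -> response ->
quantize, with the display LUT as a final optional mapping.  The noise
sample is drawn in the dose domain (see :mod:`voxelrad.detector`), so the
response conversion is the last physical stage.

Everything is deterministic given (config, phantom, seed): the same seed
reproduces the radiograph bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detector as det_mod
from .detector import DetectorModel, add_noise, dose_to_pv, load_detector, quantize
from .dosimetry import DoseImage, total_dose
from .materials import load_material_tables
from .phantom import VoxelPhantom, read_nrrd
from .projection import Geometry, project
from .scatter_grid import apply_grid, scatter_dose
from .spectrum import Spectrum, bundled_spectrum, load_spectrum, scale_fluence

__all__ = [
    "SimulationConfig",
    "RadiographImage",
    "simulate_radiograph",
    "apply_lut",
    "simulate_flat_field",
    "resolve_phantom",
]


@dataclass
class SimulationConfig:
    """All knobs of one simulated exposure.

    ``spectrum`` is either a path to a spectrum CSV or a tube potential for
    the bundled analytic spectra.  ``lut_window`` is (centre, width) in pixel
    values.
    """

    spectrum: str | float = 80
    mAs: float = 2.0
    detector: str = "kodak_dr7500"
    sid_cm: float = 180.0
    rows: int = 128
    cols: int = 128
    pitch_mm: float | None = None  # default: the detector's pitch
    projection_angle_deg: float = 0.0
    craniocaudal_angle_deg: float = 0.0
    n_steps: int | None = None
    grid: bool = True
    scatter: bool = True
    noise: bool = True
    material_mode: str = "uniform"
    lut: str = "linear"
    lut_window: tuple[float, float] | None = None
    seed: int = 0
    detector_y_mm: float | None = None

    def __post_init__(self) -> None:
        if self.mAs <= 0:
            raise ValueError("mAs must be positive")
        if self.sid_cm <= 0:
            raise ValueError("SID must be positive")
        if self.lut not in ("linear", "sigmoid"):
            raise ValueError("lut must be 'linear' or 'sigmoid'")
        if self.lut_window is not None and self.lut_window[1] <= 0:
            raise ValueError("LUT window width must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        if "lut_window" in doc and doc["lut_window"] is not None:
            doc["lut_window"] = tuple(doc["lut_window"])
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RadiographImage:
    """Quantized pixel-value image at detector bit depth, with provenance."""

    pixel_values: np.ndarray
    pitch_mm: float
    bit_depth: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vmax = (1 << self.bit_depth) - 1
        if self.pixel_values.min() < 0 or self.pixel_values.max() > vmax:
            raise ValueError("pixel values outside the detector's integer range")

    def write_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.pixel_values.astype(np.uint16))


def _resolve_spectrum(spec: str | float, mAs: float) -> Spectrum:
    if isinstance(spec, (int, float)) or str(spec).replace(".", "", 1).isdigit():
        base = bundled_spectrum(float(spec))
    else:
        base = load_spectrum(spec)
    return scale_fluence(base, mAs)


def resolve_phantom(spec: str) -> VoxelPhantom:
    """Phantom from ``builder:<name>`` or an NRRD path.

    Builders: ``builder:slab``, ``builder:edge``, ``builder:torso`` (with
    their default parameters).
    """
    from . import phantom as ph

    if str(spec).startswith("builder:"):
        name = str(spec).split(":", 1)[1]
        builders = {
            "slab": ph.make_slab,
            "edge": ph.make_edge_phantom,
            "torso": ph.make_torso_surrogate,
        }
        if name not in builders:
            raise ValueError(f"unknown builder {name!r}; have {sorted(builders)}")
        return builders[name]()
    return read_nrrd(spec)


def simulate_radiograph(
    config: SimulationConfig,
    phantom: VoxelPhantom,
    det: DetectorModel | None = None,
) -> tuple[RadiographImage, DoseImage]:
    """Run the full pipeline; returns (noisy radiograph, noiseless dose map).

    The dose map is the final (scatter- and grid-corrected) incident air
    kerma before noise; the radiograph is its noisy, response-converted,
    quantized counterpart.  Per-stage wall times are recorded in the
    radiograph's metadata.
    """
    det = det or load_detector(config.detector)
    tables = load_material_tables()
    spectrum = _resolve_spectrum(config.spectrum, config.mAs)
    kvp = spectrum.kvp_label
    pitch = config.pitch_mm or det.pixel_pitch_mm
    geometry = Geometry(
        rows=config.rows,
        cols=config.cols,
        pitch_mm=pitch,
        sid_cm=config.sid_cm,
        projection_angle_deg=config.projection_angle_deg,
        craniocaudal_angle_deg=config.craniocaudal_angle_deg,
        n_steps=config.n_steps,
        detector_y_mm=config.detector_y_mm,
        rotation_centre_mm=tuple(
            np.asarray(phantom.origin_mm) + phantom.extent_mm / 2.0
        ),
    )
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        stage = "project"
        t0 = time.perf_counter()
        fluence = project(phantom, geometry, spectrum, tables, config.material_mode)
        timings[stage] = time.perf_counter() - t0

        stage = "dose"
        t0 = time.perf_counter()
        primary = total_dose(fluence, geometry, tables)
        timings[stage] = time.perf_counter() - t0

        stage = "scatter"
        t0 = time.perf_counter()
        if config.scatter and det.scatter_c_s:
            scatter = scatter_dose(primary, det, kvp)
        else:
            scatter = DoseImage(np.zeros_like(primary.kerma_uGy), pitch)
        timings[stage] = time.perf_counter() - t0

        stage = "grid"
        t0 = time.perf_counter()
        final = apply_grid(primary, scatter, det, kvp, grid_present=config.grid)
        timings[stage] = time.perf_counter() - t0

        stage = "noise"
        t0 = time.perf_counter()
        noisy = add_noise(final, det, kvp, config.seed) if config.noise else final
        timings[stage] = time.perf_counter() - t0

        stage = "response"
        t0 = time.perf_counter()
        pv = dose_to_pv(noisy, det, kvp)
        image = quantize(pv, det.bit_depth)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"simulation failed in stage '{stage}': {exc}") from exc

    meta = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "detector": det.name,
        "kvp": kvp,
        "seed": config.seed,
        "stage_seconds": {k: round(v, 4) for k, v in timings.items()},
    }
    return RadiographImage(image, pitch, det.bit_depth, meta), final


def apply_lut(
    pv_image: np.ndarray,
    lut_kind: str = "linear",
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Display mapping of pixel values to grey levels in [0, 255] (float).

    Linear: affine ramp across the window, clamped.  Sigmoid: logistic
    centred at the window centre whose slope spans the window width (the
    centre maps to mid-grey exactly).  Monotone non-decreasing in the input.
    """
    pv = np.asarray(pv_image, dtype=float)
    if window is None:
        lo, hi = float(pv.min()), float(pv.max())
        window = ((lo + hi) / 2.0, max(hi - lo, 1.0))
    centre, width = window
    if width <= 0:
        raise ValueError("window width must be positive")
    if lut_kind == "linear":
        out = np.clip((pv - (centre - width / 2.0)) / width, 0.0, 1.0)
    elif lut_kind == "sigmoid":
        out = 1.0 / (1.0 + np.exp(-4.0 * (pv - centre) / width))
    else:
        raise ValueError(f"unknown LUT kind {lut_kind!r}")
    return out * 255.0


def simulate_flat_field(
    dose_uGy: float,
    rows: int,
    cols: int,
    det: DetectorModel,
    kvp: float,
    global_seed: int = 0,
    image_id: int = 0,
) -> DoseImage:
    """Homogeneous exposure at a given incident air kerma, with noise.

    The flat-field equivalent of a direct detector exposure: every pixel
    receives ``dose_uGy`` and the detector's dose-dependent noise.  The
    workhorse of the variance closed-loop calibration.
    """
    if dose_uGy < 0:
        raise ValueError("dose must be non-negative")
    flat = DoseImage(np.full((rows, cols), float(dose_uGy)), det.pixel_pitch_mm)
    return add_noise(flat, det, kvp, global_seed, image_id)
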