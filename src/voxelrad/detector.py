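"""Detector response, dose-dependent noise, and the per-pixel hybrid RNG.

Response
--------
Digital radiography detectors without projection-specific processing follow a
logarithmic response, ``PV = b + a * ln(K_air)``: one global gain ``a`` per
detector and a per-beam-quality offset ``b`` (the beam label is the tube
potential in kV).

Noise
-----
The flat-field variance decomposes into Poissonian, multiplicative and
additive components, ``sigma^2 = alpha*D + beta*D^2 + gamma`` with the
incident air kerma D in uGy.  The noise sample is added to the *dose* image
before response conversion, so the pixel-value noise of a log-responding
detector inherits the physically expected behaviour (PV noise ~ a*sigma/D,
SNR rising with exposure).  ``alpha`` and ``beta`` are anchored per detector
at 80 and 120 kV and interpolated linearly in kV elsewhere; ``gamma``
defaults to 0 (the additive term is typically below 1% of total noise).

Random numbers
--------------
Per-pixel independent streams from a hybrid generator: three Tausworthe
shift-register components combined (XOR) with a linear congruential
generator, mapped through Box-Muller to standard normals.  Each pixel's
four component states come from a multiplicative (Park-Miller-style)
scramble of a unique linear pixel index followed by an avalanche mix, so
adjacent pixels get uncorrelated streams.  The constants are collected in
one table below; the requirement is statistical quality and determinism,
not bit-compatibility with any particular implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import as_file, files
from pathlib import Path

import numpy as np
import yaml

from .dosimetry import DoseImage

__all__ = [
    "RngState",
    "taus_lcg_uniform",
    "box_muller",
    "pixel_seed",
    "image_rng",
    "standard_normal_field",
    "DetectorModel",
    "load_detector",
    "list_detectors",
    "dose_to_pv",
    "pv_to_dose",
    "add_noise",
    "quantize",
    "DOSE_FLOOR_UGY",
]

# ---------------------------------------------------------------------------
# RNG constant table (the single authoritative copy)
#
#   Tausworthe components (S1, S2, S3, mask):  classical three-component set
#   LCG component:        z4 <- 1664525 * z4 + 1013904223   (mod 2^32)
#   Seed scramble:        Park-Miller multiplier 16807 on the linear pixel
#                         index, golden-ratio Weyl constants for image id and
#                         global seed, then a 64-bit avalanche finalizer
#                         (multiply-xorshift rounds).
_TAUS_PARAMS = (
    (13, 19, 12, np.uint32(4294967294)),
    (2, 25, 4, np.uint32(4294967288)),
    (3, 11, 17, np.uint32(4294967280)),
)
_TAUS_MIN = (np.uint32(2), np.uint32(8), np.uint32(16))
_LCG_A = np.uint32(1664525)
_LCG_C = np.uint32(1013904223)
_PARK_MILLER = np.uint64(16807)
_WEYL_IMAGE = np.uint64(0x9E3779B97F4A7C15)
_WEYL_SEED = np.uint64(0xBF58476D1CE4E5B9)
_MIX_M1 = np.uint64(0xFF51AFD7ED558CCD)
_MIX_M2 = np.uint64(0xC4CEB9FE1A85EC53)

_U32_NORM = float(2.0**-32)

#: air-kerma floor applied before ln() in the response conversion, uGy;
#: far below any clinically simulated dose.
DOSE_FLOOR_UGY = 1e-4


def _avalanche64(x: np.ndarray) -> np.ndarray:
    """64-bit multiply-xorshift finalizer (full avalanche)."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(33)
    x *= _MIX_M1
    x ^= x >> np.uint64(33)
    x *= _MIX_M2
    x ^= x >> np.uint64(33)
    return x


@dataclass
class RngState:
    """State of the combined Tausworthe + LCG generator.

    Components may be scalars or arrays of identical shape (one independent
    stream per element).  State advance is deterministic.
    """

    z1: np.ndarray
    z2: np.ndarray
    z3: np.ndarray
    z4: np.ndarray

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, dtype=np.uint32)
        self.z2 = np.asarray(self.z2, dtype=np.uint32)
        self.z3 = np.asarray(self.z3, dtype=np.uint32)
        self.z4 = np.asarray(self.z4, dtype=np.uint32)
        # Tausworthe components have minimum-seed constraints (low bits are
        # annihilated by the mask); correct deterministically at init.
        for name, zmin in zip(("z1", "z2", "z3"), _TAUS_MIN):
            z = getattr(self, name)
            setattr(self, name, np.where(z < np.uint32(128), z + np.uint32(128), z))

    @property
    def shape(self):
        return self.z1.shape

    def uniform(self) -> np.ndarray:
        """Advance every stream one step; return uniforms strictly in (0, 1)."""
        with np.errstate(over="ignore"):
            for name, (s1, s2, s3, mask) in zip(("z1", "z2", "z3"), _TAUS_PARAMS):
                z = getattr(self, name)
                b = ((z << np.uint32(s1)) ^ z) >> np.uint32(s2)
                setattr(self, name, ((z & mask) << np.uint32(s3)) ^ b)
            self.z4 = _LCG_A * self.z4 + _LCG_C
        combined = self.z1 ^ self.z2 ^ self.z3 ^ self.z4
        # +0.5 keeps the output strictly inside (0, 1): ln(u) stays finite
        return (combined.astype(np.float64) + 0.5) * _U32_NORM


def taus_lcg_uniform(state: RngState) -> tuple[np.ndarray, RngState]:
    """One combined-generator draw; returns (value in (0,1), advanced state)."""
    return state.uniform(), state


def box_muller(u1, u2):
    """Map two uniforms in (0,1) to two independent standard normals.

    ``x1 = sqrt(-2 ln u1) cos(2 pi u2)``, ``x2 = sqrt(-2 ln u1) sin(2 pi u2)``;
    the radius identity ``x1^2 + x2^2 = -2 ln u1`` holds exactly.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.any(u1 <= 0) or np.any(u1 > 1) or np.any(u2 < 0) or np.any(u2 > 1):
        raise ValueError("Box-Muller inputs must lie in (0, 1]")
    r = np.sqrt(-2.0 * np.log(u1))
    return r * np.cos(2.0 * np.pi * u2), r * np.sin(2.0 * np.pi * u2)


# images narrower than 2^21 columns keep the linear pixel index unique
_INDEX_STRIDE = np.uint64(1) << np.uint64(21)


def pixel_seed(row, col, image_id: int = 0, global_seed: int = 0) -> RngState:
    """Independent RNG state for a pixel (or arrays of pixels).

    Distinct (row, col, image_id, global_seed) combinations yield distinct,
    uncorrelated streams; identical ones reproduce bit-exactly.
    """
    row = np.asarray(row, dtype=np.uint64)
    col = np.asarray(col, dtype=np.uint64)
    idx = row * _INDEX_STRIDE + col
    with np.errstate(over="ignore"):
        base = (
            (idx + np.uint64(1)) * _PARK_MILLER
            + np.uint64(image_id % (1 << 32)) * _WEYL_IMAGE
            + np.uint64(global_seed % (1 << 32)) * _WEYL_SEED
        )
        h1 = _avalanche64(base)
        h2 = _avalanche64(base + _WEYL_IMAGE)
    lo = np.uint64(0xFFFFFFFF)
    return RngState(
        (h1 & lo).astype(np.uint32),
        (h1 >> np.uint64(32)).astype(np.uint32),
        (h2 & lo).astype(np.uint32),
        (h2 >> np.uint64(32)).astype(np.uint32),
    )


def image_rng(
    rows: int,
    cols: int,
    image_id: int = 0,
    global_seed: int = 0,
    index_mode: str = "pixel",
) -> RngState:
    """RNG states for a full detector grid, one stream per pixel.

    ``index_mode="pixel"`` (default) seeds from the unique (row, col) pair.
    ``index_mode="row"`` deliberately collapses the index to the row number
    alone — the classic wrong choice in which streams collide and the noise
    degenerates into correlated streaks; kept for demonstrating and testing
    that pathology.
    """
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if index_mode == "pixel":
        return pixel_seed(r, c, image_id, global_seed)
    if index_mode == "row":
        return pixel_seed(r, np.zeros_like(c), image_id, global_seed)
    raise ValueError(f"unknown index_mode {index_mode!r}")


def standard_normal_field(
    rows: int,
    cols: int,
    image_id: int = 0,
    global_seed: int = 0,
    index_mode: str = "pixel",
) -> np.ndarray:
    """One standard-normal sample per pixel from per-pixel streams."""
    state = image_rng(rows, cols, image_id, global_seed, index_mode)
    u1 = state.uniform()
    u2 = state.uniform()
    x1, _ = box_muller(u1, u2)
    return x1


# ---------------------------------------------------------------------------
# Detector models


def _interp_map(mapping: dict, kvp: float) -> float:
    """Linear interpolation/extrapolation in kV over a {kV: value} map."""
    if not mapping:
        raise KeyError("empty parameter map")
    keys = np.array(sorted(float(k) for k in mapping))
    vals = np.array([float(mapping[k]) for k in sorted(mapping, key=float)])
    if kvp in keys:
        return float(vals[np.searchsorted(keys, kvp)])
    if keys.size == 1:
        return float(vals[0])
    # linear with end-segment extrapolation
    i = int(np.clip(np.searchsorted(keys, kvp) - 1, 0, keys.size - 2))
    t = (kvp - keys[i]) / (keys[i + 1] - keys[i])
    return float(vals[i] + t * (vals[i + 1] - vals[i]))


@dataclass
class DetectorModel:
    """Parameters of one named detector.

    ``response_b``, ``noise``, ``grid_*`` and ``scatter_*`` are keyed by tube
    potential (kV) and interpolated linearly between anchors.  The noise
    triplets are the measured flat-field decomposition coefficients; the
    response, grid and scatter values shipped with the presets are documented
    plausible defaults (manufacturer calibrations are not public) and are
    meant to be overridden from a YAML model file when real calibrations
    exist.
    """

    name: str
    pixel_pitch_mm: float
    bit_depth: int
    response_a: float
    response_b: dict
    noise: dict  # kV -> {"alpha","beta","gamma"}
    grid_f_p: dict = field(default_factory=dict)
    grid_f_s: dict = field(default_factory=dict)
    scatter_sigma_mm: dict = field(default_factory=dict)
    scatter_c_s: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.response_a == 0:
            raise ValueError("response gain a must be non-zero")
        if self.bit_depth < 1:
            raise ValueError("bit depth must be >= 1")
        for kv, coeffs in self.noise.items():
            a, b, g = coeffs["alpha"], coeffs["beta"], coeffs.get("gamma", 0.0)
            if a < 0 or b < 0 or g < 0:
                raise ValueError(f"noise coefficients at {kv} kV must be >= 0")
        for m in (self.grid_f_p, self.grid_f_s):
            for kv, v in m.items():
                if not 0 < v <= 1:
                    raise ValueError(f"grid factor at {kv} kV must be in (0, 1]")

    # --- per-beam-quality lookups -----------------------------------------
    def b_of(self, kvp: float) -> float:
        if not self.response_b:
            raise KeyError(f"{self.name}: no response offsets configured")
        return _interp_map(self.response_b, float(kvp))

    def noise_coeffs(self, kvp: float) -> tuple[float, float, float]:
        if not self.noise:
            raise KeyError(
                f"{self.name}: no noise coefficients; available labels: []"
            )
        alpha = _interp_map({k: self.noise[k]["alpha"] for k in self.noise}, kvp)
        beta = _interp_map({k: self.noise[k]["beta"] for k in self.noise}, kvp)
        gamma = _interp_map(
            {k: self.noise[k].get("gamma", 0.0) for k in self.noise}, kvp
        )
        return alpha, beta, gamma

    def f_p(self, kvp: float) -> float:
        return _interp_map(self.grid_f_p, float(kvp))

    def f_s(self, kvp: float) -> float:
        return _interp_map(self.grid_f_s, float(kvp))

    def sigma_mm(self, kvp: float) -> float:
        return _interp_map(self.scatter_sigma_mm, float(kvp))

    def c_s(self, kvp: float) -> float:
        return _interp_map(self.scatter_c_s, float(kvp))

    # --- serialization ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            pixel_pitch_mm=float(doc["pixel_pitch_mm"]),
            bit_depth=int(doc["bit_depth"]),
            response_a=float(doc["response"]["a"]),
            response_b={float(k): float(v) for k, v in doc["response"]["b"].items()},
            noise={
                float(k): {kk: float(vv) for kk, vv in v.items()}
                for k, v in doc["noise"].items()
            },
            grid_f_p={float(k): float(v) for k, v in doc.get("grid", {}).get("f_p", {}).items()},
            grid_f_s={float(k): float(v) for k, v in doc.get("grid", {}).get("f_s", {}).items()},
            scatter_sigma_mm={
                float(k): float(v)
                for k, v in doc.get("scatter", {}).get("sigma_mm", {}).items()
            },
            scatter_c_s={
                float(k): float(v)
                for k, v in doc.get("scatter", {}).get("c_s", {}).items()
            },
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "bit_depth": self.bit_depth,
            "response": {"a": self.response_a, "b": dict(self.response_b)},
            "noise": {k: dict(v) for k, v in self.noise.items()},
            "grid": {"f_p": dict(self.grid_f_p), "f_s": dict(self.grid_f_s)},
            "scatter": {
                "sigma_mm": dict(self.scatter_sigma_mm),
                "c_s": dict(self.scatter_c_s),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


_PRESET_FILES = {
    "philips_digitaldiagnost": "philips_digitaldiagnost.yaml",
    "kodak_dr7500": "kodak_dr7500.yaml",
    "kodak_cr900": "kodak_cr900.yaml",
}


def list_detectors() -> list[str]:
    return sorted(_PRESET_FILES)


def load_detector(name_or_path: str | Path) -> DetectorModel:
    """Load a preset by name, or any detector model YAML by path."""
    key = str(name_or_path).lower().replace(" ", "_").replace(".", "")
    if key in _PRESET_FILES:
        res = files("voxelrad").joinpath(f"data/detectors/{_PRESET_FILES[key]}")
        with as_file(res) as p:
            return DetectorModel.from_yaml(p)
    path = Path(name_or_path)
    if path.is_file():
        return DetectorModel.from_yaml(path)
    raise FileNotFoundError(
        f"unknown detector {name_or_path!r}; presets: {list_detectors()}"
    )


# ---------------------------------------------------------------------------
# Response and noise


def dose_to_pv(dose: DoseImage, det: DetectorModel, beam_label: float) -> np.ndarray:
    """Convert air kerma to real-valued pixel values, PV = b + a ln(K).

    Doses at or below ``DOSE_FLOOR_UGY`` map to the floor's PV, keeping the
    logarithm finite.
    """
    b = det.b_of(beam_label)
    k = np.maximum(dose.kerma_uGy, DOSE_FLOOR_UGY)
    return b + det.response_a * np.log(k)


def pv_to_dose(pv: np.ndarray, det: DetectorModel, beam_label: float) -> np.ndarray:
    """Invert the response: K = exp((PV - b) / a)."""
    return np.exp((np.asarray(pv, float) - det.b_of(beam_label)) / det.response_a)


def add_noise(
    dose: DoseImage,
    det: DetectorModel,
    beam_label: float,
    global_seed: int = 0,
    image_id: int = 0,
) -> DoseImage:
    """Add the dose-dependent noise sample to a dose image.

    Per pixel, adds ``x * sigma(D)`` with ``x`` one Box-Muller standard
    normal from that pixel's stream and ``sigma^2 = alpha*D + beta*D^2 +
    gamma`` (uGy^2).  With all three coefficients zero the image is returned
    unchanged.  Results are clamped at zero (kerma cannot be negative).
    """
    alpha, beta, gamma = det.noise_coeffs(beam_label)
    d = dose.kerma_uGy
    if alpha == 0 and beta == 0 and gamma == 0:
        return DoseImage(d.copy(), dose.pitch_mm, dict(dose.meta))
    sigma = np.sqrt(alpha * d + beta * d * d + gamma)
    x = standard_normal_field(d.shape[0], d.shape[1], image_id, global_seed)
    noisy = np.maximum(d + x * sigma, 0.0)
    meta = dict(dose.meta)
    meta.update({"noise_seed": int(global_seed), "image_id": int(image_id)})
    return DoseImage(noisy, dose.pitch_mm, meta)


def quantize(pv: np.ndarray, bit_depth: int) -> np.ndarray:
    """Round and clip pixel values to the detector's integer range."""
    vmax = (1 << bit_depth) - 1
    out = np.clip(np.rint(np.asarray(pv, float)), 0, vmax)
    return out.astype(np.uint16 if bit_depth <= 16 else np.uint32)
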