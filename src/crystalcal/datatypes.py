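"""Core containers shared across the calibration pipeline.

Axis convention: arrays are ordered (Z, Y, X) with Z the optical axis
(slowest-varying); physical coordinates are nanometres; voxel centres sit
at ``index * voxel + origin``.  The crystal growth direction is Y unless a
container says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "UFloat",
    "LatticeSpec",
    "ParticleSet",
    "OpticsModel",
    "NoiseSpec",
    "ImageStack",
    "LateralResult",
    "AxialResult",
    "ScalingMeasurement",
    "BeadCandidate",
    "PSFVolume",
    "LobeBalance",
    "OrderParameters",
    "AnisotropyReport",
]


@dataclass(frozen=True)
class UFloat:
    """A value with a one-sigma uncertainty, propagated to first order."""

    value: float
    sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def __mul__(self, other: "UFloat | float") -> "UFloat":
        if isinstance(other, UFloat):
            v = self.value * other.value
            sd = math.hypot(other.value * self.sd, self.value * other.sd)
            return UFloat(v, sd)
        return UFloat(self.value * other, abs(other) * self.sd)

    __rmul__ = __mul__

    def __truediv__(self, other: "UFloat | float") -> "UFloat":
        if isinstance(other, UFloat):
            if other.value == 0:
                raise ZeroDivisionError("division by zero-valued UFloat")
            v = self.value / other.value
            sd = abs(v) * math.hypot(
                self.sd / self.value if self.value else 0.0,
                other.sd / other.value,
            )
            return UFloat(v, sd)
        return UFloat(self.value / other, self.sd / abs(other))

    def __add__(self, other: "UFloat | float") -> "UFloat":
        if isinstance(other, UFloat):
            return UFloat(self.value + other.value, math.hypot(self.sd, other.sd))
        return UFloat(self.value + other, self.sd)

    __radd__ = __add__

    def __sub__(self, other: "UFloat | float") -> "UFloat":
        if isinstance(other, UFloat):
            return UFloat(self.value - other.value, math.hypot(self.sd, other.sd))
        return UFloat(self.value - other, self.sd)

    def as_dict(self) -> dict:
        return {"value": self.value, "sd": self.sd}

    def __format__(self, spec: str) -> str:
        return f"{self.value:{spec}} ± {self.sd:{spec}}"


# ---------------------------------------------------------------------------
# Synthetic-sample specifications


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a close-packed colloidal crystal grown by vertical deposition.

    Parameters
    ----------
    nn_growth:
        Nearest-neighbour centre distance along the growth axis, nm.  For the
        physical test sample this is the effective particle diameter
        (particles touch along the drying direction).
    compression:
        Growth/oblique nearest-neighbour distance ratio ``c <= 1``.  The
        drying front compresses in-plane bonds along the growth direction;
        c = 0.96 reproduces the ~4 % anisotropy seen in such crystals.
        Internally realised as an affine scaling of the growth-axis
        coordinates of an ideal hexagonal layer by ``c * sqrt(3 / (4 - c^2))``.
    n_layers / layers_extent:
        Number of (111) layers and particles per side within each layer.
    stacking:
        Explicit stacking sequence over {A, B, C}; when None the sequence is
        generated by cycling ABC with the cycle direction reversed per layer
        with probability ``fault_prob`` (random hexagonal close packing).
    """

    nn_growth: float = 538.0
    compression: float = 0.96
    n_layers: int = 8
    layers_extent: int = 16
    stacking: str | None = None
    fault_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.nn_growth <= 0:
            raise ValueError("nn_growth must be > 0")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")
        if self.n_layers <= 0 or self.layers_extent <= 0:
            raise ValueError("n_layers and layers_extent must be positive")
        if not 0 <= self.fault_prob <= 1:
            raise ValueError("fault_prob must be in [0, 1]")
        if self.stacking is not None:
            letters = set(self.stacking)
            if not letters <= {"A", "B", "C"}:
                raise ValueError("stacking letters must be A, B or C")
            for a, b in zip(self.stacking, self.stacking[1:]):
                if a == b:
                    raise ValueError(
                        "stacking may not repeat a letter in consecutive layers"
                    )

    @property
    def affine_factor(self) -> float:
        """Affine growth-axis scale factor realising the NN-distance ratio."""
        c = self.compression
        return c * math.sqrt(3.0 / (4.0 - c * c))

    @property
    def layer_spacing(self) -> float:
        """(111) interlayer spacing, sqrt(6)/3 x nn_growth, nm."""
        return math.sqrt(6.0) / 3.0 * self.nn_growth


CORE_DIAMETERS_NM = {"fluorescent": 45.0, "gold": 80.0, "none": 0.0}


@dataclass
class ParticleSet:
    """Particle centres (nm, (z, y, x)) with per-particle core metadata."""

    centers: np.ndarray  # (N, 3) float, (z, y, x) nm
    core_type: np.ndarray  # (N,) str labels in {fluorescent, gold, none}
    core_diameter: np.ndarray  # (N,) nm
    layer_index: np.ndarray | None = None  # (N,) int, None for non-crystal sets
    growth_axis: str = "y"
    diameter: np.ndarray | None = None  # (N,) total sphere diameter, nm
    stacking: str | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("particle centres must be finite")
        self.core_type = np.asarray(self.core_type, dtype=object)
        self.core_diameter = np.asarray(self.core_diameter, dtype=float)
        labelled = self.core_type != "none"
        if np.any(self.core_diameter[labelled] <= 0):
            raise ValueError("core_diameter must be > 0 for labelled cores")
        if self.layer_index is not None:
            self.layer_index = np.asarray(self.layer_index, dtype=int)

    def __len__(self) -> int:
        return self.centers.shape[0]

    def select(self, mask: np.ndarray) -> "ParticleSet":
        return ParticleSet(
            centers=self.centers[mask],
            core_type=self.core_type[mask],
            core_diameter=self.core_diameter[mask],
            layer_index=None if self.layer_index is None else self.layer_index[mask],
            growth_axis=self.growth_axis,
            diameter=None if self.diameter is None else self.diameter[mask],
            stacking=self.stacking,
        )


PSFMode = Literal[
    "confocal",
    "sted2d_eff",
    "stedz_eff",
    "excitation_refl",
    "depletion2d_refl",
    "depletionz_refl",
]

#: modes whose kernels image the fluorescent cores
FLUORESCENCE_MODES = {"confocal", "sted2d_eff", "stedz_eff"}
#: modes whose kernels image the gold cores in reflection
REFLECTION_MODES = {"excitation_refl", "depletion2d_refl", "depletionz_refl"}


@dataclass(frozen=True)
class OpticsModel:
    """Phenomenological optical model of one imaging mode.

    ``axial_scaling`` is the refractive-index-mismatch factor s mapping
    apparent (stage) axial distances to true distances: true = apparent * s.
    Rendering therefore stretches axial coordinates by 1/s before
    rasterisation; s = 1 means matched media.
    """

    mode: PSFMode = "confocal"
    fwhm_lateral: float = 230.0
    fwhm_axial: float = 600.0
    lobe_sep: float = 700.0
    lobe_asymmetry: float = 1.0
    voxel: tuple[float, float, float] = (100.0, 45.0, 45.0)  # (dz, dy, dx) nm
    axial_scaling: float = 1.0

    def __post_init__(self):
        if self.fwhm_lateral <= 0 or self.fwhm_axial <= 0:
            raise ValueError("FWHMs must be > 0")
        if not 0 < self.axial_scaling <= 1.2:
            raise ValueError("axial_scaling must be in (0, 1.2]")
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel sizes must be > 0")
        if self.lobe_asymmetry <= 0:
            raise ValueError("lobe_asymmetry must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Shot + read noise model: Poisson on scaled intensity, then Gaussian."""

    photons_per_unit: float = 0.0  # 0 disables shot noise
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.photons_per_unit < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class ImageStack:
    """3D intensity volume, axis order (Z, Y, X), with voxel sizes in nm."""

    data: np.ndarray
    voxel: tuple[float, float, float]  # (dz, dy, dx) nm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3D (Z, Y, X)")
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel sizes must be > 0")
        self.voxel = tuple(float(v) for v in self.voxel)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def z_positions(self) -> np.ndarray:
        """Physical (apparent) Z position of each plane centre, nm."""
        return self.origin[0] + np.arange(self.data.shape[0]) * self.voxel[0]


# ---------------------------------------------------------------------------
# Result records


@dataclass
class LateralResult:
    delta_x: UFloat
    delta_y: UFloat
    sigma_eff: UFloat
    growth_axis: str
    nm_per_px: tuple[float, float]
    slices_used: list[float]
    per_slice: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "delta_x_nm": self.delta_x.as_dict(),
            "delta_y_nm": self.delta_y.as_dict(),
            "sigma_eff_nm": self.sigma_eff.as_dict(),
            "growth_axis": self.growth_axis,
            "nm_per_px": list(self.nm_per_px),
            "slices_used_um": list(self.slices_used),
            "per_slice": self.per_slice,
        }


@dataclass
class AxialResult:
    apparent_spacing: UFloat
    r_squared: float
    scaling_factor: UFloat
    corrected_spacing: UFloat
    theoretical_d111: UFloat | None
    n_peaks: int

    def as_dict(self) -> dict:
        return {
            "apparent_spacing_nm": self.apparent_spacing.as_dict(),
            "r_squared": self.r_squared,
            "scaling_factor": self.scaling_factor.as_dict(),
            "corrected_d111_nm": self.corrected_spacing.as_dict(),
            "theoretical_d111_nm": (
                None if self.theoretical_d111 is None else self.theoretical_d111.as_dict()
            ),
            "n_peaks": self.n_peaks,
        }


@dataclass
class ScalingMeasurement:
    h_true: UFloat
    h_apparent_empty: UFloat
    h_apparent_filled: UFloat
    miscalibration: UFloat
    h_corrected: UFloat
    s: UFloat
    n_medium: float | None = None

    def as_dict(self) -> dict:
        return {
            "h_true_um": self.h_true.as_dict(),
            "h_apparent_empty_um": self.h_apparent_empty.as_dict(),
            "h_apparent_filled_um": self.h_apparent_filled.as_dict(),
            "miscalibration": self.miscalibration.as_dict(),
            "h_corrected_um": self.h_corrected.as_dict(),
            "scaling_factor": self.s.as_dict(),
            "scaling_factor_display": f"{self.s.value:.3f}",
            "n_medium": self.n_medium,
            "note": "s is a single depth-independent multiplicative factor",
        }


@dataclass(frozen=True)
class BeadCandidate:
    position: tuple[float, float, float]  # (z, y, x) nm, sub-voxel
    peak_intensity: float
    min_neighbour_separation: float
    border_margin_ok: bool


@dataclass
class PSFVolume:
    data: np.ndarray
    voxel: tuple[float, float, float]
    fwhm: tuple[float, float, float]  # (z, y, x) nm
    n_beads: int
    depth: float | None = None  # µm from the cover glass
    mode: str | None = None

    def as_dict(self) -> dict:
        return {
            "fwhm_nm": {"z": self.fwhm[0], "y": self.fwhm[1], "x": self.fwhm[2]},
            "voxel_nm": list(self.voxel),
            "n_beads": self.n_beads,
            "depth_um": self.depth,
            "mode": self.mode,
        }


@dataclass(frozen=True)
class LobeBalance:
    ratio: float  # top-lobe peak / bottom-lobe peak
    lobe_positions: tuple[float, float]  # (z_top, z_bottom) nm

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("lobe ratio must be > 0")


@dataclass
class OrderParameters:
    q4: np.ndarray  # neighbourhood-averaged q4 per particle
    q6: np.ndarray
    phase_label: np.ndarray  # {"FCC", "HCP", "other"}
    neighbour_count: np.ndarray


@dataclass
class AnisotropyReport:
    nn_growth_mean: float
    nn_oblique_mean: float
    compression_pct: float
    layer_spacing: float | None = None
    layer_r_squared: float | None = None

    def as_dict(self) -> dict:
        return {
            "nn_growth_mean_nm": self.nn_growth_mean,
            "nn_oblique_mean_nm": self.nn_oblique_mean,
            "compression_pct": self.compression_pct,
            "layer_spacing_nm": self.layer_spacing,
            "layer_r_squared": self.layer_r_squared,
        }
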