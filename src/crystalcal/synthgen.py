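"""Synthetic test-sample generator.

Emulates the physical calibration sample: an FCC colloidal crystal of
core-shell silica beads (fluorescent or gold cores) grown by vertical
deposition with its (111) plane on the coverslip, a sparse-probe sample of
beads in an unlabeled scaffold, phenomenological confocal / STED optical
kernels, rendered 3D image stacks with shot noise, and Fabry-Perot fringe
spectra for interferometric cell-height measurement.

Every stochastic operation takes an explicit seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.ndimage import shift as ndi_shift
from scipy.signal import fftconvolve

from .datatypes import (
    CORE_DIAMETERS_NM,
    FLUORESCENCE_MODES,
    REFLECTION_MODES,
    ImageStack,
    LatticeSpec,
    NoiseSpec,
    OpticsModel,
    ParticleSet,
)

__all__ = [
    "build_crystal",
    "generate_stacking",
    "assign_cores",
    "psf_kernel",
    "render_volume",
    "sparse_sample",
    "fringe_spectrum",
]

_GAUSS_K = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = _GAUSS_K * sigma


def generate_stacking(n_layers: int, fault_prob: float, seed: int) -> str:
    """Random hexagonal close packing: cycle ABC, reversing the cycle
    direction independently per layer with probability ``fault_prob``."""
    rng = np.random.default_rng(seed)
    letters = "ABC"
    idx = 0
    direction = 1
    out = ["A"]
    for _ in range(1, n_layers):
        if fault_prob > 0 and rng.random() < fault_prob:
            direction = -direction
        idx = (idx + direction) % 3
        out.append(letters[idx])
    return "".join(out)


def build_crystal(spec: LatticeSpec) -> ParticleSet:
    """Build hexagonal (111) layers stacked along Z.

    Within a layer the ideal hexagonal lattice (NN distance
    ``nn_growth / compression``) has one nearest-neighbour direction along
    the growth axis (Y); growth-axis coordinates are then scaled by the
    affine factor so that the growth-axis NN distance is exactly
    ``nn_growth`` and the growth/oblique NN ratio is ``compression``.
    Layers are stacked at spacing sqrt(6)/3 * nn_growth following the ABC
    offsets of close packing.
    """
    stacking = spec.stacking or generate_stacking(
        spec.n_layers, spec.fault_prob, spec.seed
    )
    if len(stacking) < spec.n_layers:
        raise ValueError("stacking shorter than n_layers")
    stacking = stacking[: spec.n_layers]

    ca = spec.affine_factor
    a = spec.nn_growth / ca  # ideal in-plane NN distance before compression
    d = spec.layer_spacing

    # in-plane lattice vectors (x, y); a2 along the growth axis
    a1 = np.array([a * math.sqrt(3.0) / 2.0, a / 2.0])
    a2 = np.array([0.0, a])
    offsets = {
        "A": np.array([0.0, 0.0]),
        "B": np.array([a * math.sqrt(3.0) / 6.0, a / 2.0]),
        "C": np.array([a * math.sqrt(3.0) / 3.0, 0.0]),
    }

    n = spec.layers_extent
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ii = ii.ravel()
    # de-shear: a1 has a growth-axis component, so shift the row index to
    # keep each layer an approximately rectangular region (not a
    # parallelogram whose slanted edges defeat bounding-box interior tests)
    jj = jj.ravel() - ii // 2

    centers = []
    layer_idx = []
    for k, letter in enumerate(stacking):
        off = offsets[letter]
        x = ii * a1[0] + off[0]
        y = (ii * a1[1] + jj * a2[1] + off[1]) * ca
        z = np.full_like(x, k * d, dtype=float)
        centers.append(np.column_stack([z, y, x]))
        layer_idx.append(np.full(x.shape, k, dtype=int))

    centers = np.concatenate(centers)
    layer_idx = np.concatenate(layer_idx)
    n_tot = centers.shape[0]
    return ParticleSet(
        centers=centers,
        core_type=np.array(["none"] * n_tot, dtype=object),
        core_diameter=np.zeros(n_tot),
        layer_index=layer_idx,
        growth_axis="y",
        diameter=np.full(n_tot, spec.nn_growth),
        stacking=stacking,
    )


def assign_cores(
    particles: ParticleSet, gold_fraction: float = 1.0 / 101.0, seed: int = 0
) -> ParticleSet:
    """Label each particle gold with probability ``gold_fraction``, else
    fluorescent (the physical sample used a ~1:100 gold:fluorescent ratio)."""
    if not 0 <= gold_fraction <= 1:
        raise ValueError("gold_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gold = rng.random(len(particles)) < gold_fraction
    core_type = np.where(gold, "gold", "fluorescent").astype(object)
    core_diameter = np.where(
        gold, CORE_DIAMETERS_NM["gold"], CORE_DIAMETERS_NM["fluorescent"]
    )
    return ParticleSet(
        centers=particles.centers.copy(),
        core_type=core_type,
        core_diameter=core_diameter,
        layer_index=None if particles.layer_index is None else particles.layer_index.copy(),
        growth_axis=particles.growth_axis,
        diameter=None if particles.diameter is None else particles.diameter.copy(),
        stacking=particles.stacking,
    )


# ---------------------------------------------------------------------------
# Optical kernels


def _axis_grids(optics: OpticsModel, extent_sigmas: float = 4.0):
    """Centred coordinate grids (nm) covering >= 4 FWHM per axis."""
    half = []
    extents = [
        optics.fwhm_axial + (optics.lobe_sep if optics.mode == "depletionz_refl" else 0),
        optics.fwhm_lateral,
        optics.fwhm_lateral,
    ]
    for fwhm, v in zip(extents, optics.voxel):
        h = max(int(math.ceil(2.0 * fwhm / v)), 1)
        half.append(h)
    grids = [np.arange(-h, h + 1) * v for h, v in zip(half, optics.voxel)]
    return grids  # (z, y, x) 1D coordinate arrays


def psf_kernel(optics: OpticsModel) -> np.ndarray:
    """Build the 3D kernel of an imaging mode on the voxel grid, sum = 1.

    confocal / effective-STED modes and the excitation reflection pattern
    are anisotropic Gaussians; ``depletion2d_refl`` is a lateral doughnut
    I(r) ~ (r^2/w^2) exp(-2 r^2/w^2) times an axial Gaussian;
    ``depletionz_refl`` is two axially displaced Gaussian lobes (separation
    ``lobe_sep``, top/bottom peak ratio ``lobe_asymmetry``) times a lateral
    Gaussian.
    """
    for name, fwhm, vox in (
        ("axial", optics.fwhm_axial, optics.voxel[0]),
        ("lateral", optics.fwhm_lateral, optics.voxel[1]),
        ("lateral", optics.fwhm_lateral, optics.voxel[2]),
    ):
        if fwhm < vox:
            warnings.warn(
                f"{name} FWHM {fwhm} nm below one voxel ({vox} nm): kernel degenerate",
                stacklevel=2,
            )
    z, y, x = _axis_grids(optics)
    sz = optics.fwhm_axial / _GAUSS_K
    sl = optics.fwhm_lateral / _GAUSS_K
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]
    r2 = yy**2 + xx**2

    mode = optics.mode
    if mode in FLUORESCENCE_MODES or mode == "excitation_refl":
        k = np.exp(-0.5 * (zz / sz) ** 2) * np.exp(-0.5 * r2 / sl**2)
    elif mode == "depletion2d_refl":
        # doughnut: null on axis, peak ring at r = w/sqrt... (w sets the ring)
        w = optics.fwhm_lateral
        k = (r2 / w**2) * np.exp(-2.0 * r2 / w**2) * np.exp(-0.5 * (zz / sz) ** 2)
    elif mode == "depletionz_refl":
        half_sep = optics.lobe_sep / 2.0
        top = optics.lobe_asymmetry * np.exp(-0.5 * ((zz - half_sep) / sz) ** 2)
        bottom = np.exp(-0.5 * ((zz + half_sep) / sz) ** 2)
        k = (top + bottom) * np.exp(-0.5 * r2 / sl**2)
    else:  # pragma: no cover - guarded by OpticsModel typing
        raise ValueError(f"unknown PSF mode {mode!r}")

    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate kernel (zero mass)")
    return k / s


# ---------------------------------------------------------------------------
# Rasterisation and rendering


def _sphere_fill(shape, center_vox, radius_vox, subsamples: int | None = None):
    """Partial-volume fill fractions of a solid sphere on a voxel grid.

    ``center_vox`` and ``radius_vox`` are in units of voxels per axis
    (anisotropic radius allowed).  Fill fraction per voxel is estimated by
    sub-voxel sampling; the per-axis sampling density adapts to the sphere
    size so that at least ~8 samples span the diameter (a fixed coarse grid
    would quantise the deposited mass of cores smaller than a voxel).
    """
    rz, ry, rx = radius_vox
    cz, cy, cx = center_vox
    z0, z1 = int(math.floor(cz - rz - 1)), int(math.ceil(cz + rz + 1))
    y0, y1 = int(math.floor(cy - ry - 1)), int(math.ceil(cy + ry + 1))
    x0, x1 = int(math.floor(cx - rx - 1)), int(math.ceil(cx + rx + 1))
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1, y1, x1 = min(z1, shape[0] - 1), min(y1, shape[1] - 1), min(x1, shape[2] - 1)
    if z1 < z0 or y1 < y0 or x1 < x0:
        return np.zeros((0, 0, 0)), (0, 0, 0)

    if subsamples is None:
        # >= ~16 samples across the diameter per axis, capped for tiny cores
        ns = [min(max(3, int(math.ceil(8.0 / max(r, 1e-9)))), 48) for r in (rz, ry, rx)]
    elif np.iterable(subsamples):
        ns = [int(s) for s in subsamples]
    else:
        ns = [subsamples] * 3
    subs = [(np.arange(n) + 0.5) / n - 0.5 for n in ns]
    zs = np.add.outer(np.arange(z0, z1 + 1), subs[0]).ravel()
    ys = np.add.outer(np.arange(y0, y1 + 1), subs[1]).ravel()
    xs = np.add.outer(np.arange(x0, x1 + 1), subs[2]).ravel()
    dz = ((zs - cz) / rz) ** 2
    dy = ((ys - cy) / ry) ** 2
    dx = ((xs - cx) / rx) ** 2
    inside = (
        dz[:, None, None] + dy[None, :, None] + dx[None, None, :]
    ) <= 1.0
    nz, ny, nx = z1 - z0 + 1, y1 - y0 + 1, x1 - x0 + 1
    frac = inside.reshape(nz, ns[0], ny, ns[1], nx, ns[2]).mean(axis=(1, 3, 5))
    return frac, (z0, y0, x0)


def render_volume(
    particles: ParticleSet,
    optics: OpticsModel,
    noise: NoiseSpec | None = None,
    extent: tuple[float, float, float] = (4000.0, 10000.0, 10000.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ImageStack:
    """Render an image stack of the mode-appropriate cores.

    Each core is deposited as a sub-voxel-positioned solid sphere of its
    core diameter (partial-volume weighted), the volume is convolved with
    ``psf_kernel(optics)``, and axial coordinates are mapped
    ``z_apparent = z_true / axial_scaling`` before rasterisation (refractive
    index mismatch shrinks or stretches apparent depths).  Noise, when
    requested, is Poisson on ``photons_per_unit x intensity`` (output in
    counts) followed by additive Gaussian read noise.  Rendering is linear
    in the particle set.
    """
    vz, vy, vx = optics.voxel
    shape = tuple(
        max(int(round(e / v)), 1) for e, v in zip(extent, (vz, vy, vx))
    )
    kernel = psf_kernel(optics)
    if any(ks > s for ks, s in zip(kernel.shape, shape)):
        raise ValueError(
            f"extent {shape} voxels smaller than the PSF kernel {kernel.shape}"
        )

    wanted = "fluorescent" if optics.mode in FLUORESCENCE_MODES else "gold"
    img = np.zeros(shape, dtype=float)
    centers = particles.centers
    for i in range(len(particles)):
        if particles.core_type[i] != wanted:
            continue
        z, y, x = centers[i]
        z_app = z / optics.axial_scaling
        cz = (z_app - origin[0]) / vz
        cy = (y - origin[1]) / vy
        cx = (x - origin[2]) / vx
        r = particles.core_diameter[i] / 2.0
        # rasterise voxel-aligned, then apply the sub-voxel offset as a
        # linear-interpolation shift: a core smaller than a voxel would
        # otherwise snap to the nearest voxel centre and lose its position
        ci = tuple(float(round(c)) for c in (cz, cy, cx))
        frac, (z0, y0, x0) = _sphere_fill(shape, ci, (r / vz, r / vy, r / vx))
        if frac.size:
            offset = (cz - ci[0], cy - ci[1], cx - ci[2])
            frac = ndi_shift(frac, offset, order=1, mode="constant", cval=0.0)
            img[
                z0 : z0 + frac.shape[0],
                y0 : y0 + frac.shape[1],
                x0 : x0 + frac.shape[2],
            ] += frac

    img = fftconvolve(img, kernel, mode="same")
    np.clip(img, 0.0, None, out=img)

    if noise is not None and (noise.photons_per_unit > 0 or noise.read_sigma > 0):
        rng = np.random.default_rng(noise.seed)
        if noise.photons_per_unit > 0:
            img = rng.poisson(img * noise.photons_per_unit).astype(float)
        if noise.read_sigma > 0:
            img = img + rng.normal(0.0, noise.read_sigma, size=img.shape)

    return ImageStack(data=img, voxel=(vz, vy, vx), origin=origin)


# ---------------------------------------------------------------------------
# Sparse-probe sample


def sparse_sample(
    box: tuple[float, float, float],
    scaffold_diameter_mean: float = 310.0,
    scaffold_pdi: float = 0.10,
    ratio: tuple[float, float, float] = (85000.0, 99.0, 1.0),
    seed: int = 0,
    n_particles: int | None = None,
    probe_diameter: float = 505.0,
    max_attempts_per_particle: int = 5000,
) -> ParticleSet:
    """Random sequential addition of non-overlapping spheres in ``box`` (nm).

    ``ratio`` is the (scaffold : fluorescent : gold) number ratio; each
    particle's class is drawn from it.  Scaffold diameters are normal with
    the given polydispersity (sd = pdi x mean); probe particles have the
    crystal bead diameter with fluorescent (45 nm) or gold (80 nm) cores.
    When ``n_particles`` is None, only the probes implied by one ratio unit
    are placed (useful for PSF test fields).
    """
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0) or ratio.sum() <= 0:
        raise ValueError("ratio entries must be >= 0 with a positive sum")
    if n_particles is None:
        n_particles = int(round(ratio[1] + ratio[2])) or 1
        p = np.array([0.0, ratio[1], ratio[2]])
    else:
        p = ratio
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    classes = rng.choice(3, size=n_particles, p=p)
    diameters = np.where(
        classes == 0,
        np.maximum(
            rng.normal(scaffold_diameter_mean, scaffold_pdi * scaffold_diameter_mean, n_particles),
            1.0,
        ),
        probe_diameter,
    )

    box = np.asarray(box, dtype=float)
    dmax = diameters.max()
    # grid-accelerated overlap checks: cell edge >= max diameter
    cell = dmax
    ncell = np.maximum((box // cell).astype(int), 1)
    grid: dict[tuple[int, int, int], list[int]] = {}
    centers = np.empty((n_particles, 3))

    def _cell_of(pt):
        return tuple(np.minimum((pt // cell).astype(int), ncell - 1))

    placed = 0
    for i in range(n_particles):
        r_i = diameters[i] / 2.0
        ok = False
        for _ in range(max_attempts_per_particle):
            pt = rng.random(3) * (box - diameters[i]) + r_i
            ci = _cell_of(pt)
            clash = False
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        for j in grid.get((ci[0] + dz, ci[1] + dy, ci[2] + dx), ()):
                            sep = np.linalg.norm(pt - centers[j])
                            if sep < r_i + diameters[j] / 2.0:
                                clash = True
                                break
                        if clash:
                            break
                    if clash:
                        break
                if clash:
                    break
            if not clash:
                centers[i] = pt
                grid.setdefault(ci, []).append(i)
                placed += 1
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"sphere packing failed after {max_attempts_per_particle} retries; "
                f"placed {placed}/{n_particles} (fill too high for box {box.tolist()})"
            )

    core_type = np.array(
        ["none", "fluorescent", "gold"], dtype=object
    )[classes]
    core_diameter = np.array(
        [0.0, CORE_DIAMETERS_NM["fluorescent"], CORE_DIAMETERS_NM["gold"]]
    )[classes]
    return ParticleSet(
        centers=centers,
        core_type=core_type,
        core_diameter=core_diameter,
        layer_index=None,
        growth_axis="y",
        diameter=diameters,
    )


# ---------------------------------------------------------------------------
# Fabry-Perot fringes


def fringe_spectrum(
    height_um: float,
    n_medium: float = 1.0,
    wavenumber_grid: np.ndarray | None = None,
    amplitude: float = 1.0,
    visibility: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-beam interference spectrum of a cell of optical thickness n*h.

    I(nu) = A (1 + V cos(4 pi n h nu)) with nu in cm^-1 and h in cm; the
    fringe period is 1 / (2 n h) cm^-1.  Returns (wavenumber, intensity).
    """
    if height_um <= 0:
        raise ValueError("height must be > 0")
    if n_medium < 1:
        raise ValueError("n_medium must be >= 1")
    if wavenumber_grid is None:
        wavenumber_grid = np.linspace(2000.0, 8000.0, 6001)
    nu = np.asarray(wavenumber_grid, dtype=float)
    h_cm = height_um * 1e-4
    period = 1.0 / (2.0 * n_medium * h_cm)
    dnu = np.max(np.diff(nu))
    if dnu > period / 2.0:
        raise ValueError(
            f"wavenumber grid spacing {dnu:.3g} cm^-1 too coarse for fringe "
            f"period {period:.3g} cm^-1"
        )
    intensity = amplitude * (1.0 + visibility * np.cos(4.0 * np.pi * n_medium * h_cm * nu))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, nu.shape)
    return nu, intensity
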