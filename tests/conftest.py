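"""Shared fixtures: every dataset is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from crystalcal import LatticeSpec, NoiseSpec, OpticsModel, ParticleSet
from crystalcal import synthgen

# study conditions for the end-to-end lattice recovery: a ~10 x 10 um,
# 8-layer crystal with sigma_eff = 538 nm, 4 % growth compression, axial
# scaling 0.982 and shot noise at SNR ~ 20
CRYSTAL_SPEC = dict(
    nn_growth=538.0, compression=0.96, n_layers=8, layers_extent=24,
    fault_prob=0.0, seed=1,
)
CRYSTAL_OPTICS = dict(
    mode="confocal", fwhm_lateral=220.0, fwhm_axial=300.0,
    voxel=(100.0, 45.0, 45.0), axial_scaling=0.982,
)
APPARENT_SPACING = 538.0 * np.sqrt(6) / 3 / 0.982  # ~447.3 nm
D111_TRUE = 538.0 * np.sqrt(6) / 3  # ~439.3 nm


@pytest.fixture(scope="session")
def crystal_particles() -> ParticleSet:
    spec = LatticeSpec(**CRYSTAL_SPEC)
    return synthgen.assign_cores(synthgen.build_crystal(spec), 1.0 / 101.0, seed=2)


@pytest.fixture(scope="session")
def crystal_stack(crystal_particles):
    optics = OpticsModel(**CRYSTAL_OPTICS)
    noise = NoiseSpec(photons_per_unit=1e5, seed=3)
    return synthgen.render_volume(
        crystal_particles, optics, noise,
        extent=(4800.0, 10000.0, 10000.0), origin=(-700.0, 0.0, 0.0),
    )


def place_beads(
    n=12, box=(4000.0, 8000.0, 8000.0), margin=1300.0, minsep=1700.0, seed=5
) -> ParticleSet:
    """Well-separated fluorescent 45 nm cores for PSF extraction fields."""
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.random(3) * (np.array(box) - 2 * margin) + margin
        if all(np.linalg.norm(p - q) > minsep for q in pts):
            pts.append(p)
    return ParticleSet(
        centers=np.array(pts),
        core_type=np.array(["fluorescent"] * n, dtype=object),
        core_diameter=np.full(n, 45.0),
    )


def bead_field(mode: str, fwhm_axial: float, seed=5, noise_seed=11):
    """Render a sparse-bead volume for one imaging mode (SNR >> 20)."""
    beads = place_beads(seed=seed)
    optics = OpticsModel(
        mode=mode, fwhm_lateral=230.0, fwhm_axial=fwhm_axial,
        voxel=(50.0, 45.0, 45.0), axial_scaling=1.0,
    )
    noise = NoiseSpec(photons_per_unit=3e5, seed=noise_seed)
    stack = synthgen.render_volume(beads, optics, noise, extent=(4000.0, 8000.0, 8000.0))
    return beads, optics, stack


@pytest.fixture(scope="session")
def confocal_bead_field():
    return bead_field("confocal", 600.0)


@pytest.fixture(scope="session")
def stedz_bead_field():
    return bead_field("stedz_eff", 300.0)


def stacking_environment_oracle(stacking: str) -> dict[int, str]:
    """A layer is HCP-like iff its two sandwiching layers share the letter."""
    return {
        k: ("HCP" if stacking[k - 1] == stacking[k + 1] else "FCC")
        for k in range(1, len(stacking) - 1)
    }
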