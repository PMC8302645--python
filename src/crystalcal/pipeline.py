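"""End-to-end orchestration: simulate -> lateral -> axial -> structure.

A single structured config (YAML on disk, plain dict in memory) drives
every stage; all randomness derives from one global seed via
``numpy.random.SeedSequence`` so a config + seed pair is fully
reproducible.  The report is a versioned JSON document carrying every
stage result with uncertainties and provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .datatypes import LatticeSpec, NoiseSpec, OpticsModel, UFloat
from . import axial, lateral, scaling, structure, synthgen

__all__ = ["RunConfig", "default_config", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Pipeline parameters; see ``default_config`` for the schema."""

    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            params=raw,
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw["outdir"]) if "outdir" in raw else None,
        )


def default_config(seed: int = 0) -> dict:
    """Default synthetic-study conditions mirroring the physical sample."""
    return {
        "seed": seed,
        "crystal": {
            "nn_growth": 538.0,
            "compression": 0.96,
            "n_layers": 8,
            "layers_extent": 22,
            "fault_prob": 0.0,
            "gold_fraction": 1.0 / 101.0,
        },
        "optics": {
            "mode": "confocal",
            "fwhm_lateral": 220.0,
            "fwhm_axial": 300.0,
            "voxel": [100.0, 45.0, 45.0],
            "axial_scaling": 0.982,
        },
        "noise": {"photons_per_unit": 1e5, "read_sigma": 0.0},
        "render": {"extent": [4600.0, 10000.0, 10000.0], "origin": [-700.0, 0.0, 0.0]},
        "lateral": {},  # slice_layers default: quarter, half, three-quarter height
        "scaling": {
            "h_true": [94.257, 0.008],
            "h_empty": [98.0, 0.2],
            "h_filled": [99.9, 0.2],
            "n_medium": 1.4286,
        },
    }


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages and return the JSON-ready report."""
    if isinstance(config, dict):
        config = RunConfig(params=config, seed=int(config.get("seed", 0)))
    p = config.params or default_config(config.seed)
    for key in ("crystal", "optics", "noise"):
        if key not in p:
            raise ValueError(f"config missing required section '{key}'")

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(p, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }

    # --- simulate -------------------------------------------------------
    c = p["crystal"]
    spec = LatticeSpec(
        nn_growth=c["nn_growth"],
        compression=c["compression"],
        n_layers=c["n_layers"],
        layers_extent=c["layers_extent"],
        fault_prob=c.get("fault_prob", 0.0),
        seed=seeds[0],
    )
    particles = synthgen.assign_cores(
        synthgen.build_crystal(spec), c.get("gold_fraction", 1.0 / 101.0), seed=seeds[1]
    )
    o = p["optics"]
    optics = OpticsModel(
        mode=o.get("mode", "confocal"),
        fwhm_lateral=o["fwhm_lateral"],
        fwhm_axial=o["fwhm_axial"],
        voxel=tuple(o["voxel"]),
        axial_scaling=o.get("axial_scaling", 1.0),
    )
    noise = NoiseSpec(
        photons_per_unit=p["noise"].get("photons_per_unit", 0.0),
        read_sigma=p["noise"].get("read_sigma", 0.0),
        seed=seeds[2],
    )
    render_cfg = p.get("render", {})
    extent = tuple(render_cfg.get("extent", (4600.0, 10000.0, 10000.0)))
    origin = tuple(render_cfg.get("origin", (-700.0, 0.0, 0.0)))
    try:
        stack = synthgen.render_volume(particles, optics, noise, extent=extent,
                                       origin=origin)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # --- scaling factor -------------------------------------------------
    sc = p.get("scaling", {})
    if sc:
        chain = scaling.scaling_chain(
            UFloat(*sc["h_true"]),
            UFloat(*sc["h_empty"]),
            UFloat(*sc["h_filled"]),
            n_medium=sc.get("n_medium"),
        )
        s = chain.s
        report["scaling"] = chain.as_dict()
    else:
        s = UFloat(optics.axial_scaling, 0.0)

    # --- lateral --------------------------------------------------------
    d_app = spec.layer_spacing / optics.axial_scaling
    default_layers = sorted({
        max(1, min(spec.n_layers - 1, round(spec.n_layers * f)))
        for f in (0.25, 0.5, 0.75)
    })
    slice_layers = p.get("lateral", {}).get("slice_layers", default_layers)
    z_slices_um = [k * d_app / 1000.0 for k in slice_layers]
    try:
        lat = lateral.calibrate_lateral(stack, z_slices_um)
    except Exception as exc:
        raise RuntimeError(f"stage 'lateral' failed: {exc}") from exc
    report["lateral"] = lat.as_dict()

    # --- axial ----------------------------------------------------------
    try:
        ax = axial.calibrate_axial(stack, scaling_factor=s, sigma_eff=lat.sigma_eff)
    except Exception as exc:
        raise RuntimeError(f"stage 'axial' failed: {exc}") from exc
    report["axial"] = ax.as_dict()

    # --- structure (on ground-truth coordinates) ------------------------
    try:
        ops = structure.classify_structure(particles.centers)
        inner = structure.interior_mask(particles.centers, margin=1.2 * spec.nn_growth)
        aniso = structure.bond_anisotropy(
            particles.centers, growth_axis="y", layer_index=particles.layer_index
        )
        counts = {
            lbl: int(np.sum(ops.phase_label[inner] == lbl))
            for lbl in ("FCC", "HCP", "other")
        }
        report["structure"] = {
            "interior_phase_counts": counts,
            "anisotropy": aniso.as_dict(),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'structure' failed: {exc}") from exc

    if config.outdir is not None:
        from .io import write_json, write_particles, write_stack

        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stack(stack, outdir / "stack.tif")
        write_particles(particles, outdir / "particles.csv")
        write_json(report, outdir / "report.json")
    return report
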