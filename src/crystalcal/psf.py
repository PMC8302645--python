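"""PSF extraction from sparse fluorescent beads and Z-STED lobe balance.

The workflow mirrors the sparse-probe measurement: locate well-separated
beads away from the volume boundaries, align and average them with
sub-voxel precision, deconvolve the average with a solid sphere the size
of the fluorescent core (Wiener, frequency domain), and report FWHMs per
axis.  Reflection images of the Z-STED depletion pattern are profiled
along Z to balance the two axial lobes with the objective correction
collar.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.ndimage import maximum_filter, shift as nd_shift
from scipy.optimize import brentq
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .datatypes import BeadCandidate, ImageStack, LobeBalance, PSFVolume
from .synthgen import _sphere_fill

__all__ = [
    "detect_beads",
    "average_beads",
    "sphere_kernel",
    "deconvolve_sphere",
    "fwhm",
    "lobe_balance",
    "optimize_collar",
    "extract_psf",
]

log = logging.getLogger(__name__)


def detect_beads(
    volume: ImageStack,
    threshold: float | None = None,
    min_separation: float = 1500.0,
    margin: float | None = None,
    merge_radius: float = 500.0,
) -> list[BeadCandidate]:
    """Locate isolated bead signals.

    Local maxima above ``threshold`` (default: mean + 5 sd of the volume)
    are refined to sub-voxel centres by an intensity-weighted centroid over
    a 5^3 window.  Maxima within ``merge_radius`` (nm) of a brighter
    maximum are treated as shot-noise duplicates of the same bead and
    merged into it.  Candidates closer than ``min_separation`` (nm) to
    another candidate are BOTH removed; candidates within ``margin``
    (default: min_separation / 2) of any volume face are removed.
    """
    data = volume.data
    vz, vy, vx = volume.voxel
    if threshold is None:
        threshold = float(data.mean() + 5.0 * data.std())
    if margin is None:
        margin = min_separation / 2.0

    local_max = (data == maximum_filter(data, size=3)) & (data > threshold)
    coords = np.argwhere(local_max)
    if coords.size == 0:
        return []

    # merge duplicate maxima of one bead, keeping the brightest
    if merge_radius > 0 and len(coords) > 1:
        nm = coords * np.array([vz, vy, vx])
        order = np.argsort(data[tuple(coords.T)])[::-1]
        kept: list[int] = []
        tree_pts = []
        for i in order:
            p = nm[i]
            if all(np.linalg.norm(p - nm[j]) > merge_radius for j in kept):
                kept.append(i)
        coords = coords[sorted(kept)]

    # sub-voxel centroid over a 5^3 window
    positions = []
    peaks = []
    for cz, cy, cx in coords:
        sl = tuple(
            slice(max(c - 2, 0), min(c + 3, s))
            for c, s in zip((cz, cy, cx), data.shape)
        )
        w = data[sl].astype(float)
        w = np.clip(w - w.min(), 0, None)
        if w.sum() <= 0:
            centroid = np.array([cz, cy, cx], dtype=float)
        else:
            grids = np.meshgrid(
                *[np.arange(s.start, s.stop) for s in sl], indexing="ij"
            )
            centroid = np.array([float((g * w).sum() / w.sum()) for g in grids])
        positions.append(centroid * np.array([vz, vy, vx]) + np.array(volume.origin))
        peaks.append(float(data[cz, cy, cx]))
    positions = np.asarray(positions)

    # mutual-separation rule: both members of a close pair are rejected
    tree = cKDTree(positions)
    pairs = tree.query_pairs(min_separation)
    too_close = set()
    for i, j in pairs:
        too_close.add(i)
        too_close.add(j)
    if len(positions) > 1:
        dists, _ = tree.query(positions, k=2)
        nearest = dists[:, 1]
    else:
        nearest = np.full(len(positions), np.inf)

    extent_nm = np.array(volume.origin) + np.array(data.shape) * np.array([vz, vy, vx])
    out = []
    for i, pos in enumerate(positions):
        margin_ok = bool(
            np.all(pos - np.array(volume.origin) >= margin)
            and np.all(extent_nm - pos >= margin)
        )
        if i in too_close or not margin_ok:
            continue
        out.append(
            BeadCandidate(
                position=tuple(pos),
                peak_intensity=peaks[i],
                min_neighbour_separation=float(nearest[i]),
                border_margin_ok=margin_ok,
            )
        )
    return out


def average_beads(
    volume: ImageStack,
    candidates: list[BeadCandidate],
    box_nm: tuple[float, float, float] = (3000.0, 2000.0, 2000.0),
    order: int = 3,
) -> tuple[np.ndarray, int]:
    """Sub-voxel-aligned average of bead subvolumes, normalised to unit sum.

    Each candidate subvolume is shifted by its fractional offset (cubic
    spline interpolation by default; ``order=1`` for linear) so the bead
    centre lands on the centre voxel, then all are summed; candidates whose
    box would clip the volume are skipped with a log entry.  Returns
    (average, n_beads).
    """
    if not candidates:
        raise ValueError("no bead candidates to average")
    data = volume.data.astype(float)
    vox = np.array(volume.voxel)
    half = np.array([max(int(round(b / 2.0 / v)), 1) for b, v in zip(box_nm, vox)])

    acc = np.zeros(2 * half + 1)
    n_used = 0
    for cand in candidates:
        pos_vox = (np.array(cand.position) - np.array(volume.origin)) / vox
        base = np.round(pos_vox).astype(int)
        frac = pos_vox - base
        lo = base - half - 1
        hi = base + half + 2
        if np.any(lo < 0) or np.any(hi > np.array(data.shape)):
            log.info("bead at %s skipped: extraction box clips the volume", cand.position)
            continue
        sub = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        shifted = nd_shift(sub, -frac, order=order, mode="nearest")
        acc += shifted[1:-1, 1:-1, 1:-1]
        n_used += 1
    if n_used == 0:
        raise ValueError("all candidates clipped; enlarge the volume or shrink the box")
    acc = np.clip(acc, 0, None)
    return acc / acc.sum(), n_used


def sphere_kernel(diameter: float, voxel: tuple[float, float, float]) -> np.ndarray:
    """Partial-volume anti-aliased solid sphere, centred, sum = 1.

    A core much smaller than a voxel degenerates to a single-voxel delta.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    vz, vy, vx = voxel
    r = diameter / 2.0
    half = [max(int(math.ceil(r / v)) + 1, 1) for v in voxel]
    shape = tuple(2 * h + 1 for h in half)
    # built once per deconvolution: afford a fine sub-voxel grid
    ns = [min(max(5, int(math.ceil(32.0 * v / max(diameter, 1e-9)))), 96)
          for v in voxel]
    frac, origin = _sphere_fill(
        shape, tuple(float(h) for h in half), (r / vz, r / vy, r / vx),
        subsamples=ns,
    )
    k = np.zeros(shape)
    k[
        origin[0] : origin[0] + frac.shape[0],
        origin[1] : origin[1] + frac.shape[1],
        origin[2] : origin[2] + frac.shape[2],
    ] = frac
    if k.sum() <= 0:  # core far below voxel size: delta kernel
        k[half[0], half[1], half[2]] = 1.0
    return k / k.sum()


def _centre_on_argmax(vol: np.ndarray) -> np.ndarray:
    centre = tuple(s // 2 for s in vol.shape)
    peak = np.unravel_index(np.argmax(vol), vol.shape)
    return np.roll(vol, tuple(c - p for c, p in zip(centre, peak)), axis=(0, 1, 2))


def deconvolve_sphere(
    average: np.ndarray,
    core_diameter: float,
    voxel: tuple[float, float, float],
    regularization: float = 1e-3,
    mode: str | None = None,
    depth: float | None = None,
    n_beads: int = 1,
) -> PSFVolume:
    """Wiener deconvolution of a bead average by the known spherical core.

    W = conj(S) / (|S|^2 + eps max|S|^2) with eps = ``regularization``;
    the output is clipped at zero, re-centred on its maximum, normalised to
    unit sum and annotated with per-axis FWHMs.
    """
    if regularization <= 0:
        raise ValueError("regularization must be > 0")
    avg = np.asarray(average, dtype=float)
    sph = sphere_kernel(core_diameter, voxel)
    pad = np.zeros_like(avg)
    centre = tuple(s // 2 for s in avg.shape)
    sl = tuple(
        slice(c - s // 2, c - s // 2 + s) for c, s in zip(centre, sph.shape)
    )
    pad[sl] = sph
    S = np.fft.fftn(np.fft.ifftshift(pad))
    A = np.fft.fftn(avg)
    S2 = np.abs(S) ** 2
    W = np.conj(S) / (S2 + regularization * S2.max())
    out = np.real(np.fft.ifftn(A * W))
    out = np.clip(out, 0, None)
    out = _centre_on_argmax(out)
    out /= out.sum()
    fwhms = tuple(fwhm(out, axis, voxel) for axis in range(3))
    return PSFVolume(
        data=out, voxel=tuple(voxel), fwhm=fwhms, n_beads=n_beads, depth=depth, mode=mode
    )


def fwhm(volume: np.ndarray, axis: int, voxel: tuple[float, float, float]) -> float:
    """FWHM (nm) of the axis profile through the global maximum.

    Half-maximum crossings are found by linear interpolation on both sides
    of the peak; a profile that never drops below half maximum raises.
    """
    vol = np.asarray(volume, dtype=float)
    peak = np.unravel_index(np.argmax(vol), vol.shape)
    sl = list(peak)
    sl[axis] = slice(None)
    profile = vol[tuple(sl)].astype(float)
    i0 = int(peak[axis])
    top = profile[i0]
    floor = profile.min()
    half = floor + (top - floor) / 2.0

    def _cross(direction: int) -> float:
        i = i0
        while 0 <= i + direction < len(profile):
            j = i + direction
            if profile[j] <= half:
                # linear interpolation between i and j
                t = (profile[i] - half) / (profile[i] - profile[j])
                return i + direction * t
            i = j
        raise ValueError(f"unresolved: profile does not drop below half max (axis {axis})")

    left = _cross(-1)
    right = _cross(+1)
    return float((right - left) * voxel[axis])


def lobe_balance(
    reflection_volume: ImageStack, centre: tuple[int, int] | None = None
) -> LobeBalance:
    """Z-STED axial lobe balance from a Z line profile.

    The profile runs along Z through the lateral (Y, X) position of the
    global intensity maximum (or the given ``centre``); the two most
    prominent lobes give ratio = top-lobe peak / bottom-lobe peak, where
    "top" is the larger Z position.
    """
    data = reflection_volume.data
    if centre is None:
        _, y0, x0 = np.unravel_index(np.argmax(data), data.shape)
    else:
        y0, x0 = centre
    profile = data[:, y0, x0].astype(float)
    idx, props = find_peaks(profile, prominence=0.05 * (profile.max() - profile.min() + 1e-300))
    if len(idx) < 2:
        raise ValueError(f"fewer than two axial lobes found ({len(idx)})")
    order = np.argsort(props["prominences"])[::-1][:2]
    lobes = np.sort(idx[order])
    z = reflection_volume.z_positions()
    bottom_i, top_i = lobes[0], lobes[1]
    ratio = profile[top_i] / profile[bottom_i]
    return LobeBalance(
        ratio=float(ratio), lobe_positions=(float(z[top_i]), float(z[bottom_i]))
    )


def optimize_collar(
    simulator,
    cc_range: tuple[float, float],
    xtol: float = 1e-4,
) -> tuple[float, float]:
    """Correction-collar setting that balances the Z-STED lobes.

    ``simulator`` maps a collar setting to a reflection ImageStack; the
    root of log(lobe ratio) is bracketed on ``cc_range`` and solved by
    Brent's method.  Returns (cc_setting, achieved_ratio).
    """
    lo, hi = cc_range

    def f(cc):
        return math.log(lobe_balance(simulator(cc)).ratio)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo, 1.0
    if f_hi == 0.0:
        return hi, 1.0
    if f_lo * f_hi > 0:
        raise ValueError(
            f"lobe ratio does not bracket 1 on cc range [{lo}, {hi}] "
            f"(log-ratios {f_lo:.3g}, {f_hi:.3g})"
        )
    cc = brentq(f, lo, hi, xtol=xtol * (hi - lo))
    return float(cc), float(math.exp(f(cc)))


def extract_psf(
    volumes: list[ImageStack],
    core_diameter: float = 45.0,
    mode: str | None = None,
    depth: float | None = None,
    threshold: float | None = None,
    min_separation: float = 1500.0,
    box_nm: tuple[float, float, float] = (3000.0, 2000.0, 2000.0),
    regularization: float = 1e-3,
) -> PSFVolume:
    """detect -> average -> deconvolve across one or more volumes."""
    if not volumes:
        raise ValueError("no volumes given")
    acc = None
    n_total = 0
    for vol in volumes:
        cands = detect_beads(vol, threshold=threshold, min_separation=min_separation)
        if not cands:
            continue
        avg, n = average_beads(vol, cands, box_nm=box_nm)
        acc = avg * n if acc is None else acc + avg * n
        n_total += n
    if acc is None or n_total == 0:
        raise ValueError("no usable beads found in any volume")
    acc /= acc.sum()
    return deconvolve_sphere(
        acc,
        core_diameter,
        volumes[0].voxel,
        regularization=regularization,
        mode=mode,
        depth=depth,
        n_beads=n_total,
    )
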