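"""Axial calibration from the (111) layer periodicity.

The mean intensity per Z plane of a crystal stack oscillates with the
layer period.  Gaussian fits refine each layer peak, a linear fit of peak
position against layer index gives the apparent interlayer distance, and
multiplying by the refractive-index axial scaling factor yields the true
d111, which can be compared with the close-packing closed form
d111 = sqrt(6) sigma / 3.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import linregress

from .datatypes import AxialResult, ImageStack, UFloat

__all__ = [
    "z_profile",
    "layer_peak_positions",
    "fit_layer_spacing",
    "correct_spacing",
    "fcc_layer_spacing",
    "calibrate_axial",
]


def z_profile(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity per Z plane; returns (positions_nm, profile)."""
    if stack.data.shape[0] < 8:
        raise ValueError("stack needs at least 8 planes for a Z profile")
    profile = stack.data.mean(axis=(1, 2))
    return stack.z_positions(), profile


def _gauss(z, amp, mu, sig, off):
    return amp * np.exp(-0.5 * ((z - mu) / sig) ** 2) + off


def layer_peak_positions(
    positions: np.ndarray,
    profile: np.ndarray,
    prominence_frac: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Layer peak centres (nm) refined by per-peak Gaussian least squares.

    Local maxima above ``prominence_frac`` of the profile dynamic range are
    refined on a window of +-(pitch/3) around each peak; centres are
    returned sorted ascending together with their fit sds.
    """
    positions = np.asarray(positions, dtype=float)
    profile = np.asarray(profile, dtype=float)
    dyn = profile.max() - profile.min()
    if dyn <= 0:
        raise ValueError("insufficient layers: flat profile")
    idx, _ = find_peaks(profile, prominence=prominence_frac * dyn)
    if len(idx) < 3:
        raise ValueError(f"insufficient layers: found {len(idx)} peaks, need >= 3")
    pitch = float(np.median(np.diff(positions[idx])))
    dz = float(np.mean(np.diff(positions)))
    half = max(int(round(pitch / 3.0 / dz)), 2)

    centres, sds = [], []
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, len(positions))
        z, p = positions[lo:hi], profile[lo:hi]
        p0 = [p.max() - p.min(), positions[i], pitch / 4.0, p.min()]
        try:
            popt, pcov = curve_fit(_gauss, z, p, p0=p0, maxfev=5000)
            mu = float(popt[1])
            sd = float(math.sqrt(max(pcov[1, 1], 0.0)))
            if not (z[0] - dz <= mu <= z[-1] + dz):
                raise RuntimeError
        except (RuntimeError, ValueError):
            mu, sd = float(positions[i]), dz / 2.0
        centres.append(mu)
        sds.append(sd)
    order = np.argsort(centres)
    return np.asarray(centres)[order], np.asarray(sds)[order]


def fit_layer_spacing(positions: np.ndarray) -> tuple[UFloat, float, float]:
    """OLS fit of peak position vs layer index.

    Indices are assigned by rank order; skipped layers are detected from
    the gap structure (each position is re-indexed by its rounded multiple
    of the median gap).  Returns (slope +- stderr, intercept, R^2).
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    if len(pos) < 3:
        raise ValueError("need at least 3 peak positions")
    gaps = np.diff(pos)
    if np.all(gaps == 0):
        raise ValueError("degenerate positions (all equal)")
    base = float(np.median(gaps))
    index = np.round((pos - pos[0]) / base).astype(int)
    if len(np.unique(index)) < len(index):  # re-indexing collided; use rank
        index = np.arange(len(pos))
    res = linregress(index, pos)
    return (
        UFloat(float(res.slope), float(res.stderr)),
        float(res.intercept),
        float(res.rvalue**2),
    )


def correct_spacing(apparent: UFloat | float, s: UFloat | float) -> UFloat:
    """True spacing = apparent x axial scaling factor, uncertainty propagated."""
    a = apparent if isinstance(apparent, UFloat) else UFloat(float(apparent))
    su = s if isinstance(s, UFloat) else UFloat(float(s))
    if a.value <= 0 or su.value <= 0:
        raise ValueError("apparent spacing and scaling factor must be > 0")
    return a * su


def fcc_layer_spacing(sigma: UFloat | float) -> UFloat:
    """FCC (111) interlayer spacing for touching spheres: sqrt(6) sigma / 3."""
    u = sigma if isinstance(sigma, UFloat) else UFloat(float(sigma))
    if u.value <= 0:
        raise ValueError("sigma must be > 0")
    return u * (math.sqrt(6.0) / 3.0)


def calibrate_axial(
    stack: ImageStack,
    scaling_factor: UFloat | float = 1.0,
    sigma_eff: UFloat | float | None = None,
    prominence_frac: float = 0.10,
    trim_edge_peaks: bool = True,
) -> AxialResult:
    """Full axial chain: Z profile -> peak fits -> linear fit -> correction.

    The outermost layer peaks see the tail of only one neighbour and are
    pulled inward by it; with ``trim_edge_peaks`` (default) they are
    dropped from the linear fit whenever at least six peaks were found.
    """
    positions, profile = z_profile(stack)
    centres, _ = layer_peak_positions(positions, profile, prominence_frac)
    if trim_edge_peaks and len(centres) >= 6:
        centres = centres[1:-1]
    slope, _, r2 = fit_layer_spacing(centres)
    s = scaling_factor if isinstance(scaling_factor, UFloat) else UFloat(float(scaling_factor))
    corrected = correct_spacing(slope, s)
    theo = None if sigma_eff is None else fcc_layer_spacing(sigma_eff)
    return AxialResult(
        apparent_spacing=slope,
        r_squared=r2,
        scaling_factor=s,
        corrected_spacing=corrected,
        theoretical_d111=theo,
        n_peaks=len(centres),
    )
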