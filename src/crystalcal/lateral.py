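"""Lateral calibration from the in-plane periodicity of the crystal.

The (111) plane of the crystal lies parallel to the coverslip, so XY
slices show a (slightly anisotropic) hexagonal arrangement.  The Fourier
power spectrum of a slice has a six-fold peak arrangement; the first peaks
on the two scan-axis frequency profiles give the characteristic real-space
distances Delta_X and Delta_Y.  Because the particles touch along the
growth direction (Y by convention), the effective particle diameter is
sigma_eff = 2 * Delta_Y, which calibrates the lateral pixel sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from .datatypes import ImageStack, LateralResult, UFloat

__all__ = [
    "PowerSpectrum",
    "fft_power",
    "peak_spacing_along_axis",
    "calibrate_lateral",
    "effective_diameter",
    "lateral_pixel_calibration",
]


@dataclass
class PowerSpectrum:
    """2D power spectrum with DC at the centre and physical frequency axes."""

    power: np.ndarray  # (ny, nx)
    freq_y: np.ndarray  # cycles / nm
    freq_x: np.ndarray

    @property
    def dc_index(self) -> tuple[int, int]:
        return int(np.argmin(np.abs(self.freq_y))), int(np.argmin(np.abs(self.freq_x)))


def fft_power(
    image: np.ndarray,
    pixel_size: tuple[float, float],
    blur_px: float = 1.0,
    window: bool = True,
) -> PowerSpectrum:
    """Power spectrum of an XY slice with DC at the centre.

    A Hann window suppresses edge leakage before the FFT and a Gaussian
    blur of ``blur_px`` pixels (default 1, as in the reference workflow)
    reduces noise in the spectrum.  ``pixel_size`` is (dy, dx) in nm.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValueError("slice must be 2D and at least 64x64 px")
    dy, dx = pixel_size
    if dy <= 0 or dx <= 0:
        raise ValueError("pixel sizes must be > 0 (missing calibration?)")
    work = img - img.mean()
    if window:
        wy = np.hanning(img.shape[0])[:, None]
        wx = np.hanning(img.shape[1])[None, :]
        work = work * wy * wx
    spec = np.fft.fftshift(np.abs(np.fft.fft2(work)) ** 2)
    if blur_px and blur_px > 0:
        spec = gaussian_filter(spec, blur_px)
    fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0], d=dy))
    fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1], d=dx))
    return PowerSpectrum(power=spec, freq_y=fy, freq_x=fx)


def _gauss(f, amp, mu, sig, off):
    return amp * np.exp(-0.5 * ((f - mu) / sig) ** 2) + off


def _fit_peak(freqs: np.ndarray, profile: np.ndarray, i_peak: int, half_window: int = 3):
    """Least-squares Gaussian refinement of a profile peak; returns (f, sd)."""
    lo = max(i_peak - half_window, 0)
    hi = min(i_peak + half_window + 1, len(freqs))
    f = freqs[lo:hi]
    p = profile[lo:hi]
    df = abs(np.mean(np.diff(f)))
    p0 = [p.max() - p.min(), freqs[i_peak], df, p.min()]
    try:
        popt, pcov = curve_fit(_gauss, f, p, p0=p0, maxfev=5000)
        mu = float(popt[1])
        sd = float(math.sqrt(max(pcov[1, 1], 0.0)))
        if not (f[0] - df <= mu <= f[-1] + df):
            raise RuntimeError
    except (RuntimeError, ValueError):
        # fall back to the discrete bin with half-bin uncertainty
        mu, sd = float(freqs[i_peak]), df / 2.0
    return mu, sd


def _first_peak(freqs, profile, expected_freq=None, floor_factor=5.0,
                peak_frac=0.2, dc_exclude=4):
    """Index of the first usable non-DC peak on the positive-frequency side.

    A candidate must be a local maximum above both ``floor_factor`` x the
    median spectral floor and ``peak_frac`` x the strongest non-DC value
    (the PSF envelope makes the fundamental the strongest lattice peak, so
    this rejects leakage shoulders without skipping the fundamental).
    """
    pos = np.where(freqs > 0)[0]
    pos = pos[dc_exclude:] if len(pos) > dc_exclude else pos
    if len(pos) < 3:
        raise ValueError("profile too short for peak search")
    prof = profile[pos]
    floor = np.median(prof)
    if expected_freq is not None:
        band = (freqs[pos] >= 0.5 * expected_freq) & (freqs[pos] <= 2.0 * expected_freq)
        if not band.any():
            raise ValueError("expected frequency outside the searchable band")
        cand = pos[band]
        return int(cand[np.argmax(profile[cand])])
    thresh = max(floor_factor * floor, peak_frac * prof.max())
    for k in range(1, len(pos) - 1):
        if prof[k] > thresh and prof[k] >= prof[k - 1] and prof[k] >= prof[k + 1]:
            return int(pos[k])
    raise ValueError("no lattice periodicity detected")


def peak_spacing_along_axis(
    spectrum: PowerSpectrum,
    axis: str,
    expected_delta_nm: float | None = None,
) -> UFloat:
    """Real-space distance of the first spectral peak along a scan axis.

    Draws the frequency profile through the origin along ``axis`` ('y' or
    'x'), locates the first non-DC peak (within [0.5x, 2x] the expected
    frequency when one is configured), refines the +f and -f peaks by
    Gaussian least squares over a +-3-bin window, averages the pair and
    returns Delta = 1/f with the fit sd propagated (first-order).
    """
    iy0, ix0 = spectrum.dc_index
    if axis == "y":
        freqs, profile = spectrum.freq_y, spectrum.power[:, ix0]
    elif axis == "x":
        freqs, profile = spectrum.freq_x, spectrum.power[iy0, :]
    else:
        raise ValueError("axis must be 'y' or 'x'")

    exp_f = None if expected_delta_nm is None else 1.0 / expected_delta_nm
    results = []
    for sign in (+1, -1):
        f_s = sign * freqs
        i_peak = _first_peak(f_s, profile, expected_freq=exp_f)
        mu, sd = _fit_peak(f_s, profile, i_peak)
        results.append((abs(mu), sd))
    f_mean = float(np.mean([r[0] for r in results]))
    f_sd = float(np.linalg.norm([r[1] for r in results]) / 2.0)
    if f_mean <= 0:
        raise ValueError("no lattice periodicity detected")
    delta = 1.0 / f_mean
    return UFloat(delta, f_sd / f_mean**2)


def calibrate_lateral(
    stack: ImageStack,
    z_positions_um,
    growth_axis_hint: str | None = None,
    expected_delta_nm: dict | None = None,
    blur_px: float = 1.0,
) -> LateralResult:
    """Measure Delta_X / Delta_Y on XY slices and derive sigma_eff.

    ``z_positions_um`` are apparent distances from the coverslip (the
    reference workflow used 1.3, 3.6 and 5.9 um); each is mapped to the
    nearest plane.  The growth axis is the axis with the smaller real-space
    first-peak distance (particles touch along it, halving the projected
    period) unless a hint is given.  sigma_eff = 2 * Delta_growth.
    """
    dz, dy, dx = stack.voxel
    per_slice = []
    deltas = {"y": [], "x": []}
    expected_delta_nm = expected_delta_nm or {}
    for z_um in np.atleast_1d(z_positions_um):
        iz = int(round((z_um * 1000.0 - stack.origin[0]) / dz))
        if not 0 <= iz < stack.data.shape[0]:
            raise ValueError(f"slice at {z_um} um outside the stack")
        spec = fft_power(stack.data[iz], (dy, dx), blur_px=blur_px)
        row = {"z_um": float(z_um)}
        for ax in ("y", "x"):
            d = peak_spacing_along_axis(
                spec, ax, expected_delta_nm=expected_delta_nm.get(ax)
            )
            deltas[ax].append(d)
            row[f"delta_{ax}_nm"] = d.as_dict()
        per_slice.append(row)

    def _combine(vals: list[UFloat]) -> UFloat:
        v = np.array([u.value for u in vals])
        if len(v) > 1:
            return UFloat(float(v.mean()), float(v.std(ddof=1)))
        return vals[0]

    delta_y = _combine(deltas["y"])
    delta_x = _combine(deltas["x"])

    if growth_axis_hint is not None:
        growth = growth_axis_hint
    else:
        growth = "y" if delta_y.value < delta_x.value else "x"
    delta_growth = delta_y if growth == "y" else delta_x
    sigma = effective_diameter(delta_growth)
    return LateralResult(
        delta_x=delta_x,
        delta_y=delta_y,
        sigma_eff=sigma,
        growth_axis=growth,
        nm_per_px=(dy, dx),
        slices_used=[float(z) for z in np.atleast_1d(z_positions_um)],
        per_slice=per_slice,
    )


def effective_diameter(delta_growth: UFloat | float) -> UFloat:
    """Effective particle diameter from the growth-axis distance: 2 Delta."""
    u = delta_growth if isinstance(delta_growth, UFloat) else UFloat(float(delta_growth))
    if u.value <= 0:
        raise ValueError("delta_growth must be > 0")
    return UFloat(2.0 * u.value, 2.0 * u.sd)


def lateral_pixel_calibration(measured_delta_px: float, reference_delta_nm: float) -> float:
    """nm-per-pixel calibration factor from a measured lattice distance."""
    if measured_delta_px <= 0 or reference_delta_nm <= 0:
        raise ValueError("inputs must be > 0")
    return reference_delta_nm / measured_delta_px
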