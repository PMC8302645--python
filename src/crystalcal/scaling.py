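"""Axial scaling factor for refractive-index-mismatched samples.

High-NA confocal axial distances are distorted when the sample refractive
index differs from the immersion medium.  The correction chain measured
interferometrically: (1) the true cell height from Fabry-Perot fringes,
(2) the apparent height of the empty cell (giving the stage
miscalibration), (3) the apparent height of the solvent-filled cell,
corrected for the miscalibration, and finally s = h_true / h_corrected,
the multiplicative factor mapping apparent to true axial distances.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar

from .datatypes import ScalingMeasurement, UFloat

__all__ = [
    "height_from_fringes",
    "stage_miscalibration",
    "corrected_height",
    "scaling_factor",
    "scaling_chain",
]


def _as_ufloat(x) -> UFloat:
    return x if isinstance(x, UFloat) else UFloat(float(x))


def height_from_fringes(
    wavenumber: np.ndarray, intensity: np.ndarray, n_medium: float = 1.0
) -> UFloat:
    """Cell height (um) from the dominant Fabry-Perot fringe frequency.

    The fringe period in wavenumber is 1/(2 n h); the dominant frequency is
    located on a periodogram and refined by maximising the continuous DTFT
    magnitude between the neighbouring bins.  The sd follows the
    single-tone Cramer-Rao bound evaluated with the residual noise after
    subtracting the fitted cosine.
    """
    nu = np.asarray(wavenumber, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if nu.ndim != 1 or nu.shape != y.shape or len(nu) < 16:
        raise ValueError("need matching 1D wavenumber/intensity arrays")
    dnu = float(np.mean(np.diff(nu)))
    if dnu <= 0:
        raise ValueError("wavenumber grid must be increasing")
    span = nu[-1] - nu[0]
    yc = y - y.mean()

    # periodogram peak (exclude DC bin)
    spec = np.abs(np.fft.rfft(yc)) ** 2
    freqs = np.fft.rfftfreq(len(yc), d=dnu)  # "frequency" in cm (cycles per cm^-1)
    if len(spec) < 4:
        raise ValueError("spectrum too short")
    i0 = 1 + int(np.argmax(spec[1:]))
    peak, others = spec[i0], np.median(spec[1:])
    if others > 0 and peak < 20.0 * others:
        raise ValueError("no dominant fringe frequency found")
    if (freqs[i0] * span) < 5:
        raise ValueError("fewer than 5 fringes resolvable on the grid")

    def neg_dtft(f):
        ph = np.exp(-2j * np.pi * f * nu)
        return -np.abs(np.sum(yc * ph)) ** 2

    lo = freqs[max(i0 - 1, 1)]
    hi = freqs[min(i0 + 1, len(freqs) - 1)]
    res = minimize_scalar(neg_dtft, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    f_hat = float(res.x)  # = 2 n h, in cm

    # residual-noise Cramer-Rao bound for a single tone
    ph = np.exp(-2j * np.pi * f_hat * nu)
    c = np.sum(yc * ph) / len(nu)
    amp = 2.0 * abs(c)
    model = 2.0 * np.real(c * np.exp(2j * np.pi * f_hat * nu))
    sigma2 = float(np.var(yc - model))
    n = len(nu)
    if amp > 0 and sigma2 > 0:
        var_f = 12.0 * sigma2 / ((2.0 * np.pi * amp / 2.0) ** 2 * n * (n**2 - 1) * dnu**2)
        sd_f = math.sqrt(var_f)
    else:
        sd_f = 0.0

    h_cm = f_hat / (2.0 * n_medium)
    sd_cm = sd_f / (2.0 * n_medium)
    return UFloat(h_cm * 1e4, sd_cm * 1e4)  # um


def stage_miscalibration(h_apparent_empty, h_true) -> UFloat:
    """Fractional stage miscalibration: h_apparent_empty / h_true - 1."""
    he, ht = _as_ufloat(h_apparent_empty), _as_ufloat(h_true)
    if he.value <= 0 or ht.value <= 0:
        raise ValueError("heights must be > 0")
    return he / ht - 1.0


def corrected_height(h_apparent, miscalibration) -> UFloat:
    """Apparent height divided by (1 + miscalibration), sd propagated."""
    ha, m = _as_ufloat(h_apparent), _as_ufloat(miscalibration)
    denom = 1.0 + m.value
    if denom <= 0:
        raise ValueError("1 + miscalibration must be > 0")
    v = ha.value / denom
    sd = math.hypot(ha.sd / denom, ha.value * m.sd / denom**2)
    return UFloat(v, sd)


def scaling_factor(h_true, h_corrected) -> UFloat:
    """Axial scaling factor s = h_true / h_corrected."""
    ht, hc = _as_ufloat(h_true), _as_ufloat(h_corrected)
    if ht.value <= 0 or hc.value <= 0:
        raise ValueError("heights must be > 0")
    return ht / hc


def scaling_chain(
    h_true, h_apparent_empty, h_apparent_filled, n_medium: float | None = None
) -> ScalingMeasurement:
    """Compose the full measurement chain into a ScalingMeasurement."""
    ht = _as_ufloat(h_true)
    he = _as_ufloat(h_apparent_empty)
    hf = _as_ufloat(h_apparent_filled)
    m = stage_miscalibration(he, ht)
    hc = corrected_height(hf, m)
    s = scaling_factor(ht, hc)
    return ScalingMeasurement(
        h_true=ht,
        h_apparent_empty=he,
        h_apparent_filled=hf,
        miscalibration=m,
        h_corrected=hc,
        s=s,
        n_medium=n_medium,
    )
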