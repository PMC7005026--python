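"""Membrane-probe spectroscopy reductions.

Covers the four probe read-outs used to characterize reconstituted
membranes and the sensor construct embedded in them:

* C-Laurdan generalized polarization (GP) — two-channel contrast of the
  emission spectrum, +1 for the most ordered and −1 for the most
  disordered bilayer;
* ratiometric FRET (E_rel) between a donor/acceptor-labeled protomer pair,
  with acceptor-based normalization of the raw spectra;
* FCS autocorrelation fitting with a two-dimensional diffusion + triplet
  model, and conversion of the diffusion time to a diffusion coefficient;
* the semi-quantitative cwEPR proximity index I_Lf/I_Mf (low-field to
  mid-field first-derivative amplitude ratio).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lmfit import Parameters, minimize
from scipy.signal import find_peaks

from .containers import CorrelationCurve, EmissionSpectrum, EPRSpectrum

__all__ = [
    "gp",
    "acceptor_normalize",
    "fret_erel",
    "fcs_model",
    "FcsFit",
    "fit_fcs",
    "diffusion_coefficient",
    "epr_proximity_index",
]

GP_CH1 = (400.0, 460.0)  # nm, ordered-phase channel
GP_CH2 = (470.0, 530.0)  # nm, disordered-phase channel


def _band_integral(spectrum: EmissionSpectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral over [lo, hi], inserting exact band edges."""
    wl, inten = spectrum.wavelength, spectrum.intensity
    edges = np.array([lo, hi])
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.unique(np.concatenate([edges, inner]))
    vals = np.interp(grid, wl, inten)
    return float(np.trapezoid(vals, grid))


def gp(spectrum: EmissionSpectrum, blank: Optional[EmissionSpectrum] = None) -> float:
    """Generalized polarization of a C-Laurdan emission spectrum.

    GP = (I_Ch1 − I_Ch2) / (I_Ch1 + I_Ch2) with I_Ch1 the integral over
    400–460 nm and I_Ch2 over 470–530 nm, after optional blank subtraction
    (negative intensities clipped at zero).
    """
    if spectrum.wavelength[0] > GP_CH1[0] or spectrum.wavelength[-1] < GP_CH2[1]:
        raise ValueError(
            "spectrum must cover 400-530 nm; got "
            f"[{spectrum.wavelength[0]}, {spectrum.wavelength[-1]}] nm"
        )
    if blank is not None:
        if not np.array_equal(blank.wavelength, spectrum.wavelength):
            raise ValueError("blank must share the spectrum's wavelength grid")
        spectrum = EmissionSpectrum(
            wavelength=spectrum.wavelength,
            intensity=np.clip(spectrum.intensity - blank.intensity, 0.0, None),
            excitation=spectrum.excitation,
            blank_subtracted=True,
        )
    i_ch1 = _band_integral(spectrum, *GP_CH1)
    i_ch2 = _band_integral(spectrum, *GP_CH2)
    total = i_ch1 + i_ch2
    if total <= 0:
        raise ValueError("no intensity in either GP channel")
    return (i_ch1 - i_ch2) / total


def acceptor_normalize(
    donor_ex: EmissionSpectrum, acceptor_ex: EmissionSpectrum
) -> EmissionSpectrum:
    """Normalize a donor-excitation spectrum to the maximal acceptor signal.

    Dividing by the peak intensity after direct acceptor excitation corrects
    for variations in reconstitution yield between samples.
    """
    peak = float(np.max(acceptor_ex.intensity))
    if peak <= 0:
        raise ValueError("acceptor spectrum has no positive intensity")
    return EmissionSpectrum(
        wavelength=donor_ex.wavelength,
        intensity=donor_ex.intensity / peak,
        excitation=donor_ex.excitation,
        blank_subtracted=donor_ex.blank_subtracted,
    )


def fret_erel(
    spectrum: EmissionSpectrum,
    donor_wavelength: float = 525.0,
    acceptor_wavelength: float = 614.0,
) -> float:
    """Ratiometric FRET efficiency E_rel = I_A / (I_D + I_A).

    Intensities are read at the donor and acceptor emission wavelengths
    (default 525 and 614 nm) by linear interpolation on the native grid.
    """
    i_d = spectrum.interp(donor_wavelength)
    i_a = spectrum.interp(acceptor_wavelength)
    total = i_d + i_a
    if total <= 0:
        raise ValueError("donor + acceptor intensity is zero")
    return i_a / total


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------

def fcs_model(
    lag: np.ndarray, n_particles: float, tau_d: float, triplet: float, tau_t: float
) -> np.ndarray:
    """Two-dimensional diffusion + triplet autocorrelation model.

    G(tau) = (1 + T/(1−T) e^(−tau/tau_T)) · (1/N) · (1 + tau/tau_D)^(−1)
    """
    lag = np.asarray(lag, dtype=float)
    trip = 1.0 + (triplet / (1.0 - triplet)) * np.exp(-lag / tau_t)
    return trip / n_particles / (1.0 + lag / tau_d)


@dataclass
class FcsFit:
    """Result of a 2D+triplet fit to an autocorrelation curve."""

    n_particles: float
    tau_d: float
    triplet: float
    tau_t: float
    stderr: dict
    converged: bool
    residual_rms: float
    triplet_pinned: bool
    message: str = ""


def _fcs_initial_guess(curve: CorrelationCurve) -> tuple[float, float]:
    g0 = float(np.mean(curve.g[:3]))
    n0 = 1.0 / g0 if g0 > 0 else 1.0
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau_d0 = float(curve.lag[below[0]]) if len(below) else float(curve.lag[-1])
    return max(n0, 1e-6), tau_d0


def fit_fcs(curve: CorrelationCurve, with_triplet: bool = True) -> FcsFit:
    """Weighted least-squares fit of the 2D+triplet model to a curve.

    Initial guesses come from the curve itself (N from 1/G at small lags,
    tau_D from the half-amplitude lag).  Per-point SDs weight the residuals
    when present.  Non-convergence and a triplet fraction pinned at its
    bound are flagged rather than silently returned.
    """
    if len(curve.lag) < 8 or curve.lag[-1] / curve.lag[0] < 100.0:
        raise ValueError("curve must have >=8 points spanning >=2 decades of lag")
    n0, tau_d0 = _fcs_initial_guess(curve)
    tau_min, tau_max = float(curve.lag[0]), float(curve.lag[-1])

    params = Parameters()
    params.add("n_particles", value=n0, min=1e-9)
    params.add("tau_d", value=tau_d0, min=tau_min / 100.0, max=tau_max * 100.0)
    t_max = 0.9999
    params.add("triplet", value=0.1 if with_triplet else 0.0,
               min=0.0, max=t_max, vary=with_triplet)
    params.add("tau_t", value=max(5.0 * tau_min, 1e-7),
               min=tau_min / 100.0, max=tau_max, vary=with_triplet)

    weights = 1.0 / curve.sd if curve.sd is not None else None

    def residual(p):
        model = fcs_model(curve.lag, p["n_particles"].value, p["tau_d"].value,
                          p["triplet"].value, p["tau_t"].value)
        res = model - curve.g
        return res * weights if weights is not None else res

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = minimize(residual, params, method="leastsq")

    p = out.params
    res = residual(p)
    rms = float(np.sqrt(np.mean(np.asarray(res) ** 2)))
    pinned = bool(with_triplet and (
        p["triplet"].value >= t_max - 1e-6 or p["triplet"].value <= 1e-9
    ))
    # tau_d escaping to a bound means the decay time is not identifiable
    tau_d_pinned = (
        p["tau_d"].value >= tau_max * 100.0 * (1.0 - 1e-6)
        or p["tau_d"].value <= tau_min / 100.0 * (1.0 + 1e-6)
    )
    converged = bool(out.success) and bool(getattr(out, "errorbars", False)) \
        and not tau_d_pinned
    stderr = {
        name: (p[name].stderr if p[name].stderr is not None else float("nan"))
        for name in ("n_particles", "tau_d", "triplet", "tau_t")
    }
    return FcsFit(
        n_particles=float(p["n_particles"].value),
        tau_d=float(p["tau_d"].value),
        triplet=float(p["triplet"].value),
        tau_t=float(p["tau_t"].value),
        stderr=stderr,
        converged=converged,
        residual_rms=rms,
        triplet_pinned=pinned,
        message=str(out.message),
    )


def diffusion_coefficient(tau_d_s: float, beam_waist_um: float) -> float:
    """Diffusion coefficient from a 2D diffusion time: D = w² / (4 τ_D), µm²/s."""
    if tau_d_s <= 0 or beam_waist_um <= 0:
        raise ValueError("tau_D and beam waist must be positive")
    return beam_waist_um**2 / (4.0 * tau_d_s)


# ---------------------------------------------------------------------------
# cwEPR
# ---------------------------------------------------------------------------

def epr_proximity_index(
    spectrum: EPRSpectrum,
    min_prominence: float = 0.02,
    normalize: str = "max",
) -> float:
    """Semi-quantitative proximity index I_Lf / I_Mf of a cwEPR spectrum.

    The ratio of the low-field to the mid-field positive-lobe amplitude of
    the first-derivative spectrum; higher values indicate a shorter average
    interspin distance.  The mid-field line is taken as the tallest positive
    peak of the intensity-normalized spectrum and the low-field line as the
    strongest resolvable peak at lower field; the result is invariant to
    field offset and to global intensity rescaling.
    """
    amp = spectrum.amplitude.astype(float)
    span = float(np.max(amp) - np.min(amp))
    if span <= 0:
        raise ValueError("flat spectrum: no resolvable lines")
    if normalize == "max":
        amp = amp / np.max(np.abs(amp))
    elif normalize == "area":
        area = np.trapezoid(np.abs(amp), spectrum.field)
        amp = amp / area
    else:
        raise ValueError("normalize must be 'max' or 'area'")

    prominence = min_prominence * (np.max(amp) - np.min(amp))
    peaks, _ = find_peaks(amp, prominence=prominence)
    peaks = peaks[amp[peaks] > 0]
    if len(peaks) < 2:
        raise ValueError("fewer than two resolvable positive extrema")
    mid = peaks[np.argmax(amp[peaks])]
    low_candidates = peaks[peaks < mid]
    if len(low_candidates) == 0:
        raise ValueError("no resolvable low-field line below the mid-field line")
    low = low_candidates[np.argmax(amp[low_candidates])]
    i_mf = float(amp[mid])
    i_lf = float(amp[low])
    if i_mf <= 0:
        raise ValueError("mid-field amplitude is not positive")
    return i_lf / i_mf
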