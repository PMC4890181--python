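"""PAM fluorescence parameters and psi-type CD band amplitudes.

Saturating-pulse analysis extracts, for every annotated pulse, the maximal
fluorescence in the light F_m' (windowed maximum) and the preceding steady
state F (200-ms pre-window mean), from which the standard parameters follow:

    NPQ    = (F_m - F_m') / F_m'
    Phi_II = (F_m' - F)  / F_m'

CD spectra are normalized to the red-most absorption peak and psi-type band
amplitudes are read as two-point differences against fixed reference
wavelengths (505/550, 675/600 and 690/750 nm by default), with linear
interpolation between grid points.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import CdSpectrum, FluorTrace

__all__ = [
    "PamSeries",
    "PSI_BAND_PAIRS",
    "extract_pulse_values",
    "compute_npq",
    "compute_phi_ii",
    "analyze_pam",
    "normalize_cd",
    "psi_band_amplitude",
    "psi_band_amplitudes",
]

#: Default psi-type band / reference wavelength pairs (nm).
PSI_BAND_PAIRS = {"505": (505.0, 550.0), "675": (675.0, 600.0), "690": (690.0, 750.0)}


@dataclass
class PamSeries:
    """Per-pulse PAM quantities (arrays aligned with ``pulse_times``)."""

    pulse_times: np.ndarray
    f_m_prime: np.ndarray
    f_steady: np.ndarray
    npq: np.ndarray
    phi_ii: np.ndarray


def extract_pulse_values(
    trace: FluorTrace, window_ms: float = 800.0, steady_ms: float = 200.0
):
    """Per-pulse ``(f_m_prime, f_steady)`` arrays.

    ``f_m_prime`` is the fluorescence maximum within +-``window_ms``/2 of
    each pulse time, ``f_steady`` the mean of the ``steady_ms`` immediately
    preceding that window. Raises on pulses whose windows fall outside the
    trace or overlap each other.
    """
    pulses = trace.pulse_times
    if pulses.size == 0:
        return np.array([]), np.array([])
    half = window_ms / 2000.0
    steady = steady_ms / 1000.0
    if np.any(np.diff(pulses) < 2 * half):
        raise ValueError("overlapping pulse windows")
    fm_prime = np.empty(pulses.size)
    f_steady = np.empty(pulses.size)
    for k, tp in enumerate(pulses):
        if tp - half - steady < trace.time[0] - 1e-9 or tp + half > trace.time[-1] + 1e-9:
            raise ValueError(f"pulse window at {tp} s outside trace")
        win = (trace.time >= tp - half) & (trace.time <= tp + half)
        pre = (trace.time >= tp - half - steady) & (trace.time < tp - half)
        if not np.any(win) or not np.any(pre):
            raise ValueError(f"empty analysis window for pulse at {tp} s")
        fm_prime[k] = trace.fluorescence[win].max()
        f_steady[k] = trace.fluorescence[pre].mean()
    return fm_prime, f_steady


def compute_npq(f_m, f_m_prime):
    """Non-photochemical quenching, (F_m - F_m')/F_m'.

    A value below zero (F_m' exceeding the dark F_m) is returned with a
    warning; it flags an anomalous trace rather than a computational error.
    """
    f_m_prime = np.asarray(f_m_prime, dtype=float)
    if np.any(f_m_prime <= 0):
        raise ValueError("f_m_prime must be > 0")
    npq = (f_m - f_m_prime) / f_m_prime
    if np.any(np.asarray(npq) < 0):
        warnings.warn("negative NPQ: F_m' exceeds dark F_m", stacklevel=2)
    return npq if npq.ndim else float(npq)


def compute_phi_ii(f_m_prime, f_steady):
    """Photosystem II quantum yield, (F_m' - F)/F_m'."""
    f_m_prime = np.asarray(f_m_prime, dtype=float)
    if np.any(f_m_prime <= 0):
        raise ValueError("f_m_prime must be > 0")
    phi = (f_m_prime - np.asarray(f_steady, dtype=float)) / f_m_prime
    return phi if phi.ndim else float(phi)


def analyze_pam(
    trace: FluorTrace, window_ms: float = 800.0, steady_ms: float = 200.0
) -> PamSeries:
    """Full saturating-pulse analysis of a fluorescence trace."""
    fm_prime, f_steady = extract_pulse_values(trace, window_ms, steady_ms)
    return PamSeries(
        pulse_times=trace.pulse_times.copy(),
        f_m_prime=fm_prime,
        f_steady=f_steady,
        npq=np.asarray(compute_npq(trace.f_m, fm_prime)),
        phi_ii=np.asarray(compute_phi_ii(fm_prime, f_steady)),
    )


def normalize_cd(spectrum: CdSpectrum, red_peak_absorption: float) -> CdSpectrum:
    """Divide the CD signal by the red-most absorption-peak value.

    Applying factors a then b equals applying a*b once; the accumulated
    factor is recorded in ``normalization``.
    """
    if not red_peak_absorption > 0:
        raise ValueError("red_peak_absorption must be > 0")
    prior = spectrum.normalization or 1.0
    return CdSpectrum(
        wavelength_nm=spectrum.wavelength_nm.copy(),
        cd_signal=spectrum.cd_signal / red_peak_absorption,
        normalization=prior * red_peak_absorption,
        metadata=dict(spectrum.metadata),
    )


def _cd_at(spectrum: CdSpectrum, wavelength: float) -> float:
    wl = spectrum.wavelength_nm
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}] nm"
        )
    return float(np.interp(wavelength, wl, spectrum.cd_signal))


def psi_band_amplitude(
    spectrum: CdSpectrum, band_nm: float, reference_nm: float
) -> float:
    """Psi-type band amplitude: CD(band) - CD(reference).

    Two-point difference with linear interpolation; invariant to adding a
    constant offset to the whole spectrum.
    """
    return _cd_at(spectrum, band_nm) - _cd_at(spectrum, reference_nm)


def psi_band_amplitudes(spectrum: CdSpectrum, pairs: dict = None) -> dict:
    """Amplitudes for the standard band/reference pairs (505/550, 675/600,
    690/750 nm), or any mapping of name -> (band, reference)."""
    pairs = PSI_BAND_PAIRS if pairs is None else pairs
    return {
        name: psi_band_amplitude(spectrum, band, ref)
        for name, (band, ref) in pairs.items()
    }
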