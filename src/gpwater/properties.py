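"""Bulk-property estimators for liquid-water trajectories.

Every estimator follows the standard analysis protocol for this kind of
simulation study:

* radial distribution functions with the intramolecular pairs included by
  default (the convention used when comparing against scattering data that
  has the intramolecular peaks removed separately);
* self-diffusion from the Einstein relation (MSD slope / 6) with the
  hydrodynamic finite-size correction
  ``D_inf = D(L) + kB T xi / (6 pi eta L)``, ``xi = 2.837297`` for a cubic
  box;
* density maximum and thermal expansion from an analytically differentiated
  cubic fit of rho(T) / V(T);
* vaporisation enthalpy as the gas-liquid difference of per-molecule
  enthalpies; isobaric heat capacity as the derivative of a quadratic
  enthalpy fit;
* IR spectrum from the Fourier transform of the total-dipole autocorrelation
  with a selectable quantum correction factor (harmonic by default);
* static relative permittivity from the total-dipole fluctuation formula,
  with and without the ``<M>`` subtraction;
* ensemble uncertainties from leave-one-out cross-validation (RMS shift of
  the ensemble mean when one trajectory is dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import C_CM_PER_PS, COULOMB, HBAR, KB

__all__ = [
    "XI_CUBIC",
    "rdf",
    "msd",
    "diffusion_einstein",
    "yeh_hummer_correct",
    "cubic_fit_extremum",
    "rho_max",
    "thermal_expansion",
    "enthalpy_vaporization",
    "heat_capacity",
    "ir_spectrum",
    "relative_permittivity",
    "loo_uncertainty",
    "ensemble_spread",
]

#: periodic self-interaction constant of a cubic box (hydrodynamic
#: finite-size correction); reproduced by
#: :func:`gpwater.electrostatics.self_interaction_constant`.
XI_CUBIC = 2.837297

KB_SI = 1.380649e-23


# --------------------------------------------------------------------------
# structure

def rdf(frames, elements, molecules, pair: str, box_length: float,
        bin_width: float = 0.05, r_max: float | None = None,
        include_intramolecular: bool = True):
    """Shell-normalised radial distribution function.

    Parameters
    ----------
    frames : (n_frames, n_atoms, 3) positions
    elements : length n_atoms species labels
    molecules : (n_mol, 3) site indices (used only when excluding
        intramolecular pairs)
    pair : "OO", "OH" or "HH"
    r_max : defaults to L/2 and may not exceed it

    Returns ``(r_centres, g)``.
    """
    frames = np.asarray(frames, dtype=float)
    L = float(box_length)
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half box length {L / 2}")
    elements = np.asarray(elements)
    sp = {"O": elements == "O", "H": elements == "H"}
    a, b = pair[0], pair[1]
    idx_a = np.flatnonzero(sp[a])
    idx_b = np.flatnonzero(sp[b])

    mol_id = np.empty(elements.size, dtype=int)
    for m, idx in enumerate(np.asarray(molecules)):
        mol_id[idx] = m

    ii, jj = np.meshgrid(idx_a, idx_b, indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    if a == b:
        keep = ii < jj
    else:
        keep = np.ones(ii.size, dtype=bool)
    if not include_intramolecular:
        keep &= mol_id[ii] != mol_id[jj]
    ii, jj = ii[keep], jj[keep]

    nbins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    centres = 0.5 * (edges[1:] + edges[:-1])
    if ii.size == 0:
        return centres, np.zeros(nbins)
    hist = np.zeros(nbins)
    for pos in frames:
        d = pos[ii] - pos[jj]
        d -= L * np.round(d / L)
        r = np.sqrt(np.einsum("mi,mi->m", d, d))
        hist += np.histogram(r, bins=edges)[0]
    hist /= frames.shape[0]

    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # ideal-gas pair count in each shell for this pair selection
    n_pairs = ii.size * (2.0 if a == b else 1.0)  # ordered-pair density
    rho_pairs = n_pairs / L ** 3
    g = 2.0 * hist / (rho_pairs * shell) if a == b else hist / (rho_pairs * shell)
    return centres, g


# --------------------------------------------------------------------------
# diffusion

@dataclass
class DiffusionResult:
    D: float                 # A^2/ps
    slope: float             # MSD slope A^2/ps
    intercept: float
    linearity: float         # ratio of late/early window slopes (1 = linear)
    nonlinear: bool


def molecular_centers(frames, molecules, masses):
    """Centre-of-mass trajectory (n_frames, n_mol, 3); needs unwrapped input."""
    frames = np.asarray(frames, dtype=float)
    molecules = np.asarray(molecules)
    m = np.asarray(masses, dtype=float)[molecules]           # (n_mol, 3)
    w = m / m.sum(axis=1, keepdims=True)
    return np.einsum("fmsx,ms->fmx", frames[:, molecules], w)


def msd(centers, max_lag: int | None = None) -> np.ndarray:
    """Mean-squared displacement over all time origins (FFT-free, strided)."""
    centers = np.asarray(centers, dtype=float)
    n = centers.shape[0]
    if max_lag is None:
        max_lag = n // 2
    out = np.empty(max_lag + 1)
    out[0] = 0.0
    for lag in range(1, max_lag + 1):
        d = centers[lag:] - centers[:-lag]
        out[lag] = np.mean(np.einsum("fmx,fmx->fm", d, d))
    return out


def detect_wrapped(centers, box_length: float) -> bool:
    """Heuristic input guard: frame-to-frame jumps > L/2 mean wrapped input."""
    d = np.abs(np.diff(np.asarray(centers), axis=0))
    return bool(np.any(d > box_length / 2.0))


def diffusion_einstein(centers, dt_ps: float, fit_start: int, fit_stop: int,
                       box_length: float | None = None) -> DiffusionResult:
    """Einstein-relation diffusion: least-squares MSD slope / 6.

    ``fit_start``/``fit_stop`` select the lag window (in frames).  The
    ``linearity`` diagnostic compares the slopes of the two halves of the fit
    window; ballistic or arrested motion is flagged as nonlinear.
    """
    centers = np.asarray(centers, dtype=float)
    if box_length is not None and detect_wrapped(centers, box_length):
        raise ValueError("centre trajectory looks wrapped (jumps > L/2); "
                         "unwrapped coordinates are required")
    if fit_stop > centers.shape[0] - 1:
        raise ValueError("fit window extends beyond the trajectory")
    m = msd(centers, max_lag=fit_stop)
    lags = np.arange(fit_stop + 1) * dt_ps
    sel = slice(fit_start, fit_stop + 1)
    slope, intercept = np.polyfit(lags[sel], m[sel], 1)
    mid = (fit_start + fit_stop) // 2
    s1 = np.polyfit(lags[fit_start:mid + 1], m[fit_start:mid + 1], 1)[0]
    s2 = np.polyfit(lags[mid:fit_stop + 1], m[mid:fit_stop + 1], 1)[0]
    linearity = s2 / s1 if s1 != 0 else np.inf
    nonlinear = not (0.7 < linearity < 1.4)
    return DiffusionResult(D=slope / 6.0, slope=slope, intercept=intercept,
                           linearity=float(linearity), nonlinear=nonlinear)


def yeh_hummer_correct(D_L: float, box_length_m: float, temperature: float,
                       viscosity_pa_s: float) -> float:
    """Finite-size correction ``D_inf = D(L) + kB T xi / (6 pi eta L)`` (SI)."""
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be positive")
    if box_length_m <= 0 or temperature <= 0:
        raise ValueError("box length and temperature must be positive")
    return D_L + KB_SI * temperature * XI_CUBIC / (
        6.0 * math.pi * viscosity_pa_s * box_length_m)


# --------------------------------------------------------------------------
# fits in temperature

@dataclass
class ExtremumResult:
    T_extremum: float | None
    coeffs: np.ndarray
    kind: str                # "maximum", "minimum" or "none"


def cubic_fit_extremum(T, y, find: str = "maximum") -> ExtremumResult:
    """Least-squares cubic fit and the analytic interior extremum of it."""
    T = np.asarray(T, dtype=float)
    y = np.asarray(y, dtype=float)
    if T.size < 4:
        raise ValueError("need at least 4 temperatures for a cubic fit")
    c = np.polyfit(T, y, 3)
    der = np.polyder(c)
    roots = np.roots(der)
    roots = roots[np.isreal(roots)].real
    second = np.polyval(np.polyder(der), roots)
    want = second < 0 if find == "maximum" else second > 0
    inside = (roots >= T.min()) & (roots <= T.max()) & want
    if not np.any(inside):
        return ExtremumResult(T_extremum=None, coeffs=c, kind="none")
    r = roots[inside]
    vals = np.polyval(c, r)
    pick = int(np.argmax(vals)) if find == "maximum" else int(np.argmin(vals))
    return ExtremumResult(T_extremum=float(r[pick]), coeffs=c, kind=find)


def rho_max(T, density) -> ExtremumResult:
    """Temperature of maximum density from the cubic-fit protocol."""
    return cubic_fit_extremum(T, density, find="maximum")


def thermal_expansion(T, V):
    """alpha(T) = (1/V) dV/dT from an analytically differentiated cubic fit.

    Returns ``(alpha_on_grid, coeffs)``; alpha is negative wherever the
    fitted volume decreases with temperature.
    """
    T = np.asarray(T, dtype=float)
    V = np.asarray(V, dtype=float)
    if T.size < 4:
        raise ValueError("need at least 4 temperatures for a cubic fit")
    c = np.polyfit(T, V, 3)
    dv = np.polyval(np.polyder(c), T)
    vfit = np.polyval(c, T)
    return dv / vfit, c


def enthalpy_vaporization(T_gas, H_gas, T_liq, H_liq):
    """Per-molecule dH_vap(T) = H_gas - H_liq on a shared temperature grid."""
    T_gas = np.asarray(T_gas, dtype=float)
    T_liq = np.asarray(T_liq, dtype=float)
    if T_gas.shape != T_liq.shape or not np.allclose(T_gas, T_liq):
        raise ValueError("gas and liquid enthalpies must share a temperature grid")
    return np.asarray(H_gas, dtype=float) - np.asarray(H_liq, dtype=float)


def heat_capacity(T, H_liq):
    """C_P(T) = dH/dT of a quadratic fit of the liquid enthalpy.

    Returns ``(C_P_on_grid, coeffs)``.
    """
    T = np.asarray(T, dtype=float)
    H = np.asarray(H_liq, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 temperatures for a quadratic fit")
    if np.ptp(T) == 0:
        raise ValueError("degenerate temperature grid")
    c = np.polyfit(T, H, 2)
    return np.polyval(np.polyder(c), T), c


# --------------------------------------------------------------------------
# dipole-based properties

def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Unbiased ACF of each column via FFT, averaged over columns."""
    n = x.shape[0]
    x = x - x.mean(axis=0)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft((f * f.conj()).real, n=nfft, axis=0)[:n]
    acf /= (n - np.arange(n))[:, None]
    return acf.sum(axis=1)


def quantum_correction(kind: str, omega_ps: np.ndarray, temperature: float) -> np.ndarray:
    """Classical-to-quantum lineshape factors (choice is largely cosmetic).

    omega is angular frequency in rad/ps.
    """
    x = HBAR * omega_ps / (KB * temperature)     # beta hbar omega
    if kind == "none":
        return np.ones_like(x)
    if kind == "harmonic":
        out = np.ones_like(x)
        nz = x != 0
        out[nz] = x[nz] / (-np.expm1(-x[nz]))
        return out
    if kind == "standard":
        return 2.0 / (1.0 + np.exp(-x))
    if kind == "schofield":
        return np.exp(x / 2.0)
    raise ValueError(f"unknown quantum correction {kind!r}")


def ir_spectrum(M, dt_fs: float, temperature: float = 298.0,
                correction: str = "harmonic", window: str | None = None,
                max_wavenumber: float = 5000.0):
    """IR lineshape from the total-dipole ACF.

    Parameters
    ----------
    M : (n, 3) total system dipole time series (e*A), uniformly spaced
    dt_fs : sampling interval
    window : None (match the plain ACF transform) or "hann"

    Returns ``(wavenumbers_cm1, intensity)`` with the intensity normalised to
    a maximum of 1.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] != 3:
        raise ValueError("dipole series must be (n, 3)")
    n = M.shape[0]
    if n < 4:
        raise ValueError("dipole series too short")
    acf = _autocorrelation(M)
    if window == "hann":
        acf = acf * np.hanning(2 * n)[n:]
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    dt_ps = dt_fs * 1e-3
    spec = np.fft.rfft(acf)
    freq_ps = np.fft.rfftfreq(acf.size, d=dt_ps)      # 1/ps
    omega = 2.0 * math.pi * freq_ps
    intensity = spec.real * quantum_correction(correction, omega, temperature)
    wavenumber = freq_ps / C_CM_PER_PS
    keep = wavenumber <= max_wavenumber
    wavenumber, intensity = wavenumber[keep], intensity[keep]
    peak = np.abs(intensity).max()
    if peak > 0:
        intensity = intensity / peak
    return wavenumber, intensity


@dataclass
class PermittivityResult:
    eps_r: float             # with <M> subtracted (fluctuation formula)
    eps_r_no_mean: float     # assuming <M> = 0
    mean_M: np.ndarray
    warning: str | None = None


def relative_permittivity(M, volume_A3: float, temperature: float,
                          min_samples: int = 100) -> PermittivityResult:
    """Static dielectric constant from total-dipole fluctuations.

    ``eps_r = 1 + 4 pi ke (<M^2> - <M>^2) / (3 V kB T)`` in this package's
    units (M in e*A, V in A^3); the variant that drops ``<M>`` (valid for a
    long, well-sampled trajectory) is reported alongside.
    """
    M = np.asarray(M, dtype=float)
    mean = M.mean(axis=0)
    fluct = float(np.mean(np.einsum("ni,ni->n", M, M)) - mean @ mean)
    raw = float(np.mean(np.einsum("ni,ni->n", M, M)))
    pref = 4.0 * math.pi * COULOMB / (3.0 * volume_A3 * KB * temperature)
    warning = None
    if M.shape[0] < min_samples:
        warning = (f"only {M.shape[0]} samples; the dipole fluctuation is "
                   "unlikely to be converged")
    return PermittivityResult(eps_r=1.0 + pref * fluct,
                              eps_r_no_mean=1.0 + pref * raw,
                              mean_M=mean, warning=warning)


# --------------------------------------------------------------------------
# ensemble uncertainty

def loo_uncertainty(estimates) -> float:
    """RMS shift of the ensemble mean under leave-one-out removal."""
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise ValueError("leave-one-out needs at least 2 trajectories")
    total = x.mean()
    loo = (x.sum() - x) / (x.size - 1)
    return float(np.sqrt(np.mean((total - loo) ** 2)))


def ensemble_spread(mean_estimate: float, per_box_estimates) -> float:
    """RMS deviation between an ensemble-average estimate and the per-box
    values (the convention used for diffusion-coefficient uncertainties)."""
    x = np.asarray(per_box_estimates, dtype=float)
    return float(np.sqrt(np.mean((x - mean_estimate) ** 2)))
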