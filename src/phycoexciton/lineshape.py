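"""Spectral densities, lineshape functions and homogeneous optical spectra.

Two levels of theory are provided for the multichromophoric spectra:

``modified_redfield``
    secular response: one stick per exciton state at its eigenenergy,
    broadened by the exciton-weighted lineshape function
    ``g_k(t) = sum_n C_nk^4 g_n(t)`` plus exponential lifetime damping with
    half the total modified-Redfield depopulation rate.

``cumulant``
    second-order cumulant response in the exciton basis: the same diagonal
    lineshape plus the non-Markovian, frequency-dependent lifetime kernel
    built from off-diagonal exciton fluctuations (its Markovian limit is the
    Redfield depopulation rate).

Both reduce exactly to the monomer response
``Re integral exp(i(w - eps) t - g(t)) dt`` for a single site.

Units: energies/wavenumbers cm^-1, time fs; a phase ``w t`` is
``TWO_PI_C * nu * t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from .exciton import ExcitonStates, ExcitonSystem, diagonalize
from .units import KB_CM1, TWO_PI_C, C_CM_PER_FS, thermal_energy


class LineshapeError(ValueError):
    """Raised on invalid lineshape input or non-converged quadrature."""


# ---------------------------------------------------------------------------
# Spectral density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VibronicMode:
    """Damped intramolecular mode: frequency, Huang-Rhys factor, damping (cm^-1)."""

    omega: float
    huang_rhys: float
    gamma: float = 10.0

    def __post_init__(self):
        if self.omega <= 0:
            raise LineshapeError(f"mode frequency must be positive, got {self.omega}")
        if self.huang_rhys < 0:
            raise LineshapeError("Huang-Rhys factor must be non-negative")
        if self.gamma < 0:
            raise LineshapeError("mode damping must be non-negative")

    @property
    def reorganization(self) -> float:
        """lambda_j = S_j * omega_j in cm^-1."""
        return self.huang_rhys * self.omega


@dataclass(frozen=True)
class SpectralDensity:
    """Overdamped Brownian oscillator continuum plus discrete vibronic modes.

    J(w) = 2 lambda_c gamma_c w / (w^2 + gamma_c^2)
         + sum_j 2 lambda_j omega_j^2 gamma_j w / ((w^2 - omega_j^2)^2 + gamma_j^2 w^2)
    """

    lambda_c: float = 0.0
    gamma_c: float = 53.0
    modes: tuple[VibronicMode, ...] = ()

    def __post_init__(self):
        if self.lambda_c < 0:
            raise LineshapeError("lambda_c must be non-negative")
        if self.gamma_c <= 0:
            raise LineshapeError("gamma_c must be positive")
        object.__setattr__(self, "modes", tuple(self.modes))

    @property
    def reorganization(self) -> float:
        """Total reorganization energy lambda = lambda_c + sum_j S_j omega_j."""
        return self.lambda_c + sum(m.reorganization for m in self.modes)

    @classmethod
    def from_dict(cls, data: dict) -> "SpectralDensity":
        modes = tuple(
            VibronicMode(
                omega=float(m["omega_cm1"]),
                huang_rhys=float(m["S"]),
                gamma=float(m.get("gamma_cm1", 10.0)),
            )
            for m in data.get("modes", ())
        )
        return cls(
            lambda_c=float(data.get("lambda_c_cm1", 0.0)),
            gamma_c=float(data.get("gamma_c_cm1", 53.0)),
            modes=modes,
        )

    def to_dict(self) -> dict:
        return {
            "lambda_c_cm1": self.lambda_c,
            "gamma_c_cm1": self.gamma_c,
            "modes": [
                {"omega_cm1": m.omega, "S": m.huang_rhys, "gamma_cm1": m.gamma}
                for m in self.modes
            ],
        }


def read_spectral_density(path) -> SpectralDensity:
    return SpectralDensity.from_dict(json.loads(Path(path).read_text()))


def write_spectral_density(sd: SpectralDensity, path) -> None:
    Path(path).write_text(json.dumps(sd.to_dict(), indent=1))


def evaluate_J(sd: SpectralDensity, omega_grid) -> np.ndarray:
    """Evaluate J(w) on a non-negative wavenumber grid (cm^-1).

    Undamped modes (gamma == 0) are delta functions and contribute nothing to
    the plotted density; they are handled analytically in the lineshape.
    """
    w = np.asarray(omega_grid, dtype=float)
    if np.any(w < 0):
        raise LineshapeError("evaluate_J requires a non-negative frequency grid")
    J = 2.0 * sd.lambda_c * sd.gamma_c * w / (w**2 + sd.gamma_c**2)
    for m in sd.modes:
        if m.gamma == 0:
            continue
        J = J + (
            2.0 * m.reorganization * m.omega**2 * m.gamma * w
            / ((w**2 - m.omega**2) ** 2 + (m.gamma * w) ** 2)
        )
    return J


def reorganization_energy(sd: SpectralDensity) -> float:
    """Closed-form total reorganization energy (cm^-1)."""
    return sd.reorganization


def stokes_calibrate(target_stokes: float, modes: Sequence[VibronicMode] = ()) -> float:
    """Continuum reorganization energy reproducing a target Stokes shift.

    The Stokes shift of a single site is ``2 * (lambda_c + sum_j S_j omega_j)``;
    solve for lambda_c.  Raises if the vibronic part alone already exceeds the
    target.
    """
    lambda_v = sum(m.reorganization for m in modes)
    lambda_c = 0.5 * target_stokes - lambda_v
    if lambda_c < 0:
        raise LineshapeError(
            f"target Stokes shift {target_stokes} cm^-1 is infeasible: vibronic "
            f"reorganization alone gives {2 * lambda_v} cm^-1"
        )
    return lambda_c


# ---------------------------------------------------------------------------
# Lineshape function g(t)
# ---------------------------------------------------------------------------

DEFAULT_TIME_GRID = np.arange(0.0, 3000.0 + 1e-9, 1.0)  # fs


@dataclass(frozen=True)
class LineshapeTable:
    """g(t) and derivatives sampled on a uniform time grid.

    ``g`` is dimensionless; ``gdot`` is in fs^-1 and ``gddot`` in fs^-2
    (derivatives with respect to time in fs).  ``reorganization`` is the
    closed-form lambda in cm^-1.
    """

    time: np.ndarray          # fs, uniform, starting at 0
    g: np.ndarray             # complex
    gdot: np.ndarray          # complex, fs^-1
    gddot: np.ndarray         # complex, fs^-2
    reorganization: float     # cm^-1
    temperature: float        # K
    spectral_density: SpectralDensity = None

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def _quadrature_grid(sd: SpectralDensity, kt: float, t_max: float) -> np.ndarray:
    """Frequency grid for the g(t) quadrature.

    Log-spaced points resolve the low-frequency OBO shoulder; a linear section
    resolves the cos/sin oscillations (period 1/(c t_max)) up to a cutoff
    beyond which every remaining integrand decays at least like 1/nu^3.
    Damped modes get dense local windows.
    """
    g = sd.gamma_c
    gammas = [m.gamma for m in sd.modes if m.gamma > 0]
    nu_hi = max(4000.0, 8.0 * kt, 20.0 * g,
                *[m.omega + 25.0 * m.gamma for m in sd.modes if m.gamma > 0] or [0.0])
    dnu = min(1.5, g / 8.0, *[gj / 8.0 for gj in gammas] or [np.inf],
              1.0 / (C_CM_PER_FS * max(t_max, 1.0) * 8.0))
    lo_edge = min(10.0, g)
    pieces = [
        np.geomspace(g * 1e-6, lo_edge, 800),
        np.arange(lo_edge, nu_hi, dnu),
    ]
    grid = np.unique(np.concatenate(pieces))
    return grid


def lineshape_function(
    sd: SpectralDensity,
    temperature: float = 300.0,
    time_grid: np.ndarray | None = None,
) -> LineshapeTable:
    """Second-order lineshape function from J(w) with detailed balance.

    g(t) = (1/pi) int dw J(w)/w^2 [coth(w/2kT)(1 - cos wt) + i(sin wt - wt)]

    evaluated by trapezoidal quadrature on an adaptive frequency grid;
    undamped modes are added in closed form.  The quadrature is validated
    against the closed-form reorganization energy (0.5%); failure raises
    rather than silently truncating.
    """
    kt = thermal_energy(temperature)
    t = DEFAULT_TIME_GRID.copy() if time_grid is None else np.asarray(time_grid, float)
    if t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise LineshapeError("time grid must start at 0 and increase")

    n_t = len(t)
    g = np.zeros(n_t, dtype=complex)
    gdot = np.zeros(n_t, dtype=complex)
    gddot = np.zeros(n_t, dtype=complex)

    damped_modes = [m for m in sd.modes if m.gamma > 0 and m.huang_rhys > 0]
    has_continuum = sd.lambda_c > 0 or damped_modes

    if has_continuum:
        cont_sd = SpectralDensity(sd.lambda_c, sd.gamma_c, tuple(damped_modes))
        nu = _quadrature_grid(cont_sd, kt, float(t[-1]))
        J = evaluate_J(cont_sd, nu)
        # convergence guard: quadrature lambda (plus the analytic OBO tail
        # beyond the cutoff) must match the closed form
        lam_closed = cont_sd.reorganization
        obo_tail = sd.lambda_c * (1.0 - (2.0 / np.pi) * np.arctan(nu[-1] / sd.gamma_c))
        lam_quad = np.trapezoid(J / nu, nu) / np.pi + obo_tail
        if abs(lam_quad - lam_closed) > 5e-3 * max(lam_closed, 1e-12):
            raise LineshapeError(
                "spectral-density quadrature did not converge: "
                f"lambda {lam_quad:.4f} vs closed form {lam_closed:.4f} cm^-1"
            )
        coth = 1.0 / np.tanh(nu / (2.0 * kt))
        J2 = J / nu**2
        J1 = J / nu
        # the secular -i*lambda*t term of Im g (and its derivative) is exact;
        # only oscillatory integrands are quadratured, so truncation at nu_hi
        # costs O(1/nu_hi^3)
        chunk = 128
        for i0 in range(0, n_t, chunk):
            tt = t[i0 : i0 + chunk, None]
            phi = TWO_PI_C * nu[None, :] * tt
            cos_phi, sin_phi = np.cos(phi), np.sin(phi)
            g_re = np.trapezoid(J2 * coth * (1.0 - cos_phi), nu, axis=1)
            g_im = np.trapezoid(J2 * sin_phi, nu, axis=1)
            gd_re = np.trapezoid(J1 * coth * sin_phi, nu, axis=1)
            gd_im = np.trapezoid(J1 * cos_phi, nu, axis=1)
            gdd_re = np.trapezoid(J * coth * cos_phi, nu, axis=1)
            gdd_im = np.trapezoid(-J * sin_phi, nu, axis=1)
            sl = slice(i0, i0 + len(tt))
            tt1 = tt[:, 0]
            g[sl] += (g_re + 1j * g_im) / np.pi - 1j * TWO_PI_C * lam_closed * tt1
            gdot[sl] += TWO_PI_C * ((gd_re + 1j * gd_im) / np.pi - 1j * lam_closed)
            gddot[sl] += TWO_PI_C**2 * (gdd_re + 1j * gdd_im) / np.pi

    # undamped modes in closed form
    for m in sd.modes:
        if m.gamma > 0 or m.huang_rhys == 0:
            continue
        S, w = m.huang_rhys, m.omega
        coth = 1.0 / np.tanh(w / (2.0 * kt))
        phi = TWO_PI_C * w * t
        g += S * (coth * (1.0 - np.cos(phi)) + 1j * (np.sin(phi) - phi))
        gdot += S * TWO_PI_C * w * (coth * np.sin(phi) + 1j * (np.cos(phi) - 1.0))
        gddot += S * (TWO_PI_C * w) ** 2 * (coth * np.cos(phi) - 1j * np.sin(phi))

    return LineshapeTable(
        time=t, g=g, gdot=gdot, gddot=gddot,
        reorganization=sd.reorganization, temperature=temperature,
        spectral_density=sd,
    )


def _broadcast_lineshapes(
    lineshapes, n_sites: int
) -> list[LineshapeTable]:
    """Accept a single shared table or one per site."""
    if isinstance(lineshapes, LineshapeTable):
        return [lineshapes] * n_sites
    tables = list(lineshapes)
    if len(tables) != n_sites:
        raise LineshapeError(
            f"need one lineshape per site: got {len(tables)} for {n_sites} sites"
        )
    t0 = tables[0].time
    for tab in tables[1:]:
        if len(tab.time) != len(t0) or not np.allclose(tab.time, t0):
            raise LineshapeError("per-site lineshapes must share one time grid")
    return tables


# ---------------------------------------------------------------------------
# Modified Redfield rates
# ---------------------------------------------------------------------------

def modified_redfield_rates(
    states: ExcitonStates,
    lineshapes,
    temperature: float = 300.0,
    tail_tolerance: float = 0.02,
) -> np.ndarray:
    """Modified-Redfield rate matrix K (fs^-1) for uncorrelated site baths.

    ``K[kp, k]`` is the transfer rate from exciton state k to kp (kp != k);
    the diagonal carries minus the column sums, so the lifetime of state k is
    ``-1 / K[k, k]``.  For localized states (no shared site amplitude) all
    interstate rates vanish identically.
    """
    n = states.n_states
    tables = _broadcast_lineshapes(lineshapes, n)
    t = tables[0].time

    C = states.coefficients
    g_site = np.array([tab.g for tab in tables])        # (n, nt)
    gd_site = np.array([tab.gdot for tab in tables])
    gdd_site = np.array([tab.gddot for tab in tables])
    lam_site = np.array([tab.reorganization for tab in tables])

    def combo(a, b, c, d, arr):
        w = C[:, a] * C[:, b] * C[:, c] * C[:, d]       # (n_sites,)
        return np.tensordot(w, arr, axes=(0, 0))

    def lam_combo(a, b, c, d):
        w = C[:, a] * C[:, b] * C[:, c] * C[:, d]
        return float(np.dot(w, lam_site))

    K = np.zeros((n, n))
    eps = states.energies
    for k in range(n):
        for kp in range(n):
            if kp == k:
                continue
            w_mix = C[:, k] ** 2 * C[:, kp] ** 2
            if not np.any(np.abs(w_mix) > 1e-300):
                continue
            g_kkkk = combo(k, k, k, k, g_site)
            g_pppp = combo(kp, kp, kp, kp, g_site)
            g_kkpp = combo(k, k, kp, kp, g_site)
            gdd_kpkp = combo(k, kp, kp, k, gdd_site)
            gd_a = combo(k, kp, k, k, gd_site)
            gd_b = combo(k, kp, kp, kp, gd_site)
            lam_a = lam_combo(k, kp, k, k)
            phase = (
                1j * TWO_PI_C * (eps[k] - eps[kp]) * t
                - 2j * TWO_PI_C * (lam_combo(k, k, k, k) - lam_combo(k, k, kp, kp)) * t
            )
            envelope = np.exp(phase - g_kkkk - g_pppp + 2.0 * g_kkpp)
            bracket = gdd_kpkp - (gd_a - gd_b + 2j * TWO_PI_C * lam_a) ** 2
            integrand = envelope * bracket
            peak = np.max(np.abs(integrand))
            if peak > 0 and np.abs(integrand[-1]) > tail_tolerance * peak:
                raise LineshapeError(
                    "modified-Redfield integrand has not decayed on the time "
                    f"grid (tail {np.abs(integrand[-1]) / peak:.2e} of peak); "
                    "extend the grid"
                )
            rate = 2.0 * np.trapezoid(integrand.real, t)
            K[kp, k] = max(rate, 0.0)
    np.fill_diagonal(K, 0.0)
    K[np.diag_indices(n)] = -K.sum(axis=0)
    return K


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    """Spectra on a strictly increasing wavenumber grid (arbitrary units)."""

    wavenumber: np.ndarray
    od: np.ndarray | None = None
    cd: np.ndarray | None = None
    flu: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        if np.any(np.diff(self.wavenumber) <= 0):
            raise LineshapeError("wavenumber grid must be strictly increasing")

    def shifted(self, delta: float) -> "SpectrumResult":
        """Rigidly translate the spectrum by +delta cm^-1."""
        meta = dict(self.metadata)
        meta["shift_cm1"] = meta.get("shift_cm1", 0.0) + delta
        return SpectrumResult(
            wavenumber=self.wavenumber + delta,
            od=self.od, cd=self.cd, flu=self.flu, metadata=meta,
        )

    def channels(self) -> dict:
        return {
            name: arr
            for name, arr in (("od", self.od), ("cd", self.cd), ("flu", self.flu))
            if arr is not None
        }


def default_wavenumber_grid(system: ExcitonSystem, margin: float = 3000.0,
                            step: float = 2.0) -> np.ndarray:
    e = system.energies
    return np.arange(e.min() - margin, e.max() + margin + step, step)


_PAD = 1 << 16  # zero-padded FFT length; 1 fs sampling -> ~0.51 cm^-1 resolution


def _tail_window(n: int, frac: float = 0.1) -> np.ndarray:
    """Cosine-squared ramp to zero over the last `frac` of the grid."""
    w = np.ones(n)
    n_tail = max(int(n * frac), 2)
    s = np.linspace(0.0, 1.0, n_tail)
    w[-n_tail:] = np.cos(0.5 * np.pi * s) ** 2
    return w


def _half_fourier(f_t: np.ndarray, dt: float, detunings: np.ndarray) -> np.ndarray:
    """Re of the half-Fourier transform of f(t), evaluated at detunings (cm^-1).

    Computes ``Re[ dt * (sum_j f_j exp(i w t_j) - f_0/2) ]`` (trapezoid rule;
    the endpoint term vanishes because f is tail-damped) on the FFT grid, then
    interpolates with a cubic spline.
    """
    n = len(f_t)
    F = _PAD * np.fft.ifft(f_t, n=_PAD)       # sum_j f_j exp(+2pi i jk/PAD)
    spectrum = dt * (F - 0.5 * f_t[0])
    freqs = np.fft.fftfreq(_PAD, d=dt * C_CM_PER_FS)   # cm^-1
    order = np.argsort(freqs)
    freqs, spectrum = freqs[order], spectrum[order]
    lo, hi = np.min(detunings), np.max(detunings)
    if lo < freqs[0] or hi > freqs[-1]:
        raise LineshapeError("requested wavenumber grid exceeds the FFT bandwidth")
    margin = 60.0
    sel = (freqs >= lo - margin) & (freqs <= hi + margin)
    spline = CubicSpline(freqs[sel], spectrum[sel].real)
    return spline(detunings)


def _exciton_lineshape_exponents(
    states: ExcitonStates, tables: list[LineshapeTable], theory: str,
    rates: np.ndarray | None, temperature: float,
):
    """Per-state complex exponent h_k(t): response f_k = exp(-i eps_k t - h_k)."""
    n = states.n_states
    t = tables[0].time
    C = states.coefficients
    g_site = np.array([tab.g for tab in tables])
    lam_site = np.array([tab.reorganization for tab in tables])

    h = np.empty((n, len(t)), dtype=complex)
    lam_k = np.empty(n)
    for k in range(n):
        w_diag = C[:, k] ** 4
        h[k] = np.tensordot(w_diag, g_site, axes=(0, 0))
        lam_k[k] = float(np.dot(w_diag, lam_site))

    if theory == "modified_redfield":
        if n > 1:
            if rates is None:
                rates = modified_redfield_rates(states, tables, temperature)
            depop = -np.diag(rates)                     # fs^-1
            h += 0.5 * depop[:, None] * t[None, :]
    elif theory == "cumulant":
        gdd_site = np.array([tab.gddot for tab in tables])
        eps = states.energies
        for k in range(n):
            for kp in range(n):
                if kp == k:
                    continue
                w_mix = C[:, k] ** 2 * C[:, kp] ** 2
                if not np.any(np.abs(w_mix) > 1e-300):
                    continue
                corr = np.tensordot(w_mix, gdd_site, axes=(0, 0))
                kernel = corr * np.exp(-1j * TWO_PI_C * (eps[kp] - eps[k]) * t)
                # int_0^t (t - tau) kernel(tau) dtau = t*H1 - H2
                H1 = cumulative_trapezoid(kernel, t, initial=0.0)
                H2 = cumulative_trapezoid(kernel * t, t, initial=0.0)
                h[k] += t * H1 - H2
    else:
        raise LineshapeError(f"unknown theory {theory!r}")
    return h, lam_k, rates


def _spectrum(
    states: ExcitonStates, tables, weights: np.ndarray, grid: np.ndarray,
    theory: str, rates, temperature: float, emission: bool,
    clip_negative: bool,
) -> np.ndarray:
    tables = _broadcast_lineshapes(tables, states.n_states)
    t = tables[0].time
    dt = tables[0].dt
    window = _tail_window(len(t))
    h, lam_k, _ = _exciton_lineshape_exponents(states, tables, theory, rates, temperature)
    out = np.zeros_like(grid, dtype=float)
    for k in range(states.n_states):
        if weights[k] == 0.0:
            continue
        if emission:
            # response exp(i(w - eps + 2 lam) t - g*(t)): fold the +2 lam
            # phase into the stick position
            stick = states.energies[k] - 2.0 * lam_k[k]
            f_t = window * np.exp(-np.conj(h[k]))
        else:
            stick = states.energies[k]
            f_t = window * np.exp(-h[k])
        out += weights[k] * _half_fourier(f_t, dt, grid - stick)
    if clip_negative:
        # quadrature ripple can undershoot zero at the 1e-8-of-peak level;
        # clamp it so OD/FLU stay non-negative
        floor = -1e-6 * max(np.max(np.abs(out)), 1e-300)
        out[(out < 0) & (out > floor)] = 0.0
    return out


def absorption_spectrum(
    states: ExcitonStates,
    system: ExcitonSystem,
    lineshapes,
    rates: np.ndarray | None = None,
    theory: str = "modified_redfield",
    wavenumber_grid: np.ndarray | None = None,
    temperature: float = 300.0,
) -> SpectrumResult:
    """Homogeneous absorption spectrum (dipole-strength weighted sticks)."""
    grid = default_wavenumber_grid(system) if wavenumber_grid is None else np.asarray(wavenumber_grid, float)
    od = _spectrum(states, lineshapes, states.dipole_strengths, grid, theory,
                   rates, temperature, emission=False, clip_negative=True)
    return SpectrumResult(wavenumber=grid, od=od,
                          metadata={"theory": theory, "temperature_K": temperature})


def cd_spectrum(
    states: ExcitonStates,
    system: ExcitonSystem,
    lineshapes,
    rates: np.ndarray | None = None,
    theory: str = "modified_redfield",
    wavenumber_grid: np.ndarray | None = None,
    temperature: float = 300.0,
) -> SpectrumResult:
    """Circular dichroism: rotational-strength weighted sticks, same lineshapes."""
    grid = default_wavenumber_grid(system) if wavenumber_grid is None else np.asarray(wavenumber_grid, float)
    cd = _spectrum(states, lineshapes, states.rotational_strengths, grid, theory,
                   rates, temperature, emission=False, clip_negative=False)
    return SpectrumResult(wavenumber=grid, cd=cd,
                          metadata={"theory": theory, "temperature_K": temperature})


def fluorescence_spectrum(
    states: ExcitonStates,
    system: ExcitonSystem,
    lineshapes,
    temperature: float = 300.0,
    theory: str = "modified_redfield",
    rates: np.ndarray | None = None,
    wavenumber_grid: np.ndarray | None = None,
) -> SpectrumResult:
    """Fluorescence with Boltzmann-weighted emitting-state populations.

    Each exciton emits at ``eps_k - 2 lambda_k`` (Stokes shift of 2 lambda for
    a monomer) with the conjugate lineshape; populations are
    ``exp(-eps_k / kT)`` normalized over states.
    """
    if temperature <= 0:
        raise LineshapeError("temperature must be positive")
    grid = default_wavenumber_grid(system) if wavenumber_grid is None else np.asarray(wavenumber_grid, float)
    eps = states.energies
    kt = KB_CM1 * temperature
    pop = np.exp(-(eps - eps.min()) / kt)
    pop /= pop.sum()
    weights = pop * states.dipole_strengths
    flu = _spectrum(states, lineshapes, weights, grid, theory, rates,
                    temperature, emission=True, clip_negative=True)
    return SpectrumResult(wavenumber=grid, flu=flu,
                          metadata={"theory": theory, "temperature_K": temperature})


def homogeneous_spectra(
    system: ExcitonSystem,
    lineshapes,
    theory: str = "modified_redfield",
    temperature: float = 300.0,
    wavenumber_grid: np.ndarray | None = None,
) -> SpectrumResult:
    """OD, CD and FLU of one system in a single result (shared rates)."""
    states = diagonalize(system)
    tables = _broadcast_lineshapes(lineshapes, system.n_sites)
    rates = None
    if theory == "modified_redfield" and system.n_sites > 1:
        rates = modified_redfield_rates(states, tables, temperature)
    grid = default_wavenumber_grid(system) if wavenumber_grid is None else np.asarray(wavenumber_grid, float)
    od = absorption_spectrum(states, system, tables, rates, theory, grid, temperature)
    cd = cd_spectrum(states, system, tables, rates, theory, grid, temperature)
    flu = fluorescence_spectrum(states, system, tables, temperature, theory, rates, grid)
    return SpectrumResult(wavenumber=grid, od=od.od, cd=cd.cd, flu=flu.flu,
                          metadata={"theory": theory, "temperature_K": temperature})


def write_spectrum_csv(result: SpectrumResult, path) -> None:
    """CSV with `# key: value` metadata header lines."""
    lines = [f"# {k}: {v}" for k, v in sorted(result.metadata.items())]
    chans = result.channels()
    cols = ["wavenumber_cm1"] + list(chans)
    lines.append(",".join(cols))
    data = np.column_stack([result.wavenumber] + [chans[c] for c in chans])
    for row in data:
        lines.append(",".join(f"{x:.8g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path) -> SpectrumResult:
    meta = {}
    rows = []
    header = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif header is None:
            header = line.split(",")
        elif line.strip():
            rows.append([float(x) for x in line.split(",")])
    arr = np.array(rows)
    kwargs = {}
    for i, col in enumerate(header):
        if col in ("od", "cd", "flu"):
            kwargs[col] = arr[:, i]
    return SpectrumResult(wavenumber=arr[:, 0], metadata=meta, **kwargs)
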