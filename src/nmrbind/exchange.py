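"""Two-site chemical-exchange forward models for in-phase 15N coherences.

The transverse magnetization of a spin exchanging between a free state A
(resonance offset 0, rate R2A) and a ligand-bound state B (offset
``delta_omega`` rad/s, rate R2B) evolves under the 2x2 complex matrix::

    L = [[-R2A - k_on_app,  k_off               ],
         [ k_on_app,       -R2B - k_off + i*dw  ]]

Three observables derive from L:

* ``cpmg_r2eff`` -- effective transverse rate during a constant-time CPMG
  train, by explicit propagation through tau-180-tau echo units (the
  refocusing pulse acts as complex conjugation on in-phase coherence).
* ``carver_richards_r2eff`` -- the standard closed-form approximation,
  used as an independent oracle and for fast previews.
* ``delta_ex`` -- the exchange-induced displacement of the observed (slowly
  relaxing) resonance from its apo position: the imaginary part of the
  eigenvalue of L with the largest real part.

``lineshape_shift`` simulates the free-precession FID densely and locates
the spectral maximum, providing a model-free oracle for ``delta_ex``.

Chemical-shift differences are carried in ppm (field-independent); the
conversion to rad/s folds the 15N/1H gyromagnetic ratio magnitude into a
single global sign convention (positive delta_omega = downfield bound
state) since only relative signs are identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .binding import BindingState

__all__ = [
    "GAMMA_RATIO_N_H",
    "ppm_to_rads",
    "rads_to_ppm",
    "SpinParams",
    "CpmgSchedule",
    "DispersionCurve",
    "snap_nu_cpmg",
    "cpmg_r2eff",
    "cpmg_r2eff_profile",
    "carver_richards_r2eff",
    "luz_meiboom_r2eff",
    "delta_ex",
    "delta_ex_rads",
    "lineshape_shift",
]

#: |gamma_15N / gamma_1H|
GAMMA_RATIO_N_H = 0.101329118


def ppm_to_rads(delta_ppm, field_mhz: float):
    """15N shift difference in ppm -> angular frequency (rad/s) at a field
    given as the spectrometer 1H frequency in MHz."""
    return 2.0 * np.pi * field_mhz * GAMMA_RATIO_N_H * np.asarray(delta_ppm)


def rads_to_ppm(delta_rads, field_mhz: float):
    return np.asarray(delta_rads) / (2.0 * np.pi * field_mhz * GAMMA_RATIO_N_H)


@dataclass(frozen=True)
class SpinParams:
    """Per-residue parameters entering the exchange matrix.

    ``r2_apo`` maps spectrometer 1H frequency (MHz) to the intrinsic
    transverse rate of the apo state at that field (s^-1); the bound-state
    rate is tied to it by ``r2_bound_scale`` (default 5, reflecting the
    molecular-weight ratio of complex to free protein).
    """

    residue_id: int
    delta_omega: float  # ppm, bound minus apo
    r2_apo: Mapping[float, float]
    r2_bound_scale: float = 5.0

    def __post_init__(self) -> None:
        if not self.r2_bound_scale > 0:
            raise ValueError("r2_bound_scale must be > 0")
        for f, r in self.r2_apo.items():
            if not r > 0:
                raise ValueError(f"r2_apo must be > 0 (field {f}: {r})")

    def r2a(self, field_mhz: float) -> float:
        return self.r2_apo[field_mhz]

    def r2b(self, field_mhz: float) -> float:
        return self.r2_bound_scale * self.r2_apo[field_mhz]


def snap_nu_cpmg(nu_cpmg, t_relax: float):
    """Snap requested CPMG field strengths to values compatible with the
    constant-time delay (even integer number of tau-180-tau units), as the
    acquisition software does.  Zero stays zero."""
    nu = np.asarray(nu_cpmg, dtype=float)
    n = np.rint(2.0 * t_relax * nu)
    n = np.where((n % 2 == 1), n + 1, n)
    n = np.where((nu > 0) & (n < 2), 2, n)
    return n / (2.0 * t_relax)


@dataclass(frozen=True)
class CpmgSchedule:
    """Acquisition schedule of one dispersion experiment."""

    field_mhz: float
    t_relax: float
    nu_cpmg: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.t_relax > 0:
            raise ValueError("t_relax must be > 0")
        n = 2.0 * self.t_relax * np.asarray(self.nu_cpmg)
        bad = ~np.isclose(n, np.rint(n), atol=1e-6) | (np.rint(n) % 2 != 0)
        if np.any(bad):
            snapped = snap_nu_cpmg(self.nu_cpmg, self.t_relax)
            raise ValueError(
                "nu_cpmg values incompatible with t_relax (need an even number "
                f"of echo units); nearest compatible values: {snapped.tolist()}"
            )


@dataclass(frozen=True)
class DispersionCurve:
    """Measured R2,eff(nu_CPMG) for one residue at one field."""

    residue_id: int
    field_mhz: float
    nu_cpmg: tuple[float, ...]
    r2eff: tuple[float, ...]
    sigma: tuple[float, ...]
    t_relax: float = 0.04

    def __post_init__(self) -> None:
        if not (len(self.nu_cpmg) == len(self.r2eff) == len(self.sigma)):
            raise ValueError("nu_cpmg, r2eff and sigma must have equal length")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("every fitted point needs sigma > 0")


# ---------------------------------------------------------------------------
# propagator core
# ---------------------------------------------------------------------------

def _expm2(m: np.ndarray) -> np.ndarray:
    """Closed-form matrix exponential of a stack of 2x2 complex matrices.

    exp(M) = e^s (cosh(q) I + sinh(q)/q (M - s I)) with s = tr(M)/2 and
    q^2 = s^2 - det(M); the sinh(q)/q factor goes over to its series for
    small |q| so the near-degenerate case needs no branch.
    """
    s = 0.5 * (m[..., 0, 0] + m[..., 1, 1])
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    q = np.sqrt(s * s - det + 0j)
    small = np.abs(q) < 1e-6
    qs = np.where(small, 1.0, q)
    sinhc = np.where(small, 1.0 + q * q / 6.0, np.sinh(qs) / qs)
    coshq = np.cosh(q)
    eye = np.eye(2, dtype=complex)
    out = coshq[..., None, None] * eye + sinhc[..., None, None] * (
        m - s[..., None, None] * eye
    )
    return np.exp(s)[..., None, None] * out


def _evolution_matrix(dw_rads, r2a, r2b, k_on_app, k_off) -> np.ndarray:
    dw_rads, r2a, r2b = np.broadcast_arrays(dw_rads, r2a, r2b)
    shape = dw_rads.shape
    L = np.zeros(shape + (2, 2), dtype=complex)
    L[..., 0, 0] = -r2a - k_on_app
    L[..., 0, 1] = k_off
    L[..., 1, 0] = k_on_app
    L[..., 1, 1] = -r2b - k_off + 1j * dw_rads
    return L


def cpmg_r2eff_profile(
    dw_rads,
    r2a,
    r2b,
    k_on_app: float,
    k_off: float,
    nu_cpmg,
    t_relax: float,
) -> np.ndarray:
    """Vectorized R2,eff by matrix propagation.

    All array arguments broadcast together; ``nu_cpmg`` entries of 0 are
    treated as the reference (free-precession decay of the A line real
    part).  Echo unit: tau-180-tau with tau = 1/(4 nu); the 180 pulse is
    complex conjugation of the magnetization vector.  Starting vector is
    the equilibrium populations (1-p_B, p_B); R2,eff is extracted from the
    magnitude |M_A(T)|, consistent with intensity-based measurement.
    """
    dw_rads = np.asarray(dw_rads, dtype=float)
    nu = np.asarray(nu_cpmg, dtype=float)
    dw_rads, r2a, r2b, nu = np.broadcast_arrays(dw_rads, r2a, r2b, nu)
    k_tot = k_on_app + k_off
    p_b = k_on_app / k_tot if k_tot > 0 else 0.0
    m0 = np.empty(dw_rads.shape + (2,), dtype=complex)
    m0[..., 0] = 1.0 - p_b
    m0[..., 1] = p_b

    L = _evolution_matrix(dw_rads, r2a, r2b, k_on_app, k_off)
    n_units = np.rint(2.0 * t_relax * nu).astype(int)
    if np.any((nu > 0) & ((n_units % 2 != 0) | (n_units < 2))):
        raise ValueError("nu_cpmg incompatible with t_relax (odd/zero echo count)")

    with np.errstate(divide="ignore"):
        tau = np.where(nu > 0, 1.0 / (4.0 * np.maximum(nu, 1e-300)), 0.0)
    P = _expm2(L * tau[..., None, None])

    m = m0.copy()
    active_any = n_units > 0
    for step in range(int(n_units.max(initial=0))):
        act = (n_units > step) & active_any
        if not np.any(act):
            break
        # one unit: tau evolution, 180 (conjugate), tau evolution
        m_new = np.einsum("...ij,...j->...i", P, m)
        np.conj(m_new, out=m_new)
        m_new = np.einsum("...ij,...j->...i", P, m_new)
        m = np.where(act[..., None], m_new, m)

    # nu == 0 points: plain free precession over the full delay
    zero = nu == 0
    if np.any(zero):
        Pfull = _expm2(L * t_relax)
        m_free = np.einsum("...ij,...j->...i", Pfull, m0)
        m = np.where(zero[..., None], m_free, m)

    amp = np.abs(m[..., 0])
    ref = 1.0 - p_b
    if np.any(amp >= ref * (1.0 + 1e-9)):
        raise RuntimeError(
            "non-physical magnetization |M_A(T)| >= M_A(0); "
            "check rates and schedule"
        )
    return -np.log(amp / ref) / t_relax


def cpmg_r2eff(
    spin: SpinParams,
    state: BindingState,
    field_mhz: float,
    nu_cpmg,
    t_relax: float = 0.04,
):
    """R2,eff for one residue at one field (scalar or array over nu)."""
    dw = ppm_to_rads(spin.delta_omega, field_mhz)
    out = cpmg_r2eff_profile(
        dw,
        spin.r2a(field_mhz),
        spin.r2b(field_mhz),
        state.k_on_app,
        state.k_off,
        nu_cpmg,
        t_relax,
    )
    return out if np.ndim(nu_cpmg) else float(out)


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def _echo_train_closed_form(dw, r2a, r2b, k_on_app, k_off, nu, t_relax, p_b):
    """Exact R2,eff from eigen-projectors of the echo-pair matrix.

    No iteration: Q**(N/2) is evaluated from the two eigenvalues of the
    2x2 pair matrix (integer powers of complex scalars are exact under
    exp(m log z)), with a first-order fallback at eigenvalue degeneracy.
    """
    n_units = np.rint(2.0 * t_relax * np.asarray(nu)).astype(int)
    if np.any((n_units % 2 != 0) | (n_units < 2)):
        raise ValueError("nu_cpmg incompatible with t_relax (odd/zero echo count)")
    m = (n_units // 2).astype(float)

    L = _evolution_matrix(dw, r2a, r2b, k_on_app, k_off)
    tau = 1.0 / (4.0 * np.asarray(nu))
    P = _expm2(L * tau[..., None, None])
    Pc = np.conj(P)
    Q = P @ Pc @ Pc @ P

    s = 0.5 * (Q[..., 0, 0] + Q[..., 1, 1])
    det = Q[..., 0, 0] * Q[..., 1, 1] - Q[..., 0, 1] * Q[..., 1, 0]
    q = np.sqrt(s * s - det + 0j)
    lam1, lam2 = s + q, s - q
    eye = np.eye(2, dtype=complex)

    degen = np.abs(q) < 1e-12 * np.maximum(np.abs(s), 1e-300)
    qsafe = np.where(degen, 1.0, lam1 - lam2)
    pow1 = np.power(lam1, m)
    pow2 = np.power(lam2, m)
    qm = (
        pow1[..., None, None] * (Q - lam2[..., None, None] * eye)
        - pow2[..., None, None] * (Q - lam1[..., None, None] * eye)
    ) / qsafe[..., None, None]
    if np.any(degen):
        # Q = lam*I + N with N nilpotent: Q**m = lam**m I + m lam**(m-1) N
        lam = s
        qm_d = np.power(lam, m)[..., None, None] * eye + (
            m * np.power(lam, m - 1.0)
        )[..., None, None] * (Q - lam[..., None, None] * eye)
        qm = np.where(degen[..., None, None], qm_d, qm)

    m0 = np.zeros(np.shape(dw) + (2,), dtype=complex)
    m0[..., 0] = 1.0 - p_b
    m0[..., 1] = p_b
    ma = np.abs(np.einsum("...ij,...j->...i", qm, m0)[..., 0])
    out = -np.log(ma / (1.0 - p_b)) / t_relax
    return out if out.shape else float(out)

def carver_richards_r2eff(
    dw_rads, r2a, r2b, k_on_app: float, k_off: float, nu_cpmg,
    t_relax: float = 0.04, exact: bool = True,
):
    """Closed-form R2,eff for a two-site CPMG echo train.

    With ``exact=True`` (default) the echo train is solved analytically:
    the pair of echo units is a linear map Q = P conj(P) conj(P) P on the
    magnetization vector (P = exp(L tau), refocusing = conjugation), and
    Q**(N/2) follows from the 2x2 eigen-projectors -- exact for any even
    echo count, including the initial-condition amplitude term that the
    classic asymptotic formula drops.  With ``exact=False`` the classic
    Carver-Richards large-N expression is returned (no ``t_relax``
    dependence); it deviates from the propagator by up to ~ln(a)/T at low
    nu_CPMG, where a is the projection of the start vector on the slow
    mode.  Array arguments broadcast.
    """
    dw = np.asarray(dw_rads, dtype=float)
    nu = np.asarray(nu_cpmg, dtype=float)
    dw, r2a, r2b, nu = np.broadcast_arrays(dw, r2a, r2b, nu)
    kex = k_on_app + k_off
    if kex == 0:
        return np.broadcast_to(r2a, dw.shape).copy()
    p_b = k_on_app / kex
    p_a = 1.0 - p_b
    if np.any(nu <= 0):
        raise ValueError("carver_richards_r2eff needs nu_cpmg > 0")
    if exact:
        return _echo_train_closed_form(
            dw, r2a, r2b, k_on_app, k_off, nu, t_relax, p_b
        )

    # d = (R2A + kAB) - (R2B + kBA), the real part of the eigenvalue gap
    d = r2a - r2b - p_a * kex + p_b * kex
    psi = d * d - dw * dw + 4.0 * p_a * p_b * kex * kex
    zeta = 2.0 * dw * d
    root = np.sqrt(psi * psi + zeta * zeta)
    dplus = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    dminus = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)
    tau_cp = 1.0 / (2.0 * nu)  # time between refocusing pulses
    eta_plus = (tau_cp / np.sqrt(2.0)) * np.sqrt(np.maximum(psi + root, 0.0))
    eta_minus = (tau_cp / np.sqrt(2.0)) * np.sqrt(np.maximum(root - psi, 0.0))
    arg = dplus * np.cosh(eta_plus) - dminus * np.cos(eta_minus)
    arg = np.maximum(arg, 1.0)
    r2 = 0.5 * (r2a + r2b + kex - np.arccosh(arg) / tau_cp)
    return r2 if r2.shape else float(r2)


def luz_meiboom_r2eff(dw_rads, r2a, r2b, k_on_app: float, k_off: float, nu_cpmg):
    """Fast-exchange (Luz-Meiboom) limit:
    R2bar + pA pB dw^2/kex * (1 - (4 nu/kex) tanh(kex/(4 nu)))."""
    dw = np.asarray(dw_rads, dtype=float)
    nu = np.asarray(nu_cpmg, dtype=float)
    kex = k_on_app + k_off
    if kex == 0:
        return np.broadcast_to(r2a, np.broadcast(dw, nu).shape).copy()
    p_b = k_on_app / kex
    p_a = 1.0 - p_b
    r2bar = p_a * np.asarray(r2a) + p_b * np.asarray(r2b)
    x = kex / (4.0 * nu)
    return r2bar + p_a * p_b * dw * dw / kex * (1.0 - np.tanh(x) / x)


# ---------------------------------------------------------------------------
# exchange-induced shifts
# ---------------------------------------------------------------------------

def delta_ex_rads(dw_rads: float, r2a: float, r2b: float, k_on_app: float, k_off: float) -> float:
    """Exchange-induced shift of the observed resonance (rad/s).

    Imaginary part of the eigenvalue of the free-precession matrix whose
    real part is largest (the slowly decaying, observed line), relative to
    the apo frequency (0).  At exact coalescence the two eigenvalues
    degenerate; the mean shift is returned with a warning.
    """
    if k_on_app == 0.0:
        return 0.0
    L = _evolution_matrix(np.array(dw_rads, dtype=float), r2a, r2b, k_on_app, k_off)
    lam = np.linalg.eigvals(L)
    gap = abs(lam[0] - lam[1])
    scale = max(abs(lam[0]), abs(lam[1]), 1.0)
    if gap < 1e-9 * scale:
        warnings.warn(
            "degenerate eigenvalues at coalescence; reporting mean shift",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.mean(lam.imag))
    return float(lam[np.argmax(lam.real)].imag)


def delta_ex(spin: SpinParams, state: BindingState, field_mhz: float) -> float:
    """Exchange-induced shift in ppm for one residue at one field."""
    dw = float(ppm_to_rads(spin.delta_omega, field_mhz))
    shift = delta_ex_rads(
        dw, spin.r2a(field_mhz), spin.r2b(field_mhz), state.k_on_app, state.k_off
    )
    return float(rads_to_ppm(shift, field_mhz))


def lineshape_shift(
    dw_rads: float,
    r2a: float,
    r2b: float,
    k_on_app: float,
    k_off: float,
    t_max: float | None = None,
    n_points: int = 16384,
) -> float:
    """Observed-peak position (rad/s) from a dense FID simulation.

    Samples the total transverse signal s(t) = sum_i [exp(L t) M0]_i on a
    dense grid, evaluates its discrete-time Fourier transform, and refines
    the position of the spectral maximum by bounded scalar optimization.
    Serves as an independent oracle for :func:`delta_ex_rads`.
    """
    kex = k_on_app + k_off
    p_b = k_on_app / kex if kex > 0 else 0.0
    m0 = np.array([1.0 - p_b, p_b], dtype=complex)
    L = _evolution_matrix(np.array(dw_rads, dtype=float), r2a, r2b, k_on_app, k_off)

    decay = min(r2a, r2b)
    if t_max is None:
        t_max = 12.0 / decay
    t = np.linspace(0.0, t_max, n_points)
    lam, V = np.linalg.eig(L)
    c = V @ np.diag(np.linalg.solve(V, m0))  # columns scaled by mode amplitudes
    mode_amps = c.sum(axis=0)  # total detected amplitude of each mode
    fid = mode_amps[0] * np.exp(lam[0] * t) + mode_amps[1] * np.exp(lam[1] * t)

    def neg_spec(omega: float) -> float:
        return -np.abs(np.sum(fid * np.exp(-1j * omega * t)))

    # coarse scan then golden-section refinement
    span = max(abs(dw_rads), 10.0 * decay)
    grid = np.linspace(-0.2 * span, 1.2 * span, 2001)
    vals = [neg_spec(w) for w in grid]
    w0 = grid[int(np.argmin(vals))]
    dw_grid = grid[1] - grid[0]
    res = minimize_scalar(
        neg_spec, bounds=(w0 - 2 * dw_grid, w0 + 2 * dw_grid), method="bounded",
        options={"xatol": 1e-10 * max(span, 1.0)},
    )
    return float(res.x)
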