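"""Amide hydrogen-exchange rates from water-magnetization buildup curves.

A WEX-type experiment inverts water and follows the transfer of its
longitudinal magnetization to amide protons during an interval T.  With a
single water pool relaxing at R1w, an amide pool relaxing at R1a and
exchanging with water at k_obs, the transferred intensity is the two-pool
solution

    I(T) = A k_obs (exp(-R1w T) - exp(-(R1a + k_obs) T)) / (R1a + k_obs - R1w)

which rises from zero, peaks, and decays with the water.  Fitted k_obs are
converted to protection factors against supplied intrinsic (random-coil)
rates:  log P = log10(1.5 * k_int / k_obs), the 1.5 scaling keeping log P
non-negative for fully exposed amides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "HxSeries",
    "wex_buildup",
    "fit_wex_buildup",
    "fit_wex_dataset",
    "protection_factor",
]


@dataclass(frozen=True)
class HxSeries:
    """Buildup series of one residue: water-inversion intervals (s) and
    transferred intensities, normalized by the reference (equilibrium)
    amide intensity.

    The reference matters: the buildup observables are only the overall
    amplitude A k/(R1a + k - R1w) and the rate R1a + k, so with a floating
    amplitude the rate constants trade off freely.  Anchoring A to the
    reference intensity makes k_obs identifiable from a single curve.
    """

    residue_id: int
    t_s: tuple[float, ...]
    intensity: tuple[float, ...]
    reference: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s)
        if len(t) < 4:
            raise ValueError("need >= 4 buildup points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("T values must be strictly increasing")
        if not self.reference > 0:
            raise ValueError("reference intensity must be > 0")


def wex_buildup(t, a: float, k_obs: float, r1a: float, r1w: float):
    """Two-pool transfer intensity I(T); handles the rate-degenerate limit
    R1a + k_obs -> R1w analytically (I = A k T exp(-R1w T))."""
    t = np.asarray(t, dtype=float)
    denom = r1a + k_obs - r1w
    if abs(denom) < 1e-8 * max(abs(r1w), 1.0):
        return a * k_obs * t * np.exp(-r1w * t)
    return a * k_obs * (np.exp(-r1w * t) - np.exp(-(r1a + k_obs) * t)) / denom


def fit_wex_buildup(
    series: HxSeries,
    r1w: float,
    amplitude: float | None = None,
    fit_amplitude: bool = False,
) -> tuple[float, float]:
    """Fit {k_obs, R1a} to one buildup with the water rate fixed.

    The transfer amplitude A is anchored to the series' reference
    intensity (or ``amplitude`` if given): a floating amplitude makes the
    pair (k_obs, R1a) structurally degenerate, so ``fit_amplitude=True``
    is offered only for data where an independent check of k_obs exists.
    Returns (k_obs, sigma_k_obs) from the fit covariance; k_obs is kept
    positive through a log parameterization.
    """
    t = np.asarray(series.t_s)
    y = np.asarray(series.intensity) / series.reference
    a_fixed = amplitude if amplitude is not None else 1.0
    t_pos = t[np.abs(y) > 0.1 * np.max(np.abs(y))]
    t_peak = float(t_pos[0]) if len(t_pos) else float(t[len(t) // 2])
    k0 = max(1.0 / max(t_peak, 1e-3), 1.0)

    if fit_amplitude:
        def model(tt, a, log_k, r1a):
            return wex_buildup(tt, a, np.exp(log_k), r1a, r1w)
        p0 = (a_fixed, np.log(k0), 2.0)
    else:
        def model(tt, log_k, r1a):
            return wex_buildup(tt, a_fixed, np.exp(log_k), r1a, r1w)
        p0 = (np.log(k0), 2.0)

    popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=20000)
    idx = 1 if fit_amplitude else 0
    k = float(np.exp(popt[idx]))
    k_err = (
        float(k * np.sqrt(pcov[idx, idx]))
        if np.isfinite(pcov[idx, idx])
        else float("nan")
    )
    return k, k_err


def fit_wex_dataset(
    series_list: list[HxSeries], r1w: float | None = None
) -> pd.DataFrame:
    """Fit all residues; if ``r1w`` is None it is first fitted globally
    (single water pool shared by every residue) and then held fixed.

    Returns a DataFrame (residue_id, k_obs, k_obs_err, r1w).
    """
    if r1w is None:
        r1w = _fit_shared_r1w(series_list)
    rows = []
    for s in series_list:
        k, ke = fit_wex_buildup(s, r1w)
        rows.append({"residue_id": s.residue_id, "k_obs": k, "k_obs_err": ke,
                     "r1w": r1w})
    return pd.DataFrame(rows)


def _fit_shared_r1w(series_list: list[HxSeries], r1w0: float = 0.5) -> float:
    """Global fit of the shared water rate across residues."""
    n = len(series_list)

    def resid(x):
        r1w = np.exp(x[0])
        out = []
        for i, s in enumerate(series_list):
            log_k, r1a = x[1 + 2 * i: 3 + 2 * i]
            y = np.asarray(s.intensity) / s.reference
            scale = max(np.max(np.abs(y)), 1e-12)
            out.append(
                (wex_buildup(np.asarray(s.t_s), 1.0, np.exp(log_k), r1a, r1w)
                 - y) / scale
            )
        return np.concatenate(out)

    x0 = [np.log(r1w0)]
    for s in series_list:
        t = np.asarray(s.t_s)
        y = np.asarray(s.intensity)
        t_pos = t[np.abs(y) > 0.1 * np.max(np.abs(y))]
        t_peak = float(t_pos[0]) if len(t_pos) else float(t[len(t) // 2])
        x0 += [np.log(max(1.0 / max(t_peak, 1e-3), 1.0)), 2.0]
    sol = least_squares(resid, x0, max_nfev=200 * (1 + 2 * n))
    return float(np.exp(sol.x[0]))


def protection_factor(k_obs: float, k_int: float, scale: float = 1.5) -> float:
    """log10 protection factor, log P = log10(scale * k_int / k_obs)."""
    if not (k_obs > 0 and k_int > 0):
        raise ValueError("k_obs and k_int must be > 0")
    return float(np.log10(scale * k_int / k_obs))
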