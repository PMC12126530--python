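"""R1, R1rho-derived R2 and heteronuclear NOE from intensity series.

Longitudinal and rotating-frame rates come from single-exponential fits
I(t) = A exp(-R t) with uncertainties from the fit covariance matrix.
R1rho is converted to R2 through the spin-lock tilt angle theta (the angle
between the effective field and B0):

    R2 = (R1rho - R1 cos^2 theta) / sin^2 theta

The steady-state 15N{1H} NOE is the saturated/reference intensity ratio
with first-order error propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecaySeries",
    "SpinLockGeometry",
    "fit_exponential",
    "r2_from_r1rho",
    "het_noe",
    "process_decay_table",
]


@dataclass(frozen=True)
class DecaySeries:
    """Intensity decay of one residue; replicates at equal delays are
    averaged before fitting."""

    residue_id: int
    delays: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.delays)) < 3:
            raise ValueError("need >= 3 distinct delays for an exponential fit")
        if len(self.delays) != len(self.intensities):
            raise ValueError("delays and intensities must match in length")


@dataclass(frozen=True)
class SpinLockGeometry:
    """Spin-lock field and resonance offset defining the tilt angle."""

    spinlock_hz: float  # nu_1, e.g. 1500 Hz
    offset_hz: float

    def __post_init__(self) -> None:
        if not self.spinlock_hz > 0:
            raise ValueError("spin-lock field must be > 0")

    @property
    def theta(self) -> float:
        """Tilt angle in (0, pi/2]; pi/2 on resonance."""
        if self.offset_hz == 0.0:
            return np.pi / 2.0
        return float(np.arctan2(self.spinlock_hz, abs(self.offset_hz)))


def fit_exponential(series: DecaySeries) -> tuple[float, float]:
    """Least-squares fit of I(t) = A exp(-R t); returns (R, sigma_R).

    Negative tail points are retained (no truncation); the start is a
    log-linear regression on the positive points.  A failed fit returns
    (nan, nan) rather than raising.
    """
    t = np.asarray(series.delays, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    # average replicates at identical delays
    tu = np.unique(t)
    if len(tu) != len(t):
        y = np.array([np.mean(y[t == v]) for v in tu])
        t = tu
    pos = y > 0
    if np.sum(pos) >= 2:
        slope, icept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(icept)), float(-slope))
    else:
        p0 = (float(np.max(np.abs(y))), 1.0)
    try:
        popt, pcov = curve_fit(
            lambda tt, a, r: a * np.exp(-r * tt), t, y, p0=p0, maxfev=10000
        )
    except RuntimeError:
        return float("nan"), float("nan")
    r = float(popt[1])
    r_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return r, r_err


def r2_from_r1rho(r1rho: float, r1: float, theta: float) -> float:
    """R2 = (R1rho - R1 cos^2 theta) / sin^2 theta; theta in (0, pi/2]."""
    if not 0.0 < theta <= np.pi / 2.0:
        raise ValueError(f"theta must be in (0, pi/2], got {theta}")
    s2 = np.sin(theta) ** 2
    return float((r1rho - r1 * np.cos(theta) ** 2) / s2)


def het_noe(
    i_sat: float, i_ref: float, sigma_sat: float = 0.0, sigma_ref: float = 0.0
) -> tuple[float, float]:
    """Steady-state NOE = I_sat/I_ref with first-order error propagation."""
    if i_ref == 0.0:
        raise ValueError("reference intensity must be nonzero")
    noe = i_sat / i_ref
    err = np.sqrt(
        (sigma_sat / i_ref) ** 2 + (i_sat * sigma_ref / i_ref**2) ** 2
    )
    return float(noe), float(err)


def process_decay_table(
    df: pd.DataFrame, kind: str = "rate"
) -> pd.DataFrame:
    """Fit every residue of a tidy table (residue_id, delay_s, intensity
    [, replicate]); returns (residue_id, rate, rate_err)."""
    del kind
    rows = []
    for rid, grp in df.groupby("residue_id"):
        s = DecaySeries(
            residue_id=int(rid),
            delays=tuple(grp["delay_s"]),
            intensities=tuple(grp["intensity"]),
        )
        r, e = fit_exponential(s)
        rows.append({"residue_id": int(rid), "rate": r, "rate_err": e})
    return pd.DataFrame(rows)
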