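"""Fluorescence polarisation and the hyperbolic binding isotherm.

Polarisation of each well is P = (I_par - I_perp) / (I_par + I_perp); the
titration is fitted to the four-parameter logistic with unit Hill slope,

    y = b + (t - b) / (1 + K_d / x),

a rectangular hyperbola whose inflection gives K_d under a 1:1 model (the
curve passes through (K_d, (b+t)/2) by construction).  An optional free
Hill slope is available behind a flag; competition-mode data report the
raw inflection as an IC50 without conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FourPLFit", "polarisation", "fit_4pl"]


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    kd: float
    hill: float
    bottom_err: float
    top_err: float
    kd_err: float
    identifiable: bool = True

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.kd / x) ** self.hill
        )


def polarisation(i_par, i_perp):
    """P = (I_par - I_perp) / (I_par + I_perp), elementwise."""
    i_par = np.asarray(i_par, dtype=float)
    i_perp = np.asarray(i_perp, dtype=float)
    denom = i_par + i_perp
    if np.any(denom == 0):
        raise ValueError("zero total intensity (I_par + I_perp = 0)")
    out = (i_par - i_perp) / denom
    return out if out.shape else float(out)


def fit_4pl(
    x,
    y,
    sigma=None,
    free_hill: bool = False,
) -> FourPLFit:
    """Weighted least-squares fit of the binding isotherm.

    ``x`` are titrant concentrations (> 0, any consistent unit — K_d comes
    back in the same unit), ``y`` the polarisation values.  Needs >= 4
    points spanning the inflection.  A curve with no resolvable curvature
    is returned flagged ``identifiable=False`` instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 titration points")
    if np.any(x <= 0):
        raise ValueError("titrant concentrations must be > 0")

    b0 = float(np.min(y))
    t0 = float(np.max(y))
    half = 0.5 * (b0 + t0)
    kd0 = float(x[int(np.argmin(np.abs(y - half)))])

    if free_hill:
        def model(xx, b, t, log_kd, hill):
            return b + (t - b) / (1.0 + (np.exp(log_kd) / xx) ** hill)
        p0 = (b0, t0, np.log(kd0), 1.0)
    else:
        def model(xx, b, t, log_kd):
            return b + (t - b) / (1.0 + np.exp(log_kd) / xx)
        p0 = (b0, t0, np.log(kd0))

    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, sigma=sigma, maxfev=20000)
    except RuntimeError:
        return FourPLFit(b0, t0, float("nan"), 1.0, float("nan"),
                         float("nan"), float("nan"), identifiable=False)
    perr = np.sqrt(np.abs(np.diag(pcov)))
    kd = float(np.exp(popt[2]))
    kd_err = float(kd * perr[2])
    hill = float(popt[3]) if free_hill else 1.0
    # flat curve: amplitude indistinguishable from zero
    amp = abs(popt[1] - popt[0])
    spread = float(np.std(y))
    identifiable = bool(amp > 1e-12 and (spread == 0.0 or amp > 0.5 * spread)
                        and np.isfinite(kd_err))
    return FourPLFit(
        bottom=float(popt[0]), top=float(popt[1]), kd=kd, hill=hill,
        bottom_err=float(perr[0]), top_err=float(perr[1]), kd_err=kd_err,
        identifiable=identifiable,
    )
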