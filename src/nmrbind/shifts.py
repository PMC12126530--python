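"""Chemical-shift perturbation analysis and fast-exchange population tools.

Combined amide CSPs use the standard 15N down-weighting,
Delta_comb = sqrt(dH^2 + (0.2 dN)^2).  Significance is set by the
iteratively corrected standard deviation (Schumann-style): values more
than 3 SD above the mean are trimmed, the SD recomputed, and the loop
repeated until stable; residues above twice the corrected SD are flagged.
Because CSPs are magnitudes, the final corrected SD is computed about zero
by default while the trimming test stays about the mean (both centers are
configurable — the two conventions circulate).

For a variant in fast exchange between reference closed and open states,
the observed peak position interpolates linearly between the reference
positions, giving a per-residue open-state population; a small exchange
broadening term then places the exchange rate via the fast-limit relation
R_ex = p(1-p) dw^2 / k_ex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CspRecord",
    "ShiftTriplet",
    "combined_csp",
    "corrected_sd_cutoff",
    "analyse_csps",
    "open_population",
    "kex_from_rex",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CspRecord:
    residue_id: int
    d_h: float
    d_n: float
    combined: float
    significant: bool


@dataclass(frozen=True)
class ShiftTriplet:
    """Peak positions (ppm) of one residue in the closed reference, open
    reference and variant spectra."""

    residue_id: int
    delta_closed: float
    delta_open: float
    delta_obs: float
    sigma: float = 0.01  # ppm, measurement precision of a peak position


def combined_csp(d_h, d_n):
    """Delta_comb = sqrt(dH^2 + (0.2 dN)^2), elementwise."""
    d_h = np.asarray(d_h, dtype=float)
    d_n = np.asarray(d_n, dtype=float)
    out = np.sqrt(d_h**2 + (0.2 * d_n) ** 2)
    return out if out.shape else float(out)


def corrected_sd_cutoff(
    csps,
    trim_center: str = "mean",
    final_center: str = "zero",
) -> tuple[float, float, np.ndarray]:
    """Iteratively trimmed significance cutoff for a CSP set.

    Values more than 3 SD above the ``trim_center`` ("mean" or "zero") are
    removed and the SD recomputed until no further value exceeds the test;
    the corrected SD of the survivors is then computed about
    ``final_center`` and the cutoff is twice that.  The surviving set
    shrinks monotonically, so the procedure terminates.

    Returns (sigma_corr, cutoff, significant_mask) where the mask flags
    input values above the cutoff.  All-identical inputs give a zero SD
    (flagged via a log warning).
    """
    x = np.asarray(csps, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 CSP values")

    def sd_about(v: np.ndarray, center: str) -> float:
        if center == "zero":
            return float(np.sqrt(np.mean(v**2)))
        if center == "mean":
            return float(np.std(v))
        raise ValueError("center must be 'mean' or 'zero'")

    keep = np.ones(len(x), dtype=bool)
    while True:
        v = x[keep]
        mu = float(np.mean(v)) if trim_center == "mean" else 0.0
        sd = sd_about(v, trim_center)
        new_keep = keep & (x <= mu + 3.0 * sd)
        if new_keep.sum() == keep.sum() or new_keep.sum() < 2:
            keep = new_keep if new_keep.sum() >= 2 else keep
            break
        keep = new_keep

    sigma_corr = sd_about(x[keep], final_center)
    if sigma_corr == 0.0:
        logger.warning("corrected SD is zero (identical CSP values); cutoff 0")
    cutoff = 2.0 * sigma_corr
    return sigma_corr, cutoff, x > cutoff


def analyse_csps(
    df: pd.DataFrame,
    trim_center: str = "mean",
    final_center: str = "zero",
) -> tuple[pd.DataFrame, float]:
    """CSP table (residue_id, dH_ppm, dN_ppm) -> records with significance.

    Returns (table with combined/significant columns, cutoff)."""
    comb = combined_csp(df["dH_ppm"], df["dN_ppm"])
    _, cutoff, sig = corrected_sd_cutoff(
        comb, trim_center=trim_center, final_center=final_center
    )
    out = df.copy()
    out["combined_ppm"] = comb
    out["significant"] = sig
    return out, cutoff


def open_population(
    shifts: list[ShiftTriplet], noise_floor: float = 0.05
) -> tuple[float, pd.DataFrame]:
    """Open-state population from fast-exchange peak positions.

    Per residue p = (obs - closed) / (open - closed), clipped to [0, 1];
    residues whose reference separation is below ``noise_floor`` (ppm) are
    excluded and logged.  The aggregate is the inverse-variance-weighted
    mean, with per-residue variance sigma_p^2 = 2 sigma^2 / (open-closed)^2
    (obs and reference positions equally uncertain).

    Returns (p_open, per-residue table).
    """
    rows = []
    for s in shifts:
        sep = s.delta_open - s.delta_closed
        if abs(sep) < noise_floor:
            logger.warning(
                "residue %d excluded: reference separation %.4f ppm below "
                "floor %.4f", s.residue_id, abs(sep), noise_floor,
            )
            continue
        p = float(np.clip((s.delta_obs - s.delta_closed) / sep, 0.0, 1.0))
        var = 2.0 * s.sigma**2 / sep**2
        rows.append({"residue_id": s.residue_id, "p_open": p, "var": var})
    if not rows:
        raise ValueError("no residue passed the reference-separation floor")
    tab = pd.DataFrame(rows)
    w = 1.0 / tab["var"]
    p_open = float(np.sum(w * tab["p_open"]) / np.sum(w))
    return p_open, tab


def kex_from_rex(p_open: float, dw_rads: float, r_ex: float) -> float:
    """Fast-limit exchange rate k_ex = p(1-p) dw^2 / R_ex.

    Valid only when exchange is fast on the shift timescale (k_ex >> |dw|);
    the caller is responsible for that check — the formula itself returns a
    small k_ex for large R_ex, which would contradict the assumption.
    """
    if not r_ex > 0:
        raise ValueError(f"R_ex must be > 0, got {r_ex}")
    return float(p_open * (1.0 - p_open) * dw_rads**2 / r_ex)
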