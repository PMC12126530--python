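"""Ground-truth generators for every observable the package analyses.

Each generator draws from a seeded ``numpy.random.Generator`` and returns
plain DataFrames plus a manifest dict recording the truth parameters, so a
fixture can be reproduced bit-exactly from its manifest.  Defaults emulate
the acquisition this package targets: 3-field (600/800/950 MHz) constant-
time CPMG with a 40 ms delay and duplicated points, 2% Gaussian intensity
noise applied at the intensity level (so the duplicate-difference error
estimator is exercised), shift differences of a few ppm, and the DNAJB6
JD-GF-like binding truth (k_off = 580 s^-1, K_d = 380 uM, 200/20 uM
sample).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import ExchangeParams, TitrationCondition, binding_state
from .exchange import (
    cpmg_r2eff_profile,
    delta_ex_rads,
    ppm_to_rads,
    rads_to_ppm,
    snap_nu_cpmg,
)
from .globalfit import Dataset, DeltaExPoint, DispersionCurve, r2eff_from_intensities
from .hx import wex_buildup
from .rdc import saupe_matrix_from_components

__all__ = [
    "CpmgTruth",
    "gen_cpmg_titration",
    "gen_decays",
    "gen_hx",
    "gen_csp",
    "gen_rdc",
    "gen_fp",
    "save_bundle",
]

DEFAULT_FIELDS = (600.0, 800.0, 950.0)


@dataclass(frozen=True)
class CpmgTruth:
    """Truth parameters of a simulated titration (concentrations in uM)."""

    k_off: float = 580.0
    kd_uM: float = 380.0
    jdp_total_uM: float = 200.0
    hsc_total_uM: float = 20.0
    n_spins: int = 15
    fields: tuple[float, ...] = DEFAULT_FIELDS
    t_relax: float = 0.04
    n_nu: int = 12
    nu_max: float = 1000.0
    noise: float = 0.02  # fractional intensity noise
    n_duplicates: int = 2  # nu_CPMG values measured twice
    r2_bound_scale: float = 5.0
    delta_omega_range: tuple[float, float] = (1.0, 4.0)  # ppm
    r2_apo_range: tuple[float, float] = (8.0, 20.0)  # s^-1 at 600 MHz
    with_delta_ex: bool = True

    @property
    def params(self) -> ExchangeParams:
        return ExchangeParams.from_kd(self.kd_uM * 1e-6, self.k_off)

    @property
    def condition(self) -> TitrationCondition:
        return TitrationCondition.from_uM(self.jdp_total_uM, self.hsc_total_uM)


def _nu_grid(truth: CpmgTruth) -> np.ndarray:
    grid = snap_nu_cpmg(np.linspace(25.0, truth.nu_max, truth.n_nu), truth.t_relax)
    return np.unique(grid)


def gen_cpmg_titration(
    seed: int, truth: CpmgTruth | None = None
) -> tuple[Dataset, dict]:
    """Simulate one titration condition: multi-field dispersion curves and
    exchange-induced shifts for ``n_spins`` residues.

    Noise enters at the intensity level; R2,eff and its uncertainty are then
    recovered through the duplicate-difference estimator, exactly as for
    measured data.  Returns the assembled :class:`Dataset` plus a manifest
    sufficient to regenerate it bit-exactly.
    """
    truth = truth or CpmgTruth()
    rng = np.random.default_rng(seed)
    st = binding_state(truth.condition, truth.params)
    nu = _nu_grid(truth)

    dws = rng.uniform(*truth.delta_omega_range, truth.n_spins)
    dws *= rng.choice([-1.0, 1.0], truth.n_spins)
    r2_600 = rng.uniform(*truth.r2_apo_range, truth.n_spins)

    curves = []
    dex_points = []
    spin_truth = []
    for i in range(truth.n_spins):
        rid = i + 1
        spin_r2 = {}
        for f in truth.fields:
            # mild field dependence of the intrinsic rate, as for real spins
            r2a = r2_600[i] * (f / 600.0) ** 0.5
            spin_r2[f] = r2a
            dw = float(ppm_to_rads(dws[i], f))
            r2eff = cpmg_r2eff_profile(
                dw, r2a, truth.r2_bound_scale * r2a, st.k_on_app, st.k_off,
                nu, truth.t_relax,
            )
            # duplicate the first n_duplicates nu values (acquisition habit)
            nu_meas = np.concatenate([nu, nu[: truth.n_duplicates]])
            r2_meas = np.concatenate([r2eff, r2eff[: truth.n_duplicates]])
            i0 = 1.0
            inten = i0 * np.exp(-r2_meas * truth.t_relax)
            if truth.noise > 0:
                inten = inten * (1.0 + truth.noise * rng.standard_normal(len(inten)))
            df = r2eff_from_intensities(nu_meas, inten, i0, truth.t_relax)
            # noiseless duplicates scatter by exactly zero; keep the points
            # with a nominal weight instead of dropping the curve
            nominal = truth.noise / truth.t_relax if truth.noise > 0 else 0.5
            bad = ~np.isfinite(df["sigma"]) | (df["sigma"] <= 0)
            df.loc[bad, "sigma"] = nominal
            curves.append(
                DispersionCurve(
                    residue_id=rid,
                    field_mhz=f,
                    nu_cpmg=tuple(df["nu_cpmg"]),
                    r2eff=tuple(df["r2eff"]),
                    sigma=tuple(df["sigma"]),
                    t_relax=truth.t_relax,
                )
            )
        if truth.with_delta_ex:
            f0 = truth.fields[0]
            dex = float(
                rads_to_ppm(
                    delta_ex_rads(
                        float(ppm_to_rads(dws[i], f0)),
                        spin_r2[f0],
                        truth.r2_bound_scale * spin_r2[f0],
                        st.k_on_app,
                        st.k_off,
                    ),
                    f0,
                )
            )
            sigma_dex = 0.002
            if truth.noise > 0:
                dex += sigma_dex * rng.standard_normal()
            dex_points.append(
                DeltaExPoint(residue_id=rid, field_mhz=f0, delta_ex=dex,
                             sigma=sigma_dex)
            )
        spin_truth.append(
            {"residue_id": rid, "delta_omega_ppm": float(dws[i]),
             "r2_apo": {str(f): float(v) for f, v in spin_r2.items()}}
        )

    ds = Dataset(
        condition=truth.condition,
        curves=tuple(curves),
        delta_ex=tuple(dex_points),
        name=f"synthetic_seed{seed}",
    )
    manifest = {
        "kind": "cpmg_titration",
        "seed": seed,
        "truth": asdict(truth),
        "derived": {
            "k_on": truth.params.k_on,
            "k_ex": st.k_ex,
            "p_bound": st.p_bound,
            "hsc_free_uM": st.hsc_free * 1e6,
            "nu_cpmg": nu.tolist(),
        },
        "spins": spin_truth,
    }
    return ds, manifest


def gen_decays(
    seed: int,
    rates=(2.0, 5.0, 15.0),
    delays=(0.01, 0.03, 0.06, 0.1, 0.15, 0.25, 0.4, 0.6),
    amplitude: float = 1.0,
    noise: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Exponential decay series I(t) = A exp(-R t), one residue per rate."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, r in enumerate(rates):
        t = np.asarray(delays, dtype=float)
        ideal = amplitude * np.exp(-r * t)
        meas = ideal + noise * amplitude * rng.standard_normal(len(t))
        for tj, ij in zip(t, meas):
            rows.append({"residue_id": i + 1, "delay_s": tj, "intensity": ij,
                         "replicate": 0})
    df = pd.DataFrame(rows)
    manifest = {"kind": "decays", "seed": seed, "rates": list(rates),
                "delays": list(delays), "noise": noise, "amplitude": amplitude}
    return df, manifest


def gen_hx(
    seed: int,
    k_obs_values=(10.0, 17.0, 25.0, 33.0, 40.0),
    r1w: float = 0.3,
    r1a: float = 2.0,
    amplitude: float = 1.0,
    noise: float = 0.02,
    t_points=(0.0005, 0.002, 0.005, 0.012, 0.025, 0.05, 0.1, 0.2, 0.4, 0.9),
) -> tuple[pd.DataFrame, dict]:
    """Water-exchange buildup curves over the 10-40 s^-1 linker regime."""
    rng = np.random.default_rng(seed)
    t = np.asarray(t_points, dtype=float)
    rows = []
    for i, k in enumerate(k_obs_values):
        ideal = wex_buildup(t, amplitude, k, r1a, r1w)
        scale = max(abs(ideal).max(), 1e-12)
        meas = ideal + noise * scale * rng.standard_normal(len(t))
        for tj, ij in zip(t, meas):
            rows.append({"residue_id": i + 1, "T_s": tj, "intensity": ij})
    df = pd.DataFrame(rows)
    manifest = {"kind": "hx", "seed": seed, "k_obs": list(k_obs_values),
                "r1w": r1w, "r1a": r1a, "noise": noise,
                "T_s": list(map(float, t))}
    return df, manifest


def gen_csp(
    seed: int,
    n: int = 20,
    scale_h: float = 0.01,
    scale_n: float = 0.05,
    n_outliers: int = 1,
    outlier_h: float = 0.35,
    outlier_n: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-residue 1H/15N shift differences with planted outliers.

    The bulk is half-normal noise around zero (CSPs are magnitudes of
    random perturbations); ``n_outliers`` residues receive large, genuine
    perturbations.
    """
    rng = np.random.default_rng(seed)
    d_h = np.abs(rng.normal(0.0, scale_h, n))
    d_n = np.abs(rng.normal(0.0, scale_n, n))
    out_idx = rng.choice(n, size=n_outliers, replace=False) if n_outliers else []
    for j in out_idx:
        d_h[j] = outlier_h * rng.uniform(0.8, 1.2)
        d_n[j] = outlier_n * rng.uniform(0.8, 1.2)
    df = pd.DataFrame(
        {"residue_id": np.arange(1, n + 1), "dH_ppm": d_h, "dN_ppm": d_n}
    )
    manifest = {"kind": "csp", "seed": seed, "n": n,
                "outlier_residues": sorted(int(j) + 1 for j in out_idx)}
    return df, manifest


def gen_rdc(
    seed: int,
    saupe=(4e-4, -2e-4, 1.5e-4, -1e-4, 2.5e-4),
    n: int = 30,
    dmax: float = 21700.0,
    noise_hz: float = 0.0,
    sigma_hz: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Couplings from a known alignment tensor on seeded random unit vectors.

    ``saupe`` is (Sxx, Syy, Sxy, Sxz, Syz); ``dmax`` the static coupling
    scale (Hz).  Returns a table with the vectors included so the fit can be
    run without a coordinate model.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    S = saupe_matrix_from_components(np.asarray(saupe, dtype=float))
    d = np.array([dmax * (vi @ S @ vi) for vi in v])
    if noise_hz > 0:
        d = d + noise_hz * rng.standard_normal(n)
    df = pd.DataFrame(
        {"residue_id": np.arange(1, n + 1), "coupling_type": "NH",
         "D_Hz": d, "sigma_Hz": sigma_hz,
         "vx": v[:, 0], "vy": v[:, 1], "vz": v[:, 2], "dmax_Hz": dmax}
    )
    manifest = {"kind": "rdc", "seed": seed, "saupe": list(map(float, saupe)),
                "dmax_Hz": dmax, "noise_hz": noise_hz, "n": n}
    return df, manifest


def gen_fp(
    seed: int,
    b: float = 0.05,
    t: float = 0.25,
    kd_uM: float = 5.0,
    conc_uM=(0.1, 0.3, 0.6, 1.0, 2.0, 3.5, 6.0, 10.0, 20.0, 40.0, 80.0, 160.0),
    noise: float = 0.0,
    i_total: float = 1000.0,
) -> tuple[pd.DataFrame, dict]:
    """Plate-reader parallel/perpendicular intensities along a titration.

    Polarisation follows the hyperbolic isotherm with bottom ``b``, top
    ``t`` and inflection ``kd_uM``; intensities are reconstructed from the
    polarisation at constant total intensity, then noised fractionally.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(conc_uM, dtype=float)
    p = b + (t - b) / (1.0 + kd_uM / x)
    i_par = 0.5 * i_total * (1.0 + p)
    i_perp = 0.5 * i_total * (1.0 - p)
    if noise > 0:
        i_par = i_par * (1.0 + noise * rng.standard_normal(len(x)))
        i_perp = i_perp * (1.0 + noise * rng.standard_normal(len(x)))
    df = pd.DataFrame({"conc_uM": x, "I_par": i_par, "I_perp": i_perp})
    manifest = {"kind": "fp", "seed": seed, "b": b, "t": t, "kd_uM": kd_uM,
                "noise": noise}
    return df, manifest


def save_bundle(out_dir: str | Path, tables: dict[str, pd.DataFrame],
                manifest: dict) -> None:
    """Write CSV tables plus the truth manifest next to them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
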