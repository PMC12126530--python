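"""Alignment-tensor fitting of residual dipolar couplings by SVD.

A coupling measured between nuclei i and j under partial alignment is a
linear function of the five independent components of the Saupe order
matrix S:

    D = Dmax(r) * sum_ab S_ab c_a c_b,        Dmax = -mu0 gi gj h / (16 pi^3 r^3)

with c the internuclear unit vector in the molecular frame and r the
internuclear distance.  Observations therefore assemble into a linear
least-squares problem (the classic SVD treatment); agreement between
observed and back-calculated couplings is summarized by the Clore-Garrett
quality factor R = 100 * sqrt(<(Dobs - Dcalc)^2> / (2 <Dobs^2>)) %.

Supported coupling types: one-bond N-H ("NH", atoms N(i)/H(i)) and
two-bond C'-H ("CH", atoms C'(i-1)/HN(i)), geometry taken from the
coordinate model (an effective N-H length override is available since
libration-corrected lengths are conventional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import h as PLANCK_H
from scipy.constants import mu_0 as MU_0

__all__ = [
    "GYROMAGNETIC",
    "RdcObservation",
    "AlignmentTensor",
    "parse_selection",
    "dmax",
    "fit_saupe",
    "svd_fit_tensor",
    "r_factor",
    "saupe_matrix_from_components",
    "IllConditionedError",
]

#: gyromagnetic ratios, rad s^-1 T^-1
GYROMAGNETIC = {"H": 267.52218744e6, "N": -27.116e6, "C": 67.2828e6}

_TYPE_NUCLEI = {"NH": ("N", "H"), "CH": ("C", "H")}


class IllConditionedError(RuntimeError):
    """Raised when the RDC design matrix is rank deficient."""


@dataclass(frozen=True)
class RdcObservation:
    """One measured coupling (Hz) with its uncertainty."""

    residue_id: int
    coupling_type: str  # "NH" (1D_NH) or "CH" (2D_C'H)
    d_obs: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.coupling_type not in _TYPE_NUCLEI:
            raise ValueError(f"unknown coupling type {self.coupling_type!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class AlignmentTensor:
    """Five independent Saupe components (Sxx, Syy, Sxy, Sxz, Syz).

    The full 3x3 matrix is symmetric and traceless by construction
    (Szz = -Sxx - Syy).  Derived magnitudes follow the usual ordering of
    principal values |Szz'| >= |Syy'| >= |Sxx'|.
    """

    components: tuple[float, float, float, float, float]

    @property
    def matrix(self) -> np.ndarray:
        return saupe_matrix_from_components(np.asarray(self.components))

    @property
    def eigenvalues(self) -> np.ndarray:
        """Principal values ordered by increasing |.| (Sxx', Syy', Szz')."""
        w = np.linalg.eigvalsh(self.matrix)
        return w[np.argsort(np.abs(w))]

    @property
    def axial(self) -> float:
        """Principal component of largest magnitude, Szz'."""
        return float(self.eigenvalues[2])

    @property
    def rhombicity(self) -> float:
        """R = (2/3)(Sxx' - Syy')/Szz' in [0, 2/3] up to sign conventions."""
        sxx, syy, szz = self.eigenvalues
        return float((2.0 / 3.0) * (sxx - syy) / szz)


def saupe_matrix_from_components(c: np.ndarray) -> np.ndarray:
    sxx, syy, sxy, sxz, syz = c
    return np.array(
        [[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, -sxx - syy]]
    )


def dmax(nuc_i: str, nuc_j: str, r_angstrom: float) -> float:
    """Static dipolar scale (Hz) for a nucleus pair at distance r."""
    gi, gj = GYROMAGNETIC[nuc_i], GYROMAGNETIC[nuc_j]
    r = r_angstrom * 1e-10
    return -MU_0 * gi * gj * PLANCK_H / (16.0 * np.pi**3 * r**3)


def parse_selection(sel: str) -> set[int]:
    """Parse a residue selection like ``"1-75,100-105!48,57,58"``:
    comma-separated ranges, with exclusions after ``!``."""
    if "!" in sel:
        inc_str, exc_str = sel.split("!", 1)
    else:
        inc_str, exc_str = sel, ""

    def expand(s: str) -> set[int]:
        out: set[int] = set()
        for tok in filter(None, (t.strip() for t in s.split(","))):
            if "-" in tok:
                a, b = tok.split("-")
                out.update(range(int(a), int(b) + 1))
            else:
                out.add(int(tok))
        return out

    return expand(inc_str) - expand(exc_str)


def fit_saupe(
    vectors: np.ndarray,
    d_obs: np.ndarray,
    dmax_arr: np.ndarray,
    sigma: np.ndarray | None = None,
) -> tuple[AlignmentTensor, np.ndarray]:
    """Linear least-squares Saupe fit on explicit unit vectors.

    Parameters
    ----------
    vectors : (n, 3) internuclear unit vectors.
    d_obs : (n,) observed couplings (Hz).
    dmax_arr : (n,) static scale per observation (Hz).
    sigma : optional (n,) weights; plain least squares when omitted (the
        default, matching common practice when uncertainties are uniform).

    Returns (tensor, d_calc).
    """
    v = np.asarray(vectors, dtype=float)
    d = np.asarray(d_obs, dtype=float)
    dm = np.broadcast_to(np.asarray(dmax_arr, dtype=float), d.shape)
    if len(d) < 5:
        raise ValueError("need >= 5 observations for the 5 Saupe components")
    cx, cy, cz = v[:, 0], v[:, 1], v[:, 2]
    A = np.stack(
        [cx * cx - cz * cz, cy * cy - cz * cz, 2 * cx * cy, 2 * cx * cz,
         2 * cy * cz], axis=1,
    ) * dm[:, None]
    b = d
    if sigma is not None:
        w = 1.0 / np.asarray(sigma, dtype=float)
        A = A * w[:, None]
        b = b * w
    cond = np.linalg.cond(A)
    if cond > 1e8:
        raise IllConditionedError(
            f"RDC design matrix ill-conditioned (cond={cond:.3g}); "
            "internuclear vectors are near-collinear"
        )
    s, *_ = np.linalg.lstsq(A, b, rcond=None)
    tensor = AlignmentTensor(components=tuple(float(v_) for v_ in s))
    S = tensor.matrix
    d_calc = dm * np.einsum("ni,ij,nj->n", v, S, v)
    return tensor, d_calc


def svd_fit_tensor(
    observations: list[RdcObservation],
    structure,
    selection: str | set[int] | None = None,
    weighted: bool = False,
    r_nh_override: float | None = 1.041,
) -> tuple[AlignmentTensor, pd.DataFrame]:
    """Fit the alignment tensor against a coordinate model.

    ``structure`` is a :class:`nmrbind.io.StructureModel`; vectors and
    distances are resolved per observation from the coordinates, except
    that the effective N-H bond length defaults to the conventional
    libration-corrected 1.041 A (pass ``r_nh_override=None`` to use the
    model geometry).  Observations whose atoms are missing from the model
    are reported together in the raised error.
    """
    if isinstance(selection, str):
        selection = parse_selection(selection)
    obs = [
        o for o in observations
        if selection is None or o.residue_id in selection
    ]
    vectors, dms, d_obs, sig, kept = [], [], [], [], []
    missing = []
    for o in obs:
        nuc_i, nuc_j = _TYPE_NUCLEI[o.coupling_type]
        try:
            vec, r = structure.internuclear_vector(o.residue_id, o.coupling_type)
        except KeyError as e:
            missing.append(f"residue {o.residue_id} {o.coupling_type}: {e}")
            continue
        if o.coupling_type == "NH" and r_nh_override is not None:
            r = r_nh_override
        vectors.append(vec)
        dms.append(dmax(nuc_i, nuc_j, r))
        d_obs.append(o.d_obs)
        sig.append(o.sigma)
        kept.append(o)
    if missing:
        raise KeyError("atoms missing from model: " + "; ".join(missing))
    tensor, d_calc = fit_saupe(
        np.asarray(vectors), np.asarray(d_obs), np.asarray(dms),
        sigma=np.asarray(sig) if weighted else None,
    )
    table = pd.DataFrame(
        {
            "residue_id": [o.residue_id for o in kept],
            "coupling_type": [o.coupling_type for o in kept],
            "d_obs": d_obs,
            "d_calc": d_calc,
            "sigma": sig,
        }
    )
    return tensor, table


def r_factor(d_obs, d_calc, denominator: str = "observed") -> float:
    """Clore-Garrett R-factor in percent.

    ``denominator="observed"`` (default) uses the observed RMS:
    R = 100 sqrt(<(obs-calc)^2> / (2 <obs^2>)).  The "powder" variant
    replaces 2<obs^2> with the expectation for couplings drawn from an
    isotropic powder of the fitted tensor; it is provided because both
    conventions circulate.
    """
    d_obs = np.asarray(d_obs, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_obs.size == 0:
        raise ValueError("empty coupling lists")
    ms_obs = float(np.mean(d_obs**2))
    if ms_obs == 0.0:
        raise ValueError("all observed couplings are zero")
    if denominator == "observed":
        denom = 2.0 * ms_obs
    elif denominator == "powder":
        denom = 2.0 * float(np.mean(d_calc**2))
        if denom == 0.0:
            raise ValueError("powder denominator is zero (zero tensor)")
    else:
        raise ValueError("denominator must be 'observed' or 'powder'")
    return float(100.0 * np.sqrt(np.mean((d_obs - d_calc) ** 2) / denom))
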