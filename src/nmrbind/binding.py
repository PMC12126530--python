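"""Stoichiometric layer of the two-state binding model.

A ligand (here Hsc70) binds an NMR-visible species (a J-domain protein
construct) in a simple bimolecular scheme::

    JDP + Hsc  <-- k_on / k_off -->  JDP:Hsc          K_d = k_off / k_on

At NMR concentrations the reactants are comparable, so ligand depletion
matters: the free-ligand concentration is obtained from material balance,
which reduces to a quadratic in the bound fraction of the visible species.
The bound fraction ``p_B`` depends on the totals and K_d only; the kinetic
constants then give the pseudo-first-order on-rate ``k_on_app = k_on *
[Hsc]_free`` and the exchange rate ``k_ex = k_on_app + k_off`` that enter
the chemical-exchange forward models.

All concentrations in this module are molar.  File and CLI interfaces use
micromolar and convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "ExchangeParams",
    "TitrationCondition",
    "BindingState",
    "bound_fraction",
    "binding_state",
    "koff_from_kex",
    "kd_from_kex",
]


@dataclass(frozen=True)
class ExchangeParams:
    """Global kinetic parameters of the bimolecular exchange.

    Parameters
    ----------
    k_on : float
        Bimolecular association rate constant (M^-1 s^-1), > 0.
    k_off : float
        Dissociation rate constant (s^-1), >= 0.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on}")
        if self.k_off < 0:
            raise ValueError(f"k_off must be >= 0, got {self.k_off}")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant K_d = k_off / k_on (M)."""
        return self.k_off / self.k_on

    @classmethod
    def from_kd(cls, kd: float, k_off: float) -> "ExchangeParams":
        """Build from (K_d, k_off), the pair the fits report."""
        if not kd > 0:
            raise ValueError(f"kd must be > 0, got {kd}")
        return cls(k_on=k_off / kd, k_off=k_off)


@dataclass(frozen=True)
class TitrationCondition:
    """Total concentrations of one sample (molar).

    ``jdp_total`` is the NMR-visible species, ``hsc_total`` the unlabelled
    ligand added to it.
    """

    jdp_total: float
    hsc_total: float

    def __post_init__(self) -> None:
        if self.jdp_total < 0 or self.hsc_total < 0:
            raise ValueError(
                f"concentrations must be >= 0, got jdp_total={self.jdp_total}, "
                f"hsc_total={self.hsc_total}"
            )

    @classmethod
    def from_uM(cls, jdp_total_uM: float, hsc_total_uM: float) -> "TitrationCondition":
        return cls(jdp_total=jdp_total_uM * 1e-6, hsc_total=hsc_total_uM * 1e-6)


@dataclass(frozen=True)
class BindingState:
    """Derived state of the visible species at one condition.

    Attributes
    ----------
    p_bound : float
        Bound fraction of the NMR-visible species, in [0, 1].
    hsc_free : float
        Free ligand concentration (M).
    k_on_app : float
        Pseudo-first-order on-rate ``k_on * hsc_free`` (s^-1).
    k_off : float
        Dissociation rate (s^-1), carried along for the exchange matrix.
    """

    p_bound: float
    hsc_free: float
    k_on_app: float
    k_off: float

    @property
    def k_ex(self) -> float:
        """Exchange rate k_ex = k_on_app + k_off (s^-1)."""
        return self.k_on_app + self.k_off


def bound_fraction(cond: TitrationCondition, kd: float) -> float:
    """Bound fraction of the visible species from material balance.

    Solves the mass-action equilibrium with ligand depletion.  Writing
    b = [JDP]_tot + [Hsc]_tot + K_d, the complex concentration is the
    physical (smaller) root ``(b - sqrt(b^2 - 4 [JDP]_tot [Hsc]_tot)) / 2``.
    It is evaluated in the algebraically equivalent form
    ``2 [JDP]_tot [Hsc]_tot / (b + sqrt(...))`` which avoids cancellation at
    small bound fractions and yields the correct analytic limit
    ``p -> hsc_total / (hsc_total + kd)`` as ``jdp_total -> 0``.
    """
    if not kd > 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    j, h = cond.jdp_total, cond.hsc_total
    if h == 0.0:
        return 0.0
    b = j + h + kd
    disc = b * b - 4.0 * j * h
    if disc < 0.0:
        # mathematically disc >= Kd^2 > 0; tiny negatives are rounding
        disc = 0.0
    p = 2.0 * h / (b + disc**0.5)
    # guard rounding at the boundaries
    return min(max(p, 0.0), 1.0)


def binding_state(cond: TitrationCondition, params: ExchangeParams) -> BindingState:
    """Full binding state (populations and rates) at one condition."""
    p = bound_fraction(cond, params.kd)
    hsc_free = max(cond.hsc_total - p * cond.jdp_total, 0.0)
    return BindingState(
        p_bound=p,
        hsc_free=hsc_free,
        k_on_app=params.k_on * hsc_free,
        k_off=params.k_off,
    )


def koff_from_kex(cond: TitrationCondition, kd: float, k_ex: float) -> float:
    """Dissociation rate consistent with a measured k_ex at one condition.

    Since ``k_ex = k_off (1 + hsc_free / K_d)`` and the free-ligand
    concentration depends on K_d only, k_off follows in closed form.
    """
    p = bound_fraction(cond, kd)
    hsc_free = max(cond.hsc_total - p * cond.jdp_total, 0.0)
    return k_ex * kd / (kd + hsc_free)


def kd_from_kex(
    cond: TitrationCondition,
    k_off: float,
    k_ex: float,
    bracket: tuple[float, float] = (1e-9, 1.0),
) -> float:
    """K_d consistent with measured (k_off, k_ex) at one condition.

    Root-finds the material-balance system: K_d such that
    ``binding_state`` with ``k_on = k_off / K_d`` returns the target k_ex.
    Requires ``k_ex > k_off`` (some ligand must be present).
    """
    if not k_ex > k_off:
        raise ValueError(f"k_ex ({k_ex}) must exceed k_off ({k_off})")

    def resid(kd: float) -> float:
        params = ExchangeParams.from_kd(kd, k_off)
        return binding_state(cond, params).k_ex - k_ex

    lo, hi = bracket
    return brentq(resid, lo, hi, xtol=1e-15, rtol=1e-14)
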