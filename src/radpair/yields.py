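"""Closed-form ultimate singlet/triplet yields of the radical pair.

With identical spin-selective reaction rates k for the singlet and
triplet channels and a phenomenological spin-relaxation rate r, the
ultimate fractional triplet yield has a closed spectral form.  Writing
W[m,n] = |⟨m|P̂_S|n⟩|² for eigenstates |m⟩ of the spin Hamiltonian with
eigenfrequencies ω_m, and L[m,n] = k(k+r)/((k+r)² + (ω_m−ω_n)²):

    Φ_T(singlet-born) = 3/4 + k/(4(k+r)) − (1/M)  Σ_{m,n} W L
    Φ_T(triplet-born) = 3/4 − k/(12(k+r)) + (1/3M) Σ_{m,n} W L

and Φ_S = 1 − Φ_T in either case.  The double sum runs over all pairs
including m = n, where the Lorentzian reduces to k/(k+r); degenerate
pairs need no special handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constants import K_DEFAULT, R_DEFAULT
from .spin import EigenSystem, RadicalPairSystem

__all__ = [
    "KineticsParams",
    "YieldResult",
    "triplet_yield",
    "triplet_yield_singlet_born",
    "triplet_yield_triplet_born",
    "yield_ratio",
    "percentage_change",
]

Born = Literal["singlet", "triplet"]

#: Yields this far outside [0, 1] are treated as floating-point noise and
#: clipped; anything worse raises.
_CLIP_GUARD = 1e-10


@dataclass(frozen=True)
class KineticsParams:
    """Radical-pair kinetics: reaction rate k and spin-relaxation rate r.

    Both in s⁻¹; 1/k is the pair lifetime and 1/r the coherence lifetime.
    The singlet and triplet reaction rates are identical (both equal k).
    """

    k_per_s: float = K_DEFAULT
    r_per_s: float = R_DEFAULT

    def __post_init__(self) -> None:
        if self.k_per_s <= 0:
            raise ValueError("reaction rate k must be positive")
        if self.r_per_s < 0:
            raise ValueError("relaxation rate r must be non-negative")


@dataclass(frozen=True)
class YieldResult:
    """Fractional triplet/singlet yields for a stated initial condition."""

    born: Born
    phi_t: float
    phi_s: float


def _checked(phi_t: float, born: Born) -> YieldResult:
    if not -_CLIP_GUARD <= phi_t <= 1 + _CLIP_GUARD:
        raise ValueError(f"triplet yield {phi_t!r} is outside [0, 1] beyond tolerance")
    phi_t = float(np.clip(phi_t, 0.0, 1.0))
    return YieldResult(born=born, phi_t=phi_t, phi_s=1.0 - phi_t)


def lorentzian_overlap_sum(eig: EigenSystem, kin: KineticsParams) -> float:
    """(1/M) Σ_{m,n} |⟨m|P̂_S|n⟩|² · k(k+r)/((k+r)² + (ω_m−ω_n)²)."""
    w, delta = eig.singlet_overlap_weights()
    kr = kin.k_per_s + kin.r_per_s
    lorentz = kin.k_per_s * kr / (kr**2 + delta**2)
    return float((w * lorentz).sum() / eig.n_nuclear_configs)


def triplet_yield(eig: EigenSystem, kin: KineticsParams, born: Born) -> YieldResult:
    """Ultimate fractional triplet yield for a singlet- or triplet-born pair."""
    kr = kin.k_per_s + kin.r_per_s
    s = lorentzian_overlap_sum(eig, kin)
    if born == "singlet":
        phi_t = 0.75 + kin.k_per_s / (4 * kr) - s
    elif born == "triplet":
        phi_t = 0.75 - kin.k_per_s / (12 * kr) + s / 3
    else:
        raise ValueError(f"born must be 'singlet' or 'triplet', got {born!r}")
    return _checked(phi_t, born)


def triplet_yield_singlet_born(eig: EigenSystem, kin: KineticsParams) -> YieldResult:
    return triplet_yield(eig, kin, "singlet")


def triplet_yield_triplet_born(eig: EigenSystem, kin: KineticsParams) -> YieldResult:
    return triplet_yield(eig, kin, "triplet")


def yield_ratio(
    system: RadicalPairSystem,
    b_numerator_ut: float,
    b_denominator_ut: float,
    kin: KineticsParams,
    born: Born = "singlet",
) -> float:
    """Triplet-yield ratio Φ_T(B_num)/Φ_T(B_den) for one initial condition.

    The conventional comparison puts the geomagnetic field in the
    numerator and the hypomagnetic field in the denominator, so a ratio
    above 1 means the triplet product (superoxide) is suppressed under
    field shielding.
    """
    if b_numerator_ut < 0 or b_denominator_ut < 0:
        raise ValueError("field magnitudes must be non-negative")
    num = triplet_yield(system.with_field(b_numerator_ut).eigensystem(), kin, born).phi_t
    den = triplet_yield(system.with_field(b_denominator_ut).eigensystem(), kin, born).phi_t
    if den < np.finfo(float).eps:
        raise ZeroDivisionError(f"denominator triplet yield {den!r} is below machine epsilon")
    return num / den


def percentage_change(phi_gmf: float, phi_hmf: float) -> float:
    """Percentage drop in yield going from the control field to the shielded one.

    100·(Φ_GMF − Φ_HMF)/Φ_GMF, i.e. the control value is the baseline.
    """
    if phi_gmf <= 0:
        raise ValueError("baseline yield must be positive")
    return 100.0 * (phi_gmf - phi_hmf) / phi_gmf
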