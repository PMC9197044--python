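"""Spin-operator algebra and the radical-pair spin Hamiltonian.

The model is a pair of spin-1/2 radical electrons (A on the flavin
semiquinone FADH•, B on superoxide O₂•⁻), each optionally coupled to
nuclear spins through isotropic Fermi-contact hyperfine interactions, in
a static magnetic field along z:

    H = ω S_Az + ω S_Bz + Σ_i a_i S_(e_i) · I_i        (rad/s)

with ω = γ_e B. Because every coupling is isotropic, only the field
magnitude matters and the z axis is chosen along the field without loss
of generality.

Tensor-factor order is fixed as electron A ⊗ electron B ⊗ nuclei in list
order; all projectors are embedded accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from functools import reduce
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import GAMMA_E

__all__ = [
    "Nucleus",
    "RadicalPairSystem",
    "EigenSystem",
    "spin_operators",
    "field_to_angular_frequency",
    "build_hamiltonian",
    "diagonalize",
    "fadh_superoxide_pair",
]

#: Hermiticity tolerance, relative to the largest matrix entry.
HERMITICITY_RTOL = 1e-12

#: Guard against accidentally huge Hilbert spaces (4M above this aborts).
MAX_DIMENSION = 4096


def _as_half_integer(spin: float | str | Fraction) -> float:
    """Validate a spin quantum number and return it as a float.

    Accepts floats, Fractions, and strings such as ``"5/2"``.
    """
    value = float(Fraction(spin))
    if value < 0 or round(2 * value) != 2 * value:
        raise ValueError(
            f"spin quantum number must be a non-negative half-integer, got {spin!r}"
        )
    return value


def spin_operators(spin: float | str | Fraction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the (Sx, Sy, Sz) matrices for a spin-I particle.

    Built from the standard angular-momentum ladder operators in the
    |I, m⟩ basis ordered m = I, I-1, …, -I; dimension 2I+1.

    Raises
    ------
    ValueError
        If ``spin`` is not a non-negative half-integer.
    """
    i = _as_half_integer(spin)
    n = int(round(2 * i + 1))
    m = i - np.arange(n)
    sz = np.diag(m).astype(complex)
    s_plus = np.zeros((n, n), dtype=complex)
    for col in range(1, n):
        mm = m[col]
        s_plus[col - 1, col] = np.sqrt(i * (i + 1) - mm * (mm + 1))
    sx = (s_plus + s_plus.conj().T) / 2
    sy = (s_plus - s_plus.conj().T) / 2j
    return sx, sy, sz


def field_to_angular_frequency(field_ut: float, gyromagnetic_rad_s_t: float = GAMMA_E) -> float:
    """Convert a field (or field-unit HFCC) in μT to angular frequency, rad/s."""
    return gyromagnetic_rad_s_t * field_ut * 1e-6


@dataclass(frozen=True)
class Nucleus:
    """A nuclear spin hyperfine-coupled to one of the two radical electrons.

    Parameters
    ----------
    label:
        Short identifier, e.g. ``"H5"`` or ``"17O"``.
    spin:
        Nuclear spin quantum number I (non-negative half-integer).
    hfcc_ut:
        Signed isotropic Fermi-contact coupling constant, μT.
    electron:
        Which radical electron the nucleus couples to, ``"A"`` or ``"B"``.
    """

    label: str
    spin: float
    hfcc_ut: float
    electron: Literal["A", "B"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "spin", _as_half_integer(self.spin))
        if self.electron not in ("A", "B"):
            raise ValueError(f"electron must be 'A' or 'B', got {self.electron!r}")

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


@dataclass(frozen=True)
class RadicalPairSystem:
    """Two spin-1/2 radical electrons, their coupled nuclei, and a static field.

    The Hilbert space has dimension 4M where M is the product of nuclear
    multiplicities (M = 1 with no nuclei).
    """

    nuclei: tuple[Nucleus, ...] = ()
    field_ut: float = 0.0
    gamma_e: float = GAMMA_E

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        if self.field_ut < 0:
            raise ValueError("field magnitude must be non-negative (only |B| matters)")
        if self.gamma_e <= 0:
            raise ValueError("gyromagnetic ratio must be positive")
        if self.dimension > MAX_DIMENSION:
            raise ValueError(
                f"Hilbert dimension 4M = {self.dimension} exceeds the guard "
                f"({MAX_DIMENSION}); reduce the nuclear basis"
            )

    @property
    def n_nuclear_configs(self) -> int:
        """M, the number of nuclear spin configurations."""
        out = 1
        for nuc in self.nuclei:
            out *= nuc.multiplicity
        return out

    @property
    def dimension(self) -> int:
        return 4 * self.n_nuclear_configs

    def with_field(self, field_ut: float) -> "RadicalPairSystem":
        return replace(self, field_ut=field_ut)

    def with_nucleus(self, nucleus: Nucleus) -> "RadicalPairSystem":
        return replace(self, nuclei=self.nuclei + (nucleus,))

    def hamiltonian(self) -> np.ndarray:
        return build_hamiltonian(self)

    def eigensystem(self) -> "EigenSystem":
        return diagonalize(self.hamiltonian(), self.n_nuclear_configs)


def _embed(ops: dict[int, np.ndarray], dims: Sequence[int]) -> np.ndarray:
    """Kronecker-embed single-site operators into the full product space."""
    factors: list[np.ndarray] = [
        ops.get(site, np.eye(d, dtype=complex)) for site, d in enumerate(dims)
    ]
    return reduce(np.kron, factors)


def _electron_singlet_projector() -> np.ndarray:
    up = np.array([1.0, 0.0])
    down = np.array([0.0, 1.0])
    singlet = (np.kron(up, down) - np.kron(down, up)) / np.sqrt(2.0)
    return np.outer(singlet, singlet).astype(complex)


def singlet_projector(n_nuclear_configs: int) -> np.ndarray:
    """P̂_S = |S⟩⟨S| ⊗ 1_M on the 4M-dimensional space (rank M)."""
    return np.kron(_electron_singlet_projector(), np.eye(n_nuclear_configs, dtype=complex))


def triplet_projector(n_nuclear_configs: int) -> np.ndarray:
    """P̂_T = 1 − P̂_S (rank 3M)."""
    return np.eye(4 * n_nuclear_configs, dtype=complex) - singlet_projector(n_nuclear_configs)


def build_hamiltonian(system: RadicalPairSystem) -> np.ndarray:
    """Assemble the Zeeman + isotropic-hyperfine Hamiltonian, in rad/s.

    H = ω(S_Az + S_Bz) + Σ_i a_i S_(e_i)·I_i with ω = γ_e B; each term is
    Kronecker-embedded into the 4M-dimensional product space in the fixed
    A ⊗ B ⊗ nuclei order.
    """
    dims = [2, 2] + [nuc.multiplicity for nuc in system.nuclei]
    sx, sy, sz = spin_operators(0.5)
    omega = field_to_angular_frequency(system.field_ut, system.gamma_e)

    h = omega * (_embed({0: sz}, dims) + _embed({1: sz}, dims))
    for j, nuc in enumerate(system.nuclei):
        e_site = 0 if nuc.electron == "A" else 1
        a_omega = field_to_angular_frequency(nuc.hfcc_ut, system.gamma_e)
        ix, iy, iz = spin_operators(nuc.spin)
        for s_e, i_n in ((sx, ix), (sy, iy), (sz, iz)):
            h = h + a_omega * _embed({e_site: s_e, 2 + j: i_n}, dims)
    return h


@dataclass(frozen=True)
class EigenSystem:
    """Eigendecomposition of the spin Hamiltonian with attached projectors.

    ``eigenvalues_rad_s`` holds ω_m in ascending order; ``eigenvectors``
    columns are the corresponding |m⟩. The singlet projector has rank M,
    the triplet projector rank 3M, and they sum to the identity.
    """

    eigenvalues_rad_s: np.ndarray
    eigenvectors: np.ndarray
    singlet_projector: np.ndarray
    triplet_projector: np.ndarray
    n_nuclear_configs: int
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def dimension(self) -> int:
        return self.eigenvalues_rad_s.size

    def singlet_overlap_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (W, Δω): W[m,n] = |⟨m|P̂_S|n⟩|² and Δω[m,n] = ω_m − ω_n.

        These two matrices are the only ingredients the yield formulas
        and the time-domain traces need, so they are cached.
        """
        if "weights" not in self._cache:
            v = self.eigenvectors
            s_eig = v.conj().T @ self.singlet_projector @ v
            w = np.abs(s_eig) ** 2
            omega = self.eigenvalues_rad_s
            self._cache["weights"] = (w, omega[:, None] - omega[None, :])
        return self._cache["weights"]


def diagonalize(hamiltonian: np.ndarray, n_nuclear_configs: int | None = None) -> EigenSystem:
    """Diagonalize a Hermitian spin Hamiltonian and attach the projectors.

    Parameters
    ----------
    hamiltonian:
        Hermitian matrix of dimension 4M in rad/s.
    n_nuclear_configs:
        M; inferred from the matrix dimension when omitted.

    Raises
    ------
    ValueError
        If the matrix is not Hermitian to within :data:`HERMITICITY_RTOL`
        (relative to the largest entry), or the dimension is not 4M.
    """
    h = np.asarray(hamiltonian, dtype=complex)
    scale = np.abs(h).max() or 1.0
    deviation = np.abs(h - h.conj().T).max()
    if deviation > HERMITICITY_RTOL * scale:
        raise ValueError(
            f"Hamiltonian is not Hermitian: max |H - H†| = {deviation:.3e} "
            f"exceeds {HERMITICITY_RTOL:.0e} × max|entry| = {HERMITICITY_RTOL * scale:.3e}"
        )
    dim = h.shape[0]
    if n_nuclear_configs is None:
        if dim % 4:
            raise ValueError(f"dimension {dim} is not 4M for integer M")
        n_nuclear_configs = dim // 4
    if dim != 4 * n_nuclear_configs:
        raise ValueError(f"dimension {dim} does not match 4M = {4 * n_nuclear_configs}")

    eigenvalues, eigenvectors = np.linalg.eigh(h)
    return EigenSystem(
        eigenvalues_rad_s=eigenvalues,
        eigenvectors=eigenvectors,
        singlet_projector=singlet_projector(n_nuclear_configs),
        triplet_projector=triplet_projector(n_nuclear_configs),
        n_nuclear_configs=n_nuclear_configs,
    )


def fadh_superoxide_pair(field_ut: float, gamma_e: float = GAMMA_E) -> RadicalPairSystem:
    """The default [FADH• … O₂•⁻] pair: one H5 proton on electron A.

    The superoxide electron carries no hyperfine coupling because ¹⁶O has
    zero nuclear spin; see :mod:`radpair.isotope` for the ¹⁷O variant.
    """
    from .constants import A1_H5_UT

    return RadicalPairSystem(
        nuclei=(Nucleus("H5", 0.5, A1_H5_UT, "A"),),
        field_ut=field_ut,
        gamma_e=gamma_e,
    )
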