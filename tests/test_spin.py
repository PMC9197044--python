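"""Spin operators, Hamiltonian assembly, and eigendecomposition."""

import numpy as np
import pytest

from radpair import (
    GMF_UT,
    KineticsParams,
    Nucleus,
    RadicalPairSystem,
    build_hamiltonian,
    diagonalize,
    field_to_angular_frequency,
    spin_operators,
    triplet_yield_singlet_born,
)
from radpair.constants import GAMMA_E
from radpair.spin import MAX_DIMENSION


@pytest.mark.parametrize("spin", [0.5, 1.0, 1.5, 2.5, "5/2"])
def test_spin_operators_algebra(spin):
    """Ladder-built matrices satisfy the su(2) algebra and Casimir identity."""
    sx, sy, sz = spin_operators(spin)
    i = float(sz[0, 0].real)
    n = sx.shape[0]
    assert n == int(round(2 * i + 1))
    # commutators [Sx, Sy] = i Sz and cyclic
    np.testing.assert_allclose(sx @ sy - sy @ sx, 1j * sz, atol=1e-12)
    np.testing.assert_allclose(sy @ sz - sz @ sy, 1j * sx, atol=1e-12)
    np.testing.assert_allclose(sz @ sx - sx @ sz, 1j * sy, atol=1e-12)
    # Casimir S² = I(I+1)·1
    casimir = sx @ sx + sy @ sy + sz @ sz
    np.testing.assert_allclose(casimir, i * (i + 1) * np.eye(n), atol=1e-12)
    # Sz diagonal I, I-1, ..., -I
    np.testing.assert_allclose(np.diag(sz).real, i - np.arange(n), atol=1e-15)


def test_spin_half_matrices_are_textbook():
    sx, sy, sz = spin_operators(0.5)
    np.testing.assert_allclose(sz, np.diag([0.5, -0.5]))
    np.testing.assert_allclose(sx, np.array([[0, 0.5], [0.5, 0]]))
    np.testing.assert_allclose(sy, np.array([[0, -0.5j], [0.5j, 0]]))


@pytest.mark.parametrize("bad", [0.3, -0.5, "2/3"])
def test_non_half_integer_spin_rejected(bad):
    with pytest.raises(ValueError, match="half-integer"):
        spin_operators(bad)


def test_field_conversion_is_gamma_times_tesla():
    assert field_to_angular_frequency(1e6, GAMMA_E) == pytest.approx(GAMMA_E)
    assert field_to_angular_frequency(0.0) == 0.0


class TestHamiltonian:
    def test_dimensions(self, pair_o16):
        assert pair_o16.dimension == 8
        assert pair_o16.hamiltonian().shape == (8, 8)
        two = pair_o16.with_nucleus(Nucleus("17O", "5/2", 1886.8, "B"))
        assert two.dimension == 48
        assert two.n_nuclear_configs == 12

    def test_zeeman_only_spectrum(self):
        """Two bare electrons in a field: eigenvalues {+ω, 0, 0, −ω}."""
        system = RadicalPairSystem(nuclei=(), field_ut=50.0)
        omega = field_to_angular_frequency(50.0)
        eig = system.eigensystem()
        np.testing.assert_allclose(
            eig.eigenvalues_rad_s, [-omega, 0.0, 0.0, omega], atol=1e-3
        )

    def test_hermitian(self, pair_o16):
        h = pair_o16.hamiltonian()
        np.testing.assert_allclose(h, h.conj().T, atol=1e-12 * np.abs(h).max())

    def test_dimension_guard(self):
        with pytest.raises(ValueError, match="guard"):
            RadicalPairSystem(
                nuclei=tuple(
                    Nucleus(f"n{i}", "5/2", 100.0, "A") for i in range(5)
                ),
                field_ut=1.0,
            )
        assert 4 * 6**5 > MAX_DIMENSION  # the guard is what rejected it

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            RadicalPairSystem(nuclei=(), field_ut=-1.0)


class TestDiagonalize:
    def test_diagonal_input(self):
        h = np.diag([3.0, 1.0, 2.0, 0.0]).astype(complex)
        eig = diagonalize(h)
        np.testing.assert_allclose(eig.eigenvalues_rad_s, [0.0, 1.0, 2.0, 3.0])
        np.testing.assert_allclose(np.abs(eig.eigenvectors), np.eye(4)[:, [3, 1, 2, 0]])

    def test_reconstruction_and_projectors(self, pair_o16, eig_gmf):
        h = pair_o16.hamiltonian()
        v, w = eig_gmf.eigenvectors, eig_gmf.eigenvalues_rad_s
        np.testing.assert_allclose(v @ np.diag(w) @ v.conj().T, h, atol=1e-6 * np.abs(h).max())
        m = eig_gmf.n_nuclear_configs
        assert np.trace(eig_gmf.singlet_projector).real == pytest.approx(m)
        assert np.trace(eig_gmf.triplet_projector).real == pytest.approx(3 * m)
        np.testing.assert_allclose(
            eig_gmf.singlet_projector + eig_gmf.triplet_projector,
            np.eye(4 * m),
            atol=1e-15,
        )

    def test_spectator_nucleus_doubles_degeneracy(self):
        """Zeeman-only with one uncoupled spin-1/2: every level is doubled."""
        system = RadicalPairSystem(
            nuclei=(Nucleus("x", 0.5, 0.0, "A"),), field_ut=50.0
        )
        w = np.sort(system.eigensystem().eigenvalues_rad_s)
        np.testing.assert_allclose(w[0::2], w[1::2], atol=1e-3)

    def test_overlap_weights_sum_to_m(self, eig_gmf):
        """Σ_{m,n} |⟨m|P̂_S|n⟩|² = Tr P̂_S² = M by idempotence."""
        w, _ = eig_gmf.singlet_overlap_weights()
        assert w.sum() == pytest.approx(eig_gmf.n_nuclear_configs, abs=1e-10)

    def test_non_hermitian_rejected(self):
        h = np.zeros((4, 4), dtype=complex)
        h[0, 1] = 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            diagonalize(h)


class TestSymmetries:
    def test_yield_invariant_under_nuclei_permutation(self, default_kinetics):
        """Reordering the nuclear tensor factors must not move the yield."""
        n1 = Nucleus("H5", 0.5, -802.9, "A")
        n2 = Nucleus("17O", "5/2", 1886.8, "B")
        a = RadicalPairSystem(nuclei=(n1, n2), field_ut=GMF_UT)
        b = RadicalPairSystem(nuclei=(n2, n1), field_ut=GMF_UT)
        phi_a = triplet_yield_singlet_born(a.eigensystem(), default_kinetics).phi_t
        phi_b = triplet_yield_singlet_born(b.eigensystem(), default_kinetics).phi_t
        assert phi_a == pytest.approx(phi_b, abs=1e-10)

    def test_field_sign_symmetry(self, pair_o16, default_kinetics):
        """Φ depends on |B| only: negating every Zeeman term changes nothing."""
        h_pos = pair_o16.hamiltonian()
        # flip the field by flipping the sign of the Zeeman part
        zero = pair_o16.with_field(0.0).hamiltonian()
        h_neg = zero - (h_pos - zero)
        phi_pos = triplet_yield_singlet_born(diagonalize(h_pos), default_kinetics).phi_t
        phi_neg = triplet_yield_singlet_born(diagonalize(h_neg), default_kinetics).phi_t
        assert phi_pos == pytest.approx(phi_neg, abs=1e-10)

    def test_hfcc_sign_symmetry(self, default_kinetics):
        """With a single nucleus the yield is even in the coupling sign too."""
        for sign in (+1, -1):
            system = RadicalPairSystem(
                nuclei=(Nucleus("H5", 0.5, sign * 802.9, "A"),), field_ut=GMF_UT
            )
            phi = triplet_yield_singlet_born(system.eigensystem(), default_kinetics).phi_t
            assert phi == pytest.approx(0.596924, abs=1e-5)
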