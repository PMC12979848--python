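import numpy as np
import pytest

from qgdm.graph_operators import (
    SIGMA_X,
    SIGMA_Y,
    SIGMA_Z,
    EdgeOperatorField,
    ExtendedLaplacianSpec,
    VertexOperatorField,
    extended_quantum_laplacian,
    lift_site_operators,
    quantum_divergence,
    quantum_enhanced_laplacian,
    quantum_gradient,
    swap_operator,
)
from qgdm.hilbert_space import CompositeSpace, PureState, random_density, random_pure_state
from qgdm.network_core import ProteinGraph, classical_laplacian

from conftest import random_graph


class TestQuantumEnhancedLaplacian:
    def test_hbar_zero_is_classical(self, triangle):
        lq = quantum_enhanced_laplacian(triangle, {"a": 1.0, "b": 2.0}, hbar=0.0)
        assert np.allclose(lq, classical_laplacian(triangle))

    def test_two_path_with_unit_frequencies(self):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        lq = quantum_enhanced_laplacian(g, {"a": 1.0, "b": 1.0}, hbar=1.0)
        assert np.allclose(lq, [[2, -1], [-1, 2]])

    def test_uniform_omega_shifts_spectrum(self, rng):
        g = random_graph(rng, 6)
        omega = 0.7
        base = np.sort(np.linalg.eigvalsh(classical_laplacian(g)))
        shifted = np.sort(
            np.linalg.eigvalsh(
                quantum_enhanced_laplacian(g, {v: omega for v in g.vertices})
            )
        )
        assert np.allclose(shifted, base + omega, atol=1e-10)


class TestSwapOperator:
    def test_exchanges_basis_states(self, two_qubit_space):
        p = swap_operator(two_qubit_space, "a", "b")
        psi01 = np.array([0, 1, 0, 0], dtype=complex)
        psi10 = np.array([0, 0, 1, 0], dtype=complex)
        assert np.allclose(p @ psi01, psi10)

    def test_fixes_symmetric_products(self, rng, two_qubit_space):
        v = rng.standard_normal(2) + 1j * rng.standard_normal(2)
        v /= np.linalg.norm(v)
        prod = np.kron(v, v)
        p = swap_operator(two_qubit_space, "a", "b")
        assert np.allclose(p @ prod, prod)

    @pytest.mark.parametrize("d", [2, 3])
    def test_involution_hermitian_unitary(self, d):
        sp = CompositeSpace(["a", "b", "c"], d)
        p = swap_operator(sp, "a", "c")
        assert np.allclose(p @ p, np.eye(sp.total_dim))
        assert np.allclose(p, p.conj().T)

    def test_unequal_dims_rejected(self):
        sp = CompositeSpace(["a", "b"], [2, 3])
        with pytest.raises(ValueError, match="equal local dims"):
            swap_operator(sp, "a", "b")


def _extended_laplacian_oracle(spec, space):
    """Nested-loop basis construction: explicit digit swaps + sigma_z signs."""
    dims = space.local_dims
    n = space.n_sites
    d = space.total_dim
    pos = {s: k for k, s in enumerate(space.site_order)}
    strides = [int(np.prod(dims[k + 1:])) for k in range(n)]

    def digits(idx):
        out = []
        for k in range(n):
            out.append((idx // strides[k]) % dims[k])
        return out

    op = np.zeros((d, d), dtype=complex)
    for col in range(d):
        dig = digits(col)
        for (a, b), w in spec.graph.weights.items():
            ia, ib = pos[a], pos[b]
            swapped = list(dig)
            swapped[ia], swapped[ib] = swapped[ib], swapped[ia]
            row = sum(v * strides[k] for k, v in enumerate(swapped))
            op[col, col] += w
            op[row, col] -= w
        for v in spec.graph.vertices:
            w_i = spec.omega(v)
            if w_i:
                sign = 1.0 if dig[pos[v]] == 0 else -1.0
                op[col, col] += spec.hbar * w_i * sign
    return op


class TestExtendedQuantumLaplacian:
    def test_annihilates_symmetric_product_single_edge(self, rng, two_qubit_space):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        op = extended_quantum_laplacian(ExtendedLaplacianSpec(g), two_qubit_space)
        v = rng.standard_normal(2) + 1j * rng.standard_normal(2)
        v /= np.linalg.norm(v)
        assert np.linalg.norm(op @ np.kron(v, v)) < 1e-12

    def test_single_edge_action_on_01(self, two_qubit_space):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        op = extended_quantum_laplacian(ExtendedLaplacianSpec(g), two_qubit_space)
        psi01 = np.array([0, 1, 0, 0], dtype=complex)
        expected = np.array([0, 1, -1, 0], dtype=complex)  # |01> - |10>
        assert np.allclose(op @ psi01, expected)

    def test_pure_onsite_term_eigenvalue(self, two_qubit_space):
        # no edges, omega on both: |00> has eigenvalue 2*omega under
        # sigma_z |0> = +|0>
        omega = 0.8
        g = ProteinGraph(["a", "b"])
        spec = ExtendedLaplacianSpec(g, {"a": omega, "b": omega})
        op = extended_quantum_laplacian(spec, two_qubit_space)
        psi00 = np.array([1, 0, 0, 0], dtype=complex)
        assert np.allclose(op @ psi00, 2 * omega * psi00)

    def test_topological_part_psd_and_symmetric_kernel(self, rng):
        for n in (2, 3, 4):
            g = random_graph(rng, n, p=0.8)
            if not g.edges:
                continue
            sp = CompositeSpace(g.vertices, 2)
            op = extended_quantum_laplacian(ExtendedLaplacianSpec(g), sp)
            assert np.allclose(op, op.conj().T)
            assert np.linalg.eigvalsh(op)[0] > -1e-10
            v = rng.standard_normal(2) + 1j * rng.standard_normal(2)
            v /= np.linalg.norm(v)
            prod = v
            for _ in range(n - 1):
                prod = np.kron(prod, v)
            assert np.linalg.norm(op @ prod) < 1e-10

    def test_matches_nested_loop_oracle(self, rng):
        for n in (2, 3):
            g = random_graph(rng, n, p=0.9)
            sp = CompositeSpace(g.vertices, 2)
            spec = ExtendedLaplacianSpec(
                g, {v: float(rng.uniform(-1, 1)) for v in g.vertices}
            )
            assert np.allclose(
                extended_quantum_laplacian(spec, sp),
                _extended_laplacian_oracle(spec, sp),
            )

    def test_omega_on_non_qubit_site_rejected(self):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        sp = CompositeSpace(["a", "b"], [3, 3])
        with pytest.raises(ValueError, match="two-level"):
            extended_quantum_laplacian(
                ExtendedLaplacianSpec(g, {"a": 1.0}), sp
            )


class TestQuantumGradient:
    def test_equal_operators_give_zero(self, two_qubit_space):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        f = lift_site_operators({"a": SIGMA_X, "b": SIGMA_X}, two_qubit_space)
        grad = quantum_gradient(f, g)
        assert np.allclose(grad[("a", "b")], 0)

    def test_pauli_commutator(self):
        # [sigma_z, sigma_x] = 2i sigma_y, single shared qubit space
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        f = VertexOperatorField({"a": SIGMA_X, "b": SIGMA_Z})
        grad = quantum_gradient(f, g)
        assert np.allclose(grad[("a", "b")], 2j * SIGMA_Y)

    def test_sqrt_weight_scaling(self):
        g1 = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        g4 = ProteinGraph(["a", "b"], {("a", "b"): 4.0})
        f = VertexOperatorField({"a": SIGMA_X, "b": SIGMA_Z})
        assert np.allclose(
            quantum_gradient(f, g4)[("a", "b")],
            2 * quantum_gradient(f, g1)[("a", "b")],
        )

    def test_antisymmetry_and_bilinear_scaling(self, rng):
        g = random_graph(rng, 4, p=0.9)
        ops1 = {
            v: rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
            for v in g.vertices
        }
        f1 = VertexOperatorField(ops1)
        g1 = quantum_gradient(f1, g)
        for a, b in g.edges:
            assert np.allclose(g1[(a, b)], -g1[(b, a)])
        # the commutator is bilinear in the field: scaling f by c scales the
        # gradient by c^2
        f_scaled = VertexOperatorField({v: 2.5 * ops1[v] for v in g.vertices})
        gsc = quantum_gradient(f_scaled, g)
        for a, b in g.edges:
            assert np.allclose(gsc[(a, b)], 2.5**2 * g1[(a, b)])

    def test_missing_vertex_operator_errors(self):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        f = VertexOperatorField({"a": SIGMA_X})
        with pytest.raises(KeyError):
            quantum_gradient(f, g)


class TestQuantumDivergence:
    def _rho_locals(self, g, rng, dim=2):
        sp = CompositeSpace(["loc"], dim)
        return {v: random_density(sp, rng) for v in g.vertices}

    def test_zero_field_gives_zero(self, rng):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.0})
        field = EdgeOperatorField(
            {("a", "b"): np.zeros((2, 2)), ("b", "a"): np.zeros((2, 2))}
        )
        div = quantum_divergence(field, g, self._rho_locals(g, rng))
        assert np.allclose(div["a"], 0) and np.allclose(div["b"], 0)

    def test_maximally_mixed_identity_formula(self, rng):
        # anticommutator with I/d: (div F)(i) = (2/d) sum_j sqrt(W) F(i,j)
        d = 2
        g = ProteinGraph(["a", "b", "c"], {("a", "b"): 2.0, ("a", "c"): 3.0})
        fops = {}
        for e in [("a", "b"), ("b", "a"), ("a", "c"), ("c", "a")]:
            m = rng.standard_normal((d, d))
            fops[e] = m + m.T  # Hermitian
        field = EdgeOperatorField(fops)
        sp = CompositeSpace(["loc"], d)
        from qgdm.hilbert_space import DensityMatrix

        rho = {v: DensityMatrix(sp, np.eye(d) / d) for v in g.vertices}
        div = quantum_divergence(field, g, rho)
        expected = (2 / d) * (
            np.sqrt(2.0) * fops[("a", "b")] + np.sqrt(3.0) * fops[("a", "c")]
        )
        assert np.allclose(div["a"], expected)

    def test_isolated_vertex_zero(self, rng):
        g = ProteinGraph(["a", "b", "x"], {("a", "b"): 1.0})
        fops = {("a", "b"): np.eye(2), ("b", "a"): np.eye(2)}
        div = quantum_divergence(
            EdgeOperatorField(fops), g, self._rho_locals(g, rng)
        )
        assert np.allclose(div["x"], 0)

    def test_hermiticity_preserved(self, rng):
        g = ProteinGraph(["a", "b"], {("a", "b"): 1.7})
        m = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
        herm = m + m.conj().T
        field = EdgeOperatorField({("a", "b"): herm, ("b", "a"): herm})
        div = quantum_divergence(field, g, self._rho_locals(g, rng))
        assert np.allclose(div["a"], div["a"].conj().T)
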