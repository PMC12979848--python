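import numpy as np
import pytest
import scipy.linalg

from qgdm.hilbert_space import (
    CompositeSpace,
    DensityMatrix,
    PureState,
    partial_trace,
    random_density,
    random_pure_state,
)
from qgdm.quantum_measures import (
    BoundCheck,
    EntropyOptions,
    ModulePartition,
    check_bound,
    cooperative_probability,
    CooperativityParams,
    cooperativity_factor,
    entanglement_bound,
    entanglement_entropy,
    interaction_entropy,
    l1_coherence,
    von_neumann_entropy,
)


class TestVonNeumannEntropy:
    def test_pure_state_zero(self, rng):
        sp = CompositeSpace(["a", "b"], 2)
        for _ in range(5):
            rho = random_pure_state(sp, rng).to_density()
            assert von_neumann_entropy(rho) == pytest.approx(0.0, abs=1e-9)

    def test_maximally_mixed_qubit_one_bit(self, qubit_space):
        rho = DensityMatrix(qubit_space, np.eye(2) / 2)
        assert von_neumann_entropy(rho) == pytest.approx(1.0)

    def test_biased_diagonal_scalar_formula(self, qubit_space):
        rho = DensityMatrix(qubit_space, np.diag([0.25, 0.75]))
        expected = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert von_neumann_entropy(rho) == pytest.approx(expected, abs=1e-12)

    def test_natural_log_base(self, qubit_space):
        rho = DensityMatrix(qubit_space, np.eye(2) / 2)
        opts = EntropyOptions(log_base=np.e)
        assert von_neumann_entropy(rho, opts) == pytest.approx(np.log(2))

    def test_bounded_by_log_dim(self, rng):
        sp = CompositeSpace(["a", "b"], 2)
        for _ in range(10):
            s = von_neumann_entropy(random_density(sp, rng))
            assert -1e-12 <= s <= 2.0 + 1e-9


class TestInteractionEntropy:
    def test_pure_product_zero(self, rng, two_qubit_space):
        va = rng.standard_normal(2) + 1j * rng.standard_normal(2)
        vb = rng.standard_normal(2) + 1j * rng.standard_normal(2)
        psi = PureState.from_product(two_qubit_space, [va, vb])
        assert interaction_entropy(psi.to_density()) == pytest.approx(0.0, abs=1e-9)

    def test_bell_state_printed_sign(self, bell_state):
        # joint entropy 0, marginals 1 bit each -> H = -2 as printed
        assert interaction_entropy(bell_state.to_density()) == pytest.approx(-2.0, abs=1e-9)
        assert interaction_entropy(
            bell_state.to_density(), conventional=True
        ) == pytest.approx(2.0, abs=1e-9)

    def test_mixed_product_additivity(self, rng, two_qubit_space):
        rho_a = random_density(CompositeSpace(["a"], 2), rng)
        rho_b = random_density(CompositeSpace(["b"], 2), rng)
        joint = DensityMatrix(two_qubit_space, np.kron(rho_a.matrix, rho_b.matrix))
        assert interaction_entropy(joint) == pytest.approx(0.0, abs=1e-9)

    def test_sign_identity_with_entanglement_entropy(self, rng, two_qubit_space):
        rho = random_density(two_qubit_space, rng)
        h = interaction_entropy(rho)
        s = entanglement_entropy(rho, (["a"], ["b"]))
        assert h == pytest.approx(-s, abs=1e-9)

    def test_wrong_site_count_rejected(self, rng):
        sp = CompositeSpace(["a", "b", "c"], 2)
        with pytest.raises(ValueError, match="two-site"):
            interaction_entropy(random_density(sp, rng))


class TestL1Coherence:
    def test_diagonal_is_zero(self, qubit_space):
        assert l1_coherence(DensityMatrix(qubit_space, np.diag([0.3, 0.7]))) == 0.0

    def test_plus_state_is_one(self, plus_state):
        assert l1_coherence(plus_state.to_density()) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        sp = CompositeSpace(["a", "b"], 2)
        rho = random_density(sp, rng)
        oracle = sum(
            abs(rho.matrix[i, j])
            for i in range(4)
            for j in range(4)
            if i != j
        )
        assert l1_coherence(rho) == pytest.approx(oracle, abs=1e-12)

    def test_basis_dependence(self, qubit_space):
        # a diagonal state has zero coherence; rotating by Hadamard creates it
        rho = DensityMatrix(qubit_space, np.diag([0.9, 0.1]))
        had = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        rotated = DensityMatrix(qubit_space, had @ rho.matrix @ had)
        assert l1_coherence(rho) == 0.0
        assert l1_coherence(rotated) > 0.5


class TestEntanglementEntropy:
    def test_product_state_zero(self, rng, two_qubit_space):
        rho_a = random_density(CompositeSpace(["a"], 2), rng)
        rho_b = random_density(CompositeSpace(["b"], 2), rng)
        joint = DensityMatrix(two_qubit_space, np.kron(rho_a.matrix, rho_b.matrix))
        assert entanglement_entropy(joint, (["a"], ["b"])) == pytest.approx(0.0, abs=1e-9)

    def test_bell_state_two_bits(self, bell_state):
        assert entanglement_entropy(
            bell_state.to_density(), (["a"], ["b"])
        ) == pytest.approx(2.0, abs=1e-9)

    def test_pure_state_purity_symmetry(self, rng):
        # globally pure: S(A:B) = 2 S(rho_A)
        sp = CompositeSpace(["a", "b", "c"], 2)
        rho = random_pure_state(sp, rng).to_density()
        s_ab = entanglement_entropy(rho, (["a"], ["b", "c"]))
        s_a = von_neumann_entropy(partial_trace(rho, ["a"]))
        assert s_ab == pytest.approx(2 * s_a, abs=1e-8)

    def test_local_unitary_invariance(self, rng, two_qubit_space):
        rho = random_density(two_qubit_space, rng)
        s0 = entanglement_entropy(rho, (["a"], ["b"]))
        ua = scipy.linalg.expm(1j * _random_hermitian(rng, 2))
        ub = scipy.linalg.expm(1j * _random_hermitian(rng, 2))
        u = np.kron(ua, ub)
        rotated = DensityMatrix(two_qubit_space, u @ rho.matrix @ u.conj().T)
        assert entanglement_entropy(rotated, (["a"], ["b"])) == pytest.approx(
            s0, abs=1e-9
        )

    def test_bad_partitions_rejected(self, rng, two_qubit_space):
        rho = random_density(two_qubit_space, rng)
        with pytest.raises(ValueError):
            entanglement_entropy(rho, (["a"], []))
        with pytest.raises(ValueError):
            entanglement_entropy(rho, (["a"], ["a"]))
        with pytest.raises(ValueError):
            entanglement_entropy(rho, (["a"], ["c"]))

    def test_subadditivity_on_random_states(self, rng):
        sp = CompositeSpace(["a", "b"], [4, 4])
        for _ in range(50):
            rho = random_density(sp, rng)
            s_ab = von_neumann_entropy(rho)
            s_a = von_neumann_entropy(partial_trace(rho, ["a"]))
            s_b = von_neumann_entropy(partial_trace(rho, ["b"]))
            assert s_ab <= s_a + s_b + 1e-9


def _random_hermitian(rng, d):
    m = rng.standard_normal((d, d)) + 1j * rng.standard_normal((d, d))
    return (m + m.conj().T) / 2


class TestCooperativity:
    def test_zero_entanglement_independent_binding(self):
        assert cooperativity_factor(0.0, 2.0) == 1.0

    def test_zero_alpha(self):
        assert cooperativity_factor(5.0, 0.0) == 1.0

    def test_bell_state_half_alpha(self, bell_state):
        s = entanglement_entropy(bell_state.to_density(), (["a"], ["b"]))
        assert cooperativity_factor(s, 0.5) == pytest.approx(2.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cooperativity_factor(-1.0, 0.5)
        with pytest.raises(ValueError):
            cooperativity_factor(1.0, -0.5)

    def test_cooperative_probability_caps_at_one(self, bell_state):
        params = CooperativityParams(5.0, (("a",), ("b",)))
        p = cooperative_probability(bell_state.to_density(), params, 0.5)
        assert p == 1.0


class TestEntanglementBound:
    def test_modules_two_three(self):
        part = ModulePartition((("a", "b"), ("c", "d", "e")), local_dim=2)
        bound = entanglement_bound(part)
        assert bound.pairwise[(0, 1)] == pytest.approx(2.0)  # min{2,3} * log2(2)

    def test_single_module_no_inter_terms(self):
        part = ModulePartition((("a", "b"),), local_dim=2)
        assert entanglement_bound(part).pairwise == {}

    def test_singleton_modules(self):
        part = ModulePartition((("a",), ("b",)), local_dim=2)
        assert entanglement_bound(part).pairwise[(0, 1)] == pytest.approx(1.0)

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ModulePartition((("a", "b"), ("b", "c")))


class TestCheckBound:
    def test_random_pure_states_satisfy_bound(self, rng):
        # Monte-Carlo: S(rho_m) <= min sizes * log d across 2|2 bipartitions
        sp = CompositeSpace(["a", "b", "c", "d"], 2)
        part = ModulePartition((("a", "b"), ("c", "d")), local_dim=2)
        for _ in range(100):
            rho = random_pure_state(sp, rng).to_density()
            res = check_bound(rho, part)
            assert res.holds

    def test_product_state_full_margin(self, rng):
        sp = CompositeSpace(["a", "b"], 2)
        part = ModulePartition((("a",), ("b",)), local_dim=2)
        rho_a = random_pure_state(CompositeSpace(["a"], 2), rng).to_density()
        rho_b = random_pure_state(CompositeSpace(["b"], 2), rng).to_density()
        joint = DensityMatrix(sp, np.kron(rho_a.matrix, rho_b.matrix))
        res = check_bound(joint, part)
        assert res.worst_margin == pytest.approx(1.0, abs=1e-9)

    def test_maximally_entangled_two_by_two(self):
        # both readings reported: S(rho_A) saturates the bound at 2 bits,
        # the mutual-information reading reaches 4 bits (twice the bound)
        sp = CompositeSpace(["a", "b", "c", "d"], 2)
        amps = np.zeros(16, dtype=complex)
        for k in range(4):
            amps[k * 4 + k] = 0.5  # sum_k |k>_AB |k>_CD / 2
        rho = PureState(sp, amps).to_density()
        part = ModulePartition((("a", "b"), ("c", "d")), local_dim=2)
        res = check_bound(rho, part)
        d = res.details[(0, 1)]
        assert d["bound"] == pytest.approx(2.0)
        assert d["entanglement_entropy"] == pytest.approx(2.0, abs=1e-9)
        assert d["mutual_information"] == pytest.approx(4.0, abs=1e-9)
        assert res.holds and res.worst_margin == pytest.approx(0.0, abs=1e-9)

    def test_partition_must_cover_sites(self, rng, two_qubit_space):
        rho = random_density(two_qubit_space, rng)
        with pytest.raises(ValueError, match="cover"):
            check_bound(rho, ModulePartition((("a",),)))
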