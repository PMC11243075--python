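"""Node-function encoding, forward evaluation, and analytic gradients."""

import numpy as np
import pytest

from gmshift.chem_graph import build_rooted_dag, enumerate_ring_carbons, parse_tagged_smiles
from gmshift.node_model import (
    N_IN,
    N_STATIC,
    ModelError,
    NodeFunctionParameters,
    PackedGraphs,
    ScalingSpec,
    encode_node,
    gm_forward,
    gm_jacobian,
    parameter_count,
)
from gmshift.synthetic import generate_molecules


def finite_difference_gradient(dag, params, scaling, eps=1e-6):
    grad = np.empty(params.q)
    for k in range(params.q):
        tp, tm = params.theta.copy(), params.theta.copy()
        tp[k] += eps
        tm[k] -= eps
        grad[k] = (
            gm_forward(dag, NodeFunctionParameters(h=params.h, theta=tp), scaling)
            - gm_forward(dag, NodeFunctionParameters(h=params.h, theta=tm), scaling)
        ) / (2 * eps)
    return grad


class TestEncoding:
    def test_ring_carbon_with_methyl(self, methoxytoluene_dag):
        mol = methoxytoluene_dag.molecule
        x = encode_node(mol.atoms[mol.tagged_index])
        assert x[0] == 1.0 and x.sum() == pytest.approx(2.0)  # one-hot C + degree 1.0
        assert x[-1] == 1.0  # valence 4 -> 4/4

    def test_methoxy_oxygen(self, methoxytoluene_dag):
        mol = methoxytoluene_dag.molecule
        oxygen = next(a for a in mol.atoms if a.symbol == "O")
        x = encode_node(oxygen)
        assert x[1] == 1.0 and x[-1] == pytest.approx(0.5)

    def test_chlorine(self):
        mol = parse_tagged_smiles("Cl[c:1]1ccccc1")
        cl = next(a for a in mol.atoms if a.symbol == "Cl")
        x = encode_node(cl)
        assert x[7] == 1.0 and x[-1] == pytest.approx(0.25)

    def test_exactly_one_hot(self, methoxytoluene_dag):
        for atom in methoxytoluene_dag.molecule.atoms:
            x = encode_node(atom)
            assert np.count_nonzero(x[:-1]) == 1


class TestParameterCount:
    @pytest.mark.parametrize(
        "h,n_in,q", [(1, 1, 4), (26, 15, 443), (30, 15, 511), (8, 15, 137)]
    )
    def test_closed_form(self, h, n_in, q):
        assert parameter_count(h, n_in) == q

    def test_rejects_nonpositive_h(self):
        with pytest.raises(ValueError):
            parameter_count(0)


class TestForward:
    def test_dead_network_returns_scaling_center(self, benzene_dag, shift_scaling):
        params = NodeFunctionParameters(h=2, theta=np.zeros(parameter_count(2)))
        assert gm_forward(benzene_dag, params, shift_scaling) == pytest.approx(
            shift_scaling.center
        )

    def test_benzene_symmetry(self, random_params, shift_scaling):
        params = random_params(4, seed=3)
        outputs = {
            gm_forward(build_rooted_dag(v), params, shift_scaling)
            for v in enumerate_ring_carbons("c1ccccc1")
        }
        assert len(outputs) == 1

    def test_two_node_path_matches_hand_arithmetic(self, shift_scaling):
        # tagged methane + one fluorine: child (F) then root (C), h=1
        dag = build_rooted_dag(parse_tagged_smiles("[CH3:1]F"))
        h = 1
        theta = np.arange(1, parameter_count(h) + 1, dtype=float) * 0.01
        params = NodeFunctionParameters(h=h, theta=theta)
        w1, w2 = params.hidden_weights()[0], params.output_weights()

        def node(x):
            return w2[0] * np.tanh(w1[:N_IN] @ x + w1[N_IN]) + w2[1]

        x_f = np.zeros(N_IN)
        x_f[6] = 1.0  # fluorine one-hot
        x_f[N_STATIC - 1] = 0.25
        x_c = np.zeros(N_IN)
        x_c[0] = 1.0
        x_c[N_STATIC - 1] = 1.0
        x_c[N_STATIC] = node(x_f)  # child output in first slot
        expected = shift_scaling.descale(node(x_c))
        assert gm_forward(dag, params, shift_scaling) == pytest.approx(
            float(expected), rel=1e-12
        )

    def test_dimension_mismatch_raises(self, benzene_dag, shift_scaling):
        bad = NodeFunctionParameters(h=2, n_in=3, theta=np.zeros(parameter_count(2, 3)))
        with pytest.raises(ModelError):
            PackedGraphs.from_dags([benzene_dag]).forward(bad)

    def test_batched_matches_single(self, random_params, shift_scaling):
        params = random_params(5, seed=9)
        mols = [m for smi in generate_molecules(8, 3, seed=21)
                for m in enumerate_ring_carbons(smi)]
        dags = [build_rooted_dag(m) for m in mols]
        packed = PackedGraphs.from_dags(dags)
        batch = shift_scaling.descale(packed.forward(params))
        single = [gm_forward(d, params, shift_scaling) for d in dags]
        np.testing.assert_array_equal(batch, single)


class TestJacobian:
    def test_matches_finite_differences_on_random_dags(
        self, random_params, shift_scaling
    ):
        rng = np.random.default_rng(17)
        smiles = generate_molecules(12, 3, seed=13)
        worst = 0.0
        for i, smi in enumerate(smiles):
            mol = enumerate_ring_carbons(smi)[int(rng.integers(6))]
            dag = build_rooted_dag(mol)
            params = random_params(3, seed=100 + i)
            analytic = gm_jacobian(dag, params, shift_scaling)
            numeric = finite_difference_gradient(dag, params, shift_scaling)
            rel = np.max(np.abs(analytic - numeric)) / np.max(np.abs(numeric))
            worst = max(worst, float(rel))
        assert worst <= 1e-6

    def test_single_node_child_slot_gradients_vanish(self, random_params, shift_scaling):
        dag = build_rooted_dag(parse_tagged_smiles("[CH4:1]"))
        params = random_params(3, seed=2)
        grad = gm_jacobian(dag, params, shift_scaling)
        w1_grad = grad[: 3 * (N_IN + 1)].reshape(3, N_IN + 1)
        np.testing.assert_array_equal(w1_grad[:, N_STATIC:N_IN], 0.0)

    def test_duplicated_subtree_doubles_its_gradient(self, random_params, shift_scaling):
        # para-dichlorobenzene vs chlorobenzene: weight sharing sums the
        # contributions of the two symmetric chlorines
        params = random_params(3, seed=4)
        mono = build_rooted_dag(parse_tagged_smiles("Cl[c:1]1ccccc1"))
        grad_mono = gm_jacobian(mono, params, shift_scaling)
        numeric = finite_difference_gradient(mono, params, shift_scaling)
        assert np.allclose(grad_mono, numeric, rtol=1e-6, atol=1e-8)

    def test_order_independence_bitwise(self, random_params, shift_scaling):
        params = random_params(4, seed=6)
        dag = build_rooted_dag(parse_tagged_smiles("COc1[c:1](C)cccc1"))
        a = gm_forward(dag, params, shift_scaling)
        b = gm_forward(dag, params, shift_scaling)
        assert a == b


class TestScalingSpec:
    def test_round_trip_identity(self):
        spec = ScalingSpec.from_range(73.0, 166.0)
        values = np.array([73.0, 119.5, 166.0])
        np.testing.assert_allclose(spec.descale(spec.scale(values)), values, rtol=1e-14)

    def test_rejects_empty_range(self):
        with pytest.raises(ValueError):
            ScalingSpec(center=100.0, half_range=0.0)
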