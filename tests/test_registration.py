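"""MST construction, exact tree DP, warping, and TRE evaluation."""

import numpy as np
import pytest

from dwisr.metrics import psnr
from dwisr.phantoms import DeformationSpec, apply_deformation
from dwisr.registration import (
    DisplacementField,
    brute_force_tree_energy,
    build_mst,
    label_offsets,
    minimum_tree_cost_bruteforce,
    mrf_register,
    tre,
    tree_dp_minimize,
    warp,
)


def _random_tree(n, rng):
    """Random spanning tree: each node attaches to a random earlier node."""
    return [(i + 1, int(rng.integers(0, i + 1)), 0.0) for i in range(n - 1)]


class TestBuildMST:
    def test_constant_image_tree_has_n_minus_1_edges(self):
        g = build_mst(np.zeros((16, 16)), 4)
        assert len(g.tree_edges) == g.n_nodes - 1
        assert all(c == 0.0 for *_, c in g.tree_edges)

    def test_tree_cost_matches_exhaustive_minimum(self, rng):
        """Oracle: enumerate all spanning trees of the 3x3 block graph via
        Pruefer sequences, restricted to grid edges (non-edges get inf)."""
        img = rng.random((12, 12))
        g = build_mst(img, 4)
        costs = {}
        for u, v in g.neighbor_pairs:
            bv = img.reshape(3, 4, 3, 4)
            ru, cu, rv, cv = u // 3, u % 3, v // 3, v % 3
            costs[(u, v)] = float(np.abs(bv[ru, :, cu] - bv[rv, :, cv]).mean())

        def lookup(a, b):
            key = (min(a, b), max(a, b))
            return costs.get(key, np.inf)

        best = minimum_tree_cost_bruteforce(9, lookup)
        total = sum(c for *_, c in g.tree_edges)
        assert total == pytest.approx(best, abs=1e-12)

    def test_deterministic_tie_breaking(self):
        img = np.zeros((16, 16))  # every edge cost ties at 0
        a = build_mst(img, 4).tree_edges
        b = build_mst(img, 4).tree_edges
        assert a == b

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            build_mst(np.zeros((4, 4)), 4)


class TestTreeDP:
    def test_four_node_path_matches_brute_force(self, rng):
        data = rng.random((4, 5))
        pair = rng.random((5, 5))
        pair = (pair + pair.T) / 2
        edges = [(1, 0, 0.0), (2, 1, 0.0), (3, 2, 0.0)]
        _, e_dp = tree_dp_minimize(edges, data, pair, 0.8)
        # exhaustive loop over 5^4 assignments
        best = np.inf
        for l0 in range(5):
            for l1 in range(5):
                for l2 in range(5):
                    for l3 in range(5):
                        e = (data[0, l0] + data[1, l1] + data[2, l2] + data[3, l3]
                             + 0.8 * (pair[l1, l0] + pair[l2, l1] + pair[l3, l2]))
                        best = min(best, e)
        assert e_dp == pytest.approx(best, abs=1e-12)

    def test_random_trees_match_brute_force(self):
        """Exact DP equals exhaustive enumeration on random 6-node trees."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            edges = _random_tree(6, rng)
            data = rng.random((6, 27))
            pair = rng.random((27, 27))
            pair = (pair + pair.T) / 2
            _, e_dp = tree_dp_minimize(edges, data, pair, 0.5)
            e_bf = brute_force_tree_energy(edges, data, pair, 0.5)
            assert e_dp == pytest.approx(e_bf, abs=1e-9)

    def test_labels_achieve_reported_energy(self, rng):
        edges = _random_tree(6, rng)
        data = rng.random((6, 9))
        pair = rng.random((9, 9))
        labels, e_dp = tree_dp_minimize(edges, data, pair, 0.3)
        e_check = data[np.arange(6), labels].sum() + 0.3 * sum(
            pair[labels[u], labels[v]] for u, v, _ in edges
        )
        assert e_dp == pytest.approx(e_check, abs=1e-12)


class TestMrfRegister:
    def test_identical_images_give_zero_data_term(self, shepp64):
        f, e, _ = mrf_register(shepp64, shepp64, label_range=2, kappa=0.1, levels=1)
        assert e.data_term == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(f.labels, 0.0)

    def test_energy_breakdown_sums_exactly(self, shepp64):
        moving = np.roll(shepp64, (1, 0), (0, 1))
        _, e, _ = mrf_register(shepp64, moving, label_range=2, kappa=0.5, levels=1)
        assert e.total == e.data_term + e.reg_term

    def test_pure_shift_recovered_without_regularization(self, shepp64):
        moving = shepp64
        fixed = np.roll(shepp64, (-2, 0), (0, 1))  # fixed(p) = moving(p + (2,0))
        f, e, _ = mrf_register(fixed, moving, block_size=8, label_range=3,
                               label_step=1, kappa=0.0, levels=1)
        # the shift is identifiable wherever a block has intensity structure;
        # flat blocks tie and resolve to the zero label
        bv = fixed.reshape(8, 8, 8, 8).swapaxes(1, 2)
        textured = bv.std(axis=(2, 3)) > 1e-6
        interior = np.zeros((8, 8), bool)
        interior[2:6, 2:6] = True
        sel = textured & interior
        assert sel.sum() >= 8
        assert np.allclose(f.labels[sel][:, 0], 2.0)
        assert np.allclose(f.labels[sel][:, 1], 0.0)

    def test_zero_label_range_returns_identity_field(self, shepp64):
        f, e, _ = mrf_register(shepp64, np.roll(shepp64, 1, 0), label_range=0)
        assert not np.any(f.labels)
        assert e.data_term > 0

    def test_shape_mismatch_rejected(self, shepp64):
        with pytest.raises(ValueError):
            mrf_register(shepp64, shepp64[:32, :32])

    def test_energy_history_non_increasing(self, shepp64):
        spec = DeformationSpec(kind="rbf_nonrigid", max_displacement=3.0, seed=3)
        warped, _ = apply_deformation(shepp64, spec)
        _, _, hist = mrf_register(warped, shepp64, label_range=3, kappa=0.05, levels=3)
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_kappa_monotonicity_of_total_variation(self, shepp64):
        spec = DeformationSpec(kind="rbf_nonrigid", max_displacement=3.0, seed=4)
        warped, _ = apply_deformation(shepp64, spec)
        tvs = []
        for kappa in (0.0, 0.1, 1.0, 10.0):
            f, _, _ = mrf_register(warped, shepp64, label_range=3, kappa=kappa, levels=1)
            lab = f.labels
            tv = np.abs(np.diff(lab, axis=0)).sum() + np.abs(np.diff(lab, axis=1)).sum()
            tvs.append(tv)
        assert all(b <= a + 1e-9 for a, b in zip(tvs, tvs[1:]))

    def test_registration_recovers_rbf_deformation(self, shepp64):
        spec = DeformationSpec(kind="rbf_nonrigid", max_displacement=3.0, seed=3)
        warped, tfield = apply_deformation(shepp64, spec)
        f, _, _ = mrf_register(warped, shepp64, block_size=6, label_range=3,
                               kappa=0.5, levels=3)
        rng = np.random.default_rng(0)
        lm = np.stack([rng.uniform(8, 55, 20), rng.uniform(8, 55, 20)], 1)
        assert tre(tfield, f.dense(shepp64.shape), lm) < 0.5 * tre(
            tfield, np.zeros_like(tfield), lm
        )


class TestWarp:
    def test_zero_field_is_identity(self, shepp64):
        f = DisplacementField(np.zeros((8, 8, 2)), 3, 1, 8)
        assert np.allclose(warp(shepp64, f), shepp64, atol=1e-10)

    def test_integer_shift_matches_roll_in_interior(self, shepp64):
        lab = np.zeros((8, 8, 2))
        lab[..., 1] = 2.0
        f = DisplacementField(lab, 3, 1, 8)
        out = warp(shepp64, f)
        rolled = np.roll(shepp64, -2, axis=1)
        assert np.allclose(out[4:-4, 4:-4], rolled[4:-4, 4:-4], atol=1e-8)

    def test_warping_by_estimated_field_reduces_mse(self, shepp64):
        spec = DeformationSpec(kind="rbf_nonrigid", max_displacement=2.0, seed=6)
        warped, _ = apply_deformation(shepp64, spec)
        f, _, _ = mrf_register(warped, shepp64, label_range=3, kappa=0.05, levels=2)
        compensated = warp(shepp64, f)
        assert ((compensated - warped) ** 2).mean() < ((shepp64 - warped) ** 2).mean()


class TestTRE:
    def test_identical_fields_give_zero(self):
        f = np.random.default_rng(0).normal(size=(2, 16, 16))
        lm = np.array([[4.0, 4.0], [10.0, 12.0]])
        assert tre(f, f, lm) == 0.0

    def test_three_four_five_triangle(self):
        tl = np.zeros((3, 16, 16))
        tl[0] = 3.0
        tl[1] = 4.0
        td = np.zeros((3, 16, 16))
        lm = np.array([[5.0, 5.0], [8.0, 2.0], [1.0, 9.0]])
        assert tre(tl, td, lm) == pytest.approx(5.0)

    def test_matches_direct_formula_on_random_fields(self, rng):
        tl = rng.normal(size=(2, 32, 32))
        td = rng.normal(size=(2, 32, 32))
        lm = np.stack([rng.integers(0, 32, 20), rng.integers(0, 32, 20)], 1).astype(float)
        expect = np.mean([
            np.sqrt(
                (tl[0, int(r), int(c)] - td[0, int(r), int(c)]) ** 2
                + (tl[1, int(r), int(c)] - td[1, int(r), int(c)]) ** 2
            )
            for r, c in lm
        ])
        assert tre(tl, td, lm) == pytest.approx(expect, abs=1e-10)

    def test_landmark_outside_domain_rejected(self):
        f = np.zeros((2, 8, 8))
        with pytest.raises(ValueError):
            tre(f, f, np.array([[9.0, 1.0]]))
        with pytest.raises(ValueError):
            tre(f, f, np.zeros((0, 2)))
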