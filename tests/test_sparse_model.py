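import numpy as np
import pytest

from dwidenoise_sr.patches import PatchSet, extract_patches
from dwidenoise_sr.sparse_model import (
    CodingBudget,
    Dictionary,
    init_dct_dictionary,
    ksvd_update_atom,
    learn_dictionary,
    load_dictionary,
    save_dictionary,
    sparse_code,
)


def patchset_from_matrix(pm: np.ndarray) -> PatchSet:
    """Wrap an (n_pix, N) matrix as a PatchSet with dummy geometry."""
    side = int(round(np.sqrt(pm.shape[0])))
    origins = np.zeros((pm.shape[1], 3), dtype=np.int64)
    return PatchSet(
        patches=pm, origins=origins, patch_side=side, image_shape=(side, side, 1)
    )


def random_dictionary(rng, n_pix, k) -> Dictionary:
    a = rng.standard_normal((n_pix, k))
    a /= np.linalg.norm(a, axis=0)
    return Dictionary(atoms=a)


class TestDCTDictionary:
    @pytest.mark.parametrize("side,k", [(8, 256), (6, 100)])
    def test_shapes(self, side, k):
        d = init_dct_dictionary(side, k)
        assert d.atoms.shape == (side**2, k)

    def test_first_atom_constant(self):
        d = init_dct_dictionary(8, 256)
        assert np.allclose(d.atoms[:, 0], 1.0 / 8)

    def test_unit_norm_columns(self):
        d = init_dct_dictionary(6, 100)
        assert np.allclose(np.linalg.norm(d.atoms, axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("side,k", [(8, 200), (8, 64), (8, 49)])
    def test_invalid_sizes_rejected(self, side, k):
        with pytest.raises(ValueError, match="perfect square"):
            init_dct_dictionary(side, k)

    def test_overcompleteness_enforced_by_type(self, rng):
        a = rng.standard_normal((16, 16))
        a /= np.linalg.norm(a, axis=0)
        with pytest.raises(ValueError, match="overcomplete"):
            Dictionary(atoms=a)


class TestSparseCode:
    def test_single_atom_patch_exact(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = d.atoms[:, [7]].copy()
        codes = sparse_code(
            patchset_from_matrix(pm), d, CodingBudget(1.2, 0.0, 16)
        )
        dense = codes.dense()
        assert np.count_nonzero(dense) == 1
        assert dense[7, 0] == pytest.approx(1.0, abs=1e-9)
        assert codes.residual_norms[0] < 1e-8
        assert not codes.infeasible[0]

    def test_huge_budget_gives_zero_code(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = rng.standard_normal((16, 3))
        budget = CodingBudget(10.0, 10.0, 16)  # bound 16000 >> ||patch||^2
        codes = sparse_code(patchset_from_matrix(pm), d, budget)
        assert codes.coefficients.nnz == 0
        assert np.allclose(codes.residual_norms, np.linalg.norm(pm, axis=0))

    def test_residual_norms_consistent(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = rng.standard_normal((16, 40))
        codes = sparse_code(patchset_from_matrix(pm), d, CodingBudget(1.0, 0.3, 16))
        recon = codes.reconstruct(d)
        recomputed = np.linalg.norm(pm - recon, axis=0)
        assert np.max(np.abs(recomputed - codes.residual_norms)) < 1e-8

    def test_budget_satisfied_or_flagged(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = rng.standard_normal((16, 40))
        budget = CodingBudget(1.0, 0.2, 16, max_nonzeros=3)
        codes = sparse_code(patchset_from_matrix(pm), d, budget)
        ok = ~codes.infeasible
        assert np.all(codes.residual_norms[ok] ** 2 <= budget.error_bound * (1 + 1e-6))

    def test_infeasible_flagged_not_silent(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = rng.standard_normal((16, 5))
        budget = CodingBudget(1.0, 0.0, 16, max_nonzeros=1)  # sigma=0, cap 1
        codes = sparse_code(patchset_from_matrix(pm), d, budget)
        assert np.all(codes.infeasible)
        assert np.all(codes.residual_norms > 0)

    def test_support_cap_respected(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = rng.standard_normal((16, 30))
        codes = sparse_code(
            patchset_from_matrix(pm), d, CodingBudget(1.0, 0.05, 16, max_nonzeros=4)
        )
        support = np.diff(codes.coefficients.tocsc().indptr)
        assert support.max() <= 4

    def test_matches_sklearn_lars_path(self, rng):
        """Independent cross-check of the path solver against sklearn."""
        from sklearn.linear_model import lars_path

        for _ in range(10):
            d = random_dictionary(rng, 16, 26)
            y = rng.standard_normal(16)
            budget_val = 0.25 * float(y @ y)
            n_pix = 16
            sigma = np.sqrt(budget_val / (1.0 * n_pix))
            codes = sparse_code(
                patchset_from_matrix(y[:, None]), d, CodingBudget(1.0, sigma, n_pix)
            )
            beta = codes.dense()[:, 0]
            resid2 = float(np.sum((y - d.atoms @ beta) ** 2))
            assert resid2 <= budget_val * (1 + 1e-8)
            # sklearn path point with the same residual must have the same l1
            alphas, _, coefs = lars_path(d.atoms, y, method="lasso")
            resid = np.sum((y[:, None] - d.atoms @ coefs) ** 2, axis=0)
            i = int(np.argmax(resid <= budget_val))
            lo, hi = coefs[:, max(i - 1, 0)], coefs[:, i]
            from scipy.optimize import brentq

            if resid[i] >= budget_val or i == 0:
                ref = hi
            else:
                t = brentq(
                    lambda t: np.sum((y - d.atoms @ (lo + t * (hi - lo))) ** 2)
                    - budget_val,
                    0.0,
                    1.0,
                )
                ref = lo + t * (hi - lo)
            assert np.sum(np.abs(beta)) == pytest.approx(
                np.sum(np.abs(ref)), abs=1e-6
            )


class TestKSVDAtomUpdate:
    def test_single_using_patch(self, rng):
        d = random_dictionary(rng, 16, 32)
        p = rng.standard_normal(16)
        pm = p[:, None].copy()
        import scipy.sparse as sp
        from dwidenoise_sr.sparse_model import SparseCodeSet

        dense = np.zeros((32, 1))
        dense[5, 0] = 0.1  # only atom 5 used; its current value is irrelevant
        codes = SparseCodeSet(
            coefficients=sp.csr_matrix(dense),
            residual_norms=np.array([np.linalg.norm(p - d.atoms @ dense[:, 0])]),
            infeasible=np.zeros(1, bool),
        )
        nd, nc = ksvd_update_atom(5, d, codes, patchset_from_matrix(pm))
        atom = nd.atoms[:, 5]
        expected = p / np.linalg.norm(p)
        if np.sign(expected[np.argmax(np.abs(expected) > 1e-12)]) != np.sign(
            atom[np.argmax(np.abs(atom) > 1e-12)]
        ):
            expected = -expected
        assert np.allclose(atom, expected, atol=1e-10)
        assert abs(abs(nc.dense()[5, 0]) - np.linalg.norm(p)) < 1e-10
        assert nc.residual_norms[0] < 1e-10

    def test_unused_atom_replaced_by_worst_patch(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = rng.standard_normal((16, 6))
        pm[:, 3] *= 10  # worst-represented patch by construction
        codes = sparse_code(
            patchset_from_matrix(pm), d, CodingBudget(1.0, 10.0, 16)
        )  # huge budget -> all-zero codes, every atom unused
        nd, nc = ksvd_update_atom(4, d, codes, patchset_from_matrix(pm))
        target = pm[:, 3] / np.linalg.norm(pm[:, 3])
        got = nd.atoms[:, 4]
        assert min(np.max(np.abs(got - target)), np.max(np.abs(got + target))) < 1e-12
        assert (nc.dense() == codes.dense()).all()

    def test_out_of_range_rejected(self, rng):
        d = random_dictionary(rng, 16, 32)
        pm = rng.standard_normal((16, 4))
        codes = sparse_code(patchset_from_matrix(pm), d, CodingBudget(1.0, 0.5, 16))
        with pytest.raises(ValueError, match="range"):
            ksvd_update_atom(32, d, codes, patchset_from_matrix(pm))

    def test_restricted_error_never_increases(self, rng):
        for _ in range(5):
            d = random_dictionary(rng, 16, 32)
            pm = rng.standard_normal((16, 50))
            codes = sparse_code(
                patchset_from_matrix(pm), d, CodingBudget(1.0, 0.4, 16, max_nonzeros=4)
            )
            before = codes.total_error()
            nd, nc = ksvd_update_atom(
                int(rng.integers(32)), d, codes, patchset_from_matrix(pm)
            )
            assert nc.total_error() <= before + 1e-9


class TestLearnDictionary:
    def test_one_iteration_loop_contract(self, rng):
        d = random_dictionary(rng, 16, 24)
        pm = rng.standard_normal((16, 60))
        _, _, hist = learn_dictionary(
            patchset_from_matrix(pm), d, CodingBudget(1.0, 0.3, 16), n_iterations=1
        )
        assert len(hist) == 1

    def test_unit_norm_atoms_after_training(self, rng):
        d = random_dictionary(rng, 16, 24)
        pm = rng.standard_normal((16, 80))
        nd, _, _ = learn_dictionary(
            patchset_from_matrix(pm), d, CodingBudget(1.0, 0.3, 16), n_iterations=4
        )
        assert np.allclose(np.linalg.norm(nd.atoms, axis=0), 1.0, atol=1e-9)

    def test_update_half_step_monotone(self, rng):
        d = random_dictionary(rng, 16, 24)
        pm = rng.standard_normal((16, 100))
        _, _, hist = learn_dictionary(
            patchset_from_matrix(pm),
            d,
            CodingBudget(1.0, 0.3, 16, max_nonzeros=4),
            n_iterations=6,
        )
        for err_code, err_update in hist:
            assert err_update <= err_code * (1 + 1e-12)

    def test_planted_atoms_recovered_under_sparsity_cap(self):
        """Training on exactly-2-sparse data with a support cap of 2 recovers
        most of the planted generator atoms (|correlation| > 0.99)."""
        rng = np.random.default_rng(2)
        gen = rng.standard_normal((16, 24))
        gen /= np.linalg.norm(gen, axis=0)
        n = 600
        pm = np.zeros((16, n))
        for i in range(n):
            atoms = rng.choice(24, size=2, replace=False)
            w = rng.uniform(0.5, 2.0, 2) * rng.choice([-1, 1], 2)
            pm[:, i] = gen[:, atoms] @ w
        init = rng.standard_normal((16, 24))
        init /= np.linalg.norm(init, axis=0)
        learned, _, _ = learn_dictionary(
            patchset_from_matrix(pm),
            Dictionary(init),
            CodingBudget(1.0, 0.0, 16, max_nonzeros=2),
            n_iterations=30,
        )
        corr = np.abs(gen.T @ learned.atoms).max(axis=1)
        assert np.sum(corr > 0.99) >= 18

    def test_empty_patchset_rejected(self, rng):
        d = random_dictionary(rng, 16, 24)
        with pytest.raises(ValueError, match="empty"):
            learn_dictionary(
                patchset_from_matrix(np.empty((16, 0))),
                d,
                CodingBudget(1.0, 0.3, 16),
            )

    def test_deterministic_given_seed(self, rng):
        pm = np.random.default_rng(4).standard_normal((16, 500))
        d = random_dictionary(np.random.default_rng(5), 16, 24)
        budget = CodingBudget(1.0, 0.3, 16, max_nonzeros=3)
        r1 = learn_dictionary(
            patchset_from_matrix(pm), d, budget, n_iterations=3, seed=9,
            train_subsample=300,
        )
        r2 = learn_dictionary(
            patchset_from_matrix(pm), d, budget, n_iterations=3, seed=9,
            train_subsample=300,
        )
        assert np.array_equal(r1[0].atoms, r2[0].atoms)
        assert np.array_equal(r1[1].dense(), r2[1].dense())


class TestDictionaryIO:
    def test_save_load_round_trip(self, rng, tmp_path):
        d = random_dictionary(rng, 16, 24)
        path = tmp_path / "dict.npz"
        save_dictionary(d, path, patch_side=4, k=24, iterations=7, seed=3)
        loaded, meta = load_dictionary(path)
        assert np.array_equal(loaded.atoms, d.atoms)
        assert meta["patch_side"] == 4
        assert meta["seed"] == 3
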