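"""Overcomplete dictionaries, error-constrained sparse coding, K-SVD updates.

The sparse model approximates each vectorized image patch y as Psi @ alpha
with Psi an overcomplete (n_pix x k, k > n_pix) unit-norm dictionary and
alpha sparse.  Coding minimizes ||alpha||_1 subject to
||y - Psi alpha||^2 <= C * n_pix * sigma^2 (the noise-matched error budget);
dictionary training alternates a coding pass with sequential rank-1 K-SVD
atom updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from ._lars import batch_lasso_budget
from .patches import PatchSet

__all__ = [
    "Dictionary",
    "SparseCodeSet",
    "CodingBudget",
    "init_dct_dictionary",
    "sparse_code",
    "ksvd_update_atom",
    "learn_dictionary",
    "save_dictionary",
    "load_dictionary",
]


@dataclass
class Dictionary:
    """Unit-norm overcomplete atom matrix Psi, shape (n_pix, k), k > n_pix."""

    atoms: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.atoms, dtype=float)
        if a.ndim != 2:
            raise ValueError("atoms must be a 2D matrix")
        n_pix, k = a.shape
        if k <= n_pix:
            raise ValueError(f"dictionary must be overcomplete: k={k} <= n_pix={n_pix}")
        norms = np.linalg.norm(a, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("every dictionary column must have unit norm")
        self.atoms = a

    @property
    def n_pix(self) -> int:
        return self.atoms.shape[0]

    @property
    def k(self) -> int:
        return self.atoms.shape[1]

    def gram(self) -> np.ndarray:
        return self.atoms.T @ self.atoms


@dataclass
class SparseCodeSet:
    """Sparse coefficients (k x n_patches) plus per-patch residual norms."""

    coefficients: sp.csr_matrix
    residual_norms: np.ndarray
    infeasible: np.ndarray  # per-patch flag: residual budget not met

    @property
    def n_patches(self) -> int:
        return self.coefficients.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.coefficients.todense())

    def reconstruct(self, dictionary: Dictionary) -> np.ndarray:
        """Coded patches Psi @ alpha, shape (n_pix, n_patches)."""
        return dictionary.atoms @ self.coefficients

    def total_error(self) -> float:
        """Total squared representation error, sum of residual_norms^2."""
        return float(np.sum(self.residual_norms**2))


@dataclass
class CodingBudget:
    """Per-patch residual budget C * n_pix * sigma^2 and optional support cap."""

    c_const: float
    sigma: float
    n_pix: int
    max_nonzeros: int | None = None

    def __post_init__(self):
        if self.c_const <= 0:
            raise ValueError("c_const must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def error_bound(self) -> float:
        return self.c_const * self.n_pix * self.sigma**2


def init_dct_dictionary(patch_side: int, k: int) -> Dictionary:
    """Overcomplete separable 2D-DCT dictionary.

    With r = sqrt(k), builds r sampled 1D cosine atoms
    v_p[i] = cos(i * p * pi / r) on i = 0..patch_side-1 (mean-removed for
    p > 0), and takes all r^2 outer products, each normalized.  The first
    atom is the constant patch 1/patch_side.
    """
    r = int(round(np.sqrt(k)))
    if r * r != k or k <= patch_side**2:
        raise ValueError(
            f"k must be a perfect square > patch_side^2; got k={k}, "
            f"patch_side={patch_side}"
        )
    i = np.arange(patch_side)
    basis = np.empty((patch_side, r))
    for p in range(r):
        v = np.cos(i * p * np.pi / r)
        if p > 0:
            v = v - v.mean()
        basis[:, p] = v / np.linalg.norm(v)
    atoms = np.kron(basis, basis)  # column p*r+q = v_p (rows) x v_q (cols)
    atoms /= np.linalg.norm(atoms, axis=0, keepdims=True)
    return Dictionary(atoms=atoms)


def _code_matrix(
    patch_matrix: np.ndarray, dictionary: Dictionary, budget: CodingBudget
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense coding of a patch matrix; returns (codes, residual2, feasible)."""
    psi = dictionary.atoms
    G = psi.T @ psi
    C0 = psi.T @ patch_matrix
    Y2 = np.einsum("ij,ij->j", patch_matrix, patch_matrix)
    cap = budget.max_nonzeros if budget.max_nonzeros is not None else dictionary.k
    return batch_lasso_budget(G, C0, Y2, budget.error_bound, cap)


def sparse_code(
    patches: PatchSet, dictionary: Dictionary, budget: CodingBudget
) -> SparseCodeSet:
    """Error-constrained min-l1 coding of every patch in the set.

    Each patch gets the minimum-l1 coefficient vector whose squared residual
    meets the ``C * n_pix * sigma^2`` budget (exact lasso-path solution with
    closed-form interpolation at the crossing).  Patches that cannot meet the
    budget — e.g. sigma = 0 with a support cap — keep their best code and are
    flagged in ``infeasible`` rather than silently accepted.
    """
    if dictionary.n_pix != patches.n_pix:
        raise ValueError(
            f"dictionary n_pix {dictionary.n_pix} != patch n_pix {patches.n_pix}"
        )
    codes, _r2, _feas = _code_matrix(patches.patches, dictionary, budget)
    # exact residuals (the path solver's incremental r2 carries ~1e-12 noise)
    resid = patches.patches - dictionary.atoms @ codes
    r2 = np.einsum("ij,ij->j", resid, resid)
    y2 = np.einsum("ij,ij->j", patches.patches, patches.patches)
    feasible = r2 <= budget.error_bound + 1e-10 * (y2 + 1.0)
    return SparseCodeSet(
        coefficients=sp.csr_matrix(codes),
        residual_norms=np.sqrt(np.maximum(r2, 0.0)),
        infeasible=~feasible,
    )


def _rank1(E: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Leading singular triple (u, s, v) of E, sign-canonicalized so the
    first nonzero entry of u is positive."""
    n, m = E.shape
    if m <= n:
        U, S, Vt = np.linalg.svd(E, full_matrices=False)
        u, s, v = U[:, 0], S[0], Vt[0]
    else:
        M = E @ E.T
        w, V = np.linalg.eigh(M)
        u = V[:, -1]
        s = float(np.sqrt(max(w[-1], 0.0)))
        v = (E.T @ u) / s if s > 0 else np.zeros(m)
    nz = np.flatnonzero(np.abs(u) > 1e-12)
    if nz.size and u[nz[0]] < 0:
        u = -u
        v = -v
    return u, float(s), v


def _ksvd_sweep(
    psi: np.ndarray,
    codes: np.ndarray,
    patch_matrix: np.ndarray,
    atom_order: np.ndarray | None = None,
) -> None:
    """In-place sequential K-SVD pass over all atoms.

    For each atom m: patches using m are found, the restricted residual
    E_m (atom m's contribution removed) is formed, and its best rank-1
    factorization replaces the atom and the corresponding coefficients.
    Unused atoms are left untouched here (handled by the replacement step
    in ``learn_dictionary``).
    """
    k = psi.shape[1]
    order = atom_order if atom_order is not None else np.arange(k)
    # residual with full reconstruction, updated incrementally per atom
    R = patch_matrix - psi @ codes
    for m in order:
        row = codes[m]
        used = np.flatnonzero(row)
        if used.size == 0:
            continue
        # E_m = residual restricted to users, with atom m's contribution added back
        Em = R[:, used] + np.outer(psi[:, m], row[used])
        u, s, v = _rank1(Em)
        if s <= 0:
            continue
        psi[:, m] = u
        codes[m, used] = s * v
        R[:, used] = Em - np.outer(u, s * v)


def ksvd_update_atom(
    m: int,
    dictionary: Dictionary,
    codes: SparseCodeSet,
    patches: PatchSet,
) -> tuple[Dictionary, SparseCodeSet]:
    """Single K-SVD atom update (functional wrapper over the in-place sweep).

    Atom m is replaced by the leading left singular vector of the restricted
    representation error E_m, and the coefficients of the patches using m by
    the matching scaled right singular vector; if no patch uses m, the atom
    is replaced by the normalized worst-represented patch and the
    coefficients are untouched.
    """
    if not (0 <= m < dictionary.k):
        raise ValueError(f"atom index {m} out of range [0, {dictionary.k})")
    psi = dictionary.atoms.copy()
    dense = codes.dense()
    row = dense[m]
    used = np.flatnonzero(row)
    if used.size == 0:
        worst = int(np.argmax(codes.residual_norms))
        p = patches.patches[:, worst]
        nrm = np.linalg.norm(p)
        atom = p / nrm if nrm > 0 else psi[:, m]
        nz = np.flatnonzero(np.abs(atom) > 1e-12)
        if nz.size and atom[nz[0]] < 0:
            atom = -atom
        psi[:, m] = atom
    else:
        _ksvd_sweep(psi, dense, patches.patches, atom_order=np.array([m]))
    resid = patches.patches - psi @ dense
    rn = np.linalg.norm(resid, axis=0)
    new_codes = SparseCodeSet(
        coefficients=sp.csr_matrix(dense),
        residual_norms=rn,
        infeasible=codes.infeasible.copy(),
    )
    return Dictionary(atoms=psi), new_codes


def _replace_degenerate_atoms(
    psi: np.ndarray,
    codes: np.ndarray,
    patch_matrix: np.ndarray,
    max_corr: float = 0.99,
) -> int:
    """Replace unused and near-duplicate atoms by worst-represented patches.

    Returns the number of atoms replaced.  Coefficients are not modified;
    the next coding pass re-codes against the refreshed dictionary.
    """
    k = psi.shape[1]
    resid2 = np.sum((patch_matrix - psi @ codes) ** 2, axis=0)
    order_worst = np.argsort(resid2)[::-1]
    usage = np.count_nonzero(codes, axis=1)
    replaced = 0
    next_pick = 0
    G = np.abs(psi.T @ psi)
    np.fill_diagonal(G, 0.0)
    for m in range(k):
        dup = np.any(G[m, :m] > max_corr)  # only compare to earlier atoms
        if usage[m] > 0 and not dup:
            continue
        while next_pick < order_worst.size:
            p = patch_matrix[:, order_worst[next_pick]]
            next_pick += 1
            nrm = np.linalg.norm(p)
            if nrm > 1e-12:
                atom = p / nrm
                nz = np.flatnonzero(np.abs(atom) > 1e-12)
                if nz.size and atom[nz[0]] < 0:
                    atom = -atom
                psi[:, m] = atom
                codes[m, :] = 0.0
                replaced += 1
                # keep duplicate detection coherent for later atoms
                G[m, :] = np.abs(psi.T @ psi[:, m])
                G[:, m] = G[m, :]
                G[m, m] = 0.0
                break
        else:
            break
    return replaced


def learn_dictionary(
    patches: PatchSet,
    init: Dictionary,
    budget: CodingBudget,
    n_iterations: int = 15,
    seed: int = 0,
    rel_tol: float = 0.0,
    train_subsample: int | None = 40_000,
) -> tuple[Dictionary, SparseCodeSet, list[tuple[float, float]]]:
    """Alternate sparse coding and K-SVD atom sweeps.

    Runs up to ``n_iterations`` rounds of (coding pass, sequential atom
    sweep); the history records the total squared representation error after
    each half-step as ``(after_coding, after_update)`` pairs — the update
    half-step never increases it.  If ``rel_tol > 0``, training stops early
    once the coding-stage error improves by less than ``rel_tol`` relative
    to the previous round.  When the patch pool exceeds ``train_subsample``,
    a seeded uniform subsample is used for training and the returned code
    set comes from a final coding pass over *all* patches.
    """
    if patches.n_patches == 0:
        raise ValueError("empty patch set")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if init.n_pix != patches.n_pix:
        raise ValueError("init dictionary does not match patch size")

    rng = np.random.default_rng(seed)
    pm = patches.patches
    subsampled = train_subsample is not None and patches.n_patches > train_subsample
    if subsampled:
        pick = rng.choice(patches.n_patches, size=train_subsample, replace=False)
        pick.sort()
        train = pm[:, pick]
    else:
        train = pm

    psi = init.atoms.copy()
    history: list[tuple[float, float]] = []
    prev_code_err = np.inf
    for _ in range(n_iterations):
        codes, r2, _feas = _code_matrix(train, Dictionary(atoms=psi), budget)
        err_code = float(np.sum(r2))
        _ksvd_sweep(psi, codes, train)
        err_update = float(np.sum((train - psi @ codes) ** 2))
        history.append((err_code, err_update))
        _replace_degenerate_atoms(psi, codes, train)
        # re-normalize defensively (SVD atoms are unit norm up to rounding)
        psi /= np.linalg.norm(psi, axis=0, keepdims=True)
        if rel_tol > 0 and np.isfinite(prev_code_err):
            if err_code >= prev_code_err * (1.0 - rel_tol):
                break
        prev_code_err = err_code

    final_dict = Dictionary(atoms=psi)
    final_codes = sparse_code(patches, final_dict, budget)
    return final_dict, final_codes, history


def save_dictionary(dictionary: Dictionary, path: str | Path, **metadata) -> None:
    """Persist atoms plus provenance metadata in an .npz container."""
    meta = {k: np.asarray(v) for k, v in metadata.items()}
    np.savez(path, atoms=dictionary.atoms, **meta)


def load_dictionary(path: str | Path) -> tuple[Dictionary, dict]:
    with np.load(path) as z:
        atoms = z["atoms"]
        meta = {k: z[k][()] for k in z.files if k != "atoms"}
    return Dictionary(atoms=atoms), meta
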