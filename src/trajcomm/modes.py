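"""Covariance PCA of Cα displacements and anisotropic network model modes.

PCA diagonalizes the 3N×3N covariance of aligned, mean-removed node
displacements (essential dynamics); the top modes describe the softest
collective motions.  The ANM builds the standard elastic-network
Hessian — uniform springs between Cα pairs within a cutoff — for a
single structure; its six zero modes are the rigid-body motions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

DEFAULT_N_MODES = 5
ANM_CUTOFF = 15.0  # Å
ANM_GAMMA = 1.0  # uniform spring constant
_ZERO_MODE_TOL = 1e-8  # relative to the largest eigenvalue


class ModeError(ValueError):
    pass


@dataclass
class ModeSet:
    """Eigenpairs of a covariance (pca) or Hessian (anm) problem.

    ``eigenvalues`` are descending for PCA (Å²) and ascending internal
    (rigid-body modes removed) for ANM; ``eigenvectors`` has shape
    (3N, n_modes), columns orthonormal.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    origin: str  # "pca" | "anm"
    n_atoms: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode_vectors(self, k: int) -> np.ndarray:
        """Mode k (0-based) reshaped to per-atom 3-vectors."""
        return self.eigenvectors[:, k].reshape(self.n_atoms, 3)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude component of each mode is positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def covariance_pca(displacements: np.ndarray, n_modes: int = DEFAULT_N_MODES) -> ModeSet:
    """PCA of aligned node displacements.

    ``displacements``: (n_frames, N, 3), already fitted and
    mean-removed (see :func:`trajcomm.network.build_node_trajectory`).
    The covariance uses the 1/(n_frames − 1) sample normalization.
    """
    d = np.asarray(displacements, dtype=float)
    if d.ndim != 3 or d.shape[2] != 3:
        raise ModeError("displacements must have shape (n_frames, N, 3)")
    n_frames, n_atoms, _ = d.shape
    if n_frames < 2:
        raise ModeError("PCA requires at least 2 frames")
    x = d.reshape(n_frames, 3 * n_atoms)
    x = x - x.mean(axis=0)
    if n_frames <= 3 * n_atoms:
        import logging

        logging.getLogger(__name__).warning(
            "only %d frames for %d coordinates; covariance is rank-deficient",
            n_frames, 3 * n_atoms,
        )
    cov = x.T @ x / (n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    k = min(n_modes, len(evals))
    return ModeSet(evals[:k], evecs[:, :k], origin="pca", n_atoms=n_atoms)


def mode_rmsf(mode_set: ModeSet, k: int) -> np.ndarray:
    """Per-residue RMSF contribution of mode k (0-based): sqrt(λ_k |v_k,i|²)."""
    if not 0 <= k < mode_set.n_modes:
        raise IndexError(f"mode index {k} out of range (n_modes={mode_set.n_modes})")
    v = mode_set.mode_vectors(k)
    lam = float(mode_set.eigenvalues[k])
    return np.sqrt(lam * np.sum(v**2, axis=1))


def block_pca(
    displacements: np.ndarray, n_blocks: int = 2, n_modes: int = DEFAULT_N_MODES
) -> tuple[list[ModeSet], np.ndarray]:
    """PCA per contiguous trajectory block plus cross-block mode overlaps.

    Returns the per-block mode sets and, for consecutive block pairs,
    the absolute inner products |v_k^(b) · v_k^(b+1)| per mode, shape
    (n_blocks − 1, n_modes).  With one block this is plain PCA.
    """
    d = np.asarray(displacements, dtype=float)
    n_frames = d.shape[0]
    if n_blocks < 1:
        raise ModeError("n_blocks must be ≥ 1")
    edges = np.linspace(0, n_frames, n_blocks + 1, dtype=int)
    sets = []
    for b in range(n_blocks):
        block = d[edges[b]:edges[b + 1]]
        if block.shape[0] < 2:
            raise ModeError(f"block {b} has fewer than 2 frames")
        sets.append(covariance_pca(block, n_modes=n_modes))
    k = min(s.n_modes for s in sets)
    overlaps = np.empty((max(n_blocks - 1, 0), k))
    for b in range(n_blocks - 1):
        va, vb = sets[b].eigenvectors[:, :k], sets[b + 1].eigenvectors[:, :k]
        overlaps[b] = np.abs(np.sum(va * vb, axis=0))
    return sets, overlaps


def anm_hessian(coords: np.ndarray, cutoff: float = ANM_CUTOFF, gamma: float = ANM_GAMMA) -> np.ndarray:
    """Standard ANM Hessian: uniform springs between pairs within cutoff."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    h = np.zeros((3 * n, 3 * n))
    dmat = squareform(pdist(coords))
    for i in range(n):
        for j in range(i + 1, n):
            dij = dmat[i, j]
            if dij > cutoff or dij == 0:
                continue
            rij = coords[j] - coords[i]
            block = -gamma * np.outer(rij, rij) / dij**2
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
            h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return h


def anm_modes(
    coords: np.ndarray,
    cutoff: float = ANM_CUTOFF,
    gamma: float = ANM_GAMMA,
    n_modes: int | None = None,
) -> tuple[ModeSet, np.ndarray]:
    """ANM normal modes of a single structure.

    Requires the contact network at ``cutoff`` to be connected (else the
    error names the components).  Returns the internal modes (ascending
    eigenvalue, the 6 rigid-body zero modes excluded) and the 6 zero
    eigenvalues for inspection.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ModeError("ANM requires at least 2 sites")
    adj = (squareform(pdist(coords)) <= cutoff).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = [int(np.sum(labels == c)) for c in range(n_comp)]
        raise ModeError(
            f"contact network disconnected at {cutoff} Å: {n_comp} components of sizes {sizes}"
        )
    h = anm_hessian(coords, cutoff=cutoff, gamma=gamma)
    evals, evecs = np.linalg.eigh(h)
    tol = _ZERO_MODE_TOL * max(float(evals[-1]), 1e-30)
    zero_mask = np.abs(evals) <= tol
    n_zero = int(zero_mask.sum())
    zero_evals = evals[zero_mask]
    internal = ~zero_mask
    evals_int = np.clip(evals[internal], 0.0, None)
    evecs_int = _fix_signs(evecs[:, internal])
    if n_modes is not None:
        evals_int = evals_int[:n_modes]
        evecs_int = evecs_int[:, :n_modes]
    mode_set = ModeSet(evals_int, evecs_int, origin="anm", n_atoms=n)
    if n_zero != 6:
        import logging

        logging.getLogger(__name__).warning(
            "expected 6 rigid-body zero modes, found %d", n_zero
        )
    return mode_set, zero_evals
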