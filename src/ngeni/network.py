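"""Elastic network construction and coarse-grained normal mode analysis.

The elastic network model (ENM) connects every pair of C-alpha beads closer
than a distance cutoff with an identical Hookean spring.  Its stiffness
(Hessian) matrix is the standard anisotropic-network super-element form:
for each spring (i, j) with current separation d = x_i - x_j the 3x3
off-diagonal block is -(d d^T)/|d|^2 and diagonal blocks are minus the sum
of the off-diagonal blocks in their row.  A connected network has exactly
six zero modes (three translations, three infinitesimal rotations), which
are excluded from the returned mode basis.

Two contact rules are used by the pathway driver:

* ``"current"`` — springs between beads close in the *given* conformation;
  this is the network whose normal modes guide each iteration step.
* the *union* cost network (:func:`build_cost_network`) — springs present in
  either end-point conformation, held fixed along the pathway so that every
  spring has a well-defined interpolated target distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import ArpackNoConvergence, eigsh
from scipy.spatial import cKDTree

from .errors import ConnectivityError, GeometryError, ParameterError, SolverError
from .structures import CoarseGrainedStructure, StructurePair

#: relative eigenvalue threshold below which a mode counts as rigid-body
RIGID_TOL = 1e-8

#: largest dense problem (3n) handled by the direct LAPACK eigensolver
DENSE_LIMIT = 600


def _n_rigid_modes(n: int) -> int:
    # A two-bead system has only five rigid modes (rotation about its own
    # axis is the zero vector); any larger non-degenerate system has six.
    return 5 if n == 2 else 6


@dataclass
class ElasticNetwork:
    """Binary spring topology over ``n`` beads.

    ``edges`` is an ``(S, 2)`` integer array with ``i < j`` per row; the
    symmetric linking matrix k_ij is implied (1 on listed pairs, else 0).
    """

    n: int
    cutoff: float
    edges: np.ndarray
    rule: str = "current"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and not np.all(self.edges[:, 0] < self.edges[:, 1]):
            raise ParameterError("edges must satisfy i < j")

    @property
    def n_springs(self) -> int:
        return self.edges.shape[0]

    @property
    def density(self) -> float:
        """Fraction of off-diagonal pairs connected by a spring."""
        total = self.n * (self.n - 1) // 2
        return self.n_springs / total if total else 0.0

    def linking_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix k_ij with zero diagonal."""
        k = np.zeros((self.n, self.n))
        if self.edges.size:
            k[self.edges[:, 0], self.edges[:, 1]] = 1.0
            k[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return k

    def adjacency(self) -> sp.csr_matrix:
        ones = np.ones(self.n_springs)
        a = sp.coo_matrix(
            (np.concatenate([ones, ones]),
             (np.concatenate([self.edges[:, 0], self.edges[:, 1]]),
              np.concatenate([self.edges[:, 1], self.edges[:, 0]]))),
            shape=(self.n, self.n),
        )
        return a.tocsr()

    def union(self, other: "ElasticNetwork") -> "ElasticNetwork":
        """Network containing every spring present in either operand."""
        if self.n != other.n:
            raise ParameterError("cannot union networks over different bead counts")
        merged = {tuple(e) for e in self.edges} | {tuple(e) for e in other.edges}
        edges = np.array(sorted(merged), dtype=int).reshape(-1, 2)
        return ElasticNetwork(
            n=self.n, cutoff=max(self.cutoff, other.cutoff), edges=edges, rule="union"
        )

    def to_edge_list_text(self) -> str:
        """Sparse coordinate-list export (1-based indices) for inspection."""
        lines = [f"# elastic network: n={self.n} cutoff={self.cutoff} rule={self.rule}"]
        lines += [f"{i + 1}\t{j + 1}" for i, j in self.edges]
        return "\n".join(lines) + "\n"


@dataclass
class ModeBasis:
    """The ``m`` lowest non-rigid normal modes of an intermediate.

    ``modes`` is ``(3n, m)`` with orthonormal columns; row block
    ``modes[3i:3i+3]`` is V_i, the per-residue slice of the basis.
    Eigenvalues are the associated (ascending, positive) stiffnesses.
    """

    modes: np.ndarray
    eigenvalues: np.ndarray
    m: int

    def __post_init__(self) -> None:
        if self.modes.shape[1] != self.m or self.eigenvalues.shape != (self.m,):
            raise ParameterError("inconsistent mode basis shapes")

    def block(self, i: int) -> np.ndarray:
        """V_i, the (3, m) slice of the basis for residue i."""
        return self.modes[3 * i : 3 * i + 3]

    def displacement(self, weights: np.ndarray) -> np.ndarray:
        """delta_i = V_i C_w for all residues, as an (n, 3) array."""
        return (self.modes @ np.asarray(weights, float)).reshape(-1, 3)


def build_network(
    structure: CoarseGrainedStructure | np.ndarray,
    cutoff: float = 12.0,
    rule: str = "current",
    require_connected: bool = True,
) -> ElasticNetwork:
    """Connect beads closer than ``cutoff`` Angstrom with unit springs."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    coords = structure.coords if isinstance(structure, CoarseGrainedStructure) else np.asarray(structure, float)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    edges = np.sort(pairs, axis=1)
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
    net = ElasticNetwork(n=coords.shape[0], cutoff=cutoff, edges=edges, rule=rule)
    if require_connected:
        check_connected(net)
    return net


def build_cost_network(pair: StructurePair, cutoff: float = 12.0) -> ElasticNetwork:
    """Union of the two end-point contact networks.

    Held fixed over all iterations so every spring's target distance is
    defined from both end points throughout the interpolation.
    """
    a = build_network(pair.start, cutoff, rule="current", require_connected=False)
    b = build_network(pair.end, cutoff, rule="current", require_connected=False)
    net = a.union(b)
    check_connected(net)
    return net


def check_connected(network: ElasticNetwork) -> None:
    """Raise :class:`ConnectivityError` naming components if disconnected."""
    n_comp, labels = connected_components(network.adjacency(), directed=False)
    if n_comp != 1:
        sizes = np.bincount(labels)
        members = [np.flatnonzero(labels == c)[:5].tolist() for c in range(n_comp)]
        raise ConnectivityError(
            f"elastic network has {n_comp} components (sizes {sizes.tolist()}; "
            f"first members {members}); increase the cutoff"
        )


def build_hessian(
    structure: CoarseGrainedStructure | np.ndarray, network: ElasticNetwork
) -> sp.csr_matrix:
    """Assemble the 3n x 3n ENM stiffness matrix (uniform spring constant 1)."""
    coords = structure.coords if isinstance(structure, CoarseGrainedStructure) else np.asarray(structure, float)
    n = coords.shape[0]
    if network.n != n:
        raise ParameterError(f"network is over {network.n} beads, structure has {n}")
    i, j = network.edges[:, 0], network.edges[:, 1]
    d = coords[i] - coords[j]
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < 1e-12):
        bad = network.edges[r2 < 1e-12][:3].tolist()
        raise GeometryError(f"coincident connected residues (springs {bad})")
    # off-diagonal super-elements -(d d^T)/|d|^2, shape (S, 3, 3)
    blocks = -d[:, :, None] * d[:, None, :] / r2[:, None, None]

    ax, bx = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    ax, bx = ax.ravel(), bx.ravel()
    rows = np.concatenate([(3 * i)[:, None] + ax, (3 * j)[:, None] + ax], axis=0)
    cols = np.concatenate([(3 * j)[:, None] + bx, (3 * i)[:, None] + bx], axis=0)
    vals = np.concatenate([blocks.reshape(-1, 9)] * 2, axis=0)

    diag = np.zeros((n, 3, 3))
    np.add.at(diag, i, -blocks)
    np.add.at(diag, j, -blocks)
    drows = (3 * np.arange(n))[:, None] + ax
    dcols = (3 * np.arange(n))[:, None] + bx

    h = sp.coo_matrix(
        (
            np.concatenate([vals.ravel(), diag.reshape(-1, 9).ravel()]),
            (
                np.concatenate([rows.ravel(), drows.ravel()]),
                np.concatenate([cols.ravel(), dcols.ravel()]),
            ),
        ),
        shape=(3 * n, 3 * n),
    )
    return h.tocsr()


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the rigid-body subspace (3n x 5 or 6).

    Three uniform translations plus infinitesimal rotations about the
    centroid, orthonormalized; for a two-bead system the on-axis rotation
    degenerates and only five columns are returned.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    cols = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        cols.append(t.ravel())
    for axis in range(3):
        w = np.zeros(3)
        w[axis] = 1.0
        cols.append(np.cross(w, centered).ravel())
    b = np.stack(cols, axis=1)
    q, r = np.linalg.qr(b)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-|.| component of each column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def compute_modes(hessian: sp.spmatrix | np.ndarray, m: int, method: str = "auto") -> ModeBasis:
    """Extract the ``m`` lowest non-rigid normal modes of an ENM Hessian.

    ``method``: ``"dense"`` (LAPACK), ``"sparse"`` (shift-invert Lanczos,
    scaling as O(n m^2)), or ``"auto"`` (dense when 3n <= 600 or when the
    full non-rigid spectrum is requested, sparse otherwise).
    """
    h = sp.csr_matrix(hessian)
    dim = h.shape[0]
    n = dim // 3
    n_rigid = _n_rigid_modes(n)
    max_m = dim - n_rigid
    if not 1 <= m <= max_m:
        raise ParameterError(f"mode count m={m} out of range [1, {max_m}] for n={n}")
    if method == "auto":
        method = "dense" if (dim <= DENSE_LIMIT or m + n_rigid >= dim - 1) else "sparse"

    if method == "dense":
        evals, evecs = eigh(h.toarray())
    elif method == "sparse":
        k = m + n_rigid
        try:
            # shift-invert around a small negative sigma: the spectrum is
            # nonnegative, so H - sigma*I is positive definite and
            # factorizable even though H itself is singular.
            evals, evecs = eigsh(h, k=k, sigma=-1e-2, which="LM")
        except ArpackNoConvergence as exc:
            raise SolverError(
                f"Lanczos eigensolver did not converge (k={k}, dim={dim}): {exc}"
            ) from exc
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    else:
        raise ParameterError(f"unknown eigensolver method {method!r}")

    scale = max(float(np.max(evals)), float(h.diagonal().max()), 1e-30)
    tol = RIGID_TOL * scale
    n_zero = int(np.sum(evals < tol))
    if n_zero != n_rigid:
        raise ConnectivityError(
            f"expected {n_rigid} rigid-body modes, found {n_zero} eigenvalues below "
            f"{tol:.3e} (degenerate or disconnected network)"
        )
    sel = slice(n_zero, n_zero + m)
    modes = _fix_signs(np.ascontiguousarray(evecs[:, sel]))
    return ModeBasis(modes=modes, eigenvalues=np.asarray(evals[sel], float), m=m)
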