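"""Transition pathway generation by normal mode-guided interpolation.

Given two end-point conformations x (start) and y (end), the method walks
from x to y in ``s`` iterations.  At step k the target distance of every
cost-network spring (i, j) is the linear interpolation

    l_ij = (1 - alpha) |x_i - x_j| + alpha |y_i - y_j|,   alpha = k / s,

and the step displacement minimizes the distance-mismatch cost

    C = 1/2 sum_springs ( |x_i + d_i - x_j - d_j| - l_ij )^2 .

A second-order Taylor expansion of C in the displacement yields a quadratic
model 1/2 C_w^T L1 C_w + 1/2 L2 C_w + L3 whose stationary point is solved
in closed form.  The two variants differ only in the search space for d:

* NGENI:  d_i = V_i C_w, a combination of the m lowest normal modes of the
  current intermediate's elastic network (m unknowns);
* ENI baseline: d ranges over all 3n Cartesian degrees of freedom with the
  six rigid-body directions projected out.

With m equal to the full non-rigid count the two search spaces coincide,
so full-mode NGENI and ENI produce the same pathway up to solver
tolerance — the package's primary internal consistency oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .errors import (
    DimensionError,
    GeometryError,
    ParameterError,
    SolverError,
    StepFailureError,
)
from .network import (
    ElasticNetwork,
    ModeBasis,
    build_cost_network,
    build_hessian,
    build_network,
    compute_modes,
    rigid_body_basis,
)
from .structures import CoarseGrainedStructure, StructurePair, rmsd

log = logging.getLogger(__name__)

#: end-point RMSD below which the transition is treated as trivial (no steps)
TRIVIAL_RMSD = 0.05


def iteration_count(end_to_end_rmsd: float) -> int:
    """Number of iterations for a given end-to-end RMSD (Angstrom).

    The step count is ten times the RMSD, rounded to the nearest integer,
    so that consecutive intermediates are about 0.1 A apart.
    """
    if end_to_end_rmsd < 0:
        raise ParameterError("RMSD must be nonnegative")
    return int(math.floor(10.0 * end_to_end_rmsd + 0.5))


# ---------------------------------------------------------------------------
# Quadratic cost model
# ---------------------------------------------------------------------------

def projector(x: np.ndarray) -> np.ndarray:
    """A(x) = I - x x^T / |x|^2, the projector onto the plane normal to x."""
    x = np.asarray(x, float)
    nrm2 = float(x @ x)
    if nrm2 < 1e-18:
        raise GeometryError("projector undefined for near-zero vector")
    return np.eye(3) - np.outer(x, x) / nrm2


@dataclass
class TargetDistances:
    """Interpolated per-spring target distances l_ij at scale factor alpha."""

    network: ElasticNetwork
    l: np.ndarray  # (S,) target distances, aligned with network.edges
    alpha: float

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, float)
        if self.l.shape != (self.network.n_springs,):
            raise DimensionError("one target distance per spring required")
        if np.any(self.l <= 0):
            raise GeometryError("target distances must be positive")


def target_distances(
    pair: StructurePair, network: ElasticNetwork, alpha: float
) -> TargetDistances:
    """Per-spring targets l_ij = (1-alpha)|x_i-x_j| + alpha|y_i-y_j|."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("alpha must lie in [0, 1]")
    i, j = network.edges[:, 0], network.edges[:, 1]
    d0 = np.linalg.norm(pair.start.coords[i] - pair.start.coords[j], axis=1)
    d1 = np.linalg.norm(pair.end.coords[i] - pair.end.coords[j], axis=1)
    return TargetDistances(network=network, l=(1.0 - alpha) * d0 + alpha * d1, alpha=alpha)


@dataclass
class QuadraticCost:
    """Coefficients of the quadratic cost model.

    cost(C_w) ~= 1/2 C_w^T lambda1 C_w + 1/2 lambda2 C_w + lambda3,
    with lambda3 equal to the exact cost at zero displacement (half the
    sum of squared distance mismatches over the springs).
    """

    lambda1: np.ndarray  # (m, m), symmetric
    lambda2: np.ndarray  # (m,)
    lambda3: float
    ops: int = 0  # multiply-accumulate tally of the assembly (see docs)

    @property
    def m(self) -> int:
        return self.lambda2.shape[0]

    def value(self, c: np.ndarray) -> float:
        """Evaluate the quadratic model at weight vector ``c``."""
        c = np.asarray(c, float)
        return float(0.5 * c @ self.lambda1 @ c + 0.5 * self.lambda2 @ c + self.lambda3)


@dataclass
class WeightVector:
    """Mode weighting constants c_1..c_m of one step displacement."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, float).ravel()
        if not np.all(np.isfinite(self.c)):
            raise SolverError("non-finite weighting constants")


def _edge_operator(network: ElasticNetwork) -> sp.csr_matrix:
    """Sparse (3S x 3n) operator mapping displacements to per-spring
    differences d_i - d_j."""
    i, j = network.edges[:, 0], network.edges[:, 1]
    s = network.n_springs
    rows = np.repeat(3 * np.arange(s), 3) + np.tile(np.arange(3), s)
    cols_i = np.repeat(3 * i, 3) + np.tile(np.arange(3), s)
    cols_j = np.repeat(3 * j, 3) + np.tile(np.arange(3), s)
    data = np.concatenate([np.ones(3 * s), -np.ones(3 * s)])
    return sp.coo_matrix(
        (data, (np.concatenate([rows, rows]), np.concatenate([cols_i, cols_j]))),
        shape=(3 * s, 3 * network.n),
    ).tocsr()


def _spring_terms(
    coords: np.ndarray, targets: TargetDistances
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-spring pieces of the Taylor expansion.

    Returns ``(p1_blocks, p2_flat, r, lambda3)`` where ``p1_blocks`` is
    (S, 3, 3) with P1 = (1 - l/r) I + (l/r) e e^T, ``p2_flat`` is the
    concatenation of the row vectors P2 = 2 (1 - l/r) (x_i - x_j)^T, ``r``
    the current spring lengths, and ``lambda3 = 1/2 sum (r - l)^2``.
    """
    edges = targets.network.edges
    d = coords[edges[:, 0]] - coords[edges[:, 1]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise GeometryError("coincident beads on a cost-network spring")
    l = targets.l
    ratio = l / r
    e = d / r[:, None]
    eye = np.eye(3)[None, :, :]
    p1 = (1.0 - ratio)[:, None, None] * eye + ratio[:, None, None] * (
        e[:, :, None] * e[:, None, :]
    )
    p2 = (2.0 * (1.0 - ratio))[:, None] * d
    lambda3 = 0.5 * float(np.sum((r - l) ** 2))
    return p1, p2.ravel(), r, lambda3


def _block_diag(blocks: np.ndarray) -> sp.bsr_matrix:
    """Block-diagonal sparse matrix from an (S, 3, 3) block stack."""
    s = blocks.shape[0]
    if s == 0:
        return sp.bsr_matrix((0, 0))
    return sp.bsr_matrix(
        (blocks, np.arange(s), np.arange(s + 1)), shape=(3 * s, 3 * s)
    )


def _assemble_reduced(
    coords: np.ndarray, basis_matrix: np.ndarray, targets: TargetDistances
) -> QuadraticCost:
    """Assemble lambda1/lambda2/lambda3 in the column space of
    ``basis_matrix`` (3n x m)."""
    net = targets.network
    s = net.n_springs
    m = basis_matrix.shape[1]
    p1, p2_flat, _, lam3 = _spring_terms(coords, targets)
    g = _edge_operator(net)
    w = g @ basis_matrix  # (3S, m): per-spring V_i - V_j stacked
    pb = _block_diag(p1)
    pw = pb @ w if s else np.zeros((0, m))
    lam1 = w.T @ pw
    lam1 = 0.5 * (lam1 + lam1.T)  # enforce exact symmetry
    lam2 = p2_flat @ w if s else np.zeros(m)
    # multiply-accumulate tally: G@V (2 entries/row), P@W (9m per spring),
    # W^T P W (3S m^2), p2@W (3S m)
    ops = 2 * 3 * s * m + 9 * s * m + 3 * s * m * m + 3 * s * m
    return QuadraticCost(lambda1=lam1, lambda2=np.asarray(lam2, float).ravel(), lambda3=lam3, ops=ops)


def assemble_cost(
    current: CoarseGrainedStructure | np.ndarray,
    basis: ModeBasis,
    network: ElasticNetwork,
    targets: TargetDistances,
) -> QuadraticCost:
    """Quadratic cost model of one step in mode coordinates.

    ``network`` must be the cost network the targets were computed on.
    """
    coords = current.coords if isinstance(current, CoarseGrainedStructure) else np.asarray(current, float)
    if targets.network is not network:
        if targets.network.n_springs != network.n_springs or not np.array_equal(
            targets.network.edges, network.edges
        ):
            raise DimensionError("targets were computed on a different network")
    if basis.modes.shape[0] != 3 * coords.shape[0]:
        raise DimensionError("mode basis does not match structure size")
    return _assemble_reduced(coords, basis.modes, targets)


def solve_weights(cost: QuadraticCost, cond_limit: float = 1e12) -> WeightVector:
    """Solve the stationarity condition lambda1 C_w + 1/2 lambda2^T = 0.

    Ill-conditioned or singular systems fall back to a pseudo-inverse
    (minimum-norm least-squares) solve, logged once per call.  The returned
    weights never increase the quadratic model relative to C_w = 0: if the
    stationary point is a saddle that would, the 1-D minimizer along the
    stationary direction is returned instead (or zero).
    """
    l1, l2 = cost.lambda1, cost.lambda2
    b = -0.5 * l2
    use_pinv = False
    try:
        cond = np.linalg.cond(l1)
        use_pinv = not np.isfinite(cond) or cond > cond_limit
    except np.linalg.LinAlgError:
        use_pinv = True
    if use_pinv:
        log.info("solve_weights: ill-conditioned lambda1, using least-squares solve")
        c = np.linalg.lstsq(l1, b, rcond=None)[0]
    else:
        try:
            c = np.linalg.solve(l1, b)
        except np.linalg.LinAlgError:
            log.info("solve_weights: singular lambda1, using least-squares solve")
            c = np.linalg.lstsq(l1, b, rcond=None)[0]
    if not np.all(np.isfinite(c)):
        raise SolverError("weight solve produced non-finite values")

    # descent guard for indefinite lambda1 (large-step regime)
    scale = abs(cost.lambda3) + 1.0
    if cost.value(c) > cost.value(np.zeros_like(c)) + 1e-12 * scale:
        a_quad = float(c @ l1 @ c)
        b_lin = float(l2 @ c)
        if a_quad > 0:
            t = -0.5 * b_lin / a_quad
            c = t * c
        else:
            c = np.zeros_like(c)
        if cost.value(c) > cost.value(np.zeros_like(c)) + 1e-12 * scale:
            c = np.zeros_like(c)
    return WeightVector(c=c)


def exact_cost(
    current: CoarseGrainedStructure | np.ndarray,
    basis: ModeBasis | None,
    c: WeightVector | np.ndarray | None,
    network: ElasticNetwork,
    targets: TargetDistances,
    displacement: np.ndarray | None = None,
) -> float:
    """The exact (non-Taylor) distance-mismatch cost of a candidate step.

    The displacement may be given either as mode weights (``basis`` + ``c``)
    or directly as an (n, 3) array.
    """
    coords = current.coords if isinstance(current, CoarseGrainedStructure) else np.asarray(current, float)
    if displacement is None:
        if basis is None or c is None:
            raise ParameterError("provide either (basis, c) or displacement")
        cw = c.c if isinstance(c, WeightVector) else np.asarray(c, float)
        displacement = basis.displacement(cw)
    moved = coords + displacement
    i, j = network.edges[:, 0], network.edges[:, 1]
    r = np.linalg.norm(moved[i] - moved[j], axis=1)
    return 0.5 * float(np.sum((r - targets.l) ** 2))


# ---------------------------------------------------------------------------
# Pathway driver
# ---------------------------------------------------------------------------

@dataclass
class PathwayConfig:
    """Run configuration.

    modes:
        Mode count m, or ``"full"`` for the complete non-rigid basis
        (3n - 6).  Default 30, the count found sufficient for convergence
        on a broad protein set ("optimum" variant).
    cutoff:
        ENM distance cutoff in Angstrom (default 12).
    steps:
        Iteration count s, or ``None`` for the automatic rule
        s = round(10 x end-to-end RMSD).
    safeguard:
        When True, a step whose exact cost exceeds the pre-step cost is
        retried at half displacement (up to 5 halvings).  Off by default:
        the bare iteration is the reference behavior.
    """

    modes: int | Literal["full"] = 30
    cutoff: float = 12.0
    steps: int | None = None
    safeguard: bool = False
    eigensolver: str = "auto"

    def resolve_m(self, n: int) -> int:
        full = 3 * n - 6
        if self.modes == "full":
            return full
        m = int(self.modes)
        if m < 1:
            raise ParameterError(f"mode count must be >= 1, got {m}")
        return min(m, full)


@dataclass
class StepRecord:
    """Per-iteration diagnostics of a pathway run."""

    step: int
    alpha: float
    rmsd_prev: float
    rmsd_to_end: float
    cost_exact: float
    cost_quadratic: float
    n_modes: int
    op_count: int
    weights: WeightVector | None = None


@dataclass
class TransitionPathway:
    """An ordered sequence of conformations from start to end.

    ``conformations[0]`` is the start structure; the remaining ``s``
    entries are the computed intermediates, the last of which (at
    interpolation scale alpha = 1) is the pathway terminus.
    ``final_residual`` is its RMSD to the *given* end structure — the
    quantity the convergence condition judges against the experimental
    resolution.
    """

    conformations: list[CoarseGrainedStructure]
    records: list[StepRecord] = field(default_factory=list)
    method: str = "ngeni"
    final_residual: float = 0.0
    s: int = 0

    def alpha_of(self, index: int) -> float:
        return index / self.s if self.s else 0.0

    @property
    def weights(self) -> list[WeightVector | None]:
        return [r.weights for r in self.records]

    def last_computed(self) -> CoarseGrainedStructure:
        """The last conformation produced by the iteration itself."""
        return self.conformations[-1]

    def monotone_violations(self, tol: float = 1e-9) -> list[int]:
        """Steps where the RMSD to the end structure increased (flagged,
        never silently accepted)."""
        out = []
        prev = None
        for rec in self.records:
            if prev is not None and rec.rmsd_to_end > prev + tol:
                out.append(rec.step)
            prev = rec.rmsd_to_end
        return out


def _solve_cartesian(
    coords: np.ndarray, targets: TargetDistances
) -> tuple[np.ndarray, float, int]:
    """One ENI step: minimize the quadratic model over all Cartesian DOF
    with rigid-body directions projected out.

    Returns ``(displacement (n,3), quadratic cost at solution, op count)``.
    """
    net = targets.network
    n = coords.shape[0]
    dim = 3 * n
    s = net.n_springs
    p1, p2_flat, _, lam3 = _spring_terms(coords, targets)
    g = _edge_operator(net)
    pb = _block_diag(p1)
    h = (g.T @ (pb @ g)).toarray()  # Cartesian lambda1, (3n, 3n)
    grad = np.asarray(g.T @ p2_flat).ravel()  # Cartesian lambda2^T

    rb = rigid_body_basis(coords)  # (3n, 6)
    # project rigid directions out of the system: Hp = P H P with P = I - R R^T
    rh = rb.T @ h
    hr = h @ rb
    rhr = rb.T @ hr
    hp = h - rb @ rh - hr @ rb.T + rb @ rhr @ rb.T
    hp = 0.5 * (hp + hp.T)
    rho = max(float(np.abs(np.diag(h)).mean()), 1.0)
    m_sys = hp + rho * (rb @ rb.T)
    b = -0.5 * (grad - rb @ (rb.T @ grad))
    try:
        d = np.linalg.solve(m_sys, b)
    except np.linalg.LinAlgError:
        d = np.linalg.lstsq(m_sys, b, rcond=None)[0]
    if not np.all(np.isfinite(d)):
        raise SolverError("Cartesian step solve produced non-finite values")
    quad = float(0.5 * d @ h @ d + 0.5 * grad @ d + lam3)
    # MAC tally: sparse assembly (36 S) + projection products + rank-6
    # updates + the solve modeled at its sparse/back-substitution cost
    # (dense factorization excluded; see docs/methods.md).
    ops = 36 * s + 4 * 6 * dim * dim + 6 * dim * dim + 2 * dim * dim
    return d.reshape(-1, 3), quad, ops


def _run(pair: StructurePair, config: PathwayConfig, method: str) -> TransitionPathway:
    start, end = pair.start, pair.end
    n = pair.n
    r0 = rmsd(start, end)
    s = config.steps if config.steps is not None else iteration_count(r0)
    if config.steps is not None and config.steps < 0:
        raise ParameterError("steps must be nonnegative")
    if r0 < TRIVIAL_RMSD or s == 0:
        return TransitionPathway(
            conformations=[start.with_coords(start.coords, label=f"{start.label} step 0")],
            records=[], method=method, final_residual=r0, s=0,
        )

    cost_net = build_cost_network(pair, config.cutoff)
    m = config.resolve_m(n) if method == "ngeni" else 0
    cur = start.coords.copy()
    confs = [start.with_coords(start.coords, label=f"{start.label} step 0")]
    records: list[StepRecord] = []

    for k in range(1, s + 1):
        alpha = k / s
        targets = target_distances(pair, cost_net, alpha)
        cost0 = exact_cost(cur, None, None, cost_net, targets, displacement=np.zeros((n, 3)))
        if method == "ngeni":
            nma_net = build_network(cur, config.cutoff, rule="current")
            hess = build_hessian(cur, nma_net)
            basis = compute_modes(hess, m, method=config.eigensolver)
            qcost = assemble_cost(cur, basis, cost_net, targets)
            wv = solve_weights(qcost)
            delta = basis.displacement(wv.c)
            quad_val = qcost.value(wv.c)
            ops = qcost.ops + n * m * m  # + Lanczos-model NMA cost
            n_modes = m
        else:
            delta, quad_val, ops = _solve_cartesian(cur, targets)
            wv = None
            n_modes = 3 * n - 6
        cost1 = exact_cost(cur, None, None, cost_net, targets, displacement=delta)
        if config.safeguard and cost1 > cost0 * (1 + 1e-9):
            for _ in range(5):
                delta = 0.5 * delta
                cost1 = exact_cost(cur, None, None, cost_net, targets, displacement=delta)
                if cost1 <= cost0 * (1 + 1e-9):
                    break
            else:
                raise StepFailureError(
                    f"step {k}: exact cost increased from {cost0:.6g} to {cost1:.6g} "
                    "even after 5 halvings"
                )
        new = cur + delta
        records.append(
            StepRecord(
                step=k,
                alpha=alpha,
                rmsd_prev=rmsd(new, cur),
                rmsd_to_end=rmsd(new, end.coords),
                cost_exact=cost1,
                cost_quadratic=quad_val,
                n_modes=n_modes,
                op_count=ops,
                weights=wv,
            )
        )
        cur = new
        confs.append(start.with_coords(cur, label=f"{start.label} step {k}"))

    pathway = TransitionPathway(
        conformations=confs,
        records=records,
        method=method,
        final_residual=rmsd(cur, end.coords),
        s=s,
    )
    violations = pathway.monotone_violations()
    if violations:
        log.warning(
            "%s pathway: RMSD to end increased at steps %s", method, violations
        )
    return pathway


def run_ngeni(pair: StructurePair, config: PathwayConfig | None = None) -> TransitionPathway:
    """Generate a mode-guided pathway from ``pair.start`` to ``pair.end``.

    Each step recomputes the elastic network and the m lowest normal modes
    of the current intermediate, then takes the cost-minimizing step in
    mode space.  Deterministic given the configuration.
    """
    return _run(pair, config or PathwayConfig(), "ngeni")


def run_eni(pair: StructurePair, config: PathwayConfig | None = None) -> TransitionPathway:
    """Generate the baseline pathway over all Cartesian degrees of freedom.

    Minimizes the same per-step quadratic cost without mode truncation
    (rigid-body directions projected out); serves as the oracle for
    full-mode equivalence.
    """
    return _run(pair, config or PathwayConfig(), "eni")
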