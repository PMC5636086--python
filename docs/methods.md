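# Methods

## Model

A protein conformation is a chain of C-alpha beads. The elastic network
connects every bead pair within a distance cutoff by a Hookean spring of
unit stiffness; the network's Hessian is the standard anisotropic-network
form (per-spring super-element −(d dᵀ)/‖d‖², diagonal blocks closing each
block row to zero). For a connected, non-degenerate network the Hessian is
positive semidefinite with exactly six zero modes (three translations,
three infinitesimal rotations); a two-bead system has five, and collinear
arrangements are rejected as degenerate rather than silently accepted.

A transition between end points x (start) and y (end) is discretized into
`s = round(10 × RMSD(x, y))` steps, so consecutive intermediates are
roughly 0.1 Å apart. Step k targets the per-spring distances
`l_ij = (1 − α)‖x_i − x_j‖ + α‖y_i − y_j‖` with `α = k/s` and takes the
displacement minimizing the quadratic (second-order Taylor) model of the
distance-mismatch cost. The mode-guided variant restricts the displacement
to the m lowest non-rigid normal modes of the *current* intermediate,
recomputed every step; the Cartesian baseline minimizes the same model
over all degrees of freedom with the six rigid directions projected out.
Both drivers are fully deterministic.

Two networks coexist by design. The NMA network is rebuilt from the
current intermediate each step (its modes must reflect the present
geometry). The cost network is the union of the two end-point contact
sets and is held fixed across all iterations, because the interpolated
target of a spring needs both end-point distances to be defined; whether
the original formulation rebuilds it per step is not documented anywhere
we could find, and the union rule is the choice that keeps every target
well-posed.

The quadratic model's constant term is half the sum of squared distance
mismatches, so the model and the exact cost agree identically at zero
displacement; the per-spring matrices are
`P⁽¹⁾ = (1 − l/r) I + (l/r) e eᵀ` and `P⁽²⁾ = 2(1 − l/r)(x_i − x_j)ᵀ`
with r the current spring length and e its unit vector.

## Iteration schedule and terminus

α runs from 1/s to 1 inclusive: the final computed step solves against the
end structure's own distances, and that computed conformation stands as
the pathway terminus. Its RMSD to the given end structure is reported as
the final residual and is what the convergence condition compares against
the pair's experimental resolution. (The alternative — stopping at
α = (s−1)/s and appending the given end structure — caps the best
attainable residual at ~0.1 Å by construction and makes sub-0.1 Å recovery
meaningless; driving α to 1 is the reading under which full-basis runs
recover synthetic end points to ~10⁻³ Å.) No per-step rescaling forces an
exact 0.1 Å increment; the increment emerges from the schedule.

## Numerical choices

* **Weight solve.** The stationary system is solved directly; if the
  condition number exceeds 1e12 (or the solve fails) a minimum-norm
  least-squares solve is used and logged. Because `Λ⁽¹⁾` can be indefinite
  when targets stretch springs (`l > r`), a descent guard rejects any
  solution that would raise the quadratic model above its value at zero,
  substituting the 1-D minimizer along the stationary direction (or zero).
* **Eigensolver.** Dense LAPACK up to 3n = 600 or when the full spectrum
  is requested; otherwise shift-invert Lanczos at a small negative shift
  (the spectrum is nonnegative, so H − σI is positive definite). Rigid
  modes are excluded by an eigenvalue threshold of 1e-8 relative to the
  spectral scale, with a hard check that exactly the expected number fall
  below it. Eigenvector signs are fixed by making each mode's
  largest-magnitude component positive, so outputs are identical across
  solvers and runs.
* **Superposition.** Kabsch with reflection correction (SVD); every RMSD
  in the package is C-alpha, mass-unweighted, after optimal superposition,
  including the re-superposition applied when comparing intermediates.
  Raw (unsuperposed) coordinates are what propagates step to step; mode
  bases exclude rigid directions, so drift is negligible.
* **Safeguard.** Optionally (off by default), a step whose exact cost
  exceeds the pre-step cost is retried at half displacement up to five
  times. The default is the bare iteration, which is the reference
  behavior; the safeguard exists for aggressive step schedules.
* **Degenerate inputs.** Identical end points (RMSD < 0.05 Å) yield a
  single-conformation pathway; coincident connected beads, disconnected
  networks, and sub-3-residue selections raise typed errors.

## Operation counters

Each step record carries a multiply-accumulate tally of the step's
dominant linear-algebra products: for the mode-guided variant the
edge-difference and mode-projection products of the cost assembly
(~3·springs·m², plus an n·m² Lanczos-model NMA term), for the Cartesian
baseline the sparse assembly, rigid-space projection and solve of the
dense 3n-dimensional system (~const·(3n)²). The counter models the linear
solve at the sparse-solver cost the method targets (proportional to the
stored matrix entries) rather than the dense LAPACK factorization actually
used at test sizes; it is a complexity model for scaling assertions, not a
wall-clock measurement, and no wall-clock claim is made or tested.

## Synthetic fixtures

The generator emulates the phenomenology that matters to the algorithm:
two internally rigid arms of a C-alpha chain related by a hinge bend
(rotation about an axis perpendicular to the chain through the central
bead), a shear-like dihedral rotation about the central virtual bond, or a
twist about the overall chain axis — plus a seeded Gaussian perturbation
kind for non-rigid deformations. The backbone is a coarse helix (100° turn
and 1.42 Å rise per residue, radius 2.3 Å) with exact 3.8 Å virtual bonds:
non-collinear, hence a well-conditioned ENM, and densely connected under
the 12 Å cutoff. Default amplitude is 60°, giving end-to-end RMSDs from
~1.3 Å (twist, n = 20) to ~5.9 Å (hinge, n = 50); the three rigid-arm
kinds preserve every consecutive C-alpha distance exactly in both
conformations, because any rotation about a point fixes distances to that
point.

What the fixtures do not emulate: real contact-map heterogeneity
(secondary structure, side-chain packing), multi-domain networks with
weakly coupled interfaces, or experimental coordinate noise. Passing the
synthetic suite therefore demonstrates the correctness of the machinery —
cost assembly, solvers, equivalence of bases, schedule — not the
biological fidelity of any particular protein's pathway; the
integration tests on real open/closed pairs (which require downloading
PDB entries) cover that end.

On these small chains, truncating to 30 modes (often more than half the
spectrum at n = 20–50) leaves residuals of a few tenths of an Angstrom
and mean-bond drift up to ~0.08 Å, with occasional sub-0.01 Å
non-monotonic wiggles in the approach to the end state — all flagged by
the pathway object rather than hidden. Full-basis runs recover end points
to ~10⁻³ Å with bond drift below 0.01 Å.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 12 Å | ENM contact distance; the common C-alpha ENM choice. The original method's cutoff is undocumented, so quantitative comparisons against its published tables are tolerance-based, and topology-sensitive results should be read with that in mind. |
| `modes` | 30 | mode count m; 30 low modes suffice for convergence across a broad benchmark of two-state proteins ("optimum" variant). `"full"` = 3n − 6. |
| `steps` | auto | s = round(10 × end-to-end RMSD), i.e. ~0.1 Å per step. |
| `safeguard` | off | cost-increase step halving (see above). |
| spring constant | 1 | uniform, dimensionless; only mode shapes and relative stiffness matter to the pathway. |

## Problem sizes used in the shipped checks

The test suite and examples run entirely on generated fixtures with
n = 12–200 beads (equivalence checks at n = 20/50/100, scaling counters at
n = 50/100/200 with 3 steps each, recovery at n = 20–40 with the full
schedule), which keeps the whole suite in the seconds range while
exercising every code path including the sparse eigensolver. The
reference-pair step counts recomputed by `scripts/acceptance.py` use the
published end-point RMSDs of adenylate kinase (7.1 Å, 214 residues) and
the group II chaperonin (15.4 Å, 3928 residues) as inputs.

## Known limitations

* The method interpolates geometry; it makes no thermodynamic or kinetic
  claim — no energy barriers, no transition states, no double-well
  potential.
* Targets that stretch springs make the quadratic model indefinite; the
  descent guard keeps steps sane, but strongly expanding transitions on
  sparse networks may need the safeguard or more steps.
* Residue correspondence is by (chain, residue number), not sequence
  alignment; renumbered crystal forms surface as dropped residues.
* Only C-alpha coarse graining is supported; no all-atom reconstruction
  of intermediates.
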