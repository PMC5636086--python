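# ngeni — normal mode-guided elastic network interpolation

`ngeni` generates coarse-grained conformational transition pathways between
two end-point structures of a protein — for example the open and closed
crystal forms of an enzyme — for structural biologists and modellers who
need physically plausible intermediates without running molecular dynamics.

## The method

Each residue is reduced to its C-alpha position. Spatially close residues
(within a 12 Å cutoff by default) are connected by identical Hookean
springs — the elastic network model (ENM). Writing the start and end
coordinates as {x_i} and {y_i}, the pathway is built in
`s = round(10 × RMSD(x, y))` iterations. At step `k` every spring `(i, j)`
of the cost network is assigned the interpolated target distance

    l_ij = (1 − α)‖x_i − x_j‖ + α‖y_i − y_j‖,   α = k/s,

and the step displacement minimizes the distance-mismatch cost

    C = ½ Σ_(i<j) k_ij ( ‖x_i + δ_i − x_j − δ_j‖ − l_ij )².

The defining idea is the search space for δ. Normal mode analysis of the
current intermediate's ENM Hessian yields its vibrational modes; the step
displacement is constrained to a linear combination of the `m` lowest
non-rigid modes,

    δ_i = V_i C_w ,      V_i ∈ R^(3×m),  C_w = (c_1 … c_m)^T,

so each step moves along the molecule's intrinsic collective motions. A
second-order Taylor expansion turns `C` into a quadratic
`½ C_wᵀ Λ⁽¹⁾ C_w + ½ Λ⁽²⁾ C_w + Λ⁽³⁾` whose stationary condition
`Λ⁽¹⁾C_w + ½(Λ⁽²⁾)ᵀ = 0` is solved in closed form. Iterating — recomputing
the network and modes at every intermediate — produces the pathway.

Two variants are provided:

* **`run_ngeni`** — the mode-guided method; `modes=30` by default (the
  "optimum" count: low-frequency collective modes dominate large
  transitions), `modes="full"` for the complete non-rigid basis;
* **`run_eni`** — the conventional elastic network interpolation baseline,
  which minimizes the same per-step cost over all 3n Cartesian degrees of
  freedom. With the full mode basis the two are the same minimization in
  different bases, which the test suite verifies to machine precision.

Per-step work for the mode-guided variant scales as O(n·m²) (sparse
Lanczos NMA plus cost assembly over ~n springs), against O(n²) for the
Cartesian baseline — the practical argument for truncating the basis on
large assemblies.

## Worked example

```python
from ngeni import FixtureSpec, PathwayConfig, make_pair, rmsd, run_ngeni
from ngeni.metrics import bond_geometry

pair = make_pair(FixtureSpec(kind="hinge", n=40))   # 60° two-arm hinge bend
print(f"end-to-end RMSD: {rmsd(pair.start, pair.end):.2f} A")
pathway = run_ngeni(pair, PathwayConfig(modes=30))
print(f"iterations: {pathway.s}, final residual: {pathway.final_residual:.3f} A")
print(f"bond deviation: {bond_geometry(pathway).max_bond_deviation:.4f} A")
```

prints

```
end-to-end RMSD: 4.74 A
iterations: 47, final residual: 0.483 A
bond deviation: 0.0776 A
```

A 4.74 Å hinge transition is covered in 47 steps of ~0.1 Å. Using only 30
of the 114 non-rigid modes, the computed terminus lands 0.48 Å from the
true end structure (the full basis reaches 0.003 Å), and the mean virtual
C-alpha bond never drifts more than 0.08 Å from its canonical 3.8 Å — the
intermediates stay geometrically protein-like.

The same run from the shell, on any pair of PDB files:

```bash
ngeni pathway start.pdb end.pdb --modes 30 -o run/      # trajectory + metrics CSV
ngeni sweep start.pdb end.pdb --resolution 2.0          # convergence vs mode count
ngeni compare run_a/pathway.pdb run_b/pathway.pdb       # average inter-pathway RMSD
```

The scripts in `examples/` demonstrate each capability end to end:
`hinge_pathway.py`, `full_vs_eni_equivalence.py`,
`mode_convergence_sweep.py`, `mode_contributions.py`.

## Real structure pairs

Everything above runs on synthetic fixtures generated in-repo. To
reproduce the classic open/closed comparisons, download the PDB entries
(e.g. adenylate kinase `4ake`/`1ake`, group II chaperonin `3iyf`/`3j03`)
into `data/pdb/` as lowercase `<id>.pdb` files; the two integration tests
in `tests/test_acceptance.py` then run automatically:

```bash
mkdir -p data/pdb && cd data/pdb
for id in 4ake 1ake 3iyf 3j03; do wget https://files.rcsb.org/download/$id.pdb; done
```

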