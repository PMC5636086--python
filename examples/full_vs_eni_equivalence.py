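"""Full-mode interpolation is a change of basis of the Cartesian solver.

Runs the mode-guided method with the complete non-rigid basis (3n - 6
modes) and the conventional full-Cartesian elastic network interpolation
on the same hinge fixture, then measures the average RMSD between
corresponding intermediates.  The two pathways should agree to solver
precision: restricting steps to the full mode basis only re-expresses the
same search space.
"""

from ngeni import FixtureSpec, PathwayConfig, compare_pathways, make_pair, run_eni, run_ngeni

pair = make_pair(FixtureSpec(kind="hinge", n=20))
full = run_ngeni(pair, PathwayConfig(modes="full"))
eni = run_eni(pair, PathwayConfig())

comp = compare_pathways(full, eni)
print(f"steps: {full.s}")
print(f"average inter-pathway RMSD: {comp.average_rmsd:.2e} A")
print(f"largest per-step RMSD:      {comp.per_step_rmsd.max():.2e} A")

# Values at machine precision (~1e-15 A) confirm the equivalence; on real
# proteins the analogous comparison across independent implementations
# stays well below experimental resolution.
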