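"""How many normal modes does a transition need?

Sweeps the mode count m over {5, 10, 20, 30, full} on a 40-bead hinge
fixture and reports each pathway's final residual against a 1.0 A
convergence threshold (the synthetic stand-in for an experimental
resolution).  Low-frequency collective modes dominate hinge motions, so
the residual drops steeply with the first few tens of modes.
"""

from ngeni import FixtureSpec, PathwayConfig, convergence_check, make_pair, run_ngeni
from ngeni.metrics import format_convergence_table

pair = make_pair(FixtureSpec(kind="hinge", n=40))
resolution = 1.0

row = {"name": "hinge-40", "resolution": resolution}
print("m\tfinal residual (A)\tconverged")
for m in [5, 10, 20, 30, "full"]:
    pathway = run_ngeni(pair, PathwayConfig(modes=m))
    check = convergence_check(pathway, pair.end, resolution)
    row[m] = check
    print(f"{m}\t{check.residual:.3f}\t\t{'O' if check.converged else 'X'}")

print()
print(format_convergence_table([row]))
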