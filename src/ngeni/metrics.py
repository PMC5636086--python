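"""Pathway quality metrics.

Four families of diagnostics:

* inter-pathway comparison — the per-step superposed RMSD between two
  pathways' corresponding intermediates, and its average over all steps;
* the convergence condition — whether the last computed intermediate falls
  within the pair's experimental resolution of the end structure;
* mode-contribution profiles — the step-averaged |c_k| of each normal
  mode's weighting constant, and Pearson correlations between profiles;
* C-alpha pseudo-bond geometry — per-step mean virtual bond length
  (~3.8 A in real chains) and pseudo-bond angle, a physical-realism check
  on the intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComparisonError, DimensionError, ParameterError
from .pathway import TransitionPathway
from .structures import CoarseGrainedStructure, rmsd


@dataclass
class PathwayComparison:
    """Per-step and average RMSD between two pathways."""

    per_step_rmsd: np.ndarray
    average_rmsd: float


@dataclass
class ConvergenceResult:
    converged: bool
    residual: float
    resolution: float


@dataclass
class ModeContributionProfile:
    """Step-averaged |c_k| per mode; absolute values neutralize the
    eigenvector sign ambiguity."""

    mean_abs_weights: np.ndarray

    @property
    def m(self) -> int:
        return self.mean_abs_weights.shape[0]


@dataclass
class BondGeometry:
    """Per-step pseudo-bond statistics of a pathway."""

    per_step: pd.DataFrame  # columns: step, mean_bond_length, mean_bond_angle
    max_bond_deviation: float  # |per-step mean - mean of the two end-point means|, max over steps


def _conformations(p) -> list[CoarseGrainedStructure]:
    if isinstance(p, TransitionPathway):
        return p.conformations
    return list(p)


def compare_pathways(p1, p2) -> PathwayComparison:
    """Average superposed RMSD between corresponding intermediates.

    Accepts :class:`TransitionPathway` objects or plain conformation lists.
    Lengths may differ by one appended end point; the common prefix by step
    index is compared.
    """
    c1, c2 = _conformations(p1), _conformations(p2)
    if abs(len(c1) - len(c2)) > 1:
        raise ComparisonError(f"pathway lengths {len(c1)} vs {len(c2)} are incompatible")
    k = min(len(c1), len(c2))
    if c1[0].n != c2[0].n:
        raise ComparisonError(f"residue counts differ: {c1[0].n} vs {c2[0].n}")
    vals = np.array([rmsd(c1[i], c2[i]) for i in range(k)])
    return PathwayComparison(per_step_rmsd=vals, average_rmsd=float(vals.mean()))


def convergence_check(
    pathway: TransitionPathway, end: CoarseGrainedStructure, resolution: float
) -> ConvergenceResult:
    """Convergence condition: the last *computed* intermediate must lie
    within the experimental resolution of the end structure."""
    if resolution <= 0:
        raise ParameterError("resolution must be positive")
    residual = rmsd(pathway.last_computed(), end)
    return ConvergenceResult(
        converged=residual < resolution, residual=residual, resolution=resolution
    )


def mode_profile(pathway: TransitionPathway) -> ModeContributionProfile:
    """Mean |c_k| across all iteration steps, per mode index."""
    weights = [r.weights for r in pathway.records]
    if not weights or any(w is None for w in weights):
        raise ParameterError("pathway carries no per-step weighting constants")
    stack = np.vstack([np.abs(w.c) for w in weights])
    return ModeContributionProfile(mean_abs_weights=stack.mean(axis=0))


def profile_correlation(
    a: ModeContributionProfile, b: ModeContributionProfile, k: int
) -> float:
    """Pearson correlation of the first ``k`` entries of two profiles."""
    if k < 2:
        raise ParameterError("correlation needs at least 2 modes")
    if a.m < k or b.m < k:
        raise ParameterError(f"profiles cover {a.m} and {b.m} modes; need >= {k}")
    xa, xb = a.mean_abs_weights[:k], b.mean_abs_weights[:k]
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ParameterError("zero variance in a profile; correlation undefined")
    return float(np.corrcoef(xa, xb)[0, 1])


def _bond_indices(structure: CoarseGrainedStructure) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive-residue bond pairs and angle triplets within chains.

    A bond joins residues of the same chain with residue numbers differing
    by exactly 1 (chain breaks and insertion-coded residues are excluded
    from the statistics)."""
    keys = []
    for chain, number, _ in structure.residue_ids:
        digits = number.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        try:
            keys.append((chain, int(digits), number != digits))
        except ValueError:
            keys.append((chain, None, True))
    bonds = []
    for i in range(len(keys) - 1):
        (c1, n1, ic1), (c2, n2, ic2) = keys[i], keys[i + 1]
        if c1 == c2 and n1 is not None and n2 is not None and not ic1 and not ic2 and n2 - n1 == 1:
            bonds.append((i, i + 1))
    bonds = np.asarray(bonds, int).reshape(-1, 2)
    bond_set = {tuple(b) for b in bonds}
    triplets = np.asarray(
        [(i - 1, i, i + 1) for (_, i) in bonds if (i, i + 1) in bond_set and i >= 1
         and (i - 1, i) in bond_set],
        int,
    ).reshape(-1, 3)
    return bonds, triplets


def bond_geometry(pathway) -> BondGeometry:
    """Per-step mean pseudo-bond length and angle along a pathway.

    ``max_bond_deviation`` is the largest deviation of any step's mean bond
    length from the average of the two end-point means — the quantity used
    to judge geometric realism of the intermediates.
    """
    confs = _conformations(pathway)
    if confs[0].n < 3:
        raise DimensionError("bond geometry needs at least 3 residues")
    bonds, triplets = _bond_indices(confs[0])
    if bonds.shape[0] == 0:
        raise DimensionError("no consecutive-residue bonds found")
    rows = []
    for k, conf in enumerate(confs):
        x = conf.coords
        blen = np.linalg.norm(x[bonds[:, 0]] - x[bonds[:, 1]], axis=1)
        if triplets.shape[0]:
            u = x[triplets[:, 0]] - x[triplets[:, 1]]
            v = x[triplets[:, 2]] - x[triplets[:, 1]]
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))).mean())
        else:
            ang = float("nan")
        rows.append({"step": k, "mean_bond_length": float(blen.mean()), "mean_bond_angle": ang})
    df = pd.DataFrame(rows)
    endpoint_mean = 0.5 * (df.mean_bond_length.iloc[0] + df.mean_bond_length.iloc[-1])
    dev = float(np.max(np.abs(df.mean_bond_length.to_numpy() - endpoint_mean)))
    return BondGeometry(per_step=df, max_bond_deviation=dev)


def records_frame(pathway: TransitionPathway, include_weights: bool = False) -> pd.DataFrame:
    """Per-step metrics of a run as a DataFrame (the CSV schema)."""
    rows = []
    for r in pathway.records:
        row = {
            "step": r.step,
            "alpha": r.alpha,
            "rmsd_prev": r.rmsd_prev,
            "rmsd_to_end": r.rmsd_to_end,
            "cost_exact": r.cost_exact,
            "cost_quadratic": r.cost_quadratic,
            "n_modes": r.n_modes,
            "op_count": r.op_count,
        }
        if include_weights and r.weights is not None:
            for idx, val in enumerate(r.weights.c, start=1):
                row[f"c_{idx}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def format_convergence_table(rows: list[dict]) -> str:
    """One-page text table of convergence results (one row per run).

    Each row dict needs keys ``name``, ``resolution`` and one entry per
    mode count mapping to a :class:`ConvergenceResult`.
    """
    if not rows:
        return "(no runs)\n"
    mode_keys = [k for k in rows[0] if k not in ("name", "resolution")]
    header = "Protein\tResolution (A)\t" + "\t".join(str(k) for k in mode_keys)
    lines = [header]
    for row in rows:
        marks = [
            "O" if row[k].converged else "X" for k in mode_keys
        ]
        lines.append(f"{row['name']}\t{row['resolution']:.2f}\t" + "\t".join(marks))
    return "\n".join(lines) + "\n"
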