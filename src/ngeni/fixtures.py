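"""Deterministic synthetic two-conformation bead chains.

Real transition pairs (open/closed crystal forms) are large downloads; the
fixtures here reproduce the *phenomenology* that matters to the algorithm —
two rigid arms of a C-alpha chain related by a hinge bend, shear slide, or
twist about the chain axis — at any size, with canonical 3.8 A virtual
bonds, without any external data.

The reference geometry is a coarse helix (rotation 100 degrees and rise
~1.4 A per residue, radius 2.3 A), which keeps the chain non-collinear and
well connected under the usual 12 A elastic-network cutoff.  Hinge and
twist motions rotate the second arm about an axis through the hinge bead,
so every consecutive C-alpha distance is exactly preserved in both
conformations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .structures import CoarseGrainedStructure, StructurePair

#: canonical C-alpha virtual bond length, Angstrom
BOND_LENGTH = 3.8

_HELIX_TURN_DEG = 100.0
_HELIX_RADIUS = 2.3


@dataclass
class FixtureSpec:
    """Recipe for a synthetic two-conformation pair.

    kind:
        ``hinge`` (bend the second arm about an axis perpendicular to the
        chain), ``shear`` (dihedral rotation about the hinge bond — the far
        arm slides laterally), ``twist`` (rotate the second arm about the
        overall chain axis), or ``random-perturb`` (seeded Gaussian
        displacement).  The three rigid-arm kinds preserve every
        consecutive C-alpha distance exactly in both conformations.
    n:
        Residue count (>= 12 so each arm has >= 6 residues).
    angle_deg:
        Rotation amplitude in degrees, in [0, 180) (hinge/shear/twist).
    perturb_scale:
        Per-coordinate Gaussian sigma in Angstrom (random-perturb kind).
    """

    kind: Literal["hinge", "shear", "twist", "random-perturb"] = "hinge"
    n: int = 20
    bond_length: float = BOND_LENGTH
    angle_deg: float = 60.0
    perturb_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("hinge", "shear", "twist", "random-perturb"):
            raise ParameterError(f"unknown fixture kind {self.kind!r}")
        if self.n < 12:
            raise ParameterError("fixtures need n >= 12 (>= 6 residues per arm)")
        if self.bond_length <= 0:
            raise ParameterError("bond length must be positive")
        if not 0.0 <= self.angle_deg < 180.0:
            raise ParameterError("angle must lie in [0, 180) degrees")


def helix_chain(n: int, bond_length: float = BOND_LENGTH) -> np.ndarray:
    """Reference C-alpha chain: a coarse helix with exact bond lengths."""
    theta = math.radians(_HELIX_TURN_DEG)
    chord2 = 2.0 * _HELIX_RADIUS**2 * (1.0 - math.cos(theta))
    if bond_length**2 <= chord2:
        raise ParameterError(
            f"bond length {bond_length} too short for helix radius {_HELIX_RADIUS}"
        )
    rise = math.sqrt(bond_length**2 - chord2)
    idx = np.arange(n)
    return np.stack(
        [
            _HELIX_RADIUS * np.cos(idx * theta),
            _HELIX_RADIUS * np.sin(idx * theta),
            idx * rise,
        ],
        axis=1,
    )


def _default_ids(n: int) -> list[tuple[str, str, str]]:
    return [("A", str(i + 1), "GLY") for i in range(n)]


def make_pair(spec: FixtureSpec) -> StructurePair:
    """Build a start/end conformation pair from a fixture recipe.

    Deterministic given the spec; the seed is used only by the
    ``random-perturb`` kind.
    """
    spec.validate()
    start = helix_chain(spec.n, spec.bond_length)
    hinge = spec.n // 2  # pivot bead; arm B = beads after it
    pivot = start[hinge]
    arm = slice(hinge + 1, spec.n)
    end = start.copy()

    if spec.kind == "hinge":
        chain_dir = start[-1] - start[0]
        local = start[hinge + 1] - start[hinge - 1]
        axis = np.cross(chain_dir, local)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(math.radians(spec.angle_deg) * axis)
        end[arm] = rot.apply(start[arm] - pivot) + pivot
    elif spec.kind == "twist":
        axis = start[-1] - start[0]
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(math.radians(spec.angle_deg) * axis)
        end[arm] = rot.apply(start[arm] - pivot) + pivot
    elif spec.kind == "shear":
        # dihedral rotation about the hinge bond: the far arm slides
        # laterally while every consecutive C-alpha distance is preserved
        axis = start[hinge + 1] - start[hinge]
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(math.radians(spec.angle_deg) * axis)
        end[arm] = rot.apply(start[arm] - pivot) + pivot
    else:  # random-perturb
        rng = np.random.default_rng(spec.seed)
        end = start + rng.normal(scale=spec.perturb_scale, size=start.shape)

    ids = _default_ids(spec.n)
    label = f"{spec.kind}-n{spec.n}"
    return StructurePair(
        start=CoarseGrainedStructure(ids, start, label=f"{label}-start"),
        end=CoarseGrainedStructure(list(ids), end, label=f"{label}-end"),
        resolution=1.0,
    )


def make_pdb_text(structure: CoarseGrainedStructure) -> str:
    """Render a structure as single-model C-alpha-only PDB text."""
    from .structures import format_structure_pdb

    return format_structure_pdb(structure) + "END\n"
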