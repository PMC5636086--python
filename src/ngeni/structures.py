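"""Coarse-grained C-alpha structures: PDB input, residue pairing, superposition.

A protein is represented by the ordered positions of its alpha carbons
(one bead per residue).  The two conformational end points of a transition
are held in a :class:`StructurePair` with a one-to-one residue
correspondence established by (chain id, residue number).  All RMSD values
in this package follow a single convention: C-alpha only, mass-unweighted,
after optimal (Kabsch) superposition.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.SVDSuperimposer import SVDSuperimposer

from .errors import (
    DimensionError,
    EmptySelectionError,
    FormatError,
    PairingError,
    ParameterError,
    SolverError,
)

log = logging.getLogger(__name__)

#: (chain id, residue number with insertion code, residue name)
ResidueID = tuple[str, str, str]


@dataclass
class CoarseGrainedStructure:
    """Ordered C-alpha coordinates with residue labels.

    Parameters
    ----------
    residue_ids:
        One ``(chain, number, name)`` triple per bead.  ``number`` is the
        PDB residue number with any insertion code concatenated
        (e.g. ``"52A"``), so it is stored as a string.
    coords:
        ``(n, 3)`` array of positions in Angstrom.
    label:
        Free-text provenance (PDB id, fixture name, pathway step).
    """

    residue_ids: list[ResidueID]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DimensionError(f"coords must be (n, 3), got {self.coords.shape}")
        if len(self.residue_ids) != self.coords.shape[0]:
            raise DimensionError(
                f"{len(self.residue_ids)} residue ids vs {self.coords.shape[0]} coordinates"
            )
        if self.coords.shape[0] < 3:
            raise DimensionError("a coarse-grained structure needs at least 3 residues")
        if not np.all(np.isfinite(self.coords)):
            raise DimensionError("coordinates must be finite")
        keys = [(c, r) for c, r, _ in self.residue_ids]
        if len(set(keys)) != len(keys):
            raise DimensionError("duplicate (chain, residue number) keys")

    @property
    def n(self) -> int:
        """Number of residues (beads)."""
        return self.coords.shape[0]

    def keys(self) -> list[tuple[str, str]]:
        """(chain, residue number) keys, the pairing identity of each bead."""
        return [(c, r) for c, r, _ in self.residue_ids]

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "CoarseGrainedStructure":
        """Copy of this structure with new coordinates (same residues)."""
        return CoarseGrainedStructure(
            residue_ids=list(self.residue_ids),
            coords=np.asarray(coords, dtype=float),
            label=self.label if label is None else label,
        )


@dataclass
class StructurePair:
    """Two end-point conformations with matched residues.

    ``resolution`` is the representative experimental resolution of the
    pair (the smaller of the two crystallographic resolutions); it is the
    yardstick of the convergence condition and is optional for synthetic
    fixtures (default 1.0 A).
    """

    start: CoarseGrainedStructure
    end: CoarseGrainedStructure
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.start.n != self.end.n:
            raise PairingError(
                f"end points have {self.start.n} vs {self.end.n} residues; pair them first"
            )
        if self.start.keys() != self.end.keys():
            raise PairingError("end points carry different residue keys; pair them first")
        if self.resolution <= 0:
            raise ParameterError("resolution must be positive")

    @property
    def n(self) -> int:
        return self.start.n

    def reversed(self) -> "StructurePair":
        """The reverse transition (end -> start)."""
        return StructurePair(start=self.end, end=self.start, resolution=self.resolution)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _as_handle(source: str | os.PathLike | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source)  # noqa: SIM115 - caller closes via parser


def _pick_ca(residue):
    """Return the CA atom of a residue, resolving altlocs to max occupancy."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
        # ties: max() keeps the first encountered
        return best
    return atom


def _structure_from_model(model, chains, label: str) -> CoarseGrainedStructure:
    residue_ids: list[ResidueID] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for chain in sorted(model, key=lambda c: c.id):
        if chains is not None and chain.id not in chains:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():  # HETATM record (water, ligand, ...)
                continue
            atom = _pick_ca(residue)
            if atom is None:
                skipped += 1
                continue
            number = f"{resseq}{icode.strip()}"
            residue_ids.append((chain.id, number, residue.get_resname()))
            rows.append(np.asarray(atom.get_coord(), dtype=float))
    if skipped:
        log.warning("%s: skipped %d residues lacking a CA atom", label, skipped)
    if not rows:
        raise EmptySelectionError(f"{label}: no C-alpha atoms after selection")
    if len(rows) < 3:
        raise EmptySelectionError(f"{label}: only {len(rows)} C-alpha atoms; need >= 3")
    return CoarseGrainedStructure(residue_ids, np.vstack(rows), label=label)


def read_calpha(
    pdb_source: str | os.PathLike | IO[str],
    chains: str | Sequence[str] | None = None,
    model_index: int = 0,
    label: str | None = None,
) -> CoarseGrainedStructure:
    """Read one model of a PDB file as a C-alpha bead structure.

    Parameters
    ----------
    pdb_source:
        Path or open text handle with PDB-format content.
    chains:
        Chain id(s) to keep; ``None`` keeps every chain.
    model_index:
        Which MODEL block to read (0-based; 0 = first/lowest).
    """
    if isinstance(chains, str):
        chains = set(chains)
    elif chains is not None:
        chains = set(chains)
    if label is None:
        label = os.path.basename(str(pdb_source)) if not hasattr(pdb_source, "read") else "<stream>"
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", _as_handle(pdb_source))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"could not parse PDB input {label}: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"{label}: PDB input contains no models")
    if not 0 <= model_index < len(models):
        raise FormatError(f"{label}: model index {model_index} out of range (have {len(models)})")
    return _structure_from_model(models[model_index], chains, label)


def read_calpha_models(
    pdb_source: str | os.PathLike | IO[str],
    chains: str | Sequence[str] | None = None,
) -> list[CoarseGrainedStructure]:
    """Read every model of a (multi-model) PDB file, in order."""
    if isinstance(chains, str):
        chains = set(chains)
    elif chains is not None:
        chains = set(chains)
    label = os.path.basename(str(pdb_source)) if not hasattr(pdb_source, "read") else "<stream>"
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", _as_handle(pdb_source))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"could not parse PDB input {label}: {exc}") from exc
    out = [
        _structure_from_model(model, chains, f"{label}#model{i}")
        for i, model in enumerate(structure)
    ]
    if not out:
        raise FormatError(f"{label}: PDB input contains no models")
    return out


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_structures(
    a: CoarseGrainedStructure,
    b: CoarseGrainedStructure,
    resolution: float = 1.0,
) -> StructurePair:
    """Match residues of two structures by (chain, residue number).

    Residues present in only one structure are dropped from both (the count
    is logged).  Raises :class:`PairingError` below 3 common residues.
    Pairing is idempotent: pairing an already-matched pair is the identity.
    """
    keys_a = a.keys()
    keys_b = b.keys()
    common = set(keys_a) & set(keys_b)
    if len(common) < 3:
        raise PairingError(
            f"only {len(common)} residues common to {a.label!r} and {b.label!r}; need >= 3"
        )
    dropped = (len(keys_a) - len(common)) + (len(keys_b) - len(common))
    if dropped:
        log.info(
            "pair_structures: dropped %d unmatched residues (%s: %d -> %d, %s: %d -> %d)",
            dropped, a.label, len(keys_a), len(common), b.label, len(keys_b), len(common),
        )
    mask_a = [k in common for k in keys_a]
    idx_a = np.flatnonzero(mask_a)
    sub_a = CoarseGrainedStructure(
        [a.residue_ids[i] for i in idx_a], a.coords[idx_a], label=a.label
    )
    pos_b = {k: i for i, k in enumerate(keys_b)}
    idx_b = np.array([pos_b[keys_a[i]] for i in idx_a])
    sub_b = CoarseGrainedStructure(
        [b.residue_ids[i] for i in idx_b], b.coords[idx_b], label=b.label
    )
    # keep a's residue names on b's side of the key check: names may differ
    # (e.g. point mutants); identity is (chain, number) only.
    sub_b.residue_ids = [
        (c, r, sub_b.residue_ids[i][2]) for i, (c, r, _) in enumerate(sub_a.residue_ids)
    ]
    return StructurePair(start=sub_a, end=sub_b, resolution=resolution)


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def superpose_arrays(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of two (n, 3) coordinate arrays.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation + translation`` best fits ``target`` in the
    least-squares sense.  The rotation is always proper (det = +1);
    reflections are corrected.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DimensionError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    sup = SVDSuperimposer()
    sup.set(target, mobile)
    sup.run()
    rot, tran = sup.get_rotran()
    if np.linalg.det(rot) <= 0:  # SVDSuperimposer corrects this; belt and braces
        raise SolverError("superposition produced an improper rotation")
    return rot, tran, float(sup.get_rms())


def superpose(
    mobile: CoarseGrainedStructure, target: CoarseGrainedStructure
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of two structures (see :func:`superpose_arrays`)."""
    return superpose_arrays(mobile.coords, target.coords)


def rmsd(a, b) -> float:
    """Superposed C-alpha RMSD in Angstrom between structures or arrays."""
    ca = a.coords if isinstance(a, CoarseGrainedStructure) else np.asarray(a, float)
    cb = b.coords if isinstance(b, CoarseGrainedStructure) else np.asarray(b, float)
    return superpose_arrays(ca, cb)[2]


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _split_number(number: str) -> tuple[int, str]:
    """Split a residue-number key back into (resseq, icode)."""
    digits = number.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    icode = number[len(digits):] or " "
    try:
        return int(digits), icode[:1]
    except ValueError:
        return 0, " "


def format_structure_pdb(
    structure: CoarseGrainedStructure, serial_start: int = 1
) -> str:
    """Render one structure as C-alpha ATOM records (no MODEL wrapper)."""
    lines = []
    serial = serial_start
    prev_chain = None
    for (chain, number, name), (x, y, z) in zip(structure.residue_ids, structure.coords):
        if prev_chain is not None and chain != prev_chain:
            lines.append(f"TER   {'':>5}      {'':>3} {prev_chain}")
        resseq, icode = _split_number(number)
        lines.append(
            f"ATOM  {serial:>5}  CA  {name:>3} {chain[:1]}{resseq:>4}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
        serial += 1
        prev_chain = chain
    lines.append(f"TER   {'':>5}      {'':>3} {prev_chain}")
    return "\n".join(lines) + "\n"


def write_pathway(pathway, sink: str | os.PathLike | IO[str]) -> None:
    """Write a transition pathway as a multi-model PDB file.

    One MODEL/ENDMDL block per conformation, in order; each block carries a
    REMARK line with the iteration index and the interpolation scale factor
    alpha, so a trajectory is self-describing.
    """
    conformations = pathway.conformations
    if not conformations:
        raise DimensionError("pathway has no conformations")
    own = not hasattr(sink, "write")
    handle: IO[str] = open(sink, "w") if own else sink  # type: ignore[assignment]
    try:
        for k, conf in enumerate(conformations):
            alpha = pathway.alpha_of(k)
            handle.write(f"MODEL     {k + 1:>4}\n")
            handle.write(f"REMARK 250 NGENI STEP {k} ALPHA {alpha:.6f}\n")
            handle.write(format_structure_pdb(conf))
            handle.write("ENDMDL\n")
        handle.write("END\n")
    finally:
        if own:
            handle.close()
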