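"""Multi-frame structure model, Ballesteros–Weinstein addressing, and superposition.

The trajectory container is deliberately minimal: ordered frames of named atoms,
addressable by (chain, residue number, atom name) or — through a :class:`ResidueMap`
— by Ballesteros–Weinstein (BW) code such as ``"7.47"``.  Coordinates are in Å.
The reference structure is assumed membrane-aligned with +z pointing toward the
extracellular side (OPM convention); downstream z-displacement and XY-projection
metrics inherit this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
from scipy.spatial.transform import Rotation


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class StructuralError(ValueError):
    """Raised when frames of one trajectory have inconsistent atom sets."""


class LookupCodeError(KeyError):
    """Raised when a Ballesteros–Weinstein code is not in the residue map."""


class MissingAtomError(KeyError):
    """Raised when a resolved residue lacks the requested atom."""


class DegenerateAlignmentError(ValueError):
    """Raised when an alignment selection has <3 atoms or is collinear."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: PDB atom name, residue identity, chain and position (Å)."""

    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {pos!r}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        object.__setattr__(self, "position", pos)


class Frame:
    """One trajectory frame: an ordered collection of atoms with unique keys."""

    def __init__(self, index: int, atoms: Sequence[AtomRecord]):
        if index < 0:
            raise ValueError("frame index must be >= 0")
        self.index = index
        self.atoms = list(atoms)
        self._lookup: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in self._lookup:
                raise ValueError(f"duplicate atom {key} in frame {index}")
            self._lookup[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def atom_keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(self._lookup)

    def coord(self, chain_id: str, residue_number: int, atom_name: str) -> np.ndarray:
        key = (chain_id, residue_number, atom_name)
        try:
            return self.atoms[self._lookup[key]].position
        except KeyError:
            raise MissingAtomError(
                f"atom {atom_name!r} not found in chain {chain_id} residue "
                f"{residue_number} of frame {self.index}"
            ) from None

    def coords(self) -> np.ndarray:
        """All positions as an (n_atoms, 3) array, in atom order."""
        return np.array([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray, index: int | None = None) -> "Frame":
        """A copy of this frame with replaced coordinates (same atoms, same order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.atom_name, a.residue_name, a.chain_id, a.residue_number, c)
            for a, c in zip(self.atoms, coords)
        ]
        return Frame(self.index if index is None else index, atoms)


class Trajectory:
    """Ordered frames sharing one atom ordering, tagged with replicate/condition."""

    def __init__(self, frames: Sequence[Frame], replicate_id: str = "", condition: str = ""):
        frames = list(frames)
        if not frames:
            raise ValueError("a trajectory needs at least one frame")
        keys0 = frames[0].atom_keys()
        for f in frames[1:]:
            if f.atom_keys() != keys0:
                raise StructuralError(
                    f"frame {f.index} atom set differs from frame {frames[0].index}"
                )
        self.frames = frames
        self.replicate_id = replicate_id
        self.condition = condition

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


@dataclass
class ResidueMap:
    """Ballesteros–Weinstein code → (chain, residue number, residue name).

    Codes are strings like ``"2.39"`` or loop labels like ``"ECL2"``.  TM helix
    ranges used for alignment are carried separately as
    ``tm_ranges[name] = (chain_id, first_residue, last_residue)``.
    """

    residues: Mapping[str, tuple[str, int, str]]
    tm_ranges: Mapping[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = dict(self.residues)
        self.tm_ranges = dict(self.tm_ranges)

    def __contains__(self, code: str) -> bool:
        return code in self.residues

    def lookup(self, code: str) -> tuple[str, int, str]:
        try:
            return self.residues[code]
        except KeyError:
            raise LookupCodeError(f"Ballesteros–Weinstein code {code!r} not in map") from None

    def resolve(self, code: str, atom_name: str, frame: Frame) -> np.ndarray:
        """Position of ``atom_name`` on the residue addressed by ``code``."""
        chain, resnum, _ = self.lookup(code)
        return frame.coord(chain, resnum, atom_name)

    def tm_residue_ids(self, names: Iterable[str]) -> list[tuple[str, int]]:
        out = []
        for name in names:
            try:
                chain, lo, hi = self.tm_ranges[name]
            except KeyError:
                raise LookupCodeError(f"TM range {name!r} not in map") from None
            out.extend((chain, r) for r in range(lo, hi + 1))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResidueMap":
        """Load from a YAML config with ``residues`` and optional ``tm_ranges`` keys.

        residues:  {"2.39": {chain: A, resnum: 94, resname: THR}, ...}
        tm_ranges: {TM2: {chain: A, first: 88, last: 100}, ...}
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        residues = {
            str(code): (str(v["chain"]), int(v["resnum"]), str(v.get("resname", "UNK")))
            for code, v in raw.get("residues", {}).items()
        }
        tm_ranges = {
            str(name): (str(v["chain"]), int(v["first"]), int(v["last"]))
            for name, v in raw.get("tm_ranges", {}).items()
        }
        return cls(residues, tm_ranges)


def default_residue_map(chain_id: str = "A") -> ResidueMap:
    """Kappa-opioid receptor residue map with author numbering.

    Covers the residues the per-frame observables need plus minimal TM2/TM3/TM5
    anchor ranges for superposition.
    """
    residues = {
        "2.39": (chain_id, 94, "THR"),
        "2.60": (chain_id, 115, "GLN"),
        "5.39": (chain_id, 227, "LYS"),
        "6.48": (chain_id, 287, "TRP"),
        "6.58": (chain_id, 297, "GLU"),
        "7.43": (chain_id, 320, "TYR"),
        "7.47": (chain_id, 324, "SER"),
        "7.48": (chain_id, 325, "LEU"),
        "7.53": (chain_id, 330, "TYR"),
        "8.47": (chain_id, 334, "ASP"),
    }
    tm_ranges = {
        "TM2": (chain_id, 96, 98),
        "TM3": (chain_id, 135, 137),
        "TM5": (chain_id, 230, 232),
    }
    return ResidueMap(residues, tm_ranges)


# ---------------------------------------------------------------------------
# PDB I/O (delegated to biotite; minimal dialect: ATOM/HETATM, MODEL, ENDMDL)
# ---------------------------------------------------------------------------

def read_multimodel_pdb(
    path: str | Path, replicate_id: str = "", condition: str = ""
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`, one frame per MODEL.

    A file without MODEL tags yields a single-frame trajectory.  Atom order is
    preserved.  Inconsistent atom sets across MODEL blocks raise
    :class:`StructuralError`; malformed records raise :class:`PDBParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = _pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises assorted errors on bad files
        msg = str(exc)
        if "model" in msg.lower() and "atoms" in msg.lower():
            raise StructuralError(f"inconsistent MODEL blocks in {path}: {msg}") from exc
        raise PDBParseError(f"cannot parse PDB file {path}: {msg}") from exc
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    frames = []
    n = stack.array_length()
    names = stack.atom_name
    resnames = stack.res_name
    chains = stack.chain_id
    resnums = stack.res_id
    for m in range(stack.stack_depth()):
        coords = stack.coord[m]
        atoms = [
            AtomRecord(names[i], resnames[i], chains[i], int(resnums[i]), coords[i])
            for i in range(n)
        ]
        frames.append(Frame(m, atoms))
    return Trajectory(frames, replicate_id=replicate_id, condition=condition)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a standard multi-model PDB (MODEL/ENDMDL per frame)."""
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    template = traj.frames[0]
    n = len(template)
    arr = struc.AtomArray(n)
    arr.coord = template.coords().astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in template.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in template.atoms])
    arr.res_name = np.array([a.residue_name for a in template.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in template.atoms], dtype="U6")
    arr.element = np.array(
        [_guess_element(a.atom_name) for a in template.atoms], dtype="U2"
    )
    stack = struc.stack([arr] * len(traj))
    stack.coord = np.array([f.coords() for f in traj.frames], dtype=np.float32)
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    # single-model stacks are written without MODEL framing; add it for a
    # uniform multi-model dialect
    if not any(line.startswith("MODEL") for line in pdb_file.lines):
        pdb_file.lines = ["MODEL        1", *pdb_file.lines, "ENDMDL"]
    pdb_file.write(str(path))


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0] if stripped else "X"


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSpec:
    """Cα selection defining the superposition, plus the reference frame.

    ``selection`` lists (chain_id, residue_number) pairs whose Cα atoms anchor
    the least-squares fit; the conventional choice is the TM2/TM3/TM5 helices.
    """

    selection: Sequence[tuple[str, int]]
    reference: Frame
    atom_name: str = "CA"

    @classmethod
    def from_tm_ranges(
        cls, rmap: ResidueMap, reference: Frame, tm_names: Sequence[str] = ("TM2", "TM3", "TM5")
    ) -> "AlignmentSpec":
        return cls(rmap.tm_residue_ids(tm_names), reference)

    def select_coords(self, frame: Frame) -> np.ndarray:
        return np.array(
            [frame.coord(c, r, self.atom_name) for c, r in self.selection]
        )


def superpose(frame: Frame, spec: AlignmentSpec) -> tuple[Frame, float]:
    """Least-squares rigid superposition of a frame onto the reference.

    Rotation + translation only (determinant +1; no scaling or reflection),
    fitted on the selection's Cα atoms and applied to every atom of the frame.
    Returns the transformed frame and the selection RMSD in Å.
    """
    mobile = spec.select_coords(frame)
    target = spec.select_coords(spec.reference)
    if len(mobile) < 3:
        raise DegenerateAlignmentError("alignment selection needs at least 3 atoms")
    mob_c = mobile - mobile.mean(axis=0)
    tgt_c = target - target.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(tgt_c, tol=1e-8) < 2:
        raise DegenerateAlignmentError("alignment selection is collinear")
    rot, _ = Rotation.align_vectors(tgt_c, mob_c)
    moved_sel = rot.apply(mob_c) + target.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved_sel - target) ** 2, axis=1))))
    all_coords = rot.apply(frame.coords() - mobile.mean(axis=0)) + target.mean(axis=0)
    return frame.with_coords(all_coords), rmsd
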