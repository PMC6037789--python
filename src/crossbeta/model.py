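"""Data model for multi-chain peptide systems.

A :class:`Frame` is one snapshot of ``N`` identical short peptide chains; a
:class:`Trajectory` is a time-ordered sequence of frames.  All coordinates are
in Ångström and all internal residue indexing is 0-based; file-format serial
numbers exist only inside the I/O layer.

Periodic boundaries: a cubic box edge may be attached to a frame (Å).  When
present, inter-chain distance computations apply the minimum-image convention;
chains themselves are assumed whole (not wrapped mid-chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructureError

# 1-letter <-> 3-letter amino-acid codes (20 standard residues + UNK).
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}
AA_3TO1["UNK"] = "X"

#: Backbone atom labels; everything else is treated as side chain.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "H", "OXT"})

N_H_LENGTH = 1.00  # Å, amide N-H bond used when reconstructing hydrogens


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


@dataclass
class Atom:
    """A single atom with label, element and Cartesian position (Å)."""

    name: str
    position: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.element:
            self.element = _element_from_name(self.name)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES


@dataclass
class Residue:
    """One amino-acid residue: 0-based chain index, 3-letter name, atoms."""

    index_in_chain: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def position(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise StructureError(f"residue {self.name}{self.index_in_chain} lacks atom {name!r}")
        return a.position

    @property
    def is_proline(self) -> bool:
        return self.name == "PRO"

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.name, "X")


@dataclass
class Peptide:
    """An ordered chain of residues."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for r in self.residues for a in r.atoms if a.is_heavy]
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass
class Frame:
    """One snapshot: ``N`` peptides, a time stamp (ns), optional cubic box (Å)."""

    time: float
    peptides: list[Peptide] = field(default_factory=list)
    box_edge: float | None = None

    def __post_init__(self) -> None:
        if not self.peptides:
            raise StructureError("a frame must contain at least one peptide")

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)


@dataclass
class Trajectory:
    """Time-ordered frames plus free-form metadata."""

    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def minimum_image(vectors: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    With no box the vectors are returned unchanged (open boundaries).
    """
    if box_edge is None:
        return vectors
    vectors = np.asarray(vectors, dtype=float)
    return vectors - box_edge * np.round(vectors / box_edge)


def end_to_end_distance(peptide: Peptide) -> float:
    """Euclidean distance (Å) between the first and last residue CA atoms."""
    if len(peptide) < 2:
        raise StructureError("end-to-end distance requires at least two residues")
    first = peptide.residues[0].position("CA")
    last = peptide.residues[-1].position("CA")
    return float(np.linalg.norm(last - first))


def place_amide_h(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Planar amide H: on the bisector opposite C(prev) and CA, 1.00 Å from N."""
    u1 = c_prev - n
    u1 /= np.linalg.norm(u1)
    u2 = ca - n
    u2 /= np.linalg.norm(u2)
    direction = -(u1 + u2)
    norm = np.linalg.norm(direction)
    if norm < 1e-8:
        raise StructureError("degenerate backbone geometry: cannot place amide H")
    return n + N_H_LENGTH * direction / norm


def reconstruct_amide_h(frame: Frame) -> Frame:
    """Return a frame in which every missing amide hydrogen has been rebuilt.

    H is placed in the C(prev)–N–CA plane on the external bisector, 1.00 Å from
    N.  Prolines and chain N-termini never receive an H; hydrogens already
    present are left untouched.  Raises :class:`StructureError` if a residue
    lacks the N or CA needed for the construction.
    """
    new_peptides = []
    for pep in frame.peptides:
        new_residues = []
        for i, res in enumerate(pep.residues):
            atoms = list(res.atoms)
            if i > 0 and not res.is_proline and res.atom("H") is None:
                n = res.atom("N")
                ca = res.atom("CA")
                if n is None or ca is None:
                    raise StructureError(
                        f"chain {pep.chain_id} residue {res.name}{i}: "
                        "missing N or CA, cannot reconstruct amide H"
                    )
                prev_c = pep.residues[i - 1].atom("C")
                if prev_c is None:
                    raise StructureError(
                        f"chain {pep.chain_id} residue {i - 1}: missing C, "
                        "cannot reconstruct amide H of the next residue"
                    )
                h = place_amide_h(prev_c.position, n.position, ca.position)
                # keep backbone order N, H, CA, ... when inserting
                insert_at = next(
                    (k + 1 for k, a in enumerate(atoms) if a.name == "N"), 0
                )
                atoms.insert(insert_at, Atom("H", h, element="H"))
            new_residues.append(Residue(res.index_in_chain, res.name, atoms))
        new_peptides.append(Peptide(pep.chain_id, new_residues))
    return Frame(frame.time, new_peptides, frame.box_edge)


def frame_has_amide_h(frame: Frame) -> bool:
    """True if every residue that should carry an amide H actually does."""
    for pep in frame.peptides:
        for i, res in enumerate(pep.residues):
            if i > 0 and not res.is_proline and res.atom("H") is None:
                return False
    return True


def transform_frame(frame: Frame, rotation: np.ndarray, translation: np.ndarray) -> Frame:
    """Apply a rigid motion ``x -> R x + t`` to every atom (testing helper)."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    peptides = []
    for pep in frame.peptides:
        residues = []
        for res in pep.residues:
            atoms = [
                Atom(a.name, rotation @ a.position + translation, element=a.element)
                for a in res.atoms
            ]
            residues.append(Residue(res.index_in_chain, res.name, atoms))
        peptides.append(Peptide(pep.chain_id, residues))
    return Frame(frame.time, peptides, frame.box_edge)
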