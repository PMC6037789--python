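"""Reading and writing multi-frame coordinate files.

Two on-disk formats are supported:

* multi-model PDB (``MODEL``/``ENDMDL`` blocks of ``ATOM`` records) — the
  primary format.  Only the subset needed for identical-chain peptide systems
  is handled: no altlocs, no insertion codes, no HETATM chemistry.  Frame
  times are carried in ``REMARK 250 t=<ns>`` records written by this module;
  files without them get times 0, 1, 2, … ns in model order.
* a plain-text dialect (extension ``.xyzt`` by convention) documented in
  ``docs/plain_format.md``: a header line ``natoms nchains nres_per_chain
  box_edge_A`` (box 0 means open boundaries) followed by per-frame blocks of a
  ``t_ns`` line and ``natoms`` lines ``chain res atomname x y z``.  The
  dialect carries no residue identities; residues read from it are typed UNK.
"""

from __future__ import annotations

from pathlib import Path

from .errors import ParseError, StructureError
from .model import Atom, Frame, Peptide, Residue, Trajectory, frame_has_amide_h

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Parse a multi-model PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` block (a file without MODEL records yields a
    single frame).  Chain and residue order are preserved.  Malformed ATOM
    records raise :class:`ParseError` naming the line; models whose chain
    composition differs raise :class:`StructureError`.  Missing amide
    hydrogens are recorded in ``trajectory.metadata["needs_amide_h"]`` rather
    than treated as an error.
    """
    path = Path(path)
    frames: list[Frame] = []
    model_time: float | None = None
    chains: dict[str, list[Residue]] = {}
    chain_order: list[str] = []
    current: tuple[str, int] | None = None  # (chain_id, resseq) being filled
    in_model = False
    saw_model_records = False

    def flush_model(default_time: float) -> None:
        nonlocal chains, chain_order, current, model_time
        if not chain_order:
            return
        peptides = []
        for cid in chain_order:
            residues = chains[cid]
            for idx, res in enumerate(residues):
                res.index_in_chain = idx
            peptides.append(Peptide(cid, residues))
        time = model_time if model_time is not None else default_time
        frames.append(Frame(time, peptides, box_edge=box_edge))
        chains, chain_order, current, model_time = {}, [], None, None

    box_edge: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                except ValueError as exc:
                    raise ParseError(f"{path.name} line {lineno}: bad CRYST1 record") from exc
                if abs(a - b) < 1e-6 and abs(a - c) < 1e-6 and a > 0:
                    box_edge = a
            elif rec.startswith("REMARK") and "t=" in line:
                try:
                    model_time = float(line.split("t=")[1].split()[0])
                except (IndexError, ValueError):
                    pass
            elif rec == "MODEL ":
                saw_model_records = True
                in_model = True
            elif rec == "ENDMDL":
                flush_model(default_time=float(len(frames)))
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if rec == "HETATM":
                    continue  # out of scope: no HETATM chemistry
                if line[16] not in (" ", ""):
                    raise ParseError(
                        f"{path.name} line {lineno}: alternate locations are not supported"
                    )
                if len(line) > 26 and line[26] not in (" ", "\n", ""):
                    raise ParseError(
                        f"{path.name} line {lineno}: insertion codes are not supported"
                    )
                name = line[12:16].strip()
                resname = line[17:20].strip() or "UNK"
                chain_id = line[21].strip() or "A"
                try:
                    resseq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name} line {lineno}: malformed ATOM record"
                    ) from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                if chain_id not in chains:
                    chains[chain_id] = []
                    chain_order.append(chain_id)
                if current != (chain_id, resseq):
                    chains[chain_id].append(Residue(len(chains[chain_id]), resname))
                    current = (chain_id, resseq)
                chains[chain_id][-1].atoms.append(Atom(name, (x, y, z), element=element))
            # TER / END / other records: ignored
    if in_model or (not saw_model_records and chain_order):
        flush_model(default_time=float(len(frames)))

    if not frames:
        raise ParseError(f"{path.name}: no coordinate frames found")

    signature = None
    for i, frame in enumerate(frames):
        sig = [(p.chain_id, p.sequence, [len(r.atoms) for r in p.residues])
               for p in frame.peptides]
        if signature is None:
            signature = sig
        elif sig != signature:
            raise StructureError(
                f"{path.name}: model {i + 1} has a different chain composition "
                "from model 1"
            )

    needs_h = not all(frame_has_amide_h(f) for f in frames)
    return Trajectory(frames, metadata={"source": str(path), "needs_amide_h": needs_h})


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (coordinates to 0.001 Å)."""
    path = Path(path)
    lines: list[str] = []
    box = trajectory.frames[0].box_edge if trajectory.frames else None
    if box is not None:
        lines.append(
            f"CRYST1{box:9.3f}{box:9.3f}{box:9.3f}  90.00  90.00  90.00 P 1           1"
        )
    for imodel, frame in enumerate(trajectory.frames, start=1):
        lines.append(f"MODEL     {imodel:4d}")
        lines.append(f"REMARK 250 t= {frame.time:.6f} ns")
        serial = 1
        for pep in frame.peptides:
            for res in pep.residues:
                for atom in res.atoms:
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    x, y, z = atom.position
                    lines.append(
                        f"ATOM  {serial:5d} {name}{res.name:>4s} {pep.chain_id}"
                        f"{res.index_in_chain + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                        f"          {atom.element:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}      {pep.residues[-1].name:>3s} {pep.chain_id}"
                         f"{len(pep.residues):4d}")
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# plain-text dialect
# ---------------------------------------------------------------------------

def read_plain(path: str | Path) -> Trajectory:
    """Read the plain-text trajectory dialect (see module docstring)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path.name}: empty file")
    header = lines[0].split()
    if len(header) != 4:
        raise ParseError(f"{path.name} line 1: header must be "
                         "'natoms nchains nres_per_chain box_edge_A'")
    try:
        natoms, nchains, nres = int(header[0]), int(header[1]), int(header[2])
        box = float(header[3])
    except ValueError as exc:
        raise ParseError(f"{path.name} line 1: malformed header") from exc
    box_edge = box if box > 0 else None

    frames: list[Frame] = []
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            t_ns = float(lines[i])
        except ValueError as exc:
            raise ParseError(f"{path.name} line {i + 1}: expected a time stamp") from exc
        block = lines[i + 1: i + 1 + natoms]
        if len(block) < natoms:
            raise ParseError(f"{path.name} line {i + 1}: truncated frame block")
        chains: list[list[Residue]] = [
            [Residue(r, "UNK") for r in range(nres)] for _ in range(nchains)
        ]
        for j, record in enumerate(block):
            parts = record.split()
            if len(parts) != 6:
                raise ParseError(f"{path.name} line {i + 2 + j}: expected "
                                 "'chain res atomname x y z'")
            try:
                c, r = int(parts[0]), int(parts[1])
                xyz = (float(parts[3]), float(parts[4]), float(parts[5]))
            except ValueError as exc:
                raise ParseError(f"{path.name} line {i + 2 + j}: malformed record") from exc
            if not (0 <= c < nchains and 0 <= r < nres):
                raise ParseError(f"{path.name} line {i + 2 + j}: chain/residue "
                                 "index out of range")
            chains[c][r].atoms.append(Atom(parts[2], xyz))
        peptides = [Peptide(_CHAIN_IDS[c], residues) for c, residues in enumerate(chains)]
        frames.append(Frame(t_ns, peptides, box_edge=box_edge))
        i += 1 + natoms

    if not frames:
        raise ParseError(f"{path.name}: no frames found")
    needs_h = not all(frame_has_amide_h(f) for f in frames)
    return Trajectory(frames, metadata={"source": str(path), "needs_amide_h": needs_h})


def write_plain(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the plain-text dialect."""
    path = Path(path)
    first = trajectory.frames[0]
    natoms = sum(len(r.atoms) for p in first.peptides for r in p.residues)
    nchains = first.n_peptides
    nres = len(first.peptides[0])
    box = first.box_edge if first.box_edge is not None else 0.0
    out = [f"{natoms} {nchains} {nres} {box:.6f}"]
    for frame in trajectory.frames:
        out.append(f"{frame.time:.6f}")
        for c, pep in enumerate(frame.peptides):
            for res in pep.residues:
                for atom in res.atoms:
                    x, y, z = atom.position
                    out.append(
                        f"{c} {res.index_in_chain} {atom.name} "
                        f"{x:.6f} {y:.6f} {z:.6f}"
                    )
    path.write_text("\n".join(out) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Dispatch on extension: ``.pdb`` -> PDB reader, anything else -> plain."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return read_multimodel_pdb(path)
    return read_plain(path)
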