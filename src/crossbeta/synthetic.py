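"""Synthetic labeled conformations: coils, helices, β-sheets and β-barrels.

The builders produce frames with correct backbone hydrogen-bond geometry and
a :class:`GroundTruth` record of what every detector should find, so the
whole analysis stack can be validated without any simulation output.

Two construction routes are used:

* :func:`build_chain` grows a single chain from ideal bond lengths/angles and
  per-residue (φ, ψ) dihedrals (natural-extension-reference-frame chaining);
  (−120°, 120°) gives an extended strand, (−57°, −47°) an α-helix, and coil
  mode draws dihedrals from a uniform mixture over the allowed Ramachandran
  basins with a 2.5 Å self-clash rejection.
* sheet and barrel assemblies use an idealised periodic strand template
  (3.5 Å rise, 4.85 Å inter-strand spacing, alternating pleat) whose
  donors/acceptors are laid out so that every intended ladder hydrogen bond
  satisfies N–O ≤ 3.3 Å with the amide H aimed straight at its acceptor
  (N–H···O = 180°), a comfortable margin inside the 3.5 Å / 120° detection
  rule.  Barrels place the strands on a cylinder of radius
  r = d / (2·sin(π/n)); closed antiparallel arrangements require an even
  strand count (alternating strand directions cannot close an odd ring).

Side chains are reduced to a single CB pseudo-atom (CA stands in for
glycine).  Gaussian coordinate noise, when requested, is applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .model import Atom, Frame, Peptide, Residue, Trajectory, place_amide_h, AA_1TO3
from .io import _CHAIN_IDS

# --- template geometry (Å / degrees) ---------------------------------------
TEMPLATE_RISE = 3.5          # axial rise per residue of a template strand
STRAND_SPACING = 4.85        # inter-strand spacing d
PLEAT = 0.6                  # CA pleat amplitude normal to the H-bond plane
FLAT_ZIGZAG = 0.35           # lateral N/C offset toward the H-bond partner
CA_AXIAL = 1.15              # axial offset of CA from N within a residue
C_AXIAL = 2.3                # axial offset of C (and O) from N
O_LATERAL = 1.23             # C=O bond projected toward the partner strand
CB_LENGTH = 1.5              # CA–CB pseudo side chain
LAYER_SPACING = 8.0          # sheet–sheet stacking distance in double layers
BARREL_TARGET_NO = 2.9       # target N–O chord length inside barrels
AXIAL_TOLERANCE = 1.25       # max axial donor/acceptor mismatch for a bond

# --- ideal covalent geometry for dihedral-built chains ----------------------
BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O = 1.458, 1.525, 1.329, 1.229
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA, ANG_CA_C_O = 111.2, 116.2, 121.7, 120.5

#: measured end-to-end rise per residue of a (−120°, 120°) dihedral-built strand
EXTENDED_RISE = 3.32

DEFAULT_SEQUENCE = "SSNNFGAILSS"  # islet-amyloid 19–29 fragment

MOTIFS = ("coil", "helix", "parallel_sheet", "antiparallel_sheet", "barrel",
          "double_layer")

# Ramachandran basins for coil sampling: (phi range, psi range, weight)
COIL_BASINS = (
    ((-150.0, -90.0), (90.0, 170.0), 0.45),   # β / extended
    ((-80.0, -60.0), (120.0, 160.0), 0.25),   # polyproline II
    ((-70.0, -50.0), (-50.0, -25.0), 0.25),   # right-handed helical
    ((50.0, 70.0), (25.0, 55.0), 0.05),       # left-handed helical
)
CLASH_DISTANCE = 2.5


@dataclass
class BuildSpec:
    """Recipe for one synthetic assembly."""

    motif: str
    n_strands: int = 6
    sequence: str = DEFAULT_SEQUENCE
    registry: int = 0          # inter-strand residue offset (open sheets only)
    noise_sigma: float = 0.0   # Å, i.i.d. Gaussian per coordinate
    seed: int = 0
    box_edge_nm: float | None = None

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise GenerationError(f"unknown motif {self.motif!r}; choose from {MOTIFS}")
        if self.motif == "barrel" and not 4 <= self.n_strands <= 12:
            raise GenerationError("barrels support 4..12 strands")
        if self.n_strands < 1:
            raise GenerationError("n_strands must be positive")
        if len(self.sequence) < 4:
            raise GenerationError("sequence must have at least 4 residues")
        bad = set(self.sequence.upper()) - set(AA_1TO3)
        if bad:
            raise GenerationError(f"unknown residue codes: {sorted(bad)}")


@dataclass
class GroundTruth:
    """What the detectors are expected to report for a built frame."""

    labels: list[str]                             # per-peptide motif label
    pairing_edges: list[tuple[int, int, str]]     # (u, v, orientation)
    sheets: list[list[int]]                       # member lists per sheet
    barrels: list[list[int]]                      # member lists per barrel
    e_interior: tuple[int, int] | None = None     # residues expected E (lo..hi)
    traces: dict = field(default_factory=dict)    # expected per-frame traces

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "pairing_edges": [[u, v, o] for u, v, o in self.pairing_edges],
            "sheets": self.sheets,
            "barrels": self.barrels,
            "e_interior": list(self.e_interior) if self.e_interior else None,
            "traces": self.traces,
        }


# ---------------------------------------------------------------------------
# dihedral-built single chains
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position atom D from internal coordinates relative to the path a-b-c."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone_from_dihedrals(phi: np.ndarray, psi: np.ndarray):
    """N/CA/C/O arrays for a chain with the given per-residue dihedrals."""
    n_res = len(phi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    CA[0] = N[0] + np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANG_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res):
        if i < n_res - 1:
            N_next = _place_atom(N[i], CA[i], C[i], BOND_C_N, ANG_CA_C_N, psi[i])
            CA[i + 1] = _place_atom(CA[i], C[i], N_next, BOND_N_CA, ANG_C_N_CA, 180.0)
            C[i + 1] = _place_atom(C[i], N_next, CA[i + 1], BOND_CA_C, ANG_N_CA_C,
                                   phi[i + 1])
            O[i] = _place_atom(N_next, CA[i], C[i], BOND_C_O, ANG_CA_C_O, 180.0)
            N[i + 1] = N_next
        else:
            O[i] = _place_atom(N[i], CA[i], C[i], BOND_C_O, ANG_CA_C_O, psi[i] + 180.0)
    return N, CA, C, O


def _chain_from_backbone(sequence: str, N, CA, C, O, chain_id: str = "A") -> Peptide:
    residues = []
    for i, letter in enumerate(sequence.upper()):
        name = AA_1TO3[letter]
        atoms = [Atom("N", N[i])]
        if i > 0 and name != "PRO":
            atoms.append(Atom("H", place_amide_h(C[i - 1], N[i], CA[i]), element="H"))
        atoms.append(Atom("CA", CA[i]))
        atoms.append(Atom("C", C[i]))
        atoms.append(Atom("O", O[i]))
        if name != "GLY":
            cb = _place_atom(C[i], N[i], CA[i], 1.53, 110.5, -120.0)
            atoms.append(Atom("CB", cb))
        residues.append(Residue(i, name, atoms))
    return Peptide(chain_id, residues)


def build_chain(
    sequence: str,
    phi: float | np.ndarray = -120.0,
    psi: float | np.ndarray = 120.0,
    chain_id: str = "A",
) -> Peptide:
    """A single chain from ideal geometry and per-residue (φ, ψ) dihedrals."""
    n_res = len(sequence)
    phi = np.full(n_res, phi, dtype=float) if np.isscalar(phi) else np.asarray(phi)
    psi = np.full(n_res, psi, dtype=float) if np.isscalar(psi) else np.asarray(psi)
    if len(phi) != n_res or len(psi) != n_res:
        raise GenerationError("phi/psi arrays must match the sequence length")
    N, CA, C, O = _backbone_from_dihedrals(phi, psi)
    return _chain_from_backbone(sequence, N, CA, C, O, chain_id)


def _has_self_clash(peptide: Peptide) -> bool:
    coords, res_idx = [], []
    for r, res in enumerate(peptide.residues):
        for a in res.atoms:
            if a.is_heavy:
                coords.append(a.position)
                res_idx.append(r)
    coords = np.array(coords)
    res_idx = np.array(res_idx)
    delta = coords[None, :, :] - coords[:, None, :]
    dist2 = np.einsum("ijk,ijk->ij", delta, delta)
    sep = np.abs(res_idx[None, :] - res_idx[:, None])
    mask = sep >= 2
    return bool(np.any(dist2[mask] < CLASH_DISTANCE**2))


def build_coil_chain(
    sequence: str, rng: np.random.Generator, chain_id: str = "A", max_tries: int = 200
) -> Peptide:
    """A random-coil chain: basin-sampled dihedrals with self-clash rejection."""
    weights = np.array([w for _p, _s, w in COIL_BASINS])
    weights = weights / weights.sum()
    for _ in range(max_tries):
        idx = rng.choice(len(COIL_BASINS), size=len(sequence), p=weights)
        phi = np.array([rng.uniform(*COIL_BASINS[i][0]) for i in idx])
        psi = np.array([rng.uniform(*COIL_BASINS[i][1]) for i in idx])
        peptide = build_chain(sequence, phi, psi, chain_id)
        if not _has_self_clash(peptide):
            return peptide
    raise GenerationError("could not build a clash-free coil chain")


# ---------------------------------------------------------------------------
# template sheets and barrels
# ---------------------------------------------------------------------------

@dataclass
class _ChainPlan:
    direction: int   # +1 or -1 along the strand axis
    phase: int       # parity of the residues facing the *next* strand
    z0: float        # axial offset


def _sheet_layout(
    n_strands: int,
    n_res: int,
    orientation: str,
    registry: int,
    closed: bool,
    sequence: str = "",
) -> tuple[list[_ChainPlan], list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Chain placements and intended (donor, acceptor) ladder bonds."""
    if closed and registry != 0:
        raise GenerationError("barrels do not support a registry shift")
    if abs(registry) > n_res - 3:
        raise GenerationError("registry shift larger than the strand allows")
    antiparallel = orientation == "antiparallel"
    if closed and antiparallel and n_strands % 2:
        raise GenerationError(
            "closed antiparallel barrels require an even strand count"
        )
    r, reg = TEMPLATE_RISE, registry
    plans = [_ChainPlan(direction=1, phase=0, z0=0.0)]
    for c in range(1, n_strands):
        prev = plans[-1]
        if antiparallel:
            plans.append(
                _ChainPlan(
                    direction=-prev.direction,
                    phase=(prev.phase + n_res + reg) % 2,
                    z0=prev.z0 + prev.direction * ((n_res - 1 - reg) * r + C_AXIAL),
                )
            )
        else:
            plans.append(
                _ChainPlan(
                    direction=prev.direction,
                    phase=(prev.phase + reg) % 2,
                    z0=prev.z0 + prev.direction * reg * r,
                )
            )

    def axial_n(c: int, k: int) -> float:
        return plans[c].z0 + plans[c].direction * k * r

    def axial_o(c: int, k: int) -> float:
        return plans[c].z0 + plans[c].direction * (k * r + C_AXIAL)

    def faces_next(c: int, k: int) -> bool:
        return (k + plans[c].phase) % 2 == 0

    def can_donate(k: int) -> bool:
        return k >= 1 and (not sequence or sequence[k].upper() != "P")

    bonds: list[tuple[tuple[int, int], tuple[int, int]]] = []
    n_pairs = n_strands if closed else n_strands - 1
    for c in range(n_pairs):
        nxt = (c + 1) % n_strands
        pair_bonds = []
        anti_pair = plans[c].direction != plans[nxt].direction
        for k in range(n_res):
            if not faces_next(c, k):
                continue
            m = (n_res - 1 - k - reg) if anti_pair else (k - 1 - reg)
            if not 0 <= m < n_res or faces_next(nxt, m):
                continue
            if can_donate(k) and abs(axial_n(c, k) - axial_o(nxt, m)) <= AXIAL_TOLERANCE:
                pair_bonds.append(((c, k), (nxt, m)))
            # antiparallel pairs are mutual: the partner donates straight back
            if anti_pair and can_donate(m) and (
                abs(axial_n(nxt, m) - axial_o(c, k)) <= AXIAL_TOLERANCE
            ):
                pair_bonds.append(((nxt, m), (c, k)))
        if not anti_pair:
            # second H-bond direction of a parallel pair: donors on the next chain
            for m in range(n_res):
                if faces_next(nxt, m) or not can_donate(m):
                    continue
                k2 = m + reg - 1
                if not 0 <= k2 < n_res or not faces_next(c, k2):
                    continue
                if abs(axial_n(nxt, m) - axial_o(c, k2)) <= AXIAL_TOLERANCE:
                    pair_bonds.append(((nxt, m), (c, k2)))
        if len(pair_bonds) < 2:
            raise GenerationError(
                f"strand pair {c}-{nxt} would carry fewer than two ladder bonds"
            )
        bonds.extend(pair_bonds)
    return plans, bonds


def _template_positions(
    plans: list[_ChainPlan],
    n_res: int,
    sequence: str,
    geometry: str,
    zigzag: float,
    radius: float | None = None,
    layer_z: float = 0.0,
    flip_normal: bool = False,
    x_shift: float = 0.0,
) -> list[dict[tuple[int, str], np.ndarray]]:
    """Cartesian atom positions (all but H) for template strands.

    ``geometry`` is "flat" (strands stacked along y, sheet normal z) or
    "cylinder" (strands on a cylinder about the global z axis).
    """
    out: list[dict[tuple[int, str], np.ndarray]] = []
    n_strands = len(plans)
    for c, plan in enumerate(plans):
        atoms: dict[tuple[int, str], np.ndarray] = {}

        def put(k: int, name: str, axial: float, lateral: float, normal: float):
            if flip_normal:
                normal = -normal
            if geometry == "flat":
                pos = np.array(
                    [axial + x_shift, c * STRAND_SPACING + lateral, layer_z + normal]
                )
            else:
                theta = 2.0 * math.pi * c / n_strands + lateral / radius
                rho = radius + normal
                pos = np.array(
                    [rho * math.cos(theta), rho * math.sin(theta), axial]
                )
            atoms[(k, name)] = pos

        for k in range(n_res):
            sigma = 1 if (k + plan.phase) % 2 == 0 else -1
            pleat = PLEAT * (1 if k % 2 == 0 else -1)
            a_n = plan.z0 + plan.direction * k * TEMPLATE_RISE
            a_ca = plan.z0 + plan.direction * (k * TEMPLATE_RISE + CA_AXIAL)
            a_c = plan.z0 + plan.direction * (k * TEMPLATE_RISE + C_AXIAL)
            put(k, "N", a_n, sigma * zigzag, 0.0)
            put(k, "CA", a_ca, 0.0, pleat)
            put(k, "C", a_c, sigma * zigzag, 0.0)
            put(k, "O", a_c, sigma * (zigzag + O_LATERAL), 0.0)
            if sequence[k].upper() != "G":
                sign = 1 if k % 2 == 0 else -1
                put(k, "CB", a_ca, 0.0, sign * (PLEAT + CB_LENGTH))
        out.append(atoms)
    return out


def _assemble_peptides(
    sequence: str,
    positions: list[dict[tuple[int, str], np.ndarray]],
    bonds: list[tuple[tuple[int, int], tuple[int, int]]],
    chain_offset: int = 0,
) -> list[Peptide]:
    """Turn template positions into peptides, aiming each donor H at its acceptor."""
    n_res = len(sequence)
    acceptor_of: dict[tuple[int, int], tuple[int, int]] = {
        donor: acceptor for donor, acceptor in bonds
    }
    peptides = []
    for c, atom_map in enumerate(positions):
        residues = []
        for k, letter in enumerate(sequence.upper()):
            name = AA_1TO3[letter]
            atoms = [Atom("N", atom_map[(k, "N")])]
            if k > 0 and name != "PRO":
                n_pos = atom_map[(k, "N")]
                target = acceptor_of.get((c, k))
                if target is not None:
                    o_pos = positions[target[0]][(target[1], "O")]
                    direction = o_pos - n_pos
                    h = n_pos + direction / np.linalg.norm(direction)
                else:
                    h = place_amide_h(
                        atom_map[(k - 1, "C")], n_pos, atom_map[(k, "CA")]
                    )
                atoms.append(Atom("H", h, element="H"))
            atoms.append(Atom("CA", atom_map[(k, "CA")]))
            atoms.append(Atom("C", atom_map[(k, "C")]))
            atoms.append(Atom("O", atom_map[(k, "O")]))
            if (k, "CB") in atom_map:
                atoms.append(Atom("CB", atom_map[(k, "CB")]))
            residues.append(Residue(k, name, atoms))
        peptides.append(Peptide(_CHAIN_IDS[chain_offset + c], residues))
    return peptides


def _barrel_zigzag(n_strands: int) -> tuple[float, float]:
    """(radius, lateral zigzag) giving the target N–O chord on the cylinder."""
    radius = STRAND_SPACING / (2.0 * math.sin(math.pi / n_strands))
    half_chord = BARREL_TARGET_NO / 2.0
    delta_phi = 2.0 * math.asin(half_chord / radius)
    zigzag = (radius * (2.0 * math.pi / n_strands - delta_phi) - O_LATERAL) / 2.0
    if zigzag <= 0.05:
        raise GenerationError(
            f"no feasible donor/acceptor layout for a {n_strands}-strand barrel"
        )
    return radius, zigzag


def _apply_noise(peptides: list[Peptide], sigma: float, rng: np.random.Generator):
    if sigma <= 0:
        return
    for pep in peptides:
        for res in pep.residues:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, sigma, 3)


def _pair_orientations(plans: list[_ChainPlan], closed: bool) -> list[tuple[int, int, str]]:
    edges = []
    n = len(plans)
    n_pairs = n if closed else n - 1
    for c in range(n_pairs):
        nxt = (c + 1) % n
        kind = "antiparallel" if plans[c].direction != plans[nxt].direction else "parallel"
        edges.append((min(c, nxt), max(c, nxt), kind))
    return edges


def build_sheet(spec: BuildSpec) -> tuple[Frame, GroundTruth]:
    """An open single- or double-layer β-sheet with ground truth."""
    if spec.motif not in ("parallel_sheet", "antiparallel_sheet", "double_layer"):
        raise GenerationError(f"build_sheet cannot build motif {spec.motif!r}")
    rng = np.random.default_rng(spec.seed)
    sequence = spec.sequence.upper()
    n_res = len(sequence)
    orientation = "antiparallel" if spec.motif == "antiparallel_sheet" else "parallel"
    plans, bonds = _sheet_layout(spec.n_strands, n_res, orientation, spec.registry,
                                 closed=False, sequence=sequence)
    positions = _template_positions(plans, n_res, sequence, "flat", FLAT_ZIGZAG)
    if spec.motif == "double_layer":
        pos2 = _template_positions(
            plans, n_res, sequence, "flat", FLAT_ZIGZAG,
            layer_z=LAYER_SPACING, flip_normal=True, x_shift=1.75,
        )
        bonds2 = [
            ((d[0] + spec.n_strands, d[1]), (a[0] + spec.n_strands, a[1]))
            for d, a in bonds
        ]
        peptides = _assemble_peptides(sequence, positions, bonds)
        peptides += _assemble_peptides(sequence, pos2, bonds2,
                                       chain_offset=spec.n_strands)
        all_edges = _pair_orientations(plans, closed=False)
        edges = all_edges + [(u + spec.n_strands, v + spec.n_strands, o)
                             for u, v, o in all_edges]
        sheets = [list(range(spec.n_strands)),
                  list(range(spec.n_strands, 2 * spec.n_strands))]
        labels = ["double_layer"] * (2 * spec.n_strands)
    else:
        peptides = _assemble_peptides(sequence, positions, bonds)
        edges = _pair_orientations(plans, closed=False)
        sheets = [list(range(spec.n_strands))]
        labels = [spec.motif] * spec.n_strands
    _apply_noise(peptides, spec.noise_sigma, rng)
    frame = Frame(0.0, peptides,
                  box_edge=spec.box_edge_nm * 10.0 if spec.box_edge_nm else None)
    n_peptides = len(peptides)
    sheet_sizes = [len(s) for s in sheets]
    truth = GroundTruth(
        labels=labels,
        pairing_edges=edges,
        sheets=sheets,
        barrels=[],
        e_interior=(1, n_res - 2),
        traces={
            "largest_oligomer": n_peptides if spec.motif == "double_layer"
            else spec.n_strands,
            "largest_beta_sheet_oligomer": n_peptides
            if spec.motif == "double_layer" else spec.n_strands,
            "mass_weighted_mean_sheet_size": float(
                sum(s * s for s in sheet_sizes) / sum(sheet_sizes)
            ),
            "total_barrel_size": 0,
        },
    )
    return frame, truth


def build_barrel(spec: BuildSpec) -> tuple[Frame, GroundTruth]:
    """A closed β-barrel of 4–12 strands with ground truth."""
    if spec.motif != "barrel":
        raise GenerationError(f"build_barrel cannot build motif {spec.motif!r}")
    rng = np.random.default_rng(spec.seed)
    sequence = spec.sequence.upper()
    n_res = len(sequence)
    orientation = "antiparallel" if spec.n_strands % 2 == 0 else "parallel"
    if spec.registry != 0:
        raise GenerationError("barrels do not support a registry shift")
    # allow explicit orientation through metadata-free convention: even counts
    # default to antiparallel (the common motif); parallel is available via
    # build_barrel_oriented.
    return build_barrel_oriented(spec, orientation, rng)


def build_barrel_oriented(
    spec: BuildSpec, orientation: str, rng: np.random.Generator | None = None
) -> tuple[Frame, GroundTruth]:
    """Barrel with an explicit strand orientation pattern."""
    rng = rng or np.random.default_rng(spec.seed)
    sequence = spec.sequence.upper()
    n_res = len(sequence)
    plans, bonds = _sheet_layout(spec.n_strands, n_res, orientation, 0, closed=True,
                                 sequence=sequence)
    radius, zigzag = _barrel_zigzag(spec.n_strands)
    positions = _template_positions(plans, n_res, sequence, "cylinder", zigzag,
                                    radius=radius)
    peptides = _assemble_peptides(sequence, positions, bonds)
    _apply_noise(peptides, spec.noise_sigma, rng)
    frame = Frame(0.0, peptides,
                  box_edge=spec.box_edge_nm * 10.0 if spec.box_edge_nm else None)
    truth = GroundTruth(
        labels=["barrel"] * spec.n_strands,
        pairing_edges=_pair_orientations(plans, closed=True),
        sheets=[list(range(spec.n_strands))],
        barrels=[list(range(spec.n_strands))],
        e_interior=(1, n_res - 2),
        traces={
            "largest_oligomer": spec.n_strands,
            "largest_beta_sheet_oligomer": spec.n_strands,
            "mass_weighted_mean_sheet_size": float(spec.n_strands),
            "total_barrel_size": spec.n_strands,
        },
    )
    return frame, truth


def _bounding_radius(peptides: list[Peptide]) -> float:
    coords = np.concatenate([
        np.array([a.position for r in p.residues for a in r.atoms])
        for p in peptides
    ])
    center = coords.mean(axis=0)
    return float(np.max(np.linalg.norm(coords - center, axis=1)))


def _center(peptides: list[Peptide]) -> np.ndarray:
    coords = np.concatenate([
        np.array([a.position for r in p.residues for a in r.atoms])
        for p in peptides
    ])
    return coords.mean(axis=0)


def _translate(peptides: list[Peptide], shift: np.ndarray) -> None:
    for pep in peptides:
        for res in pep.residues:
            for atom in res.atoms:
                atom.position = atom.position + shift


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    w, x, y, z = quat
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _rotate(peptides: list[Peptide], rotation: np.ndarray) -> None:
    center = _center(peptides)
    for pep in peptides:
        for res in pep.residues:
            for atom in res.atoms:
                atom.position = rotation @ (atom.position - center) + center


def build_dispersed(spec: BuildSpec) -> tuple[Frame, GroundTruth]:
    """n separated monomers, coil or helical, with no inter-chain contacts."""
    if spec.motif not in ("coil", "helix"):
        raise GenerationError(f"build_dispersed cannot build motif {spec.motif!r}")
    rng = np.random.default_rng(spec.seed)
    chains: list[Peptide] = []
    for c in range(spec.n_strands):
        if spec.motif == "coil":
            pep = build_coil_chain(spec.sequence, rng, _CHAIN_IDS[c])
            _rotate([pep], _random_rotation(rng))
        else:
            pep = build_chain(spec.sequence, -57.0, -47.0, _CHAIN_IDS[c])
        chains.append(pep)
    pitch = 2.0 * max(_bounding_radius([p]) for p in chains) + 8.0
    side = max(1, math.ceil(spec.n_strands ** (1.0 / 3.0)))
    for idx, pep in enumerate(chains):
        cell = np.array([idx % side, (idx // side) % side, idx // (side * side)])
        _translate([pep], cell * pitch - _center([pep]))
    _apply_noise(chains, spec.noise_sigma, rng)
    frame = Frame(0.0, chains,
                  box_edge=spec.box_edge_nm * 10.0 if spec.box_edge_nm else None)
    truth = GroundTruth(
        labels=[spec.motif] * spec.n_strands,
        pairing_edges=[],
        sheets=[],
        barrels=[],
        e_interior=None,
        traces={
            "largest_oligomer": 1,
            "largest_beta_sheet_oligomer": 0,
            "mass_weighted_mean_sheet_size": 0.0,
            "total_barrel_size": 0,
        },
    )
    return frame, truth


def build_frame(spec: BuildSpec) -> tuple[Frame, GroundTruth]:
    """Dispatch a single BuildSpec to the right builder."""
    if spec.motif in ("coil", "helix"):
        return build_dispersed(spec)
    if spec.motif == "barrel":
        return build_barrel(spec)
    return build_sheet(spec)


# ---------------------------------------------------------------------------
# composite scenes and scripted trajectories
# ---------------------------------------------------------------------------

def compose_scene(
    specs: list[BuildSpec], seed: int = 0, time: float = 0.0
) -> tuple[Frame, GroundTruth]:
    """Several assemblies in one frame, spatially separated (no cross contacts)."""
    units = []
    for i, spec in enumerate(specs):
        sub_spec = BuildSpec(
            motif=spec.motif, n_strands=spec.n_strands, sequence=spec.sequence,
            registry=spec.registry, noise_sigma=spec.noise_sigma,
            seed=spec.seed + 7919 * i + seed, box_edge_nm=None,
        )
        units.append(build_frame(sub_spec))
    pitch = 2.0 * max(_bounding_radius(f.peptides) for f, _t in units) + 12.0
    side = max(1, math.ceil(len(units) ** (1.0 / 3.0)))

    peptides: list[Peptide] = []
    labels: list[str] = []
    edges: list[tuple[int, int, str]] = []
    sheets: list[list[int]] = []
    barrels: list[list[int]] = []
    offset = 0
    traces_parts = []
    for idx, (unit_frame, unit_truth) in enumerate(units):
        cell = np.array([idx % side, (idx // side) % side, idx // (side * side)],
                        dtype=float)
        shift = cell * pitch - _center(unit_frame.peptides)
        _translate(unit_frame.peptides, shift)
        for c, pep in enumerate(unit_frame.peptides):
            peptides.append(Peptide(_CHAIN_IDS[offset + c], pep.residues))
        labels.extend(unit_truth.labels)
        edges.extend((u + offset, v + offset, o) for u, v, o in unit_truth.pairing_edges)
        sheets.extend([m + offset for m in s] for s in unit_truth.sheets)
        barrels.extend([m + offset for m in b] for b in unit_truth.barrels)
        traces_parts.append(unit_truth.traces)
        offset += unit_frame.n_peptides

    sheet_sizes = [len(s) for s in sheets]
    traces = {
        "largest_oligomer": max(t["largest_oligomer"] for t in traces_parts),
        "largest_beta_sheet_oligomer": max(
            t["largest_beta_sheet_oligomer"] for t in traces_parts
        ),
        "mass_weighted_mean_sheet_size": (
            float(sum(s * s for s in sheet_sizes) / sum(sheet_sizes))
            if sheet_sizes else 0.0
        ),
        "total_barrel_size": sum(t["total_barrel_size"] for t in traces_parts),
    }
    frame = Frame(time, peptides)
    truth = GroundTruth(labels, edges, sheets, barrels, None, traces)
    return frame, truth


def build_trajectory(
    script: list[tuple[float, list[BuildSpec]]],
    frames_per_ns: float = 1.0,
    seed: int = 0,
) -> tuple[Trajectory, list[GroundTruth]]:
    """A scripted trajectory: scenes held for their durations, emitted at a stride.

    Scene transitions are instantaneous; the per-frame ground truth carries
    the expected time-series traces, making the script itself the oracle for
    end-to-end tests.
    """
    if not script:
        raise GenerationError("the script needs at least one scene")
    frames = []
    truths = []
    t = 0.0
    dt = 1.0 / frames_per_ns
    for i, (duration, specs) in enumerate(script):
        scene_frame, scene_truth = compose_scene(specs, seed=seed + 104729 * i)
        n_frames = max(1, int(round(duration * frames_per_ns)))
        for _ in range(n_frames):
            frames.append(Frame(t, scene_frame.peptides, scene_frame.box_edge))
            truths.append(scene_truth)
            t += dt
    return Trajectory(frames, metadata={"seed": seed, "scripted": True}), truths


def sweep_frames(
    seed: int = 0,
    sequence: str = DEFAULT_SEQUENCE,
    n_range: range = range(4, 13),
    n_coil_frames: int = 50,
    coil_chains: int = 6,
    noise_sigma: float = 0.0,
) -> list[tuple[str, Frame, GroundTruth]]:
    """The standard detector-validation sweep.

    Open parallel and antiparallel sheets and closed barrels over the strand
    counts in ``n_range`` (antiparallel barrels on even counts only — odd
    alternating rings cannot close), plus coil-only frames that must yield no
    sheet or barrel detections.
    """
    cases: list[tuple[str, Frame, GroundTruth]] = []
    for n in n_range:
        for motif in ("parallel_sheet", "antiparallel_sheet"):
            spec = BuildSpec(motif, n, sequence, noise_sigma=noise_sigma, seed=seed)
            cases.append((f"{motif}_{n}", *build_sheet(spec)))
        spec = BuildSpec("barrel", n, sequence, noise_sigma=noise_sigma, seed=seed)
        cases.append((
            f"parallel_barrel_{n}",
            *build_barrel_oriented(spec, "parallel", np.random.default_rng(seed)),
        ))
        if n % 2 == 0:
            cases.append((
                f"antiparallel_barrel_{n}",
                *build_barrel_oriented(spec, "antiparallel",
                                       np.random.default_rng(seed)),
            ))
    for i in range(n_coil_frames):
        spec = BuildSpec("coil", coil_chains, sequence,
                         noise_sigma=noise_sigma, seed=seed + 31 * i + 1)
        cases.append((f"coil_{i}", *build_dispersed(spec)))
    return cases
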