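"""Per-frame aggregate topology: oligomers, β-sheets and β-barrels.

Two graphs are built per frame.  The *contact graph* has one node per peptide
and an edge wherever any inter-peptide heavy-atom pair is within the contact
cutoff (0.55 nm); its connected components are the oligomers.  The *pairing
graph* has an edge between two chains that each contribute at least two
consecutive strand (E) residues linked by at least two backbone hydrogen
bonds; its connected components of two or more strands are the β-sheets.
A sheet is a β-barrel when it is closed: every strand has at least two
hydrogen-bonded neighbours and the pairing subgraph is 2-edge-connected
(every strand lies on a cycle), with a minimum of four strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import AnalysisConfig
from .hbond import HBond, SSAssignment, detect_hbonds, assign_secondary_structure, strand_segments
from .model import Frame, frame_has_amide_h, minimum_image, reconstruct_amide_h


@dataclass
class SheetRecord:
    """A single β-sheet: its strands, pairing edges, and barrel flag."""

    member_peptides: frozenset[int]
    strand_adjacency: list[tuple[int, int, str, int]]  # (u, v, orientation, n_hbonds)
    is_barrel: bool = False

    @property
    def size(self) -> int:
        return len(self.member_peptides)


def build_contact_graph(frame: Frame, config: AnalysisConfig | None = None) -> nx.Graph:
    """Peptide contact graph: edge iff some heavy-atom pair is ≤ the cutoff."""
    config = config or AnalysisConfig()
    graph = nx.Graph()
    graph.add_nodes_from(range(frame.n_peptides))
    coords = [p.heavy_coords() for p in frame.peptides]
    cutoff = config.contact_cutoff_A
    for p in range(frame.n_peptides):
        for q in range(p + 1, frame.n_peptides):
            delta = minimum_image(
                coords[q][None, :, :] - coords[p][:, None, :], frame.box_edge
            )
            if np.any(np.einsum("ijk,ijk->ij", delta, delta) <= cutoff * cutoff):
                graph.add_edge(p, q)
    return graph


def oligomers(contact_graph: nx.Graph) -> list[list[int]]:
    """Connected components of the contact graph, largest first.

    An isolated peptide is an oligomer of size 1 (a monomer).
    """
    comps = [sorted(c) for c in nx.connected_components(contact_graph)]
    comps.sort(key=lambda c: (-len(c), c))
    return comps


def pair_strands(
    frame: Frame,
    ss: SSAssignment,
    hbonds: list[HBond],
    config: AnalysisConfig | None = None,
) -> nx.Graph:
    """β-sheet pairing graph.

    Edge (p, q) iff each chain contributes ≥ ``min_consecutive_E`` consecutive
    strand residues and those residues are linked by ≥ ``min_ladder_hbonds``
    backbone hydrogen bonds.  Each edge carries the total H-bond count and an
    orientation label: parallel if the dot product of the two paired strand
    segment directions (first CA → last CA) is positive, else antiparallel.
    """
    config = config or AnalysisConfig()
    segments = strand_segments(ss)

    # map residue -> id of its qualifying strand segment, per chain
    seg_of: dict[tuple[int, int], tuple[int, int]] = {}
    seg_span: dict[tuple[int, int], tuple[int, int]] = {}
    for c, runs in enumerate(segments):
        for s, (start, length) in enumerate(runs):
            if length >= config.min_consecutive_E:
                seg_span[(c, s)] = (start, length)
                for r in range(start, start + length):
                    seg_of[(c, r)] = (c, s)

    pairwise: dict[tuple[int, int], dict[tuple, int]] = {}
    for bond in hbonds:
        if bond.donor[0] == bond.acceptor[0]:
            continue
        sd = seg_of.get(bond.donor)
        sa = seg_of.get(bond.acceptor)
        if sd is None or sa is None:
            continue
        p, q = sorted((sd[0], sa[0]))
        key = (sd, sa) if sd[0] < sa[0] else (sa, sd)
        pairwise.setdefault((p, q), {})
        pairwise[(p, q)][key] = pairwise[(p, q)].get(key, 0) + 1

    def _direction(chain: int, seg: tuple[int, int]) -> np.ndarray:
        start, length = seg_span[seg]
        pep = frame.peptides[chain]
        first = pep.residues[start].position("CA")
        last = pep.residues[start + length - 1].position("CA")
        return last - first

    graph = nx.Graph()
    graph.add_nodes_from(sorted({c for (c, _s) in seg_span}))
    for (p, q), by_segpair in pairwise.items():
        total = sum(by_segpair.values())
        if total < config.min_ladder_hbonds:
            continue
        (seg_p, seg_q), _ = max(by_segpair.items(), key=lambda kv: (kv[1], kv[0]))
        dot = float(np.dot(_direction(p, seg_p), _direction(q, seg_q)))
        orientation = "parallel" if dot > 0 else "antiparallel"
        graph.add_edge(p, q, hbonds=total, orientation=orientation)
    return graph


def sheets_and_layers(pairing_graph: nx.Graph) -> list[SheetRecord]:
    """Connected components of the pairing graph with ≥ 2 strands, as sheets."""
    records = []
    for comp in nx.connected_components(pairing_graph):
        if len(comp) < 2:
            continue
        sub = pairing_graph.subgraph(comp)
        adjacency = [
            (min(u, v), max(u, v), d["orientation"], d["hbonds"])
            for u, v, d in sub.edges(data=True)
        ]
        adjacency.sort()
        records.append(SheetRecord(frozenset(comp), adjacency))
    records.sort(key=lambda s: (-s.size, sorted(s.member_peptides)))
    return records


def detect_barrels(
    sheets: list[SheetRecord], config: AnalysisConfig | None = None
) -> tuple[list[SheetRecord], int]:
    """Flag closed sheets as β-barrels; return (sheets, total barrel size).

    Closure requires every strand to have degree ≥ 2 in the pairing subgraph
    *and* the subgraph to be 2-edge-connected, with at least
    ``barrel_min_size`` strands.  The total barrel size is the number of
    peptides inside barrels in the frame.
    """
    config = config or AnalysisConfig()
    flagged = []
    total = 0
    for sheet in sheets:
        graph = nx.Graph()
        graph.add_nodes_from(sheet.member_peptides)
        graph.add_edges_from((u, v) for u, v, _o, _h in sheet.strand_adjacency)
        closed = (
            sheet.size >= config.barrel_min_size
            and min(dict(graph.degree).values()) >= 2
            and not next(nx.bridges(graph), None)
        )
        flagged.append(SheetRecord(sheet.member_peptides, sheet.strand_adjacency, closed))
        if closed:
            total += sheet.size
    return flagged, total


def beta_sheet_oligomers(
    contact_graph: nx.Graph, sheets: list[SheetRecord]
) -> list[frozenset[int]]:
    """Groups of sheets inter-connected by heavy-atom contacts.

    Each group is the union of the member peptides of its sheets; the group
    size counts the peptides in β-sheet conformation within the complex
    (peptides outside any sheet — e.g. coil chains merely in contact — are
    excluded).
    """
    group_graph = nx.Graph()
    group_graph.add_nodes_from(range(len(sheets)))
    for i in range(len(sheets)):
        for j in range(i + 1, len(sheets)):
            if any(
                contact_graph.has_edge(p, q)
                for p in sheets[i].member_peptides
                for q in sheets[j].member_peptides
            ):
                group_graph.add_edge(i, j)
    groups = []
    for comp in nx.connected_components(group_graph):
        members: set[int] = set()
        for i in comp:
            members |= sheets[i].member_peptides
        groups.append(frozenset(members))
    groups.sort(key=lambda g: (-len(g), sorted(g)))
    return groups


@dataclass
class FrameAnalysis:
    """Everything the ensemble statistics need from one frame."""

    time: float
    n_peptides: int
    hbonds: list[HBond]
    ss: SSAssignment
    contact_graph: nx.Graph
    pairing_graph: nx.Graph
    oligomers: list[list[int]] = field(default_factory=list)
    sheets: list[SheetRecord] = field(default_factory=list)
    beta_sheet_oligomers: list[frozenset[int]] = field(default_factory=list)
    total_barrel_size: int = 0

    @property
    def barrels(self) -> list[SheetRecord]:
        return [s for s in self.sheets if s.is_barrel]


def analyze_frame(frame: Frame, config: AnalysisConfig | None = None) -> FrameAnalysis:
    """Run the full per-frame analysis chain on one snapshot."""
    config = config or AnalysisConfig()
    if not frame_has_amide_h(frame):
        frame = reconstruct_amide_h(frame)
    hbonds = detect_hbonds(frame, config)
    ss = assign_secondary_structure(frame, hbonds, config)
    contact = build_contact_graph(frame, config)
    pairing = pair_strands(frame, ss, hbonds, config)
    sheets = sheets_and_layers(pairing)
    sheets, total_barrel = detect_barrels(sheets, config)
    return FrameAnalysis(
        time=frame.time,
        n_peptides=frame.n_peptides,
        hbonds=hbonds,
        ss=ss,
        contact_graph=contact,
        pairing_graph=pairing,
        oligomers=oligomers(contact),
        sheets=sheets,
        beta_sheet_oligomers=beta_sheet_oligomers(contact, sheets),
        total_barrel_size=total_barrel,
    )


def topology_dict(analysis: FrameAnalysis) -> dict:
    """JSON-serialisable per-frame topology dump."""
    return {
        "time_ns": analysis.time,
        "oligomers": [list(map(int, o)) for o in analysis.oligomers],
        "sheets": [
            {
                "members": sorted(map(int, s.member_peptides)),
                "edges": [
                    {"u": int(u), "v": int(v), "orientation": o, "hbonds": int(h)}
                    for u, v, o, h in s.strand_adjacency
                ],
                "is_barrel": bool(s.is_barrel),
            }
            for s in analysis.sheets
        ],
        "beta_sheet_oligomers": [sorted(map(int, g)) for g in analysis.beta_sheet_oligomers],
        "total_barrel_size": int(analysis.total_barrel_size),
    }
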