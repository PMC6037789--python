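"""Backbone hydrogen bonds and per-residue secondary structure.

Hydrogen bonds use a single geometric rule: backbone N–O distance ≤ 3.5 Å
and N–H···O angle (measured at H) ≥ 120°.  Secondary structure is assigned
from that bond set with the Kabsch–Sander ladder/turn patterns ("DSSP-lite"),
collapsed to the four states strand (E), helix (H), turn (T) and coil (C)
with conflict priority E > H > T > C.  Using the geometric rule as the one
bond definition keeps the strand assignment and the β-sheet pairing criterion
mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import StructureError
from .model import Frame, minimum_image

ResidueId = tuple[int, int]  # (chain index, residue index), both 0-based


@dataclass(frozen=True)
class HBond:
    """One backbone N–H···O=C hydrogen bond."""

    donor: ResidueId      # residue providing N–H
    acceptor: ResidueId   # residue providing C=O
    distance_NO: float    # Å
    angle_NHO: float      # degrees, at H


@dataclass
class SSAssignment:
    """Per-residue secondary-structure states, one of E/H/T/C."""

    states: np.ndarray  # (n_chains, n_res) array of single characters

    def label(self, chain: int, residue: int) -> str:
        return str(self.states[chain, residue])

    @property
    def n_chains(self) -> int:
        return self.states.shape[0]

    @property
    def n_residues(self) -> int:
        return self.states.shape[1]

    def fraction(self, state: str) -> float:
        return float(np.mean(self.states == state))

    def chain_string(self, chain: int) -> str:
        return "".join(self.states[chain])

    def to_dataframe(self, time: float | None = None) -> pd.DataFrame:
        rows = [
            {"chain": c, "residue": r, "state": self.states[c, r]}
            for c in range(self.n_chains)
            for r in range(self.n_residues)
        ]
        df = pd.DataFrame(rows)
        if time is not None:
            df.insert(0, "time_ns", time)
        return df


def _uniform_length(frame: Frame) -> int:
    lengths = {len(p) for p in frame.peptides}
    if len(lengths) != 1:
        raise StructureError("all chains in a frame must share one sequence length")
    return lengths.pop()


def detect_hbonds(frame: Frame, config: AnalysisConfig | None = None) -> list[HBond]:
    """All backbone N–H···O=C bonds satisfying the distance and angle rule.

    Intra- and inter-chain bonds are both returned; pairs within one residue
    or between adjacent residues of the same chain (|Δindex| < 2) are
    excluded.  Amide hydrogens must be present (see
    :func:`crossbeta.model.reconstruct_amide_h`); prolines never donate.
    """
    config = config or AnalysisConfig()
    donors: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    acceptors: list[tuple[int, int, np.ndarray]] = []
    for c, pep in enumerate(frame.peptides):
        for r, res in enumerate(pep.residues):
            n, h = res.atom("N"), res.atom("H")
            if n is not None and h is not None and not res.is_proline:
                donors.append((c, r, n.position, h.position))
            o = res.atom("O")
            if o is not None and res.atom("C") is not None:
                acceptors.append((c, r, o.position))
    if not donors or not acceptors:
        return []

    n_pos = np.array([d[2] for d in donors])
    h_pos = np.array([d[3] for d in donors])
    o_pos = np.array([a[2] for a in acceptors])

    # minimum-image O positions relative to each donor N
    delta = minimum_image(o_pos[None, :, :] - n_pos[:, None, :], frame.box_edge)
    dist = np.linalg.norm(delta, axis=2)
    o_eff = n_pos[:, None, :] + delta
    u_hn = n_pos[:, None, :] - h_pos[:, None, :]
    u_ho = o_eff - h_pos[:, None, :]
    cosang = np.sum(u_hn * u_ho, axis=2) / (
        np.linalg.norm(u_hn, axis=2) * np.linalg.norm(u_ho, axis=2)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    ok = (dist <= config.hbond_dist_A) & (angle >= config.hbond_angle_deg)
    bonds: list[HBond] = []
    for i, j in zip(*np.nonzero(ok)):
        dc, dr = donors[i][0], donors[i][1]
        ac, ar = acceptors[j][0], acceptors[j][1]
        if (dc, dr) == (ac, ar):
            continue
        if dc == ac and abs(dr - ar) < 2:
            continue
        bonds.append(HBond((dc, dr), (ac, ar), float(dist[i, j]), float(angle[i, j])))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def assign_secondary_structure(
    frame: Frame, hbonds: list[HBond], config: AnalysisConfig | None = None
) -> SSAssignment:
    """Four-state secondary structure from the geometric H-bond set.

    E: residues in β-ladders (two or more consecutive Kabsch–Sander bridges,
    parallel or antiparallel).  H: runs of two or more consecutive i→i+4
    turn bonds (residues i+1..i+4).  T: residues spanned by isolated
    i→i+3/i+4/i+5 turn bonds.  C otherwise.  Priority on conflict:
    E > H > T > C.
    """
    del config  # thresholds enter through the bond set itself
    n_chains = frame.n_peptides
    n_res = _uniform_length(frame)
    # hb holds (acceptor, donor) pairs: "CO of x bonds NH of y"
    hb = {(b.acceptor, b.donor) for b in hbonds}

    def has(acc: ResidueId, don: ResidueId) -> bool:
        if not (0 <= acc[1] < n_res and 0 <= don[1] < n_res):
            return False
        return (acc, don) in hb

    states = np.full((n_chains, n_res), "C", dtype="<U1")

    # --- turns -------------------------------------------------------------
    turn4 = np.zeros((n_chains, n_res), dtype=bool)
    turn_spans: list[tuple[int, int, int]] = []  # (chain, start, k)
    for c in range(n_chains):
        for i in range(n_res):
            for k in (3, 4, 5):
                if has((c, i), (c, i + k)):
                    turn_spans.append((c, i, k))
                    if k == 4:
                        turn4[c, i] = True
    for c, i, k in turn_spans:
        states[c, i + 1: i + k] = np.where(
            states[c, i + 1: i + k] == "C", "T", states[c, i + 1: i + k]
        )

    # --- helices -----------------------------------------------------------
    for c in range(n_chains):
        for i in range(n_res - 1):
            if turn4[c, i] and turn4[c, i + 1]:
                states[c, i + 1: i + 5] = "H"

    # --- bridges and ladders ----------------------------------------------
    bridges: dict[tuple[ResidueId, ResidueId], str] = {}
    residues_near_bonds = sorted(
        {rid for b in hbonds for rid in (b.donor, b.acceptor)}
    )
    candidates = set()
    for c, r in residues_near_bonds:
        for dr in (-1, 0, 1):
            if 0 <= r + dr < n_res:
                candidates.add((c, r + dr))
    cand = sorted(candidates)
    for x in cand:
        for y in cand:
            c1, i = x
            c2, j = y
            if (c1, i) >= (c2, j):
                continue
            if c1 == c2 and j - i < 3:
                continue
            parallel = (
                (has((c1, i - 1), (c2, j)) and has((c2, j), (c1, i + 1)))
                or (has((c2, j - 1), (c1, i)) and has((c1, i), (c2, j + 1)))
            )
            antiparallel = (
                (has((c1, i), (c2, j)) and has((c2, j), (c1, i)))
                or (has((c1, i - 1), (c2, j + 1)) and has((c2, j - 1), (c1, i + 1)))
            )
            if parallel:
                bridges[(x, y)] = "P"
            elif antiparallel:
                bridges[(x, y)] = "A"

    def _neighbor(pair, step):
        (c1, i), (c2, j) = pair
        kind = bridges[pair]
        dj = step if kind == "P" else -step
        nb = ((c1, i + step), (c2, j + dj))
        return nb if nb in bridges and bridges[nb] == kind else None

    for pair in bridges:
        if _neighbor(pair, +1) or _neighbor(pair, -1):
            (c1, i), (c2, j) = pair
            states[c1, i] = "E"
            states[c2, j] = "E"

    return SSAssignment(states)


def strand_segments(ss: SSAssignment) -> list[list[tuple[int, int]]]:
    """Maximal runs of E per chain as ``(start, length)`` tuples.

    The run length is the β-strand length (number of consecutive residues of
    a chain in strand conformation).
    """
    result: list[list[tuple[int, int]]] = []
    for c in range(ss.n_chains):
        runs: list[tuple[int, int]] = []
        start = None
        for r in range(ss.n_residues):
            if ss.states[c, r] == "E":
                if start is None:
                    start = r
            elif start is not None:
                runs.append((start, r - start))
                start = None
        if start is not None:
            runs.append((start, ss.n_residues - start))
        result.append(runs)
    return result
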