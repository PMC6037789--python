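"""Ensemble-averaged and time-resolved aggregation statistics.

The central statistic is the mass-weighted mean object size

    n̄ = (Σᵢ nᵢ²) / (Σᵢ nᵢ)

over the sizes nᵢ of the objects (oligomers, β-sheets or β-barrels) in an
analysis window; the matching mass-weighted distribution P(s) ∝ s·c(s) is the
probability that a randomly chosen peptide sits in an object of size s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .hbond import SSAssignment, strand_segments
from .model import Frame, minimum_image, Trajectory
from .topology import FrameAnalysis, analyze_frame


def analyze_trajectory(
    trajectory: Trajectory, config: AnalysisConfig | None = None
) -> list[FrameAnalysis]:
    """Per-frame analyses for a whole trajectory (the input to everything below)."""
    config = config or AnalysisConfig()
    return [analyze_frame(frame, config) for frame in trajectory.frames]


def equilibrium_window(items: list, fraction: float = 0.5) -> list:
    """The final ``fraction`` of a frame sequence (the equilibrated part)."""
    if not items:
        return []
    start = int(np.ceil(len(items) * (1.0 - fraction)))
    start = min(start, len(items) - 1)
    return items[start:]


def mass_weighted_mean(object_sizes: list[int]) -> float:
    """Eq.-style mass-weighted mean size (Σ nᵢ²)/(Σ nᵢ)."""
    if len(object_sizes) == 0:
        raise ValueError("mass_weighted_mean requires at least one object")
    sizes = np.asarray(object_sizes, dtype=float)
    return float(np.sum(sizes**2) / np.sum(sizes))


@dataclass
class SizeDistribution:
    """Mass-weighted probability over integer object sizes."""

    sizes: np.ndarray        # integer support, ascending
    probability: np.ndarray  # mass-weighted probability per size
    object_sizes: list[int]  # the pooled nᵢ
    n_objects: int

    @property
    def mean(self) -> float:
        """Mass-weighted mean; equals Σ s·P(s) by construction."""
        return mass_weighted_mean(self.object_sizes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "probability": self.probability})


def mass_weighted_distribution(object_sizes: list[int]) -> SizeDistribution:
    """P(s) = s·c(s) / Σ s'·c(s') over pooled object sizes."""
    if len(object_sizes) == 0:
        return SizeDistribution(np.array([], dtype=int), np.array([]), [], 0)
    sizes = np.asarray(object_sizes, dtype=int)
    support, counts = np.unique(sizes, return_counts=True)
    weights = support * counts
    prob = weights / weights.sum()
    return SizeDistribution(support, prob, list(map(int, sizes)), len(sizes))


def oligomer_size_distribution(analyses: list[FrameAnalysis]) -> SizeDistribution:
    return mass_weighted_distribution(
        [len(o) for a in analyses for o in a.oligomers]
    )


def sheet_size_distribution(analyses: list[FrameAnalysis]) -> SizeDistribution:
    return mass_weighted_distribution(
        [s.size for a in analyses for s in a.sheets]
    )


def residue_beta_propensity(ss_per_frame: list[SSAssignment]) -> pd.DataFrame:
    """Per-sequence-position fraction of (frame × chain) observations in E.

    Also reports the coil fraction per position; window selection is the
    caller's job (use :func:`equilibrium_window`).
    """
    if not ss_per_frame:
        raise ValueError("no frames in window")
    stacked = np.concatenate([ss.states for ss in ss_per_frame], axis=0)
    return pd.DataFrame(
        {
            "residue": np.arange(stacked.shape[1]),
            "beta_propensity": np.mean(stacked == "E", axis=0),
            "coil_propensity": np.mean(stacked == "C", axis=0),
        }
    )


def secondary_structure_content(ss_per_frame: list[SSAssignment]) -> dict[str, float]:
    """Overall mean fraction of residues per state across the window."""
    stacked = np.concatenate([ss.states for ss in ss_per_frame], axis=0)
    return {state: float(np.mean(stacked == state)) for state in "EHTC"}


def alignment_ratio(analyses: list[FrameAnalysis]) -> tuple[float, float] | None:
    """(antiparallel, parallel) fractions, weighted by per-edge H-bond counts.

    Returns None when the window holds no pairing edges (undefined, not zero).
    """
    anti = para = 0
    for a in analyses:
        for _u, _v, data in a.pairing_graph.edges(data=True):
            if data["orientation"] == "antiparallel":
                anti += data["hbonds"]
            else:
                para += data["hbonds"]
    total = anti + para
    if total == 0:
        return None
    return anti / total, para / total


def strand_length_distribution(ss_per_frame: list[SSAssignment]) -> pd.DataFrame:
    """Normalised histogram of maximal E-run lengths over chains and frames."""
    lengths = [
        length
        for ss in ss_per_frame
        for runs in strand_segments(ss)
        for _start, length in runs
    ]
    if not lengths:
        return pd.DataFrame({"length": [], "probability": []})
    support, counts = np.unique(lengths, return_counts=True)
    return pd.DataFrame({"length": support, "probability": counts / counts.sum()})


def barrel_statistics(
    analyses: list[FrameAnalysis],
) -> tuple[float, SizeDistribution]:
    """Per-peptide barrel probability and mass-weighted barrel-size distribution.

    probability = (Σ over frames of peptides inside barrels) / (N × frames).
    """
    if not analyses:
        raise ValueError("no frames in window")
    n_peptides = analyses[0].n_peptides
    in_barrel = sum(a.total_barrel_size for a in analyses)
    probability = in_barrel / (n_peptides * len(analyses))
    sizes = [s.size for a in analyses for s in a.barrels]
    return probability, mass_weighted_distribution(sizes)


def timeseries(analyses: list[FrameAnalysis]) -> pd.DataFrame:
    """The four per-frame aggregation traces.

    Columns: largest oligomer size, largest β-sheet oligomer size,
    mass-weighted mean β-sheet size (0 when the frame holds no sheet) and
    total β-barrel size.
    """
    rows = []
    for a in analyses:
        sheet_sizes = [s.size for s in a.sheets]
        rows.append(
            {
                "time_ns": a.time,
                "largest_oligomer": max((len(o) for o in a.oligomers), default=0),
                "largest_beta_sheet_oligomer": max(
                    (len(g) for g in a.beta_sheet_oligomers), default=0
                ),
                "mass_weighted_mean_sheet_size": (
                    mass_weighted_mean(sheet_sizes) if sheet_sizes else 0.0
                ),
                "total_barrel_size": a.total_barrel_size,
            }
        )
    return pd.DataFrame(rows)


def contact_frequency_maps(
    frames: list[Frame], config: AnalysisConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-peptide residue–residue contact frequency maps.

    Entry (i, j) is the fraction of (frame × ordered chain pair) observations
    in which residues i and j on *different* chains share a heavy-atom pair
    within the contact cutoff; returned as (backbone–backbone map,
    side-chain–side-chain map), both symmetric.  Glycine contributes its CA
    as the side-chain proxy.
    """
    config = config or AnalysisConfig()
    if not frames:
        raise ValueError("no frames in window")
    n_res = len(frames[0].peptides[0])
    cutoff2 = config.contact_cutoff_A**2
    bb_hits = np.zeros((n_res, n_res))
    sc_hits = np.zeros((n_res, n_res))
    observations = 0

    def _coords(res, backbone: bool) -> np.ndarray:
        if backbone:
            pts = [a.position for a in res.atoms if a.is_heavy and a.is_backbone]
        else:
            pts = [a.position for a in res.atoms if a.is_heavy and not a.is_backbone]
            if not pts:  # glycine: CA stands in for the side chain
                ca = res.atom("CA")
                pts = [ca.position] if ca is not None else []
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    for frame in frames:
        box = frame.box_edge
        per_chain_bb = [[_coords(r, True) for r in p.residues] for p in frame.peptides]
        per_chain_sc = [[_coords(r, False) for r in p.residues] for p in frame.peptides]
        n_pep = frame.n_peptides
        for p in range(n_pep):
            for q in range(n_pep):
                if p == q:
                    continue
                observations += 1
                for i in range(n_res):
                    for j in range(n_res):
                        for hits, per_chain in ((bb_hits, per_chain_bb), (sc_hits, per_chain_sc)):
                            a, b = per_chain[p][i], per_chain[q][j]
                            if a.size == 0 or b.size == 0:
                                continue
                            delta = minimum_image(b[None, :, :] - a[:, None, :], box)
                            if np.any(np.einsum("ijk,ijk->ij", delta, delta) <= cutoff2):
                                hits[i, j] += 1
    if observations == 0:
        return bb_hits, sc_hits
    # both ordered pairs (p,q) and (q,p) are counted, so the maps are symmetric
    return bb_hits / observations, sc_hits / observations
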