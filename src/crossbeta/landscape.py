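"""2D free-energy landscape over oligomer size and per-chain β-content.

Each oligomer in each frame contributes one observation
(n_oligomer, n_β-sheet), where n_β-sheet is the average number of strand (E)
residues per chain inside that oligomer.  The potential of mean force is

    PMF(n_oligomer, n_β-sheet) = −k_B·T · ln P(n_oligomer, n_β-sheet)

shifted so the global minimum is 0 kcal/mol; unsampled bins are reported as
missing (NaN / absent rows), never as infinities.  The full trajectory is
used, not just the equilibrated window — the landscape is meant to cover the
assembly pathway, transition states included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import FrameAnalysis

#: Boltzmann constant in kcal/(mol·K) (CODATA, via R = 1.987204e-3 kcal/mol/K)
KB_KCAL_MOL_K = 0.0019872


def oligomer_observations(
    analyses: list[FrameAnalysis], per_peptide: bool = False
) -> np.ndarray:
    """(n_obs, 2) array of (oligomer size, mean E residues per chain).

    With ``per_peptide=True`` each oligomer is counted once per member
    peptide instead of once per occurrence.
    """
    obs: list[tuple[float, float]] = []
    for a in analyses:
        e_per_chain = np.sum(a.ss.states == "E", axis=1)
        for olig in a.oligomers:
            size = len(olig)
            n_beta = float(np.sum(e_per_chain[list(olig)])) / size
            repeat = size if per_peptide else 1
            obs.extend([(float(size), n_beta)] * repeat)
    return np.asarray(obs, dtype=float).reshape(-1, 2)


@dataclass
class LandscapeGrid:
    """Histogram, probabilities and PMF over the 2D order-parameter grid."""

    oligomer_sizes: np.ndarray  # integer axis values, ascending
    beta_bin_edges: np.ndarray  # left-closed bin edges for n_β-sheet
    counts: np.ndarray          # (n_sizes, n_beta_bins) observation counts
    probability: np.ndarray
    pmf: np.ndarray             # kcal/mol, NaN where unsampled, min 0
    temperature: float          # K

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table of the sampled bins only."""
        rows = []
        for i, s in enumerate(self.oligomer_sizes):
            for j in range(len(self.beta_bin_edges) - 1):
                if self.counts[i, j] == 0:
                    continue
                rows.append(
                    {
                        "n_oligomer": int(s),
                        "n_beta_bin_left": float(self.beta_bin_edges[j]),
                        "count": int(self.counts[i, j]),
                        "probability": float(self.probability[i, j]),
                        "pmf_kcal_mol": float(self.pmf[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def pmf(
    observations: np.ndarray,
    temperature: float = 300.0,
    bin_width: float = 1.0,
) -> LandscapeGrid:
    """Bin observations, normalise, and apply the −k_B·T·ln P transform."""
    observations = np.asarray(observations, dtype=float).reshape(-1, 2)
    if observations.shape[0] == 0:
        raise ValueError("the PMF requires at least one observation")
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    sizes = observations[:, 0].astype(int)
    beta = observations[:, 1]
    size_axis = np.arange(1, sizes.max() + 1)
    n_beta_bins = int(np.floor(beta.max() / bin_width)) + 1
    edges = np.arange(n_beta_bins + 1) * bin_width

    counts = np.zeros((len(size_axis), n_beta_bins))
    beta_idx = np.minimum((beta / bin_width).astype(int), n_beta_bins - 1)
    for s, b in zip(sizes, beta_idx):
        counts[s - 1, b] += 1

    probability = counts / counts.sum()
    with np.errstate(divide="ignore"):
        raw = -KB_KCAL_MOL_K * temperature * np.log(
            np.where(probability > 0, probability, np.nan)
        )
    pmf_grid = raw - np.nanmin(raw)
    return LandscapeGrid(size_axis, edges, counts, probability, pmf_grid, temperature)
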