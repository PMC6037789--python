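"""End-to-end orchestration: read a trajectory, run every analysis, write results.

Outputs are plain TSV/JSON files plus a run manifest (configuration echo,
package version, input checksum) so that any result bundle can be traced back
to its inputs.  Given the same configuration and inputs the bundle is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .errors import CrossBetaError
from .io import read_trajectory, write_multimodel_pdb
from .landscape import oligomer_observations, pmf
from .metrics import (
    alignment_ratio,
    analyze_trajectory,
    barrel_statistics,
    contact_frequency_maps,
    equilibrium_window,
    oligomer_size_distribution,
    residue_beta_propensity,
    secondary_structure_content,
    sheet_size_distribution,
    strand_length_distribution,
    timeseries,
)
from .synthetic import BuildSpec, build_frame
from .topology import topology_dict
from .model import Trajectory


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(
    config: AnalysisConfig,
    input_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """Analyse one trajectory file and write the full result bundle.

    Returns the manifest dictionary.  Raises :class:`CrossBetaError` on
    unreadable input or invalid configuration before any computation.
    """
    config.validate()
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    if not input_path.exists():
        raise CrossBetaError(f"input file not found: {input_path}")
    out_dir.mkdir(parents=True, exist_ok=True)

    trajectory = read_trajectory(input_path)
    if not trajectory.frames:
        raise CrossBetaError("empty trajectory")

    analyses = analyze_trajectory(trajectory, config)
    window = equilibrium_window(analyses, config.equilibrium_fraction)
    window_frames = equilibrium_window(trajectory.frames, config.equilibrium_fraction)
    ss_window = [a.ss for a in window]

    _write_tsv(timeseries(analyses), out_dir / "timeseries.tsv")
    _write_tsv(
        oligomer_size_distribution(window).to_dataframe(),
        out_dir / "oligomer_size_distribution.tsv",
    )
    _write_tsv(
        sheet_size_distribution(window).to_dataframe(),
        out_dir / "sheet_size_distribution.tsv",
    )
    barrel_prob, barrel_dist = barrel_statistics(window)
    _write_tsv(barrel_dist.to_dataframe(), out_dir / "barrel_size_distribution.tsv")
    _write_tsv(residue_beta_propensity(ss_window), out_dir / "beta_propensity.tsv")
    _write_tsv(strand_length_distribution(ss_window), out_dir / "strand_lengths.tsv")

    ratio = alignment_ratio(window)
    align_df = pd.DataFrame(
        [
            {
                "antiparallel_fraction": ratio[0] if ratio else np.nan,
                "parallel_fraction": ratio[1] if ratio else np.nan,
            }
        ]
    )
    _write_tsv(align_df, out_dir / "alignment.tsv")

    bb_map, sc_map = contact_frequency_maps(window_frames, config)
    _write_tsv(pd.DataFrame(bb_map), out_dir / "contact_map_backbone.tsv")
    _write_tsv(pd.DataFrame(sc_map), out_dir / "contact_map_sidechain.tsv")

    grid = pmf(
        oligomer_observations(analyses),
        temperature=config.pmf_temperature_K,
        bin_width=config.pmf_beta_bin,
    )
    _write_tsv(grid.to_dataframe(), out_dir / "landscape.tsv")

    topo = [topology_dict(a) for a in analyses]
    (out_dir / "topology.json").write_text(json.dumps(topo, indent=1, sort_keys=True))

    manifest = {
        "package": "crossbeta",
        "version": __version__,
        "config": config.to_dict(),
        "input": str(input_path),
        "input_sha256": _checksum(input_path),
        "n_frames": len(trajectory.frames),
        "n_peptides": trajectory.frames[0].n_peptides,
        "window_frames": len(window),
        "secondary_structure_content": secondary_structure_content(ss_window),
        "barrel_probability": barrel_prob,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_generate(spec: BuildSpec, out_dir: str | Path, name: str | None = None) -> Path:
    """Build one synthetic frame, write PDB plus ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame, truth = build_frame(spec)
    stem = name or f"{spec.motif}_{spec.n_strands}"
    pdb_path = out_dir / f"{stem}.pdb"
    write_multimodel_pdb(Trajectory([frame]), pdb_path)
    sidecar = {
        "spec": {
            "motif": spec.motif,
            "n_strands": spec.n_strands,
            "sequence": spec.sequence,
            "registry": spec.registry,
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
            "box_edge_nm": spec.box_edge_nm,
        },
        "ground_truth": truth.to_dict(),
    }
    (out_dir / f"{stem}.truth.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )
    return pdb_path
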