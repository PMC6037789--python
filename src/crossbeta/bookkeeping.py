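"""Simulation-campaign bookkeeping: concentrations, unit conversions, Debye screening.

Closed-form arithmetic for setting up and summarising discrete-molecular-
dynamics (DMD) aggregation campaigns: peptide concentration in a cubic box,
the box edge needed for a target concentration, DMD time-unit conversion
(1 unit ≈ 50 fs), the 1:1-salt ionic strength implied by a Debye screening
length, and accumulated sampling time.  Physical constants are pinned to
CODATA-2018 values.
"""

from __future__ import annotations

from dataclasses import dataclass


import pandas as pd

# CODATA-2018 constants
AVOGADRO = 6.02214076e23          # 1/mol
BOLTZMANN_J_K = 1.380649e-23      # J/K
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

DMD_TIME_UNIT_FS = 50.0  # nominal DMD time unit


def concentration_mM(n_peptides: int, box_edge_nm: float) -> float:
    """Peptide concentration (mM) of n identical chains in a cubic box."""
    if n_peptides <= 0 or box_edge_nm <= 0:
        raise ValueError("peptide count and box edge must be positive")
    volume_L = (box_edge_nm * 1e-8) ** 3  # nm -> dm, cubed -> litres
    return n_peptides / (AVOGADRO * volume_L) * 1e3


def box_edge_for_concentration(n_peptides: int, target_mM: float) -> float:
    """Cubic box edge (nm) giving the target concentration; inverse of above."""
    if n_peptides <= 0 or target_mM <= 0:
        raise ValueError("peptide count and target concentration must be positive")
    volume_L = n_peptides / (AVOGADRO * target_mM * 1e-3)
    return volume_L ** (1.0 / 3.0) * 1e8


def dmd_units_to_ns(n_units: float, time_unit_fs: float = DMD_TIME_UNIT_FS) -> float:
    """Convert DMD time units to nanoseconds (1 unit ≈ 50 fs by default)."""
    if n_units < 0:
        raise ValueError("the number of time units cannot be negative")
    return n_units * time_unit_fs * 1e-6


def debye_ionic_strength_mM(
    screening_length_A: float,
    temperature_K: float = 300.0,
    rel_permittivity: float = 78.5,
) -> float:
    """Ionic strength (mM, 1:1 salt) implied by a Debye screening length.

    I = ε_r ε₀ k_B T / (2 N_A e² λ_D²), converted from mol/m³ (≡ mM).
    """
    if screening_length_A <= 0 or temperature_K <= 0 or rel_permittivity <= 0:
        raise ValueError("all inputs must be positive")
    lam = screening_length_A * 1e-10  # m
    ionic = (
        rel_permittivity
        * VACUUM_PERMITTIVITY
        * BOLTZMANN_J_K
        * temperature_K
        / (2.0 * AVOGADRO * ELEMENTARY_CHARGE**2 * lam**2)
    )
    return ionic  # mol/m^3 == mmol/L


def campaign_total_us(n_runs: int, run_length_ns: float) -> float:
    """Accumulated simulation time (µs) of a campaign of independent runs."""
    if n_runs <= 0 or run_length_ns < 0:
        raise ValueError("run count must be positive and run length non-negative")
    return n_runs * run_length_ns / 1000.0


@dataclass
class SystemSpec:
    """One row of a simulation campaign plan."""

    n_peptides: int
    box_edge_nm: float
    n_runs: int
    run_length_ns: float
    dmd_time_unit_fs: float = DMD_TIME_UNIT_FS

    def __post_init__(self) -> None:
        if min(self.n_peptides, self.box_edge_nm, self.n_runs,
               self.run_length_ns, self.dmd_time_unit_fs) <= 0:
            raise ValueError("all SystemSpec fields must be positive")

    @property
    def concentration_mM(self) -> float:
        return concentration_mM(self.n_peptides, self.box_edge_nm)

    @property
    def total_us(self) -> float:
        return campaign_total_us(self.n_runs, self.run_length_ns)

    @property
    def dmd_units_per_run(self) -> float:
        return self.run_length_ns * 1e6 / self.dmd_time_unit_fs


def campaign_table(systems: list[SystemSpec]) -> pd.DataFrame:
    """Campaign summary table (one row per molecular system)."""
    return pd.DataFrame(
        {
            "n_peptides": [s.n_peptides for s in systems],
            "box_edge_nm": [s.box_edge_nm for s in systems],
            "concentration_mM": [round(s.concentration_mM, 1) for s in systems],
            "n_runs": [s.n_runs for s in systems],
            "run_length_ns": [s.run_length_ns for s in systems],
            "total_us": [s.total_us for s in systems],
            "dmd_units_per_run": [s.dmd_units_per_run for s in systems],
        }
    )
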