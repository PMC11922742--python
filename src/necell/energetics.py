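"""Pump-leak flux-balance model of the resting ATP cost of excitable cells.

The model assumes the resting membrane conductance is composed solely of a
sodium-selective and a potassium-selective fraction, ``g_in = g_Na + g_K``,
and that at steady state the electrogenic Na+/K+-ATPase current balances the
passive leak fluxes with the canonical 3 Na+ out : 2 K+ in stoichiometry per
ATP hydrolysed.  Solving the two ion balances

    Na influx:  g_Na * (E_Na - V) = 3 * F * a      (a = pump cycles, mol/s)
    K  efflux:  g_K  * (V - E_K)  = 2 * F * a

under the conductance-sum constraint gives the closed forms implemented here:

    g_Na     = 3 * g_in * (V - E_K) / (V + 2*E_Na - 3*E_K)
    ATP rate = g_in * (E_Na - V) * (V - E_K) / (F * (V + 2*E_Na - 3*E_K))

The module also carries the discrete cost arithmetic used alongside the
resting budget: charge cost per action potential, vesicle counts from
capacitance steps, vesicle packaging cost, and the bulk ATP-production
ceiling converted to a per-cell rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (
    AVOGADRO,
    E_CHARGE,
    FARADAY,
    FF_TO_F,
    MV_TO_V,
    NM_TO_CM,
    PA_TO_A,
    PF_TO_F,
    PL_TO_ML,
    PMOL_TO_MOL,
    R_GAS,
    UF_PER_CM2_TO_F_PER_CM2,
    UG_TO_G,
)

__all__ = [
    "IonEnvironment",
    "RestingMeasurement",
    "PumpSolution",
    "DiscreteCostAssumptions",
    "ProductionAssumptions",
    "InvalidRegimeError",
    "nernst",
    "partition_conductance",
    "resting_atp_rate",
    "ap_charge_cost",
    "vesicle_count_from_capacitance",
    "vesicle_release_cost",
    "cells_per_ug_protein",
    "production_rate_per_cell",
    "energy_budget_cohort",
    "round_to_sig_figs",
]


class InvalidRegimeError(ValueError):
    """Resting potential outside (E_K, E_Na): the pump-leak model has no
    physical solution (one conductance fraction would be negative)."""


@dataclass(frozen=True)
class IonEnvironment:
    """Reversal potentials and physical constants shared by every formula.

    The default reversal potentials are the values used for the
    gluconate-pipette / Ringer-bath recording configuration: E_Na = +53.8 mV
    and E_K = -108.4 mV, taken as given rather than recomputed from the
    solution compositions.
    """

    E_Na: float = 53.8     # mV
    E_K: float = -108.4    # mV
    T: float = 296.15      # K (room temperature, 23 C)
    F: float = FARADAY     # C/mol
    R_gas: float = R_GAS   # J/(mol K)
    e_charge: float = E_CHARGE
    N_A: float = AVOGADRO

    def __post_init__(self) -> None:
        if not self.E_Na > self.E_K:
            raise ValueError(f"E_Na ({self.E_Na}) must exceed E_K ({self.E_K})")
        for name in ("T", "F", "R_gas", "e_charge", "N_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RestingMeasurement:
    """One cell's junction-corrected resting potential and input conductance."""

    V: float               # mV
    g_in: float            # nS
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.g_in > 0:
            raise ValueError(f"g_in must be positive, got {self.g_in}")

    @property
    def R_in(self) -> float:
        """Input resistance in MOhm (1/g_in with g_in in nS gives GOhm;
        scaled to the conventional MOhm)."""
        return 1e3 / self.g_in


@dataclass(frozen=True)
class PumpSolution:
    """Solved conductance partition, pump current and ATP consumption."""

    g_Na: float                 # nS
    g_K: float                  # nS
    I_Na: float                 # pA, inward sodium leak at rest
    I_pump: float               # pA, electrogenic pump current = I_Na / 3
    atp_rate_mol: float         # mol ATP s^-1 cell^-1
    atp_rate_molecules: float   # molecules s^-1 cell^-1


@dataclass(frozen=True)
class DiscreteCostAssumptions:
    """Typical-cell assumptions for the per-event cost estimates."""

    C_m: float = 20.0             # pF membrane capacitance
    dV_ap: float = 60.0           # mV depolarization amplitude per AP
    dC_vesicles: float = 20.0     # fF capacitance increase per AP
    d_vesicle: float = 40.0       # nm vesicle diameter
    c_spec: float = 1.0           # uF/cm^2 specific membrane capacitance
    atp_per_vesicle: float = 23_400.0

    def __post_init__(self) -> None:
        for name in ("C_m", "dV_ap", "d_vesicle", "c_spec", "atp_per_vesicle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dC_vesicles < 0:
            raise ValueError("dC_vesicles must be non-negative")


@dataclass(frozen=True)
class ProductionAssumptions:
    """Bulk ATP-production ceiling and the cell-geometry constants used to
    convert it to a per-cell rate."""

    bulk_rate: float = 20.0     # pmol ATP / ug protein / min
    cell_volume: float = 1.0    # pl
    dry_fraction: float = 0.25  # dimensionless, protein == dry mass
    density: float = 1.0        # g/ml

    def __post_init__(self) -> None:
        if not (0 < self.dry_fraction <= 1):
            raise ValueError("dry_fraction must be in (0, 1]")
        for name in ("cell_volume", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bulk_rate < 0:
            raise ValueError("bulk_rate must be non-negative")


def nernst(z: int, c_out: float, c_in: float,
           env: IonEnvironment | None = None) -> float:
    """Nernst equilibrium potential in mV.

    Parameters
    ----------
    z : ion valence (non-zero integer)
    c_out, c_in : extracellular / intracellular concentration (mM, same units)
    env : constants and temperature; defaults to :class:`IonEnvironment`.
    """
    env = env or IonEnvironment()
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be strictly positive")
    if z == 0:
        raise ValueError("valence must be non-zero")
    volts = (env.R_gas * env.T) / (z * env.F) * math.log(c_out / c_in)
    return volts / MV_TO_V


def _check_regime(m: RestingMeasurement, env: IonEnvironment) -> None:
    if m.V <= env.E_K:
        raise InvalidRegimeError(
            f"V = {m.V} mV <= E_K = {env.E_K} mV: no valid partition "
            "(potassium bound violated)")
    if m.V >= env.E_Na:
        raise InvalidRegimeError(
            f"V = {m.V} mV >= E_Na = {env.E_Na} mV: no valid partition "
            "(sodium bound violated)")


def partition_conductance(m: RestingMeasurement,
                          env: IonEnvironment | None = None) -> PumpSolution:
    """Partition the input conductance into Na- and K-selective fractions.

    Requires E_K < V < E_Na; outside that interval the flux balance has no
    non-negative solution and :class:`InvalidRegimeError` is raised.
    """
    env = env or IonEnvironment()
    _check_regime(m, env)
    denom = m.V + 2 * env.E_Na - 3 * env.E_K
    g_Na = 3 * m.g_in * (m.V - env.E_K) / denom
    g_K = m.g_in - g_Na
    I_Na = g_Na * (env.E_Na - m.V)  # nS * mV = pA
    return PumpSolution(
        g_Na=g_Na, g_K=g_K, I_Na=I_Na, I_pump=I_Na / 3,
        atp_rate_mol=math.nan, atp_rate_molecules=math.nan,
    )


def resting_atp_rate(m: RestingMeasurement,
                     env: IonEnvironment | None = None) -> PumpSolution:
    """Complete pump-leak solution including the resting ATP consumption rate.

    ATP rate (mol/s) = g_in (E_Na - V)(V - E_K) / (F (V + 2 E_Na - 3 E_K)),
    evaluated with nS.mV = pA bookkeeping, equal to I_Na / (3F).
    """
    env = env or IonEnvironment()
    part = partition_conductance(m, env)
    denom = m.V + 2 * env.E_Na - 3 * env.E_K
    rate_pA = m.g_in * (env.E_Na - m.V) * (m.V - env.E_K) / denom
    rate_mol = rate_pA * PA_TO_A / env.F
    return replace(part, atp_rate_mol=rate_mol,
                   atp_rate_molecules=rate_mol * env.N_A)


def ap_charge_cost(a: DiscreteCostAssumptions | None = None,
                   env: IonEnvironment | None = None) -> float:
    """ATP molecules needed to extrude the sodium charge of one action
    potential: C_m * dV / (3 e).

    A conservative lower bound: it assumes no temporal overlap of the sodium
    and potassium voltage-gated currents.
    """
    a = a or DiscreteCostAssumptions()
    env = env or IonEnvironment()
    charge = a.C_m * PF_TO_F * a.dV_ap * MV_TO_V   # coulombs
    return charge / (3 * env.e_charge)


def vesicle_count_from_capacitance(a: DiscreteCostAssumptions | None = None) -> float:
    """Vesicle count explaining a capacitance step: dC / (c_spec * pi * d^2).

    Uses the sphere surface area pi d^2 and returns the raw (unrounded) count;
    use :func:`round_to_sig_figs` for a one-significant-figure headline.
    """
    a = a or DiscreteCostAssumptions()
    area_cm2 = math.pi * (a.d_vesicle * NM_TO_CM) ** 2
    cap_per_vesicle = a.c_spec * UF_PER_CM2_TO_F_PER_CM2 * area_cm2  # farad
    return a.dC_vesicles * FF_TO_F / cap_per_vesicle


def vesicle_release_cost(n_vesicles: float,
                         a: DiscreteCostAssumptions | None = None) -> float:
    """ATP molecules to package ``n_vesicles`` vesicles (n x cost-per-vesicle)."""
    a = a or DiscreteCostAssumptions()
    if n_vesicles < 0:
        raise ValueError("vesicle count must be non-negative")
    return n_vesicles * a.atp_per_vesicle


def cells_per_ug_protein(p: ProductionAssumptions | None = None) -> float:
    """Cells per microgram of protein from cell volume, density and dry
    fraction, treating dry mass as protein mass."""
    p = p or ProductionAssumptions()
    protein_per_cell_g = p.cell_volume * PL_TO_ML * p.density * p.dry_fraction
    return UG_TO_G / protein_per_cell_g


def production_rate_per_cell(p: ProductionAssumptions | None = None,
                             env: IonEnvironment | None = None) -> float:
    """Per-cell ATP production ceiling, molecules s^-1 cell^-1, from a bulk
    rate in pmol per ug protein per minute."""
    p = p or ProductionAssumptions()
    env = env or IonEnvironment()
    per_cell_pmol_min = p.bulk_rate / cells_per_ug_protein(p)
    return per_cell_pmol_min * PMOL_TO_MOL / 60.0 * env.N_A


def round_to_sig_figs(x: float, n: int = 1) -> float:
    """Round to ``n`` significant figures (reporting helper; stored values are
    never rounded)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + n - 1)


def energy_budget_cohort(measurements: list[RestingMeasurement],
                         env: IonEnvironment | None = None) -> pd.DataFrame:
    """Per-cell resting ATP budget with per-condition aggregates.

    Returns a tidy frame with one ``row_type='cell'`` row per valid cell and
    one ``row_type='aggregate'`` row per condition (mean, s.e.m., n).  Cells
    whose V falls outside (E_K, E_Na) are flagged ``row_type='excluded'`` with
    the reason, never silently clipped.  Deterministic given input order.
    """
    env = env or IonEnvironment()
    rows: list[dict] = []
    for m in measurements:
        try:
            sol = resting_atp_rate(m, env)
        except InvalidRegimeError as err:
            rows.append({
                "row_type": "excluded", "cell_id": m.cell_id,
                "condition": m.condition, "V_mV": m.V, "gin_nS": m.g_in,
                "reason": str(err),
            })
            continue
        rows.append({
            "row_type": "cell", "cell_id": m.cell_id,
            "condition": m.condition, "V_mV": m.V, "gin_nS": m.g_in,
            "g_Na_nS": sol.g_Na, "g_K_nS": sol.g_K,
            "I_pump_pA": sol.I_pump,
            "atp_rate_mol_s": sol.atp_rate_mol,
            "atp_rate_molecules_s": sol.atp_rate_molecules,
        })
    cols = ["row_type", "cell_id", "condition", "V_mV", "gin_nS", "g_Na_nS",
            "g_K_nS", "I_pump_pA", "atp_rate_mol_s", "atp_rate_molecules_s",
            "sem_molecules_s", "n_cells", "reason"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    cells = df[df["row_type"] == "cell"]
    aggs = []
    for cond, grp in cells.groupby("condition", sort=False):
        vals = grp["atp_rate_molecules_s"].to_numpy()
        aggs.append({
            "row_type": "aggregate", "condition": cond,
            "atp_rate_molecules_s": float(np.mean(vals)),
            "sem_molecules_s": (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                                if len(vals) > 1 else math.nan),
            "n_cells": len(vals),
        })
    out = pd.concat([df, pd.DataFrame(aggs)], ignore_index=True) if aggs else df
    return out.reindex(columns=[c for c in cols if c in out.columns])
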