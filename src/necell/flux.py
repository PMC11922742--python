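"""Growth-normalized metabolite exchange rates and derived indices.

Exchange experiments measure metabolite concentrations in mock (medium-only)
and cell-containing wells before/after an incubation.  Cell growth over the
incubation is modelled as a two-point exponential fit; the area under the
growth curve (integrated cell-time, cell.h) normalizes the concentration
difference into a per-cell molar rate.  The glycolysis index is the ratio of
lactate secretion to glucose consumption: 2 is the stoichiometric ceiling for
purely glucose-derived lactate, 0 indicates fully oxidative metabolism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluxExperiment",
    "ExchangeRates",
    "growth_rate",
    "integrated_cells",
    "exchange_rate",
    "glycolysis_index",
    "srb_doubling",
    "lactate_crossover",
]

#: |kT| below this uses the k -> 0 limit N0*T for the integrated cell-time
_KT_BRANCH = 1e-10

#: mM * ml -> fmol  (1e-3 mol/l * 1e-3 l = 1e-6 mol = 1e9 fmol)
_MM_ML_TO_FMOL = 1e9


@dataclass
class FluxExperiment:
    """One exchange experiment: cell counts, duration, medium volume and
    paired mock / cell-containing concentrations per metabolite (mM).

    ``conc_mock`` / ``conc_sample`` map metabolite name -> sequence of
    replicate concentrations.  Mock replicates are averaged into a single
    reference by default; ``paired=True`` pairs them index-wise with sample
    replicates instead.
    """

    N0: float                      # cells at start
    Nf: float                      # cells at end
    T: float = 24.0                # h
    volume: float = 2.0            # ml
    conc_mock: dict[str, list[float]] = field(default_factory=dict)
    conc_sample: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N0 <= 0 or self.Nf <= 0:
            raise ValueError("cell counts must be positive")
        if self.T <= 0 or self.volume <= 0:
            raise ValueError("duration and volume must be positive")
        if set(self.conc_mock) != set(self.conc_sample):
            raise ValueError("mock and sample must cover identical metabolites")


@dataclass(frozen=True)
class ExchangeRates:
    """Growth parameters and per-metabolite exchange rates.

    Rates are fmol cell^-1 h^-1, secretion-positive / consumption-negative.
    ``rates`` holds the replicate mean, ``sem`` the standard error (NaN for a
    single replicate).
    """

    k: float                       # h^-1
    integrated_cell_time: float    # cell.h
    rates: dict[str, float]
    sem: dict[str, float]
    per_replicate: dict[str, tuple[float, ...]]


def growth_rate(N0: float, Nf: float, T: float) -> float:
    """Exponential growth rate k = ln(Nf/N0)/T from initial and final counts
    (exact two-point fit)."""
    if N0 <= 0 or Nf <= 0:
        raise ValueError("cell counts must be positive")
    if T <= 0:
        raise ValueError("duration must be positive")
    return math.log(Nf / N0) / T


def integrated_cells(N0: float, k: float, T: float) -> float:
    """Area under N0*exp(k t) over [0, T]: the average cell-time (cell.h).

    N0 (e^{kT} - 1) / k, with the continuous limit N0*T at |kT| < 1e-10."""
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    if abs(k * T) < _KT_BRANCH:
        return N0 * T
    return N0 * math.expm1(k * T) / k


def exchange_rate(exp: FluxExperiment, paired: bool = False) -> ExchangeRates:
    """Per-cell metabolite exchange rates from mock-vs-sample differences.

    rate = (conc_sample - conc_mock) * volume / integrated_cell_time,
    reported in fmol cell^-1 h^-1 with the secretion-positive convention.
    """
    if not exp.conc_mock:
        raise ValueError("experiment has no metabolite measurements")
    k = growth_rate(exp.N0, exp.Nf, exp.T)
    cell_time = integrated_cells(exp.N0, k, exp.T)
    rates: dict[str, float] = {}
    sems: dict[str, float] = {}
    per_rep: dict[str, tuple[float, ...]] = {}
    for met in exp.conc_sample:
        mock = np.asarray(exp.conc_mock[met], dtype=float)
        sample = np.asarray(exp.conc_sample[met], dtype=float)
        if mock.size == 0:
            raise ValueError(f"missing mock measurement for {met}")
        if paired:
            if mock.shape != sample.shape:
                raise ValueError("paired mode requires equal replicate counts")
            deltas = sample - mock
        else:
            deltas = sample - float(np.mean(mock))
        rep_rates = deltas * exp.volume * _MM_ML_TO_FMOL / cell_time
        per_rep[met] = tuple(float(r) for r in rep_rates)
        rates[met] = float(np.mean(rep_rates))
        sems[met] = (float(np.std(rep_rates, ddof=1) / np.sqrt(rep_rates.size))
                     if rep_rates.size > 1 else math.nan)
    return ExchangeRates(k=k, integrated_cell_time=cell_time, rates=rates,
                         sem=sems, per_replicate=per_rep)


#: lactate yield per glucose for pure fermentation; indices above this imply
#: non-glucose lactate sources
GLYCOLYSIS_INDEX_CEILING = 2.0


def glycolysis_index(rates: ExchangeRates, lactate: str = "lactate",
                     glucose: str = "glucose") -> float:
    """Lactate secretion rate / |glucose consumption rate| (dimensionless).

    Defined only when glucose is net consumed (negative rate).  Values above
    2 exceed the stoichiometric ceiling of purely glucose-derived lactate.
    """
    try:
        lac = rates.rates[lactate]
        glc = rates.rates[glucose]
    except KeyError as err:
        raise ValueError(f"metabolite not measured: {err}") from err
    if glc >= 0:
        raise ValueError(
            "glycolysis index undefined: no net glucose consumption "
            f"(rate = {glc:+.3g} fmol/cell/h)")
    return lac / abs(glc)


def srb_doubling(X0: float, Xn: float, days: float = 3.0) -> float:
    """Doublings per day from endpoint absorbances: (ln(Xn/X0)/ln 2)/days."""
    if X0 <= 0 or Xn <= 0:
        raise ValueError("absorbances must be positive")
    if days <= 0:
        raise ValueError("days must be positive")
    return (math.log(Xn / X0) / math.log(2)) / days


def lactate_crossover(titration: list[tuple[float, float]]) -> float | None:
    """Smallest supplied lactate concentration (mM) at which net lactate flux
    turns to consumption (<= 0); ``None`` if flux stays secretory throughout
    (the non-neuroendocrine pattern).

    ``titration`` is a list of (supplied mM, net flux) with strictly
    increasing supplied concentrations.
    """
    if len(titration) < 2:
        raise ValueError("titration needs at least 2 points")
    concs = [c for c, _ in titration]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("supplied concentrations must be strictly increasing")
    for conc, flux in titration:
        if flux <= 0:
            return conc
    return None
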