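"""Feature extraction from current-clamp sweep sets.

Implements the three statistics used to characterise neuroendocrine versus
non-neuroendocrine phenotypes: the resting membrane potential read shortly
after breakthrough, the passive input resistance / time constant /
capacitance from small hyperpolarizing steps, and the excitability score
(maximum overshoot of the peak voltage above the steady-state depolarized
voltage across a ladder of depolarizing steps, zero without a consistent
overshoot in more than one sweep).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Sweep",
    "SweepSet",
    "PassiveFit",
    "ExcitabilityResult",
    "correct_junction",
    "estimate_v_rest",
    "fit_passive",
    "sweep_overshoot",
    "excitability",
]


@dataclass(frozen=True)
class Sweep:
    stimulus_pA: float
    voltage_mV: np.ndarray  # mV, uniformly sampled


@dataclass
class SweepSet:
    """A run of current-clamp sweeps sharing a time base and step timing.

    ``junction_potential`` is the liquid junction potential (mV) for the
    gluconate-pipette / NaCl-bath configuration; ``prenulled=True`` (the
    default) means the amplifier offset already accounts for it and voltages
    are reported as-is.
    """

    sample_interval: float                 # s
    sweeps: list[Sweep]
    step_onset: float                      # s
    step_offset: float                     # s
    breakthrough_time: float = 0.0         # s, for V_rest traces
    junction_potential: float = 10.0       # mV
    prenulled: bool = True

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not self.sweeps:
            raise ValueError("sweep set must contain at least one sweep")
        n = len(self.sweeps[0].voltage_mV)
        if any(len(s.voltage_mV) != n for s in self.sweeps):
            raise ValueError("all sweeps must have the same length")
        duration = n * self.sample_interval
        if not (self.step_onset < self.step_offset <= duration + 1e-12):
            raise ValueError("require step_onset < step_offset <= trace end")

    @property
    def n_samples(self) -> int:
        return len(self.sweeps[0].voltage_mV)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval


@dataclass(frozen=True)
class PassiveFit:
    R_in: float        # MOhm
    tau: float         # ms
    C: float           # pF  (tau/R_in, unit-consistent)
    V_baseline: float  # mV
    rmse: float        # mV (NaN if any per-sweep fit failed to converge)
    n_sweeps_used: int

    @property
    def g_in(self) -> float:
        """Input conductance in nS, for the energetics module."""
        return 1e3 / self.R_in


@dataclass(frozen=True)
class ExcitabilityResult:
    per_sweep_overshoot: tuple[float, ...]  # mV, one per depolarizing sweep
    excitability: float                     # mV
    n_overshoot_sweeps: int                 # sweeps above threshold
    rebound_used: bool
    threshold: float                        # mV, the consistency threshold


def correct_junction(V_raw: float | np.ndarray, s: SweepSet):
    """Junction-correct a raw voltage reading.

    With a potassium-gluconate pipette in a NaCl bath the pipette is positive,
    so the true membrane potential is more negative than the raw reading:
    V = V_raw - LJP.  If the amplifier was prenulled the reading is already
    correct and is returned unchanged.
    """
    if s.prenulled:
        return V_raw
    return V_raw - s.junction_potential


def estimate_v_rest(s: SweepSet, window_s: float = 3.0,
                    early_window_s: float = 0.5,
                    drift_threshold_mV: float = 5.0) -> float:
    """Resting potential: median voltage over the first ``window_s`` seconds
    after breakthrough, on the zero-current sweep.

    If the recording drifts by more than ``drift_threshold_mV`` across that
    window (dialysis of the cytoplasm by pipette solution), the read falls
    back to the first ``early_window_s`` seconds, which reflect the
    unperturbed cell.
    """
    zero = [sw for sw in s.sweeps if sw.stimulus_pA == 0]
    if not zero:
        raise ValueError("V_rest estimation requires a zero-current sweep")
    v = np.asarray(zero[0].voltage_mV, dtype=float)
    t = s.time
    t0 = s.breakthrough_time
    if t[-1] - t0 < early_window_s:
        raise ValueError("trace must cover at least the early window after "
                         "breakthrough")
    in_window = (t >= t0) & (t <= min(t0 + window_s, t[-1]))
    if not in_window.any():
        raise ValueError("V_rest window lies outside the trace")
    seg = v[in_window]
    # drift check: early vs late median within the window
    n_early = max(1, int(round(early_window_s / s.sample_interval)))
    if len(seg) > 2 * n_early:
        drift = abs(np.median(seg[-n_early:]) - np.median(seg[:n_early]))
        if drift > drift_threshold_mV:
            seg = seg[:n_early]
    return float(correct_junction(np.median(seg), s))


def _rc_response(t, V_base, IR, tau):
    return V_base + IR * (1.0 - np.exp(-t / tau))


def fit_passive(s: SweepSet, stim_range_pA: tuple[float, float] = (2.0, 4.0)
                ) -> PassiveFit:
    """Passive membrane properties from small hyperpolarizing steps.

    Fits V(t) = V_base + I R_in (1 - exp(-(t - t_on)/tau)) on the step
    interval of every sweep whose stimulus is hyperpolarizing with magnitude
    inside ``stim_range_pA``, then averages R_in and tau across qualifying
    sweeps.  C = tau / R_in (ms / MOhm -> nF, reported in pF).

    Numerical choices: tau is bounded above by a third of the step duration
    (the protocol presumes steps lasting at least 3 tau, and an unbounded fit
    can chase noise into a quasi-linear ramp); fits ending on that bound are
    treated as non-convergent.  The per-sweep estimates are averaged with
    weights proportional to the squared stimulus, since the estimator
    variance at fixed noise scales with the inverse square of the voltage
    deflection.
    """
    lo, hi = stim_range_pA
    qualifying = [sw for sw in s.sweeps
                  if sw.stimulus_pA < 0 and lo <= abs(sw.stimulus_pA) <= hi]
    if not qualifying:
        raise ValueError(
            f"no hyperpolarizing sweeps with |I| in [{lo}, {hi}] pA")
    t = s.time
    sel = (t >= s.step_onset) & (t < s.step_offset)
    t_rel = t[sel] - s.step_onset
    step_dur = float(t_rel[-1])
    tau_max = step_dur / 3.0
    Rs, taus, bases, resid, wts, n_ok = [], [], [], [], [], 0
    converged = True
    for sw in qualifying:
        v = np.asarray(sw.voltage_mV, dtype=float)[sel]
        v0 = v[0]
        p0 = (v0, v[-1] - v0, min(max(step_dur / 10.0, s.sample_interval),
                                  tau_max / 2))
        try:
            popt, _ = curve_fit(
                _rc_response, t_rel, v, p0=p0, maxfev=5000,
                bounds=([-np.inf, -np.inf, s.sample_interval / 10.0],
                        [np.inf, np.inf, tau_max]))
        except RuntimeError:
            converged = False
            continue
        V_base, IR, tau = popt
        if tau <= 0 or tau >= tau_max * 0.999:
            converged = False
            continue
        # IR in mV, I in pA -> R in GOhm; report MOhm
        Rs.append(IR / sw.stimulus_pA * 1e3)
        taus.append(tau * 1e3)  # s -> ms
        bases.append(V_base)
        resid.append(np.sqrt(np.mean((v - _rc_response(t_rel, *popt)) ** 2)))
        wts.append(sw.stimulus_pA ** 2)
        n_ok += 1
    if n_ok == 0:
        raise ValueError("no passive fit converged on the qualifying sweeps")
    R_in = float(np.average(Rs, weights=wts))
    tau = float(np.average(taus, weights=wts))
    return PassiveFit(
        R_in=R_in, tau=tau, C=tau / R_in * 1e3,
        V_baseline=float(np.mean(bases)),
        rmse=float(np.mean(resid)) if converged else math.nan,
        n_sweeps_used=n_ok,
    )


def sweep_overshoot(sweep: Sweep, s: SweepSet,
                    steady_fraction: float = 0.2,
                    rebound_window_s: float = 0.2) -> tuple[float, bool]:
    """Overshoot of one depolarizing sweep.

    The steady-state depolarized voltage is the mean over the final
    ``steady_fraction`` of the step.  The overshoot is the larger of the
    in-step peak and the peak in a post-offset rebound window, minus the
    steady state; rebound spikes, when present, are typically the largest and
    win this maximum.  Negative differences are reported as 0.
    """
    if sweep.stimulus_pA <= 0:
        raise ValueError("overshoot is defined for depolarizing sweeps")
    t = s.time
    v = np.asarray(sweep.voltage_mV, dtype=float)
    in_step = (t >= s.step_onset) & (t < s.step_offset)
    n_step = int(in_step.sum())
    n_steady = int(round(n_step * steady_fraction))
    if n_steady < 1:
        raise ValueError("step window shorter than the steady-state window")
    step_v = v[in_step]
    steady = float(np.mean(step_v[-n_steady:]))
    peak_in = float(np.max(step_v))
    rebound_sel = (t >= s.step_offset) & (t < s.step_offset + rebound_window_s)
    peak_rebound = float(np.max(v[rebound_sel])) if rebound_sel.any() else -np.inf
    rebound_flag = peak_rebound > peak_in
    overshoot = max(peak_in, peak_rebound) - steady
    if overshoot <= 0:
        return 0.0, False
    return overshoot, rebound_flag


def excitability(s: SweepSet, theta: float = 5.0,
                 steady_fraction: float = 0.2,
                 rebound_window_s: float = 0.2) -> ExcitabilityResult:
    """Excitability of a run: maximum overshoot across progressively larger
    depolarizing steps, zero unless more than one sweep shows a clear
    overshoot (> ``theta`` mV)."""
    depol = [sw for sw in s.sweeps if sw.stimulus_pA > 0]
    if len(depol) < 2:
        raise ValueError("excitability requires at least 2 depolarizing sweeps")
    overshoots, flags = [], []
    for sw in depol:
        o, f = sweep_overshoot(sw, s, steady_fraction, rebound_window_s)
        overshoots.append(o)
        flags.append(f)
    n_over = sum(1 for o in overshoots if o > theta)
    if n_over <= 1:
        return ExcitabilityResult(tuple(overshoots), 0.0, n_over, False, theta)
    i_max = int(np.argmax(overshoots))
    return ExcitabilityResult(tuple(overshoots), overshoots[i_max], n_over,
                              flags[i_max], theta)
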