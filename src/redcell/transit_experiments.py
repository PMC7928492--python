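"""Pre-built capillary-transit experiments and metric extraction.

The reference ("Ref") experiment runs a two-minute baseline, a 0.4 s
capillary transit (CVF jumps from 1e-5 to 0.9 with PIEZO1 open: PzCa = 70,
PzA = 50 h^-1), then instant egress with PIEZO1 closure, CVF back to 1e-5
and the medium restored to its baseline snapshot, followed for a
configurable post-transit period.  The sweeps reproduce the standard
perturbations: PIEZO1 calcium permeability, PMCA strength (with the
reference state rebuilt for each pump strength), Gardos knockout,
Jacobs-Stewart rate scaling, and the microfluidic-constriction calcium
transient at low external calcium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .model_core import SystemState, TransportParams
from .protocol_engine import ProtocolStage, SimulationOutput, run_protocol
from .reference_state import ReferenceTargets, build_reference_state

__all__ = [
    "TransitMetrics",
    "reference_protocol",
    "run_reference_transit",
    "extract_metrics",
    "sweep_pzca",
    "sweep_pmca",
    "gardos_knockout",
    "sweep_js",
    "ca_transient_emulation",
    "cumulative_ca_gain",
    "BASELINE_S",
    "TRANSIT_CVF",
    "CIRCULATION_CVF",
]

BASELINE_S = 120.0
TRANSIT_CVF = 0.9
CIRCULATION_CVF = 1e-5


@dataclass
class TransitMetrics:
    """Scalar summary of one transit simulation.

    Times are in seconds (``t_recovery`` may span days of model time);
    volume displacements are relative (RCV units).
    """

    peak_dRCV: float = 0.0
    undershoot_dRCV: float = 0.0
    plateau_dRCV: float = 0.0
    t_peak: float = float("nan")
    t_below_baseline: float = float("nan")
    t_recovery: float = float("nan")
    Em_excursion: float = 0.0
    Em_baseline: float = float("nan")
    Em_max: float = float("nan")
    Em_min: float = float("nan")
    t_gardos_off: float = float("nan")
    t_pmca_off: float = float("nan")
    ca_peak: float = 0.0


def reference_protocol(follow_s: float = 300.0,
                       baseline_s: float = BASELINE_S,
                       transit_overrides: dict | None = None,
                       follow_overrides: dict | None = None,
                       transit_s: float | None = None,
                       follow_epochs: int = 2500,
                       restore: bool = True) -> list[ProtocolStage]:
    """The Ref three-stage protocol (baseline / transit / recovery)."""
    t_transit = 0.4 if transit_s is None else transit_s
    return [
        ProtocolStage(duration=baseline_s, cvf=CIRCULATION_CVF,
                      epochs=111, frequency_factor=1e-5, name="DS1 baseline"),
        ProtocolStage(duration=t_transit, cvf=TRANSIT_CVF, piezo_open=True,
                      overrides=dict(transit_overrides or {}),
                      epochs=200, frequency_factor=1.0, name="DS2 transit"),
        ProtocolStage(duration=follow_s, cvf=CIRCULATION_CVF,
                      restore_medium=restore,
                      overrides=dict(follow_overrides or {}),
                      epochs=follow_epochs, frequency_factor=1e-5,
                      name="DS2 recovery"),
    ]


def extract_metrics(output: SimulationOutput,
                    baseline_s: float = BASELINE_S,
                    os_s: float | None = None,
                    em_window_s: float = 5.0,
                    recovery_fraction: float = 0.05,
                    flux_tolerance: float = 0.01) -> TransitMetrics:
    """Derive transit metrics from a Ref-style simulation table.

    Baseline fluxes and Em are read from the last pre-transit sample.  The
    Gardos/PMCA off-times are the last instants after PIEZO1 closure at
    which the respective flux deviates from baseline by more than
    ``flux_tolerance`` (relative); recovery time is the first post-minimum
    instant at which |RCV - 1| drops below ``recovery_fraction`` of the
    undershoot depth.
    """
    df = output.frame
    t = df["time_s"].to_numpy()
    rcv = df["RCV"].to_numpy()
    em = df["Em"].to_numpy()

    os_s = float(output.params.OS) if os_s is None else os_s
    t_open = baseline_s
    t_close = baseline_s + os_s

    pre = df[t <= t_open - 1e-12]
    if pre.empty:
        raise ValueError("no baseline samples before the transit")
    base = pre.iloc[-1]

    m = TransitMetrics()
    post = t >= t_open
    i_peak = int(np.argmax(np.where(post, rcv, -np.inf)))
    m.peak_dRCV = float(rcv[i_peak] - 1.0)
    m.t_peak = float(t[i_peak] - t_open)

    after_peak = t >= t[i_peak]
    i_min = int(np.argmin(np.where(after_peak, rcv, np.inf)))
    m.undershoot_dRCV = float(max(0.0, 1.0 - rcv[i_min]))
    m.plateau_dRCV = float(1.0 - rcv[-1])

    below = after_peak & (rcv < 1.0)
    if below.any():
        m.t_below_baseline = float(t[np.argmax(below)] - t_open)

    if m.undershoot_dRCV > 0:
        tol = recovery_fraction * m.undershoot_dRCV
        rec = (t > t[i_min]) & (np.abs(rcv - 1.0) <= tol)
        if rec.any():
            m.t_recovery = float(t[np.argmax(rec)] - t_open)

    win = (t >= t_open) & (t <= t_close + em_window_s)
    m.Em_baseline = float(base["Em"])
    m.Em_max = float(em[win].max())
    m.Em_min = float(em[win].min())
    m.Em_excursion = m.Em_max - m.Em_min

    m.ca_peak = float(df["CaI"].max())

    for col, attr in (("FKGardos", "t_gardos_off"), ("FCaPump", "t_pmca_off")):
        f = df[col].to_numpy()
        f0 = float(base[col])
        scale = max(abs(f0), 1e-12)
        late = t > t_close
        off = late & (np.abs(f - f0) > flux_tolerance * scale)
        if off.any():
            t_last = t[off][-1]
            # first sample after the last excursion beyond tolerance
            nxt = t[t > t_last]
            setattr(m, attr, float((nxt[0] if nxt.size else t[-1]) - t_close))
        else:
            setattr(m, attr, 0.0)
    return m


def run_reference_transit(follow_minutes: float = 5.0,
                          system: SystemState | None = None,
                          params: TransportParams | None = None,
                          follow_epochs: int = 2500,
                          **protocol_kwargs) -> tuple[TransitMetrics,
                                                      SimulationOutput]:
    """Run the Ref protocol and return its metrics and full output."""
    if system is None or params is None:
        system, params = build_reference_state()
    proto = reference_protocol(follow_s=follow_minutes * 60.0,
                               follow_epochs=follow_epochs,
                               **protocol_kwargs)
    out = run_protocol(proto, system, params)
    return extract_metrics(out), out


def sweep_pzca(values, follow_minutes: float = 5.0,
               system: SystemState | None = None,
               params: TransportParams | None = None) -> list[TransitMetrics]:
    """Transit metrics for a range of PzCa values at PzA = 50 h^-1."""
    if system is None or params is None:
        system, params = build_reference_state()
    results = []
    for pzca in values:
        p = replace(params, PzCa=float(pzca))
        metrics, _ = run_reference_transit(follow_minutes, system, p)
        results.append(metrics)
    return results


def sweep_pmca(fcamax_values, follow_minutes: float = 5.0,
               targets: ReferenceTargets | None = None
               ) -> list[TransitMetrics]:
    """Transit metrics across PMCA strengths.

    The reference state is rebuilt for every FCamax so that each cell starts
    from its own exact steady state (the ground Ca leak rebalances).
    """
    tg = targets or ReferenceTargets()
    results = []
    for fmax in fcamax_values:
        tg_i = replace(tg, params=replace(tg.params, FCamax=float(fmax)))
        system, params = build_reference_state(tg_i)
        metrics, _ = run_reference_transit(follow_minutes, system, params)
        results.append(metrics)
    return results


def gardos_knockout(follow_minutes: float = 5.0,
                    targets: ReferenceTargets | None = None
                    ) -> tuple[TransitMetrics, SimulationOutput]:
    """Ref transit with the Gardos channel silenced (FKmax = 0)."""
    tg = targets or ReferenceTargets()
    tg = replace(tg, params=replace(tg.params, FKmax=0.0))
    system, params = build_reference_state(tg)
    return run_reference_transit(follow_minutes, system, params)


def sweep_js(scale_factors, follow_minutes: float = 30.0,
             targets: ReferenceTargets | None = None) -> list[TransitMetrics]:
    """Transit metrics with the Jacobs-Stewart rate scaled by each factor."""
    tg = targets or ReferenceTargets()
    kjs0 = tg.params.kJS
    results = []
    for s in scale_factors:
        tg_i = replace(tg, params=replace(tg.params, kJS=kjs0 * float(s)))
        system, params = build_reference_state(tg_i)
        metrics, _ = run_reference_transit(follow_minutes, system, params)
        results.append(metrics)
    return results


def ca_transient_emulation(os_s: float = 3.0, pzca: float = 15.0,
                           cao: float = 0.05, baseline_s: float = 3.0,
                           total_window_s: float = 9.0,
                           n_samples: int = 400
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized free-Ca transient for a slow constriction passage.

    Emulates a microfluidic-chip measurement window: ``baseline_s`` of quiet
    flow, a passage of duration ``os_s`` with PIEZO1 open at permeability
    ``pzca``, and recovery to the end of ``total_window_s``, all at low
    external calcium ``cao`` (mmol/L).  Returns (times s, CaI normalized to
    a maximum of 1); a flat zero trace if calcium never rises.
    """
    tg = ReferenceTargets(CaO=cao)
    system, params = build_reference_state(tg)
    params = replace(params, OS=os_s, PzCa=pzca, PzA=50.0)
    recovery = total_window_s - baseline_s - os_s
    if recovery <= 0:
        raise ValueError("total window must exceed baseline + open state")
    n_each = max(n_samples // 3, 10)
    proto = [
        ProtocolStage(duration=baseline_s, cvf=CIRCULATION_CVF,
                      epochs=n_each, frequency_factor=1.0, name="approach"),
        ProtocolStage(duration=os_s, cvf=CIRCULATION_CVF, piezo_open=True,
                      epochs=n_each, frequency_factor=1.0,
                      name="constriction"),
        ProtocolStage(duration=recovery, cvf=CIRCULATION_CVF,
                      epochs=n_each, frequency_factor=1.0, name="recovery"),
    ]
    out = run_protocol(proto, system, params)
    t = out.frame["time_s"].to_numpy()
    ca = out.frame["CaI"].to_numpy()
    rise = ca - ca[0]
    peak = rise.max()
    if peak <= 0.05 * ca[0]:
        # no meaningful calcium signal (e.g. PzCa = 0): the undefined
        # normalization is reported as a flat zero trace
        return t, np.zeros_like(rise)
    return t, rise / peak


def cumulative_ca_gain(os_s: float, pzca: float,
                       system: SystemState | None = None,
                       params: TransportParams | None = None) -> float:
    """Total Ca2+ carried through PIEZO1 during one transit, mmol/Loc.

    Integrates the PIEZO1 calcium flux over the open state of a Ref-style
    transit with the given open-state duration and permeability.
    """
    if system is None or params is None:
        system, params = build_reference_state()
    p = replace(params, OS=os_s, PzCa=pzca)
    proto = reference_protocol(follow_s=5.0, transit_s=os_s,
                               follow_epochs=200)
    proto[1].epochs = 800
    out = run_protocol(proto, system, p)
    df = out.frame
    sel = df["piezo_open"] > 0.5
    t_h = df.loc[sel, "time_s"].to_numpy() / 3600.0
    flux = df.loc[sel, "FCaPiezo"].to_numpy()
    return float(np.trapezoid(flux, t_h))
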