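"""Event-driven execution of multi-stage simulation protocols.

A protocol is an ordered list of :class:`ProtocolStage` objects.  Each stage
fixes the cell volume fraction, the PIEZO1 gate, optional parameter
overrides and the output-sampling controls, and may restore the medium to
its baseline snapshot on entry (the return of the cell to the effectively
infinite systemic circulation).  Stages are integrated one at a time with a
stiff adaptive solver, so stage boundaries and the PIEZO1 closure at
t_open + OS are hit exactly rather than stepped across.

Sampling controls mirror the conventions of the original simulator's output
panel: ``accuracy`` is the number of printed decimals in the CSV,
``epochs`` the number of output rows per stage, and ``frequency_factor`` a
geometric densification of the sample grid toward the stage start (1.0
means uniform sampling; small values concentrate points just after the
event that opens the stage).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    Fluxes,
    ModelError,
    SystemState,
    TransportParams,
    compute_fluxes,
    decompose_water_flux,
    free_calcium,
    pack_state,
    system_derivatives,
    unpack_state,
)

__all__ = [
    "ProtocolStage",
    "SimulationOutput",
    "ProtocolError",
    "run_protocol",
    "restore_medium",
    "stage_sample_times",
    "write_csv",
    "write_protocol",
    "read_protocol",
    "protocol_to_text",
]

log = logging.getLogger("redcell")

SECONDS_PER_HOUR = 3600.0

RTOL = 1e-9


class ProtocolError(ValueError):
    """Malformed protocol definition or protocol file."""


@dataclass
class ProtocolStage:
    """One dynamic stage of a protocol.

    ``duration`` is in seconds.  ``overrides`` maps
    :class:`~redcell.model_core.TransportParams` field names to stage-scoped
    values (restored when the stage ends).
    """

    duration: float
    cvf: float = 1e-5
    piezo_open: bool = False
    restore_medium: bool = False
    overrides: dict = field(default_factory=dict)
    accuracy: int = 6
    epochs: int = 111
    frequency_factor: float = 1e-5
    name: str = ""

    def validate(self) -> None:
        if self.duration <= 0:
            raise ProtocolError(f"stage {self.name!r}: duration must be > 0")
        if not 0.0 < self.cvf < 1.0:
            raise ProtocolError(f"stage {self.name!r}: CVF must be in (0, 1)")
        if self.epochs < 1:
            raise ProtocolError(f"stage {self.name!r}: epochs must be >= 1")
        if self.frequency_factor <= 0:
            raise ProtocolError(
                f"stage {self.name!r}: frequency factor must be > 0")


@dataclass
class SimulationOutput:
    """Time series of every homeostatic variable and per-pathway flux."""

    frame: pd.DataFrame
    protocol: list
    params: TransportParams
    accuracy: int = 6
    deterministic: bool = True


def stage_sample_times(duration_s: float, epochs: int,
                       frequency_factor: float) -> np.ndarray:
    """Relative sample times within a stage, seconds, both endpoints included.

    A geometric grid: with frequency factor f < 1 the i-th of N points falls
    at D * (f^(1 - i/N) - f) / (1 - f), which is dense just after the stage
    start and relaxes toward the stage end; f = 1 is the uniform limit.
    """
    n = int(epochs)
    i = np.arange(n + 1, dtype=float)
    f = float(frequency_factor)
    if abs(f - 1.0) < 1e-12:
        t = duration_s * i / n
    else:
        t = duration_s * (f ** (1.0 - i / n) - f) / (1.0 - f)
    t[0] = 0.0
    t[-1] = duration_s
    return t


def _make_rhs(work: SystemState, params: TransportParams, piezo_open: bool):
    em_cache = {"em": work.cell.Em}

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        unpack_state(y, work)
        work.t = t
        dy, fl = system_derivatives(work, params, piezo_open,
                                    em_guess=em_cache["em"])
        em_cache["em"] = fl.Em
        return dy

    return rhs


def _atol_for(y0: np.ndarray) -> np.ndarray:
    # per-species absolute tolerances: the transit signals are ~1e-5
    # relative, so each state gets a floor well below its own magnitude
    return np.maximum(1e-13, 1e-11 * np.abs(y0))


def _integrate_segment(system: SystemState, params: TransportParams,
                       piezo_open: bool, t_grid_h: np.ndarray,
                       stage_index: int) -> np.ndarray:
    """Integrate over ``t_grid_h`` (hours, absolute) returning states at the
    grid points; ``system`` is left at the final state."""
    y0 = pack_state(system)
    rhs = _make_rhs(system, params, piezo_open)
    sol = solve_ivp(
        rhs, (t_grid_h[0], t_grid_h[-1]), y0, method="LSODA",
        t_eval=t_grid_h, rtol=RTOL, atol=_atol_for(y0),
    )
    if not sol.success:
        raise ProtocolError(
            f"integration failed in stage {stage_index}: {sol.message}; "
            f"last good state at t = {sol.t[-1] * SECONDS_PER_HOUR:.4f} s: "
            f"{sol.y[:, -1].tolist()}"
        )
    unpack_state(sol.y[:, -1], system)
    system.t = t_grid_h[-1]
    return sol.y.T


def restore_medium(system: SystemState) -> SystemState:
    """Reset the medium to its baseline snapshot; the cell is untouched."""
    system.medium.restore()
    return system


def _row(t_h: float, system: SystemState, params: TransportParams,
         piezo_open: bool, cvf: float) -> dict:
    c, m = system.cell, system.medium
    fl = compute_fluxes(system, params, piezo_open, em_guess=c.Em)
    dec = decompose_water_flux(system, params, piezo_open)
    cai = free_calcium(c.QCa, c.Vw, params)
    return {
        "time_s": t_h * SECONDS_PER_HOUR,
        "RCV": c.RCV,
        "Vw": c.Vw,
        "Em": fl.Em,
        "pHi": c.pHi,
        "CaI": cai,
        "QNa": c.QNa, "QK": c.QK, "QA": c.QA, "QCa": c.QCa,
        "CNa": c.CNa, "CK": c.CK, "CA": c.CA,
        "COs": fl.COs, "MOs": fl.MOs,
        "NaO": m.NaO, "KO": m.KO, "AO": m.AO, "CaO": m.CaO, "pHo": m.pHo,
        "Vm": m.Vm, "CVF": cvf,
        "piezo_open": float(piezo_open),
        "FNaLeak": fl.na_leak, "FNaPiezo": fl.na_piezo,
        "FKLeak": fl.k_leak, "FKPiezo": fl.k_piezo, "FKGardos": fl.k_gardos,
        "FALeak": fl.a_leak, "FAPiezo": fl.a_piezo,
        "FCaLeak": fl.ca_leak, "FCaPiezo": fl.ca_piezo,
        "FCaPump": fl.pmca_ca, "FNaPump": fl.pump_na, "FKPump": fl.pump_k,
        "FJS": fl.js, "Fw": fl.fw,
        "W1": dec.W1, "W2": dec.W2, "W3": dec.W3, "W4": dec.W4,
    }


def run_protocol(protocol: Sequence[ProtocolStage], system: SystemState,
                 params: TransportParams) -> SimulationOutput:
    """Run a multi-stage protocol from ``system`` (inputs are not mutated).

    The PIEZO1 gate of an open stage closes at exactly ``min(OS, duration)``
    after stage entry; the integrator is restarted on that event rather than
    stepping across it.  Runs are deterministic: identical inputs give
    byte-identical output tables.
    """
    stages = list(protocol)
    if not stages:
        raise ProtocolError("protocol has no stages")
    for st in stages:
        st.validate()

    sys_work = system.copy()
    rows: list[dict] = []
    t0_h = sys_work.t

    for idx, st in enumerate(stages):
        p_stage = replace(params, **{
            k: v for k, v in st.overrides.items() if k != "cvf"
        }).validated() if st.overrides else params
        if st.restore_medium:
            restore_medium(sys_work)
            log.info("stage %d (%s): medium restored to baseline snapshot",
                     idx, st.name or "unnamed")
        if abs(st.cvf - sys_work.CVF) > 0:
            sys_work.medium.rescale_to_cvf(st.cvf)
            sys_work.CVF = st.cvf
            log.info("stage %d (%s): CVF set to %g", idx,
                     st.name or "unnamed", st.cvf)

        dur_h = st.duration / SECONDS_PER_HOUR
        t_rel = stage_sample_times(st.duration, st.epochs,
                                   st.frequency_factor) / SECONDS_PER_HOUR
        t_abs = t0_h + t_rel

        open_h = min(p_stage.OS / SECONDS_PER_HOUR, dur_h) \
            if st.piezo_open else 0.0
        if st.piezo_open and open_h > 0:
            log.info("stage %d (%s): PIEZO1 open for %.6g s", idx,
                     st.name or "unnamed", open_h * SECONDS_PER_HOUR)

        # split the stage grid at the PIEZO1 closure event
        segments: list[tuple[np.ndarray, bool]] = []
        if st.piezo_open and open_h < dur_h:
            t_close = t0_h + open_h
            first = t_abs[t_abs <= t_close + 1e-18]
            if first.size == 0 or first[-1] < t_close - 1e-18:
                first = np.append(first, t_close)
            second = t_abs[t_abs > t_close + 1e-18]
            second = np.concatenate(([t_close], second)) \
                if second.size else np.array([t_close, t0_h + dur_h])
            segments.append((first, True))
            segments.append((second, False))
        else:
            segments.append((t_abs, bool(st.piezo_open)))

        first_row_of_stage = True
        for t_grid, is_open in segments:
            if first_row_of_stage:
                rows.append(_row(t_grid[0], sys_work, p_stage, is_open,
                                 st.cvf))
                first_row_of_stage = False
            if t_grid[-1] <= t_grid[0]:
                continue
            ys = _integrate_segment(sys_work, p_stage, is_open, t_grid, idx)
            snapshot = sys_work.copy()
            for k in range(1, len(t_grid)):
                unpack_state(ys[k], snapshot)
                rows.append(_row(t_grid[k], snapshot, p_stage, is_open,
                                 st.cvf))
        t0_h += dur_h
        sys_work.t = t0_h
        log.info("stage %d (%s) done at t = %.6g s", idx,
                 st.name or "unnamed", t0_h * SECONDS_PER_HOUR)

    frame = pd.DataFrame(rows)
    acc = max(st.accuracy for st in stages)
    return SimulationOutput(frame=frame, protocol=stages, params=params,
                            accuracy=acc)


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------


def write_csv(output: SimulationOutput, path) -> None:
    """Write the simulation table as RFC-4180 CSV.

    Columns whose magnitude stays below 1e-3 are printed in scientific
    notation with ``accuracy`` significant digits (plain decimals would
    erase, e.g., free calcium); everything else uses ``accuracy`` fixed
    decimals.
    """
    df = output.frame
    acc = output.accuracy
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        if np.nanmax(np.abs(v)) < 1e-3:
            out[col] = [f"{x:.{acc}e}" for x in v]
        else:
            out[col] = [f"{x:.{acc}f}" for x in v]
    out.to_csv(path, index=False, lineterminator="\r\n")


# ---------------------------------------------------------------------------
# Protocol file dialect
# ---------------------------------------------------------------------------

_STAGE_KEYS = {"name", "duration", "cvf", "piezo_open", "restore_medium",
               "accuracy", "epochs", "frequency_factor"}


def protocol_to_text(protocol: Iterable[ProtocolStage]) -> str:
    """Serialize a protocol in the plain-text stage dialect (round-trips)."""
    lines = ["# redcell protocol", ""]
    for st in protocol:
        lines.append("[stage]")
        if st.name:
            lines.append(f"name = {st.name}")
        lines.append(f"duration = {st.duration!r} s")
        lines.append(f"cvf = {st.cvf!r}")
        lines.append(f"piezo_open = {'yes' if st.piezo_open else 'no'}")
        lines.append(f"restore_medium = {'yes' if st.restore_medium else 'no'}")
        lines.append(f"accuracy = {st.accuracy}")
        lines.append(f"epochs = {st.epochs}")
        lines.append(f"frequency_factor = {st.frequency_factor!r}")
        for k in sorted(st.overrides):
            lines.append(f"override.{k} = {st.overrides[k]!r}")
        lines.append("")
    return "\n".join(lines)


def write_protocol(protocol: Iterable[ProtocolStage], path) -> None:
    with open(path, "w") as fh:
        fh.write(protocol_to_text(protocol))


def _parse_duration(value: str, lineno: int) -> float:
    parts = value.split()
    try:
        x = float(parts[0])
    except (ValueError, IndexError):
        raise ProtocolError(f"line {lineno}: bad duration {value!r}")
    unit = parts[1].lower() if len(parts) > 1 else "s"
    if unit in ("s", "sec", "seconds"):
        return x
    if unit in ("min", "minutes"):
        return x * 60.0
    if unit in ("h", "hr", "hours"):
        return x * 3600.0
    raise ProtocolError(f"line {lineno}: unknown time unit {unit!r}")


def _parse_bool(value: str, lineno: int) -> bool:
    v = value.strip().lower()
    if v in ("yes", "true", "1", "on"):
        return True
    if v in ("no", "false", "0", "off"):
        return False
    raise ProtocolError(f"line {lineno}: expected yes/no, got {value!r}")


def read_protocol(path) -> list[ProtocolStage]:
    """Parse a protocol file; errors carry the offending line number."""
    with open(path) as fh:
        text = fh.read()
    stages: list[ProtocolStage] = []
    current: ProtocolStage | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[stage]":
            current = ProtocolStage(duration=1.0)
            stages.append(current)
            continue
        if "=" not in line:
            raise ProtocolError(f"line {lineno}: expected 'key = value', "
                                f"got {raw!r}")
        if current is None:
            raise ProtocolError(f"line {lineno}: key outside of a [stage] "
                                "block")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        try:
            if key == "name":
                current.name = value
            elif key == "duration":
                current.duration = _parse_duration(value, lineno)
            elif key == "cvf":
                current.cvf = float(value)
            elif key == "piezo_open":
                current.piezo_open = _parse_bool(value, lineno)
            elif key == "restore_medium":
                current.restore_medium = _parse_bool(value, lineno)
            elif key == "accuracy":
                current.accuracy = int(value)
            elif key == "epochs":
                current.epochs = int(value)
            elif key == "frequency_factor":
                current.frequency_factor = float(value)
            elif key.startswith("override."):
                pname = key[len("override."):]
                if pname not in TransportParams.__dataclass_fields__:
                    raise ProtocolError(
                        f"line {lineno}: unknown parameter {pname!r}")
                current.overrides[pname] = float(value)
            else:
                raise ProtocolError(f"line {lineno}: unknown key {key!r}")
        except ProtocolError:
            raise
        except ValueError as exc:
            raise ProtocolError(f"line {lineno}: {exc}") from exc
    if not stages:
        raise ProtocolError("protocol file defines no stages")
    for st in stages:
        st.validate()
    return stages
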