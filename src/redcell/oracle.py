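"""Independent fixed-step integration oracle and protocol fixtures.

The oracle re-integrates the model with plain explicit Euler at a fixed
step, using nothing from the production path except the flux laws
themselves.  On short windows it certifies the adaptive stiff solver; a
halving (Richardson) check guards against using a step outside the Euler
stability region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_core import (
    SystemState,
    TransportParams,
    pack_state,
    system_derivatives,
    unpack_state,
)
from .protocol_engine import ProtocolStage, write_protocol
from .transit_experiments import reference_protocol

__all__ = ["OracleReport", "euler_oracle", "compare_trajectories",
           "generate_protocol_fixtures"]


@dataclass
class OracleReport:
    variable: str
    max_rel_deviation: float
    window_s: float


def euler_oracle(system: SystemState, params: TransportParams,
                 duration_s: float, dt_h: float = 1e-5,
                 piezo_open: bool = False,
                 check_convergence: bool = False,
                 convergence_tol: float = 1e-6
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Explicit-Euler trajectory: returns (times_s, states[n_steps+1, 12]).

    With ``check_convergence`` the integration is repeated at dt/2 and an
    error is raised if the endpoints disagree by more than
    ``convergence_tol`` relative (instability or too-coarse step).
    """

    def integrate(dt: float) -> tuple[np.ndarray, np.ndarray]:
        work = system.copy()
        y = pack_state(work)
        n = max(1, int(round(duration_s / 3600.0 / dt)))
        out = np.empty((n + 1, y.size))
        out[0] = y
        em = work.cell.Em
        for k in range(n):
            unpack_state(y, work)
            dy, fl = system_derivatives(work, params, piezo_open,
                                        em_guess=em)
            em = fl.Em
            y = y + dt * dy
            out[k + 1] = y
        t = np.arange(n + 1) * dt * 3600.0
        return t, out

    t, traj = integrate(dt_h)
    if check_convergence:
        _, traj2 = integrate(dt_h / 2.0)
        scale = np.maximum(np.abs(traj[-1]), 1e-12)
        rel = np.abs(traj2[-1] - traj[-1]) / scale
        if rel.max() > convergence_tol:
            raise RuntimeError(
                f"Euler step dt = {dt_h} h not converged: halving changes "
                f"the endpoint by {rel.max():.2e} relative"
            )
    return t, traj


def compare_trajectories(y_a: np.ndarray, y_b: np.ndarray,
                         names: list[str], window_s: float
                         ) -> list[OracleReport]:
    """Per-variable maximum relative deviation between two state arrays."""
    reports = []
    for j, name in enumerate(names):
        scale = np.maximum(np.abs(y_a[:, j]), 1e-12)
        dev = float(np.max(np.abs(y_a[:, j] - y_b[:, j]) / scale))
        reports.append(OracleReport(name, dev, window_s))
    return reports


def generate_protocol_fixtures(directory) -> dict[str, Path]:
    """Write the Ref protocol and every figure-variant protocol file.

    Returns a mapping from fixture name to file path.  The fixtures are
    synthetic protocol definitions (no external data): the Ref transit, the
    PzCa = 0 and PzA = 0 variants, the PzNa/PzK attribution variant, the
    Gardos knockout, the PMCA strength endpoints, the Jacobs-Stewart rate
    scalings, and the slow low-calcium constriction passage.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def ref(transit_overrides=None, follow_overrides=None, follow_s=300.0):
        return reference_protocol(follow_s=follow_s,
                                  transit_overrides=transit_overrides,
                                  follow_overrides=follow_overrides)

    fixtures: dict[str, list[ProtocolStage]] = {
        "ref": ref(),
        "fig3a_pzca0": ref(transit_overrides={"PzCa": 0.0}),
        "fig3a_pzca140": ref(transit_overrides={"PzCa": 140.0}),
        "fig3b_long": ref(follow_s=3600.0),
        "fig3c_pza0": ref(transit_overrides={"PzA": 0.0}),
        "fig3d_pznak": ref(transit_overrides={"PzNa": 1.65, "PzK": 1.53}),
        "fig6a_gardos_ko": ref(transit_overrides={"FKmax": 0.0},
                               follow_overrides={"FKmax": 0.0}),
        "fig6b_pmca_weak": ref(transit_overrides={"FCamax": 4.0},
                               follow_overrides={"FCamax": 4.0}),
        "fig6b_pmca_strong": ref(transit_overrides={"FCamax": 24.0},
                                 follow_overrides={"FCamax": 24.0}),
        "fig6e_jsx04": ref(transit_overrides={"kJS": 400.0},
                           follow_overrides={"kJS": 400.0}),
        "fig6e_jsx5": ref(transit_overrides={"kJS": 5000.0},
                          follow_overrides={"kJS": 5000.0}),
        "fig1_constriction": [
            ProtocolStage(duration=3.0, cvf=1e-5, epochs=120,
                          frequency_factor=1.0, name="approach"),
            ProtocolStage(duration=3.0, cvf=1e-5, piezo_open=True,
                          overrides={"OS": 3.0, "PzCa": 15.0},
                          epochs=120, frequency_factor=1.0,
                          name="constriction"),
            ProtocolStage(duration=3.0, cvf=1e-5, epochs=120,
                          frequency_factor=1.0, name="recovery"),
        ],
    }
    paths = {}
    for name, proto in fixtures.items():
        path = directory / f"{name}.txt"
        write_protocol(proto, path)
        paths[name] = path
    return paths
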