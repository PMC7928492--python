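"""Construction of the self-consistent baseline steady state.

The builder starts from target baseline compositions (canonical human red
cell and plasma values) and back-computes the ground leak permeabilities,
the cell anion/proton levels and the impermeant osmolyte pools so that every
net flux is exactly zero and the cell is isotonic with the medium.  Because
the per-species balances close the charge balance identically, the target
membrane potential is reproduced by the zero-current solver without further
adjustment.

Balance structure at the reference state (influx positive):

* Na:  ground leak influx  = 3 r          (r = pump cycle rate)
* K:   conductive efflux   = 2 r          (ground + resting Gardos)
* Ca:  ground leak influx  = PMCA efflux at the target free Ca
* A:   conductive influx   = JS HCl export = 2 x PMCA efflux
* H:   pump 2H influx      = JS export     (sets pHi just off Donnan)
* H2O: cell osmolarity     = medium osmolarity (sets Xi and medium X)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    CellState,
    MediumState,
    ModelError,
    SystemState,
    TransportParams,
    free_calcium,
    ghk_flux,
    nak_pump_flux,
    osmotic_coefficient,
    pack_state,
    pmca_flux,
    gardos_activation,
    solve_membrane_potential,
)

__all__ = ["ReferenceTargets", "build_reference_state", "verify_steady",
           "targets_from_system"]


@dataclass
class ReferenceTargets:
    """Target baseline composition (concentrations per liter water).

    Defaults are canonical healthy human red cell / plasma values.  The
    lumped diffusible anion A- combines Cl- and HCO3-; its cell-side level
    and the cell pH are derived, not targets.
    """

    CNa: float = 10.0  # mmol/L cell water
    CK: float = 140.0
    CaI: float = 3.0e-8  # mol/L free ionized cell Ca2+
    Em: float = -9.0  # mV, resting potential target
    NaO: float = 140.0  # mmol/L medium
    KO: float = 5.0
    AO: float = 127.0  # lumped Cl- + HCO3-
    CaO: float = 1.0  # free ionized medium Ca2+
    pHo: float = 7.4
    MOs: float = 290.0  # mOsm/L
    Vw: float = 0.7  # L water per liter of cells
    Hb: float = 5.25  # mmol/Loc (about 34 g/dL)
    CVF: float = 1e-5
    params: TransportParams = field(default_factory=TransportParams)


def _ghk_unit(z: int, em: float, ci: float, co: float) -> float:
    """GHK flux per unit permeability."""
    return ghk_flux(1.0, z, em, ci, co)


def build_reference_state(targets: ReferenceTargets | None = None
                          ) -> tuple[SystemState, TransportParams]:
    """Build the reference system and the back-computed transport parameters.

    Raises :class:`ModelError` naming the violated species if no
    non-negative permeability set can zero all fluxes for the given targets.
    """
    tg = targets or ReferenceTargets()
    p = replace(tg.params).validated()
    em = tg.Em

    # Na/K pump rate fixed by the targets; ground Na leak balances it.
    pump_na, pump_k = nak_pump_flux(tg.CNa, tg.KO, p)
    g_na = _ghk_unit(1, em, tg.CNa, tg.NaO)
    if pump_na > 0 and g_na <= 0:
        raise ModelError("infeasible targets: Na leak cannot balance the pump")
    p.PNa = pump_na / g_na if pump_na > 0 else 0.0

    # PMCA efflux at the target free Ca; ground Ca leak balances it.
    pmca0, _ = pmca_flux(tg.CaI, p)
    g_ca = _ghk_unit(2, em, tg.CaI * 1e3, tg.CaO)
    if pmca0 > 0 and g_ca <= 0:
        raise ModelError("infeasible targets: Ca leak cannot balance the PMCA")
    p.PCa = pmca0 / g_ca if pmca0 > 0 else 0.0

    # Cell anion level: the conductive anion influx must replace the
    # chloride exported by the JS cycle while it clears the pump protons.
    js_export = 2.0 * pmca0

    def anion_balance(ai: float) -> float:
        return ghk_flux(p.PA, -1, em, ai, tg.AO) - js_export

    a_nernst = tg.AO * math.exp(em / _rt_f())
    lo, hi = 1e-6, max(2.0 * tg.AO, 2.0 * a_nernst)
    if anion_balance(lo) < 0.0:
        raise ModelError("infeasible targets: anion influx cannot match the "
                         "JS export (A)")
    ai = brentq(anion_balance, lo, hi, xtol=1e-12, rtol=8.9e-16)

    # Cell pH from the JS displacement needed to export the pump protons.
    ho = 10.0 ** (-tg.pHo)
    hi_conc = (tg.AO * ho / ai) * (1.0 + js_export / p.kJS)
    pHi = -math.log10(hi_conc)

    # Ground K permeability: conductive K efflux must balance pump K influx.
    g_k = _ghk_unit(1, em, tg.CK, tg.KO)  # negative (efflux) at rest
    if g_k >= 0:
        raise ModelError("infeasible targets: no outward K gradient (K)")
    p_k_needed = pump_k / (-g_k)
    p_gardos0 = p.FKmax * gardos_activation(tg.CaI, p)
    p.PK = p_k_needed - p_gardos0
    if p.PK < 0:
        raise ModelError(
            "infeasible targets: resting Gardos conductance already exceeds "
            "the K leak budget (K)"
        )

    # Impermeant pools from isotonicity on both sides.
    cHb = tg.Hb / tg.Vw
    fhb = osmotic_coefficient(cHb, p)
    ca_free_mmol = tg.CaI * 1e3
    cXi = tg.MOs - (tg.CNa + tg.CK + ai + ca_free_mmol + fhb * cHb)
    if cXi < 0:
        raise ModelError("infeasible targets: cell osmolarity above the "
                         "medium without impermeants (Xi)")
    cXo = tg.MOs - (tg.NaO + tg.KO + tg.AO + tg.CaO)
    if cXo < 0:
        raise ModelError("infeasible targets: medium osmolarity above "
                         "target without impermeants (Xo)")

    qca = tg.CaI * 1e-3 * tg.Vw / p.alpha_ca * 1e6  # invert free_calcium
    cell = CellState(
        Vw=tg.Vw,
        QNa=tg.CNa * tg.Vw,
        QK=tg.CK * tg.Vw,
        QA=ai * tg.Vw,
        QCa=qca,
        pHi=pHi,
        Hb=tg.Hb,
        Xi=cXi * tg.Vw,
        Em=em,
        Vw_ref=tg.Vw,
        pHi_ref=pHi,
    )
    vm = (1.0 - tg.CVF) / tg.CVF
    medium = MediumState(
        MNa=tg.NaO * vm,
        MK=tg.KO * vm,
        MA=tg.AO * vm,
        MCa=tg.CaO * vm,
        MX=cXo * vm,
        Vm=vm,
        pHo=tg.pHo,
    )
    medium.take_snapshot()
    system = SystemState(cell=cell, medium=medium, CVF=tg.CVF, t=0.0)

    # Consistency check: the zero-current solver must land on the target Em.
    em_solved = solve_membrane_potential(system, p, piezo_open=False, guess=em)
    if abs(em_solved - em) > 1e-6:
        raise ModelError(
            f"reference state inconsistent: solved Em {em_solved:.4f} mV "
            f"differs from target {em:.4f} mV"
        )
    cell.Em = em_solved
    return system, p


def _rt_f() -> float:
    from .model_core import RT_F
    return RT_F


def targets_from_system(system: SystemState, params: TransportParams
                        ) -> ReferenceTargets:
    """Read reference targets back from a built system (for idempotence)."""
    c, m = system.cell, system.medium
    return ReferenceTargets(
        CNa=c.CNa,
        CK=c.CK,
        CaI=free_calcium(c.QCa, c.Vw, params),
        Em=c.Em,
        NaO=m.NaO,
        KO=m.KO,
        AO=m.AO,
        CaO=m.CaO,
        pHo=m.pHo,
        MOs=m.MOs,
        Vw=c.Vw,
        Hb=c.Hb,
        CVF=system.CVF,
        params=replace(params),
    )


def verify_steady(system: SystemState, params: TransportParams,
                  duration_s: float) -> float:
    """Integrate a quiet baseline and return the maximum relative drift.

    The drift of each state variable is |change| / max(|initial|, 1e-9);
    the membrane potential is checked on the same relative scale.
    """
    from .protocol_engine import ProtocolStage, run_protocol

    stage = ProtocolStage(duration=duration_s, cvf=system.CVF,
                          epochs=10, frequency_factor=1.0)
    out = run_protocol([stage], system, params)
    df = out.frame
    cols = ["QNa", "QK", "QA", "QCa", "pHi", "Vw", "Em", "RCV"]
    y0 = df.iloc[0][cols].to_numpy(dtype=float)
    drift = 0.0
    for i in range(len(df)):
        yi = df.iloc[i][cols].to_numpy(dtype=float)
        rel = np.abs(yi - y0) / np.maximum(np.abs(y0), 1e-9)
        drift = max(drift, float(rel.max()))
    return drift
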