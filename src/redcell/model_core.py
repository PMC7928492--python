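"""Core state types, flux laws and ODE right-hand side for the red cell model.

The model represents a human red blood cell suspended in a medium of
adjustable relative size (cell volume fraction, CVF).  Cell ion contents are
tracked in mmol per liter of original (baseline) cells ("mmol/Loc"), fluxes
in mmol/Loc per hour ("mmol/Loch"), cell water in liters per liter of
original cells, and the membrane potential in mV.  The membrane potential is
not integrated: charge relaxation is far faster than ion shifts, so Em is
solved algebraically at every evaluation from the zero-net-current condition
over all conductive pathways plus the electrogenic Na/K pump.

Pathways
--------
* Ground electrodiffusive leaks for Na+, K+, Ca2+ and the lumped diffusible
  anion A- (Cl- + HCO3-), each following the Goldman constant-field flux
  equation.
* PIEZO1: four additional electrodiffusive permeabilities (PzCa, PzNa, PzK,
  PzA) switched on only while the channel open-state flag is set.
* Gardos channel: a K+ conductance whose effective permeability is the
  maximal value FKmax scaled by a Hill function of free intracellular Ca2+.
* PMCA: saturable, electroneutral Ca2+:2H+ exchange.
* Na/K pump: saturable, 3 Na out : 2 K in (electrogenic).
* Jacobs-Stewart mechanism: electroneutral Cl-:H+ cotransport, first order
  in the displacement of the [Cl][H] product from Donnan equilibrium.
* Water: kinetic osmotic flux Fw = Lp * (COs - MOs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RT_F",
    "TransportParams",
    "CellState",
    "MediumState",
    "SystemState",
    "Fluxes",
    "WaterFluxDecomposition",
    "ModelError",
    "MembranePotentialError",
    "ghk_flux",
    "gardos_activation",
    "gardos_flux",
    "pmca_flux",
    "js_flux",
    "nak_pump_flux",
    "osmotic_coefficient",
    "cell_osmolarity",
    "water_flux",
    "free_calcium",
    "solve_membrane_potential",
    "system_derivatives",
    "decompose_water_flux",
    "pack_state",
    "unpack_state",
    "N_STATES",
]

# Thermodynamic constant RT/F at 37 C, in mV.
R_GAS = 8.31446261815324  # J/(mol K)
FARADAY = 96485.33212  # C/mol
TEMPERATURE = 310.15  # K
RT_F = R_GAS * TEMPERATURE / FARADAY * 1000.0  # mV

# Hard limit used to diagnose integrator blow-up.
EM_LIMIT = 400.0  # mV
# Bracket for the zero-current membrane potential search.
EM_BRACKET = (-150.0, 150.0)


class ModelError(ValueError):
    """Invalid model input (negative concentration, bad parameter...)."""


class MembranePotentialError(RuntimeError):
    """No zero-current membrane potential in the physical bracket."""


# ---------------------------------------------------------------------------
# Parameters and state containers
# ---------------------------------------------------------------------------


@dataclass
class TransportParams:
    """Transport and closure parameters.

    Permeabilities are in h^-1, pump maxima in mmol/Loch, Michaelis/Hill
    constants in mol/L (free Ca) or mmol/L (pump Na/K sites).  ``PNa``,
    ``PK`` and ``PCa`` are normally back-computed by the reference-state
    builder so that the baseline is an exact steady state.
    """

    # PIEZO1 open-state permeabilities and open-state duration
    PzCa: float = 70.0
    PzNa: float = 0.0
    PzK: float = 0.0
    PzA: float = 50.0
    OS: float = 0.4  # s

    # Ground electrodiffusive leaks (PNa/PK/PCa filled by the builder)
    PNa: float = 0.0165
    PK: float = 0.0153
    PA: float = 1.2
    PCa: float = 1.16

    # PMCA (electroneutral Ca2+:2H+ exchange)
    FCamax: float = 12.0  # mmol/Loch
    KmCa: float = 3.0e-7  # mol/L free Ca

    # Gardos channel
    FKmax: float = 0.2  # h^-1, maximal effective K+ permeability
    KCaGardos: float = 5.0e-6  # mol/L free Ca
    nHill: float = 2.0

    # Jacobs-Stewart Cl-:H+ cotransport
    kJS: float = 1000.0  # mmol/Loch per unit relative displacement

    # Na/K pump
    FNaKmax: float = 7.8  # mmol/Loch maximal Na extrusion
    KmNaPump: float = 3.3  # mmol/L cell Na
    KmKPump: float = 0.65  # mmol/L medium K

    # Water permeability, L/(Loc * mOsm/L * h)
    Lp: float = 4.0

    # Ca buffering: free CaI = alpha_ca * QCa / Vw (effective dynamic
    # free fraction of the rapidly exchanging Ca pool)
    alpha_ca: float = 0.3

    # Haemoglobin osmotic virial coefficients (per mmol/L water)
    virial_b1: float = 0.0645
    virial_b2: float = 0.0258

    # Proton buffering slopes: cell, mmol H per mmol Hb per pH unit;
    # medium, mmol H per liter medium per pH unit.
    hb_buffer: float = 10.0
    medium_buffer: float = 25.0

    def validated(self) -> "TransportParams":
        for name in (
            "PzCa", "PzNa", "PzK", "PzA", "OS", "PNa", "PK", "PA", "PCa",
            "FCamax", "KmCa", "FKmax", "KCaGardos", "nHill", "kJS",
            "FNaKmax", "KmNaPump", "KmKPump", "Lp", "alpha_ca",
        ):
            if getattr(self, name) < 0:
                raise ModelError(f"parameter {name} must be non-negative")
        return self


@dataclass
class CellState:
    """Intracellular state, amounts in mmol per liter of original cells."""

    Vw: float  # L water / Loc
    QNa: float
    QK: float
    QA: float
    QCa: float  # total (free + buffered) calcium
    pHi: float
    Hb: float  # mmol/Loc, fixed
    Xi: float  # impermeant non-Hb osmolytes, mmol/Loc, fixed
    Em: float = 0.0  # last zero-current solution, mV
    Vw_ref: float = 0.7  # baseline water volume, defines RCV = 1
    pHi_ref: float = 7.24

    @property
    def CNa(self) -> float:
        return self.QNa / self.Vw

    @property
    def CK(self) -> float:
        return self.QK / self.Vw

    @property
    def CA(self) -> float:
        return self.QA / self.Vw

    @property
    def cHb(self) -> float:
        return self.Hb / self.Vw

    @property
    def RCV(self) -> float:
        """Relative cell volume; total cell volume is water + fixed solids."""
        return self.Vw + (1.0 - self.Vw_ref)

    @property
    def QH(self) -> float:
        """Titration proton load relative to the reference, mmol/Loc.

        Free protons are ~1e-5 mmol/Loc and are negligible next to the
        haemoglobin-bound pool, so the load is the linear-buffer bound term.
        """
        return -(self.pHi - self.pHi_ref)

    def copy(self) -> "CellState":
        return replace(self)


@dataclass
class MediumState:
    """Extracellular compartment, tracked as amounts per liter original cells.

    ``Vm`` is the medium water volume per Loc, set by the cell volume
    fraction: Vm = (1 - CVF)/CVF.  Tracking amounts (not concentrations)
    makes cell+medium mass conservation exact by construction.
    """

    MNa: float
    MK: float
    MA: float
    MCa: float
    MX: float  # impermeant medium osmolytes (amount)
    Vm: float
    pHo: float
    snapshot: Optional[dict] = field(default=None, repr=False)

    @property
    def NaO(self) -> float:
        return self.MNa / self.Vm

    @property
    def KO(self) -> float:
        return self.MK / self.Vm

    @property
    def AO(self) -> float:
        return self.MA / self.Vm

    @property
    def CaO(self) -> float:
        return self.MCa / self.Vm

    @property
    def XO(self) -> float:
        return self.MX / self.Vm

    @property
    def MOs(self) -> float:
        """Medium osmolarity, mOsm/L (ideal solutes)."""
        return (self.MNa + self.MK + self.MA + self.MCa + self.MX) / self.Vm

    @property
    def HO(self) -> float:
        """Free medium proton concentration, mol/L."""
        return 10.0 ** (-self.pHo)

    def take_snapshot(self) -> None:
        self.snapshot = {
            "NaO": self.NaO, "KO": self.KO, "AO": self.AO,
            "CaO": self.CaO, "XO": self.XO, "pHo": self.pHo,
        }

    def restore(self) -> None:
        """Reset composition to the stored baseline snapshot (cell untouched)."""
        if self.snapshot is None:
            raise ModelError("restore medium requested but no snapshot stored")
        s = self.snapshot
        self.MNa = s["NaO"] * self.Vm
        self.MK = s["KO"] * self.Vm
        self.MA = s["AO"] * self.Vm
        self.MCa = s["CaO"] * self.Vm
        self.MX = s["XO"] * self.Vm
        self.pHo = s["pHo"]

    def rescale_to_cvf(self, cvf: float) -> None:
        """Switch to a new CVF preserving concentrations (new reservoir)."""
        if not 0.0 < cvf < 1.0:
            raise ModelError("CVF must lie in (0, 1)")
        vm_new = (1.0 - cvf) / cvf
        f = vm_new / self.Vm
        self.MNa *= f
        self.MK *= f
        self.MA *= f
        self.MCa *= f
        self.MX *= f
        self.Vm = vm_new

    def copy(self) -> "MediumState":
        m = replace(self)
        m.snapshot = dict(self.snapshot) if self.snapshot else None
        return m


@dataclass
class SystemState:
    cell: CellState
    medium: MediumState
    CVF: float = 1e-5
    t: float = 0.0  # hours

    def copy(self) -> "SystemState":
        return SystemState(self.cell.copy(), self.medium.copy(), self.CVF, self.t)


@dataclass
class Fluxes:
    """Per-pathway fluxes at one instant, mmol/Loch, influx positive."""

    na_leak: float = 0.0
    na_piezo: float = 0.0
    k_leak: float = 0.0
    k_piezo: float = 0.0
    k_gardos: float = 0.0
    a_leak: float = 0.0
    a_piezo: float = 0.0
    ca_leak: float = 0.0
    ca_piezo: float = 0.0
    pmca_ca: float = 0.0  # Ca2+ efflux, positive outward
    pump_na: float = 0.0  # Na+ efflux, positive outward
    pump_k: float = 0.0  # K+ influx
    js: float = 0.0  # HCl influx (negative = HCl extrusion)
    fw: float = 0.0  # L/Loch water influx
    Em: float = 0.0
    COs: float = 0.0
    MOs: float = 0.0

    @property
    def current(self) -> float:
        """Net charge influx (mmol charge/Loch); zero at the solved Em."""
        return (
            self.na_leak + self.na_piezo
            + self.k_leak + self.k_piezo + self.k_gardos
            + 2.0 * (self.ca_leak + self.ca_piezo)
            - (self.a_leak + self.a_piezo)
            - (self.pump_na - self.pump_k)
        )


@dataclass
class WaterFluxDecomposition:
    """Net water flux and its pathway attribution, L/Loch.

    W2-W4 are the isotonically equivalent fluid-loss rates of the Gardos,
    PMCA and Jacobs-Stewart solute fluxes (positive outward), each taken in
    excess of its share of the resting pump-leak recirculation so that all
    components vanish at the reference steady state.  W1 is the balance
    Fw + W2 + W3 + W4: the PIEZO1-led fluid gain during the open state, and
    the residual osmotic relaxation outside it.  The identity
    Fw = W1 - (W2 + W3 + W4) holds exactly by construction.
    """

    Fw: float
    W1: float
    W2: float
    W3: float
    W4: float


# ---------------------------------------------------------------------------
# Flux laws
# ---------------------------------------------------------------------------


def ghk_flux(P: float, z: int, Em: float, ci: float, co: float) -> float:
    """Goldman constant-field flux, influx positive.

    Parameters
    ----------
    P : permeability, h^-1.
    z : ion valence.
    Em : membrane potential, mV.
    ci, co : internal/external concentrations (any common unit; the flux is
        returned in P * concentration units per hour).

    Returns the analytic Em -> 0 limit ``P * (co - ci)`` at zero potential.
    """
    if P < 0:
        raise ModelError("permeability must be non-negative")
    if ci < 0 or co < 0:
        raise ModelError("negative concentration in ghk_flux")
    if abs(Em) > EM_LIMIT:
        raise ModelError(
            f"membrane potential {Em:.1f} mV beyond +/-{EM_LIMIT:.0f} mV "
            "(integrator blow-up?)"
        )
    u = z * Em / RT_F
    if u == 0.0:
        return P * (co - ci)
    if abs(u) < 1e-10:
        # series of u/(e^u - 1) and e^u, avoids 0/0 at tiny potentials
        return P * ((co - ci) - u * (co + ci) / 2.0)
    em1 = math.expm1(u)
    return P * u * (co - ci * math.exp(u)) / em1


def gardos_activation(CaI: float, params: TransportParams) -> float:
    """Hill-type fractional activation of the Gardos channel by free Ca2+."""
    if CaI < 0:
        raise ModelError("negative free calcium")
    if CaI == 0.0:
        return 0.0
    r = (CaI / params.KCaGardos) ** params.nHill
    return r / (1.0 + r)


def gardos_flux(CaI: float, params: TransportParams, Em: float,
                KI: float, KO: float) -> float:
    """Ca2+-activated K+ flux (mmol/Loch, influx positive)."""
    if params.FKmax == 0.0:
        return 0.0
    p_eff = params.FKmax * gardos_activation(CaI, params)
    return ghk_flux(p_eff, 1, Em, KI, KO)


def pmca_flux(CaI: float, params: TransportParams) -> tuple[float, float]:
    """PMCA as electroneutral Ca2+:2H+ exchange.

    Returns ``(ca_efflux, h_influx)`` in mmol/Loch; the proton influx is
    twice the calcium efflux.
    """
    if CaI < 0:
        raise ModelError("negative free calcium")
    ca_out = params.FCamax * CaI / (CaI + params.KmCa)
    return ca_out, 2.0 * ca_out


def js_flux(ClI: float, ClO: float, HI: float, HO: float, kJS: float) -> float:
    """Jacobs-Stewart electroneutral Cl-:H+ cotransport, influx positive.

    First order in the relative displacement of the [Cl][H] product from its
    Donnan equilibrium: flux = kJS * (ClO*HO - ClI*HI) / (ClO*HO).
    """
    if min(ClI, ClO, HI, HO) < 0:
        raise ModelError("negative concentration in js_flux")
    ref = ClO * HO
    if ref == 0.0:
        return 0.0
    return kJS * (ref - ClI * HI) / ref


def nak_pump_flux(NaI: float, KO: float, params: TransportParams
                  ) -> tuple[float, float]:
    """Na/K pump: returns ``(na_efflux, k_influx)``, 3:2 stoichiometry."""
    if NaI < 0 or KO < 0:
        raise ModelError("negative concentration in nak_pump_flux")
    sat = (NaI / (NaI + params.KmNaPump)) ** 3 * (KO / (KO + params.KmKPump)) ** 2
    na_out = params.FNaKmax * sat
    return na_out, 2.0 * na_out / 3.0


def osmotic_coefficient(cHb: float, params: TransportParams) -> float:
    """Nonideal haemoglobin osmotic coefficient (virial polynomial, >= 1)."""
    if cHb < 0:
        raise ModelError("negative haemoglobin concentration")
    return 1.0 + params.virial_b1 * cHb + params.virial_b2 * cHb * cHb


def free_calcium(QCa: float, Vw: float, params: TransportParams) -> float:
    """Free ionized intracellular Ca2+ (mol/L cell water).

    Constant-ratio buffering: free = alpha_ca * total concentration.
    """
    return params.alpha_ca * (QCa / Vw) * 1e-3


def cell_osmolarity(cell: CellState, params: TransportParams) -> float:
    """Cell osmolarity, mOsm/L cell water.

    Counts Na, K, A and the impermeant pool ideally, haemoglobin with its
    virial osmotic coefficient, and only the free fraction of calcium
    (buffer-bound Ca is osmotically silent).
    """
    ca_free = free_calcium(cell.QCa, cell.Vw, params) * 1e3  # mmol/L
    ideal = (cell.QNa + cell.QK + cell.QA + cell.Xi) / cell.Vw + ca_free
    return ideal + osmotic_coefficient(cell.cHb, params) * cell.cHb


def water_flux(COs: float, MOs: float, Lp: float) -> float:
    """Osmotic water flux Fw = Lp * (COs - MOs), L/Loch, influx positive."""
    if COs <= 0 or MOs <= 0:
        raise ModelError("osmolarities must be positive")
    return Lp * (COs - MOs)


# ---------------------------------------------------------------------------
# Membrane potential
# ---------------------------------------------------------------------------


def _membrane_current(Em: float, system: SystemState, params: TransportParams,
                      piezo_open: bool) -> float:
    """Net charge influx across all conductive pathways + pump, mmol/Loch."""
    cell, med = system.cell, system.medium
    cai = free_calcium(cell.QCa, cell.Vw, params)
    p_na = params.PNa + (params.PzNa if piezo_open else 0.0)
    p_k = params.PK + (params.PzK if piezo_open else 0.0)
    p_a = params.PA + (params.PzA if piezo_open else 0.0)
    p_ca = params.PCa + (params.PzCa if piezo_open else 0.0)
    p_k_total = p_k + params.FKmax * gardos_activation(cai, params)

    i_na = ghk_flux(p_na, 1, Em, cell.CNa, med.NaO)
    i_k = ghk_flux(p_k_total, 1, Em, cell.CK, med.KO)
    i_ca = ghk_flux(p_ca, 2, Em, cai * 1e3, med.CaO)
    i_a = ghk_flux(p_a, -1, Em, cell.CA, med.AO)
    pump_na, pump_k = nak_pump_flux(cell.CNa, med.KO, params)
    return i_na + i_k + 2.0 * i_ca - i_a - (pump_na - pump_k)


def solve_membrane_potential(system: SystemState, params: TransportParams,
                             piezo_open: bool = False,
                             guess: Optional[float] = None) -> float:
    """Zero-net-current membrane potential, mV.

    Solves ``sum_pathways z * flux = 0`` by bracketed root finding.  When a
    previous solution is supplied as ``guess`` a narrow bracket around it is
    tried first (the potential moves by millivolts at most between
    integrator steps), falling back to the full physical bracket.
    """

    def f(em: float) -> float:
        return _membrane_current(em, system, params, piezo_open)

    if guess is not None and EM_BRACKET[0] < guess < EM_BRACKET[1]:
        half = 0.5
        while half <= 64.0:
            lo = max(guess - half, EM_BRACKET[0])
            hi = min(guess + half, EM_BRACKET[1])
            flo, fhi = f(lo), f(hi)
            if flo == 0.0:
                return lo
            if fhi == 0.0:
                return hi
            if flo * fhi < 0.0:
                return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
            half *= 4.0
    lo, hi = EM_BRACKET
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0.0:
        raise MembranePotentialError(
            "no electroneutral solution: membrane current does not change "
            f"sign in [{lo:.0f}, {hi:.0f}] mV"
        )
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)


# ---------------------------------------------------------------------------
# Assembled derivatives
# ---------------------------------------------------------------------------

# State vector layout (hours, mmol/Loc, L/Loc, pH units):
# [QNa, QK, QA, QCa, pHi, Vw, MNa, MK, MA, MCa, pHo, Vm]
N_STATES = 12


def pack_state(system: SystemState) -> np.ndarray:
    c, m = system.cell, system.medium
    return np.array([
        c.QNa, c.QK, c.QA, c.QCa, c.pHi, c.Vw,
        m.MNa, m.MK, m.MA, m.MCa, m.pHo, m.Vm,
    ])


def unpack_state(y: np.ndarray, system: SystemState) -> SystemState:
    """Write a state vector back into ``system`` (mutated in place)."""
    c, m = system.cell, system.medium
    (c.QNa, c.QK, c.QA, c.QCa, c.pHi, c.Vw,
     m.MNa, m.MK, m.MA, m.MCa, m.pHo, m.Vm) = y
    return system


def compute_fluxes(system: SystemState, params: TransportParams,
                   piezo_open: bool = False,
                   em_guess: Optional[float] = None) -> Fluxes:
    """Solve Em and evaluate every pathway flux at the current state."""
    cell, med = system.cell, system.medium
    em = solve_membrane_potential(system, params, piezo_open, guess=em_guess)
    cell.Em = em
    cai = free_calcium(cell.QCa, cell.Vw, params)

    fl = Fluxes(Em=em)
    fl.na_leak = ghk_flux(params.PNa, 1, em, cell.CNa, med.NaO)
    fl.k_leak = ghk_flux(params.PK, 1, em, cell.CK, med.KO)
    fl.a_leak = ghk_flux(params.PA, -1, em, cell.CA, med.AO)
    fl.ca_leak = ghk_flux(params.PCa, 2, em, cai * 1e3, med.CaO)
    if piezo_open:
        fl.na_piezo = ghk_flux(params.PzNa, 1, em, cell.CNa, med.NaO)
        fl.k_piezo = ghk_flux(params.PzK, 1, em, cell.CK, med.KO)
        fl.a_piezo = ghk_flux(params.PzA, -1, em, cell.CA, med.AO)
        fl.ca_piezo = ghk_flux(params.PzCa, 2, em, cai * 1e3, med.CaO)
    fl.k_gardos = gardos_flux(cai, params, em, cell.CK, med.KO)
    fl.pmca_ca, _ = pmca_flux(cai, params)
    fl.pump_na, fl.pump_k = nak_pump_flux(cell.CNa, med.KO, params)
    hi = 10.0 ** (-cell.pHi)
    fl.js = js_flux(cell.CA, med.AO, hi, med.HO, params.kJS)
    fl.COs = cell_osmolarity(cell, params)
    fl.MOs = med.MOs
    fl.fw = water_flux(fl.COs, fl.MOs, params.Lp)
    return fl


def system_derivatives(system: SystemState, params: TransportParams,
                       piezo_open: bool = False,
                       em_guess: Optional[float] = None
                       ) -> tuple[np.ndarray, Fluxes]:
    """Time derivatives of the full state vector, units per hour.

    Membrane fluxes move matter between the cell and the medium amounts
    one-for-one, so cell+medium totals of every species (and of water) are
    conserved identically.
    """
    fl = compute_fluxes(system, params, piezo_open, em_guess=em_guess)
    cell, med = system.cell, system.medium

    dQNa = fl.na_leak + fl.na_piezo - fl.pump_na
    dQK = fl.k_leak + fl.k_piezo + fl.k_gardos + fl.pump_k
    dQA = fl.a_leak + fl.a_piezo + fl.js
    dQCa = fl.ca_leak + fl.ca_piezo - fl.pmca_ca
    # proton influx: JS HCl entry + 2 H+ per Ca2+ pumped out
    h_in = fl.js + 2.0 * fl.pmca_ca
    buf = params.hb_buffer * cell.Hb
    dpHi = -h_in / buf
    dVw = fl.fw

    dMNa, dMK, dMA, dMCa = -dQNa, -dQK, -dQA, -dQCa
    dpHo = h_in / (params.medium_buffer * med.Vm)
    dVm = -dVw

    dy = np.array([dQNa, dQK, dQA, dQCa, dpHi, dVw,
                   dMNa, dMK, dMA, dMCa, dpHo, dVm])
    return dy, fl


def decompose_water_flux(system: SystemState, params: TransportParams,
                         piezo_open: bool = False) -> WaterFluxDecomposition:
    """Attribute the net water flux to the four transit-relevant pathways.

    W2 (Gardos) is the isotonic fluid equivalent of the KCl pair flux
    through the channel; W3 (PMCA) of the net calcium extrusion (pump minus
    ground leak, CaCl2 equivalent); W4 (JS) of the HCl export in excess of
    the protons recirculated by the pump.  W1 closes the balance so that
    Fw = W1 - (W2 + W3 + W4) exactly.
    """
    fl = compute_fluxes(system, params, piezo_open)
    osm = fl.MOs
    w2 = 2.0 * (-fl.k_gardos) / osm
    w3 = 2.0 * (fl.pmca_ca - fl.ca_leak) / osm
    w4 = 2.0 * (-fl.js - 2.0 * fl.pmca_ca) / osm
    w1 = fl.fw + w2 + w3 + w4
    return WaterFluxDecomposition(Fw=fl.fw, W1=w1, W2=w2, W3=w3, W4=w4)
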