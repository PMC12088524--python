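"""Single-compartment non-spiking neuron model.

Each model cell is a passive resistor-capacitor compartment carrying a leak
conductance and a single non-inactivating voltage-gated Ca2+ channel.  The
cell does not spike; depolarising input instead recruits the Ca2+ channel and
produces a slow plateau-like potential.  Ca2+ entering through the channel
accumulates in a restricted intracellular pool, from which it is cleared
first-order back to a floor concentration; the instantaneous pool
concentration both sets the channel's Nernst reversal and drives graded
transmitter release (see :mod:`larvacpg.synapse`).

State updates use the exponential-Euler scheme: over one step each variable
relaxes exponentially toward the steady state implied by holding everything
else fixed, which is exact for piecewise-constant coefficients and
unconditionally stable at the default 1 ms step.

Sign convention: membrane currents are positive-outward, so the inward
calcium current is negative and calcium *inflow* is proportional to -I_Ca
(floored at zero: an outward channel current does not deplete the pool).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import units

__all__ = [
    "NeuronParameters",
    "NeuronState",
    "nernst_potential",
    "steady_state_activation",
    "step_activation",
    "channel_current",
    "step_calcium",
    "step_membrane_potential",
    "initial_state",
]

# Effective scale applied to the calcium inflow factor B.  The printed unit of
# B (mM s^-1 nA^-1) taken literally drives the calcium pool many orders of
# magnitude above the ~200 nM release midpoints, so the inflow factor is
# exposed as B * b_scale with b_scale calibrated once on the single
# hemisegmental-oscillator benchmark (silent at rest, sustained oscillation
# under tonic command drive, single cycle per brief pulse).  See
# docs/methods.md for the calibration procedure.
DEFAULT_B_SCALE = 1.0e-2


@dataclass(frozen=True)
class NeuronParameters:
    """Passive, calcium-channel, and calcium-pool parameters of one cell.

    All cells in the published circuits share these defaults ("physiologically
    identical"); the dataclass exists so experiments can perturb single cells.
    """

    diameter: float = 10.0  # um, spherical compartment
    C_m: float = 1.0  # uF cm^-2
    g_leak: float = 0.35  # mS cm^-2
    V_leak_eq: float = -60.0  # mV
    g_Ca_max: float = 0.08  # mS cm^-2
    V_mid: float = -40.0  # mV, half-activation of the Ca channel
    S_Ca: float = 7.5  # mV, activation slope sensitivity
    tau_m: float = 50.0  # ms, activation time constant
    B: float = 1000.0  # calcium inflow factor (nominal printed magnitude)
    b_scale: float = DEFAULT_B_SCALE  # calibrated scale, see module docstring
    tau_Ca_clr: float = 400.0  # ms, calcium clearance time constant
    Ca_i_min: float = 0.1  # nM, clearance floor
    Ca_i_init: float = 20.0  # nM, initial pool concentration
    Ca_e: float = 2.0  # mM, extracellular calcium
    temperature: float = 294.0  # K

    def __post_init__(self) -> None:
        for name in (
            "diameter", "C_m", "g_leak", "tau_m", "tau_Ca_clr",
            "S_Ca", "Ca_e", "temperature", "Ca_i_min", "b_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.g_Ca_max < 0 or self.B < 0:
            raise ValueError("g_Ca_max and B must be non-negative")

    # -- derived totals ----------------------------------------------------
    @property
    def area(self) -> float:
        """Membrane area in cm^2 (sphere surface pi * d^2)."""
        return units.sphere_area_cm2(self.diameter)

    @property
    def g_leak_total(self) -> float:
        """Total leak conductance in uS."""
        return self.g_leak * self.area * units.MS_TO_US

    @property
    def g_Ca_total(self) -> float:
        """Total maximal Ca-channel conductance in uS."""
        return self.g_Ca_max * self.area * units.MS_TO_US

    @property
    def C_total(self) -> float:
        """Total membrane capacitance in nF."""
        return self.C_m * self.area * units.UF_TO_NF

    @property
    def B_eff(self) -> float:
        """Effective inflow factor, nM ms^-1 nA^-1."""
        return self.B * self.b_scale

    def with_(self, **kwargs) -> "NeuronParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Dynamic variables of one cell.

    ``E_Ca`` is a cache of the Nernst potential at the current ``Ca_i``; it is
    refreshed whenever ``Ca_i`` changes.
    """

    V_m: float  # mV
    m: float  # Ca-channel activation gate, [0, 1]
    Ca_i: float  # nM
    E_Ca: float  # mV


def nernst_potential(Ca_i: float, Ca_e: float, temperature: float) -> float:
    """Calcium equilibrium potential in mV.

    Parameters
    ----------
    Ca_i : intracellular concentration, nM.
    Ca_e : extracellular concentration, mM.
    temperature : absolute temperature, K.
    """
    if Ca_i <= 0 or Ca_e <= 0:
        raise ValueError("concentrations must be strictly positive")
    ratio = (Ca_e * units.MM_TO_NM) / Ca_i
    return units.nernst_prefactor_mv(temperature) * math.log(ratio)


def steady_state_activation(V_m: float, V_mid: float, S_Ca: float) -> float:
    """Logistic steady-state open probability of the Ca-channel gate."""
    if S_Ca <= 0:
        raise ValueError("S_Ca must be strictly positive")
    return 1.0 / (1.0 + math.exp((V_mid - V_m) / S_Ca))


def step_activation(m: float, m_inf: float, tau_m: float, dt: float) -> float:
    """One exponential-Euler relaxation of the gate toward ``m_inf``."""
    return m_inf + (m - m_inf) * math.exp(-dt / tau_m)


def channel_current(
    g_max_density: float,
    control: float,
    area: float,
    V_m: float,
    E_eq: float,
) -> float:
    """Ohmic channel current in nA, positive outward.

    ``control`` is the conductance control factor in [0, 1]; the channel's
    instantaneous conductance is ``control * g_max_density * area``.
    """
    g_total_us = control * g_max_density * area * units.MS_TO_US
    return g_total_us * (V_m - E_eq)


def step_calcium(
    Ca_i: float,
    I_Ca: float,
    B_eff: float,
    tau_Ca_clr: float,
    Ca_i_min: float,
    dt: float,
) -> float:
    """Advance the intracellular calcium pool by one step.

    dCa/dt = B_eff * max(0, -I_Ca) - (Ca - Ca_i_min)/tau_Ca_clr, integrated
    exponentially with the inflow held constant over the step.  Inward current
    (negative under the outward-positive convention) raises the pool;
    outward current contributes nothing.
    """
    inflow = B_eff * max(0.0, -I_Ca)  # nM ms^-1
    ca_target = Ca_i_min + inflow * tau_Ca_clr
    ca_next = ca_target + (Ca_i - ca_target) * math.exp(-dt / tau_Ca_clr)
    return max(ca_next, Ca_i_min)


def step_membrane_potential(
    state: NeuronState,
    params: NeuronParameters,
    extra_conductances: tuple[tuple[float, float], ...] = (),
    I_stim: float = 0.0,
    dt: float = 1.0,
) -> float:
    """Exponential-Euler update of the membrane potential, returning mV.

    ``extra_conductances`` is a sequence of ``(g_total_uS, E_mV)`` pairs for
    synaptic and optogenetic channels; the leak and the Ca channel (at the
    state's current gate value and cached E_Ca) are included automatically.
    With all conductances and reversals frozen over the step, the update is
    the exact relaxation toward the conductance-weighted reversal offset by
    I_stim / g_total.
    """
    g_sum = params.g_leak_total + state.m * params.g_Ca_total
    gE_sum = (
        params.g_leak_total * params.V_leak_eq
        + state.m * params.g_Ca_total * state.E_Ca
    )
    for g, e in extra_conductances:
        if g < 0:
            raise ValueError("conductances must be non-negative")
        g_sum += g
        gE_sum += g * e
    v_inf = (gE_sum + I_stim) / g_sum
    return v_inf + (state.V_m - v_inf) * math.exp(-dt * g_sum / params.C_total)


def initial_state(params: NeuronParameters) -> NeuronState:
    """Silent-rest-consistent initial conditions.

    V starts at the leak reversal, the gate at its steady state for that
    voltage, and the calcium pool at its stated initial concentration with the
    Nernst reversal computed from it.
    """
    v0 = params.V_leak_eq
    return NeuronState(
        V_m=v0,
        m=steady_state_activation(v0, params.V_mid, params.S_Ca),
        Ca_i=params.Ca_i_init,
        E_Ca=nernst_potential(params.Ca_i_init, params.Ca_e, params.temperature),
    )
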