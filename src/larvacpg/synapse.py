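"""Graded chemical synapses and the simulated optogenetic chloride channel.

Transmitter is released into the cleft at a rate that is a sigmoid function of
the *presynaptic* intracellular calcium concentration and cleared first-order
with a fixed time constant; no spikes are involved.  The postsynaptic
conductance control factor is an upper-half sigmoid of the nominal cleft
transmitter concentration (zero transmitter, closed gate; saturating toward
fully open).  A per-connection gain multiplies the postsynaptic conductance
after it has been computed, which is how the detector motifs' doubled
inhibitory synapses are expressed.

The optogenetic channel models a light-gated anion conductance: a fixed
chloride conductance (reversal -70 mV) that is completely blocked except
during scheduled "illumination" windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from . import units

__all__ = [
    "SynapseParameters",
    "SynapseState",
    "OptoChannel",
    "excitatory",
    "inhibitory",
    "release_rate",
    "step_transmitter",
    "receptor_gate",
    "synaptic_current",
    "optogenetic_current",
]

# Reversal potentials and release midpoints by polarity.  The calcium
# midpoints follow the Methods prose assignment (excitatory 200 nM,
# inhibitory 185 nM); both values are plain dataclass fields, so the opposite
# assignment is a one-line change in any experiment.
EXC_REVERSAL_MV = -10.0
INH_REVERSAL_MV = -70.0
EXC_CA_MID_NM = 200.0
INH_CA_MID_NM = 185.0

Polarity = Literal["excitatory", "inhibitory"]


@dataclass(frozen=True)
class SynapseParameters:
    """Kinetic and conductance parameters of one directed graded connection."""

    polarity: Polarity = "excitatory"
    V_syn_eq: float = EXC_REVERSAL_MV  # mV
    r_max: float = 80.0  # maximum release rate (20 for midline coupling)
    # The cleft transmitter T is on an unspecified nominal unit scale; r_scale
    # fixes that scale relative to the per-ms integration of dT/dt.  The
    # default (calibrated once, with the calcium-inflow scale, on the single
    # HO and the abdominal chain) places the rest-calcium tail of the release
    # sigmoid far below the receptor binding sensitivity while plateau-level
    # calcium drives the gate through its operating range: silence at rest,
    # conditional oscillation, and full-chain wave propagation all depend on
    # this scale.  See docs/methods.md.
    r_scale: float = 2e-3
    Ca_i_mid: float = EXC_CA_MID_NM  # nM, presynaptic Ca at half-max release
    S_r: float = 15.0  # nM, release slope sensitivity
    tau_T_clr: float = 250.0  # ms, transmitter clearance time constant
    S_bind: float = 0.5  # receptor binding sensitivity (transmitter units)
    g_syn_max: float = 1.0  # mS cm^-2, maximal postsynaptic conductance density
    gain: float = 1.0  # connection gain multiplier (2 on detector outputs)

    def __post_init__(self) -> None:
        for name in ("r_max", "r_scale", "S_r", "tau_T_clr", "S_bind",
                     "g_syn_max", "gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def with_(self, **kwargs) -> "SynapseParameters":
        return replace(self, **kwargs)


def excitatory(**kwargs) -> SynapseParameters:
    """Excitatory synapse with default reversal and release midpoint."""
    kwargs.setdefault("V_syn_eq", EXC_REVERSAL_MV)
    kwargs.setdefault("Ca_i_mid", EXC_CA_MID_NM)
    return SynapseParameters(polarity="excitatory", **kwargs)


def inhibitory(**kwargs) -> SynapseParameters:
    """Inhibitory synapse with default reversal and release midpoint."""
    kwargs.setdefault("V_syn_eq", INH_REVERSAL_MV)
    kwargs.setdefault("Ca_i_mid", INH_CA_MID_NM)
    return SynapseParameters(polarity="inhibitory", **kwargs)


@dataclass
class SynapseState:
    """Cleft transmitter concentration and postsynaptic gate of one connection."""

    T: float = 0.0  # nominal cleft transmitter concentration, >= 0
    m_syn: float = 0.0  # postsynaptic conductance control factor, [0, 1)


@dataclass(frozen=True)
class OptoChannel:
    """Normally-blocked chloride conductance used to silence inhibitors.

    The channel conducts only while unblocked; the unblock schedule itself
    lives in the stimulus protocol (opto windows) so a single blueprint can be
    reused across illumination protocols.
    """

    g_opto_Cl: float = 0.2  # mS cm^-2 (0.2 or 0.8 in the published experiments)
    E_opto: float = -70.0  # mV

    def __post_init__(self) -> None:
        if self.g_opto_Cl < 0:
            raise ValueError("g_opto_Cl must be non-negative")


def release_rate(
    Ca_i_pre: float, r_max: float, Ca_i_mid: float, S_r: float
) -> float:
    """Transmitter release rate (ms^-1), sigmoid in presynaptic calcium."""
    if Ca_i_pre < 0:
        raise ValueError("presynaptic calcium must be non-negative")
    return r_max / (1.0 + math.exp((Ca_i_mid - Ca_i_pre) / S_r))


def step_transmitter(T: float, rate: float, tau_T_clr: float, dt: float) -> float:
    """Advance cleft transmitter one step: dT/dt = rate - T / tau_T_clr.

    Exponential relaxation toward the balance point rate * tau_T_clr with the
    release rate held constant over the step; never negative.
    """
    t_target = rate * tau_T_clr
    t_next = t_target + (T - t_target) * math.exp(-dt / tau_T_clr)
    return max(t_next, 0.0)


def receptor_gate(T: float, S_bind: float) -> float:
    """Postsynaptic conductance control factor, upper-half sigmoid of T."""
    if T < 0:
        raise ValueError("transmitter concentration must be non-negative")
    return 2.0 / (1.0 + math.exp(-T / S_bind)) - 1.0


def synaptic_current(
    m_syn: float,
    g_syn_max: float,
    gain: float,
    post_area: float,
    V_post: float,
    V_syn_eq: float,
) -> float:
    """Postsynaptic current in nA (positive outward).

    The gain multiplies the conductance after the gate has been computed, so a
    gain of 2 exactly doubles the current at fixed state.
    """
    g_total_us = gain * m_syn * g_syn_max * post_area * units.MS_TO_US
    return g_total_us * (V_post - V_syn_eq)


def optogenetic_current(
    chan: OptoChannel, area: float, V_post: float, unblocked: bool
) -> float:
    """Current through the optogenetic channel in nA; zero while blocked."""
    if not unblocked:
        return 0.0
    g_total_us = chan.g_opto_Cl * area * units.MS_TO_US
    return g_total_us * (V_post - chan.E_opto)
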