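"""Network assembly, stimulus protocols, and the fixed-step integrator.

A :class:`NetworkSpec` lists named cells and typed directed connections; it is
compiled into flat parameter arrays and advanced with the exponential-Euler
scheme at a fixed step (1 ms by default).  Within a step the order is:

1. stimulus events for the step are applied (pulse edges, ramp slopes,
   optogenetic unblock toggles);
2. every synapse advances its cleft transmitter using the presynaptic calcium
   from the step start, and its postsynaptic conductance is accumulated onto
   the target cell;
3. every neuron updates its gate, calcium pool, and membrane potential
   (staggered explicit scheme; see :mod:`larvacpg.membrane`).

The integration loop is compiled with numba; a pure-numpy implementation of
the identical scheme (:func:`simulate`'s ``backend="numpy"``) exists for
cross-checking and as a fallback.

Simulations are bit-reproducible given (spec, protocol, seed, dt): the only
randomness is the Poisson pulse trains, each drawn from a seed stream derived
from the protocol seed and the target cell.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .membrane import NeuronParameters, initial_state
from .synapse import OptoChannel, SynapseParameters

__all__ = [
    "CellSpec",
    "ConnectionSpec",
    "NetworkSpec",
    "Network",
    "build_network",
    "TonicCurrent",
    "PulseTrain",
    "RampCurrent",
    "OptoWindow",
    "StimulusProtocol",
    "poisson_pulse_train",
    "ramp_stimulus",
    "Recording",
    "simulate",
]


# ---------------------------------------------------------------------------
# network specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    name: str
    params: NeuronParameters = field(default_factory=NeuronParameters)
    opto: OptoChannel | None = None
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConnectionSpec:
    pre: str
    post: str
    params: SynapseParameters = field(default_factory=SynapseParameters)
    allow_self: bool = False


@dataclass
class NetworkSpec:
    """Named cells plus typed, gain-weighted directed connections."""

    cells: list[CellSpec] = field(default_factory=list)
    connections: list[ConnectionSpec] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        names = [c.name for c in self.cells]
        seen: set[str] = set()
        dupes = sorted({n for n in names if n in seen or seen.add(n)})
        if dupes:
            raise ValueError(f"duplicate cell names: {dupes}")
        known = set(names)
        missing = sorted(
            {e for c in self.connections for e in (c.pre, c.post) if e not in known}
        )
        if missing:
            raise ValueError(f"connections reference missing cells: {missing}")
        for c in self.connections:
            if c.pre == c.post and not c.allow_self:
                raise ValueError(f"self-connection on {c.pre!r} not flagged")

    def cell(self, name: str) -> CellSpec:
        for c in self.cells:
            if c.name == name:
                return c
        raise KeyError(name)


class Network:
    """A validated spec compiled to flat arrays, ready to simulate."""

    def __init__(self, spec: NetworkSpec):
        spec.validate()
        self.spec = spec
        self.cell_names = [c.name for c in spec.cells]
        self.index = {n: i for i, n in enumerate(self.cell_names)}
        self.conn_labels = [f"{c.pre}->{c.post}" for c in spec.connections]
        n = len(spec.cells)

        def vec(fn):
            return np.array([fn(c) for c in spec.cells], dtype=np.float64)

        self.g_leak = vec(lambda c: c.params.g_leak_total)
        self.E_leak = vec(lambda c: c.params.V_leak_eq)
        self.g_ca = vec(lambda c: c.params.g_Ca_total)
        self.v_mid = vec(lambda c: c.params.V_mid)
        self.s_ca = vec(lambda c: c.params.S_Ca)
        self.tau_m = vec(lambda c: c.params.tau_m)
        self.C = vec(lambda c: c.params.C_total)
        self.b_eff = vec(lambda c: c.params.B_eff)
        self.tau_ca = vec(lambda c: c.params.tau_Ca_clr)
        self.ca_min = vec(lambda c: c.params.Ca_i_min)
        self.ca_e_nm = vec(lambda c: c.params.Ca_e * 1e6)
        from . import units as _u

        self.nernst_pref = vec(lambda c: _u.nernst_prefactor_mv(c.params.temperature))
        self.opto_g = vec(
            lambda c: 0.0
            if c.opto is None
            else c.opto.g_opto_Cl * c.params.area * 1e3
        )
        self.opto_E = vec(lambda c: -70.0 if c.opto is None else c.opto.E_opto)

        m = len(spec.connections)
        self.pre = np.array([self.index[c.pre] for c in spec.connections], dtype=np.int64)
        self.post = np.array([self.index[c.post] for c in spec.connections], dtype=np.int64)

        def cvec(fn):
            return np.array([fn(c) for c in spec.connections], dtype=np.float64)

        self.e_syn = cvec(lambda c: c.params.V_syn_eq)
        # effective per-ms release rate: r_max on the nominal transmitter
        # unit scale fixed by r_scale
        self.r_max = cvec(lambda c: c.params.r_max * c.params.r_scale)
        self.ca_mid = cvec(lambda c: c.params.Ca_i_mid)
        self.s_r = cvec(lambda c: c.params.S_r)
        self.tau_t = cvec(lambda c: c.params.tau_T_clr)
        self.s_bind = cvec(lambda c: c.params.S_bind)
        # effective total conductance scale, uS: gain * density * post area
        self.g_eff = np.array(
            [
                c.params.gain
                * c.params.g_syn_max
                * spec.cell(c.post).params.area
                * 1e3
                for c in spec.connections
            ],
            dtype=np.float64,
        )
        self.n_cells = n
        self.n_conns = m

    def initial_arrays(self):
        V = np.empty(self.n_cells)
        m = np.empty(self.n_cells)
        ca = np.empty(self.n_cells)
        for i, c in enumerate(self.spec.cells):
            s = initial_state(c.params)
            V[i], m[i], ca[i] = s.V_m, s.m, s.Ca_i
        T = np.zeros(self.n_conns)
        msyn = np.zeros(self.n_conns)
        return V, m, ca, T, msyn


def build_network(spec: NetworkSpec) -> Network:
    """Validate a spec and compile it for simulation."""
    return Network(spec)


# ---------------------------------------------------------------------------
# stimulus protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TonicCurrent:
    """Constant current into one cell over [start, stop), nA."""

    cell: str
    start: float  # ms
    stop: float  # ms
    amplitude: float  # nA


@dataclass(frozen=True)
class PulseTrain:
    """Poisson train of rectangular current pulses into one cell.

    Pulse onset intervals are i.i.d. exponential with mean ``msi`` (the mean
    stimulus interval); pulses that overlap simply sum.  ``seed`` overrides
    the per-cell stream derived from the protocol seed.
    """

    cell: str
    msi: float  # ms, mean stimulus interval
    width: float = 100.0  # ms
    amplitude: float = 0.01  # nA
    start: float = 0.0  # ms, window start
    stop: float = float("inf")  # ms, window stop (bounded by run duration)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.msi <= 0:
            raise ValueError("MSI must be strictly positive")
        if self.width <= 0:
            raise ValueError("pulse width must be strictly positive")


@dataclass(frozen=True)
class RampCurrent:
    """Linearly growing current: zero at start, slope in nA/s."""

    cell: str
    start: float  # ms
    stop: float  # ms
    slope: float  # nA per second

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("ramp stop must exceed start")


@dataclass(frozen=True)
class OptoWindow:
    """Unblock the optogenetic channel of one cell (or all carriers) in a window."""

    start: float  # ms
    stop: float  # ms
    cell: str | None = None  # None -> every cell with an OptoChannel


Episode = TonicCurrent | PulseTrain | RampCurrent | OptoWindow


@dataclass
class StimulusProtocol:
    """Time-resolved injected current and optogenetic schedule per cell."""

    episodes: list[Episode] = field(default_factory=list)
    rng_seed: int = 0

    def add(self, *eps: Episode) -> "StimulusProtocol":
        self.episodes.extend(eps)
        return self


def _cell_stream_seed(rng_seed: int, cell: str, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([rng_seed, zlib.crc32(cell.encode()), k])


def poisson_pulse_train(
    msi: float,
    width: float,
    amplitude: float,
    window: tuple[float, float],
    seed,
) -> np.ndarray:
    """Draw one realisation of a Poisson pulse train; returns pulse onsets (ms).

    ``seed`` may be an int or a SeedSequence.  The onsets are the cumulative
    sums of exponential inter-onset intervals with mean ``msi`` starting at
    the window start; the expected count over a window of length D is D/msi.
    ``width`` and ``amplitude`` describe the rectangular pulse delivered at
    each onset and are validated here; the delivered waveform is realised by
    :func:`simulate` from a :class:`PulseTrain` episode.
    """
    if msi <= 0:
        raise ValueError("MSI must be strictly positive")
    if width <= 0 or amplitude is None:
        raise ValueError("pulse width must be strictly positive")
    start, stop = window
    rng = np.random.default_rng(seed)
    onsets = []
    t = start
    while True:
        t += rng.exponential(msi)
        if t >= stop:
            break
        onsets.append(t)
    return np.asarray(onsets, dtype=np.float64)


def ramp_stimulus(
    start: float, stop: float, slope: float, cells: Iterable[str]
) -> list[RampCurrent]:
    """Ramp episodes (zero at start, ``slope`` nA/s) for each target cell."""
    return [RampCurrent(cell=c, start=start, stop=stop, slope=slope) for c in cells]


def _realise_events(
    network: Network,
    protocol: StimulusProtocol,
    n_steps: int,
    dt: float,
):
    """Expand a protocol into sorted per-step event arrays.

    Returns (stim events, opto events, pulse_times).  Stimulus events carry a
    base-current delta, a slope delta (nA/ms), and a ramp-accumulator delta;
    opto events carry +-1 toggles of each cell's unblock counter.
    """
    ev: list[tuple[int, int, float, float, float]] = []
    op: list[tuple[int, int, int]] = []
    pulse_times: dict[str, np.ndarray] = {}
    per_cell_counter: dict[str, int] = {}

    def clamp_step(t: float) -> int:
        return min(max(int(round(t / dt)), 0), n_steps)

    for e in protocol.episodes:
        if isinstance(e, TonicCurrent):
            i = network.index[e.cell]
            s0, s1 = clamp_step(e.start), clamp_step(e.stop)
            if s1 > s0:
                ev.append((s0, i, e.amplitude, 0.0, 0.0))
                ev.append((s1, i, -e.amplitude, 0.0, 0.0))
        elif isinstance(e, PulseTrain):
            i = network.index[e.cell]
            k = per_cell_counter.get(e.cell, 0)
            per_cell_counter[e.cell] = k + 1
            seed = (
                e.seed
                if e.seed is not None
                else _cell_stream_seed(protocol.rng_seed, e.cell, k)
            )
            stop = min(e.stop, n_steps * dt)
            onsets = poisson_pulse_train(
                e.msi, e.width, e.amplitude, (e.start, stop), seed
            )
            snapped = []
            w_steps = max(int(round(e.width / dt)), 1)
            for t in onsets:
                s0 = clamp_step(t)
                if s0 >= n_steps:
                    continue
                snapped.append(s0 * dt)
                ev.append((s0, i, e.amplitude, 0.0, 0.0))
                ev.append((min(s0 + w_steps, n_steps), i, -e.amplitude, 0.0, 0.0))
            prev = pulse_times.get(e.cell, np.empty(0))
            pulse_times[e.cell] = np.sort(
                np.concatenate([prev, np.asarray(snapped)])
            )
        elif isinstance(e, RampCurrent):
            i = network.index[e.cell]
            s0, s1 = clamp_step(e.start), clamp_step(e.stop)
            slope_ms = e.slope / 1000.0  # nA per ms
            if s1 > s0:
                ev.append((s0, i, 0.0, slope_ms, 0.0))
                ev.append((s1, i, 0.0, -slope_ms, -slope_ms * (s1 - s0) * dt))
        elif isinstance(e, OptoWindow):
            targets = (
                [e.cell]
                if e.cell is not None
                else [c.name for c in network.spec.cells if c.opto is not None]
            )
            s0, s1 = clamp_step(e.start), clamp_step(e.stop)
            for name in targets:
                i = network.index[name]
                if s1 > s0:
                    op.append((s0, i, 1))
                    op.append((s1, i, -1))
        else:  # pragma: no cover - guarded by the Episode union
            raise TypeError(f"unknown episode type {type(e)!r}")

    ev.sort(key=lambda x: x[0])
    op.sort(key=lambda x: x[0])
    ev_step = np.array([x[0] for x in ev], dtype=np.int64)
    ev_cell = np.array([x[1] for x in ev], dtype=np.int64)
    ev_damp = np.array([x[2] for x in ev], dtype=np.float64)
    ev_dslope = np.array([x[3] for x in ev], dtype=np.float64)
    ev_dacc = np.array([x[4] for x in ev], dtype=np.float64)
    op_step = np.array([x[0] for x in op], dtype=np.int64)
    op_cell = np.array([x[1] for x in op], dtype=np.int64)
    op_delta = np.array([x[2] for x in op], dtype=np.int64)
    return (
        (ev_step, ev_cell, ev_damp, ev_dslope, ev_dacc),
        (op_step, op_cell, op_delta),
        pulse_times,
    )


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Uniform-grid traces of every recorded state variable.

    ``V``, ``m``, ``Ca``, and ``stim`` are (n_times, n_cells) arrays; ``T``
    and ``m_syn`` are (n_times, n_conns) or ``None`` if connection recording
    was disabled.  ``pulse_times`` holds the exact grid-snapped onset times of
    every Poisson pulse actually delivered, per cell.
    """

    time: np.ndarray
    cells: list[str]
    V: np.ndarray
    m: np.ndarray
    Ca: np.ndarray
    stim: np.ndarray
    conn_labels: list[str]
    T: np.ndarray | None
    m_syn: np.ndarray | None
    pulse_times: dict
    dt: float
    every: int

    def channel(self, name: str, var: str = "V") -> np.ndarray:
        return getattr(self, var)[:, self.cells.index(name)]

    def to_frame(self, vars: Sequence[str] = ("V",)):
        """Traces as a DataFrame: a time column plus one column per cell/var."""
        import pandas as pd

        data = {"time_ms": self.time}
        for var in vars:
            arr = getattr(self, var)
            for i, name in enumerate(self.cells):
                key = f"{name}:{var}" if len(vars) > 1 else name
                data[key] = arr[:, i]
        return pd.DataFrame(data)

    def save_csv(self, path, vars: Sequence[str] = ("V",)) -> None:
        self.to_frame(vars).to_csv(path, index=False)

    def save_npz(self, path) -> None:
        """Compact binary container for full-state archival."""
        np.savez_compressed(
            path, time=self.time, cells=np.array(self.cells),
            V=self.V, m=self.m, Ca=self.Ca, stim=self.stim,
            conn_labels=np.array(self.conn_labels),
            **({"T": self.T, "m_syn": self.m_syn} if self.T is not None else {}),
        )


# ---------------------------------------------------------------------------
# integration backends
# ---------------------------------------------------------------------------

def _step_numpy(net: Network, dt, V, m, ca, T, msyn, stim):
    """One integration step of the reference numpy backend (in place)."""
    rate = net.r_max / (1.0 + np.exp((net.ca_mid - ca[net.pre]) / net.s_r))
    tt = rate * net.tau_t
    T[:] = tt + (T - tt) * np.exp(-dt / net.tau_t)
    np.maximum(T, 0.0, out=T)
    msyn[:] = 2.0 / (1.0 + np.exp(-T / net.s_bind)) - 1.0
    g = net.g_eff * msyn
    gsum = np.bincount(net.post, weights=g, minlength=net.n_cells)
    gesum = np.bincount(net.post, weights=g * net.e_syn, minlength=net.n_cells)

    minf = 1.0 / (1.0 + np.exp((net.v_mid - V) / net.s_ca))
    m[:] = minf + (m - minf) * np.exp(-dt / net.tau_m)
    e_ca = net.nernst_pref * np.log(net.ca_e_nm / ca)
    g_ca_now = m * net.g_ca
    i_ca = g_ca_now * (V - e_ca)
    inflow = net.b_eff * np.maximum(0.0, -i_ca)
    ca_t = net.ca_min + inflow * net.tau_ca
    ca[:] = ca_t + (ca - ca_t) * np.exp(-dt / net.tau_ca)
    np.maximum(ca, net.ca_min, out=ca)
    g_opto = stim["opto_g"]
    gs = net.g_leak + g_ca_now + gsum + g_opto
    ge = net.g_leak * net.E_leak + g_ca_now * e_ca + gesum + g_opto * net.opto_E
    vinf = (ge + stim["I"]) / gs
    V[:] = vinf + (V - vinf) * np.exp(-dt * gs / net.C)


def _simulate_numpy(net, ev, op, n_steps, dt, every, rec, record_connections):
    V, m, ca, T, msyn = net.initial_arrays()
    base = np.zeros(net.n_cells)
    slope = np.zeros(net.n_cells)
    acc = np.zeros(net.n_cells)
    opto_ct = np.zeros(net.n_cells, dtype=np.int64)
    ev_step, ev_cell, ev_damp, ev_dslope, ev_dacc = ev
    op_step, op_cell, op_delta = op
    ie = io = 0
    for k in range(n_steps):
        while ie < ev_step.size and ev_step[ie] == k:
            c = ev_cell[ie]
            base[c] += ev_damp[ie]
            slope[c] += ev_dslope[ie]
            acc[c] += ev_dacc[ie]
            ie += 1
        while io < op_step.size and op_step[io] == k:
            opto_ct[op_cell[io]] += op_delta[io]
            io += 1
        I_now = base + acc
        if k % every == 0:
            r = k // every
            rec["V"][r] = V
            rec["m"][r] = m
            rec["Ca"][r] = ca
            rec["stim"][r] = I_now
            if record_connections:
                rec["T"][r] = T
                rec["m_syn"][r] = msyn
        stim = {"I": I_now, "opto_g": np.where(opto_ct > 0, net.opto_g, 0.0)}
        _step_numpy(net, dt, V, m, ca, T, msyn, stim)
        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise FloatingPointError(
                f"non-finite membrane potential at step {k} in cell "
                f"{net.cell_names[bad]!r}"
            )
        acc += slope * dt


def _simulate_numba(net, ev, op, n_steps, dt, every, rec, record_connections):
    from ._kernel import run_kernel

    V, m, ca, T, msyn = net.initial_arrays()
    conn_rec = 1 if record_connections else 0
    empty = np.empty((0, 0))
    status = run_kernel(
        n_steps, dt, every,
        V, m, ca, T, msyn,
        net.g_leak, net.E_leak, net.g_ca, net.v_mid, net.s_ca, net.tau_m,
        net.C, net.b_eff, net.tau_ca, net.ca_min, net.nernst_pref,
        net.ca_e_nm, net.opto_g, net.opto_E,
        net.pre, net.post, net.e_syn, net.r_max, net.ca_mid, net.s_r,
        net.tau_t, net.s_bind, net.g_eff,
        ev[0], ev[1], ev[2], ev[3], ev[4],
        op[0], op[1], op[2],
        rec["V"], rec["m"], rec["Ca"], rec["stim"],
        rec["T"] if conn_rec else empty,
        rec["m_syn"] if conn_rec else empty,
        conn_rec,
    )
    if status[0] >= 0:
        raise FloatingPointError(
            f"non-finite membrane potential at step {status[0]} in cell "
            f"{net.cell_names[status[1]]!r}"
        )


def simulate(
    network: Network | NetworkSpec,
    protocol: StimulusProtocol | None = None,
    duration: float = 1000.0,
    dt: float = 1.0,
    record_every: int = 1,
    record_connections: bool = True,
    backend: str = "numba",
) -> Recording:
    """Integrate the network under a stimulus protocol.

    Parameters
    ----------
    duration : total simulated time, ms.
    dt : fixed integration step, ms (1 ms default).
    record_every : store every k-th step (integration always runs at ``dt``).
    record_connections : also record cleft transmitter and receptor gates.
    backend : "numba" (compiled; default) or "numpy" (reference).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be strictly positive")
    if isinstance(network, NetworkSpec):
        network = build_network(network)
    protocol = protocol or StimulusProtocol()
    n_steps = int(round(duration / dt))
    ev, op, pulse_times = _realise_events(network, protocol, n_steps, dt)
    n_rec = (n_steps + record_every - 1) // record_every
    rec = {
        "V": np.empty((n_rec, network.n_cells)),
        "m": np.empty((n_rec, network.n_cells)),
        "Ca": np.empty((n_rec, network.n_cells)),
        "stim": np.empty((n_rec, network.n_cells)),
        "T": np.empty((n_rec, network.n_conns)) if record_connections else None,
        "m_syn": np.empty((n_rec, network.n_conns)) if record_connections else None,
    }
    if backend == "numba":
        _simulate_numba(network, ev, op, n_steps, dt, record_every, rec,
                        record_connections)
    elif backend == "numpy":
        _simulate_numpy(network, ev, op, n_steps, dt, record_every, rec,
                        record_connections)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    time = np.arange(n_rec) * dt * record_every
    return Recording(
        time=time,
        cells=list(network.cell_names),
        V=rec["V"],
        m=rec["m"],
        Ca=rec["Ca"],
        stim=rec["stim"],
        conn_labels=list(network.conn_labels),
        T=rec["T"],
        m_syn=rec["m_syn"],
        pulse_times=pulse_times,
        dt=dt,
        every=record_every,
    )
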