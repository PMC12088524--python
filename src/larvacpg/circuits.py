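"""Circuit blueprints for the larval locomotor network.

Every circuit is assembled from one repeated motif, the hemisegmental
oscillator (HO): a forwards excitor E_F and a backwards excitor E_B making
identical reciprocal graded connections with a single shared inhibitor I.
The constructors here wire HOs into

* the single HO with its two command neurons (C_F, C_B);
* the eight-segment abdominal chain with feed-forwards intersegmental
  excitation, command fan-in to the initiating segments, and the two
  inhibitory detector motifs (initiation detectors D_IF/D_IB, wave detectors
  D_WF/D_WB);
* the bilateral thoracic head-sweep circuit (three HO pairs, ipsilateral
  head-sweep commands C_HL/C_HR, half-centre head-sweep detectors D_HL/D_HR);
* the full bilateral model: two abdominal chains with midline excitor
  coupling and an A1/A2 chiasm, the thoracic circuit attached at T3-A1, and
  head-sweep commands standing in for C_B.

All neurons share identical physiology; circuit identity lives entirely in
the connections.  Detector inhibitory outputs carry a connection gain of 2;
midline-coordination excitatory synapses use the reduced release rate
(r_max = 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import synapse as syn
from .engine import CellSpec, ConnectionSpec, NetworkSpec, TonicCurrent
from .membrane import NeuronParameters
from .synapse import OptoChannel, SynapseParameters

__all__ = [
    "CellHandle",
    "CircuitBlueprint",
    "hemisegmental_oscillator",
    "abdominal_chain",
    "thoracic_circuit",
    "full_model",
    "apply_segment_block",
    "with_opto",
    "ABDOMINAL_SEGMENTS",
    "THORACIC_SEGMENTS",
    "WAVE_ORDER",
]

# posterior -> anterior wave order: a forwards wave peaks A8 first, T1 last
ABDOMINAL_SEGMENTS = ["A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8"]
THORACIC_SEGMENTS = ["T1", "T2", "T3"]
WAVE_ORDER = list(reversed(ABDOMINAL_SEGMENTS)) + list(reversed(THORACIC_SEGMENTS))

CELL_CLASSES = (
    "E_F", "E_B", "I", "C_F", "C_B", "C_HL", "C_HR",
    "D_IF", "D_IB", "D_WF", "D_WB", "D_HL", "D_HR",
)
INHIBITORY_CLASSES = ("I", "D_IF", "D_IB", "D_WF", "D_WB", "D_HL", "D_HR")

# amplitude used by apply_segment_block, nA: strong enough to hold an excitor
# below plateau threshold (or an inhibitor above release threshold) against
# full feed-forwards drive
BLOCK_AMPLITUDE_NA = 0.1

# Gain on the intersegmental feed-forwards connection onto the *inhibitor* of
# the next segment.  At 1.0 the relayed plateau is clipped by its own
# segment's inhibition before presynaptic calcium reaches the release range,
# and waves die mid-chain; at 0.5 the excitor-to-excitor relay regenerates
# fully at every segment while the phase-advanced inhibition is preserved.
INTERSEG_INH_FF_GAIN = 0.5

# Gain on the thoracic-to-abdominal attachment (E_B in T3 onto the backwards
# excitors of A1 and A2).  This pathway stands in for the removed backwards
# command neuron, whose synapses fired from a saturated presynaptic calcium
# level; the thoracic excitor's phasic plateaus release far less transmitter,
# so the attachment carries gain 2 (the same factor the detector outputs use)
# to restore the replaced command's postsynaptic efficacy.  At gain 1,
# backwards initiations abort at A1/A2 and the full model never produces a
# complete backwards wave.
T3_ATTACH_GAIN = 2.0


@dataclass(frozen=True)
class CellHandle:
    """Identity of one cell: class, segment (or None), side (or None)."""

    cls: str
    segment: str | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        if self.cls not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cls!r}")
        if self.side not in (None, "L", "R"):
            raise ValueError(f"side must be L, R or None, got {self.side!r}")

    @property
    def name(self) -> str:
        parts = [self.cls]
        if self.segment is not None:
            parts.append(self.segment)
        if self.side is not None:
            parts.append(self.side)
        return "_".join(parts)

    @staticmethod
    def parse(name: str) -> "CellHandle":
        parts = name.split("_")
        side = parts.pop() if parts[-1] in ("L", "R") else None
        segment = parts.pop() if parts[-1][0] in "AT" and parts[-1][1:].isdigit() else None
        return CellHandle("_".join(parts), segment, side)


@dataclass
class CircuitBlueprint:
    """A NetworkSpec plus the motif inventory that produced it."""

    spec: NetworkSpec
    motifs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def cell_names(self, cls=None, segment=None, side=None) -> list[str]:
        """Names of cells matching the given class/segment/side filters."""
        out = []
        for c in self.spec.cells:
            h = c.meta.get("handle")
            if cls is not None and h.cls != cls:
                continue
            if segment is not None and h.segment != segment:
                continue
            if side is not None and h.side != side:
                continue
            out.append(c.name)
        return out

    def roi_channels(self, side=None) -> dict[str, list[str]]:
        """Per-hemisegment ROI -> excitor cells, in posterior->anterior order.

        This is the model's analogue of the imaging ROIs drawn over motor
        regions of each hemisegment: each channel pools the hemisegment's
        excitors.  Keys are ``"A3"`` (one-sided circuits) or ``"A3_L"``.
        """
        chans: dict[str, list[str]] = {}
        for c in self.spec.cells:
            h = c.meta.get("handle")
            if h.cls not in ("E_F", "E_B") or h.segment is None:
                continue
            if side is not None and h.side != side:
                continue
            key = h.segment if h.side is None or side is not None else f"{h.segment}_{h.side}"
            chans.setdefault(key, []).append(c.name)
        order = {s: i for i, s in enumerate(WAVE_ORDER)}
        return dict(
            sorted(chans.items(), key=lambda kv: order[kv[0].split("_")[0]])
        )


def _cell(handle: CellHandle, neuron: NeuronParameters, opto=None) -> CellSpec:
    return CellSpec(handle.name, neuron, opto=opto, meta={"handle": handle})


def _exc(**kw) -> SynapseParameters:
    return syn.excitatory(**kw)


def _inh(**kw) -> SynapseParameters:
    return syn.inhibitory(**kw)


def _detector_inh() -> SynapseParameters:
    return syn.inhibitory(gain=2.0)


def _midline_exc() -> SynapseParameters:
    return syn.excitatory(r_max=20.0)


def _ff_inh_exc() -> SynapseParameters:
    """Feed-forwards excitation onto the next segment's inhibitor."""
    return syn.excitatory(gain=INTERSEG_INH_FF_GAIN)


def _ho_cells_conns(segment, side, neuron):
    """Cells and internal reciprocal connections of one HO."""
    ef = CellHandle("E_F", segment, side)
    eb = CellHandle("E_B", segment, side)
    ii = CellHandle("I", segment, side)
    cells = [_cell(h, neuron) for h in (ef, eb, ii)]
    conns = [
        ConnectionSpec(ef.name, ii.name, _exc()),
        ConnectionSpec(ii.name, ef.name, _inh()),
        ConnectionSpec(eb.name, ii.name, _exc()),
        ConnectionSpec(ii.name, eb.name, _inh()),
    ]
    return cells, conns


def hemisegmental_oscillator(
    neuron: NeuronParameters | None = None,
    include_commands: bool = True,
) -> CircuitBlueprint:
    """The 3-cell conditional oscillator with its two command neurons.

    Both excitors make identical synaptic connections to and from the single
    shared inhibitor; commands C_F and C_B excite their respective excitor.
    The circuit is silent at rest and oscillates only under command drive.
    """
    neuron = neuron or NeuronParameters()
    cells, conns = _ho_cells_conns(None, None, neuron)
    if include_commands:
        for ccls, target in (("C_F", "E_F"), ("C_B", "E_B")):
            ch = CellHandle(ccls)
            cells.append(_cell(ch, neuron))
            conns.append(ConnectionSpec(ch.name, target, _exc()))
    spec = NetworkSpec(cells, conns, metadata={"circuit": "hemisegmental_oscillator"})
    spec.validate()
    return CircuitBlueprint(spec, motifs={}, options={"include_commands": include_commands})


def _abdominal_side(
    cells, conns, neuron, side, n_segments,
    with_initiation_detectors, with_wave_detectors,
    command_cls_f="C_F", backward_command=True,
):
    """One abdominal hemichain plus its command/detector motifs (in place).

    Returns the handles of the command cells created (C_F and, when
    ``backward_command``, C_B) so callers can re-target them.
    """
    segs = ABDOMINAL_SEGMENTS[:n_segments]
    post3 = segs[-3:]  # posterior initiating segments (A6-A8 at full length)
    ant2 = segs[:2]  # anterior initiating segments (A1-A2)

    for s in segs:
        cl, co = _ho_cells_conns(s, side, neuron)
        cells.extend(cl)
        conns.extend(co)

    def n_(cls, seg):
        return CellHandle(cls, seg, side).name

    # feed-forwards intersegmental excitation: active excitor drives the next
    # segment's excitor and inhibitor in the direction of travel
    for k in range(1, n_segments):
        post_seg, ant_seg = segs[k], segs[k - 1]  # e.g. A4 and A3
        conns.append(ConnectionSpec(n_("E_F", post_seg), n_("E_F", ant_seg), _exc()))
        conns.append(ConnectionSpec(n_("E_F", post_seg), n_("I", ant_seg), _ff_inh_exc()))
        conns.append(ConnectionSpec(n_("E_B", ant_seg), n_("E_B", post_seg), _exc()))
        conns.append(ConnectionSpec(n_("E_B", ant_seg), n_("I", post_seg), _ff_inh_exc()))

    cf = CellHandle(command_cls_f, None, side)
    cells.append(_cell(cf, neuron))
    for s in post3:
        conns.append(ConnectionSpec(cf.name, n_("E_F", s), _exc()))
    cb = None
    if backward_command:
        cb = CellHandle("C_B", None, side)
        cells.append(_cell(cb, neuron))
        for s in ant2:
            conns.append(ConnectionSpec(cb.name, n_("E_B", s), _exc()))

    if with_initiation_detectors:
        dif = CellHandle("D_IF", None, side)
        cells.append(_cell(dif, neuron))
        conns.append(ConnectionSpec(cf.name, dif.name, _exc()))
        for s in ant2:
            conns.append(ConnectionSpec(dif.name, n_("E_B", s), _detector_inh()))
        dib = CellHandle("D_IB", None, side)
        cells.append(_cell(dib, neuron))
        if cb is not None:
            conns.append(ConnectionSpec(cb.name, dib.name, _exc()))
        for s in post3:
            conns.append(ConnectionSpec(dib.name, n_("E_F", s), _detector_inh()))

    if with_wave_detectors:
        dwf = CellHandle("D_WF", None, side)
        dwb = CellHandle("D_WB", None, side)
        cells.extend([_cell(dwf, neuron), _cell(dwb, neuron)])
        for s in segs:
            conns.append(ConnectionSpec(n_("E_F", s), dwf.name, _exc()))
            conns.append(ConnectionSpec(n_("E_B", s), dwb.name, _exc()))
        # each wave detector gates new initiation at both ends of the chain
        for d in (dwf, dwb):
            for s in post3:
                conns.append(ConnectionSpec(d.name, n_("E_F", s), _detector_inh()))
            for s in ant2:
                conns.append(ConnectionSpec(d.name, n_("E_B", s), _detector_inh()))
    return cf, cb


def abdominal_chain(
    n_segments: int = 8,
    with_initiation_detectors: bool = True,
    with_wave_detectors: bool = True,
    neuron: NeuronParameters | None = None,
) -> CircuitBlueprint:
    """One-sided abdominal chain of HOs with command and detector motifs.

    C_F excites the forwards excitors of the three posterior segments, C_B
    the backwards excitors of the two anterior segments.  Initiation
    detectors, driven by each command, inhibit the opposite program's
    initiating excitors; wave detectors sum excitor activity chain-wide and
    inhibit the initiating excitors at both ends.
    """
    if n_segments < 2 or n_segments > len(ABDOMINAL_SEGMENTS):
        raise ValueError(f"n_segments must be in 2..8, got {n_segments}")
    neuron = neuron or NeuronParameters()
    cells: list[CellSpec] = []
    conns: list[ConnectionSpec] = []
    _abdominal_side(
        cells, conns, neuron, None, n_segments,
        with_initiation_detectors, with_wave_detectors,
    )
    spec = NetworkSpec(cells, conns, metadata={"circuit": "abdominal_chain"})
    spec.validate()
    return CircuitBlueprint(
        spec,
        motifs={
            "initiation_detectors": with_initiation_detectors,
            "wave_detectors": with_wave_detectors,
        },
        options={"n_segments": n_segments},
    )


def _thoracic_side(cells, conns, neuron, side):
    """Three thoracic HOs for one side plus its head-sweep command."""
    for s in THORACIC_SEGMENTS:
        cl, co = _ho_cells_conns(s, side, neuron)
        cells.extend(cl)
        conns.extend(co)

    def n_(cls, seg):
        return CellHandle(cls, seg, side).name

    # posterior -> anterior feed-forwards only (no reciprocal thoracic links)
    for k in range(len(THORACIC_SEGMENTS) - 1, 0, -1):
        post_seg, ant_seg = THORACIC_SEGMENTS[k], THORACIC_SEGMENTS[k - 1]
        conns.append(ConnectionSpec(n_("E_F", post_seg), n_("E_F", ant_seg), _exc()))
        conns.append(ConnectionSpec(n_("E_F", post_seg), n_("I", ant_seg), _ff_inh_exc()))

    ch = CellHandle("C_HL" if side == "L" else "C_HR")
    cells.append(_cell(ch, neuron))
    for s in THORACIC_SEGMENTS:
        conns.append(ConnectionSpec(ch.name, n_("E_B", s), _exc()))
    return ch


def _head_sweep_detectors(cells, conns, neuron):
    """Half-centre D_HL/D_HR motif over the bilateral thoracic E_Bs."""
    for side, other in (("L", "R"), ("R", "L")):
        d = CellHandle("D_HL" if side == "L" else "D_HR")
        cells.append(_cell(d, neuron))
        for s in THORACIC_SEGMENTS:
            conns.append(
                ConnectionSpec(CellHandle("E_B", s, side).name, d.name, _exc())
            )
            conns.append(
                ConnectionSpec(d.name, CellHandle("E_B", s, other).name, _detector_inh())
            )


def thoracic_circuit(
    with_head_sweep_detectors: bool = True,
    neuron: NeuronParameters | None = None,
) -> CircuitBlueprint:
    """Bilateral thoracic head-sweep circuit: three HO pairs, T1-T3.

    Head-sweep commands excite all three ipsilateral backwards excitors; the
    head-sweep detectors D_HL/D_HR are excited by ipsilateral E_Bs and
    inhibit contralateral E_Bs in a half-centre motif.  Intersegmental
    connections run posterior->anterior only.
    """
    neuron = neuron or NeuronParameters()
    cells: list[CellSpec] = []
    conns: list[ConnectionSpec] = []
    for side in ("L", "R"):
        _thoracic_side(cells, conns, neuron, side)
    if with_head_sweep_detectors:
        _head_sweep_detectors(cells, conns, neuron)
    spec = NetworkSpec(cells, conns, metadata={"circuit": "thoracic_circuit"})
    spec.validate()
    return CircuitBlueprint(
        spec,
        motifs={"head_sweep_detectors": with_head_sweep_detectors},
        options={},
    )


def full_model(
    with_initiation_detectors: bool = True,
    with_wave_detectors: bool = True,
    with_head_sweep_detectors: bool = True,
    neuron: NeuronParameters | None = None,
) -> CircuitBlueprint:
    """The full bilateral locomotor model.

    Two abdominal chains (each with its own command and detector motifs) are
    joined by midline excitatory coupling between counterpart excitors
    (reduced release rate), plus a chiasm from each A1 backwards excitor to
    the contralateral A2 backwards excitor.  The bilateral thoracic circuit
    attaches at T3-A1 (forwards continuation A1->T3; backwards initiation
    T3->A1).  The head-sweep commands C_HL/C_HR replace C_B: they drive the
    thoracic backwards excitors and the initiation detectors D_IB, so
    backwards abdominal waves arise from head sweeps or symmetric thoracic
    activity.  Thoracic excitors also report to the wave detectors so that
    program segregation covers the whole chain.
    """
    neuron = neuron or NeuronParameters()
    cells: list[CellSpec] = []
    conns: list[ConnectionSpec] = []
    n_seg = len(ABDOMINAL_SEGMENTS)
    ch_by_side = {}
    for side in ("L", "R"):
        _abdominal_side(
            cells, conns, neuron, side, n_seg,
            with_initiation_detectors, with_wave_detectors,
            backward_command=False,
        )
        ch_by_side[side] = _thoracic_side(cells, conns, neuron, side)
    if with_head_sweep_detectors:
        _head_sweep_detectors(cells, conns, neuron)

    def n_(cls, seg, side):
        return CellHandle(cls, seg, side).name

    # midline coupling: counterpart excitors in each abdominal segment
    for s in ABDOMINAL_SEGMENTS:
        for cls in ("E_F", "E_B"):
            conns.append(ConnectionSpec(n_(cls, s, "L"), n_(cls, s, "R"), _midline_exc()))
            conns.append(ConnectionSpec(n_(cls, s, "R"), n_(cls, s, "L"), _midline_exc()))
    # chiasm: A1 backwards excitors to contralateral A2
    conns.append(ConnectionSpec(n_("E_B", "A1", "L"), n_("E_B", "A2", "R"), _midline_exc()))
    conns.append(ConnectionSpec(n_("E_B", "A1", "R"), n_("E_B", "A2", "L"), _midline_exc()))

    for side in ("L", "R"):
        # thorax attachment at T3-A1
        conns.append(ConnectionSpec(n_("E_F", "A1", side), n_("E_F", "T3", side), _exc()))
        conns.append(ConnectionSpec(n_("E_F", "A1", side), n_("I", "T3", side), _ff_inh_exc()))
        # backwards initiation: T3's E_B takes over the removed C_B command's
        # fan-out (both anterior initiating segments) at command-like efficacy
        attach = syn.excitatory(gain=T3_ATTACH_GAIN)
        conns.append(ConnectionSpec(n_("E_B", "T3", side), n_("E_B", "A1", side), attach))
        conns.append(ConnectionSpec(n_("E_B", "T3", side), n_("E_B", "A2", side), attach))
        conns.append(ConnectionSpec(n_("E_B", "T3", side), n_("I", "A1", side), _ff_inh_exc()))
        # thoracic excitors report to the ipsilateral wave detectors
        if with_wave_detectors:
            dwf = CellHandle("D_WF", None, side).name
            dwb = CellHandle("D_WB", None, side).name
            for s in THORACIC_SEGMENTS:
                conns.append(ConnectionSpec(n_("E_F", s, side), dwf, _exc()))
                conns.append(ConnectionSpec(n_("E_B", s, side), dwb, _exc()))
        # head-sweep commands stand in for C_B: both drive each side's D_IB
        if with_initiation_detectors:
            dib = CellHandle("D_IB", None, side).name
            for ch in ch_by_side.values():
                conns.append(ConnectionSpec(ch.name, dib, _exc()))

    spec = NetworkSpec(cells, conns, metadata={"circuit": "full_model"})
    spec.validate()
    return CircuitBlueprint(
        spec,
        motifs={
            "initiation_detectors": with_initiation_detectors,
            "wave_detectors": with_wave_detectors,
            "head_sweep_detectors": with_head_sweep_detectors,
        },
        options={"bilateral": True},
    )


def apply_segment_block(
    blueprint: CircuitBlueprint,
    segment: str,
    mode: str,
    window: tuple[float, float],
    amplitude: float = BLOCK_AMPLITUDE_NA,
) -> list[TonicCurrent]:
    """Stimulus fragment halting wave passage at one segment during a window.

    ``mode="forwards"`` hyperpolarises the segment's forwards excitor(s),
    ``"backwards"`` its backwards excitor(s), and ``"both"`` depolarises the
    segment's inhibitor(s), which blocks waves in either direction.  A
    zero-length window produces no episodes.  Bilateral circuits are blocked
    on both sides.
    """
    if segment not in ABDOMINAL_SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    if mode not in ("forwards", "backwards", "both"):
        raise ValueError(f"unknown block mode {mode!r}")
    start, stop = window
    if stop <= start:
        return []
    if mode == "both":
        targets = blueprint.cell_names(cls="I", segment=segment)
        amp = abs(amplitude)
    else:
        cls = "E_F" if mode == "forwards" else "E_B"
        targets = blueprint.cell_names(cls=cls, segment=segment)
        amp = -abs(amplitude)
    if not targets:
        raise ValueError(f"no blockable cells in segment {segment!r}")
    return [TonicCurrent(t, start, stop, amp) for t in targets]


def with_opto(
    blueprint: CircuitBlueprint,
    classes: tuple[str, ...] = INHIBITORY_CLASSES,
    g_opto_Cl: float = 0.2,
) -> CircuitBlueprint:
    """Copy of a blueprint with optogenetic channels in the given classes.

    The channel conducts only during :class:`~larvacpg.engine.OptoWindow`
    episodes of the protocol; placing it in all inhibitory classes reproduces
    the pan-GABAergic silencing experiments, and restricting ``classes``
    targets single motifs.
    """
    chan = OptoChannel(g_opto_Cl=g_opto_Cl)
    new_cells = []
    for c in blueprint.spec.cells:
        h = c.meta.get("handle")
        if h is not None and h.cls in classes:
            new_cells.append(replace(c, opto=chan))
        else:
            new_cells.append(c)
    spec = NetworkSpec(new_cells, list(blueprint.spec.connections),
                       metadata=dict(blueprint.spec.metadata))
    return CircuitBlueprint(spec, dict(blueprint.motifs),
                            {**blueprint.options, "opto_classes": classes,
                             "g_opto_Cl": g_opto_Cl})
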