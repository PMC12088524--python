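"""Config-driven scenario runner.

A :class:`Scenario` is a fully serialisable description of one simulation
experiment: which circuit to build (and with which motif options), the
stimulus protocol (tonic drives, Poisson pulse trains, ramps, optogenetic
unblock windows, segment blocks), the duration, step, seed, and the analysis
settings used to classify the resulting fictive motor programs.  Running a
scenario writes the ROI traces, the classified event table, and a summary
with per-kind frequencies, the transition matrix, overlap counts, and a
provenance record (package version, config hash, seed) — re-running an
archived scenario file reproduces its outputs bit for bit.

Scenario files bundled with the package (``larvacpg/scenarios/*.yaml``)
reproduce the standard experiments: the tonically driven hemisegmental
oscillator, the abdominal chain under Poisson command input, the
segment-block sweep, the thoracic circuit, and full-model runs with and
without simulated optogenetic disinhibition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, analysis, circuits
from .engine import (
    OptoWindow,
    PulseTrain,
    RampCurrent,
    StimulusProtocol,
    TonicCurrent,
    simulate,
)

__all__ = [
    "Scenario",
    "load_scenario",
    "bundled_scenarios",
    "run_scenario",
    "batch_sweep",
    "analyse_recording",
]

_CIRCUITS = {
    "hemisegmental_oscillator": circuits.hemisegmental_oscillator,
    "abdominal_chain": circuits.abdominal_chain,
    "thoracic_circuit": circuits.thoracic_circuit,
    "full_model": circuits.full_model,
}

_EPISODES = {
    "tonic": TonicCurrent,
    "pulse_train": PulseTrain,
    "ramp": RampCurrent,
    "opto_window": OptoWindow,
}


@dataclass
class Scenario:
    """One serialisable simulation experiment."""

    name: str
    circuit: str
    duration_ms: float
    circuit_options: dict = field(default_factory=dict)
    episodes: list = field(default_factory=list)  # list of dicts, "type" key
    blocks: list = field(default_factory=list)  # dicts: segment, mode, window
    opto: dict | None = None  # {"classes": [...], "g_opto_Cl": 0.2}
    dt_ms: float = 1.0
    seed: int = 0
    record_every: int = 1
    analysis: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.circuit not in _CIRCUITS:
            raise ValueError(
                f"circuit: unknown constructor {self.circuit!r}; "
                f"choose from {sorted(_CIRCUITS)}"
            )
        if self.duration_ms <= 0:
            raise ValueError("duration_ms: must be strictly positive")
        for i, ep in enumerate(self.episodes):
            if ep.get("type") not in _EPISODES:
                raise ValueError(
                    f"episodes[{i}].type: unknown episode type {ep.get('type')!r}"
                )
        for i, b in enumerate(self.blocks):
            if b.get("segment") not in circuits.ABDOMINAL_SEGMENTS:
                raise ValueError(f"blocks[{i}].segment: unknown {b.get('segment')!r}")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        sc = cls(**d)
        sc.validate()
        return sc

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    # -- realisation -------------------------------------------------------
    def build(self):
        bp = _CIRCUITS[self.circuit](**self.circuit_options)
        if self.opto:
            bp = circuits.with_opto(
                bp,
                classes=tuple(self.opto.get("classes", circuits.INHIBITORY_CLASSES)),
                g_opto_Cl=self.opto.get("g_opto_Cl", 0.2),
            )
        return bp

    def protocol(self, blueprint) -> StimulusProtocol:
        eps = []
        for d in self.episodes:
            d = dict(d)
            kind = d.pop("type")
            eps.append(_EPISODES[kind](**d))
        for b in self.blocks:
            eps.extend(
                circuits.apply_segment_block(
                    blueprint,
                    b["segment"],
                    b.get("mode", "forwards"),
                    tuple(b.get("window", (0.0, self.duration_ms))),
                    amplitude=b.get("amplitude", circuits.BLOCK_AMPLITUDE_NA),
                )
            )
        return StimulusProtocol(eps, rng_seed=self.seed)


def load_scenario(path) -> Scenario:
    return Scenario.from_dict(yaml.safe_load(Path(path).read_text()))


def bundled_scenarios() -> dict[str, Scenario]:
    """The scenario files shipped inside the package."""
    out = {}
    base = resources.files("larvacpg") / "scenarios"
    for entry in sorted(base.iterdir()):
        if entry.name.endswith(".yaml"):
            sc = Scenario.from_dict(yaml.safe_load(entry.read_text()))
            out[sc.name] = sc
    return out


def analyse_recording(blueprint, recording, settings: dict | None = None):
    """Classify a recording's fictive events and summarise them.

    Settings (all optional): ``side`` (ROI side for bilateral circuits),
    ``segments`` (channel subset), ``anterior_group``/``posterior_group``,
    ``sync_window``, ``sweep_channel`` (thoracic segment for L/R sweeps),
    ``sweep_threshold``, ``sweep_refractory``.

    Returns (events, summary dict).
    """
    s = settings or {}
    bilateral = any(
        c.meta.get("handle") and c.meta["handle"].side
        for c in blueprint.spec.cells
    )
    side = s.get("side", "L" if bilateral else None)
    frame = analysis.roi_frame(recording, blueprint, side=side,
                               segments=s.get("segments"))
    wave_chans = [c for c in frame.columns if c != "time_ms"
                  and c.split("_")[0] not in ("T1", "T2")]
    events: list = []
    if len(wave_chans) >= 2:
        # 10 mV floor: quiescent voltage channels carry no events
        table = analysis.build_peak_table(
            frame[["time_ms", *wave_chans]],
            min_range=s.get("min_range", 10.0),
        )
        kwargs = {}
        if "anterior_group" in s:
            kwargs["anterior_group"] = tuple(s["anterior_group"])
        elif blueprint.spec.metadata.get("circuit") == "abdominal_chain":
            kwargs["anterior_group"] = ("A1", "A2")
        if "posterior_group" in s:
            kwargs["posterior_group"] = tuple(s["posterior_group"])
        events = analysis.classify_events(
            table, sync_window=s.get("sync_window", 500.0), **kwargs
        )
    sweep_seg = s.get("sweep_channel", "T1")
    left_name = f"E_B_{sweep_seg}_L"
    if bilateral and left_name in recording.cells:
        events += analysis.detect_head_sweeps(
            recording.channel(left_name),
            recording.channel(f"E_B_{sweep_seg}_R"),
            recording.time,
            threshold=s.get("sweep_threshold", analysis.VOLTAGE_SWEEP_THRESHOLD),
            refractory=s.get("sweep_refractory", 2000.0),
        )
    events.sort(key=lambda e: e.start)
    analysis.annotate_metrics(events)

    duration = float(recording.time[-1] - recording.time[0]) + recording.dt
    freqs = analysis.event_frequencies(events, duration)
    tm = analysis.transition_matrix([e.kind for e in events])
    overlap = analysis.detect_overlap(events)
    summary = {
        "n_events": len(events),
        "duration_min": duration / 60000.0,
        "events_per_min": {k: round(float(v), 4) for k, v in freqs.items()},
        "transition_matrix": {
            str(r): {str(c): round(float(v), 4) for c, v in row.items()}
            for r, row in tm.iterrows()
        } if not tm.empty else {},
        "n_same_program_overlap": int(overlap["same_program_overlap"].sum())
        if len(overlap) else 0,
        "n_opposite_program_overlap": int(
            overlap["opposite_program_overlap"].sum()
        ) if len(overlap) else 0,
    }
    return events, summary


def events_frame(events) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "kind": e.kind,
            "start_ms": e.start,
            "end_ms": e.end,
            "duration_ms": e.metrics.get("duration_ms", e.end - e.start),
            "interval_ms": e.metrics.get("interval_ms", np.nan),
            "frequency_hz": e.metrics.get("frequency_hz", np.nan),
            "channels": "|".join(e.channels),
        })
    return pd.DataFrame(rows)


def run_scenario(scenario: Scenario | str | Path, outdir=None,
                 save_traces: bool = True):
    """Build, simulate, classify, and (optionally) write one scenario.

    Returns (blueprint, recording, events, summary); with ``outdir`` also
    writes ``traces.csv``, ``events.csv``, ``summary.yaml``, and an atlas of
    every cell and connection (``circuit.txt``) for auditing motif ablations.
    """
    if not isinstance(scenario, Scenario):
        scenario = load_scenario(scenario)
    scenario.validate()
    bp = scenario.build()
    prot = scenario.protocol(bp)
    rec = simulate(
        bp.spec, prot,
        duration=scenario.duration_ms,
        dt=scenario.dt_ms,
        record_every=scenario.record_every,
        record_connections=False,
    )
    events, summary = analyse_recording(bp, rec, scenario.analysis)
    summary["provenance"] = {
        "package_version": __version__,
        "scenario": scenario.name,
        "config_sha256_16": scenario.config_hash(),
        "seed": scenario.seed,
        "n_cells": len(bp.spec.cells),
        "n_connections": len(bp.spec.connections),
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if save_traces:
            traces = analysis.roi_frame(rec, bp,
                                        side=scenario.analysis.get("side"))
            if traces.shape[1] <= 1:  # no segmental ROIs (e.g. single HO)
                traces = rec.to_frame()
            traces.to_csv(out / "traces.csv", index=False)
        events_frame(events).to_csv(out / "events.csv", index=False)
        (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
        atlas = [f"# circuit: {scenario.circuit} {scenario.circuit_options}"]
        atlas += [f"cell {c.name}" for c in bp.spec.cells]
        atlas += [
            f"conn {c.pre} -> {c.post} {c.params.polarity} "
            f"r_max={c.params.r_max} gain={c.params.gain}"
            for c in bp.spec.connections
        ]
        (out / "circuit.txt").write_text("\n".join(atlas) + "\n")
        scenario.to_yaml(out / "scenario.yaml")
    return bp, rec, events, summary


def batch_sweep(template: Scenario, grid: dict, seeds, outdir=None
                ) -> pd.DataFrame:
    """Run a scenario template over a parameter grid with seed replicates.

    ``grid`` maps dotted field paths (e.g. ``"episodes.0.amplitude"``) to
    value lists; the sweep is the Cartesian product.  Returns one summary row
    per (grid cell, seed); deterministic given the grid and seed list.
    """
    import itertools

    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        for seed in seeds:
            d = json.loads(json.dumps(asdict(template)))  # deep copy
            d["seed"] = int(seed)
            for k, v in zip(keys, values):
                node = d
                *path, leaf = k.split(".")
                for part in path:
                    node = node[int(part)] if part.isdigit() else node[part]
                node[int(leaf) if leaf.isdigit() else leaf] = v
            sc = Scenario.from_dict(d)
            _, _, _, summary = run_scenario(sc, outdir=None, save_traces=False)
            row = {k: v for k, v in zip(keys, values)}
            row["seed"] = seed
            row.update({f"epm_{k}": v
                        for k, v in summary["events_per_min"].items()})
            row["n_events"] = summary["n_events"]
            rows.append(row)
    df = pd.DataFrame(rows)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep.csv", index=False)
    return df
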