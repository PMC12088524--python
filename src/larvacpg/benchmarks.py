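"""Standard quantitative experiments on the published circuits.

These are the reference protocols used to quantify the model's headline
behaviours — hemisegmental-oscillator frequency ranges, the segment-block
wave-duration/cycle-period coupling, and the full-model fictive-event
budget — shared by the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import analysis
from .circuits import (
    ABDOMINAL_SEGMENTS,
    abdominal_chain,
    apply_segment_block,
    full_model,
    hemisegmental_oscillator,
)
from .engine import (
    ConnectionSpec,
    PulseTrain,
    StimulusProtocol,
    TonicCurrent,
    simulate,
)

__all__ = [
    "COMMAND_AMP_GRID",
    "KINETICS_TAU_FACTORS",
    "KINETICS_RMAX_FACTORS",
    "MSI_BIAS_CONDITIONS",
    "ho_frequency",
    "tonic_frequency_range",
    "kinetics_frequency_range",
    "block_sweep",
    "full_model_events",
    "event_budget",
]

# Tonic command amplitudes (nA) spanning the HO's operating range; levels
# that fail to sustain a regular oscillation are excluded by measurement.
COMMAND_AMP_GRID = (0.001, 0.0015, 0.002, 0.003, 0.005, 0.008, 0.012,
                    0.02, 0.03, 0.05, 0.07, 0.09, 0.11)

# Synaptic-kinetics co-variation: transmitter clearance time and maximum
# release rate scaled about their defaults, crossing the clearance/release
# ratio over ~3 orders of magnitude.
KINETICS_TAU_FACTORS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
KINETICS_RMAX_FACTORS = (0.25, 1.0, 4.0)

# Mean-stimulus-interval bias conditions for the full model, expressed as
# (posterior, anterior-left, anterior-right) percentages of the 1 s base:
# equal 100:(100:100), forwards bias 50:(100:100), anterior bias 100:(50:100).
BASE_MSI_MS = 1000.0
MSI_BIAS_CONDITIONS = {
    "equal": (100, 100, 100),
    "forwards_bias": (50, 100, 100),
    "anterior_bias": (100, 50, 100),
}


def _scaled_kinetics_blueprint(tau_factor: float, rmax_factor: float):
    bp = hemisegmental_oscillator()
    bp.spec.connections = [
        ConnectionSpec(
            c.pre, c.post,
            c.params.with_(tau_T_clr=c.params.tau_T_clr * tau_factor,
                           r_max=c.params.r_max * rmax_factor),
        )
        for c in bp.spec.connections
    ]
    return bp


def ho_frequency(
    amplitude: float,
    tau_factor: float = 1.0,
    rmax_factor: float = 1.0,
    duration: float = 50000.0,
    dt: float = 1.0,
) -> float | None:
    """Steady oscillation frequency (Hz) of the tonically driven HO.

    Returns None when the oscillator does not sustain a regular rhythm at
    this operating point (fewer than four cycles after the 10 s transient,
    sub-8 mV swings, or cycle-period cv >= 0.2).
    """
    bp = _scaled_kinetics_blueprint(tau_factor, rmax_factor)
    prot = StimulusProtocol([TonicCurrent("C_B", 1000.0, duration, amplitude)])
    rec = simulate(bp.spec, prot, duration=duration, dt=dt,
                   record_connections=False)
    v = rec.channel("E_B")
    sel = rec.time > 10000.0
    v, t = v[sel], rec.time[sel]
    if np.ptp(v) < 8.0:
        return None
    pk, _ = find_peaks(v, prominence=8.0,
                       distance=max(int(500.0 / (t[1] - t[0])), 1))
    if len(pk) < 4:
        return None
    per = np.diff(t[pk])
    if per.std() / per.mean() >= 0.2:
        return None
    return float(1000.0 / per.mean())


def tonic_frequency_range(
    amplitudes=COMMAND_AMP_GRID, duration: float = 50000.0
) -> dict:
    """Max/min HO frequency over the command amplitudes that sustain rhythm."""
    freqs = {}
    for amp in amplitudes:
        f = ho_frequency(amp, duration=duration)
        if f is not None:
            freqs[amp] = f
    vals = list(freqs.values())
    return {
        "frequencies_hz": freqs,
        "f_min": min(vals),
        "f_max": max(vals),
        "fold_range": max(vals) / min(vals),
    }


def kinetics_frequency_range(
    tau_factors=KINETICS_TAU_FACTORS,
    rmax_factors=KINETICS_RMAX_FACTORS,
    amplitudes=(0.005, 0.02, 0.08),
) -> dict:
    """Max/min HO frequency when command strength and synaptic clearance /
    release kinetics are co-varied over the full sustaining grid."""
    vals = []
    for tf in tau_factors:
        dur = 90000.0 if tf >= 4.0 else 50000.0
        for rf in rmax_factors:
            for amp in amplitudes:
                f = ho_frequency(amp, tf, rf, duration=dur)
                if f is not None:
                    vals.append({"tau_factor": tf, "rmax_factor": rf,
                                 "amplitude": amp, "frequency_hz": f})
    df = pd.DataFrame(vals)
    return {
        "grid": df,
        "f_min": float(df["frequency_hz"].min()),
        "f_max": float(df["frequency_hz"].max()),
        "fold_range": float(df["frequency_hz"].max() / df["frequency_hz"].min()),
    }


def block_sweep(direction: str, duration: float = 90000.0,
                amplitude: float = 0.02) -> dict:
    """Wave duration vs cycle period across segment-block positions.

    For each block position (plus the unblocked chain) the abdominal model
    runs under tonic command drive with the block held for the whole run;
    per-cycle duration (20 % rise at the initiating segment to 80 % fall at
    the last intact segment) and period are pooled across positions and
    fitted by ordinary least squares.
    """
    if direction == "forwards":
        blocks = ["A1", "A2", "A3", "A4", "A5", "A6", None]
        cmd = "C_F"
    elif direction == "backwards":
        blocks = ["A3", "A4", "A5", "A6", "A7", "A8", None]
        cmd = "C_B"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    for block in blocks:
        bp = abdominal_chain()
        eps = [TonicCurrent(cmd, 1000.0, duration, amplitude)]
        if block is not None:
            eps += apply_segment_block(bp, block, direction,
                                       (1000.0, duration))
        rec = simulate(bp.spec, StimulusProtocol(eps), duration=duration,
                       record_connections=False)
        if block is None:
            segs = list(ABDOMINAL_SEGMENTS)
        else:
            i = ABDOMINAL_SEGMENTS.index(block)
            segs = (ABDOMINAL_SEGMENTS[i + 1:] if direction == "forwards"
                    else ABDOMINAL_SEGMENTS[:i])
        first, last = ((segs[-1], segs[0]) if direction == "forwards"
                       else (segs[0], segs[-1]))
        frame = analysis.roi_frame(rec, bp, segments=segs)
        table = analysis.build_peak_table(frame)
        df = analysis.progression_metrics(table, first, last)
        df["n_intact"] = len(segs)
        rows.append(df)
    data = pd.concat(rows, ignore_index=True).dropna(subset=["period_ms"])
    slope, intercept, r2 = analysis.linear_fit_r2(
        data["duration_ms"].to_numpy() / 1000.0,
        data["period_ms"].to_numpy() / 1000.0,
    )
    return {"data": data, "slope": slope, "intercept": intercept, "r2": r2}


def full_model_events(
    msi_percentages: tuple[int, int, int],
    seed: int,
    duration_min: float = 30.0,
    base_msi: float = BASE_MSI_MS,
):
    """Run the full bilateral model under one MSI bias and classify events.

    ``msi_percentages`` are (posterior, anterior-left, anterior-right)
    percentages of the base interval: 50 halves the MSI (doubles the mean
    drive).  Returns (events, summary).
    """
    from .scenarios import analyse_recording

    p, al, ar = msi_percentages
    bp = full_model()
    eps = [
        PulseTrain("C_F_L", base_msi * p / 100.0, start=1000.0),
        PulseTrain("C_F_R", base_msi * p / 100.0, start=1000.0),
        PulseTrain("C_HL", base_msi * al / 100.0, start=1000.0),
        PulseTrain("C_HR", base_msi * ar / 100.0, start=1000.0),
    ]
    rec = simulate(
        bp.spec, StimulusProtocol(eps, rng_seed=seed),
        duration=duration_min * 60000.0,
        record_every=5, record_connections=False,
    )
    events, summary = analyse_recording(bp, rec, {"side": "L",
                                                  "sweep_channel": "T1"})
    return events, summary


def event_budget(
    conditions=MSI_BIAS_CONDITIONS,
    seeds=(1, 2, 3),
    duration_min: float = 30.0,
) -> dict:
    """Mean total fictive-event rate per minute for each MSI bias condition.

    Returns the per-condition means and their maximum — the model's overall
    event budget under biased stochastic command drive.
    """
    per_condition = {}
    for name, ratios in conditions.items():
        rates = []
        for seed in seeds:
            _, summary = full_model_events(ratios, seed, duration_min)
            rates.append(summary["events_per_min"]["total"])
        per_condition[name] = float(np.mean(rates))
    return {
        "per_condition_mean": per_condition,
        "max_of_means": max(per_condition.values()),
        "n_runs": len(conditions) * len(seeds),
    }
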