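# Model and methods

This note documents what the package computes, the assumptions and
parameter choices behind it, and the points where the implementation's
behaviour is known to diverge from the biological preparation it abstracts.

## Neurons

Cells are identical spherical single compartments (diameter 10 µm, area
π·d²). The unit contract is: time ms, voltage mV, current nA, conductance
densities mS cm⁻² (totals in µS), capacitance µF cm⁻² (totals in nF),
intracellular Ca²⁺ nM, extracellular Ca²⁺ mM, temperature K; all conversion
constants live in `larvacpg.units`. Membrane currents are positive outward.

Each cell carries a fixed leak (0.35 mS cm⁻², −60 mV), one non-inactivating
voltage-gated Ca²⁺ channel (g_max 0.08 mS cm⁻², half-activation −40 mV,
slope 7.5 mV, activation τ 50 ms), and a calcium pool cleared first-order
(τ 400 ms) to a 0.1 nM floor. The Ca²⁺ reversal is recomputed from the pool
every step via the Nernst relation (2 mM external, 294 K). There are no
Na⁺/K⁺ spike currents: depolarising input recruits the Ca²⁺ channel into a
slow plateau, and the admitted calcium is what couples a cell to its
postsynaptic targets. The membrane time constant is ≈2.9 ms, so voltage is
essentially instantaneous relative to the gate (50 ms), transmitter
(250 ms) and calcium (400 ms) kinetics that set the seconds-scale rhythms.

### Calcium-inflow scale (`b_scale`)

The inflow factor B converts Ca²⁺ current to concentration change in a
restricted volume fraction. Its nominal magnitude (1000) taken at face
value in mM s⁻¹ nA⁻¹ drives the pool many orders of magnitude past the
release midpoints, so the effective inflow is B·`b_scale` (nM ms⁻¹ nA⁻¹).
`b_scale` was calibrated once on the single-HO benchmark — silence at rest,
sustained regular oscillation under tonic command drive across a wide
amplitude range, a single cycle per brief command pulse — and frozen at
0.01 (effective inflow 10 nM ms⁻¹ nA⁻¹). At this value a plateau loads the
pool to ≈120–340 nM, traversing the release-chain operating range.

### Resting point

The activation curve leaves the channel ≈6.5 % open at −60 mV, so the true
resting potential sits a few mV above the leak reversal (≈−55 mV with the
resting calcium the window current maintains). "Silent at rest" therefore
means: the network settles to a stable fixed point with no synaptic
activation and stays within 0.5 mV of it; it does not mean V = −60 mV
exactly. Initial conditions are V = −60 mV, m = m∞(V), Ca_i = 20 nM.

## Synapses

Transmitter release is graded in presynaptic calcium (sigmoid, midpoint
200 nM excitatory / 185 nM inhibitory, slope 15 nM, maximum rate r_max = 80,
or 20 for midline-coordination synapses), cleft transmitter is cleared with
τ 250 ms, and the postsynaptic conductance control factor is an upper-half
sigmoid of cleft transmitter (binding sensitivity 0.5). Reversals are
−10 mV (excitatory) and −70 mV (inhibitory); maximal conductance density is
1 mS cm⁻²; a per-connection gain multiplies the conductance after the gate
(2 on all detector inhibitory outputs). Each directed connection owns an
independent cleft state.

### Transmitter unit scale (`r_scale`)

The cleft transmitter concentration T is on a nominal, unspecified unit
scale. Read with r_max per millisecond, the product r_max·τ_T = 20 000
saturates the binding sigmoid even at the far tail of the release curve
(the gate evaluates to ≈0.09 at the 0.1 nM calcium floor), so a network
built from these numbers latches depolarised at rest — verified
numerically. The effective release rate is therefore r_max·`r_scale` with
`r_scale` = 2×10⁻³ (r_max effectively per second, up to the calibration
factor). This one scale puts the rest-calcium tail far below binding
threshold while plateau calcium sweeps the gate through its range; the
functional midpoint of the calcium→conductance chain lands at ≈125–136 nM.
`b_scale` and `r_scale` were calibrated jointly against two benchmarks
(the single HO, and full-chain wave propagation in the abdominal model) and
are the only fitted quantities in the package.

## Circuits

The circuit library follows the published architecture: per-segment HOs
(E_F, E_B, shared I, reciprocal graded connections, both excitors
identical); feed-forwards intersegmental excitation from the active excitor
to the next segment's excitor *and inhibitor*; command fan-in C_F →
E_F(A6–A8), C_B → E_B(A1–A2); initiation detectors driven by the commands
and inhibiting the opposite program's initiating excitors; wave detectors
collecting every excitor and inhibiting the initiating excitors at both
chain ends; a bilateral thoracic circuit (posterior→anterior connections
only, half-centre head-sweep detectors); and the full bilateral model with
midline excitor coupling (r_max 20), an A1→contralateral-A2 chiasm, T3–A1
attachment, thoracic input to the wave detectors, and head-sweep commands
standing in for C_B (both drive each side's D_IB).

Three wiring constants are this package's own choices where the source
architecture prints none:

* **Feed-forwards-to-inhibitor gain 0.5** (`INTERSEG_INH_FF_GAIN`). With
  the full gain, the relayed plateau is clipped by its own segment's
  inhibition before presynaptic calcium reaches the release range and waves
  die mid-chain; at 0.5 the excitor relay regenerates completely at every
  segment while the phase-advanced inhibition is retained.
* **T3→A1/A2 attachment at gain 2 with fan-out to A2**
  (`T3_ATTACH_GAIN`). This pathway replaces the backwards command neuron,
  whose synapses fired from saturated presynaptic calcium onto *two*
  initiating segments. A thoracic excitor's phasic plateaus release far
  less transmitter; carrying the attachment at gain 2 (the factor the
  architecture already uses on detector outputs) and fanning it out to both
  anterior segments restores the replaced command's efficacy. Without
  this, backwards initiations abort at A1/A2 and the full model never
  completes a backwards wave.
* **Chiasm synapses use the midline-coordination class** (r_max 20),
  matching the other crossing excitatory connections.

Segment blocks (`apply_segment_block`) hyperpolarise the targeted excitors
(−0.1 nA) or depolarise the inhibitor; optogenetic disinhibition places a
normally-blocked chloride conductance (reversal −70 mV; 0.2 or
0.8 mS cm⁻²) in any set of inhibitory classes, opened during scheduled
windows.

## Stimuli and integration

Poisson pulse trains draw i.i.d. exponential inter-onset intervals with
mean MSI; onsets snap to the integration grid and overlapping pulses sum,
so the delivered charge equals amplitude×width×count exactly. Each target
cell's train comes from an independent seed stream derived from the
protocol seed and the cell name. MSI-bias notation "100:(100:100)" means
percentages of a 1 s base interval applied to (posterior, anterior-left,
anterior-right) commands; 50 halves the interval and doubles the mean
drive. Longer bases were examined once during design and reduce program
diversity (backwards waves disappear), so the 1 s base is the default and
the study condition.

Integration is fixed-step exponential Euler, dt = 1 ms by default: within a
step, stimulus events apply first; every synapse advances its cleft state
from the presynaptic calcium at the step start; then each neuron updates
gate, calcium pool, and finally voltage with all conductances frozen over
the step (a staggered explicit scheme — the ordering differences vanish as
dt → 0 and are covered by convergence tests: halving dt changes the HO
period by <2 %, and the pure-RC response matches the closed form to 1 % at
1 ms). State variables are clamped to their domains (gate [0, 1], calcium
≥ floor, transmitter ≥ 0); a non-finite voltage aborts with the step and
cell. The compiled (numba) and reference (numpy) backends implement the
identical scheme and are cross-checked to 10⁻⁹ mV in the tests. Recording
may be decimated (the 30-minute full-model runs record every 5 ms — five
times oversampled relative to the fastest synaptic time constant and ~400×
relative to the behavioural events being classified).

## Analysis conventions

* **Peaks**: local maxima with prominence ≥0.3 and height ≥0.35 of the
  channel's baseline-to-maximum range (baseline = 10th percentile),
  separated by ≥1 s; channels whose whole range is under 10 mV (voltage
  input) are quiescent. Onset = 20 % of the rise; offset = 80 % of the
  fall completed. Wave duration runs from the initiating segment's onset to
  the final segment's offset; cycle period between equivalent onsets.
* **Waves**: progressive peaks spanning *every* analysis channel,
  posterior→anterior (forwards) or the mirror; adjacent channels may
  co-peak within the 500 ms synchrony window (the posterior group initiates
  near-synchronously), but the first-to-last spread must exceed it.
* **Bursts**: near-synchronous peaks confined to the posterior (A6–A8) or
  anterior group with nothing propagating beyond; synchrony across all
  channels is flagged separately. Waves and bursts partition the peak pool.
* **Head sweeps** (voltage input): excursions of the left−right difference
  exceeding 0.5× the channels' peak-to-peak range (a fully one-sided
  episode reaches ≈0.9; the published 5 % criterion applies to ΔF/F input
  via `scale="dff"`), 2 s refractory, and consecutive same-side excursions
  merged into one discrete bout — a change of side starts a new event.
* **Overlap**: same-program overlap = two same-direction waves propagating
  concurrently; opposite-program overlap (collision) = a forwards and a
  backwards wave active simultaneously.
* **Asymmetry KDE**: Gaussian kernel, Scott's-rule bandwidth ×4.
* Transition matrices are row-normalised first-order counts; instantaneous
  frequency is the inverse of the interval since the preceding same-kind
  event.

## What the synthetic protocols do and do not emulate

The stimulus generator reproduces the *statistics* of unpatterned command
input (Poisson pulses at a given MSI), not any real sensory stream, and the
model output is membrane potential, not a calcium-indicator signal: event
time courses are accordingly faster than GCaMP transients, and the
head-sweep reference scale had to be redefined for voltage (above). There
is no sensory feedback, neuromodulation, spiking transmission,
multi-compartment morphology, or body mechanics; passing tests demonstrate
circuit-level sufficiency of the inhibitory motifs under these idealised
conditions, not quantitative agreement with any particular preparation.

## Known limitations and divergences

* **Forwards duration–period coupling is tighter than published.** Under
  deterministic tonic drive every block position produces near-identical
  cycles, so the pooled duration-vs-period fit measures R² ≈ 0.97 in both
  directions (the claimed positive linear coupling holds; the published
  forwards value implies cycle-to-cycle scatter this protocol does not
  generate). No noise was injected to degrade the fit.
* **The full-model event budget runs high.** Waves and bursts total
  ≈1.7/min (inside the published range), but the thoracic half-centre
  alternates nearly continuously under 1 s-MSI drive, and even bout-merged
  scoring yields ≈4 discrete sweeps/min, putting the total at ≈5–6
  events/min against the published 2–4.
* **Collapse under disinhibition is graded, not absolute, at 0.8 mS cm⁻².**
  A 2.5 nS chloride conductance cannot fully silence a synaptically driven
  inhibitor here: patterned waves halve and tonic activity doubles,
  reversibly. Complete reversible collapse into tonic activity does occur
  when inhibition is silenced outright, which the hyperpolarising-ramp
  protocol reaches.
* **Wave detectors can stand in for the hemisegmental inhibitors.** With
  only the HO inhibitors silenced, the D_W loop (excitors → wave detector →
  initiating excitors) keeps a slower rhythm running in the 8-segment
  chain; rhythm generation collapses completely only when both inhibitor
  classes are removed. In the reduced three-segment, detector-free
  preparation — the configuration the experimental collapse is anchored
  to — silencing the hemisegmental inhibitors abolishes all rhythm,
  reversibly, with increased tonic activity. This detector-loop redundancy
  is a testable prediction in its own right.
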