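# Methods

## Model structure

The cell is a branched tree of cable sections. A morphology is either read
from a standard 7-column SWC file or generated synthetically
(`ca1sim.synthetic`). Multi-point SWC somata are collapsed to a single
cylinder of equal membrane area with length = diameter, so a one-point soma
round-trips exactly. Sections are cut at branch points and structure-type
changes; a child section attaches at the end of its parent (position 1.0)
unless the branch point is interior. As in common compartmental practice,
the gap between a soma sample and the first dendritic sample is treated as
attachment, not cable, and the soma's own extent contributes zero to path
distances.

**Region partition.** The apical tree is split into primary trunk, obliques,
and tuft with a deterministic rule: starting at the apical root, follow the
child with the greatest total subtree length; the trunk ends at the first
branch point where the two largest child subtrees each exceed 30% of the
remaining apical length (the terminal bifurcation). Everything distal is
tuft; remaining side branches are obliques. On an unbranched apical cable
the whole cable is primary. The synthetic generator emits ground-truth
labels so the classifier is tested against construction, not against itself.

**Discretization.** Each section gets an odd compartment count from the
d_lambda rule, `nseg = int((L/(0.1·λ₁₀₀) + 0.9)/2)·2 + 1`, with λ₁₀₀ the AC
length constant at 100 Hz. Compartment areas are truncated-cone surfaces;
axial conductances come from the exact integral of `Ra/(π r²)` over each
half-compartment (closed form for linearly tapering radius). Compartments
are Hines-ordered (parent before child), which lets the implicit step solve
the tree system exactly in one down/up sweep.

**Integration.** Crank–Nicolson on the voltage with per-step linearization
of the ionic currents about the current state, and staggered (half-step
offset) analytic-exponential updates of gating states and the calcium pool.
Default dt = 0.025 ms. The passive step response converges at the expected
second order (observed order ≈ 2.0 over dt ∈ {0.1, 0.05, 0.025} ms), and
the passive sealed-end profile matches the analytic cosh solution to <0.01%.
Non-finite state aborts the run naming the first offending compartment and
time. Synaptic events snap to the nearest time step (error ≤ dt/2).

## Mechanisms and parameters

Units: mV, ms, μm, mM, S/cm², mA/cm² (NCX `Vmax` is a current-density
scale). All defaults live in `src/ca1sim/config/mechanisms.yaml`; the table
below records the choices that matter and why.

* **Ionic conditions**: [Ca]ᵢ 50 nM, [Na]ᵢ 10 mM, [Ca]ₒ 2 mM, [Na]ₒ 140 mM,
  T = 307.15 K. With these the NCX reversal potential is −70.9 mV — just
  above the model's resting potential (≈ −73 mV), so the exchanger idles in
  weak forward mode at rest and flips into reverse mode (Ca entry) during
  EPSPs and spikes.
* **NCX kinetics**: γ = 0.35, k_sat = 0.27, km_Na = 87.5 mM, km_Ca =
  1.38 mM, Km_Ca,act = 125 nM, n_Hill = 2 (the standard allosteric–
  electrochemical exchanger formulation). `Vmax = 0.1 mA/cm²` makes NCX the
  dominant clearance path for micromolar calcium transients (severalfold
  faster than the pump at 1 μM) while keeping its electrical contribution
  far below the spike currents — which is what renders the somatic spike
  shape insensitive to NCX localization.
* **Density manipulations** scale `Vmax`; **allostery manipulations** scale
  the output of the allosteric factor (clamped at 1), not its Km. A Km-shift
  variant was considered and rejected as the default because the gradient
  figures describe a spatial scale factor; the scale route keeps gradients
  linear in the manipulated quantity.
* **K[Ca]**: `I = ḡ·m²·(V−E_K)`, `m∞ = αCa²/(αCa²+β)`, `τ = 1/(αCa²+β)`
  floored at 0.1 ms to avoid stiffness. α = 9.2·10⁴ mM⁻²ms⁻¹ and β =
  0.033 ms⁻¹ give an SK-like half-activation of 0.6 μM with τ ≈ 15 ms at
  half-activation. The classic thalamic parameterization of the same
  functional form (α = 48, β = 0.03; EC50 ≈ 25 μM) was tried first and left
  the conductance inert at this model's sub-/low-micromolar dendritic
  calcium transients, so the rates were reset to the SK scale — consistent
  with the literature attributing dendritic bAP gating to SK channels.
  Voltage dependence of α/β is structurally supported but the default is
  calcium-only (voltage factor 1).
* **Calcium pool**: submembrane shell, depth 0.1 μm, first-order decay to
  50 nM with τ = 80 ms, floor 1 nM: `d[Ca]/dt = −i_Ca/(2F·depth) −
  ([Ca]−[Ca]_rest)/τ`. Buffering is folded into the effective depth.
* **Channel complement** (reduced): transient Na⁺ with classic α/β kinetics
  shifted to a −65 mV frame (soma 0.12, axon 0.30, dendrites 0.03 S/cm² —
  the dendritic density supports decremental backpropagation), delayed
  rectifier n⁴ (soma/axon 0.036, dendrites 0.012), A-type K⁺ (0.002 S/cm²
  at the apical root growing linearly ×3 with distance), L-type Ca²⁺
  (10⁻⁴ S/cm², apical only, fixed +120 mV reversal so channel stiffness is
  decoupled from pool dynamics; the exchanger itself always uses true
  concentrations), leak 2.5·10⁻⁵ S/cm² at −65 mV, Cm 1 μF/cm², Ra
  150 Ω·cm. R/T/N-type Ca²⁺, persistent Na⁺ and KM channels are
  representable through the generic channel spec but off by default.
  Intracellular Na⁺ is held at 10 mM (the exchanger's Na flux is reported
  but not fed back).
* **Protocol constants, calibrated once and frozen**: gamma drive = 10
  single-exponential synapses (τ 2 ms, E 0 mV, weight 1.5·10⁻³ μS) placed
  uniformly by cable length on the trunk ≥ 100 μm from the soma, event
  intervals `(1−noise)·mean + noise·Exp(mean)`; bAP pulse 2 nA × 2 ms
  (exactly one somatic spike); STDP EPSP = double-exponential synapse
  (0.5/5 ms, 6·10⁻⁴ μS ≈ 4.9 mV local EPSP) at the distal-most trunk
  compartment, Δt = +10 ms (EPSP leads), 35 ms pairing window, single
  pairing per trial. Replicates: seven drive seeds for the synchronization
  analysis, ten per condition for the localization nulls, five distal-trunk
  synapse sites for the pairing table.

## Readouts

Half-width is the *above-threshold duration* t₂−t₁ at the 10 mV event
threshold, with linearly interpolated crossings — not width at
half-maximum. Depolarization time is stimulus onset to absolute voltage
peak (a threshold-crossing alternative sits behind a flag).
SPIKE-synchronization uses the adaptive coincidence window (half the
minimum of the neighbouring inter-spike intervals of both trains); boundary
spikes use whichever ISIs exist, a train without ISIs falls back to the
partner's, then to half the observation window; empty-vs-nonempty pairs
score 0 and two empty trains 1.

The pairing experiments report two potentiation indices side by side, since
the quantity is not uniquely defined by the study design: **calcium**
(default) = paired peak synaptic [Ca]ᵢ / EPSP-alone peak [Ca]ᵢ, on the view
that postsynaptic calcium is the plasticity-inducing signal; **voltage** =
paired peak depolarization / (EPSP-alone + bAP-alone peaks). The chosen
readout is recorded in all outputs. Group statistics follow the study
conventions verbatim: pairwise two-sided Mann–Whitney U at α = 0.05 plus
Tukey HSD intervals, no additional multiplicity correction.

## Gradient models

Linear gradients span the compartments that carry the mechanism, anchored
at their proximal and distal path-distance extremes; the default endpoints
(0.5, 1.5) average to 1 so gradient-vs-constant comparisons redistribute
rather than dose. On the default synthetic cell, the area-weighted mean
normalized distance is ≈ 0.49, so a 0→2 gradient preserves total capacity
to within ≈ 2–3%; this normalization is flagged in output metadata.

## What the synthetic data does and does not capture

The generator produces a CA1-like tree (20 μm soma; 400 μm trunk tapering
2.5→1 μm; three 150 μm obliques near 120/200/280 μm; a terminal
bifurcation into four 150 μm tuft branches via two 150 μm parents; two
200 μm basals; 300 μm axon; ≈ 130 compartments at d_lambda = 0.1), with
seed-jittered branch positions and angles. It reproduces the *regional
architecture* the analysis needs — a trunk with ≥ 100 μm of
synapse-eligible cable, distinct oblique/tuft subtrees, monotone path
distances — but not the statistics of real reconstructions (branch-order
and diameter distributions, spines, 3D tortuosity). Passing tests therefore
demonstrate correctness of the algorithms and the direction/insensitivity
of the mechanism effects on this reduced architecture, not quantitative
agreement with any particular reconstructed cell; absolute firing rates and
potentiation values shift with morphology and densities.

## Numerical choices and degenerate inputs

Removable singularities of the HH rate functions are expanded analytically.
The NCX conductance used in the Crank–Nicolson linearization is a central
difference over ±0.25 mV (negative slopes are dropped from the matrix for
robustness, never from the current). ΔE raises a domain error beyond
±1000 mV. Degenerate gradient targets (all compartments at one distance)
and empty localization region sets are configuration errors and a knockout,
respectively. All-identical statistical groups report p = 1 rather than
raising. Every protocol is deterministic given (config, seed): re-running an
experiment yields byte-identical CSVs.

## Known limitations

* The pairing potentiation indices are large in absolute value (≈ 70–80)
  because the EPSP-alone calcium response is nearly the resting level
  without NMDA-type synaptic calcium; relative comparisons across
  conditions are the meaningful output.
* The K[Ca]-knockout *direction* on pairing potentiation is not reproduced
  under the frozen calibration: with a conductance-based K[Ca] and
  peak-ratio readouts, removing the conductance relieves damping of the
  calcium/voltage-loaded conditions, so `cagk⁻/⁻` comes out marginally
  *above* wildtype on the calcium readout and indistinguishable (≲ 10⁻⁴
  relative) on the voltage readout. Regimes in which K[Ca] carries somatic
  repolarization (weak delayed rectifier) do produce the opposite
  direction, but only in a bistable corner where bAP propagation becomes
  fragile, and were rejected. Capturing that finding likely requires an
  explicit synaptic weight-update rule, which is outside this package's
  scope (the protocols measure single-pairing responses, not evolving
  weights).
* No spines, no extracellular fields, no stochastic gating, constant
  intracellular Na⁺, single calcium shell (no ER/mitochondrial stores).
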