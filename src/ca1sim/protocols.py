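"""Stimulation paradigms: gamma-frequency drive, single bAPs, STDP pairing.

Three protocols cover the in-silico experiments:

* orthodromic drive — ten glutamatergic synapses placed randomly (uniform by
  cable length) on the apical trunk at least 100 μm from the soma, firing at
  gamma frequency (40 Hz) with fractional-randomness ``noise`` (noise = 1 is
  Poisson); somatic spikes detected at the 10 mV threshold;
* antidromic (bAP) — a brief somatic current pulse that must elicit exactly
  one somatic action potential; per-compartment peak voltage and
  depolarization time are read out over the apical tree;
* STDP pairing — an EPSP (double-exponential synapse at the distal trunk)
  and a somatic bAP pulse separated by ``delta_t``; the EPSP-alone, bAP-alone
  and paired conditions each run from an identical initial state, and the
  synapse-site voltage and calcium readouts quantify pairing supra-additivity.

Every protocol is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cell import CellModel
from .engine import CurrentClamp, SynapseInstance, run_simulation
from .errors import PlacementError, ProtocolError
from .metrics import SPIKE_THRESHOLD_MV, detect_spikes
from .traces import TraceSet

__all__ = [
    "GammaDriveSpec", "STDPPairingSpec", "PlacedSynapse", "BAPResult",
    "PairingResult", "place_random_synapses", "gamma_drive_events",
    "run_orthodromic", "run_bap", "run_stdp_pairing",
]


@dataclass(frozen=True)
class GammaDriveSpec:
    """Random glutamatergic drive onto the apical trunk."""

    n_synapses: int = 10
    rate_hz: float = 40.0
    noise: float = 1.0            # 0 = periodic, 1 = Poisson
    min_distance_um: float = 100.0
    region: str = "apical_primary"
    duration_ms: float = 1000.0
    seed: int = 0
    weight_uS: float = 1.5e-3     # calibrated once for a physiological MFR
    tau_decay_ms: float = 2.0
    e_rev_mV: float = 0.0

    def __post_init__(self):
        if self.rate_hz <= 0 or not (0.0 <= self.noise <= 1.0):
            raise ValueError("rate must be positive and noise in [0, 1]")


@dataclass(frozen=True)
class STDPPairingSpec:
    """One bAP/EPSP pairing trial (positive delta_t: EPSP leads the bAP)."""

    bap_amplitude_nA: float = 2.0
    bap_duration_ms: float = 2.0
    delta_t_ms: float = 10.0
    pairing_window_ms: float = 35.0   # |delta_t| <= window counts as paired
    n_pairings: int = 1
    inter_pairing_interval_ms: float = 100.0
    epsp_weight_uS: float = 6.0e-4    # calibrated to a ~5 mV local EPSP
    epsp_tau_rise_ms: float = 0.5
    epsp_tau_decay_ms: float = 5.0
    e_rev_mV: float = 0.0
    onset_ms: float = 120.0           # settle time before the first EPSP
    tail_ms: float = 200.0
    synapse_compartment: Optional[int] = None  # default: distal-most trunk

    def __post_init__(self):
        if self.n_pairings < 1:
            raise ValueError("n_pairings must be >= 1")
        if not np.isfinite(self.delta_t_ms):
            raise ValueError("delta_t must be finite")


@dataclass(frozen=True)
class PlacedSynapse:
    compartment: int
    section: str
    position: float
    distance_um: float


def place_random_synapses(cell: CellModel, spec: GammaDriveSpec,
                          rng: Optional[np.random.Generator] = None,
                          ) -> List[PlacedSynapse]:
    """Sample synapse sites uniformly by arc length over eligible trunk cable.

    Eligible compartments lie in ``spec.region`` at a path distance of at
    least ``spec.min_distance_um`` from the soma.  Deterministic given the
    seed; sampling is with replacement, as independent afferents may contact
    nearby sites.
    """
    rng = rng or np.random.default_rng(spec.seed)
    eligible = [i for i in cell.compartments_in(spec.region)
                if cell.grid.distance_um[i] >= spec.min_distance_um]
    if not eligible:
        raise PlacementError(
            f"no {spec.region} compartments at >= {spec.min_distance_um} μm")
    eligible = np.asarray(eligible)
    lengths = cell.grid.length_um[eligible]
    if lengths.sum() < 50.0:
        raise PlacementError("eligible cable shorter than 50 μm")
    picks = rng.choice(len(eligible), size=spec.n_synapses,
                       p=lengths / lengths.sum())
    out = []
    for k in picks:
        i = int(eligible[k])
        out.append(PlacedSynapse(
            compartment=i,
            section=cell.grid.section_names[cell.grid.section_index[i]],
            position=float(cell.grid.position[i]),
            distance_um=float(cell.grid.distance_um[i])))
    return out


def gamma_drive_events(spec: GammaDriveSpec,
                       rng: Optional[np.random.Generator] = None,
                       ) -> List[np.ndarray]:
    """Per-synapse event times over [0, duration).

    Inter-event intervals follow the fractional-randomness contract:
    interval = (1−noise)·mean + noise·Exponential(mean) with mean =
    1000/rate ms, so noise = 0 is strictly periodic and noise = 1 a Poisson
    process at the nominal rate.
    """
    rng = rng or np.random.default_rng(spec.seed)
    mean = 1000.0 / spec.rate_hz
    out = []
    for _ in range(spec.n_synapses):
        times = []
        t = 0.0
        while True:
            t += (1.0 - spec.noise) * mean + spec.noise * rng.exponential(mean)
            if t >= spec.duration_ms:
                break
            times.append(t)
        out.append(np.asarray(times))
    return out


def run_orthodromic(cell: CellModel, drive: GammaDriveSpec,
                    sample_every_ms: float = 0.1,
                    record_currents: bool = True) -> TraceSet:
    """Gamma synaptic drive; returns traces with placements/events in meta."""
    rng = np.random.default_rng(drive.seed)
    placements = place_random_synapses(cell, drive, rng)
    events = gamma_drive_events(drive, rng)
    synapses = [
        SynapseInstance(compartment=p.compartment, kind="single_exp",
                        e_rev_mV=drive.e_rev_mV, weight_uS=drive.weight_uS,
                        tau2_ms=drive.tau_decay_ms, events_ms=ev)
        for p, ev in zip(placements, events)
    ]
    traces = run_simulation(cell, drive.duration_ms, synapses=synapses,
                            sample_every_ms=sample_every_ms,
                            record_currents=record_currents)
    traces.meta.update(drive=drive, placements=placements,
                       n_events=[len(e) for e in events])
    return traces


@dataclass
class BAPResult:
    traces: TraceSet
    pulse_onset_ms: float
    apical_compartments: np.ndarray
    peak_mV: np.ndarray            # absolute peak voltage per apical compartment
    depolarization_time_ms: np.ndarray
    somatic_spikes: int


def run_bap(cell: CellModel, amplitude_nA: float = 2.0,
            duration_ms: float = 2.0, onset_ms: float = 50.0,
            tail_ms: float = 100.0, sample_every_ms: float = 0.05,
            require_single_spike: bool = True) -> BAPResult:
    """Somatic current pulse; map the backpropagating wave over the apical tree."""
    total = onset_ms + tail_ms
    clamp = CurrentClamp(cell.soma_compartment, amplitude_nA, onset_ms,
                         duration_ms)
    tr = run_simulation(cell, total, clamps=[clamp],
                        sample_every_ms=sample_every_ms)
    train = detect_spikes(tr.t, tr.soma(), SPIKE_THRESHOLD_MV)
    if require_single_spike and len(train) != 1:
        raise ProtocolError(
            f"bAP pulse elicited {len(train)} somatic spikes (need exactly 1); "
            f"adjust amplitude ({amplitude_nA} nA) or duration ({duration_ms} ms)")
    apical = np.where(np.isin(tr.region_labels,
                              ("apical_primary", "apical_oblique",
                               "apical_tuft")))[0]
    sel = tr.t >= onset_ms
    v_ap = tr.data["V"][np.ix_(sel, apical)]
    peak = v_ap.max(axis=0)
    tpk = tr.t[sel][np.argmax(v_ap, axis=0)] - onset_ms
    return BAPResult(traces=tr, pulse_onset_ms=onset_ms,
                     apical_compartments=apical, peak_mV=peak,
                     depolarization_time_ms=tpk, somatic_spikes=len(train))


@dataclass
class PairingResult:
    """Readouts for the EPSP-alone, bAP-alone and paired conditions.

    ``conditions[name]`` holds ``peak_v_dep`` (mV above pre-stimulus
    baseline), ``peak_ca`` and ``peak_dca`` (mM), ``int_dca`` (mM·ms) at the
    synapse compartment, and ``somatic_spikes``.
    """

    conditions: Dict[str, dict]
    synapse_compartment: int
    delta_t_ms: float
    traces: Dict[str, TraceSet] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _distal_primary_compartment(cell: CellModel) -> int:
    idx = cell.compartments_in("apical_primary")
    if len(idx) == 0:
        raise ProtocolError("cell has no apical_primary compartments")
    return int(idx[np.argmax(cell.grid.distance_um[idx])])


def run_stdp_pairing(cell: CellModel, spec: STDPPairingSpec,
                     sample_every_ms: float = 0.05,
                     keep_traces: bool = False) -> PairingResult:
    """Run the three pairing conditions from identical initial states."""
    syn_comp = (spec.synapse_compartment if spec.synapse_compartment is not None
                else _distal_primary_compartment(cell))
    ipi = spec.inter_pairing_interval_ms
    epsp_times = spec.onset_ms + ipi * np.arange(spec.n_pairings)
    bap_times = epsp_times + spec.delta_t_ms
    t_end = max(epsp_times.max(), bap_times.max()) + spec.tail_ms

    def _run(with_epsp: bool, with_bap: bool) -> TraceSet:
        synapses = []
        clamps = []
        if with_epsp:
            synapses.append(SynapseInstance(
                compartment=syn_comp, kind="double_exp",
                e_rev_mV=spec.e_rev_mV, weight_uS=spec.epsp_weight_uS,
                tau1_ms=spec.epsp_tau_rise_ms, tau2_ms=spec.epsp_tau_decay_ms,
                events_ms=epsp_times))
        if with_bap:
            clamps = [CurrentClamp(cell.soma_compartment,
                                   spec.bap_amplitude_nA, t, spec.bap_duration_ms)
                      for t in bap_times]
        return run_simulation(cell, t_end, clamps=clamps, synapses=synapses,
                              sample_every_ms=sample_every_ms)

    runs = {"epsp": _run(True, False), "bap": _run(False, True),
            "paired": _run(True, True)}

    t0 = min(spec.onset_ms, float(bap_times.min())) - 1.0
    conditions: Dict[str, dict] = {}
    for name, tr in runs.items():
        sel = tr.t >= t0
        i_base = int(np.searchsorted(tr.t, t0)) - 1
        v = tr.at("V", syn_comp)
        ca = tr.at("Ca_i", syn_comp)
        v_base, ca_base = float(v[i_base]), float(ca[i_base])
        conditions[name] = dict(
            peak_v_dep=float(v[sel].max() - v_base),
            peak_ca=float(ca[sel].max()),
            peak_dca=float(ca[sel].max() - ca_base),
            int_dca=float(np.trapezoid(ca[sel] - ca_base, tr.t[sel])),
            baseline_v=v_base, baseline_ca=ca_base,
            somatic_spikes=len(detect_spikes(tr.t, tr.soma())),
        )
    result = PairingResult(
        conditions=conditions, synapse_compartment=syn_comp,
        delta_t_ms=spec.delta_t_ms,
        traces=runs if keep_traces else {},
        meta=dict(spec=spec, paired=abs(spec.delta_t_ms) <= spec.pairing_window_ms,
                  synapse_distance_um=float(cell.grid.distance_um[syn_comp])),
    )
    return result
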