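"""Synthetic inputs: CA1-like morphologies, analytic oracles, canned trains.

Everything the pipeline needs can be generated here, with explicit seeds, so
no downloaded reconstruction is required.  The reduced CA1 morphology mimics
the architecture the analysis assumes: a soma, an axon, basal dendrites, and
an apical tree made of a tapering primary trunk with oblique side branches
and a terminal tuft.  It is not a statistical model of real CA1 arbors; it
exists so that region classification, synapse placement (>= 100 μm rule) and
the localization/gradient manipulations all have well-defined ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import PlacementError
from .morphology import Morphology, Section, write_swc

__all__ = [
    "SyntheticMorphologySpec",
    "generate_ball_and_stick",
    "generate_reduced_ca1",
    "write_with_sidecar",
    "space_constant_um",
    "passive_steady_state_profile",
    "passive_cable_step_response",
    "canned_spike_trains",
]


@dataclass
class SyntheticMorphologySpec:
    """Geometry of the reduced CA1-like tree (lengths/diameters in μm)."""

    soma_length: float = 20.0
    soma_diameter: float = 20.0
    trunk_length: float = 400.0
    trunk_diam_proximal: float = 2.5
    trunk_diam_distal: float = 1.0
    n_obliques: int = 3
    oblique_length: float = 150.0
    oblique_diameter: float = 0.8
    oblique_positions: Tuple[float, ...] = (120.0, 200.0, 280.0)  # μm from soma
    oblique_jitter: float = 20.0        # ± μm jitter on attachment, per seed
    n_tuft_branches: int = 4            # terminal branches (binary tuft)
    tuft_length: float = 150.0          # per branch
    tuft_diameter: float = 0.7
    n_basal: int = 2
    basal_length: float = 200.0
    basal_diameter: float = 1.5
    axon_length: float = 300.0
    axon_diameter: float = 1.0

    def __post_init__(self):
        for name in ("soma_length", "soma_diameter", "trunk_length",
                     "oblique_length", "oblique_diameter", "tuft_length",
                     "tuft_diameter", "basal_length", "basal_diameter",
                     "axon_length", "axon_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _straight_section(name: str, structure: str, start: np.ndarray,
                      direction: np.ndarray, length: float,
                      r0: float, r1: float, parent: int,
                      parent_pos: float = 1.0) -> Section:
    direction = direction / np.linalg.norm(direction)
    end = start + direction * length
    pts = np.array([[*start, r0], [*end, r1]], dtype=float)
    return Section(name, structure, pts, parent=parent, parent_pos=parent_pos)


def generate_ball_and_stick(apical_length: float = 400.0,
                            apical_diameter: float = 1.0,
                            soma_size: float = 20.0) -> Morphology:
    """Soma plus a single unbranched apical cable (analytic test geometry)."""
    half = soma_size / 2.0
    soma = Section("soma", "soma",
                   np.array([[-half, 0, 0, soma_size / 2],
                             [half, 0, 0, soma_size / 2]]), parent=-1)
    apical = _straight_section("apical[0]", "apical", np.zeros(3),
                               np.array([0.0, 1.0, 0.0]), apical_length,
                               apical_diameter / 2, apical_diameter / 2,
                               parent=0, parent_pos=0.5)
    return Morphology([soma, apical])


def generate_reduced_ca1(spec: Optional[SyntheticMorphologySpec] = None,
                         seed: int = 0) -> Morphology:
    """Deterministic reduced CA1-like morphology with ground-truth regions.

    The returned morphology carries ``ground_truth_regions`` (section name ->
    region label) for classifier testing.  Branch attachment points and branch
    directions are jittered by ``seed``; region counts are seed-invariant.
    """
    spec = spec or SyntheticMorphologySpec()
    rng = np.random.default_rng(seed)

    half = spec.soma_length / 2.0
    soma = Section("soma", "soma",
                   np.array([[-half, 0, 0, spec.soma_diameter / 2],
                             [half, 0, 0, spec.soma_diameter / 2]]), parent=-1)
    sections: List[Section] = [soma]
    labels: Dict[str, str] = {"soma": "soma"}

    # jittered oblique attachment distances along the trunk, kept ordered and
    # inside (placement feasibility) the trunk
    pos = np.asarray(spec.oblique_positions[: spec.n_obliques], dtype=float)
    if len(pos) < spec.n_obliques:
        extra = np.linspace(100.0, spec.trunk_length - 50.0, spec.n_obliques)
        pos = extra
    pos = pos + rng.uniform(-spec.oblique_jitter, spec.oblique_jitter, len(pos))
    pos = np.clip(np.sort(pos), 30.0, spec.trunk_length - 30.0)

    # trunk: sections cut at each oblique attachment, tapering linearly
    up = np.array([0.0, 1.0, 0.0])
    r0, r1 = spec.trunk_diam_proximal / 2, spec.trunk_diam_distal / 2

    def trunk_radius(d):
        return r0 + (r1 - r0) * d / spec.trunk_length

    breaks = [0.0, *pos.tolist(), spec.trunk_length]
    trunk_idx: List[int] = []
    parent, parent_pos = 0, 0.5
    for k in range(len(breaks) - 1):
        a, b = breaks[k], breaks[k + 1]
        name = f"apical[{len([s for s in sections if s.structure=='apical'])}]"
        sec = _straight_section(name, "apical", np.array([0.0, a, 0.0]), up,
                                b - a, trunk_radius(a), trunk_radius(b),
                                parent=parent, parent_pos=parent_pos)
        sections.append(sec)
        labels[name] = "apical_primary"
        parent, parent_pos = len(sections) - 1, 1.0
        trunk_idx.append(parent)

    # obliques off the trunk at each break (except tip)
    for k in range(spec.n_obliques):
        theta = rng.uniform(0, 2 * math.pi)
        direction = np.array([math.cos(theta), 0.35, math.sin(theta)])
        name = f"apical[{len([s for s in sections if s.structure=='apical'])}]"
        sec = _straight_section(name, "apical",
                                np.array([0.0, pos[k], 0.0]), direction,
                                spec.oblique_length,
                                spec.oblique_diameter / 2, spec.oblique_diameter / 2,
                                parent=trunk_idx[k], parent_pos=1.0)
        sections.append(sec)
        labels[name] = "apical_oblique"

    # tuft: binary terminal bifurcation at the trunk tip; each daughter splits
    # again until n_tuft_branches terminal branches exist
    tip = np.array([0.0, spec.trunk_length, 0.0])
    n_terminal = max(2, spec.n_tuft_branches)
    rt = spec.tuft_diameter / 2

    def add_tuft(start, parent_idx, n_leaves, depth):
        if n_leaves == 1:
            theta = rng.uniform(0, 2 * math.pi)
            direction = np.array([0.5 * math.cos(theta), 1.0, 0.5 * math.sin(theta)])
            name = f"apical[{len([s for s in sections if s.structure=='apical'])}]"
            sec = _straight_section(name, "apical", start, direction,
                                    spec.tuft_length, rt, rt,
                                    parent=parent_idx, parent_pos=1.0)
            sections.append(sec)
            labels[name] = "apical_tuft"
            return
        left = n_leaves // 2
        for side, leaves in ((-1.0, left), (1.0, n_leaves - left)):
            theta = rng.uniform(0, 2 * math.pi)
            direction = np.array([side * 0.8 + 0.2 * math.cos(theta), 1.0,
                                  0.2 * math.sin(theta)])
            name = f"apical[{len([s for s in sections if s.structure=='apical'])}]"
            sec = _straight_section(name, "apical", start, direction,
                                    spec.tuft_length, rt, rt,
                                    parent=parent_idx, parent_pos=1.0)
            sections.append(sec)
            labels[name] = "apical_tuft"
            idx = len(sections) - 1
            if leaves > 1:
                add_tuft(sec.points[-1, :3].copy(), idx, leaves, depth + 1)

    add_tuft(tip, trunk_idx[-1], n_terminal, 0)

    # basal dendrites and axon off the soma
    for k in range(spec.n_basal):
        theta = rng.uniform(0, 2 * math.pi)
        direction = np.array([0.6 * math.cos(theta), -1.0, 0.6 * math.sin(theta)])
        name = f"basal[{k}]"
        sec = _straight_section(name, "basal", np.zeros(3), direction,
                                spec.basal_length, spec.basal_diameter / 2,
                                spec.basal_diameter / 2, parent=0, parent_pos=0.5)
        sections.append(sec)
        labels[name] = "basal"
    axon = _straight_section("axon[0]", "axon", np.zeros(3),
                             np.array([0.0, -1.0, 0.0]), spec.axon_length,
                             spec.axon_diameter / 2, spec.axon_diameter / 2,
                             parent=0, parent_pos=0.5)
    sections.append(axon)
    labels["axon[0]"] = "axon"

    m = Morphology(sections)
    # feasibility of the >=100 μm synapse placement rule on the trunk
    eligible = sum(max(0.0, s.length) for i, s in enumerate(m.sections)
                   if labels.get(s.name) == "apical_primary")
    if spec.trunk_length - 100.0 < 50.0:
        raise PlacementError(
            f"trunk length {spec.trunk_length} leaves <50 μm of cable beyond "
            f"the 100 μm placement exclusion")
    m.ground_truth_regions = labels
    return m


def write_with_sidecar(m: Morphology, swc_path) -> None:
    """Write SWC plus a JSON sidecar of ground-truth region labels."""
    write_swc(m, swc_path)
    labels = getattr(m, "ground_truth_regions", None)
    if labels is not None:
        with open(str(swc_path) + ".regions.json", "w") as fh:
            json.dump(labels, fh, indent=1)


# ---------------------------------------------------------------------------
# Analytic passive-cable oracles
# ---------------------------------------------------------------------------

def space_constant_um(diameter_um: float, g_leak_S_cm2: float,
                      Ra_ohm_cm: float) -> float:
    """DC space constant λ = sqrt(d/(4 g_leak Ra)), returned in μm."""
    d_cm = diameter_um * 1e-4
    lam_cm = math.sqrt(d_cm / (4.0 * g_leak_S_cm2 * Ra_ohm_cm))
    return lam_cm * 1e4


def passive_steady_state_profile(x_um, L_um: float, lambda_um: float,
                                 v0: float = 1.0):
    """Sealed-end cable steady state: V(x) = V0 cosh((L−x)/λ)/cosh(L/λ)."""
    x = np.asarray(x_um, dtype=float)
    return v0 * np.cosh((L_um - x) / lambda_um) / np.cosh(L_um / lambda_um)


def passive_cable_step_response(x_um, t_ms, L_um: float, lambda_um: float,
                                tau_m_ms: float, v_ss0: float = 1.0,
                                n_modes: int = 200):
    """Separation-of-variables transient for a sealed-sealed passive cable.

    A step current is injected at x = 0 at t = 0 with the cable initially at
    rest; ``v_ss0`` is the resulting steady-state voltage at x = 0.  Returns
    the deviation from rest V(x, t) (same units as ``v_ss0``).
    """
    x = np.atleast_1d(np.asarray(x_um, dtype=float))
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    v_ss = passive_steady_state_profile(x, L_um, lambda_um, v_ss0)
    # expand -V_ss in cos(nπx/L); numeric projection on a fine grid
    xi = np.linspace(0.0, L_um, 4001)
    f = -passive_steady_state_profile(xi, L_um, lambda_um, v_ss0)
    out = np.empty((len(t), len(x)))
    acc = np.zeros((len(t), len(x)))
    for n in range(n_modes):
        phi_xi = np.cos(n * math.pi * xi / L_um)
        cn = np.trapezoid(f * phi_xi, xi) * ((1.0 if n == 0 else 2.0) / L_um)
        rate = (1.0 + (n * math.pi * lambda_um / L_um) ** 2) / tau_m_ms
        acc += cn * np.outer(np.exp(-rate * t), np.cos(n * math.pi * x / L_um))
    out = v_ss[None, :] + acc
    return out.squeeze()


# ---------------------------------------------------------------------------
# Canned spike trains for metric tests
# ---------------------------------------------------------------------------

def canned_spike_trains(case: str, seed: int = 0,
                        duration_ms: float = 1000.0):
    """Named spike-train fixtures: returns (list of arrays, (t0, t1)).

    Cases: ``identical_pair`` (sync 1), ``disjoint_pair`` (sync 0),
    ``jittered_pair`` (small jitter, all coincidences inside the adaptive
    window), ``poisson_set`` (five independent 20 Hz Poisson trains).
    """
    window = (0.0, duration_ms)
    base = np.arange(50.0, duration_ms - 50.0, 50.0)
    if case == "identical_pair":
        return [base.copy(), base.copy()], window
    if case == "disjoint_pair":
        # separations (≥ 400 ms) vastly exceed both trains' 10 ms ISIs
        return [np.arange(50.0, 150.0, 10.0), np.arange(700.0, 800.0, 10.0)], window
    if case == "jittered_pair":
        rng = np.random.default_rng(seed)
        jit = rng.uniform(-1.0, 1.0, len(base))  # ≪ 50 ms ISI
        return [base.copy(), np.sort(base + jit)], window
    if case == "poisson_set":
        rng = np.random.default_rng(seed)
        trains = []
        for _ in range(5):
            isi = rng.exponential(50.0, size=200)
            t = np.cumsum(isi)
            trains.append(t[t < duration_ms])
        return trains, window
    raise ValueError(f"unknown canned case {case!r}")
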