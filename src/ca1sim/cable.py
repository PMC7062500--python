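"""Spatial discretization of a morphology and the branched-cable linear solve.

Units follow the NEURON conventions used throughout the package: mV, ms, μm,
Ω·cm (axial resistivity), μF/cm² (specific capacitance), S/cm² (conductance
density).  Absolute axial conductances are stored in siemens so that
S × mV = mA matches the membrane-current unit (mA/cm² × cm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import DiscretizationError, NumericalError
from .morphology import Morphology

__all__ = [
    "PassiveParams",
    "CompartmentGrid",
    "lambda_f_um",
    "d_lambda_nseg",
    "build_grid",
    "hines_solve",
]


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane and cytoplasm parameters (typical CA1 values)."""

    Cm: float = 1.0          # μF/cm²
    Ra: float = 150.0        # Ω·cm
    g_leak: float = 2.5e-5   # S/cm²
    E_leak: float = -65.0    # mV

    def __post_init__(self):
        if self.Cm <= 0 or self.Ra <= 0 or self.g_leak <= 0:
            raise ValueError("Cm, Ra and g_leak must be positive")

    @property
    def tau_m_ms(self) -> float:
        return self.Cm * 1e-3 / self.g_leak  # μF/cm² / (S/cm²) -> ms


def lambda_f_um(diameter_um: float, f_hz: float, Ra: float, Cm: float) -> float:
    """AC length constant at frequency f: λ_f = 1e5·sqrt(d/(4πf·Ra·Cm)) in μm."""
    if diameter_um <= 0 or f_hz <= 0 or Ra <= 0 or Cm <= 0:
        raise DiscretizationError("lambda_f requires positive geometry/parameters")
    return 1e5 * math.sqrt(diameter_um / (4.0 * math.pi * f_hz * Ra * Cm))


def d_lambda_nseg(length_um: float, diameter_um: float, Ra: float = 150.0,
                  Cm: float = 1.0, d_lambda: float = 0.1,
                  f_hz: float = 100.0) -> int:
    """Odd compartment count from the d_lambda rule.

    nseg = int((L/(d_lambda·λ_f) + 0.9) / 2) * 2 + 1, with λ_f the AC length
    constant at ``f_hz``.
    """
    if length_um < 0 or diameter_um <= 0:
        raise DiscretizationError("non-positive geometry")
    if length_um == 0:
        return 1
    lam = lambda_f_um(diameter_um, f_hz, Ra, Cm)
    return int((length_um / (d_lambda * lam) + 0.9) / 2.0) * 2 + 1


@dataclass
class CompartmentGrid:
    """Hines-ordered compartments with areas and axial conductances.

    ``parent[i] < i`` for every non-root compartment; ``g_axial_S[i]`` is the
    absolute conductance (S) between compartment i and its parent.
    """

    section_index: np.ndarray   # int, per compartment
    position: np.ndarray        # center position in [0,1] within the section
    length_um: np.ndarray
    diam_um: np.ndarray         # area-equivalent mean diameter
    area_cm2: np.ndarray
    parent: np.ndarray          # int, -1 for the root compartment
    g_axial_S: np.ndarray       # 0.0 for the root
    distance_um: np.ndarray     # path distance from the soma to the center
    section_slices: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    section_names: List[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.parent)

    def compartment_at(self, section: int, pos: float) -> int:
        start, stop = self.section_slices[section]
        nseg = stop - start
        return start + min(int(pos * nseg), nseg - 1)

    def region_labels(self, region_map) -> np.ndarray:
        """Per-compartment region labels from a section RegionMap."""
        labels = np.empty(self.n, dtype=object)
        for i in range(self.n):
            name = self.section_names[self.section_index[i]]
            labels[i] = region_map.assignment[name]
        return labels


def _radius_at(arc: np.ndarray, rad: np.ndarray, s: float) -> float:
    return float(np.interp(s, arc, rad))


def _span_breaks(arc: np.ndarray, a: float, b: float) -> np.ndarray:
    inner = arc[(arc > a) & (arc < b)]
    return np.concatenate([[a], inner, [b]])


def _frustum_area_cm2(arc, rad, a, b) -> float:
    """Lateral frustum surface over arc span [a, b] (μm inputs, cm² output)."""
    s = _span_breaks(arc, a, b)
    r = np.interp(s, arc, rad)
    dl = np.diff(s)
    slant = np.sqrt(dl ** 2 + np.diff(r) ** 2)
    area_um2 = float(np.sum(math.pi * (r[:-1] + r[1:]) * slant))
    return area_um2 * 1e-8


def _axial_resistance_ohm(arc, rad, a, b, Ra: float) -> float:
    """∫ Ra dx / (π r(x)²) over [a, b]; exact for piecewise-linear radii."""
    s = _span_breaks(arc, a, b)
    r = np.interp(s, arc, rad)
    dl = np.diff(s) * 1e-4            # μm -> cm
    r_cm = r * 1e-4
    return float(np.sum(Ra * dl / (math.pi * r_cm[:-1] * r_cm[1:])))


def build_grid(m: Morphology, p: Optional[PassiveParams] = None,
               d_lambda: float = 0.1, f_hz: float = 100.0,
               nseg_override: Optional[Dict[str, int]] = None) -> CompartmentGrid:
    """Discretize every section with the d_lambda rule (odd nseg per section).

    Areas are truncated-cone surfaces; half-compartment axial resistances come
    from the exact integral of Ra/(π r²) over each half span.  A child section
    connects to the node of the parent compartment containing its attachment
    position, through its own first half-resistance.
    """
    p = p or PassiveParams()
    nseg_override = nseg_override or {}
    d0 = m.section_start_distances()

    sec_idx: List[int] = []
    pos: List[float] = []
    length: List[float] = []
    diam: List[float] = []
    area: List[float] = []
    parent: List[int] = []
    g_ax: List[float] = []
    dist: List[float] = []
    half_r_left: List[float] = []   # Ω from compartment center to its 0-side
    half_r_right: List[float] = []
    slices: Dict[int, Tuple[int, int]] = {}

    for si, sec in enumerate(m.sections):
        L = sec.length
        if L <= 0:
            raise DiscretizationError(f"zero-length section {sec.name!r}")
        if sec.name in nseg_override:
            nseg = int(nseg_override[sec.name])
            if nseg < 1 or nseg % 2 == 0:
                raise DiscretizationError("nseg override must be odd and positive")
        elif sec.structure == "soma":
            nseg = 1
        else:
            nseg = d_lambda_nseg(L, sec.mean_diameter, p.Ra, p.Cm, d_lambda, f_hz)
        arc = sec.arc_positions()
        rad = sec.points[:, 3]
        start = len(sec_idx)
        for k in range(nseg):
            a, b = L * k / nseg, L * (k + 1) / nseg
            mid = 0.5 * (a + b)
            A = _frustum_area_cm2(arc, rad, a, b)
            if A <= 0:
                raise DiscretizationError(f"zero-area compartment in {sec.name!r}")
            sec_idx.append(si)
            pos.append((k + 0.5) / nseg)
            length.append(b - a)
            area.append(A)
            diam.append(A * 1e8 / (math.pi * (b - a)))
            half_r_left.append(_axial_resistance_ohm(arc, rad, a, mid, p.Ra))
            half_r_right.append(_axial_resistance_ohm(arc, rad, mid, b, p.Ra))
            if sec.structure == "soma":
                dist.append(0.0)
            else:
                dist.append(d0[si] + mid)
            if k == 0:
                if sec.parent < 0:
                    parent.append(-1)
                    g_ax.append(0.0)
                else:
                    ps, pe = slices[sec.parent]
                    pn = pe - ps
                    pcomp = ps + min(int(sec.parent_pos * pn), pn - 1)
                    parent.append(pcomp)
                    # child's own half-resistance to the parent node
                    g_ax.append(1.0 / half_r_left[-1])
            else:
                j = len(sec_idx) - 2
                parent.append(j)
                g_ax.append(1.0 / (half_r_right[j] + half_r_left[-1]))
        slices[si] = (start, len(sec_idx))

    return CompartmentGrid(
        section_index=np.asarray(sec_idx, dtype=np.int64),
        position=np.asarray(pos), length_um=np.asarray(length),
        diam_um=np.asarray(diam), area_cm2=np.asarray(area),
        parent=np.asarray(parent, dtype=np.int64),
        g_axial_S=np.asarray(g_ax), distance_um=np.asarray(dist),
        section_slices=slices,
        section_names=[s.name for s in m.sections],
    )


def hines_solve(diag: np.ndarray, offdiag: np.ndarray, parent: np.ndarray,
                rhs: np.ndarray) -> np.ndarray:
    """Exact O(n) solve of the symmetric tree system M x = rhs.

    ``M[i, i] = diag[i]`` and ``M[i, parent[i]] = M[parent[i], i] =
    offdiag[i]`` (offdiag[root] ignored).  Compartments must be in
    parent-before-child order.  One down-sweep eliminates children into
    parents; one up-sweep back-substitutes.
    """
    from ._kernel import hines_solve_kernel

    d = np.array(diag, dtype=np.float64)
    o = np.array(offdiag, dtype=np.float64)
    par = np.asarray(parent, dtype=np.int64)
    b = np.array(rhs, dtype=np.float64)
    x = np.empty_like(b)
    ok = hines_solve_kernel(d, o, par, b, x)
    if not ok:
        raise NumericalError("singular diagonal encountered in Hines solve")
    return x
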