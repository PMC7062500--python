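"""Equation-level membrane mechanisms.

The two mechanisms at the core of the package are implemented exactly as
published equation sets:

* **NCX** — the Na⁺/Ca²⁺ exchanger current is the product of an allosteric
  factor ``Allo = 1/(1 + (Km_Ca_act/[Ca]_i)^n)`` and an electrochemical
  driving term ΔE built from the 3 Na⁺ : 1 Ca²⁺ translocation exponentials.
  Positive current is net outward (reverse mode, Ca²⁺ entry); the current is
  zero exactly at the thermodynamic reversal potential
  ``V_rev = (RT/F)·ln([Na]_o³[Ca]_i / ([Na]_i³[Ca]_o))``.

* **K[Ca]** — a Hill-type Ca²⁺-activated K⁺ conductance,
  ``I = gbar·m²·(V−E_K)`` with ``m∞ = αCa^n/(αCa^n+β)`` and
  ``τ = 1/(αCa^n+β)`` (n = 2).

Alongside them: a first-order submembrane calcium shell with pump-like decay,
and a reduced Hodgkin–Huxley channel complement (Na, delayed rectifier,
A-type, L-type Ca) whose rate functions mirror the integration kernel.

All defaults live in ``config/mechanisms.yaml``; nothing numeric is hard
coded in two places except the gating-rate formulas, which are asserted
against the kernel by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import NamedTuple

import numpy as np
import yaml

from ._kernel import F_FARADAY, R_GAS

__all__ = [
    "IonConditions", "NCXParams", "KCaParams", "KCaState", "CaPoolParams",
    "HHChannelSpec", "load_default_config",
    "ncx_allosteric_factor", "ncx_delta_e", "ncx_reversal_potential",
    "ncx_current_and_fluxes", "NCXFluxes",
    "kca_m_inf", "kca_tau", "kca_m_step", "kca_current",
    "ca_pool_step", "hh_channel_current",
    "na_rates", "kdr_rates", "ka_steady", "cal_steady",
]


def _coerce_numbers(obj):
    # YAML 1.1 leaves exponent forms like "9.2e4" as strings
    if isinstance(obj, dict):
        return {k: _coerce_numbers(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_coerce_numbers(v) for v in obj]
    if isinstance(obj, str):
        try:
            return float(obj)
        except ValueError:
            return obj
    return obj


@lru_cache(maxsize=1)
def load_default_config() -> dict:
    """Parsed default mechanism configuration (``config/mechanisms.yaml``)."""
    ref = resources.files("ca1sim").joinpath("config/mechanisms.yaml")
    return _coerce_numbers(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonConditions:
    Ca_i: float = 5e-5     # mM
    Na_i: float = 10.0     # mM
    Ca_o: float = 2.0      # mM
    Na_o: float = 140.0    # mM
    T: float = 307.15      # K

    def __post_init__(self):
        if min(self.Ca_i, self.Na_i, self.Ca_o, self.Na_o) <= 0 or self.T <= 0:
            raise ValueError("concentrations and temperature must be positive")

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "IonConditions":
        c = (cfg or load_default_config())["ion_conditions"]
        return cls(Ca_i=c["Ca_i_mM"], Na_i=c["Na_i_mM"], Ca_o=c["Ca_o_mM"],
                   Na_o=c["Na_o_mM"], T=c["temperature_K"])


@dataclass(frozen=True)
class NCXParams:
    Vmax: float = 0.1        # mA/cm²
    gamma: float = 0.35
    ksat: float = 0.27
    km_Na: float = 87.5      # mM
    km_Ca: float = 1.38      # mM
    Km_Ca_act: float = 1.25e-4  # mM
    n_Hill: float = 2.0
    allo_scale: float = 1.0  # multiplicative allostery manipulation (<= 1 after clamp)

    def __post_init__(self):
        if self.Vmax < 0 or not (0 <= self.gamma <= 1) or self.ksat < 0:
            raise ValueError("invalid NCX parameters")
        if min(self.km_Na, self.km_Ca, self.Km_Ca_act) <= 0 or self.n_Hill <= 0:
            raise ValueError("invalid NCX half-saturation parameters")

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "NCXParams":
        c = (cfg or load_default_config())["ncx"]
        return cls(Vmax=c["Vmax_mA_cm2"], gamma=c["gamma"], ksat=c["ksat"],
                   km_Na=c["km_Na_mM"], km_Ca=c["km_Ca_mM"],
                   Km_Ca_act=c["Km_Ca_act_mM"], n_Hill=c["n_Hill"])


@dataclass(frozen=True)
class KCaParams:
    gbar: float = 0.003      # S/cm²
    E_K: float = -80.0       # mV
    n: int = 2
    alpha: float = 9.2e4     # mM⁻ⁿ ms⁻¹
    beta: float = 0.033      # ms⁻¹
    tau_min: float = 0.1     # ms

    def __post_init__(self):
        if self.gbar < 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("invalid K[Ca] parameters")

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "KCaParams":
        c = (cfg or load_default_config())["kca"]
        return cls(gbar=c["gbar_S_cm2"], E_K=c["E_K_mV"], n=c["n"],
                   alpha=c["alpha_per_mM2_ms"], beta=c["beta_per_ms"],
                   tau_min=c["tau_min_ms"])


@dataclass
class KCaState:
    m: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("activation variable m must lie in [0, 1]")


@dataclass(frozen=True)
class CaPoolParams:
    shell_depth: float = 0.1   # μm
    tau_decay: float = 80.0    # ms
    Ca_rest: float = 5e-5      # mM
    Ca_min: float = 1e-6       # mM

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "CaPoolParams":
        c = (cfg or load_default_config())["ca_pool"]
        return cls(shell_depth=c["shell_depth_um"], tau_decay=c["tau_decay_ms"],
                   Ca_rest=c["Ca_rest_mM"], Ca_min=c["Ca_min_mM"])


@dataclass(frozen=True)
class HHChannelSpec:
    """An ohmic channel ``gbar·∏ gateᵉ·(V−E)`` with inf/tau gate kinetics."""

    name: str
    gbar: float
    E_rev: float
    gates: tuple  # of (name, exponent, inf_tau_fn) with fn(V) -> (inf, tau ms)


# ---------------------------------------------------------------------------
# NCX (electrochemical × allosteric)
# ---------------------------------------------------------------------------

def ncx_allosteric_factor(Ca_i: float, p: NCXParams) -> float:
    """Allo = 1/(1 + (Km_Ca_act/[Ca]_i)^n); strictly increasing in Ca_i."""
    if np.any(np.asarray(Ca_i) <= 0):
        raise ValueError("Ca_i must be positive")
    return 1.0 / (1.0 + (p.Km_Ca_act / np.asarray(Ca_i)) ** p.n_Hill)


def ncx_reversal_potential(ions: IonConditions) -> float:
    """V_rev (mV) where the translocation numerator of ΔE vanishes."""
    rt_f = R_GAS * ions.T / F_FARADAY * 1e3  # mV
    return rt_f * math.log(ions.Na_o ** 3 * ions.Ca_i /
                           (ions.Na_i ** 3 * ions.Ca_o))


def ncx_delta_e(V: float, ions: IonConditions, p: NCXParams):
    """Electrochemical factor ΔE (mA/cm² scale): positive = net outward.

    ΔE = Vmax·([Na]_i³[Ca]_o·e^{γVF/RT} − [Na]_o³[Ca]_i·e^{(γ−1)VF/RT}) /
         ((km_Na³+[Na]_o³)(km_Ca+[Ca]_o)(1+ksat·e^{(γ−1)VF/RT}))
    """
    v = np.asarray(V, dtype=float)
    if np.any(np.abs(v) > 1000.0):
        raise ValueError("membrane potential outside ±1000 mV")
    krt = 1e-3 * F_FARADAY / (R_GAS * ions.T)  # 1/mV
    e1 = np.exp(p.gamma * krt * v)
    e2 = np.exp((p.gamma - 1.0) * krt * v)
    num = ions.Na_i ** 3 * ions.Ca_o * e1 - ions.Na_o ** 3 * ions.Ca_i * e2
    den = ((p.km_Na ** 3 + ions.Na_o ** 3) * (p.km_Ca + ions.Ca_o)
           * (1.0 + p.ksat * e2))
    out = p.Vmax * num / den
    return float(out) if np.isscalar(V) else out


class NCXFluxes(NamedTuple):
    i_total: float   # mA/cm², positive outward
    i_Ca: float      # Ca²⁺-carried component, −2·i_total
    i_Na: float      # Na⁺-carried component, +3·i_total
    j_Ca: float      # molar Ca flux into the shell: −i_Ca/(2F), per cm²


def ncx_current_and_fluxes(V: float, Ca_i: float, ions: IonConditions,
                           p: NCXParams) -> NCXFluxes:
    """Exchanger current split into its 3 Na⁺ : 1 Ca²⁺ electrogenic parts.

    ``i_total = Allo·ΔE``; the Na and Ca components satisfy
    ``i_Na + i_Ca = i_total`` and ``i_Na/i_Ca = −3/2`` at every state.
    In forward mode (V < V_rev) ``i_total < 0`` and ``j_Ca < 0`` (efflux);
    strong depolarization gives reverse-mode Ca entry (``j_Ca > 0``).
    """
    ions_here = replace(ions, Ca_i=Ca_i)
    allo = min(1.0, p.allo_scale * float(ncx_allosteric_factor(Ca_i, p)))
    phi = allo * float(ncx_delta_e(V, ions_here, p))
    i_ca = -2.0 * phi
    i_na = 3.0 * phi
    j_ca = -i_ca / (2.0 * F_FARADAY)
    return NCXFluxes(phi, i_ca, i_na, j_ca)


# ---------------------------------------------------------------------------
# K[Ca]
# ---------------------------------------------------------------------------

def kca_m_inf(Ca_i, p: KCaParams):
    """m∞ = αCa^n/(αCa^n + β); monotone in Ca, 0 at Ca = 0."""
    ca = np.asarray(Ca_i, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca_i must be non-negative")
    acan = p.alpha * ca ** p.n
    out = acan / (acan + p.beta)
    return float(out) if np.isscalar(Ca_i) else out


def kca_tau(Ca_i, p: KCaParams):
    """τ = max(1/(αCa^n + β), τ_min) in ms; decreasing in Ca above the floor."""
    ca = np.asarray(Ca_i, dtype=float)
    out = np.maximum(1.0 / (p.alpha * ca ** p.n + p.beta), p.tau_min)
    return float(out) if np.isscalar(Ca_i) else out


def kca_m_step(state: KCaState, Ca_i: float, p: KCaParams, dt: float) -> KCaState:
    """First-order relaxation of m toward m∞(Ca) with τ(Ca) over one step."""
    m_inf = kca_m_inf(Ca_i, p)
    tau = kca_tau(Ca_i, p)
    m = state.m + (1.0 - math.exp(-dt / tau)) * (m_inf - state.m)
    return KCaState(m=m)


def kca_current(V: float, s: KCaState, p: KCaParams) -> float:
    """I_K[Ca] = gbar·m²·(V − E_K) in mA/cm²."""
    return p.gbar * s.m ** p.n * (V - p.E_K)


# ---------------------------------------------------------------------------
# Calcium pool
# ---------------------------------------------------------------------------

def ca_pool_step(Ca_i: float, i_Ca_total: float, p: CaPoolParams,
                 dt: float) -> float:
    """Advance d[Ca]/dt = −i_Ca/(2F·depth) − (Ca−Ca_rest)/τ by one step.

    Inward Ca current (negative ``i_Ca_total``) raises Ca.  The decay term is
    treated implicitly (the same semi-implicit rule as the simulation
    kernel); the result is clipped at ``Ca_min``.
    """
    depth_cm = p.shell_depth * 1e-4
    src = -i_Ca_total / (2.0 * F_FARADAY * depth_cm)  # mM/ms
    ca = (Ca_i + dt * (src + p.Ca_rest / p.tau_decay)) / (1.0 + dt / p.tau_decay)
    return max(ca, p.Ca_min)


# ---------------------------------------------------------------------------
# Reduced HH channel complement (rate functions mirror the kernel)
# ---------------------------------------------------------------------------

def _vtrap(x: float, y: float) -> float:
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


def na_rates(V: float, scale: float = 1.0):
    """Transient Na⁺ channel α/β for m and h (ms⁻¹)."""
    am = 0.1 * _vtrap(V + 40.0, 10.0) * scale
    bm = 4.0 * math.exp(-(V + 65.0) / 18.0) * scale
    ah = 0.07 * math.exp(-(V + 65.0) / 20.0) * scale
    bh = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0)) * scale
    return am, bm, ah, bh


def kdr_rates(V: float, scale: float = 1.0):
    """Delayed-rectifier α/β for n (ms⁻¹)."""
    an = 0.01 * _vtrap(V + 55.0, 10.0) * scale
    bn = 0.125 * math.exp(-(V + 65.0) / 80.0) * scale
    return an, bn


def ka_steady(V: float):
    """A-type activation/inactivation (inf, tau) pairs."""
    a_inf = 1.0 / (1.0 + math.exp(-(V + 15.0) / 10.0))
    b_inf = 1.0 / (1.0 + math.exp((V + 56.0) / 8.0))
    return (a_inf, 2.0), (b_inf, 20.0)


def cal_steady(V: float):
    """L-type Ca activation (inf, tau)."""
    return 1.0 / (1.0 + math.exp(-(V + 15.0) / 6.0)), 1.5


def hh_channel_current(V: float, gates: dict, spec: HHChannelSpec,
                       dt: float):
    """Ohmic channel current with staggered-rule gate updates.

    ``gates`` maps gate name -> value in [0,1]; returns (current mA/cm²,
    updated gates).  Gates are advanced by the exact exponential relaxation
    toward inf(V) before the current is evaluated, matching the kernel's
    staggered update order.
    """
    new_gates = {}
    for name, _, fn in spec.gates:
        inf, tau = fn(V)
        x = gates[name]
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"gate {name} outside [0, 1]")
        new_gates[name] = x + (1.0 - math.exp(-dt / tau)) * (inf - x)
    g = spec.gbar
    for name, exponent, _ in spec.gates:
        g *= new_gates[name] ** exponent
    return g * (V - spec.E_rev), new_gates
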