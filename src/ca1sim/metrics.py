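"""Spike detection, waveform metrics, SPIKE-synchronization, group statistics.

The half-width here is the *above-threshold duration* t₂ − t₁ at the 10 mV
detection threshold (the event-detection convention), not the width at
half-maximal amplitude.

SPIKE-synchronization is the parameter-free coincidence measure with an
adaptive window: a spike in one train is coincident if its nearest partner
spike lies closer than half the minimum of the neighbouring inter-spike
intervals of both trains.  Boundary spikes use whichever neighbouring ISIs
exist; a train with fewer than two spikes contributes no ISI, so the window
falls back to the partner train's ISIs (and, if neither train has an ISI, to
half the observation window).  The pair value is the fraction of coincident
spikes over both trains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MetricError

__all__ = [
    "SpikeTrain", "detect_spikes", "threshold_excursions", "half_width",
    "all_half_widths", "peak_amplitude", "depolarization_time",
    "mean_firing_rate", "spike_sync_pair", "spike_sync_matrix",
    "potentiation_index", "compare_groups",
]

SPIKE_THRESHOLD_MV = 10.0


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) inside an observation window."""

    times: np.ndarray
    window: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        t0, t1 = self.window
        if len(t) and (t[0] < t0 or t[-1] > t1):
            raise ValueError("spike outside observation window")

    def __len__(self):
        return len(self.times)


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise MetricError("trace is not uniformly sampled")
    return float(dt[0])


def threshold_excursions(t: np.ndarray, v: np.ndarray,
                         threshold: float = SPIKE_THRESHOLD_MV):
    """Contiguous supra-threshold excursions as (t_up, t_down) pairs.

    Crossing times are linearly interpolated between samples.  An excursion
    still open at the end of the trace is closed at the last sample.
    """
    _check_uniform(t)
    above = v > threshold
    rises = np.where(~above[:-1] & above[1:])[0]
    falls = np.where(above[:-1] & ~above[1:])[0]
    out = []
    for r in rises:
        t_up = t[r] + (threshold - v[r]) / (v[r + 1] - v[r]) * (t[r + 1] - t[r])
        later = falls[falls >= r + 1]
        if len(later):
            f = later[0]
            t_dn = t[f] + (threshold - v[f]) / (v[f + 1] - v[f]) * (t[f + 1] - t[f])
        else:
            t_dn = t[-1]
        out.append((float(t_up), float(t_dn)))
    return out


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD_MV) -> SpikeTrain:
    """One spike per supra-threshold excursion, timed at the upward crossing."""
    exc = threshold_excursions(t, v, threshold)
    return SpikeTrain(np.array([e[0] for e in exc]),
                      (float(t[0]), float(t[-1])))


def half_width(t: np.ndarray, v: np.ndarray,
               threshold: float = SPIKE_THRESHOLD_MV,
               index: Optional[int] = None) -> float:
    """Above-threshold duration t₂ − t₁ (ms) of one excursion."""
    exc = threshold_excursions(t, v, threshold)
    if not exc:
        raise MetricError("no supra-threshold excursion in trace")
    if index is None:
        if len(exc) > 1:
            raise MetricError(f"{len(exc)} excursions; pass index to select one")
        index = 0
    t_up, t_dn = exc[index]
    return t_dn - t_up


def all_half_widths(t: np.ndarray, v: np.ndarray,
                    threshold: float = SPIKE_THRESHOLD_MV) -> np.ndarray:
    return np.array([dn - up for up, dn in threshold_excursions(t, v, threshold)])


def peak_amplitude(v: np.ndarray) -> float:
    """Absolute peak voltage (mV)."""
    if len(v) == 0:
        raise MetricError("empty trace")
    return float(np.max(v))


def depolarization_time(t: np.ndarray, v: np.ndarray, stimulus_onset: float,
                        mode: str = "peak",
                        threshold: float = SPIKE_THRESHOLD_MV) -> float:
    """Time (ms) from stimulus onset to the absolute voltage peak.

    ``mode="threshold"`` instead returns the time to the first upward
    threshold crossing after onset.
    """
    sel = t >= stimulus_onset
    if mode == "peak":
        i = int(np.argmax(v[sel]))
        return float(t[sel][i] - stimulus_onset)
    if mode == "threshold":
        exc = [e for e in threshold_excursions(t, v, threshold)
               if e[0] >= stimulus_onset]
        if not exc:
            raise MetricError("no threshold crossing after stimulus onset")
        return exc[0][0] - stimulus_onset
    raise ValueError(f"unknown mode {mode!r}")


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spikes per second over the observation window."""
    t0, t1 = train.window
    if t1 <= t0:
        raise MetricError("empty observation window")
    return len(train) / ((t1 - t0) * 1e-3)


# ---------------------------------------------------------------------------
# SPIKE-synchronization
# ---------------------------------------------------------------------------

def _neighbor_isis(times: np.ndarray, i: int):
    isis = []
    if i > 0:
        isis.append(times[i] - times[i - 1])
    if i < len(times) - 1:
        isis.append(times[i + 1] - times[i])
    return isis


def _coincidences(x: np.ndarray, y: np.ndarray, fallback: float) -> int:
    """Number of spikes of x coincident with some spike of y."""
    if len(x) == 0 or len(y) == 0:
        return 0
    j_right = np.searchsorted(y, x)
    count = 0
    for i, xi in enumerate(x):
        jr = min(j_right[i], len(y) - 1)
        jl = max(jr - 1, 0)
        j = jl if abs(y[jl] - xi) <= abs(y[jr] - xi) else jr
        isis = _neighbor_isis(x, i) + _neighbor_isis(y, j)
        tau = 0.5 * min(isis) if isis else fallback
        if abs(xi - y[j]) < tau:
            count += 1
    return count


def spike_sync_pair(a: SpikeTrain, b: SpikeTrain) -> float:
    """SPIKE-synchronization of two trains, in [0, 1]."""
    if len(a) == 0 and len(b) == 0:
        return 1.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    fallback = 0.5 * (max(a.window[1], b.window[1])
                      - min(a.window[0], b.window[0]))
    c = _coincidences(a.times, b.times, fallback) \
        + _coincidences(b.times, a.times, fallback)
    return c / (len(a) + len(b))


def spike_sync_matrix(trains: Sequence[SpikeTrain]) -> np.ndarray:
    """Symmetric pairwise SPIKE-synchronization matrix with unit diagonal."""
    if len(trains) < 2:
        raise ValueError("need at least two spike trains")
    n = len(trains)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = spike_sync_pair(trains[i], trains[j])
    return m


# ---------------------------------------------------------------------------
# STDP potentiation readouts
# ---------------------------------------------------------------------------

def potentiation_index(pairing, readout: str = "calcium") -> float:
    """Dimensionless potentiation measure from a pairing experiment.

    ``calcium`` (default): peak [Ca]ᵢ at the synapse in the paired condition
    divided by the EPSP-alone peak [Ca]ᵢ — postsynaptic calcium is treated
    as the plasticity-inducing signal.

    ``voltage``: paired peak depolarization divided by the linear sum of the
    EPSP-alone and bAP-alone peak depolarizations (supralinearity of the
    voltage envelope).

    ``pairing`` is a mapping condition -> readout dict with keys
    ``peak_ca`` and ``peak_v_dep`` for conditions ``paired``, ``epsp`` and
    ``bap`` (a :class:`~ca1sim.protocols.PairingResult` works directly).
    """
    cond = pairing.conditions if hasattr(pairing, "conditions") else pairing
    for key in ("paired", "epsp", "bap"):
        if key not in cond:
            raise MetricError(f"missing condition {key!r} in pairing result")
    if readout == "calcium":
        return cond["paired"]["peak_ca"] / cond["epsp"]["peak_ca"]
    if readout == "voltage":
        return cond["paired"]["peak_v_dep"] / (cond["epsp"]["peak_v_dep"]
                                               + cond["bap"]["peak_v_dep"])
    raise ValueError(f"unknown readout {readout!r}")


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def compare_groups(samples: Dict[str, np.ndarray],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Mann–Whitney U plus Tukey HSD intervals at the given alpha.

    Returns a tidy table (group1, group2, u_stat, p_mwu, tukey_low,
    tukey_high, significant).  Degenerate all-identical comparisons are
    reported with p = 1 rather than raised.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for k, v in samples.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 observations")

    values = np.concatenate([np.asarray(samples[k], dtype=float)
                             for k in labels])
    groups = np.concatenate([[k] * len(samples[k]) for k in labels])
    if np.ptp(values) > 0:
        tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
        tk_frame = pd.DataFrame(tk.summary().data[1:],
                                columns=tk.summary().data[0])
    else:
        tk_frame = None

    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            a, b = np.asarray(samples[g1]), np.asarray(samples[g2])
            if np.ptp(np.concatenate([a, b])) == 0:
                u, p = len(a) * len(b) / 2.0, 1.0
            else:
                u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            row = dict(group1=g1, group2=g2, u_stat=float(u), p_mwu=float(p))
            if tk_frame is not None:
                hit = tk_frame[((tk_frame.group1 == g1) & (tk_frame.group2 == g2))
                               | ((tk_frame.group1 == g2) & (tk_frame.group2 == g1))]
                if len(hit):
                    row["tukey_low"] = float(hit.iloc[0]["lower"])
                    row["tukey_high"] = float(hit.iloc[0]["upper"])
                    row["tukey_reject"] = bool(hit.iloc[0]["reject"])
            else:
                row["tukey_low"] = row["tukey_high"] = 0.0
                row["tukey_reject"] = False
            row["significant"] = bool(row["p_mwu"] < alpha)
            rows.append(row)
    return pd.DataFrame(rows)
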