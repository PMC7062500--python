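"""Recorded simulation output: time-aligned per-compartment traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["TraceSet"]


@dataclass
class TraceSet:
    """Uniformly sampled traces: ``data[var]`` is (n_times, n_compartments).

    Variables: ``V`` (mV), ``Ca_i`` (mM) and, when currents were recorded,
    ``i_ncx``, ``i_kca``, ``i_K_total``, ``i_Na_total`` (mA/cm²).
    """

    t: np.ndarray
    data: Dict[str, np.ndarray]
    soma_compartment: int
    region_labels: np.ndarray
    distance_um: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0])

    def at(self, var: str, compartment: int) -> np.ndarray:
        return self.data[var][:, compartment]

    def soma(self, var: str = "V") -> np.ndarray:
        return self.at(var, self.soma_compartment)

    def to_frame(self, var: str = "V",
                 compartments: Optional[Sequence[int]] = None) -> pd.DataFrame:
        comps = (list(compartments) if compartments is not None
                 else list(range(self.data[var].shape[1])))
        cols = {"t_ms": self.t}
        for c in comps:
            cols[f"{var}[{c}]"] = self.data[var][:, c]
        return pd.DataFrame(cols)

    def export_csv(self, path, variables: Sequence[str] = ("V",),
                   compartments: Optional[Sequence[int]] = None) -> None:
        frames = [self.to_frame(v, compartments).set_index("t_ms")
                  for v in variables]
        pd.concat(frames, axis=1).reset_index().to_csv(path, index=False,
                                                       float_format="%.9g")
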