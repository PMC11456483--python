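"""Experimental input conditions as per-population current time courses.

Each column prefers one bar orientation.  Bottom-up sensory input targets
layer 4 of both columns (ten times stronger in the column preferring the
presented bar); top-down attention targets layers 2/3 and 5 of the attended
column.  Layer 6 receives no external input.  Sensory contributions of two
simultaneously presented bars add independently.  Delivered current =
base amplitude x projection probability x column factor; all currents are
zero before stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .model_core import ConfigurationError
from .network_builder import NetworkSpec

#: Built-in condition names.  S1/S2: single bar preferred by column 1/2;
#: S1S2: both bars; _A1/_A2: attention to column 1/2; A1_only/A2_only:
#: attention without any sensory input.
CONDITION_NAMES = (
    "none", "S1", "S2", "S1S2", "S1S2_A1", "S1S2_A2", "A1_only", "A2_only",
)

#: (sensory bars shown, attended column or None) per condition.
_CONDITION_MAP: Dict[str, Tuple[Tuple[int, ...], Optional[int]]] = {
    "none": ((), None),
    "S1": ((1,), None),
    "S2": ((2,), None),
    "S1S2": ((1, 2), None),
    "S1S2_A1": ((1, 2), 1),
    "S1S2_A2": ((1, 2), 2),
    "A1_only": ((), 1),
    "A2_only": ((), 2),
}


@dataclass(frozen=True)
class StimulusCondition:
    """One experimental input scenario."""

    name: str
    sensory_base: float = 0.06      # mA/cm^2
    attention_base: float = 0.02    # mA/cm^2
    onset: float = 5000.0           # ms
    preferred_ratio: float = 10.0   # preferred : unpreferred sensory ratio

    def __post_init__(self) -> None:
        if self.name not in _CONDITION_MAP:
            raise ConfigurationError(
                f"unknown condition {self.name!r}; valid: {CONDITION_NAMES}"
            )
        if self.preferred_ratio <= 0:
            raise ConfigurationError("preferred_ratio must be positive")

    @property
    def bars(self) -> Tuple[int, ...]:
        return _CONDITION_MAP[self.name][0]

    @property
    def attended_column(self) -> Optional[int]:
        return _CONDITION_MAP[self.name][1]

    @classmethod
    def from_config(cls, name: str, config: dict) -> "StimulusCondition":
        stim = config["stimulus"]
        return cls(
            name=name,
            sensory_base=float(stim["sensory_base"]),
            attention_base=float(stim["attention_base"]),
            onset=float(stim["onset_ms"]),
            preferred_ratio=float(stim["preferred_ratio"]),
        )


def condition_currents(
    cond: StimulusCondition, spec: NetworkSpec, t: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-population ``(I_sens, I_attn)`` arrays at time ``t`` (ms).

    Before onset both arrays are zero.  After onset each bar contributes
    ``sensory_base x (projection / max projection) x column_factor`` with
    column factor 1 in the column preferring that bar and
    ``1/preferred_ratio`` in the other; attention contributes
    ``attention_base x (projection / max projection)`` in the attended
    column only.

    The projection probabilities act as relative weights normalized to
    their strongest target, so the base amplitudes are the currents
    actually delivered to the principal excitatory targets (L4E for
    sensory, L2/3E and L5E for attention) — the same convention by which
    the background-current ratio between excitatory and inhibitory
    populations is specified.  This keeps the delivered sensory :
    attention : background currents at their nominal 9 : 3 : 16 ratio.
    """
    n = spec.n_populations
    I_sens = np.zeros(n)
    I_attn = np.zeros(n)
    if t < cond.onset:
        return I_sens, I_attn
    max_sens = max(p.proj_sensory for p in spec.populations)
    max_attn = max(p.proj_attention for p in spec.populations)
    for i, pop in enumerate(spec.populations):
        if max_sens > 0:
            w_sens = cond.sensory_base * pop.proj_sensory / max_sens
            for bar in cond.bars:
                factor = 1.0 if pop.column == bar else 1.0 / cond.preferred_ratio
                I_sens[i] += w_sens * factor
        if (cond.attended_column is not None and max_attn > 0
                and pop.column == cond.attended_column):
            I_attn[i] = cond.attention_base * pop.proj_attention / max_attn
    return I_sens, I_attn


def steady_currents(
    cond: StimulusCondition, spec: NetworkSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Post-onset ``(I_sens, I_attn)`` arrays (the currents are step-constant)."""
    return condition_currents(cond, spec, cond.onset)
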