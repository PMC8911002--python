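"""Leaf relative water content (RWC).

RWC expresses the current hydration of a leaf segment relative to its
fully turgid state::

    RWC (%) = 100 * (Fw - Dw) / (Tw - Dw)

where Fw, Dw and Tw are the fresh, dry and turgid weights in grams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class LeafWeights:
    """Fresh, dry and turgid weights (g) of one leaf segment.

    Physically Tw >= Fw >= Dw > 0; mild violations (e.g. Fw slightly above
    Tw from surface water) are flagged with a warning rather than rejected.
    """

    fresh: float
    dry: float
    turgid: float

    def __post_init__(self) -> None:
        if min(self.fresh, self.dry, self.turgid) <= 0:
            raise ValueError("all weights must be positive")
        if self.fresh < self.dry or self.turgid < self.fresh:
            warnings.warn(
                f"inconsistent leaf weights (expected Tw >= Fw >= Dw): "
                f"Fw={self.fresh}, Dw={self.dry}, Tw={self.turgid}",
                stacklevel=3,
            )


def relative_water_content(w: LeafWeights) -> float:
    """RWC in percent; 0% fully dry, 100% fully turgid."""
    if w.turgid == w.dry:
        raise ValueError("zero turgid range: Tw equals Dw")
    return 100.0 * (w.fresh - w.dry) / (w.turgid - w.dry)


def rwc_table(weights: pd.DataFrame) -> pd.DataFrame:
    """RWC per row of a table with fresh/dry/turgid columns (grams)."""
    required = {"fresh", "dry", "turgid"}
    if not required <= set(weights.columns):
        raise ValueError(f"weights table needs columns {sorted(required)}")
    out = weights.copy()
    out["rwc_percent"] = [
        relative_water_content(LeafWeights(r.fresh, r.dry, r.turgid))
        for r in weights.itertuples()
    ]
    return out
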