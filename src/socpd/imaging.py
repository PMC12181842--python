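"""Striatal specific binding ratios and the DTI-ALPS glymphatic index.

The specific binding ratio (SBR) of a striatal region is its count
density over the occipital reference density, minus one. Hemispheres
are analysed as more/less affected, the more affected hemisphere being
contralateral to the body side with worse lateralized motor scores.
The DTI-ALPS index is the ratio of the mean x-axis diffusivity in
projection and association fibres to the mean of the perpendicular
diffusivities (y in projection fibres, z in association fibres); higher
values indicate better glymphatic function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_sbr",
    "assign_hemispheres",
    "compute_alps",
    "add_sbr",
    "add_alps",
    "HemisphereAssignment",
]


def compute_sbr(striatal: float, occipital: float) -> float:
    """Specific binding ratio: (striatal count density / occipital) - 1.

    Raises on a non-positive occipital reference. A negative SBR
    (striatal density below the reference region) is allowed; callers
    may flag it as sub-reference binding.
    """
    if occipital <= 0:
        raise ValueError("occipital reference count density must be positive")
    return striatal / occipital - 1.0


@dataclass(frozen=True)
class HemisphereAssignment:
    more_affected: str  # "left" | "right"
    less_affected: str
    lateralized_right: float  # motor burden on the right body side
    lateralized_left: float
    tie: bool = False

    def __post_init__(self):
        if self.more_affected == self.less_affected:
            raise ValueError("more- and less-affected hemispheres must differ")


def assign_hemispheres(lateralized_right: float, lateralized_left: float) -> HemisphereAssignment:
    """More/less-affected hemispheres from lateralized motor sums.

    The worse body side is the one with the higher lateralized motor
    score; the more affected hemisphere is contralateral to it. An
    exact tie is broken deterministically toward a left more-affected
    hemisphere and flagged.
    """
    if lateralized_right is None or lateralized_left is None:
        raise ValueError("both lateralized motor sums are required")
    r, l = float(lateralized_right), float(lateralized_left)
    if np.isnan(r) or np.isnan(l):
        raise ValueError("both lateralized motor sums are required")
    tie = r == l
    if tie:
        warnings.warn("lateralized motor tie; breaking toward left more-affected")
    worse_side = "right" if r >= l else "left"
    more = "left" if worse_side == "right" else "right"
    less = "right" if more == "left" else "left"
    return HemisphereAssignment(more, less, r, l, tie=tie)


def compute_alps(dx_proj: float, dx_assoc: float, dy_proj: float, dz_assoc: float) -> float:
    """DTI-ALPS index: mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc).

    All four diffusivities must be positive. The index is invariant to
    a common rescaling of all diffusivities and equals 1 under isotropy.
    """
    vals = (dx_proj, dx_assoc, dy_proj, dz_assoc)
    if any(v is None or not np.isfinite(v) or v <= 0 for v in vals):
        raise ValueError("all four diffusivities must be positive and finite")
    return (dx_proj + dx_assoc) / (dy_proj + dz_assoc)


def add_sbr(table: pd.DataFrame) -> pd.DataFrame:
    """Append an ``sbr`` column to a (striatal_counts, occipital_counts) table."""
    out = table.copy()
    out["sbr"] = [
        compute_sbr(s, o)
        for s, o in zip(out["striatal_counts"], out["occipital_counts"])
    ]
    out["sub_reference"] = out["sbr"] < 0
    return out


def add_alps(table: pd.DataFrame) -> pd.DataFrame:
    """Append an ``alps_index`` column to a diffusivity ROI table."""
    out = table.copy()
    out["alps_index"] = [
        compute_alps(a, b, c, d)
        for a, b, c, d in zip(out["Dx_proj"], out["Dx_assoc"], out["Dy_proj"], out["Dz_assoc"])
    ]
    return out
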