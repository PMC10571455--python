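"""Pearson correlation between SC ratings and malignancy, and SC ranking.

The ranking orders the eight non-malignancy semantic characteristics by
the absolute value of their Pearson correlation with the malignancy
rating; signed coefficients are kept so directionality (e.g. sphericity
and margin correlating negatively) remains visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

RANKABLE_SCS = [
    "subtlety",
    "internal_structure",
    "calcification",
    "sphericity",
    "margin",
    "lobulation",
    "spiculation",
    "texture",
]

#: Marker for a correlation that is undefined (zero variance in X or Y).
UNDEFINED = float("nan")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson's correlation coefficient.

    rho = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) * sum((y-ybar)^2)).
    Returns the undefined marker (NaN) when either series has zero
    variance, rather than raising or silently returning 0.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape} vs {yv.shape}")
    if xv.ndim != 1 or len(xv) < 2:
        raise ValueError("need two 1-D sequences of length >= 2")
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    sx = float(np.sum(dx * dx))
    sy = float(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        return UNDEFINED
    return float(np.sum(dx * dy) / np.sqrt(sx * sy))


@dataclass
class CorrelationReport:
    """Per-SC correlation with malignancy and the |rho| ranking."""

    rho: dict            # sc_name -> signed rho (NaN when undefined)
    abs_rho: dict        # sc_name -> |rho|
    ranking: list        # sc names, |rho| descending, ties alphabetical, undefined last
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sc": sc,
                "rho": self.rho[sc],
                "abs_rho": self.abs_rho[sc],
                "rank": self.ranking.index(sc) + 1,
                "n": self.n,
            }
            for sc in self.ranking
        ]
        return pd.DataFrame(rows)


def rank_sc_correlations(ratings_table: pd.DataFrame, sc_list: list[str] | None = None) -> CorrelationReport:
    """Rank SCs by |Pearson rho| with the malignancy rating.

    ``ratings_table`` holds one consensus row per nodule with SC-named
    columns (calcification / internal structure already on the common
    1-5 scale) plus ``malignancy``. SCs with a constant column are
    reported as undefined and ranked last.
    """
    if sc_list is None:
        sc_list = [sc for sc in RANKABLE_SCS if sc in ratings_table.columns]
    if len(ratings_table) < 10:
        raise ValueError("need at least 10 nodules")
    if "malignancy" not in ratings_table.columns:
        raise ValueError("ratings table lacks a malignancy column")
    y = ratings_table["malignancy"].to_numpy(dtype=float)
    rho = {sc: pearson(ratings_table[sc].to_numpy(dtype=float), y) for sc in sc_list}
    abs_rho = {sc: abs(r) for sc, r in rho.items()}
    defined = sorted(
        [sc for sc in sc_list if not np.isnan(rho[sc])],
        key=lambda sc: (-abs_rho[sc], sc),
    )
    undefined = sorted(sc for sc in sc_list if np.isnan(rho[sc]))
    return CorrelationReport(rho=rho, abs_rho=abs_rho, ranking=defined + undefined, n=len(ratings_table))
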