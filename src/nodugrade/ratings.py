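"""Reader-rating handling: consensus, scale normalization, binarization.

LIDC-style semantic characteristics (SCs) are rated by up to four
readers. The consensus rule averages readers 1 and 2 (cases lacking
reader 1 are discarded); calcification (1-6) and internal structure
(1-4) can be mapped affinely onto the common 1-5 scale for correlation
analysis; for grading, each SC consensus is binarized into low/high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SC_COLUMNS = ["C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9"]

SC_NAMES = {
    "C1": "subtlety",
    "C2": "internal_structure",
    "C3": "calcification",
    "C4": "sphericity",
    "C5": "margin",
    "C6": "lobulation",
    "C7": "spiculation",
    "C8": "texture",
    "C9": "malignancy",
}
SC_CODES = {v: k for k, v in SC_NAMES.items()}

#: Upper scale bound T per SC (all scales start at 1).
SC_SCALE_MAX = {
    "subtlety": 5,
    "internal_structure": 4,
    "calcification": 6,
    "sphericity": 5,
    "margin": 5,
    "lobulation": 5,
    "spiculation": 5,
    "texture": 5,
    "malignancy": 5,
}

#: The six SCs the grading models target.
GRADABLE_SCS = ["subtlety", "calcification", "sphericity", "margin", "lobulation", "spiculation"]


class CaseDiscarded(Exception):
    """Raised when the consensus rule rejects a case (no reader-1 ratings)."""


@dataclass
class ReaderRatingRecord:
    """One reader's integer SC ratings for one nodule. None = missing."""

    case_id: str
    reader_id: int
    ratings: dict = field(default_factory=dict)  # sc_name -> int or None

    def __post_init__(self):
        if not 1 <= self.reader_id <= 4:
            raise ValueError(f"reader_id must be 1-4, got {self.reader_id}")
        for sc, val in self.ratings.items():
            if sc not in SC_SCALE_MAX:
                raise ValueError(f"unknown SC {sc!r}")
            if val is not None and not 1 <= val <= SC_SCALE_MAX[sc]:
                raise ValueError(f"{sc} rating {val} outside 1-{SC_SCALE_MAX[sc]}")


@dataclass
class SCBinaryLabel:
    sc_name: str
    label: int  # 1 = high level, 0 = low level


def consensus_rating(records: list[ReaderRatingRecord]) -> dict:
    """Per-SC consensus: mean of readers 1 and 2, reader 1 alone otherwise.

    A case whose first reader is absent, or who left any SC missing, is
    discarded (raises :class:`CaseDiscarded`). Where reader 2 is present
    but skipped a single SC, reader 1's value stands in for it.
    """
    if not records:
        raise ValueError("no reader records supplied")
    by_reader = {r.reader_id: r for r in records}
    r1 = by_reader.get(1)
    if r1 is None:
        raise CaseDiscarded("reader 1 absent")
    if any(r1.ratings.get(sc) is None for sc in SC_SCALE_MAX):
        raise CaseDiscarded("reader 1 left an SC unrated")
    r2 = by_reader.get(2)
    consensus = {}
    for sc in SC_SCALE_MAX:
        v1 = r1.ratings[sc]
        if r2 is not None:
            v2 = r2.ratings.get(sc)
            consensus[sc] = (v1 + (v2 if v2 is not None else v1)) / 2.0
        else:
            consensus[sc] = float(v1)
    return consensus


def normalize_to_five(rating: float, sc_name: str) -> float:
    """Affine map of a native 1..T scale onto 1..5 (endpoints preserved).

    Only calcification (T=6) and internal structure (T=4) are rescaled;
    every other SC passes through unchanged.
    """
    t = SC_SCALE_MAX.get(sc_name)
    if t is None:
        raise ValueError(f"unknown SC {sc_name!r}")
    if not 1 <= rating <= t:
        raise ValueError(f"{sc_name} rating {rating} outside 1-{t}")
    if sc_name in ("calcification", "internal_structure"):
        return 1.0 + 4.0 * (rating - 1.0) / (t - 1.0)
    return float(rating)


def binarize(rating: float, sc_name: str) -> SCBinaryLabel:
    """Low/high binarization on the native scale.

    Most SCs: high (1) iff rating >= 3. Calcification: high iff the
    rating equals 6 (calcification absent). Malignancy follows the
    >= 3 rule. Applied to real-valued consensus means, so 2.5 -> low.
    """
    if sc_name == "calcification":
        if not 1 <= rating <= 6:
            raise ValueError(f"calcification rating {rating} outside 1-6")
        return SCBinaryLabel(sc_name, int(rating == 6))
    if sc_name not in SC_SCALE_MAX:
        raise ValueError(f"unknown SC {sc_name!r}")
    if not 1 <= rating <= SC_SCALE_MAX[sc_name]:
        raise ValueError(f"{sc_name} rating {rating} out of scale")
    return SCBinaryLabel(sc_name, int(rating >= 3))


def records_from_frame(df: pd.DataFrame) -> dict[str, list[ReaderRatingRecord]]:
    """Group a flat ratings table (case_id, reader_id, C1..C9) by case."""
    out: dict[str, list[ReaderRatingRecord]] = {}
    for _, row in df.iterrows():
        ratings = {}
        for code in SC_COLUMNS:
            val = row.get(code)
            ratings[SC_NAMES[code]] = None if pd.isna(val) else int(val)
        rec = ReaderRatingRecord(str(row["case_id"]), int(row["reader_id"]), ratings)
        out.setdefault(rec.case_id, []).append(rec)
    return out


def consensus_table(df: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """Consensus ratings per case from a flat ratings table.

    Discarded cases are dropped. With ``normalize=True``, calcification
    and internal structure are mapped onto the 1-5 scale (used before
    correlation analysis, never before binarization).
    """
    rows = []
    for case_id, records in records_from_frame(df).items():
        try:
            cons = consensus_rating(records)
        except CaseDiscarded:
            continue
        if normalize:
            cons = {sc: normalize_to_five(v, sc) for sc, v in cons.items()}
        rows.append({"case_id": case_id, **cons})
    return pd.DataFrame(rows)


def labels_table(df: pd.DataFrame) -> pd.DataFrame:
    """Binary low/high labels per case for the six gradable SCs + malignancy."""
    cons = consensus_table(df, normalize=False)
    out = {"case_id": cons["case_id"]}
    for sc in GRADABLE_SCS + ["malignancy"]:
        out[sc] = [binarize(v, sc).label for v in cons[sc]]
    return pd.DataFrame(out)
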