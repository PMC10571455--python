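"""On-disk dialect for the CLI: 16-bit PNG slices, JSON contours, CSV tables.

Layout written by ``nodugrade gen-data`` and read by the other verbs::

    DIR/
      slices/{case_id}_s{j}.png      # uint16 grayscale
      contours.json                  # case -> reader -> slice -> [[x, y], ...]
      ratings.csv                    # case_id, reader_id, C1..C9
      labels.csv                     # case_id, six SC labels + malignancy

An optional adapter for externally prepared data only needs the same
layout; no DICOM/XML ingestion is provided.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .patches import NodulePatch
from .ratings import SC_COLUMNS


def write_cohort(cases, ratings_table: pd.DataFrame, out_dir: str):
    os.makedirs(os.path.join(out_dir, "slices"), exist_ok=True)
    contours = {}
    for case in cases:
        for j, img in enumerate(case.slices):
            png = (np.clip(img, 0, 1) * 65535).astype(np.uint16)
            iio.imwrite(os.path.join(out_dir, "slices", f"{case.case_id}_s{j}.png"), png)
        contours[case.case_id] = [
            [np.asarray(c).tolist() for c in reader] for reader in case.reader_contours
        ]
    with open(os.path.join(out_dir, "contours.json"), "w") as fh:
        json.dump(contours, fh)
    ratings_table.to_csv(os.path.join(out_dir, "ratings.csv"), index=False)


def read_cohort(data_dir: str):
    """Yield (case_id, slices, reader_contours) from a gen-data directory."""
    with open(os.path.join(data_dir, "contours.json")) as fh:
        contours = json.load(fh)
    for case_id, readers in contours.items():
        n_slices = len(readers[0])
        slices = [
            iio.imread(os.path.join(data_dir, "slices", f"{case_id}_s{j}.png")).astype(float) / 65535.0
            for j in range(n_slices)
        ]
        reader_contours = [[np.asarray(c, dtype=float) for c in reader] for reader in readers]
        yield case_id, slices, reader_contours


def read_ratings(data_dir: str) -> pd.DataFrame:
    df = pd.read_csv(os.path.join(data_dir, "ratings.csv"))
    missing = [c for c in ["case_id", "reader_id", *SC_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"ratings.csv lacks columns {missing}")
    return df


def write_patches(patch_list: list, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for p in patch_list:
        stem = f"{p.case_id}_s{p.slice_index}"
        np.save(os.path.join(out_dir, f"{stem}_G.npy"), p.G.astype(np.float32))
        np.save(os.path.join(out_dir, f"{stem}_B.npy"), p.B.astype(np.uint8))
        rows.append({"case_id": p.case_id, "slice": p.slice_index,
                     "g_file": f"{stem}_G.npy", "b_file": f"{stem}_B.npy",
                     "box": json.dumps(list(p.box))})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)


def read_patches(patch_dir: str) -> list:
    manifest = pd.read_csv(os.path.join(patch_dir, "manifest.csv"))
    out = []
    for _, row in manifest.iterrows():
        out.append(NodulePatch(
            G=np.load(os.path.join(patch_dir, row["g_file"])).astype(float),
            B=np.load(os.path.join(patch_dir, row["b_file"])),
            case_id=str(row["case_id"]), slice_index=int(row["slice"]),
            box=tuple(json.loads(row["box"])),
        ))
    return out
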