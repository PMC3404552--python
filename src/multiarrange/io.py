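"""File formats: labeled-CSV RDMs, long-format CSV, JSON-Lines trial logs.

All formats are plain text and round-trip losslessly (floats are written
with 17 significant digits). An RDM is stored as a square CSV with item
identifiers as both header row and first column; undefined entries are
empty cells. The long format has columns item_i, item_j, dissimilarity
and lists each pair once. Trial logs are JSON Lines, one trial per line:

    {"trial": 1, "items": ["A", "B"], "coords": [[x, y], ...],
     "arena_diameter": 1.0}
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .core import RDM, Arrangement, ItemSet
from .design import EvidenceMatrix

__all__ = [
    "write_rdm_csv",
    "write_rdm_long_csv",
    "read_rdm_csv",
    "write_trials_jsonl",
    "read_trials_jsonl",
    "write_evidence_csv",
    "read_evidence_csv",
    "read_pair_records_csv",
]

_FLOAT_FMT = "%.17g"


def write_rdm_csv(rdm: RDM, path) -> None:
    """Write a square labeled CSV; undefined entries become empty cells."""
    vals = rdm.values.astype(object)
    vals[~rdm.defined] = np.nan
    df = pd.DataFrame(vals, index=list(rdm.items), columns=list(rdm.items))
    df.to_csv(path, float_format=_FLOAT_FMT)


def write_rdm_long_csv(rdm: RDM, path) -> None:
    """Write the defined upper-triangle pairs as item_i,item_j,dissimilarity."""
    rows = list(rdm.defined_pairs())
    df = pd.DataFrame(rows, columns=["item_i", "item_j", "dissimilarity"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_long(df: pd.DataFrame) -> RDM:
    items = sorted(set(df["item_i"].astype(str)) | set(df["item_j"].astype(str)))
    itemset = ItemSet(items)
    n = itemset.n
    values = np.zeros((n, n))
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(defined, True)
    for _, row in df.iterrows():
        i = itemset.index(str(row["item_i"]))
        j = itemset.index(str(row["item_j"]))
        values[i, j] = values[j, i] = float(row["dissimilarity"])
        defined[i, j] = defined[j, i] = True
    return RDM(itemset, values, defined)


def read_rdm_csv(path) -> RDM:
    """Read an RDM from square labeled CSV or long-format CSV (autodetected)."""
    df = pd.read_csv(path, index_col=0)
    long_cols = {"item_j", "dissimilarity"}
    if long_cols.issubset(set(df.reset_index().columns) | set(df.columns)):
        return _read_long(pd.read_csv(path))
    items = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != items:
        raise ValueError(f"{path}: row and column labels disagree")
    values = df.to_numpy(dtype=float)
    defined = ~np.isnan(values)
    values = np.where(defined, values, 0.0)
    return RDM(ItemSet(items), values, defined)


def write_trials_jsonl(trials, path) -> None:
    with open(path, "w") as fh:
        for arr in trials:
            fh.write(
                json.dumps(
                    {
                        "trial": arr.trial_index,
                        "items": list(arr.items),
                        "coords": [[x, y] for x, y in arr.coords.tolist()],
                        "arena_diameter": arr.arena_diameter,
                    }
                )
                + "\n"
            )


def read_trials_jsonl(path) -> list:
    trials = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{line_no}: invalid JSON") from exc
            arr = Arrangement(
                trial_index=rec["trial"],
                items=rec["items"],
                coords=np.asarray(rec["coords"], dtype=float),
                arena_diameter=rec.get("arena_diameter", 1.0),
            )
            n_out = arr.out_of_arena()
            if n_out:
                warnings.warn(
                    f"{path}:{line_no}: trial {arr.trial_index} has "
                    f"{n_out} icon(s) outside the arena",
                    stacklevel=2,
                )
            trials.append(arr)
    return trials


def write_evidence_csv(ev: EvidenceMatrix, path) -> None:
    df = pd.DataFrame(ev.weights, index=list(ev.items), columns=list(ev.items))
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_evidence_csv(path) -> EvidenceMatrix:
    df = pd.read_csv(path, index_col=0)
    items = [str(c) for c in df.columns]
    return EvidenceMatrix(ItemSet(items), df.to_numpy(dtype=float))


def read_pair_records_csv(path):
    """Read long-format pair records (item_i, item_j, value) for the parsers."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError(f"{path}: expected at least 3 columns, got {cols}")
    return [
        (str(r[cols[0]]), str(r[cols[1]]), float(r[cols[2]]))
        for _, r in df.iterrows()
    ]
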