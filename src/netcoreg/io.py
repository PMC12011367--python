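"""File I/O: expression matrices, edge lists, link tables, run manifests.

Expression orientation must be declared explicitly ("cells-rows" or
"genes-rows"): tools disagree on the convention and silent guessing is a
correctness hazard. Gzip-compressed text inputs are auto-detected by the
``.gz`` extension (pandas handles decompression). A sparse matrix-market
triplet plus row/column name files is accepted as an alternative expression
input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio

FLOAT_FORMAT = "%.10g"


def _sep_for(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    return "," if name.endswith(".csv") else "\t"


def read_expression(path: str | Path, orientation: str) -> pd.DataFrame:
    """Read a TSV/CSV expression matrix into a cells x genes frame."""
    path = Path(path)
    if orientation not in ("cells-rows", "genes-rows"):
        raise ValueError("orientation must be 'cells-rows' or 'genes-rows'")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "genes-rows":
        df = df.T
    return df


def read_expression_mtx(
    mtx_path: str | Path,
    row_names: str | Path,
    col_names: str | Path,
    orientation: str,
) -> pd.DataFrame:
    """Read matrix-market triplet expression with row/column name files."""
    mat = spio.mmread(str(mtx_path)).toarray()
    rows = Path(row_names).read_text().split()
    cols = Path(col_names).read_text().split()
    df = pd.DataFrame(mat, index=rows, columns=cols)
    if orientation == "genes-rows":
        df = df.T
    elif orientation != "cells-rows":
        raise ValueError("orientation must be 'cells-rows' or 'genes-rows'")
    return df


def write_expression(df: pd.DataFrame, path: str | Path, orientation: str = "cells-rows") -> None:
    path = Path(path)
    out = df if orientation == "cells-rows" else df.T
    out.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT)


def read_prior_grn(path: str | Path) -> pd.DataFrame:
    """Read a prior GRN table (columns TF, TG; extra columns pass through)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    lower = {c.lower(): c for c in df.columns}
    if "tf" not in lower or "tg" not in lower:
        df.columns = ["TF", "TG", *df.columns[2:]]
    else:
        df = df.rename(columns={lower["tf"]: "TF", lower["tg"]: "TG"})
    return df


def read_link_set(path: str | Path, signed: bool = False) -> set[tuple]:
    """Read a 2- or 3-column link list as a set of tuples."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if signed:
        if df.shape[1] < 3:
            raise ValueError(f"{path}: signed links require a third (sign) column")
        return {
            (str(a), str(b), int(s))
            for a, b, s in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
        }
    return {(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_pair_set(path: str | Path) -> set[frozenset]:
    """Read an unordered TF-TF pair list (first two columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return {frozenset((str(a), str(b))) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_edge_list(net, path: str | Path) -> None:
    """Write a :class:`~netcoreg.ppin.PPINetwork` as a 3-column TSV."""
    rows = []
    for pair, w in sorted(net.edges.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        rows.append((a, b, w))
    pd.DataFrame(rows, columns=["tf_a", "tf_b", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
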