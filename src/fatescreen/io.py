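"""Text interchange formats: GCT 1.2 matrices and GMT gene sets.

GCT 1.2 is the tab-delimited expression-matrix dialect used throughout the
connectivity-map ecosystem::

    #1.2
    <n_rows>\t<n_cols>
    NAME\tDescription\t<col_1>\t...\t<col_k>
    <gene>\t<desc>\t<v_11>\t...

GMT stores one gene set per line: ``<name>\t<description>\t<gene>...``.

Values are written with Python float ``repr`` so that a read/write round
trip reproduces every value bit-exactly.
"""

from __future__ import annotations

import os
import tempfile
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "read_gct_frame",
    "write_gct_frame",
    "read_gmt",
    "write_gmt",
    "atomic_write_text",
]


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (tmp file + rename)."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=".part")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_gct_frame(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a GCT 1.2 file.

    Returns
    -------
    values : pandas.DataFrame
        Row names (gene ids) x column names, float values.
    descriptions : pandas.Series
        The per-row Description column, indexed like ``values``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise ParseError("expected '#1.2' version header", path=path, line=1)
    if len(lines) < 3:
        raise ParseError("truncated GCT: missing dimension/header lines", path=path, line=len(lines))
    dims = lines[1].split("\t")
    if len(dims) < 2:
        dims = lines[1].split()
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise ParseError(f"bad dimension line {lines[1]!r}", path=path, line=2) from None
    header = lines[2].split("\t")
    if len(header) != n_cols + 2:
        raise ParseError(
            f"header has {len(header) - 2} data columns, dimension line says {n_cols}",
            path=path,
            line=3,
        )
    col_ids = header[2:]
    body = [ln for ln in lines[3:] if ln != ""]
    if len(body) != n_rows:
        raise ParseError(
            f"found {len(body)} data rows, dimension line says {n_rows}",
            path=path,
            line=4 + len(body),
        )
    row_ids: list[str] = []
    descs: list[str] = []
    data = np.empty((n_rows, n_cols), dtype=float)
    for i, ln in enumerate(body):
        fields = ln.split("\t")
        if len(fields) != n_cols + 2:
            raise ParseError(
                f"row has {len(fields) - 2} values, expected {n_cols}",
                path=path,
                line=4 + i,
            )
        row_ids.append(fields[0])
        descs.append(fields[1])
        try:
            data[i] = [float(x) for x in fields[2:]]
        except ValueError:
            raise ParseError("non-numeric value in data row", path=path, line=4 + i) from None
    if len(set(row_ids)) != len(row_ids):
        raise ParseError("duplicate row (gene) identifiers", path=path)
    values = pd.DataFrame(data, index=row_ids, columns=col_ids)
    return values, pd.Series(descs, index=row_ids, name="Description")


def write_gct_frame(values: pd.DataFrame, path, descriptions: pd.Series | None = None) -> None:
    """Write ``values`` (rows x columns) as GCT 1.2 text."""
    n_rows, n_cols = values.shape
    if descriptions is None:
        descriptions = pd.Series("na", index=values.index)
    out = ["#1.2", f"{n_rows}\t{n_cols}"]
    out.append("\t".join(["NAME", "Description", *map(str, values.columns)]))
    arr = values.to_numpy()
    for i, rid in enumerate(values.index):
        vals = "\t".join(repr(float(v)) for v in arr[i])
        out.append(f"{rid}\t{descriptions.iloc[i]}\t{vals}")
    atomic_write_text(path, "\n".join(out) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered ``{set_name: [genes...]}`` mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and >=1 gene", path=path, line=i
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", path=path, line=i)
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None
) -> None:
    descriptions = descriptions or {}
    out = []
    for name, genes in sets.items():
        desc = descriptions.get(name, "na")
        out.append("\t".join([name, desc, *genes]))
    atomic_write_text(path, "\n".join(out) + "\n")
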