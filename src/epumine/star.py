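"""Minimal STAR-format tabular I/O.

Covers the subset of the STAR grammar emitted by motion-correction, CTF
and 2D-classification result tables and by crYOLO CBOX coordinate files:
named ``data_`` blocks holding either flat key-value pairs or a single
``loop_`` table.  Values never contain whitespace in this subset, so no
quoting rules are needed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import pandas as pd

Block = Union[dict, pd.DataFrame]


def _fmt(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_star(path: Path | str, blocks: Mapping[str, Block]) -> Path:
    """Write ``blocks`` (name -> dict of pairs, or DataFrame for a loop)."""
    path = Path(path)
    lines: list[str] = []
    for name, block in blocks.items():
        lines.append(f"data_{name}")
        lines.append("")
        if isinstance(block, pd.DataFrame):
            lines.append("loop_")
            for i, col in enumerate(block.columns, start=1):
                lines.append(f"_{col} #{i}")
            for row in block.itertuples(index=False):
                lines.append(" ".join(_fmt(v) for v in row))
        else:
            for key, value in block.items():
                lines.append(f"_{key} {_fmt(value)}")
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path


def _coerce(column: pd.Series) -> pd.Series:
    try:
        return pd.to_numeric(column)
    except (ValueError, TypeError):
        return column


def _coerce_scalar(token: str):
    for cast in (int, float):
        try:
            return cast(token)
        except ValueError:
            continue
    return token


def read_star(path: Path | str) -> dict[str, Block]:
    """Parse a STAR file into ``{block_name: dict | DataFrame}``.

    Malformed loop rows (wrong field count) are skipped; the count of
    skipped rows is attached to the returned DataFrame as
    ``df.attrs["n_skipped"]``.
    """
    blocks: dict[str, Block] = {}
    name = None
    pairs: dict = {}
    columns: list[str] = []
    rows: list[list] = []
    n_skipped = 0
    in_loop = False

    def flush():
        nonlocal pairs, columns, rows, in_loop, n_skipped
        if name is None:
            return
        if in_loop:
            df = pd.DataFrame(rows, columns=columns)
            df = df.apply(_coerce)
            df.attrs["n_skipped"] = n_skipped
            blocks[name] = df
        else:
            blocks[name] = pairs
        pairs, columns, rows = {}, [], []
        in_loop, n_skipped = False, 0

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            flush()
            name = line[len("data_"):]
        elif line == "loop_":
            in_loop = True
        elif line.startswith("_"):
            if in_loop:
                columns.append(line.split()[0][1:])
            else:
                key, _, value = line.partition(" ")
                pairs[key[1:]] = _coerce_scalar(value.strip())
        elif in_loop:
            fields = line.split()
            if len(fields) != len(columns):
                n_skipped += 1
                continue
            rows.append([_coerce_scalar(f) for f in fields])
    flush()
    return blocks
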