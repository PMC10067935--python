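"""Plain-text readers and writers shared across the pipeline.

All tables travel as tab-separated text. Gene-set collections use the GMT
dialect (set name, description, then one member per field). Protein network
edges use the STRING export dialect: ``node1 <tab> node2 <tab> combined_score``
with scores on STRING's 0-1000 confidence scale.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._errors import ParseError

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_string_edges",
    "read_tsv",
    "write_tsv",
]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of set name -> member genes.

    Raises :class:`ParseError` (with the line number) for lines with fewer
    than three fields or for duplicate set names.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields, need >= 3 (name, description, members)",
                    str(path),
                    lineno,
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", str(path), lineno)
            members = [g for g in fields[2:] if g]
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_string_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-dialect edge list (node1, node2, combined_score).

    A header row naming the columns (optionally ``#``-prefixed) is accepted.
    Malformed rows raise :class:`ParseError` with their line number.
    """
    rows = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if not header_seen and fields[0].lstrip("# ").lower() in {"node1", "protein1"}:
                header_seen = True
                continue
            if line.startswith("#"):  # provenance comment
                continue
            if len(fields) < 3:
                raise ParseError("edge row needs 3 fields (node1, node2, combined_score)", str(path), lineno)
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(f"combined_score {fields[2]!r} is not numeric", str(path), lineno) from None
            if not 0 <= score <= 1000:
                raise ParseError(f"combined_score {score} outside [0, 1000]", str(path), lineno)
            rows.append((fields[0], fields[1], score))
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV table, skipping ``#`` comment/provenance header lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None, index: bool = False) -> None:
    """Write a TSV table, optionally preceded by a ``#`` provenance comment."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(buf.getvalue())
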