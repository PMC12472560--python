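"""Readers and writers for the tabular and graph formats the pipeline touches.

All tabular formats are tab-separated UTF-8 text; lines starting with ``#``
are comments.  Taxon and sample order is preserved exactly as read — nothing
is sorted silently.  Networks go out as GraphML (Gephi-readable) or a flat
edge CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import AsvTable, ValidationError, logger


def _read_rows(path) -> list[tuple[int, list[str]]]:
    """(1-based line number, fields) for every non-comment, non-blank line."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def read_asv_table(path) -> AsvTable:
    """Read a taxa-by-samples count TSV (first column: taxon id).

    Errors carry the offending line number; negative or non-numeric cells
    name both the taxon row and the sample column.
    """
    rows = _read_rows(path)
    if not rows:
        raise ValidationError(f"{path}: empty table")
    header_line, header = rows[0]
    sample_ids = header[1:]
    if not sample_ids:
        raise ValidationError(f"{path}:{header_line}: header has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}:{header_line}: duplicate sample ids in header")
    taxon_ids: list[str] = []
    data: list[list[int]] = []
    seen: set[str] = set()
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        tid = fields[0]
        if tid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate taxon id {tid!r}")
        seen.add(tid)
        row: list[int] = []
        for j, cell in enumerate(fields[1:]):
            try:
                val = int(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"(taxon {tid!r}, sample {sample_ids[j]!r})"
                ) from exc
            if val < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative count {val} "
                    f"(taxon {tid!r}, sample {sample_ids[j]!r})"
                )
            row.append(val)
        taxon_ids.append(tid)
        data.append(row)
    if not data:
        raise ValidationError(f"{path}: table has a header but no taxa")
    return AsvTable(pd.DataFrame(data, index=taxon_ids, columns=sample_ids))


def write_asv_table(table: AsvTable, path) -> None:
    df = table.counts.copy()
    df.insert(0, "ASV_ID", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    df = _read_two_column(path, ("asv_id", "lineage"))
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return _read_two_column(path, ("sample_id", "treatment"))


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_guild_reference(path) -> pd.DataFrame:
    from .containers import GUILD_LABELS

    df = _read_two_column(path, ("pattern", "guild"))
    bad = set(df["guild"]) - set(GUILD_LABELS)
    if bad:
        raise ValidationError(f"{path}: unknown guild labels {sorted(bad)}")
    return df


def write_guild_reference(ref: pd.DataFrame, path) -> None:
    ref.to_csv(path, sep="\t", index=False)


def _read_two_column(path, colnames: tuple[str, str]) -> pd.DataFrame:
    rows = _read_rows(path)
    if not rows:
        raise ValidationError(f"{path}: empty file")
    first = rows[0][1]
    start = 1 if [c.lower() for c in first[:2]] == list(colnames) else 0
    records = []
    for lineno, fields in rows[start:]:
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated fields")
        records.append((fields[0], fields[1]))
    return pd.DataFrame(records, columns=list(colnames))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(net, path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or a flat edge CSV.

    The edge CSV has columns ``source, target, rho, sign``.
    """
    if format == "graphml":
        g = net.graph.copy()
        g.graph["group"] = net.group or ""
        nx.write_graphml(g, path)
    elif format == "edge_csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "rho", "sign"])
            for u, v, attrs in net.graph.edges(data=True):
                w.writerow([u, v, f"{attrs['rho']:.6g}", attrs["sign"]])
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path):
    """Read a GraphML file written by :func:`write_network`."""
    from .network import CoOccurrenceNetwork

    g = nx.read_graphml(path)
    group = g.graph.pop("group", "") or None
    clean = nx.Graph()
    clean.add_nodes_from(g.nodes())
    for u, v, attrs in g.edges(data=True):
        clean.add_edge(u, v, rho=float(attrs["rho"]), sign=attrs["sign"])
    return CoOccurrenceNetwork(graph=clean, group=group)
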