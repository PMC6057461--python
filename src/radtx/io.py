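"""File formats: expression TSV, annotation TSV, GMT, edge lists, tidy CSV.

Dialects:

* expression matrix — TSV, genes as rows, header row of sample IDs, empty
  cell = non-assessable read;
* sample annotation — two-column TSV (sample, arm);
* gene sets — GMT (set_id <tab> description <tab> gene...);
* interactions — two-column edge-list TSV, optional ``#``-prefixed header;
* tidy tables — CSV, one row per observation.

Writers accept a ``header`` mapping rendered as ``# key: value`` comment
lines (used by the pipeline to stamp every output with config hash and
seed); readers skip ``#`` lines. Error messages cite 1-based line numbers.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .containers import ExpressionMatrix
from .enrichment import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "write_expression",
    "read_expression",
    "write_annotation",
    "read_annotation",
    "write_gene_list",
    "read_gene_list",
    "write_gmt",
    "read_gmt",
    "write_edges",
    "read_edges",
    "write_tidy",
    "read_tidy",
]


def _header_block(header: Mapping[str, object] | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in header.items())


def write_expression(
    matrix: ExpressionMatrix,
    values_path: str | Path,
    annotation_path: str | Path,
    header: Mapping[str, object] | None = None,
) -> None:
    buf = _io.StringIO()
    matrix.values.to_csv(buf, sep="\t", na_rep="")
    Path(values_path).write_text(_header_block(header) + buf.getvalue())
    write_annotation(matrix.arms, annotation_path, header=header)


def read_expression(
    values_path: str | Path, annotation_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
    values.index.name = "gene_id"
    arms = read_annotation(annotation_path)
    unknown = set(values.columns) - set(arms.index)
    if unknown:
        raise ValueError(f"samples missing from annotation: {sorted(unknown)}")
    return ExpressionMatrix(values, arms)


def write_annotation(
    arms: pd.Series, path: str | Path, header: Mapping[str, object] | None = None
) -> None:
    lines = [f"{sample}\t{arm}" for sample, arm in arms.items()]
    Path(path).write_text(
        _header_block(header) + "sample\tarm\n" + "\n".join(lines) + "\n"
    )


def read_annotation(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", comment="#")
    if list(frame.columns) != ["sample", "arm"]:
        raise ValueError(f"{path}: expected columns (sample, arm), got {list(frame.columns)}")
    if frame["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample identifiers")
    return frame.set_index("sample")["arm"]


def write_gene_list(
    genes: Sequence[str], path: str | Path, header: Mapping[str, object] | None = None
) -> None:
    Path(path).write_text(_header_block(header) + "".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gmt(
    collection: GeneSetCollection,
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Broad-convention GMT: set_id <tab> description <tab> gene...."""
    descriptions = descriptions or {}
    lines = []
    for sid, members in collection.sets.items():
        desc = descriptions.get(sid, "na")
        lines.append("\t".join([sid, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file.

    When ``universe`` is omitted it defaults to the union of all set
    members; the caller normally restricts it to the transcripts surviving
    preprocessing.
    """
    sets: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs set_id, description, >=1 gene")
        sid = parts[0]
        if sid in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set id {sid!r}")
        sets[sid] = tuple(dict.fromkeys(parts[2:]))
    if universe is None:
        universe = sorted({g for members in sets.values() for g in members})
    return GeneSetCollection(sets=sets, universe=tuple(universe))


def write_edges(
    graph: nx.Graph, path: str | Path, header: Mapping[str, object] | None = None
) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(tuple(sorted(e)) for e in graph.edges)]
    isolated = sorted(v for v in graph.nodes if graph.degree(v) == 0)
    iso_block = "".join(f"# node: {v}\n" for v in isolated)
    Path(path).write_text(
        _header_block(header) + iso_block + "\n".join(lines) + ("\n" if lines else "")
    )


def read_edges(path: str | Path) -> nx.Graph:
    """Two-column edge list; duplicate undirected edges deduplicated with a warning.

    ``# node:`` comment lines restore isolated nodes so write/read round-trips.
    """
    graph = nx.Graph()
    seen: set[tuple[str, str]] = set()
    duplicates = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("# node: "):
                graph.add_node(line[len("# node: ") :].strip())
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated gene ids")
        u, v = parts
        if u == v:
            raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
        key = (u, v) if u <= v else (v, u)
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        graph.add_edge(u, v)
    if duplicates:
        logger.warning("%s: %d duplicate undirected edges removed", path, duplicates)
    return graph


def write_tidy(
    frame: pd.DataFrame, path: str | Path, header: Mapping[str, object] | None = None
) -> None:
    buf = _io.StringIO()
    frame.to_csv(buf, index=False)
    Path(path).write_text(_header_block(header) + buf.getvalue())


def read_tidy(path: str | Path, schema: Sequence[str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    if schema is not None:
        missing = set(schema) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return frame
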