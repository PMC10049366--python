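"""Reference interactome loading and seed-gene mapping.

The interactome is the fixed universe every patient network lives in: an
undirected graph of protein symbols whose edges carry an integer evidence
score (STRING convention, 0-1000). Edges are pre-filtered once at a
confidence threshold; all downstream path computations treat the surviving
graph as unweighted (path length counts hops).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger("ppiclust")

#: STRING "medium confidence" cutoff, used when no threshold is given.
DEFAULT_SCORE_THRESHOLD = 400


class InteractomeError(ValueError):
    """Fatal problem with an interactome file or filter."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_interactome(
    path: str | Path,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
    score_column: int | str | None = 2,
) -> nx.Graph:
    """Load a STRING-style edge list into a filtered undirected graph.

    Parameters
    ----------
    path
        Tab- or space-separated edge list with at least two columns
        (protein_a, protein_b). ``.gz`` files are read transparently.
        A header line is detected and skipped when the score column of the
        first line is non-numeric.
    score_threshold
        Minimum evidence score an edge must carry to be retained.
    score_column
        Column holding the evidence score, by 0-based index or header name.
        ``None`` means the file has no score column and every edge gets
        score 1000.

    Returns
    -------
    networkx.Graph
        Deduplicated (max score wins), self-loop-free, threshold-filtered
        graph. Each edge has an integer ``score`` attribute. Nodes that
        appear only in dropped edges are not part of the node set.

    Raises
    ------
    InteractomeError
        Missing file, malformed line, or a threshold that leaves no edges.
    """
    path = Path(path)
    if not path.exists():
        raise InteractomeError(f"interactome file not found: {path}")

    best: dict[tuple[str, str], int] = {}
    n_self_loops = 0
    n_records = 0
    score_idx: int | None = None

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise InteractomeError(
                    f"{path}:{lineno}: expected >=2 columns, got {len(fields)}"
                )
            if lineno == 1 or score_idx is None:
                # resolve the score column; a named column implies a header
                if score_column is None:
                    score_idx = -1
                elif isinstance(score_column, str):
                    if score_column not in fields:
                        raise InteractomeError(
                            f"{path}: score column {score_column!r} not in header"
                        )
                    score_idx = fields.index(score_column)
                    continue  # header line consumed
                else:
                    score_idx = int(score_column)
                    if score_idx < len(fields):
                        try:
                            int(float(fields[score_idx]))
                        except ValueError:
                            continue  # header line
            a, b = fields[0], fields[1]
            if score_idx == -1 or score_idx >= len(fields):
                score = 1000
            else:
                try:
                    score = int(float(fields[score_idx]))
                except ValueError:
                    raise InteractomeError(
                        f"{path}:{lineno}: malformed score {fields[score_idx]!r}"
                    ) from None
            n_records += 1
            if a == b:
                n_self_loops += 1
                continue
            key = (a, b) if a <= b else (b, a)
            prev = best.get(key)
            if prev is None or score > prev:
                best[key] = score

    g = nx.Graph()
    n_below = 0
    for (a, b), score in best.items():
        if score >= score_threshold:
            g.add_edge(a, b, score=score)
        else:
            n_below += 1

    logger.info(
        "interactome %s: %d records, %d self-loops dropped, %d dedup edges, "
        "%d below threshold %d; kept %d nodes / %d edges",
        path.name, n_records, n_self_loops, len(best), n_below,
        score_threshold, g.number_of_nodes(), g.number_of_edges(),
    )
    if g.number_of_edges() == 0:
        raise InteractomeError(
            f"empty interactome: no edge passes score threshold {score_threshold}"
        )
    return g


def load_gene_protein_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (gene_symbol, protein_id) into a dict."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise InteractomeError(f"mapping file {path}: bad line {line!r}")
            mapping[fields[0]] = fields[1]
    return mapping


def map_seed_genes(
    genes: Sequence[str],
    gene_map: Mapping[str, str] | None,
    net: nx.Graph,
) -> tuple[list[str], list[str]]:
    """Convert seed gene symbols to interactome node ids.

    ``gene_map`` of ``None`` means identity (symbols are node ids).
    Duplicates are collapsed, order of first appearance preserved. Symbols
    that fail mapping or are absent from the graph are returned as dropped
    and logged, never silently discarded.
    """
    mapped: list[str] = []
    dropped: list[str] = []
    seen: set[str] = set()
    for gene in genes:
        node = gene_map.get(gene, None) if gene_map is not None else gene
        if node is None or node not in net:
            if gene not in seen:
                dropped.append(gene)
                seen.add(gene)
            continue
        if node not in seen:
            mapped.append(node)
            seen.add(node)
    if dropped:
        logger.warning("dropped %d seed genes not in interactome: %s",
                       len(dropped), ", ".join(dropped[:10]))
    return mapped, dropped
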