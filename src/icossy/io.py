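"""Readers and writers for the standard expression-analysis file formats.

Supported inputs
----------------
GCT (#1.2)
    Tab-delimited expression matrix: version line, dimension line, a header
    row (``Name``, ``Description``, sample names), then one row per probeset
    or gene.
CLS
    Three-line categorical phenotype file: counts line, ``#``-prefixed class
    name line, per-sample label line.  Exactly two phenotype classes are
    accepted.  Numeric labels (``0``/``1``) are resolved positionally against
    the class-name line, following the de-facto standard dialect.
CHIP
    Tab-delimited probe-to-gene map with a header naming a probe-id column
    and a gene-symbol column.  HGNC symbols are compared case-sensitively
    after trimming whitespace.
SIF / two-column edge list
    Gene interaction network over HGNC symbols.

Outputs: SIF / GraphML / XGMML graph exports and a TSV subnetwork ranking.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("icossy")

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "ChipMap",
    "GeneNetwork",
    "FormatError",
    "read_gct",
    "read_cls",
    "read_chip",
    "read_network_sif",
    "write_gct",
    "write_cls",
    "write_chip",
    "write_sif",
    "write_graph",
    "read_graphml",
    "read_xgmml",
    "write_ranking",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probeset/gene-by-sample matrix of real expression values.

    ``data`` is indexed by unique row identifiers (probesets for microarray,
    genes for RNA-seq) with one column per sample.  ``row_descriptions``
    carries the GCT ``Description`` column, which for RNA-seq inputs holds
    the gene map.
    """

    data: pd.DataFrame
    row_descriptions: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate row identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("expression matrix must have >= 1 row and >= 1 sample")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise FormatError("expression matrix contains non-finite values")
        self.row_descriptions = self.row_descriptions.reindex(self.data.index).fillna("")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        """Column subset preserving the given sample order."""
        keep = list(sample_ids)
        return ExpressionMatrix(self.data[keep].copy(), self.row_descriptions.copy())


@dataclass
class PhenotypeLabels:
    """Two-class phenotype assignment, in the sample order of the matrix."""

    sample_ids: list[str]
    class_names: tuple[str, str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != 2:
            raise FormatError("exactly two phenotypes required")
        counts = self.class_counts()
        for cls, n in counts.items():
            if n < 2:
                raise FormatError(f"phenotype class {cls!r} has {n} sample(s); >= 2 required")

    def labels(self) -> list[str]:
        return [self.assignment[s] for s in self.sample_ids]

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.class_names}
        for s in self.sample_ids:
            out[self.assignment[s]] += 1
        return out

    def samples_of(self, class_name: str) -> list[str]:
        return [s for s in self.sample_ids if self.assignment[s] == class_name]

    def with_sample_ids(self, sample_ids: Iterable[str]) -> "PhenotypeLabels":
        """Rebind the positional CLS labels to the matrix's sample names."""
        ids = list(sample_ids)
        if len(ids) != len(self.sample_ids):
            raise FormatError(
                f"class file labels {len(self.sample_ids)} samples "
                f"but the expression matrix has {len(ids)}"
            )
        lab = self.labels()
        return PhenotypeLabels(ids, self.class_names, dict(zip(ids, lab)))

    def subset(self, sample_ids: Iterable[str]) -> "PhenotypeLabels":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return PhenotypeLabels(keep, self.class_names, {s: self.assignment[s] for s in keep})


@dataclass
class ChipMap:
    """Many-to-one probe-to-HGNC-symbol map; unmapped probes are retained."""

    probe_to_gene: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    @property
    def gene_to_probes(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for probe, gene in self.probe_to_gene.items():
            inv.setdefault(gene, set()).add(probe)
        return inv

    @classmethod
    def from_descriptions(cls, m: ExpressionMatrix) -> "ChipMap":
        """Build the probe->gene map from a GCT Description column (RNA-seq path)."""
        mapping: dict[str, str] = {}
        unmapped: set[str] = set()
        for row_id, desc in m.row_descriptions.items():
            symbol = str(desc).strip()
            if symbol:
                mapping[str(row_id)] = symbol
            else:
                unmapped.add(str(row_id))
        if unmapped:
            logger.info("%d rows carry no gene symbol in the description column", len(unmapped))
        return cls(mapping, unmapped)


@dataclass
class GeneNetwork:
    """Undirected interaction graph over HGNC gene symbols."""

    graph: nx.Graph
    source_tag: str = ""

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], source_tag: str = "") -> "GeneNetwork":
        g = nx.Graph()
        n_loops = 0
        for a, b in edges:
            a, b = a.strip(), b.strip()
            if a == b:
                n_loops += 1
                continue
            g.add_edge(a, b)
        if n_loops:
            logger.info("dropped %d self-loop edge(s)", n_loops)
        return cls(g, source_tag)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    lines = text.split("\n")
    while lines and lines[-1].strip() == "":
        lines.pop()
    return lines


def read_gct(path: str | Path) -> ExpressionMatrix:
    """Parse a GCT #1.2 expression file.

    Raises :class:`FormatError` (naming the offending line) on a bad version
    line, a dimension mismatch, duplicate row ids, or non-numeric cells.
    Missing (NA/blank) cells are rejected: downstream rank normalization is
    undefined on missing values.
    """
    lines = _lines(path)
    if len(lines) < 4:
        raise FormatError(f"{path}: GCT needs version, dimension, header and data lines")
    if lines[0].strip() != "#1.2":
        raise FormatError(f"{path}, line 1: expected GCT version line '#1.2', got {lines[0]!r}")
    dims = lines[1].split("\t")
    try:
        n_rows, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}, line 2: malformed dimension line {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) < 3 or header[0].lower() != "name":
        raise FormatError(f"{path}, line 3: expected header 'Name\\tDescription\\t<samples>'")
    sample_ids = [h.strip() for h in header[2:]]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}, line 3: dimension line declares {n_samples} samples "
            f"but header has {len(sample_ids)}"
        )
    body = lines[3:]
    if len(body) != n_rows:
        raise FormatError(
            f"{path}: dimension line declares {n_rows} rows but body has {len(body)}"
        )
    row_ids: list[str] = []
    descriptions: list[str] = []
    values = np.empty((n_rows, n_samples))
    for i, line in enumerate(body):
        cells = line.split("\t")
        if len(cells) != n_samples + 2:
            raise FormatError(
                f"{path}, line {i + 4}: expected {n_samples + 2} columns, got {len(cells)}"
            )
        row_ids.append(cells[0].strip())
        descriptions.append(cells[1].strip())
        for j, cell in enumerate(cells[2:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}, line {i + 4}: non-numeric cell {cell!r} in column {j + 3}"
                ) from exc
            if not np.isfinite(v):
                raise FormatError(f"{path}, line {i + 4}: non-finite cell {cell!r}")
            values[i, j] = v
    seen: set[str] = set()
    dups = sorted({r for r in row_ids if r in seen or seen.add(r)})
    if dups:
        raise FormatError(f"{path}: duplicate row identifiers: {dups}")
    data = pd.DataFrame(values, index=row_ids, columns=sample_ids)
    return ExpressionMatrix(data, pd.Series(descriptions, index=row_ids))


def read_cls(path: str | Path) -> PhenotypeLabels:
    """Parse a three-line CLS phenotype file into exactly two classes."""
    lines = _lines(path)
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs counts, class-name and label lines")
    counts = lines[0].split()
    try:
        n_samples, n_classes = int(counts[0]), int(counts[1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}, line 1: malformed counts line {lines[0]!r}") from exc
    if n_classes != 2:
        raise FormatError(f"{path}: exactly two phenotypes required, file declares {n_classes}")
    name_tokens = lines[1].split()
    if not name_tokens or not name_tokens[0].startswith("#"):
        raise FormatError(f"{path}, line 2: class-name line must start with '#'")
    names = [t for t in name_tokens if t != "#"]
    if names and names[0].startswith("#"):
        names[0] = names[0][1:]
    names = [n for n in names if n]
    if len(names) != 2 or names[0] == names[1]:
        raise FormatError(f"{path}, line 2: expected two distinct class names, got {names}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}, line 3: counts line declares {n_samples} samples, label line has {len(tokens)}"
        )
    # Numeric labels are positional indices into the class-name line.
    if all(t.isdigit() for t in tokens):
        order_seen = list(dict.fromkeys(tokens))
        index_of = {tok: i for i, tok in enumerate(order_seen)}
        if len(order_seen) > 2 or any(int(t) not in (0, 1) for t in tokens):
            raise FormatError(f"{path}, line 3: numeric labels must be 0/1 over two classes")
        labels = [names[index_of[t]] for t in tokens]
    else:
        unknown = sorted(set(tokens) - set(names))
        if unknown:
            raise FormatError(f"{path}, line 3: unknown label token(s) {unknown}")
        labels = tokens
    sample_ids = [f"sample_{i + 1}" for i in range(n_samples)]
    assignment = dict(zip(sample_ids, labels))
    if len(set(labels)) != 2:
        raise FormatError(f"{path}: both declared classes must appear in the label line")
    return PhenotypeLabels(sample_ids, (names[0], names[1]), assignment)


_PROBE_COLS = {"probe set id", "probe_set_id", "probe id", "probe_id", "probe", "probeset", "id"}
_SYMBOL_COLS = {"gene symbol", "gene_symbol", "symbol"}


def read_chip(path: str | Path) -> ChipMap:
    """Parse a tab-delimited CHIP probe-to-gene map."""
    lines = _lines(path)
    if not lines:
        raise FormatError(f"{path}: empty chip file")
    header = [h.strip() for h in lines[0].split("\t")]
    lower = [h.lower() for h in header]
    try:
        probe_col = next(i for i, h in enumerate(lower) if h in _PROBE_COLS)
        symbol_col = next(i for i, h in enumerate(lower) if h in _SYMBOL_COLS)
    except StopIteration as exc:
        raise FormatError(
            f"{path}: chip header must name a probe-id and a gene-symbol column, got {header}"
        ) from exc
    mapping: dict[str, str] = {}
    unmapped: set[str] = set()
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) <= max(probe_col, symbol_col):
            raise FormatError(f"{path}, line {i}: too few columns")
        probe = cells[probe_col].strip()
        symbol = cells[symbol_col].strip()
        if not probe:
            continue
        if not symbol or symbol.upper() in {"---", "NA", "N/A"}:
            unmapped.add(probe)
            continue
        if probe in mapping and mapping[probe] != symbol:
            raise FormatError(
                f"{path}, line {i}: probe {probe!r} maps to both "
                f"{mapping[probe]!r} and {symbol!r}"
            )
        mapping[probe] = symbol
    if unmapped:
        logger.info("chip file %s: %d unmapped probe(s)", path, len(unmapped))
    return ChipMap(mapping, unmapped)


def read_network_sif(path: str | Path) -> GeneNetwork:
    """Parse a SIF (``nodeA relation nodeB [nodeC ...]``) or two-column edge list."""
    lines = [ln for ln in _lines(path) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty network file")
    edges: list[tuple[str, str]] = []
    for i, line in enumerate(lines, start=1):
        tokens = line.split()
        if len(tokens) == 2:
            edges.append((tokens[0], tokens[1]))
        elif len(tokens) >= 3:
            for target in tokens[2:]:
                edges.append((tokens[0], target))
        else:
            raise FormatError(f"{path}, line {i}: need at least two node tokens, got {line!r}")
    return GeneNetwork.from_edges(edges, source_tag=str(path))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_gct(m: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{m.data.shape[0]}\t{m.data.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(m.sample_ids) + "\n")
        for row_id in m.row_ids:
            desc = m.row_descriptions[row_id]
            vals = "\t".join(repr(float(v)) for v in m.data.loc[row_id])
            fh.write(f"{row_id}\t{desc}\t{vals}\n")


def write_cls(labels: PhenotypeLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(labels.sample_ids)} 2 1\n")
        fh.write("# " + " ".join(labels.class_names) + "\n")
        fh.write(" ".join(labels.labels()) + "\n")


def write_chip(chip: ChipMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Probe Set ID\tGene Symbol\n")
        for probe in sorted(chip.probe_to_gene):
            fh.write(f"{probe}\t{chip.probe_to_gene[probe]}\n")
        for probe in sorted(chip.unmapped):
            fh.write(f"{probe}\t\n")


def write_sif(net: GeneNetwork, path: str | Path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(nx.isolates(net.graph)):
            fh.write(f"{node}\n")


# -- graph exports -----------------------------------------------------------

_NODE_DEFAULTS = {"symbol": "", "fold_difference": 0.0, "direction": "", "role": ""}
_EDGE_DEFAULTS = {"provenance": "mis-internal"}


def _as_annotated_graph(g) -> nx.Graph:
    """Accept a StitchedGraph, an MIS, or a plain nx.Graph; fill attribute defaults."""
    if hasattr(g, "graph") and isinstance(g.graph, nx.Graph):
        h = g.graph.copy()
    elif isinstance(g, nx.Graph):
        h = g.copy()
    elif hasattr(g, "to_graph"):
        h = g.to_graph()
    else:
        raise TypeError(f"cannot export object of type {type(g).__name__}")
    if h.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty graph")
    for node, attrs in h.nodes(data=True):
        attrs.setdefault("symbol", str(node))
        for key, default in _NODE_DEFAULTS.items():
            attrs.setdefault(key, default)
        attrs["fold_difference"] = float(attrs["fold_difference"])
    for _, _, attrs in h.edges(data=True):
        for key, default in _EDGE_DEFAULTS.items():
            attrs.setdefault(key, default)
    return h


def write_graph(g, fmt: str, path: str | Path) -> None:
    """Export a subnetwork or stitched graph as SIF, GraphML or XGMML.

    Node attributes carried in GraphML/XGMML: gene ``symbol``, mean
    ``fold_difference`` between the phenotype classes, regulation
    ``direction`` (up/down).  Edge attribute: ``provenance``
    (mis-internal | bridge-edge | bridge-path); in SIF the provenance is
    used as the relation token.
    """
    h = _as_annotated_graph(g)
    fmt = fmt.strip().lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(tuple(sorted((str(e[0]), str(e[1])))) for e in h.edges):
                fh.write(f"{a}\t{h.edges[a, b]['provenance']}\t{b}\n")
            for node in sorted(nx.isolates(h)):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(h, path)
    elif fmt == "xgmml":
        _write_xgmml(h, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; expected SIF, GraphML or XGMML")


def _write_xgmml(h: nx.Graph, path: str | Path) -> None:
    root = ET.Element(
        "graph",
        {
            "label": "icossy",
            "directed": "0",
            "xmlns": "http://www.cs.rpi.edu/XGMML",
        },
    )
    for node, attrs in sorted(h.nodes(data=True)):
        el = ET.SubElement(root, "node", {"id": str(node), "label": str(node)})
        ET.SubElement(
            el, "att", {"name": "symbol", "type": "string", "value": str(attrs["symbol"])}
        )
        ET.SubElement(
            el,
            "att",
            {"name": "fold_difference", "type": "real", "value": repr(attrs["fold_difference"])},
        )
        ET.SubElement(
            el, "att", {"name": "direction", "type": "string", "value": str(attrs["direction"])}
        )
    for a, b in sorted(tuple(sorted((str(e[0]), str(e[1])))) for e in h.edges):
        el = ET.SubElement(root, "edge", {"source": a, "target": b, "label": f"{a} ({b})"})
        ET.SubElement(
            el,
            "att",
            {"name": "provenance", "type": "string", "value": h.edges[a, b]["provenance"]},
        )
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def read_xgmml(path: str | Path) -> nx.Graph:
    """Minimal XGMML reader; exists so export round-trips are verifiable."""
    ns = "{http://www.cs.rpi.edu/XGMML}"
    root = ET.parse(path).getroot()
    g = nx.Graph()
    for el in root:
        tag = el.tag.removeprefix(ns)
        atts = {a.get("name"): a.get("value") for a in el if a.tag.removeprefix(ns) == "att"}
        if tag == "node":
            g.add_node(el.get("id"), **atts)
        elif tag == "edge":
            g.add_edge(el.get("source"), el.get("target"), **atts)
    return g


def write_ranking(scores, path: str | Path) -> None:
    """Write the final ordered subnetwork ranking as TSV.

    Columns: rank, mis_id, n_genes, entropy, cv_frequency,
    representative_probesets, representative_genes.  Entropy is printed with
    8 significant digits so a re-parse agrees to 1e-6.
    """
    with open(path, "w") as fh:
        fh.write(
            "rank\tmis_id\tn_genes\tentropy\tcv_frequency\t"
            "representative_probesets\trepresentative_genes\n"
        )
        for rank, s in enumerate(scores, start=1):
            probes = ",".join(r.probeset_id for r in s.representatives)
            genes = ",".join(dict.fromkeys(r.gene for r in s.representatives))
            freq = "" if s.cv_frequency is None else str(s.cv_frequency)
            fh.write(
                f"{rank}\t{s.mis_id}\t{len(s.genes)}\t{s.entropy:.8g}\t{freq}\t{probes}\t{genes}\n"
            )
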