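"""Readers and writers for sequences, E-value tables, annotations and graphs.

Formats supported
-----------------
* multi-record FASTA (wrapped lines) via Biopython;
* BLAST tabular 12-column reports (E-value in column 11) and a plain
  three-column ``query<TAB>subject<TAB>evalue`` dialect;
* an annotation CSV with a declared header ``id,family,class,prefix,structures``
  (structures ';'-separated, may be empty);
* annotated network graphs as GraphML, Cytoscape.js element JSON and
  edge-list TSV.  GraphML and Cytoscape-JSON round-trips are lossless for
  the attribute types used (str, int, float, bool).

Distances are serialized in full double precision scientific notation:
E-values span more than 150 orders of magnitude and truncation would
destroy the network structure.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import InputFormatError, InvariantError

#: the 20 standard amino acids plus ambiguity codes B/X/Z/J, the rare
#: U (selenocysteine) and O (pyrrolysine), and the stop '*'
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BXZJUO*")

_PREFIX_RE = re.compile(r"^[A-Za-z0-9]{2,3}$")

EDGE_ROLES = ("core-shortest", "toward-core", "tree", "plain")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header,
    matching the id convention of BLAST tabular output so sequence files and
    E-value tables join without munging.
    """

    id: str
    residues: str
    description: str = ""


def _as_text_stream(stream) -> _io.StringIO:
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


def read_fasta(stream) -> list[SequenceRecord]:
    """Parse FASTA text (string or text stream) into sequence records.

    Wrapped sequence lines are concatenated and residues are uppercased.
    Raises :class:`InputFormatError` on an empty stream, an id collision, or
    a residue outside the amino-acid alphabet.
    """
    handle = _as_text_stream(stream)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        residues = str(rec.seq).upper()
        if not rec.id:
            raise InputFormatError("FASTA record with empty id")
        if rec.id in seen:
            raise InputFormatError(f"duplicate FASTA id {rec.id!r}")
        if len(residues) == 0:
            raise InputFormatError(f"record {rec.id!r} has an empty sequence")
        bad = set(residues) - AMINO_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            raise InputFormatError(
                f"record {rec.id!r} contains illegal character {ch!r}"
            )
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, residues=residues,
                           description=rec.description)
        )
    if not records:
        raise InputFormatError("no records")
    return records


def write_fasta(records: list[SequenceRecord], width: int = 60) -> str:
    """Render records as FASTA text (inverse of :func:`read_fasta`)."""
    out = _io.StringIO()
    bio = [
        _BioRecord(Seq(r.residues), id=r.id,
                   description=r.description if r.description != r.id else "")
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(out, wrap=width)
    writer.write_file(bio)
    return out.getvalue()


# ---------------------------------------------------------------------------
# E-value tables
# ---------------------------------------------------------------------------

@dataclass
class EvalueTable:
    """Directed pairwise E-values between named sequences.

    ``entries`` maps ordered ``(query, subject)`` pairs to the best
    (minimum) E-value observed; ``ids`` lists all sequence ids in first
    appearance order.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    ids: list[str] = field(default_factory=list)

    def add(self, query: str, subject: str, evalue: float) -> None:
        if evalue < 0:
            raise InputFormatError(f"negative E-value {evalue!r}")
        for name in (query, subject):
            if name not in self._seen():
                self.ids.append(name)
        key = (query, subject)
        prev = self.entries.get(key)
        if prev is None or evalue < prev:
            self.entries[key] = evalue

    def _seen(self) -> set[str]:
        # small tables only; callers needing speed should use parse_evalue_table
        return set(self.ids)

    def get(self, query: str, subject: str) -> float | None:
        return self.entries.get((query, subject))


def parse_evalue_table(stream, fmt: str = "three-col") -> EvalueTable:
    """Parse a directed E-value table.

    ``fmt`` is ``"three-col"`` (query, subject, evalue — whitespace or tab
    separated) or ``"blast-tab-12col"`` (the standard 12-column tabular
    alignment report; E-value is column 11).  Duplicate ordered pairs keep
    the minimum E-value: BLAST emits one line per HSP and the best hit is
    the standard similarity summary.  The collapse rule makes parsing
    order-insensitive.
    """
    if fmt not in ("three-col", "blast-tab-12col"):
        raise ValueError(f"unknown E-value table format {fmt!r}")
    handle = _as_text_stream(stream)
    entries: dict[tuple[str, str], float] = {}
    ids: list[str] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if fmt == "three-col":
            if len(cols) != 3:
                raise InputFormatError(
                    f"line {lineno}: expected 3 columns, got {len(cols)}"
                )
            q, s, ev_text = cols
        else:
            if len(cols) != 12:
                raise InputFormatError(
                    f"line {lineno}: expected 12 columns, got {len(cols)}"
                )
            q, s, ev_text = cols[0], cols[1], cols[10]
        try:
            ev = float(ev_text)
        except ValueError as exc:
            raise InputFormatError(
                f"line {lineno}: non-numeric E-value {ev_text!r}"
            ) from exc
        if not np.isfinite(ev) or ev < 0:
            raise InputFormatError(
                f"line {lineno}: invalid E-value {ev_text!r} (must be >= 0)"
            )
        for name in (q, s):
            if name not in seen:
                seen.add(name)
                ids.append(name)
        key = (q, s)
        prev = entries.get(key)
        if prev is None or ev < prev:
            entries[key] = ev
    return EvalueTable(entries=entries, ids=ids)


def write_evalue_table(table: EvalueTable) -> str:
    """Render a table in the three-column dialect, full precision."""
    lines = [
        f"{q}\t{s}\t{ev:.17e}" for (q, s), ev in sorted(table.entries.items())
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRow:
    family: str
    class_label: str
    prefix: str
    structures: tuple[str, ...] = ()


@dataclass
class AnnotationTable:
    """Mapping sequence id → functional annotation.

    ``prefix`` is the 2–3 alphanumeric receptor-group code used to label
    clusters (e.g. ``Pe`` for peptide receptors, ``MiR`` for a three-letter
    group), followed downstream by a three-digit cluster number.
    """

    rows: dict[str, AnnotationRow] = field(default_factory=dict)

    def get(self, seq_id: str) -> AnnotationRow | None:
        return self.rows.get(seq_id)


_ANNOTATION_COLUMNS = ("id", "family", "class", "prefix", "structures")


def read_annotations(stream) -> AnnotationTable:
    """Parse an annotation CSV with header ``id,family,class,prefix,structures``."""
    handle = _as_text_stream(stream)
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        raise InputFormatError("empty annotation stream")
    missing = set(_ANNOTATION_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise InputFormatError(
            f"annotation header missing columns: {sorted(missing)}"
        )
    rows: dict[str, AnnotationRow] = {}
    for lineno, rec in enumerate(reader, start=2):
        seq_id = (rec["id"] or "").strip()
        if not seq_id:
            raise InputFormatError(f"line {lineno}: empty id")
        if seq_id in rows:
            raise InputFormatError(f"line {lineno}: duplicate id {seq_id!r}")
        prefix = (rec["prefix"] or "").strip()
        if not _PREFIX_RE.match(prefix):
            raise InputFormatError(
                f"line {lineno}: prefix {prefix!r} is not 2-3 alphanumerics"
            )
        structures = tuple(
            s for s in (rec["structures"] or "").split(";") if s.strip()
        )
        rows[seq_id] = AnnotationRow(
            family=(rec["family"] or "").strip(),
            class_label=(rec["class"] or "").strip(),
            prefix=prefix,
            structures=structures,
        )
    return AnnotationTable(rows=rows)


def write_annotations(table: AnnotationTable) -> str:
    out = _io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(_ANNOTATION_COLUMNS)
    for seq_id in sorted(table.rows):
        row = table.rows[seq_id]
        writer.writerow(
            [seq_id, row.family, row.class_label, row.prefix,
             ";".join(row.structures)]
        )
    return out.getvalue()


# ---------------------------------------------------------------------------
# graph documents
# ---------------------------------------------------------------------------

def _native(value):
    """Cast numpy scalars to native Python so serializers type them correctly."""
    if isinstance(value, np.generic):
        return value.item()
    return value


@dataclass
class GraphDocument:
    """An annotated undirected graph ready for export.

    ``nodes`` is a list of attribute dicts each carrying an ``id`` key;
    ``edges`` a list of dicts with ``source``/``target`` keys plus
    attributes.  Exported formats carry no arrowheads, so the arrow
    semantics of a cluster diagram (shortest edge inside a zero-distance
    core, edges pointing toward the core) are encoded in the ``role`` edge
    attribute with vocabulary ``core-shortest``/``toward-core``/``tree``/
    ``plain``.
    """

    nodes: list[dict] = field(default_factory=list)
    edges: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        node_ids = set()
        for node in self.nodes:
            if "id" not in node:
                raise InvariantError("node without an 'id' attribute")
            nid = str(node["id"])
            if nid in node_ids:
                raise InvariantError(f"duplicate node id {nid!r}")
            node_ids.add(nid)
            for k, v in list(node.items()):
                node[k] = _native(v)
        normalized = []
        for edge in self.edges:
            if "source" not in edge or "target" not in edge:
                raise InvariantError("edge without source/target")
            src, tgt = str(edge["source"]), str(edge["target"])
            if src not in node_ids or tgt not in node_ids:
                raise InvariantError(
                    f"edge ({src!r}, {tgt!r}) references an unknown node"
                )
            if "distance" in edge and edge["distance"] is not None:
                if float(edge["distance"]) < 0:
                    raise InvariantError(
                        f"edge ({src!r}, {tgt!r}) has negative distance"
                    )
            e = {k: _native(v) for k, v in edge.items()}
            # undirected graph: canonical endpoint order
            if tgt < src:
                e["source"], e["target"] = tgt, src
            else:
                e["source"], e["target"] = src, tgt
            normalized.append(e)
        self.edges = normalized

    # equality is structural: node set and edge set with all attributes
    def _canonical(self):
        nodes = {n["id"]: {k: v for k, v in n.items() if k != "id"}
                 for n in self.nodes}
        edges = {
            (e["source"], e["target"]): {
                k: v for k, v in e.items() if k not in ("source", "target")
            }
            for e in self.edges
        }
        return nodes, edges

    def __eq__(self, other) -> bool:
        if not isinstance(other, GraphDocument):
            return NotImplemented
        return self._canonical() == other._canonical()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            attrs = {k: v for k, v in node.items() if k != "id"}
            g.add_node(node["id"], **attrs)
        for edge in self.edges:
            attrs = {k: v for k, v in edge.items()
                     if k not in ("source", "target")}
            g.add_edge(edge["source"], edge["target"], **attrs)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "GraphDocument":
        nodes = [{"id": str(n), **dict(data)} for n, data in g.nodes(data=True)]
        edges = [
            {"source": str(u), "target": str(v), **dict(data)}
            for u, v, data in g.edges(data=True)
        ]
        return cls(nodes=nodes, edges=edges)


GRAPH_FORMATS = ("graphml", "cytoscape-json", "edge-list-tsv")


def write_graph(doc: GraphDocument, fmt: str = "graphml") -> str:
    """Serialize a graph document; GraphML and Cytoscape-JSON round-trip."""
    doc.validate()
    if fmt == "graphml":
        g = doc.to_networkx()
        return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
    if fmt == "cytoscape-json":
        data = nx.cytoscape_data(doc.to_networkx())
        return json.dumps(data, indent=2, sort_keys=True) + "\n"
    if fmt == "edge-list-tsv":
        lines = ["source\ttarget\tdistance"]
        for edge in sorted(doc.edges,
                           key=lambda e: (e["source"], e["target"])):
            d = edge.get("distance")
            text = f"{float(d):.17e}" if d is not None else ""
            lines.append(f"{edge['source']}\t{edge['target']}\t{text}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown graph format {fmt!r}")


def read_graph(text: str, fmt: str = "graphml") -> GraphDocument:
    """Parse serialized graph text back into a :class:`GraphDocument`."""
    if fmt == "graphml":
        g = nx.parse_graphml(text)
        return GraphDocument.from_networkx(nx.Graph(g))
    if fmt == "cytoscape-json":
        g = nx.cytoscape_graph(json.loads(text))
        doc = GraphDocument.from_networkx(nx.Graph(g))
        # cytoscape_data adds presentation keys; strip them for round-trip
        for node in doc.nodes:
            node.pop("name", None)
            node.pop("value", None)
        return doc
    if fmt == "edge-list-tsv":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if lines and lines[0].startswith("source\t"):
            lines = lines[1:]
        nodes: dict[str, dict] = {}
        edges = []
        for lineno, line in enumerate(lines, start=2):
            cols = line.split("\t")
            if len(cols) != 3:
                raise InputFormatError(
                    f"line {lineno}: expected 3 columns, got {len(cols)}"
                )
            src, tgt, dist = cols
            nodes.setdefault(src, {"id": src})
            nodes.setdefault(tgt, {"id": tgt})
            edge = {"source": src, "target": tgt}
            if dist:
                edge["distance"] = float(dist)
            edges.append(edge)
        return GraphDocument(nodes=list(nodes.values()), edges=edges)
    raise ValueError(f"unknown graph format {fmt!r}")


# ---------------------------------------------------------------------------
# distance-matrix TSV persistence
# ---------------------------------------------------------------------------

def write_distance_tsv(dm) -> str:
    """Serialize a DistanceMatrix as ``id_i<TAB>id_j<TAB>distance`` lines.

    All unordered pairs are written (i < j in the matrix id order) with full
    double precision, so the matrix reconstructs exactly.
    """
    lines = []
    ids = dm.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            lines.append(f"{ids[i]}\t{ids[j]}\t{dm.values[i, j]:.17e}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_distance_tsv(text: str, meta: str = "synthetic"):
    """Parse :func:`write_distance_tsv` output back into a DistanceMatrix."""
    from .distance import DistanceMatrix  # local import to avoid a cycle

    ids: list[str] = []
    seen: set[str] = set()
    entries: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise InputFormatError(
                f"line {lineno}: expected 3 columns, got {len(cols)}"
            )
        a, b, d_text = cols
        try:
            d = float(d_text)
        except ValueError as exc:
            raise InputFormatError(
                f"line {lineno}: non-numeric distance {d_text!r}"
            ) from exc
        if d < 0:
            raise InputFormatError(f"line {lineno}: negative distance")
        for name in (a, b):
            if name not in seen:
                seen.add(name)
                ids.append(name)
        entries[(a, b)] = d
        entries[(b, a)] = d
    if not ids:
        raise InputFormatError("empty distance table")
    n = len(ids)
    index = {name: i for i, name in enumerate(ids)}
    values = np.zeros((n, n))
    for (a, b), d in entries.items():
        values[index[a], index[b]] = d
    missing = [
        (ids[i], ids[j])
        for i in range(n) for j in range(i + 1, n)
        if (ids[i], ids[j]) not in entries and (ids[j], ids[i]) not in entries
    ]
    if missing:
        raise InputFormatError(
            f"distance table incomplete; first missing pair: {missing[0]}"
        )
    return DistanceMatrix(ids=tuple(ids), values=values, meta=meta)
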