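"""Readers and writers for the standard formats the workflow touches.

Formats: FASTA (sequences), BLAST tabular hit tables (outfmt-6-like),
GenePix GPR result files, OBO 1.2 ontologies, tab-delimited probe
annotation tables, and XGMML/GraphML graph exports.

Parsing contracts are strict: duplicate ids, missing required columns and
alphabet violations raise errors rather than being silently repaired, and
no data row is silently dropped.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

#: canonical 12 columns of BLAST tabular output (``-outfmt 6``)
BLAST6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore",
]

HIT_REQUIRED = ["query_id", "subject_id", "percent_identity",
                "alignment_length", "evalue", "bitscore"]

#: GPR columns that must be present (any superset is accepted)
GPR_REQUIRED = ["Block", "Row", "Column", "ID", "F635 Median", "B635 Median",
                "F532 Median", "B532 Median", "Flags"]

#: within-field separator joining GO terms in the probe annotation table
TERM_SEPARATOR = " // "


@dataclass
class SequenceSet:
    """A set of named sequences over a declared alphabet.

    records : list of (id, description, sequence) triples, order preserved.
    alphabet : ``"nucleotide"`` or ``"protein"``.
    """

    records: list[tuple[str, str, str]]
    alphabet: str = "nucleotide"

    def __post_init__(self):
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        letters = (NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide"
                   else PROTEIN_ALPHABET)
        seen = set()
        for rid, _, seq in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"empty sequence for id {rid!r}")
            bad = set(seq.upper()) - letters
            if bad:
                raise ValueError(
                    f"sequence {rid!r} contains residues {sorted(bad)} not in "
                    f"the {self.alphabet} alphabet")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _, _ in self.records]

    def get(self, rid: str) -> str:
        for r, _, seq in self.records:
            if r == rid:
                return seq
        raise KeyError(rid)


@dataclass
class TwoColorArray:
    """Per-spot two-channel intensities of one hybridized slide.

    ``spots`` holds one row per spot with columns
    ``probe_id, block, row, column, fg_ch1, bg_ch1, fg_ch2, bg_ch2, flag``
    (ch1 = 635 nm / Cy5, ch2 = 532 nm / Cy3).  ``dye_orientation`` records
    which channel carries the treatment sample so that a dye swap can be
    folded into the log-ratio sign downstream.
    """

    spots: pd.DataFrame
    array_id: str
    dye_orientation: str = "treatment_in_ch1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dye_orientation not in ("treatment_in_ch1", "treatment_in_ch2"):
            raise ValueError(f"bad dye_orientation {self.dye_orientation!r}")
        needed = {"probe_id", "block", "row", "column",
                  "fg_ch1", "bg_ch1", "fg_ch2", "bg_ch2", "flag"}
        missing = needed - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns {sorted(missing)}")
        for c in ("fg_ch1", "bg_ch1", "fg_ch2", "bg_ch2"):
            if (self.spots[c] < 0).any():
                raise ValueError(f"negative intensities in column {c}")
        key = self.spots[["block", "row", "column"]]
        if key.duplicated().any():
            raise ValueError("duplicate (block,row,column) spot coordinates")

    def __len__(self):
        return len(self.spots)


class GoDag:
    """A GO-style directed acyclic graph of terms.

    Edges run child -> parent and carry a ``relation`` attribute; only
    ``is_a`` and ``part_of`` are treated as propagating relations.
    """

    def __init__(self, graph: nx.DiGraph, names: dict[str, str],
                 namespaces: dict[str, str]):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")
        for u, v in graph.edges():
            if u not in graph or v not in graph:  # pragma: no cover
                raise ValueError(f"edge endpoint not a known term: {u}->{v}")
        self.graph = graph
        self.names = names
        self.namespaces = namespaces

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes())

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by is_a/part_of (excl. itself)."""
        return set(nx.descendants(self.graph, term))

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes() if self.graph.out_degree(t) == 0}

    def __contains__(self, term):
        return term in self.graph

    def __len__(self):
        return self.graph.number_of_nodes()


@dataclass
class AnnotationTable:
    """Mapping from entity (probe/gene/protein) ids to sets of term ids.

    An entity mapped to an empty set is explicitly "unannotated" and is
    kept in the table.
    """

    terms: dict[str, set[str]]

    def __getitem__(self, entity):
        return self.terms[entity]

    def __contains__(self, entity):
        return entity in self.terms

    def __len__(self):
        return len(self.terms)

    def items(self):
        return self.terms.items()

    @property
    def entities(self):
        return set(self.terms)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "nucleotide") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Raises on empty files, duplicate ids and alphabet violations.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append((rec.id, desc, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description=desc)
            for rid, desc, seq in seqs.records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular hit tables

def read_hit_table(path, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt-6-like) hit table.

    Lines beginning ``#`` are skipped.  ``columns`` may declare a custom
    column map; by default the 12-column BLAST dialect is assumed and any
    extra trailing columns are ignored.  Returns a DataFrame with at least
    the columns in :data:`HIT_REQUIRED`, with typed numeric fields.
    """
    names = columns or BLAST6_COLUMNS
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(names):
                raise ValueError(
                    f"{path}:{lineno}: expected >= {len(names)} columns, "
                    f"got {len(fields)}")
            rows.append((lineno, fields[:len(names)]))
    df = pd.DataFrame([f for _, f in rows], columns=names)
    for col in ("percent_identity", "evalue", "bitscore"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = rows[bad.index[0]][0]
            raise ValueError(
                f"{path}:{lineno}: non-numeric value {bad.iloc[0]!r} "
                f"in column {col}") from exc
    try:
        df["alignment_length"] = pd.to_numeric(
            df["alignment_length"]).astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer alignment_length") from exc
    validate_hit_table(df)
    return df


def validate_hit_table(df: pd.DataFrame) -> None:
    missing = [c for c in HIT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing required columns {missing}")
    req = df[["percent_identity", "alignment_length", "evalue", "bitscore"]]
    if req.isna().any().any():
        raise ValueError("NaN in required hit-table columns")
    if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
        raise ValueError("percent_identity outside [0, 100]")
    if (df["alignment_length"] < 1).any():
        raise ValueError("alignment_length < 1")
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-value")


def write_hit_table(df: pd.DataFrame, path) -> None:
    """Write the full 12-column BLAST tabular dialect (placeholder
    coordinates filled in when only the core columns are present)."""
    out = df.copy()
    length = out["alignment_length"]
    defaults = {"mismatches": 0, "gap_opens": 0, "q_start": 1,
                "q_end": length, "s_start": 1, "s_end": length}
    for col, val in defaults.items():
        if col not in out.columns:
            out[col] = val
    out[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GenePix GPR

def read_gpr(path, array_id: str | None = None,
             dye_orientation: str = "treatment_in_ch1") -> TwoColorArray:
    """Read a GenePix GPR result file.

    The optional ATF header block (lines before the column-header line) is
    skipped.  Any column superset is accepted; only the columns in
    :data:`GPR_REQUIRED` are required.  Channel mapping is 635 nm -> ch1,
    532 nm -> ch2, recorded in ``metadata``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        cells = [c.strip().strip('"') for c in line.split("\t")]
        if "Block" in cells and "ID" in cells:
            header_idx = i
            header = cells
            break
    if header_idx is None:
        raise ValueError(f"{path}: no GPR column-header line found")
    missing = [c for c in GPR_REQUIRED if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required GPR column(s) "
                         + ", ".join(repr(c) for c in missing))
    col = {name: header.index(name) for name in header}
    rows = []
    for line in lines[header_idx + 1:]:
        if not line.strip():
            continue
        cells = [c.strip().strip('"') for c in line.split("\t")]
        rows.append({
            "probe_id": cells[col["ID"]],
            "block": int(cells[col["Block"]]),
            "row": int(cells[col["Row"]]),
            "column": int(cells[col["Column"]]),
            "fg_ch1": float(cells[col["F635 Median"]]),
            "bg_ch1": float(cells[col["B635 Median"]]),
            "fg_ch2": float(cells[col["F532 Median"]]),
            "bg_ch2": float(cells[col["B532 Median"]]),
            "flag": int(float(cells[col["Flags"]])),
        })
    spots = pd.DataFrame(rows)
    if array_id is None:
        array_id = str(path)
    return TwoColorArray(
        spots=spots, array_id=array_id, dye_orientation=dye_orientation,
        metadata={"channel_map": {"ch1": "635", "ch2": "532"},
                  "source": str(path)})


def write_gpr(array: TwoColorArray, path) -> None:
    """Write a minimal GPR file (ATF-less, tab-separated, required cols)."""
    df = array.spots.rename(columns={
        "probe_id": "ID", "block": "Block", "row": "Row", "column": "Column",
        "fg_ch1": "F635 Median", "bg_ch1": "B635 Median",
        "fg_ch2": "F532 Median", "bg_ch2": "B532 Median", "flag": "Flags"})
    cols = ["Block", "Row", "Column", "ID", "F635 Median", "B635 Median",
            "F532 Median", "B532 Median", "Flags"]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OBO

PROPAGATING_RELATIONS = ("is_a", "part_of")


def read_obo(path) -> GoDag:
    """Read an OBO 1.2 ontology into a :class:`GoDag`.

    Obsolete terms are excluded; only ``is_a`` and ``part_of`` edges are
    retained as propagating relations.
    """
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    names, namespaces = {}, {}
    for node, data in multi.nodes(data=True):
        g.add_node(node)
        names[node] = data.get("name", node)
        namespaces[node] = data.get("namespace", "biological_process")
    for child, parent, key in multi.edges(keys=True):
        if key in PROPAGATING_RELATIONS:
            g.add_edge(child, parent, relation=key)
    return GoDag(g, names, namespaces)


def write_obo(dag: GoDag, path) -> None:
    """Write a GoDag back to a minimal OBO 1.2 file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            fh.write(f"namespace: {dag.namespaces.get(term, 'biological_process')}\n")
            for parent in sorted(dag.parents(term)):
                rel = dag.graph.edges[term, parent].get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Probe annotation tables

def write_probe_annotation(table: AnnotationTable, path,
                           separator: str = TERM_SEPARATOR) -> None:
    """Write a tab-delimited probe -> GO-terms table.

    One probe per line, ``probe<TAB>termA // termB``; probes with no terms
    are still listed with an empty second field so "unannotated" is
    explicit.
    """
    with open(path, "w") as fh:
        for entity in sorted(table.terms):
            terms = separator.join(sorted(table.terms[entity]))
            fh.write(f"{entity}\t{terms}\n")


def read_probe_annotation(path, separator: str = TERM_SEPARATOR) -> AnnotationTable:
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            entity, _, rest = line.partition("\t")
            if entity in terms:
                raise ValueError(f"duplicate entity id {entity!r}")
            terms[entity] = set(t for t in rest.split(separator) if t)
    return AnnotationTable(terms)


# ---------------------------------------------------------------------------
# Graph exports

def write_graph_xgmml(graph: nx.Graph, path, label: str = "hybridization") -> None:
    """Export a graph to XGMML with node ``type`` attributes preserved."""
    root = ET.Element("graph", {
        "label": label, "directed": "0",
        "xmlns": "http://www.cs.rpi.edu/XGMML"})
    for node, data in graph.nodes(data=True):
        el = ET.SubElement(root, "node", {"id": str(node), "label": str(node)})
        ntype = data.get("type", "")
        ET.SubElement(el, "att", {"name": "type", "type": "string",
                                  "value": str(ntype)})
    for u, v, data in graph.edges(data=True):
        el = ET.SubElement(root, "edge", {"source": str(u), "target": str(v)})
        for key, val in data.items():
            ET.SubElement(el, "att", {"name": str(key), "type": "real"
                                      if isinstance(val, (int, float))
                                      else "string", "value": str(val)})
    ET.ElementTree(root).write(str(path), xml_declaration=True,
                               encoding="UTF-8")


def read_graph_xgmml(path) -> nx.Graph:
    """Re-import an XGMML file written by :func:`write_graph_xgmml`."""
    tree = ET.parse(str(path))
    root = tree.getroot()
    ns = {"x": "http://www.cs.rpi.edu/XGMML"}
    g = nx.Graph()
    for el in root.findall("x:node", ns):
        attrs = {}
        for att in el.findall("x:att", ns):
            attrs[att.get("name")] = att.get("value")
        g.add_node(el.get("id"), **attrs)
    for el in root.findall("x:edge", ns):
        attrs = {}
        for att in el.findall("x:att", ns):
            val = att.get("value")
            if att.get("type") == "real":
                val = float(val)
            attrs[att.get("name")] = val
        g.add_edge(el.get("source"), el.get("target"), **attrs)
    return g


def write_graph_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))
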