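"""Readers and writers for every on-disk format the pipeline touches.

Dialects: tab-separated, UTF-8, ``#`` comment lines allowed, no quoting.
Parsers are strict — a malformed line raises :class:`FormatError` naming
the line number or record ID.  Writers emit canonical output (sorted where
an order is not semantically meaningful, ``\\n`` line endings, ``%.6g``
floats) so identical objects produce byte-identical files.

FASTA/FASTQ go through Biopython's low-level iterators; GraphML through
networkx with list-valued attributes flattened to semicolon-joined strings.
"""

from __future__ import annotations


import networkx as nx
import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import ExpressionMatrix, FormatError, GenomicInterval, ReadRecord

FLOAT_FMT = "%.6g"


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# -- tables ----------------------------------------------------------------

def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if required_columns:
        missing = [c for c in required_columns if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
    return frame


# -- expression matrices ---------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Header row = sample IDs; first column = analyte ID."""
    matrix.values.rename_axis("analyte").to_csv(
        path, sep="\t", float_format=FLOAT_FMT, lineterminator="\n"
    )


def read_expression_tsv(path, classes: pd.Series) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate analyte ID {dup!r}")
    try:
        values = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values, classes)


def write_design_tsv(design: pd.Series, path) -> None:
    design.rename_axis("sample").rename("group").to_csv(path, sep="\t", lineterminator="\n")


def read_design_tsv(path) -> pd.Series:
    frame = read_table(path, required_columns=["sample", "group"])
    if frame["sample"].duplicated().any():
        dup = frame["sample"][frame["sample"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    return pd.Series(frame["group"].to_numpy(), index=frame["sample"].to_numpy(), name="group")


def read_classes_tsv(path) -> pd.Series:
    frame = read_table(path, required_columns=["analyte", "analyte_class"])
    return pd.Series(
        frame["analyte_class"].to_numpy(),
        index=pd.Index(frame["analyte"].to_numpy(), name="analyte"),
        name="analyte_class",
    )


# -- FASTA / FASTQ ---------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if name in out:
                raise FormatError(f"{path}: duplicate sequence ID {name!r}")
            out[name] = seq.upper()
    return out


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")


def read_fastq(path) -> list[ReadRecord]:
    out: list[ReadRecord] = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rid = title.split()[0]
            if len(seq) != len(qual):
                raise FormatError(f"{path}: record {rid!r} quality length mismatch")
            out.append(
                ReadRecord(rid, seq.upper(), np.frombuffer(qual.encode(), dtype=np.uint8) - 33)
            )
    return out


# -- BED6 ------------------------------------------------------------------

def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_bed(path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if not (0 <= start_i < end_i):
            raise FormatError(
                f"{path}:{lineno}: invalid interval [{start_i}, {end_i}) "
                "(require 0 <= start < end)"
            )
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
        out.append(GenomicInterval(chrom, start_i, end_i, strand, name))
    return out


# -- annotation (GAF-like) -------------------------------------------------

def write_gaf(annotation, path) -> None:
    rows = []
    for gene in sorted(annotation.gene_to_terms):
        for term in sorted(annotation.gene_to_terms[gene]):
            rows.append((gene, term, annotation.term_names.get(term, term)))
    write_table(pd.DataFrame(rows, columns=["gene", "term", "term_name"]), path)


def read_gaf(path):
    from .enrich import GeneSetAnnotation

    frame = read_table(path, required_columns=["gene", "term", "term_name"])
    gene_to_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for gene, term, name in zip(frame["gene"], frame["term"], frame["term_name"]):
        gene_to_terms.setdefault(gene, set()).add(term)
        term_names[term] = name
    return GeneSetAnnotation(gene_to_terms, term_names)


def read_term_list(path) -> set[str]:
    return {line for _lineno, line in _data_lines(path)}


# -- networks --------------------------------------------------------------

def write_sif(network: nx.Graph, path) -> None:
    from .netbuild import _canonical_edges

    with open(path, "w") as fh:
        for a, b, data in _canonical_edges(network):
            fh.write(f"{a}\t{data.get('edge_type', 'edge')}\t{b}\n")


def read_sif(path) -> list[tuple[str, str, str]]:
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 SIF fields")
        source, edge_type, target = fields
        out.append((source, edge_type, target))
    return out


_LIST_ATTRS = ("shared_mirnas", "channels")


def write_graphml(network: nx.Graph, path) -> None:
    g = nx.Graph()
    for node in sorted(network.nodes):
        attrs = {
            k: (";".join(v) if k in _LIST_ATTRS else v)
            for k, v in sorted(network.nodes[node].items())
            if v is not None
        }
        g.add_node(node, **attrs)
    for u, v, data in sorted(
        ((min(u, v), max(u, v), d) for u, v, d in network.edges(data=True)),
        key=lambda e: (e[2].get("edge_type", ""), e[0], e[1]),
    ):
        attrs = {
            k: (";".join(val) if k in _LIST_ATTRS else val)
            for k, val in sorted(data.items())
            if val is not None
        }
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, path, infer_numeric_types=True)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        attrs = dict(data)
        for key in _LIST_ATTRS:
            if key in attrs:
                attrs[key] = tuple(attrs[key].split(";")) if attrs[key] else ()
        out.add_node(node, **attrs)
    for u, v, data in g.edges(data=True):
        attrs = dict(data)
        for key in _LIST_ATTRS:
            if key in attrs:
                attrs[key] = tuple(attrs[key].split(";")) if attrs[key] else ()
        out.add_edge(u, v, **attrs)
    return out
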