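"""Regulatory-network construction.

Builds the three pair classes (TF-miRNA from promoter-window binding-site
intersection, miRNA-mRNA and miRNA-lncRNA from target tables restricted to
differentially expressed endpoints), assembles them into typed networkx
graphs with degree and enrichment-score node attributes, infers
competing-endogenous-RNA (ceRNA) pairs as targets sharing a miRNA, overlays
protein-protein-interaction evidence, flags immune-response membership, and
extracts gene-set-gated subnetworks.  Exports are Cytoscape-ready (SIF,
attribute tables, GraphML) in a canonical sort order so identical inputs
produce byte-identical files.

Intervals are 0-based half-open; overlap means >= 1 shared base, so touching
intervals do not overlap.  Binding-site strand is ignored (ChIP signals are
unstranded); the promoter window is strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .containers import ConfigurationError, GenomicInterval

__all__ = [
    "promoter_window",
    "generate_tf_mirna_pairs",
    "generate_mirna_target_pairs",
    "assemble_network",
    "infer_cerna_pairs",
    "overlay_ppi",
    "flag_immune",
    "extract_subnetwork",
    "export_cytoscape",
    "CeRNAPair",
    "NODE_KINDS",
    "EDGE_TYPES",
    "ALLOWED_PPI_CHANNELS",
]

NODE_KINDS = ("TF", "miRNA", "mRNA", "lncRNA")
EDGE_TYPES = ("tf_mirna", "mirna_mrna", "mirna_lncrna", "cerna", "ppi")
ALLOWED_PPI_CHANNELS = frozenset({"experiments", "textmining", "coexpression", "database"})
KNOWN_PPI_CHANNELS = ALLOWED_PPI_CHANNELS | {"neighborhood", "fusion", "cooccurence"}

P_FLOOR = 1e-300


def promoter_window(
    tss: int,
    strand: str,
    chrom: str = ".",
    upstream: int = 1500,
    downstream: int = 500,
) -> GenomicInterval:
    """Promoter interval around a 0-based TSS: upstream 1500 bp, downstream
    500 bp including the TSS base itself, mirrored on the minus strand.

    '+' strand: [max(0, tss-upstream), tss+downstream);
    '-' strand: [max(0, tss-downstream+1), tss+upstream+1).
    """
    if tss < 0:
        raise ValueError("tss must be >= 0")
    if strand == "+":
        start, end = max(0, tss - upstream), tss + downstream
    elif strand == "-":
        start, end = max(0, tss - downstream + 1), tss + upstream + 1
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return GenomicInterval(chrom, start, end, strand)


def generate_tf_mirna_pairs(
    binding_sites: dict[str, list[GenomicInterval]],
    mirna_loci: dict[str, GenomicInterval],
    de_mirnas: set[str],
    upstream: int = 1500,
    downstream: int = 500,
) -> list[tuple[str, str]]:
    """Pair TFs with DE miRNAs whose promoter window a binding site overlaps.

    ``mirna_loci`` intervals mark the transcript; the TSS is the interval
    start on '+' and ``end - 1`` on '-'.  An edge (TF, miRNA) is emitted iff
    the miRNA is DE and at least one binding site of the TF overlaps the
    promoter window by >= 1 bp on the same chromosome (site strand ignored).
    DE miRNAs without a locus are skipped with a warning.  Output is
    deduplicated and sorted.
    """
    pairs: set[tuple[str, str]] = set()
    missing = sorted(m for m in de_mirnas if m not in mirna_loci)
    if missing:
        warnings.warn(
            f"no locus for {len(missing)} DE miRNA(s) (e.g. {missing[0]!r}); skipped",
            stacklevel=2,
        )
    for mirna in sorted(de_mirnas):
        locus = mirna_loci.get(mirna)
        if locus is None:
            continue
        tss = locus.start if locus.strand == "+" else locus.end - 1
        window = promoter_window(tss, locus.strand, locus.chrom, upstream, downstream)
        for tf, sites in binding_sites.items():
            for site in sites:
                if window.overlap_length(site) >= 1:
                    pairs.add((tf, mirna))
                    break
    return sorted(pairs)


def generate_mirna_target_pairs(
    target_table: pd.DataFrame,
    de_mirnas: set[str],
    de_targets: set[str],
    direction_constraint: bool = False,
    directions: dict[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Restrict a (miRNA, target) table to DE endpoints.

    Rows are kept iff both the miRNA and the target are DE.  With
    ``direction_constraint`` the miRNA and target must additionally be DE in
    opposite directions (``directions`` maps IDs to 'up'/'down'); the
    default imposes no direction constraint, as required for downstream
    ceRNA analysis.  Output is deduplicated and sorted.
    """
    if direction_constraint and directions is None:
        raise ConfigurationError("direction_constraint=True requires directions")
    pairs: set[tuple[str, str]] = set()
    for mirna, target in zip(target_table["mirna"], target_table["target"]):
        if mirna not in de_mirnas or target not in de_targets:
            continue
        if direction_constraint:
            dm, dt = directions.get(mirna), directions.get(target)
            if dm == dt or dm not in ("up", "down") or dt not in ("up", "down"):
                continue
        pairs.add((mirna, target))
    return sorted(pairs)


def assemble_network(
    edge_lists: dict[str, list[tuple[str, str]]],
    node_kinds: dict[str, str],
    de_annotations: pd.DataFrame | None = None,
) -> nx.Graph:
    """Assemble typed edge lists into an attributed undirected network.

    ``edge_lists`` maps edge type -> list of (source, target) pairs; node
    kinds come from ``node_kinds``; per-node DE statistics (``log2fc``,
    ``p``, ``fdr``) are pulled from ``de_annotations`` when present.  Nodes
    without an annotation are created with null statistics and flagged.
    Degrees are recomputed from the final edge set; the enrichment score is
    -log10(p) with p floored at 1e-300.
    """
    g = nx.Graph()
    for edge_type, edges in edge_lists.items():
        if edge_type not in EDGE_TYPES:
            raise ConfigurationError(
                f"unknown edge type {edge_type!r}; valid: {sorted(EDGE_TYPES)}"
            )
        for u, v in edges:
            g.add_edge(u, v, edge_type=edge_type)
    import math

    for node in g.nodes:
        kind = node_kinds.get(node)
        if kind is None:
            raise ConfigurationError(f"node {node!r} has no kind")
        attrs: dict = {"kind": kind, "annotated": False}
        if de_annotations is not None and node in de_annotations.index:
            row = de_annotations.loc[node]
            p = max(float(row["p"]), P_FLOOR)
            attrs.update(
                annotated=True,
                log2fc=float(row["log2fc"]),
                p=float(row["p"]),
                fdr=float(row["fdr"]),
                enrichment_score=-math.log10(p),
            )
        g.nodes[node].update(attrs)
    for node, deg in g.degree:
        g.nodes[node]["degree"] = deg
    return g


@dataclass
class CeRNAPair:
    """An unordered pair of transcripts competing for shared miRNAs."""

    gene_a: str
    gene_b: str
    shared_mirnas: tuple[str, ...]
    ppi_supported: bool = False
    immune_pair: bool = False

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
        self.shared_mirnas = tuple(sorted(set(self.shared_mirnas)))
        if not self.shared_mirnas:
            raise ValueError("shared_mirnas must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def infer_cerna_pairs(mirna_target_edges: list[tuple[str, str]]) -> list[CeRNAPair]:
    """Infer ceRNA pairs: transcripts regulated by the same miRNA.

    For each miRNA with target set S every unordered pair from S is a ceRNA
    pair; pairs produced by several miRNAs are merged with the union of
    their shared miRNAs.  Output is sorted by (gene_a, gene_b).
    """
    targets_by_mirna: dict[str, set[str]] = {}
    for mirna, target in mirna_target_edges:
        targets_by_mirna.setdefault(mirna, set()).add(target)
    shared: dict[tuple[str, str], set[str]] = {}
    for mirna, targets in targets_by_mirna.items():
        ts = sorted(targets)
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                shared.setdefault((ts[i], ts[j]), set()).add(mirna)
    return [
        CeRNAPair(a, b, tuple(mirnas)) for (a, b), mirnas in sorted(shared.items())
    ]


def overlay_ppi(
    pairs: list[CeRNAPair],
    ppi_table: pd.DataFrame,
    de_genes: set[str],
    allowed_channels: frozenset[str] = ALLOWED_PPI_CHANNELS,
    strict: bool = False,
) -> list[CeRNAPair]:
    """Annotate ceRNA pairs with protein-protein-interaction support.

    A pair is supported iff it appears in ``ppi_table`` (columns gene_a,
    gene_b, channel; undirected) through at least one allowed evidence
    channel and at least one endpoint is DE.  Unsupported pairs are kept
    (support is an attribute) unless ``strict`` drops them.
    """
    unknown = set(ppi_table["channel"]) - KNOWN_PPI_CHANNELS
    if unknown:
        raise ConfigurationError(
            f"unknown PPI channel(s) {sorted(unknown)}; valid: {sorted(KNOWN_PPI_CHANNELS)}"
        )
    bad = allowed_channels - KNOWN_PPI_CHANNELS
    if bad:
        raise ConfigurationError(
            f"unknown allowed channel(s) {sorted(bad)}; valid: {sorted(KNOWN_PPI_CHANNELS)}"
        )
    supported: set[tuple[str, str]] = set()
    for a, b, channel in zip(ppi_table["gene_a"], ppi_table["gene_b"], ppi_table["channel"]):
        if channel not in allowed_channels:
            continue
        if a not in de_genes and b not in de_genes:
            continue
        supported.add((min(a, b), max(a, b)))
    out = []
    for pair in pairs:
        ok = pair.key in supported
        if strict and not ok:
            continue
        out.append(
            CeRNAPair(pair.gene_a, pair.gene_b, pair.shared_mirnas, ppi_supported=ok,
                      immune_pair=pair.immune_pair)
        )
    return out


def flag_immune(
    network: nx.Graph | list[CeRNAPair],
    immune_terms: set[str],
    annotation: dict[str, set[str]],
):
    """Flag immune-response nodes and pairs.

    A node/gene is immune iff it is annotated to at least one term in
    ``immune_terms``; a ceRNA pair (or network edge) is an immune pair iff
    both endpoints are immune.  Graphs are modified in place and returned;
    pair lists are returned as new lists.
    """

    def is_immune(gene: str) -> bool:
        return bool(annotation.get(gene, set()) & immune_terms)

    if isinstance(network, nx.Graph):
        for node in network.nodes:
            network.nodes[node]["immune"] = is_immune(node)
        for u, v in network.edges:
            network.edges[u, v]["immune_pair"] = (
                network.nodes[u]["immune"] and network.nodes[v]["immune"]
            )
        return network
    return [
        CeRNAPair(
            p.gene_a,
            p.gene_b,
            p.shared_mirnas,
            ppi_supported=p.ppi_supported,
            immune_pair=is_immune(p.gene_a) and is_immune(p.gene_b),
        )
        for p in network
    ]


def extract_subnetwork(network: nx.Graph, gene_set: set[str]) -> nx.Graph:
    """Induce the subnetwork anchored on a set of mRNAs.

    Retains: mRNA nodes in ``gene_set``; miRNA nodes with at least one edge
    to a retained mRNA; TF and lncRNA nodes with at least one edge to a
    retained miRNA; and exactly the edges among retained nodes.  Degrees
    are recomputed.
    """
    retained_mrna = {
        n for n, d in network.nodes(data=True) if d.get("kind") == "mRNA" and n in gene_set
    }
    retained_mirna = {
        n
        for n, d in network.nodes(data=True)
        if d.get("kind") == "miRNA" and any(v in retained_mrna for v in network.neighbors(n))
    }
    retained_other = {
        n
        for n, d in network.nodes(data=True)
        if d.get("kind") in ("TF", "lncRNA")
        and any(v in retained_mirna for v in network.neighbors(n))
    }
    keep = retained_mrna | retained_mirna | retained_other
    sub = network.subgraph(keep).copy()
    for node, deg in sub.degree:
        sub.nodes[node]["degree"] = deg
    return sub


def _canonical_edges(network: nx.Graph) -> list[tuple[str, str, dict]]:
    edges = []
    for u, v, data in network.edges(data=True):
        a, b = (u, v) if u <= v else (v, u)
        edges.append((data.get("edge_type", "edge"), a, b, data))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    return [(a, b, d) for _, a, b, d in edges]


def export_cytoscape(network: nx.Graph, directory) -> dict[str, str]:
    """Export a network as SIF + node/edge attribute TSVs + GraphML.

    Files are written in canonical order (edge type, then lexicographic
    endpoints; nodes lexicographic) so identical networks yield
    byte-identical files.  Returns {format: path}.
    """
    from pathlib import Path

    from . import io as cio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    sif_path = directory / "network.sif"
    with open(sif_path, "w") as fh:
        for a, b, data in _canonical_edges(network):
            fh.write(f"{a}\t{data.get('edge_type', 'edge')}\t{b}\n")
    paths["sif"] = str(sif_path)

    node_rows = []
    for node in sorted(network.nodes):
        d = network.nodes[node]
        node_rows.append(
            {
                "id": node,
                "kind": d.get("kind", ""),
                "log2fc": d.get("log2fc", ""),
                "p": d.get("p", ""),
                "fdr": d.get("fdr", ""),
                "degree": d.get("degree", 0),
                "enrichment_score": d.get("enrichment_score", ""),
                "immune": d.get("immune", ""),
            }
        )
    node_path = directory / "node_attributes.tsv"
    cio.write_table(pd.DataFrame(node_rows, columns=[
        "id", "kind", "log2fc", "p", "fdr", "degree", "enrichment_score", "immune",
    ]), node_path)
    paths["nodes"] = str(node_path)

    edge_rows = []
    for a, b, data in _canonical_edges(network):
        edge_rows.append(
            {
                "source": a,
                "target": b,
                "edge_type": data.get("edge_type", ""),
                "shared_mirnas": ";".join(data.get("shared_mirnas", ())),
                "channels": ";".join(sorted(data.get("channels", ()))),
                "immune_pair": data.get("immune_pair", ""),
            }
        )
    edge_path = directory / "edge_attributes.tsv"
    cio.write_table(pd.DataFrame(edge_rows, columns=[
        "source", "target", "edge_type", "shared_mirnas", "channels", "immune_pair",
    ]), edge_path)
    paths["edges"] = str(edge_path)

    graphml_path = directory / "network.graphml"
    cio.write_graphml(network, graphml_path)
    paths["graphml"] = str(graphml_path)
    return paths
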