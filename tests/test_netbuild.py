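"""Network construction: windows, pairs, assembly, ceRNA, PPI, subnetworks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cirrnet.containers import ConfigurationError, GenomicInterval
from cirrnet.netbuild import (
    assemble_network,
    export_cytoscape,
    extract_subnetwork,
    flag_immune,
    generate_mirna_target_pairs,
    generate_tf_mirna_pairs,
    infer_cerna_pairs,
    overlay_ppi,
    promoter_window,
)
from cirrnet import io as cio


class TestPromoterWindow:
    def test_plus_strand(self):
        w = promoter_window(10_000, "+")
        assert (w.start, w.end) == (8_500, 10_500)

    def test_minus_strand_mirror(self):
        w = promoter_window(10_000, "-")
        assert (w.start, w.end) == (9_501, 11_501)

    def test_clamped_at_chromosome_start(self):
        w = promoter_window(100, "+")
        assert (w.start, w.end) == (0, 600)

    def test_minus_strand_covers_mirrored_offsets(self):
        # per-base check: position tss+d for d in [-500+1? ...]; on '-' the
        # transcribed direction is decreasing coordinates, so "upstream
        # 1500" spans tss+1..tss+1500 and "downstream 500" spans
        # tss-499..tss (tss base included)
        tss = 5000
        w = promoter_window(tss, "-")
        bases = set(range(w.start, w.end))
        expected = set(range(tss - 499, tss + 1500 + 1))
        assert bases == expected


def brute_force_tf_pairs(sites, loci, de_mirnas):
    pairs = set()
    for mirna in de_mirnas:
        locus = loci.get(mirna)
        if locus is None:
            continue
        tss = locus.start if locus.strand == "+" else locus.end - 1
        w = promoter_window(tss, locus.strand, locus.chrom)
        window_bases = set(range(w.start, w.end))
        for tf, tf_sites in sites.items():
            for s in tf_sites:
                if s.chrom == w.chrom and window_bases & set(range(s.start, s.end)):
                    pairs.add((tf, mirna))
    return sorted(pairs)


class TestTFPairs:
    def locus(self, start=10_000, strand="+"):
        return {"m1": GenomicInterval("c", start, start + 80, strand, "m1")}

    def test_one_bp_overlap_emits_pair(self):
        sites = {"T": [GenomicInterval("c", 8_499, 8_501, "+", "T")]}
        assert generate_tf_mirna_pairs(sites, self.locus(), {"m1"}) == [("T", "m1")]

    def test_touching_half_open_intervals_do_not_overlap(self):
        sites = {"T": [GenomicInterval("c", 8_498, 8_500, "+", "T")]}
        assert generate_tf_mirna_pairs(sites, self.locus(), {"m1"}) == []

    def test_site_strand_ignored(self):
        sites = {"T": [GenomicInterval("c", 9_000, 9_020, "-", "T")]}
        assert generate_tf_mirna_pairs(sites, self.locus(), {"m1"}) == [("T", "m1")]

    def test_non_de_mirna_excluded(self):
        sites = {"T": [GenomicInterval("c", 9_000, 9_020, "+", "T")]}
        assert generate_tf_mirna_pairs(sites, self.locus(), set()) == []

    def test_missing_locus_warns_and_skips(self):
        sites = {"T": [GenomicInterval("c", 9_000, 9_020, "+", "T")]}
        with pytest.warns(UserWarning, match="no locus"):
            pairs = generate_tf_mirna_pairs(sites, self.locus(), {"m1", "ghost"})
        assert pairs == [("T", "m1")]

    def test_agrees_with_per_base_brute_force(self):
        rng = np.random.default_rng(17)
        genome = 10_000
        loci = {}
        for i in range(12):
            start = int(rng.integers(0, genome - 100))
            strand = "+" if rng.random() < 0.5 else "-"
            loci[f"m{i}"] = GenomicInterval("c", start, start + 80, strand, f"m{i}")
        sites = {}
        for t in range(6):
            sites[f"T{t}"] = [
                GenomicInterval(
                    "c",
                    int(s := rng.integers(0, genome - 30)),
                    int(s + rng.integers(5, 30)),
                    "+",
                    f"T{t}",
                )
                for _ in range(8)
            ]
        de = {f"m{i}" for i in range(12) if rng.random() < 0.7}
        assert generate_tf_mirna_pairs(sites, loci, de) == brute_force_tf_pairs(
            sites, loci, de
        )


class TestTargetPairs:
    table = pd.DataFrame(
        {"mirna": ["miR-1", "miR-1", "miR-2"], "target": ["G1", "G2", "G1"]}
    )

    def test_kept_without_direction_constraint(self):
        pairs = generate_mirna_target_pairs(self.table, {"miR-1"}, {"G1"})
        assert pairs == [("miR-1", "G1")]

    def test_same_direction_dropped_with_constraint(self):
        pairs = generate_mirna_target_pairs(
            self.table,
            {"miR-1"},
            {"G1"},
            direction_constraint=True,
            directions={"miR-1": "up", "G1": "up"},
        )
        assert pairs == []

    def test_opposite_direction_kept_with_constraint(self):
        pairs = generate_mirna_target_pairs(
            self.table,
            {"miR-1"},
            {"G1"},
            direction_constraint=True,
            directions={"miR-1": "up", "G1": "down"},
        )
        assert pairs == [("miR-1", "G1")]

    def test_non_de_endpoint_dropped(self):
        assert generate_mirna_target_pairs(self.table, {"miR-2"}, {"G2"}) == []


class TestAssemble:
    kinds = {"T": "TF", "m1": "miRNA", "G1": "mRNA", "G2": "mRNA"}

    def test_degrees_counted_from_final_edge_set(self):
        net = assemble_network(
            {"tf_mirna": [("T", "m1")], "mirna_mrna": [("m1", "G1"), ("m1", "G2")]},
            self.kinds,
        )
        assert net.nodes["m1"]["degree"] == 3
        assert net.nodes["T"]["degree"] == 1

    def test_empty_network(self):
        net = assemble_network({"tf_mirna": []}, {})
        assert net.number_of_nodes() == 0

    def test_enrichment_score_is_minus_log10_p(self):
        ann = pd.DataFrame(
            {"log2fc": [2.0], "p": [1e-4], "fdr": [1e-3]}, index=["G1"]
        )
        net = assemble_network({"mirna_mrna": [("m1", "G1")]}, self.kinds, ann)
        assert net.nodes["G1"]["enrichment_score"] == pytest.approx(4.0)
        assert not net.nodes["m1"]["annotated"]

    def test_degree_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 20))
            nodes = [f"n{i}" for i in range(n)]
            kinds = {v: "mRNA" for v in nodes}
            edges = set()
            for _ in range(int(rng.integers(0, 30))):
                a, b = rng.choice(n, size=2, replace=False)
                edges.add((nodes[min(a, b)], nodes[max(a, b)]))
            net = assemble_network({"cerna": sorted(edges)}, kinds)
            incident = {v: 0 for v in net.nodes}
            for a, b in edges:
                incident[a] += 1
                incident[b] += 1
            for v in net.nodes:
                assert net.nodes[v]["degree"] == incident[v]


def brute_force_cerna(edges):
    """Quadratic oracle: all mRNA pairs sharing >= 1 miRNA neighbour."""
    mirnas_by_target = {}
    for mirna, target in edges:
        mirnas_by_target.setdefault(target, set()).add(mirna)
    targets = sorted(mirnas_by_target)
    out = {}
    for a, b in itertools.combinations(targets, 2):
        shared = mirnas_by_target[a] & mirnas_by_target[b]
        if shared:
            out[(a, b)] = tuple(sorted(shared))
    return out


class TestCeRNA:
    def test_three_targets_give_three_pairs(self):
        pairs = infer_cerna_pairs([("miR-x", "A"), ("miR-x", "B"), ("miR-x", "C")])
        assert {(p.gene_a, p.gene_b) for p in pairs} == {("A", "B"), ("A", "C"), ("B", "C")}
        assert all(p.shared_mirnas == ("miR-x",) for p in pairs)

    def test_pairs_from_multiple_mirnas_are_merged(self):
        pairs = infer_cerna_pairs(
            [("miR-x", "A"), ("miR-x", "B"), ("miR-y", "A"), ("miR-y", "B")]
        )
        assert len(pairs) == 1
        assert pairs[0].shared_mirnas == ("miR-x", "miR-y")

    def test_matches_quadratic_brute_force_on_random_bipartite_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            n_mirna = int(rng.integers(1, 20))
            n_mrna = int(rng.integers(2, 60))
            edges = set()
            for _ in range(int(rng.integers(0, 150))):
                edges.add((f"miR{rng.integers(n_mirna)}", f"G{rng.integers(n_mrna)}"))
            pairs = infer_cerna_pairs(sorted(edges))
            got = {p.key: p.shared_mirnas for p in pairs}
            assert got == brute_force_cerna(sorted(edges))


class TestPPIOverlay:
    pairs = infer_cerna_pairs([("m", "A"), ("m", "B"), ("m", "C")])

    def ppi(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "channel"])

    def test_allowed_channel_with_de_endpoint_supported(self):
        out = overlay_ppi(self.pairs, self.ppi([("A", "B", "experiments")]), {"A"})
        by_key = {p.key: p for p in out}
        assert by_key[("A", "B")].ppi_supported
        assert not by_key[("A", "C")].ppi_supported

    def test_disallowed_channel_not_supported(self):
        out = overlay_ppi(self.pairs, self.ppi([("A", "B", "neighborhood")]), {"A", "B"})
        assert not any(p.ppi_supported for p in out)

    def test_no_de_endpoint_not_supported(self):
        out = overlay_ppi(self.pairs, self.ppi([("A", "B", "experiments")]), {"C"})
        assert not any(p.ppi_supported for p in out)

    def test_unknown_channel_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="valid"):
            overlay_ppi(self.pairs, self.ppi([("A", "B", "astrology")]), {"A"})

    def test_strict_mode_drops_unsupported(self):
        out = overlay_ppi(
            self.pairs, self.ppi([("A", "B", "database")]), {"A"}, strict=True
        )
        assert [p.key for p in out] == [("A", "B")]


class TestImmuneFlag:
    annotation = {"A": {"GO:1"}, "B": {"GO:1", "GO:2"}, "C": {"GO:2"}}

    def test_pair_immune_only_when_both_endpoints_immune(self):
        pairs = infer_cerna_pairs([("m", "A"), ("m", "B"), ("m", "C")])
        flagged = flag_immune(pairs, {"GO:1"}, self.annotation)
        by_key = {p.key: p.immune_pair for p in flagged}
        assert by_key == {("A", "B"): True, ("A", "C"): False, ("B", "C"): False}

    def test_empty_immune_terms_flags_nothing(self):
        pairs = infer_cerna_pairs([("m", "A"), ("m", "B")])
        flagged = flag_immune(pairs, set(), self.annotation)
        assert not any(p.immune_pair for p in flagged)

    def test_graph_nodes_and_edges_flagged(self):
        net = assemble_network(
            {"cerna": [("A", "B"), ("A", "C")]},
            {"A": "mRNA", "B": "mRNA", "C": "mRNA"},
        )
        flag_immune(net, {"GO:1"}, self.annotation)
        assert net.nodes["A"]["immune"] and net.nodes["B"]["immune"]
        assert not net.nodes["C"]["immune"]
        assert net.edges["A", "B"]["immune_pair"]
        assert not net.edges["A", "C"]["immune_pair"]


class TestSubnetwork:
    def net(self):
        kinds = {
            "T": "TF", "L": "lncRNA", "m1": "miRNA", "m2": "miRNA",
            "G1": "mRNA", "G2": "mRNA",
        }
        return assemble_network(
            {
                "tf_mirna": [("T", "m1"), ("T", "m2")],
                "mirna_mrna": [("m1", "G1"), ("m2", "G2")],
                "mirna_lncrna": [("m1", "L")],
            },
            kinds,
        )

    def test_chain_retained_through_gene_set(self):
        sub = extract_subnetwork(self.net(), {"G1"})
        assert set(sub.nodes) == {"T", "m1", "G1", "L"}

    def test_mirna_without_retained_mrna_dropped(self):
        net = assemble_network(
            {"tf_mirna": [("T", "m2")], "mirna_mrna": [("m2", "G2")]},
            {"T": "TF", "m2": "miRNA", "G2": "mRNA"},
        )
        sub = extract_subnetwork(net, set())
        assert sub.number_of_nodes() == 0

    def test_full_gene_set_is_identity(self):
        net = self.net()
        sub = extract_subnetwork(net, {"G1", "G2"})
        assert set(sub.nodes) == set(net.nodes)
        assert set(sub.edges) == set(net.edges)

    def test_degrees_recomputed(self):
        sub = extract_subnetwork(self.net(), {"G1"})
        assert sub.nodes["m1"]["degree"] == 3  # T, G1, L
        assert sub.nodes["T"]["degree"] == 1  # m2 edge gone

    def test_matches_brute_force_rule_on_random_networks(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            mrnas = [f"G{i}" for i in range(int(rng.integers(1, 8)))]
            mirnas = [f"m{i}" for i in range(int(rng.integers(1, 5)))]
            tfs = [f"T{i}" for i in range(int(rng.integers(1, 4)))]
            kinds = {**{g: "mRNA" for g in mrnas}, **{m: "miRNA" for m in mirnas},
                     **{t: "TF" for t in tfs}}
            edges_mm = sorted(
                {(m, g) for m in mirnas for g in mrnas if rng.random() < 0.3}
            )
            edges_tm = sorted(
                {(t, m) for t in tfs for m in mirnas if rng.random() < 0.3}
            )
            net = assemble_network({"mirna_mrna": edges_mm, "tf_mirna": edges_tm}, kinds)
            gene_set = {g for g in mrnas if rng.random() < 0.5}
            sub = extract_subnetwork(net, gene_set)
            keep_mrna = {g for g in mrnas if g in gene_set and g in net}
            keep_mirna = {m for (m, g) in edges_mm if g in keep_mrna}
            keep_tf = {t for (t, m) in edges_tm if m in keep_mirna}
            assert set(sub.nodes) == keep_mrna | keep_mirna | keep_tf


class TestExport:
    def test_graphml_round_trip_and_sif_line_count(self, tmp_path):
        ann = pd.DataFrame(
            {"log2fc": [1.0, -2.0], "p": [0.01, 0.001], "fdr": [0.02, 0.005]},
            index=["G1", "G2"],
        )
        net = assemble_network(
            {"mirna_mrna": [("m1", "G1"), ("m1", "G2")], "cerna": [("G1", "G2")]},
            {"m1": "miRNA", "G1": "mRNA", "G2": "mRNA"},
            ann,
        )
        net.edges["G1", "G2"].update(shared_mirnas=("m1",), ppi_supported=True)
        paths = export_cytoscape(net, tmp_path)
        back = cio.read_graphml(paths["graphml"])
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.edges))
        for v in net.nodes:
            for key, val in net.nodes[v].items():
                assert back.nodes[v][key] == pytest.approx(val) if isinstance(
                    val, float
                ) else back.nodes[v][key] == val
        assert back.edges["G1", "G2"]["shared_mirnas"] == ("m1",)
        sif_lines = open(paths["sif"]).read().splitlines()
        assert len(sif_lines) == net.number_of_edges()

    def test_empty_network_exports_valid_files(self, tmp_path):
        paths = export_cytoscape(nx.Graph(), tmp_path)
        assert open(paths["sif"]).read() == ""
        assert cio.read_graphml(paths["graphml"]).number_of_nodes() == 0

    def test_identical_networks_yield_byte_identical_exports(self, tmp_path):
        kinds = {"m1": "miRNA", "G1": "mRNA", "G2": "mRNA"}
        for d in ("a", "b"):
            net = assemble_network(
                {"mirna_mrna": [("m1", "G2"), ("m1", "G1")]}, kinds
            )
            export_cytoscape(net, tmp_path / d)
        for name in ("network.sif", "node_attributes.tsv", "edge_attributes.tsv",
                     "network.graphml"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
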