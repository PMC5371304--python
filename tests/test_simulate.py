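"""Synthetic-data generator: determinism, planted structure, noise model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cirrnet.containers import ConfigurationError
from cirrnet.netbuild import promoter_window
from cirrnet.preprocess import (
    count_mirna,
    filter_reads_qc,
    remove_contaminants,
    trim_adapter,
)
from cirrnet.simulate import (
    SimulationConfig,
    config_hash,
    simulate_annotations,
    simulate_expression,
    simulate_small_rna,
    simulate_truth,
)

TINY = dict(
    n_mrna=200, n_lncrna=30, n_mirna=20, reads_per_sample=2000,
    genome_length=1_000_000, n_tf=8, n_planted_tf_mirna=6,
    n_negative_tf_mirna=4, n_planted_mirna_mrna=20, n_decoy_mirna_mrna=10,
    n_planted_mirna_lncrna=6, n_decoy_mirna_lncrna=4, n_ppi=15, n_go_terms=10,
)


class TestConfig:
    def test_rejects_non_positive_prior(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(d0=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(s0_sq=-1)

    def test_rejects_bad_counts_and_fractions(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_mrna=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(de_fraction=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(adapter="ACGU")

    def test_hash_changes_iff_any_field_changes(self):
        base = SimulationConfig(**TINY)
        assert config_hash(base) == config_hash(SimulationConfig(**TINY))
        for name, bumped in (
            ("seed", 1), ("n_mrna", 201), ("de_fraction", 0.2), ("s0_sq", 0.06),
        ):
            other = SimulationConfig(**{**TINY, name: bumped})
            assert config_hash(other) != config_hash(base)


class TestExpression:
    def test_zero_de_fraction_plants_no_effects(self):
        cfg = SimulationConfig(**{**TINY, "de_fraction": 0.0, "de_fraction_hcc": 0.0})
        _, truth = simulate_expression(cfg)
        assert all(v == "null" for v in truth.de_labels.values())
        assert all(v == 0.0 for v in truth.true_log2fc.values())

    def test_identical_seed_gives_identical_matrices(self):
        cfg = SimulationConfig(**{**TINY, "seed": 1})
        m1, t1 = simulate_expression(cfg)
        m2, t2 = simulate_expression(SimulationConfig(**{**TINY, "seed": 1}))
        assert m1.values.equals(m2.values)
        assert t1.de_labels == t2.de_labels

    def test_labels_match_effect_signs_and_floor(self):
        cfg = SimulationConfig(**TINY)
        _, truth = simulate_expression(cfg)
        for analyte, label in truth.de_labels.items():
            lfc = truth.true_log2fc[analyte]
            if label == "null":
                assert lfc == 0.0
            else:
                assert abs(lfc) >= cfg.min_abs_log2fc
                assert (lfc > 0) == (label == "up")

    def test_de_fraction_yields_at_least_one_per_class(self):
        cfg = SimulationConfig(**{**TINY, "de_fraction": 0.001})
        _, truth = simulate_expression(cfg)
        for prefix in ("GENE", "LNC", "MIR"):
            assert len(truth.de_ids(prefix)) >= 1

    def test_sample_mean_difference_tracks_planted_effect(self):
        """Monte-Carlo check: with n=50+50 and tight noise, the observed
        group mean difference lies within +/-0.5 of the planted log2FC for
        at least 95% of DE analytes (normal-theory CI is far narrower)."""
        cfg = SimulationConfig(
            n_mrna=2000, n_lncrna=50, n_mirna=20, n_control=50, n_case=50,
            n_hcc=0, min_abs_log2fc=2.0, d0=4.0, s0_sq=0.05, seed=3,
            genome_length=1_000_000,
        )
        matrix, truth = simulate_expression(cfg)
        design = matrix.values.attrs["design"]
        case = design.index[design == "cirrhosis"]
        ctrl = design.index[design == "normal"]
        diff = matrix.values[case].mean(axis=1) - matrix.values[ctrl].mean(axis=1)
        de = [a for a in matrix.analyte_ids if truth.de_labels[a] != "null"]
        errors = np.array([abs(diff[a] - truth.true_log2fc[a]) for a in de])
        assert (errors <= 0.5).mean() >= 0.95

    def test_null_variances_follow_scaled_inverse_chi_squared_prior(self):
        """Pooled variances of null analytes are marginally s0^2 * F(d, d0);
        a KS test against that distribution should not reject."""
        cfg = SimulationConfig(
            n_mrna=2000, n_lncrna=50, n_mirna=20, de_fraction=0.0,
            de_fraction_hcc=0.0, n_hcc=0, seed=5, genome_length=1_000_000,
        )
        matrix, _ = simulate_expression(cfg)
        x = matrix.values.to_numpy()
        x1, x2 = x[:, : cfg.n_control], x[:, cfg.n_control :]
        dg = cfg.n_control + cfg.n_case - 2
        ss = ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1) + (
            (x2 - x2.mean(1, keepdims=True)) ** 2
        ).sum(1)
        s2 = ss / dg
        ks = stats.kstest(s2 / cfg.s0_sq, stats.f(dg, cfg.d0).cdf)
        assert ks.pvalue > 0.01


class TestSmallRNA:
    def test_lossless_round_trip_without_contamination_or_failures(self):
        cfg = SimulationConfig(
            **{**TINY, "contaminant_fraction": 0.0, "qc_fail_fraction": 0.0}
        )
        reads, mature, contaminants, truth = simulate_small_rna(cfg)
        trimmed = {
            s: list(trim_adapter(rs, cfg.adapter)) for s, rs in reads.items()
        }
        table = count_mirna(trimmed, mature)
        pd.testing.assert_frame_equal(
            table.counts, truth.mirna_true_counts, check_dtype=False
        )

    def test_zero_reads_gives_empty_fastq_and_zero_counts(self):
        cfg = SimulationConfig(**{**TINY, "reads_per_sample": 0})
        reads, _, _, truth = simulate_small_rna(cfg)
        assert all(len(rs) == 0 for rs in reads.values())
        assert (truth.mirna_true_counts.to_numpy() == 0).all()

    def test_constructed_failures_are_exact_and_recounted_independently(self):
        cfg = SimulationConfig(
            **{**TINY, "reads_per_sample": 1000, "qc_fail_fraction": 0.2,
               "contaminant_fraction": 0.0}
        )
        reads, mature, contaminants, truth = simulate_small_rna(cfg)
        for sample, rs in reads.items():
            expected = truth.qc_expected[sample]
            assert (
                expected["fail_length"]
                + expected["fail_quality"]
                + expected["fail_uncertainty"]
                == 200
            )
            trimmed = trim_adapter(rs, cfg.adapter)
            _, report = filter_reads_qc(trimmed)
            assert report.n_pass == expected["pass"]
            assert report.n_fail_length == expected["fail_length"]
            assert report.n_fail_quality == expected["fail_quality"]
            assert report.n_fail_uncertainty == expected["fail_uncertainty"]

    def test_contaminant_reads_are_removed_by_reference_filter(self):
        cfg = SimulationConfig(
            **{**TINY, "contaminant_fraction": 0.1, "qc_fail_fraction": 0.0}
        )
        reads, mature, contaminants, truth = simulate_small_rna(cfg)
        sample = next(iter(reads))
        trimmed = list(trim_adapter(reads[sample], cfg.adapter))
        passing, _ = filter_reads_qc(trimmed)
        clean = remove_contaminants(passing, contaminants)
        n_contam = truth.qc_expected[sample]["contaminant"]
        assert len(passing) - len(clean) == n_contam
        table = count_mirna({sample: clean}, mature)
        pd.testing.assert_series_equal(
            table.counts[sample],
            truth.mirna_true_counts[sample],
            check_dtype=False,
        )

    def test_mature_sequences_unique_and_adapter_clean(self):
        cfg = SimulationConfig(**TINY)
        _, mature, _, _ = simulate_small_rna(cfg)
        seqs = list(mature.values())
        assert len(set(seqs)) == len(seqs)
        key = cfg.adapter[:8]
        for seq in seqs:
            assert 18 <= len(seq) <= 24
            assert (seq + cfg.adapter).find(key) == len(seq)


@pytest.fixture(scope="module")
def ann():
    cfg = SimulationConfig(**TINY)
    truth = simulate_truth(cfg)
    return cfg, truth, simulate_annotations(cfg, truth)


class TestAnnotations:

    def test_planted_edges_have_overlapping_binding_sites(self, ann):
        cfg, truth, bundle = ann
        for tf, mirna in truth.planted_tf_mirna:
            locus = bundle.mirna_loci[mirna]
            tss = locus.start if locus.strand == "+" else locus.end - 1
            w = promoter_window(tss, locus.strand, locus.chrom)
            assert any(w.overlap_length(s) >= 1 for s in bundle.binding_sites[tf])

    def test_planted_negatives_have_no_overlap_anywhere(self, ann):
        cfg, truth, bundle = ann
        windows = []
        for locus in bundle.mirna_loci.values():
            tss = locus.start if locus.strand == "+" else locus.end - 1
            windows.append(promoter_window(tss, locus.strand, locus.chrom))
        negative_tfs = {tf for tf, _ in truth.planted_negative_tf_mirna}
        planted_by_tf = {}
        for tf, mirna in truth.planted_tf_mirna:
            planted_by_tf.setdefault(tf, set()).add(mirna)
        for tf, mirna in truth.planted_negative_tf_mirna:
            locus = bundle.mirna_loci[mirna]
            tss = locus.start if locus.strand == "+" else locus.end - 1
            w = promoter_window(tss, locus.strand, locus.chrom)
            for site in bundle.binding_sites[tf]:
                assert w.overlap_length(site) == 0

    def test_edge_endpoints_exist_in_universe(self, ann):
        cfg, truth, bundle = ann
        mirnas = set(bundle.mirna_loci)
        for tf, mirna in truth.planted_tf_mirna + truth.planted_negative_tf_mirna:
            assert tf in bundle.binding_sites and mirna in mirnas
        table_pairs = set(
            zip(bundle.mirna_mrna_table["mirna"], bundle.mirna_mrna_table["target"])
        )
        assert set(truth.planted_mirna_mrna) <= table_pairs
        decoys = table_pairs - set(truth.planted_mirna_mrna)
        de = truth.de_ids()
        for mirna, target in decoys:
            assert mirna not in de and target not in de

    def test_genome_too_short_is_configuration_error(self):
        cfg = SimulationConfig(**{**TINY, "genome_length": 100_000})
        truth = simulate_truth(cfg)
        with pytest.raises(ConfigurationError, match="too short"):
            simulate_annotations(cfg, truth)

    def test_planted_term_enriched_among_up_de_genes(self):
        """Simulation oracle: with odds ratio 10 the planted term's
        hypergeometric p (computed on the true up-DE set) is below 0.05 in
        at least 90% of seeds."""
        from cirrnet.enrich import enrich

        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                **{**TINY, "seed": 1000 + seed, "n_mrna": 400, "n_go_terms": 15}
            )
            truth = simulate_truth(cfg)
            bundle = simulate_annotations(cfg, truth)
            up = truth.de_ids("GENE", "up") & bundle.annotation.universe
            res = enrich(up, bundle.annotation).set_index("term")
            planted_p = min(
                res.loc[t, "p"]
                for t in truth.planted_enriched_terms
                if t in res.index
            )
            hits += planted_p < 0.05
        assert hits / n_seeds >= 0.90
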