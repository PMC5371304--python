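"""End-to-end workflow: from an input bundle directory to result tables.

Stages (each reads its declared inputs and writes its outputs under the
run's output directory; ``run_all`` chains them and records a manifest):

1. preprocess  — quantile normalization, lncRNA ID harmonization with probe
   summarization; small-RNA adapter trimming, QC filtering, contaminant
   removal, exact-match miRNA counting, TPM with zero handling.
2. de          — moderated-t contrasts: cirrhosis vs normal (mRNA + lncRNA,
   FDR policy), cirrhosis vs normal miRNA on log2 TPM (raw-p policy), and
   HCC vs cirrhosis (mRNA).
3. network     — TF-miRNA pairs (binding sites vs promoter windows),
   miRNA-mRNA and miRNA-lncRNA pairs (target tables, DE endpoints); the two
   tripartite networks, exported for Cytoscape.
4. cerna       — ceRNA pairs (shared miRNAs) with PPI evidence overlay and
   immune flags; the ceRNA network export.
5. enrich      — hypergeometric GO enrichment of both contrasts with term
   directions; immune-response subnetwork extraction.
6. compare     — DE-gene overlap (Venn) and GO-term comparison across the
   two contrasts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import netbuild, preprocess
from .containers import ConfigurationError, ExpressionMatrix, ThresholdPolicy
from .diffexpr import ModeratedTTest, overlap_de_sets
from .enrich import assign_direction, compare_term_sets, enrich

__all__ = ["PipelineConfig", "run_all", "load_config"]

_STAGES = ("preprocess", "de", "network", "cerna", "enrich", "compare")


@dataclass
class PipelineConfig:
    """Every tunable of the workflow, shipped with the study's thresholds."""

    input_dir: str = "."
    output_dir: str = "results"
    seed: int = 0
    # significance policies
    array_alpha: float = 0.05
    array_stat: str = "fdr"
    mirna_alpha: float = 0.05
    mirna_stat: str = "p"
    fc_up: float = 2.0
    # promoter window (bp around the TSS)
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    # lncRNA ID harmonization
    overlap_fraction: float = 0.90
    # small-RNA QC
    qc_min_len: int = 16
    qc_phred_floor: int = 20
    qc_hq_fraction: float = 0.90
    qc_max_uncertain: float = 0.05
    pseudo_tpm: float = 0.0001
    # enrichment
    enrich_alpha: float = 0.05
    enrich_stat: str = "fdr"
    min_term_size: int = 2
    # networks
    allowed_ppi_channels: list[str] = field(
        default_factory=lambda: ["experiments", "textmining", "coexpression", "database"]
    )
    strict_ppi: bool = False
    restrict_de_tfs: bool = False

    def __post_init__(self) -> None:
        if self.array_stat not in ("fdr", "p") or self.mirna_stat not in ("fdr", "p"):
            raise ConfigurationError("stat fields must be 'fdr' or 'p'")
        if self.enrich_stat not in ("fdr", "p"):
            raise ConfigurationError("enrich_stat must be 'fdr' or 'p'")
        for name in ("array_alpha", "mirna_alpha", "enrich_alpha"):
            if not (0 < getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if not (0 <= self.overlap_fraction < 1):
            raise ConfigurationError("overlap_fraction must be in [0, 1)")
        if self.fc_up <= 1:
            raise ConfigurationError("fc_up must be > 1")
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ConfigurationError("promoter window sizes must be >= 0")

    @property
    def array_policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(self.array_stat, self.array_alpha, self.fc_up, 1 / self.fc_up)

    @property
    def mirna_policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(self.mirna_stat, self.mirna_alpha, self.fc_up, 1 / self.fc_up)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {sorted(unknown)}; valid: {sorted(known)}"
        )
    return PipelineConfig(**data)


def _in(cfg: PipelineConfig, name: str) -> Path:
    path = Path(cfg.input_dir) / name
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def _out(cfg: PipelineConfig, name: str) -> Path:
    path = Path(cfg.output_dir) / name
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def _read_de(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame["significant"] = frame["significant"].astype(bool)
    return frame


def _write_de(frame: pd.DataFrame, path) -> None:
    frame.rename_axis("analyte").to_csv(
        path, sep="\t", float_format=cio.FLOAT_FMT, lineterminator="\n"
    )


def stage_preprocess(cfg: PipelineConfig) -> dict[str, int]:
    counts: dict[str, int] = {}
    classes = cio.read_classes_tsv(_in(cfg, "analyte_classes.tsv"))
    matrix = cio.read_expression_tsv(_in(cfg, "expression.tsv"), classes)
    matrix = preprocess.quantile_normalize(matrix)

    array_iv = cio.read_bed(_in(cfg, "array_lncrna.bed"))
    official_iv = cio.read_bed(_in(cfg, "official_lncrna.bed"))
    lnc_map = preprocess.match_lncrna_ids(array_iv, official_iv, cfg.overlap_fraction)
    mapping = {a: a for a in matrix.analyte_ids if matrix.classes[a] == "mRNA"}
    mapping.update(lnc_map)
    matrix = preprocess.summarize_probes(matrix, mapping)
    counts["analytes"] = len(matrix.analyte_ids)
    counts["lncrna_matched"] = len(lnc_map)
    cio.write_expression_tsv(matrix, _out(cfg, "normalized.tsv"))
    cio.write_table(
        matrix.classes.rename_axis("analyte").reset_index(), _out(cfg, "classes_official.tsv")
    )
    cio.write_table(
        pd.DataFrame(sorted(lnc_map.items()), columns=["array_id", "official_id"]),
        _out(cfg, "lncrna_id_map.tsv"),
    )

    mature = cio.read_fasta(_in(cfg, "mature_mirna.fasta"))
    contaminants = cio.read_fasta(_in(cfg, "contaminants.fasta"))
    design_mirna = cio.read_design_tsv(_in(cfg, "design_mirna.tsv"))
    adapter = _in(cfg, "adapter.txt").read_text().strip()
    survivors: dict[str, list] = {}
    qc_rows = []
    for sample in design_mirna.index:
        reads = cio.read_fastq(_in(cfg, f"reads/{sample}.fastq"))
        trimmed = preprocess.trim_adapter(reads, adapter)
        passing, report = preprocess.filter_reads_qc(
            trimmed,
            min_len=cfg.qc_min_len,
            phred_floor=cfg.qc_phred_floor,
            hq_fraction=cfg.qc_hq_fraction,
            max_uncertain=cfg.qc_max_uncertain,
        )
        clean = preprocess.remove_contaminants(passing, contaminants)
        survivors[sample] = clean
        for _, row in report.to_frame().iterrows():
            qc_rows.append({"sample": sample, "reason": row["reason"], "count": row["count"]})
    cio.write_table(pd.DataFrame(qc_rows), _out(cfg, "qc_report.tsv"))
    table = preprocess.count_mirna(survivors, mature)
    table = preprocess.compute_tpm(table, pseudo=cfg.pseudo_tpm)
    counts["mirnas_quantified"] = len(table.mirna_ids)
    table.counts.rename_axis("mirna").to_csv(
        _out(cfg, "mirna_counts.tsv"), sep="\t", lineterminator="\n"
    )
    table.tpm.rename_axis("mirna").to_csv(
        _out(cfg, "mirna_tpm.tsv"), sep="\t", float_format="%.10g", lineterminator="\n"
    )
    return counts


def stage_de(cfg: PipelineConfig) -> dict[str, int]:
    counts: dict[str, int] = {}
    classes = cio.read_classes_tsv(_out(cfg, "classes_official.tsv"))
    matrix = cio.read_expression_tsv(_out(cfg, "normalized.tsv"), classes)
    design = cio.read_design_tsv(_in(cfg, "design.tsv"))

    nl_lc = design[design.isin(["normal", "cirrhosis"])]
    sub = matrix.subset_samples(list(nl_lc.index))
    res_a = ModeratedTTest(sub, nl_lc, control="normal", case="cirrhosis").fit(cfg.array_policy)
    _write_de(res_a.frame, _out(cfg, "de_cirrhosis.tsv"))
    sig = res_a.frame[res_a.frame["significant"]]
    counts["de_mrna"] = int((sig["analyte_class"] == "mRNA").sum())
    counts["de_lncrna"] = int((sig["analyte_class"] == "lncRNA").sum())

    if (design == "hcc").any():
        lc_hcc = design[design.isin(["cirrhosis", "hcc"])]
        mrna = matrix.subset_class("mRNA").subset_samples(list(lc_hcc.index))
        res_b = ModeratedTTest(mrna, lc_hcc, control="cirrhosis", case="hcc").fit(cfg.array_policy)
        _write_de(res_b.frame, _out(cfg, "de_hcc.tsv"))
        counts["de_mrna_hcc"] = int(res_b.frame["significant"].sum())

    tpm = pd.read_csv(_out(cfg, "mirna_tpm.tsv"), sep="\t", index_col=0)
    design_mirna = cio.read_design_tsv(_in(cfg, "design_mirna.tsv"))
    log_tpm = ExpressionMatrix(
        np.log2(tpm), pd.Series("miRNA", index=tpm.index, name="analyte_class")
    )
    res_m = ModeratedTTest(log_tpm, design_mirna, control="normal", case="cirrhosis").fit(
        cfg.mirna_policy
    )
    _write_de(res_m.frame, _out(cfg, "de_mirna.tsv"))
    counts["de_mirna"] = int(res_m.frame["significant"].sum())
    return counts


def _node_kinds(cfg: PipelineConfig, extra: dict[str, str] | None = None) -> dict[str, str]:
    kinds: dict[str, str] = {}
    classes = cio.read_classes_tsv(_out(cfg, "classes_official.tsv"))
    kinds.update(classes.to_dict())
    de_mirna = _read_de(_out(cfg, "de_mirna.tsv"))
    kinds.update({m: "miRNA" for m in de_mirna.index})
    tf_genes = cio.read_table(_in(cfg, "tf_genes.tsv"), ["tf", "gene"])
    kinds.update({t: "TF" for t in tf_genes["tf"]})
    if extra:
        kinds.update(extra)
    return kinds


def _de_annotations(cfg: PipelineConfig) -> pd.DataFrame:
    de_a = _read_de(_out(cfg, "de_cirrhosis.tsv"))
    de_m = _read_de(_out(cfg, "de_mirna.tsv"))
    cols = ["log2fc", "p", "fdr", "direction", "significant"]
    ann = pd.concat([de_a[cols], de_m[cols]])
    # TFs inherit the statistics of their coding gene
    tf_genes = cio.read_table(_in(cfg, "tf_genes.tsv"), ["tf", "gene"])
    tf_rows = ann.reindex(tf_genes["gene"])
    tf_rows.index = tf_genes["tf"]
    return pd.concat([ann, tf_rows.dropna(how="all")])


def stage_network(cfg: PipelineConfig) -> dict[str, int]:
    counts: dict[str, int] = {}
    de_a = _read_de(_out(cfg, "de_cirrhosis.tsv"))
    de_m = _read_de(_out(cfg, "de_mirna.tsv"))
    de_mirnas = set(de_m.index[de_m["significant"]])
    sig_a = de_a[de_a["significant"]]
    de_mrnas = set(sig_a.index[sig_a["analyte_class"] == "mRNA"])
    de_lncs = set(sig_a.index[sig_a["analyte_class"] == "lncRNA"])

    loci_list = cio.read_bed(_in(cfg, "mirna_loci.bed"))
    loci = {iv.name: iv for iv in loci_list}
    sites_list = cio.read_bed(_in(cfg, "tf_binding_sites.bed"))
    sites: dict[str, list] = {}
    for iv in sites_list:
        sites.setdefault(iv.name, []).append(iv)
    if cfg.restrict_de_tfs:
        tf_genes = cio.read_table(_in(cfg, "tf_genes.tsv"), ["tf", "gene"])
        de_tfs = {
            t
            for t, g in zip(tf_genes["tf"], tf_genes["gene"])
            if g in de_a.index and bool(de_a.loc[g, "significant"])
        }
        sites = {t: s for t, s in sites.items() if t in de_tfs}

    tf_pairs = netbuild.generate_tf_mirna_pairs(
        sites, loci, de_mirnas, cfg.promoter_upstream, cfg.promoter_downstream
    )
    mm_table = cio.read_table(_in(cfg, "mirna_mrna_targets.tsv"), ["mirna", "target"])
    mm_pairs = netbuild.generate_mirna_target_pairs(mm_table, de_mirnas, de_mrnas)
    ml_table = cio.read_table(_in(cfg, "mirna_lncrna_targets.tsv"), ["mirna", "target"])
    ml_pairs = netbuild.generate_mirna_target_pairs(ml_table, de_mirnas, de_lncs)
    counts["tf_mirna_pairs"] = len(tf_pairs)
    counts["mirna_mrna_pairs"] = len(mm_pairs)
    counts["mirna_lncrna_pairs"] = len(ml_pairs)
    for name, pairs in (
        ("tf_mirna_pairs", tf_pairs),
        ("mirna_mrna_pairs", mm_pairs),
        ("mirna_lncrna_pairs", ml_pairs),
    ):
        cio.write_table(pd.DataFrame(pairs, columns=["source", "target"]), _out(cfg, f"{name}.tsv"))

    kinds = _node_kinds(cfg)
    ann = _de_annotations(cfg)
    tf_net = netbuild.assemble_network(
        {"tf_mirna": tf_pairs, "mirna_mrna": mm_pairs}, kinds, ann
    )
    lnc_net = netbuild.assemble_network(
        {"mirna_lncrna": ml_pairs, "mirna_mrna": mm_pairs}, kinds, ann
    )
    netbuild.export_cytoscape(tf_net, _out(cfg, "tf_network"))
    netbuild.export_cytoscape(lnc_net, _out(cfg, "lncrna_network"))
    counts["tf_network_nodes"] = tf_net.number_of_nodes()
    counts["lncrna_network_nodes"] = lnc_net.number_of_nodes()
    return counts


def stage_cerna(cfg: PipelineConfig) -> dict[str, int]:
    counts: dict[str, int] = {}
    mm_pairs = [
        (r["source"], r["target"])
        for _, r in cio.read_table(_out(cfg, "mirna_mrna_pairs.tsv"), ["source", "target"]).iterrows()
    ]
    pairs = netbuild.infer_cerna_pairs(mm_pairs)
    ppi = cio.read_table(_in(cfg, "ppi.tsv"), ["gene_a", "gene_b", "channel"])
    de_a = _read_de(_out(cfg, "de_cirrhosis.tsv"))
    de_genes = set(de_a.index[de_a["significant"]])
    pairs = netbuild.overlay_ppi(
        pairs, ppi, de_genes, frozenset(cfg.allowed_ppi_channels), strict=cfg.strict_ppi
    )
    annotation = cio.read_gaf(_in(cfg, "go_annotation.tsv"))
    immune_terms = cio.read_term_list(_in(cfg, "immune_terms.txt"))
    pairs = netbuild.flag_immune(pairs, immune_terms, annotation.gene_to_terms)
    counts["cerna_pairs"] = len(pairs)
    counts["ppi_supported"] = sum(p.ppi_supported for p in pairs)
    counts["immune_pairs"] = sum(p.immune_pair for p in pairs)
    cio.write_table(
        pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "shared_mirnas": ";".join(p.shared_mirnas),
                    "ppi_supported": p.ppi_supported,
                    "immune_pair": p.immune_pair,
                }
                for p in pairs
            ],
            columns=["gene_a", "gene_b", "shared_mirnas", "ppi_supported", "immune_pair"],
        ),
        _out(cfg, "cerna_pairs.tsv"),
    )
    kinds = _node_kinds(cfg)
    ann = _de_annotations(cfg)
    net = netbuild.assemble_network(
        {"cerna": [(p.gene_a, p.gene_b) for p in pairs]}, kinds, ann
    )
    for p in pairs:
        net.edges[p.gene_a, p.gene_b].update(
            shared_mirnas=p.shared_mirnas,
            ppi_supported=p.ppi_supported,
            immune_pair=p.immune_pair,
        )
    netbuild.flag_immune(net, immune_terms, annotation.gene_to_terms)
    netbuild.export_cytoscape(net, _out(cfg, "cerna_network"))
    return counts


def stage_enrich(cfg: PipelineConfig) -> dict[str, int]:
    counts: dict[str, int] = {}
    annotation = cio.read_gaf(_in(cfg, "go_annotation.tsv"))
    immune_terms = cio.read_term_list(_in(cfg, "immune_terms.txt"))
    de_a = _read_de(_out(cfg, "de_cirrhosis.tsv"))
    sig_a = de_a[de_a["significant"] & (de_a["analyte_class"] == "mRNA")]
    res_a = enrich(set(sig_a.index), annotation, cfg.min_term_size)
    res_a = assign_direction(res_a, sig_a["direction"].to_dict())
    cio.write_table(res_a, _out(cfg, "enrichment_cirrhosis.tsv"))
    counts["terms_tested"] = len(res_a)
    counts["terms_significant"] = int((res_a[cfg.enrich_stat] < cfg.enrich_alpha).sum())

    hcc_path = Path(cfg.output_dir) / "de_hcc.tsv"
    if hcc_path.exists():
        de_b = _read_de(hcc_path)
        sig_b = de_b[de_b["significant"]]
        res_b = enrich(set(sig_b.index), annotation, cfg.min_term_size)
        res_b = assign_direction(res_b, sig_b["direction"].to_dict())
        cio.write_table(res_b, _out(cfg, "enrichment_hcc.tsv"))

    # immune-response subnetworks from the tripartite networks
    sig_terms = res_a[res_a[cfg.enrich_stat] < cfg.enrich_alpha]
    immune_sig = sig_terms[sig_terms["term"].isin(immune_terms)]
    immune_genes: set[str] = set()
    for members in immune_sig["member_genes"]:
        immune_genes.update(members.split(";"))
    counts["immune_subnetwork_genes"] = len(immune_genes)
    for name in ("tf_network", "lncrna_network"):
        net = cio.read_graphml(Path(cfg.output_dir) / name / "network.graphml")
        sub = netbuild.extract_subnetwork(net, immune_genes)
        netbuild.export_cytoscape(sub, _out(cfg, f"{name}_immune"))
        counts[f"{name}_immune_nodes"] = sub.number_of_nodes()
    return counts


def stage_compare(cfg: PipelineConfig) -> dict[str, int]:
    counts: dict[str, int] = {}
    hcc_path = Path(cfg.output_dir) / "de_hcc.tsv"
    if not hcc_path.exists():
        return counts
    de_a = _read_de(_out(cfg, "de_cirrhosis.tsv"))
    de_a = de_a[de_a["analyte_class"] == "mRNA"]
    de_b = _read_de(hcc_path)
    report = overlap_de_sets(de_a, de_b)
    counts["overlap_genes"] = len(report["overlap"])
    report["directions"].rename(
        columns={"direction_a": "direction_cirrhosis", "direction_b": "direction_hcc"}
    ).to_csv(_out(cfg, "overlap_genes.tsv"), sep="\t", lineterminator="\n")

    res_a = cio.read_table(_out(cfg, "enrichment_cirrhosis.tsv"))
    res_b = cio.read_table(_out(cfg, "enrichment_hcc.tsv"))
    for frame in (res_a, res_b):
        frame["p"] = frame["p"].astype(float)
        frame["fdr"] = frame["fdr"].astype(float)
    immune_terms = cio.read_term_list(_in(cfg, "immune_terms.txt"))
    term_report = compare_term_sets(
        res_a, res_b, cfg.enrich_alpha, cfg.enrich_stat, immune_terms
    )
    counts["overlap_terms"] = len(term_report["overlap"])
    cio.write_table(term_report["overlap"], _out(cfg, "overlap_terms.tsv"))
    return counts


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage and write a run manifest.

    The manifest records the configuration hash, input checksums, per-stage
    row counts, output checksums and timestamps.  All results are
    deterministic given the inputs; the timestamps in ``manifest.json`` are
    the only non-reproducible bytes of a run.
    """
    from . import __version__

    stage_funcs = {
        "preprocess": stage_preprocess,
        "de": stage_de,
        "network": stage_network,
        "cerna": stage_cerna,
        "enrich": stage_enrich,
        "compare": stage_compare,
    }
    started = time.time()
    stage_counts: dict[str, dict[str, int]] = {}
    for stage in _STAGES:
        stage_counts[stage] = stage_funcs[stage](cfg)

    cfg_payload = json.dumps(asdict(cfg), sort_keys=True, separators=(",", ":"))
    input_dir = Path(cfg.input_dir)
    input_checksums = {
        str(p.relative_to(input_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(input_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    out_dir = Path(cfg.output_dir)
    output_checksums = {
        str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "tool_version": __version__,
        "config_hash": hashlib.sha256(cfg_payload.encode()).hexdigest(),
        "config": asdict(cfg),
        "input_checksums": input_checksums,
        "output_checksums": output_checksums,
        "stage_counts": stage_counts,
        "started": started,
        "finished": time.time(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
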