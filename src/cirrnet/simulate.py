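"""Seeded synthetic-data generator for the full pipeline.

Emulates the study's inputs at desk scale: a three-group (normal liver,
cirrhosis, early HCC) log2 expression matrix for mRNAs and lncRNAs with the
conjugate noise model the moderated t-test assumes; small-RNA FASTQ reads
built from planted mature-miRNA sequences with negative-binomial counts,
constructed QC failures and contaminant reads; and the annotation universe
(miRNA gene loci on a synthetic chromosome, TF binding sites placed to hit
or avoid promoter windows, miRNA target tables with decoys, a PPI table
with evidence channels, lncRNA transcript intervals for ID harmonization,
and a GO annotation with planted over-represented immune terms).

Everything flows from one seed through named generator streams; identical
(config, seed) yields byte-identical bundles.  The generative model:

* per-analyte variance  sigma_g^2 ~ s0_sq * d0 / ChiSq(d0)  (scaled inverse
  chi-squared, the moderated-t conjugate prior),
* x_gs = mu_g + beta_g * 1[s in case] + eps_gs,  eps_gs ~ N(0, sigma_g^2),
* beta_g = 0 for null analytes; |beta_g| >= min_abs_log2fc with random sign
  for planted DE analytes,
* miRNA read counts ~ NegativeBinomial(group mean, nb_dispersion).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigurationError, ExpressionMatrix, GenomicInterval, ReadRecord
from .enrich import GeneSetAnnotation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "AnnotationBundle",
    "SyntheticBundle",
    "simulate_truth",
    "simulate_expression",
    "simulate_small_rna",
    "simulate_annotations",
    "simulate_bundle",
    "write_bundle",
    "config_hash",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's shipped defaults.

    Sample sizes mirror the source designs: 10 normal / 10 cirrhosis /
    10 early-HCC arrays and 9 normal / 15 cirrhosis small-RNA libraries.
    """

    seed: int = 0
    # analyte universe (desk scale)
    n_mrna: int = 2000
    n_lncrna: int = 300
    n_mirna: int = 150
    # sample design
    n_control: int = 10
    n_case: int = 10
    n_hcc: int = 10
    n_control_mirna: int = 9
    n_case_mirna: int = 15
    # planted effects
    de_fraction: float = 0.1
    de_fraction_hcc: float = 0.1
    hcc_overlap_fraction: float = 0.25
    min_abs_log2fc: float = 2.0
    # conjugate noise model
    d0: float = 4.0
    s0_sq: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # small RNA-seq
    genome_length: int = 10_000_000
    reads_per_sample: int = 100_000
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    nb_dispersion: float = 0.2
    contaminant_fraction: float = 0.02
    qc_fail_fraction: float = 0.05
    n_contaminants: int = 8
    # annotation universe
    n_tf: int = 30
    n_planted_tf_mirna: int = 40
    n_negative_tf_mirna: int = 20
    n_planted_mirna_mrna: int = 200
    n_decoy_mirna_mrna: int = 150
    n_planted_mirna_lncrna: int = 40
    n_decoy_mirna_lncrna: int = 30
    n_ppi: int = 120
    n_go_terms: int = 60
    go_term_size_mean: float = 25.0
    planted_term_odds_ratio: float = 10.0
    # immune-response terms are among the largest GO categories (~5% of
    # genes), so planted terms get their own baseline membership rate
    planted_term_baseline: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_control", "n_case",
                     "n_control_mirna", "n_case_mirna", "n_contaminants", "n_tf"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_hcc < 0:
            raise ConfigurationError("n_hcc must be >= 0")
        for name in ("de_fraction", "de_fraction_hcc", "hcc_overlap_fraction",
                     "contaminant_fraction", "qc_fail_fraction", "planted_term_baseline"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise ConfigurationError("d0 and s0_sq must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.min_abs_log2fc < 0:
            raise ConfigurationError("min_abs_log2fc must be >= 0")
        if self.reads_per_sample < 0:
            raise ConfigurationError("reads_per_sample must be >= 0")
        if self.genome_length < 1:
            raise ConfigurationError("genome_length must be >= 1")
        if not self.adapter or set(self.adapter) - set("ACGT"):
            raise ConfigurationError("adapter must be a non-empty ACGT string")


def config_hash(config: SimulationConfig) -> str:
    """SHA-256 over the canonical JSON serialization of the config."""
    payload = json.dumps(asdict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class GroundTruth:
    """Planted structure for recovery tests.

    ``de_labels``/``true_log2fc`` describe the cirrhosis-vs-normal contrast
    over every analyte; the ``_hcc`` pair describes the HCC-vs-cirrhosis
    contrast over mRNAs.  Edge lists and count tables are filled in by the
    annotation and small-RNA generators.
    """

    de_labels: dict[str, str]
    true_log2fc: dict[str, float]
    de_labels_hcc: dict[str, str] = field(default_factory=dict)
    true_log2fc_hcc: dict[str, float] = field(default_factory=dict)
    planted_tf_mirna: list[tuple[str, str]] = field(default_factory=list)
    planted_negative_tf_mirna: list[tuple[str, str]] = field(default_factory=list)
    planted_mirna_mrna: list[tuple[str, str]] = field(default_factory=list)
    planted_mirna_lncrna: list[tuple[str, str]] = field(default_factory=list)
    planted_ppi: list[tuple[str, str]] = field(default_factory=list)
    planted_enriched_terms: list[str] = field(default_factory=list)
    mirna_true_counts: pd.DataFrame | None = None
    qc_expected: dict[str, dict[str, int]] = field(default_factory=dict)

    def de_ids(self, prefix: str | None = None, direction: str | None = None) -> set[str]:
        out = set()
        for analyte, label in self.de_labels.items():
            if label == "null":
                continue
            if direction is not None and label != direction:
                continue
            if prefix is not None and not analyte.startswith(prefix):
                continue
            out.add(analyte)
        return out

    def validate(self) -> None:
        for analyte, label in self.de_labels.items():
            lfc = self.true_log2fc[analyte]
            if (label == "null") != (lfc == 0.0):
                raise ValueError(f"label/effect mismatch for {analyte!r}")


@dataclass
class AnnotationBundle:
    """Synthetic counterparts of the external annotation resources."""

    mirna_loci: dict[str, GenomicInterval]
    binding_sites: dict[str, list[GenomicInterval]]
    tf_genes: dict[str, str]
    mirna_mrna_table: pd.DataFrame
    mirna_lncrna_table: pd.DataFrame
    ppi_table: pd.DataFrame
    annotation: GeneSetAnnotation
    immune_terms: set[str]
    array_lncrna: list[GenomicInterval]
    official_lncrna: list[GenomicInterval]
    lncrna_probe_map: dict[str, str]


@dataclass
class SyntheticBundle:
    """Everything a pipeline run consumes, in memory."""

    config: SimulationConfig
    expression: ExpressionMatrix
    design: pd.Series
    mirna_reads: dict[str, list[ReadRecord]]
    mature_ref: dict[str, str]
    contaminant_ref: dict[str, str]
    design_mirna: pd.Series
    annotations: AnnotationBundle
    truth: "GroundTruth | None" = None


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("truth", "expression", "smallrna", "annotations")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _n_de(fraction: float, n: int) -> int:
    if fraction == 0:
        return 0
    return max(1, int(round(fraction * n)))


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Plant DE labels and effect sizes for every analyte class.

    Deterministic in (config, seed); called internally by the other
    generators so they agree on the planted structure.
    """
    rng = _streams(config)["truth"]
    labels: dict[str, str] = {}
    lfc: dict[str, float] = {}
    for prefix, n in (("GENE", config.n_mrna), ("LNC", config.n_lncrna), ("MIR", config.n_mirna)):
        ids = _ids(prefix, n)
        n_de = _n_de(config.de_fraction, n)
        de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        magnitudes = config.min_abs_log2fc + rng.exponential(0.5, size=n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for analyte in ids:
            labels[analyte] = "null"
            lfc[analyte] = 0.0
        for j, idx in enumerate(sorted(de_idx)):
            beta = float(signs[j] * magnitudes[j])
            labels[ids[idx]] = "up" if beta > 0 else "down"
            lfc[ids[idx]] = beta

    truth = GroundTruth(de_labels=labels, true_log2fc=lfc)

    # second contrast (HCC vs cirrhosis), mRNAs only, overlapping the first
    mrna_ids = _ids("GENE", config.n_mrna)
    de_a = [g for g in mrna_ids if labels[g] != "null"]
    null_a = [g for g in mrna_ids if labels[g] == "null"]
    n_de_hcc = _n_de(config.de_fraction_hcc, config.n_mrna) if config.n_hcc else 0
    n_shared = min(len(de_a), int(round(config.hcc_overlap_fraction * n_de_hcc)))
    shared = list(rng.choice(de_a, size=n_shared, replace=False)) if n_shared else []
    n_fresh = min(len(null_a), n_de_hcc - n_shared)
    fresh = list(rng.choice(null_a, size=n_fresh, replace=False)) if n_fresh else []
    hcc_labels = {g: "null" for g in mrna_ids}
    hcc_lfc = {g: 0.0 for g in mrna_ids}
    chosen = shared + fresh
    magnitudes = config.min_abs_log2fc + rng.exponential(0.5, size=len(chosen))
    signs = rng.choice([-1.0, 1.0], size=len(chosen))
    for j, g in enumerate(chosen):
        if g in labels and labels[g] != "null" and rng.random() < 0.8:
            # genes DE in both contrasts mostly reverse direction in HCC
            sign = -1.0 if labels[g] == "up" else 1.0
        else:
            sign = float(signs[j])
        beta = float(sign * magnitudes[j])
        hcc_labels[g] = "up" if beta > 0 else "down"
        hcc_lfc[g] = beta
    truth.de_labels_hcc = hcc_labels
    truth.true_log2fc_hcc = hcc_lfc
    truth.validate()
    return truth


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the three-group log2 array matrix (mRNA + lncRNA rows).

    Group means: normal mu_g; cirrhosis mu_g + beta_g; HCC mu_g + beta_g +
    beta_hcc_g, so each contrast's planted effect is exactly its beta.
    """
    if truth is None:
        truth = simulate_truth(config)
    rng = _streams(config)["expression"]
    ids = _ids("GENE", config.n_mrna) + _ids("LNC", config.n_lncrna)
    classes = pd.Series(
        ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna,
        index=pd.Index(ids, name="analyte"),
        name="analyte_class",
    )
    n_analytes = len(ids)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_analytes)
    sigma2 = config.s0_sq * config.d0 / rng.chisquare(config.d0, size=n_analytes)
    beta_a = np.array([truth.true_log2fc[a] for a in ids])
    beta_b = np.array([truth.true_log2fc_hcc.get(a, 0.0) for a in ids])

    samples = (
        [f"NL{i:02d}" for i in range(1, config.n_control + 1)]
        + [f"LC{i:02d}" for i in range(1, config.n_case + 1)]
        + [f"HC{i:02d}" for i in range(1, config.n_hcc + 1)]
    )
    groups = (
        ["normal"] * config.n_control
        + ["cirrhosis"] * config.n_case
        + ["hcc"] * config.n_hcc
    )
    offsets = {
        "normal": np.zeros(n_analytes),
        "cirrhosis": beta_a,
        "hcc": beta_a + beta_b,
    }
    values = np.empty((n_analytes, len(samples)))
    for j, group in enumerate(groups):
        values[:, j] = mu + offsets[group] + rng.normal(0.0, np.sqrt(sigma2))
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=classes.index, columns=samples), classes
    )
    design = pd.Series(groups, index=samples, name="group")
    matrix.values.attrs["design"] = design
    return matrix, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _junction_clean(insert: str, adapter: str, key_len: int = 8) -> bool:
    """True iff adapter trimming cuts exactly at the insert/adapter junction."""
    return (insert + adapter).find(adapter[:key_len]) == len(insert)


def _draw_clean_seq(
    rng: np.random.Generator,
    length_range: tuple[int, int],
    adapter: str,
    forbidden: set[str],
    contaminants: list[str] = (),
    max_tries: int = 200,
) -> str:
    for _ in range(max_tries):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_seq(rng, length)
        if seq in forbidden:
            continue
        if not _junction_clean(seq, adapter):
            continue
        if any(seq in c for c in contaminants):
            continue
        return seq
    raise ConfigurationError(
        "could not draw a sequence compatible with the adapter after "
        f"{max_tries} tries; adapter prefix collides too often"
    )


def simulate_small_rna(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, list[ReadRecord]], dict[str, str], dict[str, str], GroundTruth]:
    """Simulate per-sample small-RNA FASTQ reads and reference FASTAs.

    Each clean read is one mature miRNA sequence followed by the 3' adapter,
    at Phred 40; per-sample per-miRNA read counts are negative-binomial
    around group means proportional to planted abundances (times the
    planted fold change in the cirrhosis group) and are recorded in
    ``truth.mirna_true_counts``.  A fixed fraction of reads copy contaminant
    subsequences and a fixed fraction are constructed to fail QC (short /
    low-quality / N-rich, cycled in that order).
    """
    if truth is None:
        truth = simulate_truth(config)
    rng = _streams(config)["smallrna"]
    mirna_ids = _ids("MIR", config.n_mirna)

    contaminants = {
        f"contam{i:02d}": _random_seq(rng, int(rng.integers(60, 91)))
        for i in range(1, config.n_contaminants + 1)
    }
    mature: dict[str, str] = {}
    seen: set[str] = set()
    contam_seqs = list(contaminants.values())
    for mirna in mirna_ids:
        seq = _draw_clean_seq(rng, (18, 24), config.adapter, seen, contam_seqs)
        mature[mirna] = seq
        seen.add(seq)

    # group means: planted abundance, fold change applied in cirrhosis
    base = rng.lognormal(0.0, 1.0, size=config.n_mirna)
    base = base / base.sum() * config.reads_per_sample
    base = np.maximum(base, 20.0)  # keep every miRNA quantifiable
    lfc = np.array([truth.true_log2fc[m] for m in mirna_ids])
    mean_case = base * np.exp2(lfc)

    samples = (
        [f"sNL{i:02d}" for i in range(1, config.n_control_mirna + 1)]
        + [f"sLC{i:02d}" for i in range(1, config.n_case_mirna + 1)]
    )
    groups = ["normal"] * config.n_control_mirna + ["cirrhosis"] * config.n_case_mirna
    disp = config.nb_dispersion
    counts = pd.DataFrame(0, index=pd.Index(mirna_ids, name="mirna"), columns=samples)
    reads: dict[str, list[ReadRecord]] = {}
    n_contam = int(round(config.contaminant_fraction * config.reads_per_sample))
    n_fail = int(round(config.qc_fail_fraction * config.reads_per_sample))
    qual_hi = 40

    for sample, group in zip(samples, groups):
        mean = base if group == "normal" else mean_case
        if config.reads_per_sample == 0:
            c = np.zeros(config.n_mirna, dtype=int)
        else:
            c = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mean))
        counts[sample] = c
        sample_reads: list[ReadRecord] = []
        for mirna, count in zip(mirna_ids, c):
            seq = mature[mirna] + config.adapter
            q = np.full(len(seq), qual_hi)
            sample_reads.extend(ReadRecord("", seq, q) for _ in range(count))
        n_contam_s = n_contam if config.reads_per_sample else 0
        for _ in range(n_contam_s):
            src = contam_seqs[int(rng.integers(len(contam_seqs)))]
            for _ in range(200):
                length = int(rng.integers(18, 25))
                start = int(rng.integers(0, len(src) - length + 1))
                sub = src[start : start + length]
                if sub not in seen and _junction_clean(sub, config.adapter):
                    break
            else:
                raise ConfigurationError("could not draw a clean contaminant read")
            seq = sub + config.adapter
            sample_reads.append(ReadRecord("", seq, np.full(len(seq), qual_hi)))
        n_fail_s = n_fail if config.reads_per_sample else 0
        fail_counts = {"length": 0, "quality": 0, "uncertainty": 0}
        for i in range(n_fail_s):
            mode = ("length", "quality", "uncertainty")[i % 3]
            fail_counts[mode] += 1
            if mode == "length":
                insert = _draw_clean_seq(rng, (1, 15), config.adapter, seen)
                seq = insert + config.adapter
                q = np.full(len(seq), qual_hi)
            elif mode == "quality":
                insert = _draw_clean_seq(rng, (20, 20), config.adapter, seen)
                seq = insert + config.adapter
                q = np.full(len(seq), qual_hi)
                q[:17] = 10  # 17/20 low-quality insert bases
            else:
                insert = list(_draw_clean_seq(rng, (20, 20), config.adapter, seen))
                for pos in rng.choice(20, size=3, replace=False):
                    insert[pos] = "N"
                insert = "".join(insert)
                if not _junction_clean(insert, config.adapter):
                    insert = "N" * 20  # unambiguous fallback, still N-rich
                seq = insert + config.adapter
                q = np.full(len(seq), qual_hi)
            sample_reads.append(ReadRecord("", seq, q))
        order = rng.permutation(len(sample_reads))
        shuffled = []
        for new_idx, old_idx in enumerate(order):
            r = sample_reads[old_idx]
            shuffled.append(ReadRecord(f"{sample}_r{new_idx:07d}", r.sequence, r.qualities))
        reads[sample] = shuffled
        truth.qc_expected[sample] = {
            "pass": int(c.sum()) + n_contam_s,
            "fail_length": fail_counts["length"],
            "fail_quality": fail_counts["quality"],
            "fail_uncertainty": fail_counts["uncertainty"],
            "contaminant": n_contam_s,
        }

    truth.mirna_true_counts = counts
    return reads, mature, contaminants, truth


def simulate_annotations(config: SimulationConfig, truth: GroundTruth) -> AnnotationBundle:
    """Generate the annotation universe consistent with the planted truth.

    miRNA loci are placed in disjoint slots on a synthetic chromosome with
    >= 12 kb margins so planted-negative binding sites can sit >= 10 kb from
    every promoter window; planted TF binding sites are placed inside the
    promoter window of their miRNA.  Target tables contain every planted
    edge plus decoy edges among null analytes only.  The GO annotation
    over-represents the planted immune terms among upregulated DE mRNAs at
    the configured odds ratio.
    """
    rng = _streams(config)["annotations"]
    mirna_ids = _ids("MIR", config.n_mirna)
    mrna_ids = _ids("GENE", config.n_mrna)
    lnc_ids = _ids("LNC", config.n_lncrna)

    slot = config.genome_length // config.n_mirna
    locus_len = 80
    margin = 12_000
    if slot < 2 * margin + locus_len + 4_000:
        raise ConfigurationError(
            f"genome_length {config.genome_length} too short to place "
            f"{config.n_mirna} miRNA loci with safe margins"
        )
    loci: dict[str, GenomicInterval] = {}
    for i, mirna in enumerate(mirna_ids):
        lo = i * slot + margin
        hi = (i + 1) * slot - margin - locus_len
        start = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        loci[mirna] = GenomicInterval("chrS", start, start + locus_len, strand, mirna)

    from .netbuild import promoter_window

    windows = {
        m: promoter_window(
            loc.start if loc.strand == "+" else loc.end - 1, loc.strand, loc.chrom
        )
        for m, loc in loci.items()
    }

    de_mirnas = sorted(truth.de_ids("MIR"))
    de_mrnas = sorted(truth.de_ids("GENE"))
    de_lncs = sorted(truth.de_ids("LNC"))
    null_mirnas = sorted(set(mirna_ids) - set(de_mirnas))
    null_mrnas = sorted(set(mrna_ids) - set(de_mrnas))
    null_lncs = sorted(set(lnc_ids) - set(de_lncs))

    tf_ids = _ids("TF", config.n_tf)
    n_de_tf = min(len(de_mrnas), config.n_tf // 2)
    tf_gene_pool = list(rng.choice(de_mrnas, size=n_de_tf, replace=False)) + list(
        rng.choice(null_mrnas, size=config.n_tf - n_de_tf, replace=False)
    )
    tf_genes = dict(zip(tf_ids, tf_gene_pool))

    def sample_pairs(rows, cols, k) -> list[tuple[str, str]]:
        total = len(rows) * len(cols)
        k = min(k, total)
        flat = rng.choice(total, size=k, replace=False)
        return sorted((rows[i // len(cols)], cols[i % len(cols)]) for i in flat)

    planted_tf = sample_pairs(tf_ids, de_mirnas, config.n_planted_tf_mirna)
    negatives: list[tuple[str, str]] = []
    pool = sorted(set((t, m) for t in tf_ids for m in de_mirnas) - set(planted_tf))
    if pool:
        idx = rng.choice(len(pool), size=min(config.n_negative_tf_mirna, len(pool)), replace=False)
        negatives = sorted(pool[i] for i in idx)

    binding_sites: dict[str, list[GenomicInterval]] = {t: [] for t in tf_ids}
    for tf, mirna in planted_tf:
        w = windows[mirna]
        site_len = int(rng.integers(10, 21))
        start = int(rng.integers(w.start, w.end - site_len + 1))
        binding_sites[tf].append(
            GenomicInterval(w.chrom, start, start + site_len, "+", tf)
        )
    window_arr = sorted((w.start, w.end) for w in windows.values())
    for tf, _mirna in negatives:
        for _ in range(500):
            start = int(rng.integers(0, config.genome_length - 20))
            if all(
                start + 20 + 10_000 <= ws or we + 10_000 <= start
                for ws, we in window_arr
            ):
                binding_sites[tf].append(
                    GenomicInterval("chrS", start, start + 20, "+", tf)
                )
                break
        else:
            raise ConfigurationError("no room for a planted-negative binding site")

    planted_mm = sample_pairs(de_mirnas, de_mrnas, config.n_planted_mirna_mrna)
    decoy_mm = (
        sample_pairs(null_mirnas, null_mrnas, config.n_decoy_mirna_mrna)
        if null_mirnas and null_mrnas
        else []
    )
    planted_ml = sample_pairs(de_mirnas, de_lncs, config.n_planted_mirna_lncrna)
    decoy_ml = (
        sample_pairs(null_mirnas, null_lncs, config.n_decoy_mirna_lncrna)
        if null_mirnas and null_lncs
        else []
    )
    mm_table = pd.DataFrame(planted_mm + decoy_mm, columns=["mirna", "target"])
    ml_table = pd.DataFrame(planted_ml + decoy_ml, columns=["mirna", "target"])

    allowed = ["experiments", "textmining", "coexpression", "database"]
    ppi_rows: list[tuple[str, str, str]] = []
    planted_ppi = []
    n_core = max(1, config.n_ppi * 2 // 3)
    # core PPI pairs live on the ceRNA structure: mRNA pairs sharing a
    # planted miRNA, so the evidence overlay has something to support
    targets_by_mirna: dict[str, list[str]] = {}
    for mirna, target in planted_mm:
        targets_by_mirna.setdefault(mirna, []).append(target)
    cerna_candidates = sorted(
        {
            (min(a, b), max(a, b))
            for targets in targets_by_mirna.values()
            for i, a in enumerate(targets)
            for b in targets[i + 1 :]
            if a != b
        }
    )
    if cerna_candidates:
        idx = rng.choice(
            len(cerna_candidates), size=min(n_core, len(cerna_candidates)), replace=False
        )
        for i in sorted(idx):
            a, b = cerna_candidates[i]
            channel = allowed[int(rng.integers(len(allowed)))]
            ppi_rows.append((a, b, channel))
            planted_ppi.append((a, b))
    # distractors: disallowed channel, and null-null pairs (no DE endpoint)
    for a, b in sample_pairs(de_mrnas, null_mrnas, max(1, config.n_ppi // 6)):
        ppi_rows.append((min(a, b), max(a, b), "neighborhood"))
    for a, b in sample_pairs(null_mrnas, null_mrnas, max(1, config.n_ppi // 6)):
        if a != b:
            ppi_rows.append((min(a, b), max(a, b), allowed[int(rng.integers(len(allowed)))]))
    ppi_table = pd.DataFrame(sorted(set(ppi_rows)), columns=["gene_a", "gene_b", "channel"])
    planted_ppi = sorted(set(planted_ppi))

    # GO annotation: background terms + planted immune terms
    planted_terms = {"GO:0006955": "immune response", "GO:0002250": "adaptive immune response"}
    gene_to_terms: dict[str, set[str]] = {g: set() for g in mrna_ids}
    term_names: dict[str, str] = dict(planted_terms)
    for i in range(1, config.n_go_terms + 1):
        term = f"GO:SIM{i:04d}"
        term_names[term] = f"synthetic process {i}"
        size = max(2, int(rng.poisson(config.go_term_size_mean)))
        for g in rng.choice(mrna_ids, size=min(size, config.n_mrna), replace=False):
            gene_to_terms[g].add(term)
    # over-represented among genes up in cirrhosis or down in HCC, mirroring
    # the immune-response direction reversal between the two contrasts
    biased = truth.de_ids("GENE", "up") | {
        g for g, lab in truth.de_labels_hcc.items() if lab == "down"
    }
    q0 = min(0.5, config.planted_term_baseline)
    odds0 = q0 / (1 - q0)
    odds1 = odds0 * config.planted_term_odds_ratio
    q1 = odds1 / (1 + odds1)
    for term in planted_terms:
        for g in mrna_ids:
            prob = q1 if g in biased else q0
            if rng.random() < prob:
                gene_to_terms[g].add(term)
    gene_to_terms = {g: t for g, t in gene_to_terms.items() if t}
    annotation = GeneSetAnnotation(gene_to_terms, term_names)

    # lncRNA ID harmonization inputs: 1:1 array->official with >90% overlap
    array_iv: list[GenomicInterval] = []
    official_iv: list[GenomicInterval] = []
    probe_map: dict[str, str] = {}
    tx_len = 1_000
    for i, lnc in enumerate(lnc_ids):
        start = 1_000 + i * (tx_len + 500)
        strand = "+" if rng.random() < 0.5 else "-"
        official_iv.append(GenomicInterval("chrL", start, start + tx_len, strand, lnc))
        shift = int(rng.integers(0, int(0.08 * tx_len)))  # keeps overlap > 90%
        array_name = f"A{lnc}"
        array_iv.append(
            GenomicInterval("chrL", start + shift, start + shift + tx_len, strand, array_name)
        )
        probe_map[array_name] = lnc

    truth.planted_tf_mirna = planted_tf
    truth.planted_negative_tf_mirna = negatives
    truth.planted_mirna_mrna = planted_mm
    truth.planted_mirna_lncrna = planted_ml
    truth.planted_ppi = planted_ppi
    truth.planted_enriched_terms = sorted(planted_terms)

    return AnnotationBundle(
        mirna_loci=loci,
        binding_sites=binding_sites,
        tf_genes=tf_genes,
        mirna_mrna_table=mm_table,
        mirna_lncrna_table=ml_table,
        ppi_table=ppi_table,
        annotation=annotation,
        immune_terms=set(planted_terms),
        array_lncrna=array_iv,
        official_lncrna=official_iv,
        lncrna_probe_map=probe_map,
    )


def simulate_bundle(config: SimulationConfig) -> tuple[SyntheticBundle, GroundTruth]:
    """Run all generators from one seed and return the full bundle."""
    truth = simulate_truth(config)
    matrix, truth = simulate_expression(config, truth)
    reads, mature, contaminants, truth = simulate_small_rna(config, truth)
    annotations = simulate_annotations(config, truth)
    design = matrix.values.attrs["design"]
    design_mirna = pd.Series(
        ["normal"] * config.n_control_mirna + ["cirrhosis"] * config.n_case_mirna,
        index=list(reads),
        name="group",
    )
    bundle = SyntheticBundle(
        config=config,
        expression=matrix,
        design=design,
        mirna_reads=reads,
        mature_ref=mature,
        contaminant_ref=contaminants,
        design_mirna=design_mirna,
        annotations=annotations,
        truth=truth,
    )
    return bundle, truth


def write_bundle(bundle: SyntheticBundle | None, truth: GroundTruth | None, directory) -> dict:
    """Write a bundle to disk in the pipeline's input formats.

    The lncRNA rows of the expression table are written under their array
    (unofficial) IDs so the pipeline exercises ID harmonization; the
    in-memory matrix keeps official IDs.  Returns the manifest (also written
    as ``manifest.json``): file paths with SHA-256 checksums, the seed and
    the config hash.  A ``None`` bundle yields a valid manifest with no
    data files.
    """
    from pathlib import Path

    from . import io as cio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def register(path) -> None:
        files.append(str(Path(path).relative_to(directory)))

    if bundle is not None:
        ann = bundle.annotations
        probe_view = bundle.expression.values.rename(
            index={v: k for k, v in ann.lncrna_probe_map.items()}
        )
        probe_classes = bundle.expression.classes.rename(
            index={v: k for k, v in ann.lncrna_probe_map.items()}
        )
        p = directory / "expression.tsv"
        cio.write_expression_tsv(ExpressionMatrix(probe_view, probe_classes), p)
        register(p)
        p = directory / "analyte_classes.tsv"
        cio.write_table(
            probe_classes.rename_axis("analyte").reset_index(), p
        )
        register(p)
        p = directory / "design.tsv"
        cio.write_design_tsv(bundle.design, p)
        register(p)
        p = directory / "design_mirna.tsv"
        cio.write_design_tsv(bundle.design_mirna, p)
        register(p)

        reads_dir = directory / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sample in sorted(bundle.mirna_reads):
            p = reads_dir / f"{sample}.fastq"
            cio.write_fastq(bundle.mirna_reads[sample], p)
            register(p)
        p = directory / "mature_mirna.fasta"
        cio.write_fasta(bundle.mature_ref, p)
        register(p)
        p = directory / "contaminants.fasta"
        cio.write_fasta(bundle.contaminant_ref, p)
        register(p)

        p = directory / "mirna_loci.bed"
        cio.write_bed(sorted(ann.mirna_loci.values(), key=lambda iv: (iv.chrom, iv.start, iv.name)), p)
        register(p)
        sites = [
            site for tf in sorted(ann.binding_sites) for site in ann.binding_sites[tf]
        ]
        p = directory / "tf_binding_sites.bed"
        cio.write_bed(sorted(sites, key=lambda iv: (iv.chrom, iv.start, iv.name)), p)
        register(p)
        p = directory / "array_lncrna.bed"
        cio.write_bed(ann.array_lncrna, p)
        register(p)
        p = directory / "official_lncrna.bed"
        cio.write_bed(ann.official_lncrna, p)
        register(p)

        p = directory / "mirna_mrna_targets.tsv"
        cio.write_table(ann.mirna_mrna_table, p)
        register(p)
        p = directory / "mirna_lncrna_targets.tsv"
        cio.write_table(ann.mirna_lncrna_table, p)
        register(p)
        p = directory / "ppi.tsv"
        cio.write_table(ann.ppi_table, p)
        register(p)
        p = directory / "tf_genes.tsv"
        cio.write_table(
            pd.DataFrame(sorted(ann.tf_genes.items()), columns=["tf", "gene"]), p
        )
        register(p)
        p = directory / "go_annotation.tsv"
        cio.write_gaf(ann.annotation, p)
        register(p)
        p = directory / "immune_terms.txt"
        with open(p, "w") as fh:
            for term in sorted(ann.immune_terms):
                fh.write(term + "\n")
        register(p)
        p = directory / "adapter.txt"
        p.write_text(bundle.config.adapter + "\n")
        register(p)

    if truth is not None:
        p = directory / "ground_truth.json"
        payload = {
            "de_labels": truth.de_labels,
            "true_log2fc": truth.true_log2fc,
            "de_labels_hcc": truth.de_labels_hcc,
            "true_log2fc_hcc": truth.true_log2fc_hcc,
            "planted_tf_mirna": truth.planted_tf_mirna,
            "planted_negative_tf_mirna": truth.planted_negative_tf_mirna,
            "planted_mirna_mrna": truth.planted_mirna_mrna,
            "planted_mirna_lncrna": truth.planted_mirna_lncrna,
            "planted_ppi": truth.planted_ppi,
            "planted_enriched_terms": truth.planted_enriched_terms,
            "qc_expected": truth.qc_expected,
            "mirna_true_counts": (
                None
                if truth.mirna_true_counts is None
                else {
                    "index": list(truth.mirna_true_counts.index),
                    "columns": list(truth.mirna_true_counts.columns),
                    "values": truth.mirna_true_counts.to_numpy().tolist(),
                }
            ),
        }
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        register(p)

    manifest = {
        "seed": bundle.config.seed if bundle is not None else None,
        "config_hash": config_hash(bundle.config) if bundle is not None else None,
        "files": {
            name: hashlib.sha256((directory / name).read_bytes()).hexdigest()
            for name in sorted(files)
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
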