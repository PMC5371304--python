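"""Expression and small-RNA preprocessing.

Covers quantile normalization of array intensities, probe-to-gene
summarization, harmonization of unofficial lncRNA identifiers by transcript
overlap, adapter trimming, read quality filtering, contaminant removal
(rRNA/tRNA/snRNA-style references), exact-match miRNA counting, and TPM
quantification with the zero-handling used for downstream differential
analysis.

Coordinates are 0-based half-open (BED convention) throughout.  Contaminant
and miRNA matching are exact and same-strand; the QC rules are applied in
fixed order (length, then quality, then uncertainty) so failure attribution
is reproducible.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Iterator

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    FormatError,
    GenomicInterval,
    MiRNACountTable,
    QCReport,
    ReadRecord,
)

__all__ = [
    "quantile_normalize",
    "summarize_probes",
    "match_lncrna_ids",
    "trim_adapter",
    "filter_reads_qc",
    "remove_contaminants",
    "count_mirna",
    "compute_tpm",
]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to a common empirical distribution.

    The reference distribution is the across-sample mean of each column's
    sorted values; every value is replaced by the reference value at its
    within-column rank, ties receiving the mean of the reference values at
    their tied ranks.  Afterwards every column has an identical multiset of
    values, and the operation is idempotent.
    """
    x = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in expression matrix")
    n_analytes, n_samples = x.shape
    if n_analytes == 0 or n_samples == 0:
        return ExpressionMatrix(matrix.values.copy(), matrix.classes.copy())
    sorted_cols = np.sort(x, axis=0)
    reference = sorted_cols.mean(axis=1)
    # mean of identical values is that value; restore bit-exactness lost to
    # float summation so the operation is exactly idempotent
    identical = (sorted_cols == sorted_cols[:, :1]).all(axis=1)
    reference[identical] = sorted_cols[identical, 0]
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_analytes)
        assigned[order] = reference
        # average assigned reference values within tie groups
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        means = np.bincount(inverse, weights=assigned) / counts
        gmin = np.full(len(counts), np.inf)
        gmax = np.full(len(counts), -np.inf)
        np.minimum.at(gmin, inverse, assigned)
        np.maximum.at(gmax, inverse, assigned)
        degenerate = gmin == gmax
        means[degenerate] = gmin[degenerate]
        out[:, j] = means[inverse]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.classes.copy())


def summarize_probes(
    matrix: ExpressionMatrix,
    probe_to_id: dict[str, str],
) -> ExpressionMatrix:
    """Collapse probe-level rows to official IDs, averaging duplicates.

    Probes mapping to the same official ID are averaged per sample; probes
    with no mapping are dropped (a warning reports how many).  An empty
    result (all probes unmapped) is returned, not raised.
    """
    mapped = matrix.values.index[matrix.values.index.isin(probe_to_id)]
    n_dropped = len(matrix.values.index) - len(mapped)
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} probe(s) with no official ID", stacklevel=2
        )
    if len(mapped) == 0:
        empty = matrix.values.iloc[0:0]
        return ExpressionMatrix(empty.copy(), matrix.classes.iloc[0:0].copy())
    sub = matrix.values.loc[mapped]
    official = pd.Index([probe_to_id[p] for p in mapped], name=sub.index.name)
    values = sub.groupby(official, sort=True).mean()
    # class of the official ID = class of its probes (must agree)
    cls = matrix.classes.loc[mapped].groupby(official, sort=True).agg(
        lambda s: s.iloc[0]
    )
    return ExpressionMatrix(values, cls)


def match_lncrna_ids(
    array_transcripts: Iterable[GenomicInterval],
    official_transcripts: Iterable[GenomicInterval],
    min_fraction: float = 0.90,
) -> dict[str, str]:
    """Map unofficial array transcripts to official IDs by region overlap.

    An array transcript ``t`` matches official transcript ``o`` iff they
    share chromosome and strand and ``overlap(t, o) / len(t)`` strictly
    exceeds ``min_fraction``.  Among qualifying candidates the largest
    overlap fraction wins; exact ties go to the lexicographically smallest
    official ID.  Array transcripts with no qualifying candidate are absent
    from the result.
    """
    officials: dict[tuple[str, str], list[GenomicInterval]] = {}
    for o in official_transcripts:
        officials.setdefault((o.chrom, o.strand), []).append(o)
    mapping: dict[str, str] = {}
    for t in array_transcripts:
        best: tuple[float, str] | None = None
        for o in officials.get((t.chrom, t.strand), []):
            frac = t.overlap_length(o) / len(t)
            if frac > min_fraction:
                key = (-frac, o.name)
                if best is None or key < best:
                    best = key
        if best is not None:
            mapping[t.name] = best[1]
    return mapping


def trim_adapter(
    reads: Iterable[ReadRecord],
    adapter: str,
    min_prefix: int = 8,
) -> Iterator[ReadRecord]:
    """Truncate each read at the first occurrence of the adapter prefix.

    The search key is the first ``min_prefix`` bases of the adapter; reads
    without an occurrence pass unchanged.  An occurrence at position 0
    yields an empty read (removed later by the length filter).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    key = adapter[:min_prefix]
    for read in reads:
        pos = read.sequence.find(key)
        if pos < 0:
            yield read
        else:
            yield ReadRecord(read.id, read.sequence[:pos], read.qualities[:pos])


def filter_reads_qc(
    reads: Iterable[ReadRecord],
    min_len: int = 16,
    phred_floor: int = 20,
    hq_fraction: float = 0.90,
    max_uncertain: float = 0.05,
) -> tuple[list[ReadRecord], QCReport]:
    """Quality-filter reads, attributing failures in fixed rule order.

    A read passes iff its length is at least ``min_len`` AND at least
    ``hq_fraction`` of its bases have Phred >= ``phred_floor`` AND at most
    ``max_uncertain`` of its bases are N calls.  Both fraction boundaries
    are inclusive.  Failures are attributed to the first violated rule in
    the order length, quality, uncertainty.
    """
    passing: list[ReadRecord] = []
    report = QCReport()
    for read in reads:
        n = len(read.sequence)
        if n < min_len:
            report.n_fail_length += 1
            continue
        n_hq = int((read.qualities >= phred_floor).sum())
        if n_hq / n < hq_fraction:
            report.n_fail_quality += 1
            continue
        n_uncertain = read.sequence.count("N")
        if n_uncertain / n > max_uncertain:
            report.n_fail_uncertainty += 1
            continue
        report.n_pass += 1
        passing.append(read)
    return passing, report


def remove_contaminants(
    reads: Iterable[ReadRecord],
    contaminant_ref: dict[str, str],
) -> list[ReadRecord]:
    """Drop reads whose sequence is an exact substring of any contaminant.

    Matching is same-strand only (no reverse complement).  An empty
    reference passes every read through with a warning.
    """
    if not contaminant_ref:
        warnings.warn("empty contaminant reference: no reads removed", stacklevel=2)
        return list(reads)
    refs = list(contaminant_ref.values())
    return [r for r in reads if not any(r.sequence in ref for ref in refs)]


def count_mirna(
    reads_per_sample: dict[str, list[ReadRecord]],
    mature_ref: dict[str, str],
) -> MiRNACountTable:
    """Count reads exactly matching mature miRNA sequences.

    A read increments a miRNA's count iff its sequence equals the mature
    sequence; non-matching reads are discarded.  Mature sequences must be
    unique (a duplicate would make assignment ambiguous).
    """
    seq_to_id: dict[str, str] = {}
    for mirna_id, seq in mature_ref.items():
        if seq in seq_to_id:
            raise FormatError(
                f"duplicate mature sequence shared by {seq_to_id[seq]!r} and {mirna_id!r}"
            )
        seq_to_id[seq] = mirna_id
    samples = list(reads_per_sample)
    counts = pd.DataFrame(0, index=pd.Index(list(mature_ref), name="mirna"), columns=samples)
    for sample, reads in reads_per_sample.items():
        for read in reads:
            mirna_id = seq_to_id.get(read.sequence)
            if mirna_id is not None:
                counts.at[mirna_id, sample] += 1
    return MiRNACountTable(counts=counts)


def compute_tpm(table: MiRNACountTable, pseudo: float = 0.0001) -> MiRNACountTable:
    """Transcripts-per-million with all-zero-row removal and a pseudo-value.

    Per sample, ``tpm = count * 1e6 / total sample count``.  miRNAs with
    zero counts in every sample are dropped; remaining zero cells are then
    set to ``pseudo`` so downstream log-scale differential analysis is
    defined.  A sample whose total count is zero has no defined TPM and is
    an error naming the sample.
    """
    counts = table.counts
    totals = counts.sum(axis=0)
    zero_samples = totals.index[totals == 0]
    if len(zero_samples):
        raise ValueError(
            f"sample {zero_samples[0]!r} has zero total count; TPM undefined"
        )
    keep = counts.index[(counts != 0).any(axis=1)]
    counts = counts.loc[keep]
    tpm = counts * 1e6 / totals
    tpm = tpm.mask(counts == 0, pseudo)
    return MiRNACountTable(counts=counts.copy(), tpm=tpm)
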