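"""Core in-memory containers shared across the pipeline.

Expression data lives in a pandas DataFrame (analytes as rows, samples as
columns) wrapped by :class:`ExpressionMatrix`, which also carries per-analyte
class labels (mRNA / lncRNA / miRNA).  Sample-to-group assignments are plain
pandas Series.  Networks are plain :class:`networkx.Graph` objects with typed
node/edge attributes (see :mod:`cirrnet.netbuild`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANALYTE_CLASSES = ("mRNA", "lncRNA", "miRNA")


class CirrnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CirrnetError):
    """Invalid configuration value or combination."""


class FormatError(CirrnetError):
    """Malformed input file; message names the offending line/record."""


@dataclass
class ExpressionMatrix:
    """An analyte x sample expression matrix with class labels.

    Parameters
    ----------
    values
        DataFrame indexed by analyte ID with sample IDs as columns.  Values
        are log2-scale after normalization; raw for count-derived tables.
    classes
        Series mapping every analyte ID to one of ``mRNA``, ``lncRNA``,
        ``miRNA``.
    """

    values: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate analyte ID: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.classes = self.classes.reindex(self.values.index)
        if self.classes.isna().any():
            missing = self.classes.index[self.classes.isna()][0]
            raise ValueError(f"analyte {missing!r} has no class label")
        bad = set(self.classes.unique()) - set(ANALYTE_CLASSES)
        if bad:
            raise ValueError(f"unknown analyte class(es): {sorted(bad)}")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample(s): {missing}")
        return ExpressionMatrix(self.values[samples].copy(), self.classes.copy())

    def subset_class(self, analyte_class: str) -> "ExpressionMatrix":
        keep = self.classes.index[self.classes == analyte_class]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.classes.loc[keep].copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.classes.equals(other.classes)


@dataclass
class ReadRecord:
    """A single small-RNA sequencing read (post-demultiplexing)."""

    id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred integers

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if len(self.qualities) and (self.qualities.min() < 0 or self.qualities.max() > 93):
            raise FormatError(f"record {self.id!r}: Phred scores outside [0, 93]")


@dataclass
class MiRNACountTable:
    """Per-sample miRNA read counts and TPM values.

    ``tpm`` is populated by :func:`cirrnet.preprocess.compute_tpm`; until then
    it is ``None``.
    """

    counts: pd.DataFrame  # miRNA x sample, non-negative integers
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class QCReport:
    """Counts of reads passing / failing each QC rule, in check order."""

    n_pass: int = 0
    n_fail_length: int = 0
    n_fail_quality: int = 0
    n_fail_uncertainty: int = 0

    @property
    def n_total(self) -> int:
        return self.n_pass + self.n_fail_length + self.n_fail_quality + self.n_fail_uncertainty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["pass", "length", "quality", "uncertainty"],
                "count": [
                    self.n_pass,
                    self.n_fail_length,
                    self.n_fail_quality,
                    self.n_fail_uncertainty,
                ],
            }
        )


@dataclass
class ThresholdPolicy:
    """Significance policy for differential-expression calls.

    ``stat_field`` selects which statistic is gated at ``alpha`` (strict
    ``<``); the fold-change gates are inclusive (``>= fc_up`` or
    ``<= fc_down``).  The shipped defaults are the array policy (FDR < 0.05,
    FC >= 2 or <= 0.5); small-RNA analyses use the raw-p variant.
    """

    stat_field: str = "fdr"
    alpha: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5

    def __post_init__(self) -> None:
        if self.stat_field not in ("fdr", "p"):
            raise ConfigurationError(f"stat_field must be 'fdr' or 'p', got {self.stat_field!r}")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.fc_up <= 1 or self.fc_down >= 1:
            raise ConfigurationError("require fc_up > 1 and fc_down < 1")
        if abs(self.fc_up * self.fc_down - 1.0) > 1e-9:
            raise ConfigurationError("fc_up must equal 1 / fc_down")


MIRNA_POLICY = ThresholdPolicy(stat_field="p")
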