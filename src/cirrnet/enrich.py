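"""Hypergeometric gene-set (GO) enrichment with BH FDR.

Given n differentially expressed genes out of a universe of N annotated
genes, a term annotating K universe genes of which k are DE has upper-tail
probability

    p = sum_{j=k}^{min(K, n)} C(K, j) C(N-K, n-j) / C(N, n),

evaluated stably in log space (log-gamma + log-sum-exp).  Terms are
BH-adjusted across exactly the tested terms, labelled with a direction (up /
down / mixed by strict majority of their DE members), and two contrasts'
term sets can be compared with per-term direction pairs and immune flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import adjust_bh

__all__ = [
    "GeneSetAnnotation",
    "hypergeom_upper",
    "enrich",
    "assign_direction",
    "compare_term_sets",
]


@dataclass
class GeneSetAnnotation:
    """Gene -> term annotation with a term-name map and a gene universe.

    The universe defaults to every gene carrying at least one annotation.
    """

    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, str]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is None:
            self.universe = set(self.gene_to_terms)
        stray = set(self.gene_to_terms) - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} annotated gene(s) outside the universe "
                f"(e.g. {sorted(stray)[0]!r})"
            )

    def term_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for term in terms:
                out.setdefault(term, set()).add(gene)
        return out


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts DE genes in a term when n DE genes are drawn without
    replacement from a universe of N genes, K of which carry the term.
    Computed as a log-space sum of the PMF over j = k .. min(K, n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    log_pmf = _log_binom(K, j) + _log_binom(N - K, n - j) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def enrich(
    de_genes: set[str],
    annotation: GeneSetAnnotation,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Test every annotation term for over-representation among DE genes.

    DE genes outside the universe are dropped (a warning reports how many).
    One result row per term with at least ``min_term_size`` universe genes
    and at least one DE member; BH adjustment runs across exactly the
    tested terms.  Rows are sorted by p ascending, ties broken by term ID.

    Returns a DataFrame with columns term, term_name, k, K, n, N, p, fdr,
    member_genes (semicolon-joined, sorted).
    """
    if not annotation.universe:
        raise ValueError("empty annotation universe")
    outside = de_genes - annotation.universe
    if outside:
        warnings.warn(
            f"{len(outside)} DE gene(s) outside the annotation universe dropped",
            stacklevel=2,
        )
    de_in = de_genes & annotation.universe
    N = len(annotation.universe)
    n = len(de_in)
    rows = []
    for term, genes in sorted(annotation.term_to_genes().items()):
        K = len(genes)
        if K < min_term_size:
            continue
        members = sorted(genes & de_in)
        k = len(members)
        if k == 0:
            continue
        rows.append(
            {
                "term": term,
                "term_name": annotation.term_names.get(term, term),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
                "member_genes": ";".join(members),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "term_name", "k", "K", "n", "N", "p", "member_genes"]
    )
    if len(result):
        result["fdr"] = adjust_bh(result["p"].to_numpy())
    else:
        result["fdr"] = pd.Series(dtype=float)
    result = result.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return result[["term", "term_name", "k", "K", "n", "N", "p", "fdr", "member_genes"]]


def assign_direction(result: pd.DataFrame, de_directions: dict[str, str]) -> pd.DataFrame:
    """Label each term up / down / mixed by strict majority of DE members.

    A term is 'up' if more than half of its DE member genes are upregulated,
    'down' if more than half are downregulated, otherwise 'mixed'.
    """
    directions = []
    for members in result["member_genes"]:
        genes = members.split(";") if members else []
        n_up = sum(1 for g in genes if de_directions.get(g) == "up")
        n_down = sum(1 for g in genes if de_directions.get(g) == "down")
        total = len(genes)
        if total and n_up * 2 > total:
            directions.append("up")
        elif total and n_down * 2 > total:
            directions.append("down")
        else:
            directions.append("mixed")
    out = result.copy()
    out["direction"] = directions
    return out


def compare_term_sets(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = 0.05,
    stat_field: str = "fdr",
    immune_terms: set[str] | None = None,
) -> dict:
    """Compare two contrasts' significant GO terms.

    Significance is ``stat_field < alpha`` (strict).  Returns the shared
    terms with per-term direction pairs (and an immune flag when a term list
    is supplied) plus each side's exclusive terms.
    """
    immune_terms = immune_terms or set()
    sig_a = a[a[stat_field] < alpha].set_index("term")
    sig_b = b[b[stat_field] < alpha].set_index("term")
    shared = sorted(set(sig_a.index) & set(sig_b.index))
    rows = []
    for term in shared:
        rows.append(
            {
                "term": term,
                "term_name": sig_a.loc[term, "term_name"],
                "direction_a": sig_a.loc[term].get("direction", "mixed"),
                "direction_b": sig_b.loc[term].get("direction", "mixed"),
                "immune": term in immune_terms,
            }
        )
    overlap = pd.DataFrame(
        rows, columns=["term", "term_name", "direction_a", "direction_b", "immune"]
    )
    return {
        "overlap": overlap,
        "only_a": sorted(set(sig_a.index) - set(sig_b.index)),
        "only_b": sorted(set(sig_b.index) - set(sig_a.index)),
    }
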