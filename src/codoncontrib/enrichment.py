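"""Hypergeometric term enrichment with BH FDR and count/q filters.

Flat over-representation testing of annotation terms (GO/KEGG-agnostic) in
a study gene set against a universe: the upper-tail hypergeometric p-value
P(X ≥ k) is computed in log space, BH-adjusted across the tested terms
(terms with at least one study-set gene), and filtered by the minimum-count
and q-value rules (defaults k ≥ 7, q < 0.05).  Includes the selector for
AAG-rich gene sets (coding-sequence AAG frequency above a threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .expression import bh_adjust
from .sequence_features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["AnnotationMap", "hypergeom_upper_tail", "enrich", "aag_rich_set"]


@dataclass
class AnnotationMap:
    """term_id → gene-id set with optional labels; empty terms are dropped."""

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: set(g) for t, g in self.terms.items() if g}

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Read a gene_id / term_id / term_label TSV (header optional)."""
        terms: dict[str, set[str]] = {}
        labels: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "gene_id":
                    continue
                if len(parts) < 2:
                    raise ValueError(f"{path}: annotation rows need gene_id and term_id")
                gene, term = parts[0], parts[1]
                terms.setdefault(term, set()).add(gene)
                if len(parts) > 2 and parts[2]:
                    labels[term] = parts[2]
        return cls(terms=terms, labels=labels)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tterm_id\tterm_label\n")
            for term in sorted(self.terms):
                label = self.labels.get(term, "")
                for gene in sorted(self.terms[term]):
                    fh.write(f"{gene}\t{term}\t{label}\n")


def _log_hyper_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(N, K, n)."""

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return log_comb(K, i) + log_comb(N - K, n - i) - log_comb(N, n)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail p = P(X ≥ k) for X ~ Hypergeometric(N, K, n), in log space.

    N = universe size, K = universe genes carrying the term, n = study-set
    size, k = study-set genes carrying the term.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    lo = max(k, 0)
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    return float(min(1.0, np.exp(logsumexp(_log_hyper_pmf(support, K, n, N)))))


def enrich(
    study_set: Iterable[str],
    universe: Iterable[str],
    annot: AnnotationMap,
    min_count: int = 7,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of annotation terms in a study gene set.

    Every term intersecting the universe and carrying ≥1 study gene is
    tested; BH runs across that family.  ``passes_filter`` applies the
    count/q rule (k ≥ ``min_count`` and q < ``q_max``).  Study genes absent
    from the universe are dropped (count logged).  Results sorted by (q, p).
    """
    universe = set(universe)
    study = set(study_set)
    dropped = study - universe
    if dropped:
        logger.info("%d study genes absent from the universe were dropped", len(dropped))
    study &= universe
    if not study:
        raise ValueError("study set is empty (after restricting to the universe)")

    N, n = len(universe), len(study)
    rows = []
    for term in sorted(annot.terms):
        members = annot.terms[term] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & study)
        if k == 0:
            continue  # k = 0 terms stay outside the BH family
        rows.append(
            {
                "term_id": term,
                "label": annot.labels.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(k, K, n, N),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "label", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["passes_filter"] = (out["k"] >= min_count) & (out["q"] < q_max)
        out = out.sort_values(["q", "p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["passes_filter"] = pd.Series(dtype=bool)
    out.attrs["study_genes_dropped"] = len(dropped)
    return out


def aag_rich_set(
    features: FeatureMatrix | pd.DataFrame,
    threshold: float = 0.08,
    feature: str = "codon:AAG",
) -> set[str]:
    """Genes whose coding-sequence AAG frequency strictly exceeds ``threshold``."""
    frame = features.values if isinstance(features, FeatureMatrix) else features
    if feature not in frame.columns:
        raise KeyError(f"feature {feature!r} not in matrix")
    col = frame[feature].to_numpy(dtype=float)
    return set(frame.index[col > threshold])
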