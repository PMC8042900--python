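"""Group comparisons of codon-frequency distributions (Kruskal–Wallis).

Genes are partitioned by their protein response (up- / down-regulated under
the fold-change and significance cutoffs), and the distribution of a chosen
feature — canonically the AAG codon frequency — is compared across groups
with the tie-corrected Kruskal–Wallis rank test.  The omnibus chi-square
p-value can be replaced by a seeded permutation p for small groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .sequence_features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneGroupSet",
    "KruskalResult",
    "GroupComparison",
    "assign_groups",
    "kruskal_wallis",
    "group_summary",
]


@dataclass
class GeneGroupSet:
    """Named gene-id groups plus the thresholds that defined them."""

    groups: dict[str, set[str]]
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        up, down = self.groups.get("up"), self.groups.get("down")
        if up is not None and down is not None and up & down:
            raise ValueError(f"up and down groups overlap: {sorted(up & down)[:5]}")
        identified = self.groups.get("identified")
        if identified is not None:
            for name in ("up", "down"):
                g = self.groups.get(name)
                if g is not None and not g <= identified:
                    raise ValueError(f"group {name!r} not contained in 'identified'")
        whole = self.groups.get("whole_genome")
        if whole is not None and identified is not None and not identified <= whole:
            raise ValueError("'identified' not contained in 'whole_genome'")

    def __getitem__(self, name: str) -> set[str]:
        return self.groups[name]

    @property
    def names(self) -> list[str]:
        return list(self.groups)


def assign_groups(
    fc_table: pd.DataFrame,
    up_fc: float = 1.2,
    down_fc: float = 0.83,
    sig_rule: str = "q",
    sig_cut: float = 0.05,
    value_col: str = "protein_fc",
    p_col: str = "protein_p",
    whole_genome: Sequence[str] | None = None,
) -> GeneGroupSet:
    """Partition genes into whole_genome / identified / up / down.

    ``up`` requires fold change > ``up_fc`` and significance; ``down``
    fold change < ``down_fc``.  ``sig_rule='q'`` applies BH over ``p_col``
    first; ``'p'`` thresholds the raw p-value.  ``whole_genome`` defaults
    to the genes in the table; pass the full catalog's gene ids to mirror
    an annotation-wide background.
    """
    if up_fc <= down_fc:
        raise ValueError(f"up_fc must exceed down_fc ({up_fc} <= {down_fc})")
    if sig_rule not in {"q", "p"}:
        raise ValueError("sig_rule must be 'q' or 'p'")
    fc = fc_table[value_col].to_numpy(dtype=float)
    p = fc_table[p_col].to_numpy(dtype=float)
    sig_values = bh_adjust(p) if sig_rule == "q" else p
    significant = sig_values < sig_cut
    genes = fc_table["gene_id"].to_numpy()

    identified = set(genes)
    up = set(genes[(fc > up_fc) & significant])
    down = set(genes[(fc < down_fc) & significant])
    whole = set(whole_genome) | identified if whole_genome is not None else set(identified)
    return GeneGroupSet(
        groups={"whole_genome": whole, "identified": identified, "up": up, "down": down},
        thresholds={
            "up_fc": up_fc,
            "down_fc": down_fc,
            "sig_rule": sig_rule,
            "sig_cut": sig_cut,
        },
    )


@dataclass
class KruskalResult:
    H: float
    p: float
    tie_correction: float
    df: int
    method: str  # 'chi-square' or 'permutation'


def _h_statistic(values: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """Tie-corrected H for pooled values split into consecutive groups."""
    N = values.size
    ranks = stats.rankdata(values)  # mid-ranks for ties
    bounds = np.cumsum(sizes)[:-1]
    h = 0.0
    for grp in np.split(ranks, bounds):
        h += grp.sum() ** 2 / grp.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    if tie == 0.0:  # every value identical
        return 0.0, tie
    return h / tie, tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    permutations: int | None = None,
    seed: int | None = None,
) -> KruskalResult:
    """Kruskal–Wallis omnibus test with mid-rank tie correction.

    p comes from the chi-square reference with k−1 df, or — when
    ``permutations`` is given — from a seeded label permutation (counting
    permuted H ≥ observed H, with the +1 continuity correction).
    Recommended for small groups (any n < 5), where the chi-square
    approximation is rough.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    sizes = np.array([a.size for a in arrays])
    values = np.concatenate(arrays)
    N = values.size
    if N < 3:
        raise ValueError("need at least 3 values in total")
    df = len(arrays) - 1
    h, tie = _h_statistic(values, sizes)
    if tie == 0.0:
        return KruskalResult(0.0, 1.0, tie, df, "degenerate")
    if permutations is None:
        p = float(stats.chi2.sf(h, df)) if h > 0 else 1.0
        return KruskalResult(h, p, tie, df, "chi-square")
    rng = np.random.default_rng(seed)
    hits = 0
    pooled = values.copy()
    for _ in range(permutations):
        rng.shuffle(pooled)
        h_perm, _ = _h_statistic(pooled, sizes)
        if h_perm >= h - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return KruskalResult(h, p, tie, df, "permutation")


@dataclass
class GroupComparison:
    """Distribution summaries per group plus the omnibus test (if ≥2 groups)."""

    feature: str
    summaries: pd.DataFrame  # group, n, min, q1, median, q3, max
    test: KruskalResult | None
    skipped_groups: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# feature\t{self.feature}\n")
            if self.test is not None:
                fh.write(
                    f"# H\t{self.test.H:.6g}\tdf\t{self.test.df}\ttie_correction\t"
                    f"{self.test.tie_correction:.6g}\tp\t{self.test.p:.6g}\tmethod\t{self.test.method}\n"
                )
            self.summaries.to_csv(fh, sep="\t", index=False)


def group_summary(
    groups: GeneGroupSet | Mapping[str, set[str]],
    features: FeatureMatrix | pd.DataFrame,
    feature_name: str,
    group_order: Sequence[str] | None = None,
    permutations: int | None = None,
    seed: int | None = None,
) -> GroupComparison:
    """Summarize one feature's distribution per gene group and test across groups.

    Groups with no genes present in the matrix are skipped with a warning;
    a single remaining group yields summaries only (no test).
    """
    frame = features.values if isinstance(features, FeatureMatrix) else features
    if feature_name not in frame.columns:
        raise KeyError(f"feature {feature_name!r} not in matrix")
    col = frame[feature_name]
    mapping = groups.groups if isinstance(groups, GeneGroupSet) else dict(groups)
    order = list(group_order) if group_order is not None else list(mapping)

    rows, samples, skipped = [], [], []
    for name in order:
        ids = [g for g in mapping[name] if g in col.index]
        if not ids:
            logger.warning("group %r has no genes in the feature matrix; skipped", name)
            skipped.append(name)
            continue
        v = col.loc[ids].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {"group": name, "n": v.size, "min": v.min(), "q1": q1, "median": med, "q3": q3, "max": v.max()}
        )
        samples.append(v)
    if not rows:
        raise ValueError("no group has genes in the feature matrix")
    summaries = pd.DataFrame(rows, columns=["group", "n", "min", "q1", "median", "q3", "max"])
    test = (
        kruskal_wallis(samples, permutations=permutations, seed=seed) if len(samples) >= 2 else None
    )
    return GroupComparison(
        feature=feature_name, summaries=summaries, test=test, skipped_groups=skipped
    )
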