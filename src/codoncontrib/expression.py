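"""Replicate abundance tables → fold changes and differential-expression calls.

Transcript tables are complete FPKM-like matrices; protein reporter-intensity
tables may contain sporadic missing values.  Protein handling follows the
reliability rule for four-replicate TMT designs: a gene is kept only when at
least three of four replicates were observed in every condition, a single
missing value is filled with the mean of the other three, and samples are
then median-normalized.

Differential calls:

* DET — transcript fold change > 2 (or < 1/2) and Benjamini–Hochberg
  q < 0.05, p from a Welch t-test on log2(abundance + 1).
* DEP — protein two-sample t-test p < 0.01 (no FDR), on log2 intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTable",
    "ImputationReport",
    "filter_and_impute_protein",
    "fold_change_rows",
    "fold_change_table",
    "call_dets",
    "call_deps",
    "bh_adjust",
    "FC_COLUMNS",
]

#: Fixed column order of the combined fold-change table.
FC_COLUMNS = [
    "gene_id",
    "contrast",
    "transcript_fc",
    "transcript_p",
    "transcript_q",
    "det",
    "protein_fc",
    "protein_p",
    "dep",
]


@dataclass
class ExpressionTable:
    """Genes × samples abundance matrix with a condition/replicate design."""

    values: pd.DataFrame  # genes × samples; NaN allowed (protein)
    conditions: pd.Series  # sample -> condition label
    replicates: pd.Series  # sample -> replicate index (1-based)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.conditions.index) or list(
            self.values.columns
        ) != list(self.replicates.index):
            raise ValueError("sample ids of values, conditions and replicates disagree")
        counts = self.conditions.value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"conditions with fewer than 2 replicates: {bad}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("negative abundance values")
        self.values.index.name = "gene_id"

    @classmethod
    def from_frame(
        cls, values: pd.DataFrame, conditions: Sequence[str], replicates: Sequence[int] | None = None
    ) -> "ExpressionTable":
        cond = pd.Series(list(conditions), index=values.columns)
        if replicates is None:
            replicates = cond.groupby(cond).cumcount() + 1
        rep = pd.Series(list(replicates), index=values.columns)
        return cls(values=values, conditions=cond, replicates=rep)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        cols = [s for s, c in self.conditions.items() if c == condition]
        if not cols:
            raise ValueError(f"condition {condition!r} not present")
        return cols

    def n_replicates(self, condition: str) -> int:
        return len(self.samples_for(condition))

    # -- IO: TSV with a two-line header (sample ids, condition:replicate) --

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(self.values.columns) + "\n")
            design = [
                f"{self.conditions[s]}:{self.replicates[s]}" for s in self.values.columns
            ]
            fh.write("#design\t" + "\t".join(design) + "\n")
            self.values.to_csv(fh, sep="\t", header=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            design_line = fh.readline().rstrip("\n").split("\t")
            if header[0] != "gene_id" or design_line[0] != "#design":
                raise ValueError(f"{path}: expected 2-line header (gene_id row, #design row)")
            values = pd.read_csv(fh, sep="\t", header=None, names=header, index_col="gene_id")
        conds, reps = [], []
        for item in design_line[1:]:
            c, _, r = item.rpartition(":")
            conds.append(c)
            reps.append(int(r))
        return cls.from_frame(values, conds, reps)


@dataclass
class ImputationReport:
    dropped_genes: dict[str, str] = field(default_factory=dict)
    n_imputed: int = 0
    scale_factors: dict[str, float] = field(default_factory=dict)


def filter_and_impute_protein(
    table: ExpressionTable,
    min_observed: int = 3,
    expected_replicates: int | None = 4,
    normalize: bool = True,
) -> tuple[ExpressionTable, ImputationReport]:
    """Apply the ≥3-of-4 reliability filter, fill single gaps, median-normalize.

    The reliability rule is applied per condition: a gene must have at least
    ``min_observed`` observed replicates in *every* condition to be retained.
    A single missing replicate is replaced by the mean of the observed ones;
    observed values are never altered by imputation.  With ``normalize``,
    every sample is scaled so its median equals the grand median of the
    imputed matrix (standard practice for TMT reporter intensities).
    """
    report = ImputationReport()
    conds = table.condition_names
    if expected_replicates is not None:
        for cond in conds:
            n = table.n_replicates(cond)
            if n != expected_replicates:
                raise ValueError(
                    f"condition {cond!r} has {n} replicates, expected {expected_replicates} "
                    "(pass expected_replicates=None to override)"
                )

    values = table.values.copy()
    keep = pd.Series(True, index=values.index)
    for cond in conds:
        cols = table.samples_for(cond)
        observed = values[cols].notna().sum(axis=1)
        keep &= observed >= min_observed
    for gene in values.index[~keep]:
        report.dropped_genes[gene] = "fewer_than_min_observed_replicates"
    values = values.loc[keep]

    for cond in conds:
        cols = table.samples_for(cond)
        block = values[cols]
        mask = block.isna()
        if mask.to_numpy().any():
            means = block.mean(axis=1)
            filled = block.apply(lambda col: col.fillna(means))
            values[cols] = filled
            report.n_imputed += int(mask.to_numpy().sum())
    assert not values.isna().to_numpy().any()

    if normalize and len(values):
        grand_median = float(np.median(values.to_numpy()))
        for s in values.columns:
            med = float(values[s].median())
            factor = grand_median / med if med > 0 else 1.0
            report.scale_factors[s] = factor
            values[s] = values[s] * factor

    out = ExpressionTable(
        values=values, conditions=table.conditions.copy(), replicates=table.replicates.copy()
    )
    return out, report


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided two-sample t-test p-values; degenerate rows → p = 1."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        # near-identical replicate rows trip scipy's precision-loss warning;
        # those rows are overwritten with p = 1 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (a.mean(axis=1) == b.mean(axis=1))
    p[degenerate] = 1.0
    p[np.isnan(p)] = 1.0
    return p


def fold_change_rows(
    table: ExpressionTable,
    control: str,
    treatment: str,
    log_transform: bool = True,
    equal_var: bool = False,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Per-gene fold change mean(treatment)/mean(control) with a t-test p-value.

    The test runs on log2(abundance + ``log_offset``) when ``log_transform``
    (Welch by default; ``equal_var=True`` for the pooled-variance test).
    Genes that are all-zero in both conditions are excluded and flagged;
    a zero control mean is stabilized by adding half the smallest nonzero
    abundance of the whole table to both means (gene flagged).
    """
    ctrl = table.values[table.samples_for(control)].to_numpy(dtype=float)
    trt = table.values[table.samples_for(treatment)].to_numpy(dtype=float)
    if np.isnan(ctrl).any() or np.isnan(trt).any():
        raise ValueError("missing values present; impute protein tables first")

    mc, mt = ctrl.mean(axis=1), trt.mean(axis=1)
    all_zero = (mc == 0) & (mt == 0)
    zero_ctrl = (mc == 0) & ~all_zero

    nonzero = table.values.to_numpy()[table.values.to_numpy() > 0]
    eps = nonzero.min() / 2 if nonzero.size else 1.0
    mc_adj = np.where(zero_ctrl, mc + eps, mc)
    mt_adj = np.where(zero_ctrl, mt + eps, mt)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mt_adj / mc_adj

    if log_transform:
        p = _two_sample_t(np.log2(trt + log_offset), np.log2(ctrl + log_offset), equal_var)
    else:
        p = _two_sample_t(trt, ctrl, equal_var)

    out = pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "fc": fc,
            "p": p,
            "flag": np.where(all_zero, "all_zero", np.where(zero_ctrl, "zero_control_mean", "")),
        }
    )
    return out[~all_zero].reset_index(drop=True)


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def call_dets(fc: np.ndarray | pd.Series, q: np.ndarray | pd.Series, fc_min: float = 2.0, q_max: float = 0.05) -> np.ndarray:
    """DET flags: |fold change| beyond ``fc_min`` in either direction and q below cutoff."""
    fc = np.asarray(fc, dtype=float)
    q = np.asarray(q, dtype=float)
    return ((fc > fc_min) | (fc < 1.0 / fc_min)) & (q < q_max)


def call_deps(p: np.ndarray | pd.Series, p_max: float = 0.01) -> np.ndarray:
    """DEP flags: protein t-test p below cutoff (no FDR)."""
    return np.asarray(p, dtype=float) < p_max


def fold_change_table(
    transcripts: ExpressionTable,
    proteins: ExpressionTable,
    control: str,
    treatment: str,
    det_fc: float = 2.0,
    det_q: float = 0.05,
    dep_p: float = 0.01,
    protein_equal_var: bool = True,
    protein_log: bool = True,
) -> pd.DataFrame:
    """Combined per-gene fold-change table for one contrast (``FC_COLUMNS`` order).

    Transcript q-values are BH-adjusted over *all* quantified transcripts
    before restricting to genes also present in the protein table, so the
    DET family matches the transcriptome-wide test.
    """
    t_rows = fold_change_rows(transcripts, control, treatment, log_transform=True, equal_var=False)
    t_rows["q"] = bh_adjust(t_rows["p"].to_numpy())
    t_rows["det"] = call_dets(t_rows["fc"], t_rows["q"], det_fc, det_q)

    p_rows = fold_change_rows(
        proteins, control, treatment, log_transform=protein_log, equal_var=protein_equal_var
    )
    p_rows["dep"] = call_deps(p_rows["p"], dep_p)

    merged = t_rows.merge(p_rows, on="gene_id", suffixes=("_t", "_p"), how="inner")
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "contrast": f"{treatment}_vs_{control}",
            "transcript_fc": merged["fc_t"],
            "transcript_p": merged["p_t"],
            "transcript_q": merged["q"],
            "det": merged["det"],
            "protein_fc": merged["fc_p"],
            "protein_p": merged["p_p"],
            "dep": merged["dep"],
        }
    )
    return out[FC_COLUMNS]
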