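"""Sequence-feature registry: codon usage, amino-acid frequency, base/GC composition, lengths.

Features are computed per transcript over its extracted regions and
assembled, together with the transcript fold change, into the genes ×
features design matrix used by the correlation screen and the regression
decomposition.  Codon frequencies are in-frame proportions over the CDS;
codons containing N are excluded from numerator and denominator, and stop
codons count toward codon usage but never toward amino-acid frequencies.

The default registry enumerates 64 codon frequencies, 20 amino-acid
frequencies, 4 base frequencies × 3 regions, GC × 3 regions, length × 3
regions, and the transcript fold change — 103 named features, each tagged
with a category so downstream reports can aggregate (codon usage,
amino-acid frequency, base frequency, GC, length, transcript).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .annotation_io import TranscriptCatalog, TranscriptSequences

__all__ = [
    "CODONS",
    "AMINO_ACIDS",
    "STOP_CODONS",
    "FeatureDescriptor",
    "FeatureMatrix",
    "AssemblyReport",
    "default_registry",
    "codon_counts",
    "codon_frequencies",
    "amino_acid_frequencies",
    "region_composition",
    "build_feature_matrix",
]

BASES = "ACGT"
#: The 64 codons in lexicographic (A<C<G<T) order.
CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product(BASES, repeat=3))

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
#: The 20 amino acids (one-letter, alphabetical).
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(_TABLE.forward_table.values())))

_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
#: codon index -> amino acid index, or -1 for stop codons.
_AA_OF_CODON = np.array(
    [
        AMINO_ACIDS.index(_TABLE.forward_table[c]) if c in _TABLE.forward_table else -1
        for c in CODONS
    ],
    dtype=np.int64,
)

# byte-level base encoding: A,C,G,T -> 0..3; N -> 4; anything else -> 5
_BASE_CODE = np.full(256, 5, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASE_CODE[ord("N")] = 4
_BASE_CODE[ord("n")] = 4

REGIONS = ("cds", "utr5", "utr3")


def _encode(seq: str) -> np.ndarray:
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 5).any():
        bad = seq[int(np.argmax(codes == 5))]
        raise ValueError(f"sequence contains character {bad!r} outside alphabet ACGTN")
    return codes


def codon_counts(cds: str, drop_incomplete: bool = False) -> np.ndarray:
    """In-frame codon counts over the 64 codons (lexicographic order).

    Codons containing N are excluded.  A trailing incomplete codon raises
    ``ValueError`` unless ``drop_incomplete`` is set.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon (length {len(cds)})")
    if len(cds) % 3 != 0:
        if not drop_incomplete:
            raise ValueError(
                f"CDS length {len(cds)} not divisible by 3; "
                "pass drop_incomplete=True to drop the trailing partial codon"
            )
        cds = cds[: len(cds) - len(cds) % 3]
    codes = _encode(cds).reshape(-1, 3)
    valid = (codes < 4).all(axis=1)
    idx = codes[valid] @ np.array([16, 4, 1])
    return np.bincount(idx, minlength=64).astype(np.int64)


def codon_frequencies(cds: str, drop_incomplete: bool = False) -> dict[str, float]:
    """Codon usage frequencies: count(c) / total counted codons, zero-filled over 64."""
    counts = codon_counts(cds, drop_incomplete=drop_incomplete)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no countable codons (all codons contain N)")
    return dict(zip(CODONS, counts / total))


def amino_acid_frequencies(cds: str, drop_incomplete: bool = False) -> dict[str, float]:
    """Amino-acid frequencies under the standard code; stop codons excluded."""
    counts = codon_counts(cds, drop_incomplete=drop_incomplete)
    aa_counts = np.zeros(len(AMINO_ACIDS))
    coding = _AA_OF_CODON >= 0
    np.add.at(aa_counts, _AA_OF_CODON[coding], counts[coding])
    total = aa_counts.sum()
    if total == 0:
        raise ValueError("no coding codons in CDS")
    return dict(zip(AMINO_ACIDS, aa_counts / total))


@dataclass
class RegionComposition:
    """Base/GC composition and raw length of one region.

    Empty (or all-N) regions report NaN frequencies — the matrix assembler
    replaces those with the genome-wide column mean and records the gene as
    region-imputed.
    """

    base_freq: dict[str, float]
    gc: float
    length: int


def region_composition(seq: str) -> RegionComposition:
    length = len(seq)
    if length == 0:
        counts = np.zeros(4)
    else:
        codes = _encode(seq)
        counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        freqs = {b: math.nan for b in BASES}
        gc = math.nan
    else:
        freqs = dict(zip(BASES, counts / total))
        gc = (counts[1] + counts[2]) / total
    return RegionComposition(base_freq=freqs, gc=gc, length=length)


# ---------------------------------------------------------------------------
# Registry and matrix assembly

CATEGORIES = ("transcript", "codon", "amino_acid", "base", "gc", "length")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")


def default_registry() -> list[FeatureDescriptor]:
    """The default 103-feature registry (see module docstring)."""
    reg = [FeatureDescriptor("transcript_fc", "transcript")]
    reg += [FeatureDescriptor(f"codon:{c}", "codon") for c in CODONS]
    reg += [FeatureDescriptor(f"aa:{a}", "amino_acid") for a in AMINO_ACIDS]
    for region in REGIONS:
        reg += [FeatureDescriptor(f"base:{b}:{region}", "base") for b in BASES]
    reg += [FeatureDescriptor(f"gc:{region}", "gc") for region in REGIONS]
    reg += [FeatureDescriptor(f"len:{region}", "length") for region in REGIONS]
    return reg


def category_of(name: str) -> str:
    """Infer a feature's category from its registry name."""
    if name == "transcript_fc":
        return "transcript"
    prefix = name.split(":", 1)[0]
    mapping = {"codon": "codon", "aa": "amino_acid", "base": "base", "gc": "gc", "len": "length"}
    if prefix not in mapping:
        raise ValueError(f"cannot infer category for feature {name!r}")
    return mapping[prefix]


@dataclass
class AssemblyReport:
    """Which genes were dropped or imputed while assembling the matrix."""

    n_candidates: int = 0
    dropped: dict[str, str] = field(default_factory=dict)  # gene -> reason
    imputed_regions: dict[str, list[str]] = field(default_factory=dict)  # region -> genes


@dataclass
class FeatureMatrix:
    """Genes × features design matrix with category-tagged columns."""

    values: pd.DataFrame
    descriptors: list[FeatureDescriptor]
    report: AssemblyReport | None = None

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        if list(self.values.columns) != names:
            raise ValueError("matrix columns do not match registry order")
        self.values.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def category_map(self) -> dict[str, str]:
        return {d.name: d.category for d in self.descriptors}

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    def write_registry(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump([{"name": d.name, "category": d.category} for d in self.descriptors], fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str | Path, registry_path: str | Path | None = None) -> "FeatureMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        if registry_path is not None:
            with open(registry_path) as fh:
                descs = [FeatureDescriptor(d["name"], d["category"]) for d in json.load(fh)]
        else:
            descs = [FeatureDescriptor(n, category_of(n)) for n in values.columns]
        return cls(values=values, descriptors=descs)


def _sequence_feature_row(rec: TranscriptSequences) -> dict[str, float]:
    row: dict[str, float] = {}
    counts = codon_counts(rec.cds)
    total = counts.sum()
    for codon, cnt in zip(CODONS, counts):
        row[f"codon:{codon}"] = cnt / total
    aa = amino_acid_frequencies(rec.cds)
    for a, f in aa.items():
        row[f"aa:{a}"] = f
    for region in REGIONS:
        comp = region_composition(getattr(rec, region))
        for b in BASES:
            row[f"base:{b}:{region}"] = comp.base_freq[b]
        row[f"gc:{region}"] = comp.gc
        row[f"len:{region}"] = comp.length
    return row


def build_feature_matrix(
    catalog: TranscriptCatalog,
    transcript_fc: Mapping[str, float] | pd.Series,
    registry: Iterable[FeatureDescriptor] | None = None,
) -> FeatureMatrix:
    """Assemble the genes × features matrix for genes with sequence and fold change.

    Genes whose CDS is out of frame are dropped (never reach codon-level
    features); genes missing a UTR get that region's base/GC features imputed
    with the column mean over genes that have the region, and length 0.
    """
    registry = list(registry) if registry is not None else default_registry()
    if not registry:
        raise ValueError("empty feature registry")
    if isinstance(transcript_fc, pd.Series):
        transcript_fc = transcript_fc.to_dict()

    report = AssemblyReport()
    by_gene = catalog.by_gene()
    report.n_candidates = len(by_gene)

    rows: dict[str, dict[str, float]] = {}
    for gene_id in sorted(by_gene):
        rec = by_gene[gene_id]
        if gene_id not in transcript_fc:
            report.dropped[gene_id] = "no_transcript_fold_change"
            continue
        if not rec.frame_ok:
            report.dropped[gene_id] = "cds_not_divisible_by_3"
            continue
        row = _sequence_feature_row(rec)
        row["transcript_fc"] = float(transcript_fc[gene_id])
        rows[gene_id] = row
    if not rows:
        raise ValueError("no genes with both sequence features and transcript fold changes")

    frame = pd.DataFrame.from_dict(rows, orient="index")
    # mean-impute composition features of absent regions, record affected genes
    for region in ("utr5", "utr3"):
        probe = f"gc:{region}"
        if probe not in frame.columns:
            continue
        missing = frame[probe].isna()
        if missing.any():
            report.imputed_regions[region] = sorted(frame.index[missing])
            cols = [f"base:{b}:{region}" for b in BASES] + [probe]
            frame[cols] = frame[cols].fillna(frame[cols].mean())
    if frame.isna().any().any():
        # e.g. every gene lacks the region: impute with 0 and record
        bad = frame.columns[frame.isna().any()].tolist()
        frame[bad] = frame[bad].fillna(0.0)
        report.imputed_regions.setdefault("all_genes", bad)  # type: ignore[arg-type]

    names = [d.name for d in registry]
    unknown = [n for n in names if n not in frame.columns]
    if unknown:
        raise ValueError(f"registry names not computable: {unknown}")
    return FeatureMatrix(values=frame[names].copy(), descriptors=registry, report=report)
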