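"""Synthetic transcript catalogs and expression tables with planted structure.

The generator emulates the statistical shape of the study inputs — a
transcript catalog with controlled codon composition (including an
AAG-enriched subset), per-gene transcript fold changes, and replicate
abundance tables whose protein log2 fold changes are a planted
linear-plus-noise function of selected features — and records the ground
truth needed for parameter-recovery tests.

Defaults mirror the study conditions: 3000 genes, standardized planted
effects 0.5 on the transcript fold change and 0.4 on the AAG codon
frequency, noise solved for a target R² of 0.6, three transcript and four
protein replicates per condition, with sporadic protein missingness.

Randomness is one seeded stream split into named substreams (sequences,
transcript fold changes, noise, missingness, annotation) so regenerating
one component never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import TranscriptCatalog, TranscriptSequences, reverse_complement
from .enrichment import AnnotationMap
from .expression import ExpressionTable
from .sequence_features import CODONS, STOP_CODONS, FeatureMatrix, build_feature_matrix

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_catalog",
    "simulate_expression",
    "simulate_annotation",
    "simulate_study",
    "write_study",
    "recovery_report",
    "RecoveryReport",
]

_SENSE = [c for c in CODONS if c not in STOP_CODONS]
_AAG_SENSE_IDX = _SENSE.index("AAG")
_SUBSTREAMS = ("sequences", "transcript_fc", "noise", "missingness", "annotation")


@dataclass
class SimulationSpec:
    """All knobs of the generator; defaults are the study conditions."""

    n_genes: int = 3000
    cds_length_codons: tuple[float, float] = (300.0, 75.0)  # mean, sd; min 10 codons
    codon_weights: Mapping[str, float] | None = None  # sense-codon weights; None = uniform
    aag_boost: tuple[float, float] = (0.10, 0.05)  # (subset fraction, added AAG frequency)
    utr5_length: tuple[float, float] = (120.0, 40.0)
    utr3_length: tuple[float, float] = (250.0, 80.0)
    effect_spec: tuple[tuple[str, float], ...] = (("transcript_fc", 0.5), ("codon:AAG", 0.4))
    transcript_fc_sd: float = 1.0  # sd of planted transcript log2 fold changes (0 = null)
    target_r2: float | None = 0.6
    noise_sd: float | None = None
    transcript_replicates: int = 3
    replicates: int = 4  # protein replicates per condition
    protein_missing_rate: float = 0.10
    conditions: tuple[str, ...] = ("20C", "30C", "40C")
    control: str = "20C"
    replicate_sd_log2: float = 0.25
    transcript_baseline_log2: tuple[float, float] = (4.0, 2.0)
    protein_baseline_log2: tuple[float, float] = (14.0, 1.5)
    explicit_utrs: bool = True
    n_terms: int = 40  # synthetic annotation terms
    term_size: tuple[int, int] = (10, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if (self.target_r2 is None) == (self.noise_sd is None):
            raise ValueError("exactly one of target_r2 and noise_sd must be set")
        if self.target_r2 is not None and not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in (0, 1)")
        if not 0.0 <= self.protein_missing_rate < 1.0:
            raise ValueError("protein_missing_rate must lie in [0, 1)")
        if self.protein_missing_rate * self.replicates > 1.0:
            raise ValueError(
                "protein_missing_rate too high for at most one missing value per gene-condition"
            )
        if self.control not in self.conditions:
            raise ValueError("control must be one of conditions")
        frac, add = self.aag_boost
        if not 0.0 <= frac <= 1.0:
            raise ValueError("aag_boost subset fraction must lie in [0, 1]")
        if self._sense_probs()[_AAG_SENSE_IDX] + add >= 1.0:
            raise ValueError("aag_boost infeasible: boosted AAG probability would reach 1")

    def _sense_probs(self) -> np.ndarray:
        if self.codon_weights is None:
            w = np.ones(len(_SENSE))
        else:
            w = np.array([float(self.codon_weights.get(c, 0.0)) for c in _SENSE])
        total = w.sum()
        if total <= 0:
            raise ValueError("codon weights must sum to a positive value")
        return w / total

    def substreams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["codon_weights"] is not None:
            d["codon_weights"] = dict(d["codon_weights"])
        return d


@dataclass
class GroundTruth:
    """Planted quantities recorded before noise is discarded."""

    betas: dict[str, float]
    noise_sd: dict[str, float]  # per treatment
    realized_r2: dict[str, float]  # per treatment: var(pred)/var(pred + noise)
    boosted_genes: set[str]
    transcript_log2fc: pd.DataFrame  # genes × treatments
    protein_log2fc: pd.DataFrame  # genes × treatments

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "betas": self.betas,
                    "noise_sd": self.noise_sd,
                    "realized_r2": self.realized_r2,
                    "boosted_genes": sorted(self.boosted_genes),
                    "transcript_log2fc": self.transcript_log2fc.to_dict(orient="index"),
                    "protein_log2fc": self.protein_log2fc.to_dict(orient="index"),
                },
                fh,
            )


@dataclass
class SimulatedCatalog:
    catalog: TranscriptCatalog
    genome: dict[str, str]
    gff3_lines: list[str]
    boosted_genes: set[str]


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _sample_codons(rng: np.random.Generator, n: int, cdf: np.ndarray) -> str:
    """Sample n sense codons by inverse-CDF lookup (fast path for big catalogs)."""
    idx = np.minimum(np.searchsorted(cdf, rng.random(n), side="right"), len(_SENSE) - 1)
    return "".join([_SENSE[i] for i in idx])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_catalog(spec: SimulationSpec, rng: np.random.Generator | None = None) -> SimulatedCatalog:
    """Generate transcripts (ATG … stop), one single-exon gene per chromosome.

    Interior codons are drawn from the sense-codon weights; a random subset
    of genes (``aag_boost``) has its interior AAG probability raised by the
    stated increment.  Strands are random, so extraction must
    reverse-complement half the catalog.  UTR bases are uniform.
    """
    rng = rng if rng is not None else spec.substreams()["sequences"]
    probs = spec._sense_probs()
    boosted_probs = probs.copy()
    frac, add = spec.aag_boost
    scale = (1.0 - probs[_AAG_SENSE_IDX] - add) / max(1.0 - probs[_AAG_SENSE_IDX], 1e-12)
    boosted_probs *= scale
    boosted_probs[_AAG_SENSE_IDX] = probs[_AAG_SENSE_IDX] + add
    boosted_probs /= boosted_probs.sum()

    width = len(str(spec.n_genes))
    gene_ids = [f"g{str(i + 1).zfill(width)}" for i in range(spec.n_genes)]
    n_boost = int(round(frac * spec.n_genes))
    boosted = set(rng.choice(gene_ids, size=n_boost, replace=False)) if n_boost else set()

    mean_c, sd_c = spec.cds_length_codons
    n_codons = np.maximum(10, np.round(rng.normal(mean_c, sd_c, spec.n_genes)).astype(int))
    utr5_len = np.maximum(0, np.round(rng.normal(*spec.utr5_length, spec.n_genes)).astype(int))
    utr3_len = np.maximum(0, np.round(rng.normal(*spec.utr3_length, spec.n_genes)).astype(int))
    strands = np.where(rng.random(spec.n_genes) < 0.5, "+", "-")
    stops = tuple(sorted(STOP_CODONS))

    sequences: dict[str, TranscriptSequences] = {}
    genome: dict[str, str] = {}
    gff: list[str] = ["##gff-version 3"]
    pad = 10
    cdf, boosted_cdf = np.cumsum(probs), np.cumsum(boosted_probs)

    for i, gene in enumerate(gene_ids):
        interior = _sample_codons(rng, n_codons[i] - 2, boosted_cdf if gene in boosted else cdf)
        cds = "ATG" + interior + stops[rng.integers(len(stops))]
        utr5 = _random_bases(rng, utr5_len[i])
        utr3 = _random_bases(rng, utr3_len[i])
        tid = f"{gene}.1"
        sequences[tid] = TranscriptSequences(
            transcript_id=tid, gene_id=gene, cds=cds, utr5=utr5, utr3=utr3
        )

        tx = utr5 + cds + utr3
        chrom = f"chr_{gene}"
        strand = strands[i]
        padded = (
            _random_bases(rng, pad)
            + (tx if strand == "+" else reverse_complement(tx))
            + _random_bases(rng, pad)
        )
        genome[chrom] = padded
        a, b = pad + 1, pad + len(tx)
        l5, lc = len(utr5), len(cds)
        if strand == "+":
            u5 = (a, a + l5 - 1)
            cd = (a + l5, a + l5 + lc - 1)
            u3 = (a + l5 + lc, b)
        else:
            u5 = (b - l5 + 1, b)
            cd = (b - l5 - lc + 1, b - l5)
            u3 = (a, b - l5 - lc)

        def row(ftype: str, start: int, end: int, attrs: str) -> str:
            return f"{chrom}\tsim\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"

        gff.append(row("gene", a, b, f"ID={gene}"))
        gff.append(row("mRNA", a, b, f"ID={tid};Parent={gene}"))
        gff.append(row("exon", a, b, f"ID={tid}.exon1;Parent={tid}"))
        if spec.explicit_utrs and l5 > 0:
            gff.append(row("five_prime_UTR", u5[0], u5[1], f"ID={tid}.utr5;Parent={tid}"))
        gff.append(row("CDS", cd[0], cd[1], f"ID={tid}.cds;Parent={tid}"))
        if spec.explicit_utrs and len(utr3) > 0:
            gff.append(row("three_prime_UTR", u3[0], u3[1], f"ID={tid}.utr3;Parent={tid}"))

    catalog = TranscriptCatalog(
        sequences=sequences,
        provenance={"source": "simulation", "seed": spec.seed, "n_transcripts": len(sequences)},
    )
    return SimulatedCatalog(catalog=catalog, genome=genome, gff3_lines=gff, boosted_genes=boosted)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _replicate_block(
    rng: np.random.Generator,
    baseline: np.ndarray,
    log2fc: np.ndarray,
    n_reps: int,
    sd: float,
) -> np.ndarray:
    n = baseline.size
    noise = rng.normal(0.0, sd, size=(n, n_reps))
    return baseline[:, None] * 2.0 ** (log2fc[:, None] + noise)


def simulate_expression(
    sim: SimulatedCatalog,
    spec: SimulationSpec,
    rngs: Mapping[str, np.random.Generator] | None = None,
    features: FeatureMatrix | None = None,
) -> tuple[ExpressionTable, ExpressionTable, GroundTruth]:
    """Replicate abundance tables with planted protein effects.

    Per treatment, transcript log2 fold changes are N(0, 1); the protein
    log2 fold change is Σ β_j · z(feature_j) + ε with ε solved from
    ``target_r2`` (or fixed at ``noise_sd``).  Replicates multiply a
    log-normal baseline by 2^(condition effect) and log-normal replicate
    noise; protein entries go missing completely at random, at most one
    per gene-condition.
    """
    rngs = rngs if rngs is not None else spec.substreams()
    rng_fc, rng_noise, rng_miss = rngs["transcript_fc"], rngs["noise"], rngs["missingness"]
    genes = sorted({rec.gene_id for rec in sim.catalog})
    n = len(genes)
    treatments = [c for c in spec.conditions if c != spec.control]

    t_log2fc = pd.DataFrame(
        rng_fc.normal(0.0, spec.transcript_fc_sd, size=(n, len(treatments))),
        index=genes, columns=treatments,
    )

    betas = dict((name, float(b)) for name, b in spec.effect_spec)
    seq_effect_names = [f for f in betas if f != "transcript_fc"]
    if seq_effect_names:
        if features is None:
            fc0 = pd.Series(1.0, index=genes)  # placeholder; sequence features only
            features = build_feature_matrix(sim.catalog, fc0)
        missing = [f for f in seq_effect_names if f not in features.values.columns]
        if missing:
            raise ValueError(f"effect features not in the registry: {missing}")
        seq_z = {f: _zscore(features.values[f].reindex(genes).to_numpy()) for f in seq_effect_names}
    else:
        seq_z = {}

    p_log2fc = {}
    noise_sds, realized = {}, {}
    for trt in treatments:
        pred = np.zeros(n)
        for name, b in betas.items():
            z = _zscore(2.0 ** t_log2fc[trt].to_numpy()) if name == "transcript_fc" else seq_z[name]
            pred += b * z
        if spec.noise_sd is not None:
            sd = spec.noise_sd
        else:
            r2 = spec.target_r2
            sd = float(pred.std() * np.sqrt((1.0 - r2) / r2)) if pred.std() > 0 else 1.0
        eps = rng_noise.normal(0.0, sd, size=n)
        y = pred + eps
        var_y = y.var()
        noise_sds[trt] = sd
        realized[trt] = float(pred.var() / var_y) if var_y > 0 else 0.0
        p_log2fc[trt] = y
    p_log2fc = pd.DataFrame(p_log2fc, index=genes, columns=treatments)

    # transcript table
    t_base = 2.0 ** rng_noise.normal(*spec.transcript_baseline_log2, size=n)
    t_cols, t_conds, t_vals = [], [], []
    for cond in spec.conditions:
        fc = np.zeros(n) if cond == spec.control else t_log2fc[cond].to_numpy()
        block = _replicate_block(rng_noise, t_base, fc, spec.transcript_replicates, spec.replicate_sd_log2)
        for r in range(spec.transcript_replicates):
            t_cols.append(f"T_{cond}_r{r + 1}")
            t_conds.append(cond)
            t_vals.append(block[:, r])
    transcripts = ExpressionTable.from_frame(
        pd.DataFrame(dict(zip(t_cols, t_vals)), index=genes), t_conds
    )

    # protein table with MCAR missingness (≤ 1 per gene-condition)
    p_base = 2.0 ** rng_noise.normal(*spec.protein_baseline_log2, size=n)
    p_cols, p_conds, blocks = [], [], []
    group_rate = spec.protein_missing_rate * spec.replicates
    for cond in spec.conditions:
        fc = np.zeros(n) if cond == spec.control else p_log2fc[cond].to_numpy()
        block = _replicate_block(rng_noise, p_base, fc, spec.replicates, spec.replicate_sd_log2)
        if group_rate > 0:
            hit = rng_miss.random(n) < group_rate
            which = rng_miss.integers(0, spec.replicates, size=n)
            block[np.arange(n)[hit], which[hit]] = np.nan
        for r in range(spec.replicates):
            p_cols.append(f"P_{cond}_r{r + 1}")
            p_conds.append(cond)
        blocks.append(block)
    proteins = ExpressionTable.from_frame(
        pd.DataFrame(np.column_stack(blocks), index=genes, columns=p_cols), p_conds
    )

    truth = GroundTruth(
        betas=betas,
        noise_sd=noise_sds,
        realized_r2=realized,
        boosted_genes=set(sim.boosted_genes),
        transcript_log2fc=t_log2fc,
        protein_log2fc=p_log2fc,
    )
    return transcripts, proteins, truth


def simulate_annotation(
    sim: SimulatedCatalog, spec: SimulationSpec, rng: np.random.Generator | None = None
) -> AnnotationMap:
    """Random annotation terms plus one term concentrated on the boosted genes."""
    rng = rng if rng is not None else spec.substreams()["annotation"]
    genes = sorted({rec.gene_id for rec in sim.catalog})
    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    lo, hi = spec.term_size
    for i in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        term = f"T{str(i + 1).zfill(4)}"
        terms[term] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        labels[term] = f"random term {i + 1}"
    if sim.boosted_genes:
        terms["T_BOOST"] = set(sim.boosted_genes)
        labels["T_BOOST"] = "planted AAG-enriched subset"
    return AnnotationMap(terms=terms, labels=labels)


@dataclass
class SimulatedStudy:
    spec: SimulationSpec
    catalog_sim: SimulatedCatalog
    transcripts: ExpressionTable
    proteins: ExpressionTable
    truth: GroundTruth
    annotation: AnnotationMap

    @property
    def catalog(self) -> TranscriptCatalog:
        return self.catalog_sim.catalog


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Run the full generator: catalog, expression tables, annotation, truth."""
    rngs = spec.substreams()
    sim = simulate_catalog(spec, rngs["sequences"])
    transcripts, proteins, truth = simulate_expression(sim, spec, rngs)
    annotation = simulate_annotation(sim, spec, rngs["annotation"])
    return SimulatedStudy(
        spec=spec,
        catalog_sim=sim,
        transcripts=transcripts,
        proteins=proteins,
        truth=truth,
        annotation=annotation,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annot.gff3, transcripts.tsv, proteins.tsv, annotations.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gff3": outdir / "annot.gff3",
        "transcripts": outdir / "transcripts.tsv",
        "proteins": outdir / "proteins.tsv",
        "annotation": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(study.catalog_sim.genome):
            seq = study.catalog_sim.genome[chrom]
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("\n".join(study.catalog_sim.gff3_lines) + "\n")
    study.transcripts.to_tsv(paths["transcripts"])
    study.proteins.to_tsv(paths["proteins"])
    study.annotation.to_tsv(paths["annotation"])
    study.truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Recovery report


@dataclass
class RecoveryReport:
    """Machine-readable verdicts of the planted-effect recovery checks."""

    checks: dict[str, bool | None]  # None = not applicable
    details: dict[str, str]

    @property
    def all_passed(self) -> bool:
        return all(v is not False for v in self.checks.values())


def recovery_report(
    truth: GroundTruth,
    contribution,
    correlations: pd.DataFrame,
    treatment: str,
    explained_tol_pct: float = 10.0,
) -> RecoveryReport:
    """Check a fitted contribution analysis against the planted ground truth.

    (a) planted features rank among the top-|effects| contributors;
    (b) correlation signs match the planted betas;
    (c) estimated total explained % within ``explained_tol_pct`` points of
        the realized R²·100.
    """
    checks: dict[str, bool | None] = {}
    details: dict[str, str] = {}

    planted = {f: b for f, b in truth.betas.items() if b != 0.0}
    if planted:
        top = contribution.top_features(len(planted))
        checks["planted_features_rank_top"] = set(planted) == set(top)
        details["planted_features_rank_top"] = f"top contributors: {top}"
    else:
        checks["planted_features_rank_top"] = None
        details["planted_features_rank_top"] = "no nonzero planted effects"

    corr = correlations.set_index("feature")
    sign_ok = True
    for f, b in planted.items():
        r = float(corr.loc[f, "r"])
        if np.sign(r) != np.sign(b):
            sign_ok = False
    checks["correlation_signs_match"] = sign_ok if planted else True
    details["correlation_signs_match"] = ", ".join(
        f"{f}: r={float(corr.loc[f, 'r']):.3f} (beta {b:+.2f})" for f, b in planted.items()
    )

    realized_pct = truth.realized_r2[treatment] * 100.0
    gap = abs(contribution.total_explained_pct - realized_pct)
    checks["explained_variance_recovered"] = gap <= explained_tol_pct
    details["explained_variance_recovered"] = (
        f"estimated {contribution.total_explained_pct:.1f}% vs realized {realized_pct:.1f}% "
        f"(gap {gap:.1f} pp)"
    )
    return RecoveryReport(checks=checks, details=details)
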