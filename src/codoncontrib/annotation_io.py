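"""Read FASTA + GFF3 annotation and extract spliced, strand-correct transcript regions.

The unit of downstream analysis is a transcript model: the coding sequence
(CDS) plus its flanking untranslated regions (5'UTR, 3'UTR), spliced in
transcript orientation so position 1 is always the 5' end.  Coordinates are
GFF3-style 1-based inclusive throughout.

GFF3 dialects differ in whether UTRs are annotated explicitly
(``five_prime_UTR``/``three_prime_UTR`` rows) or must be inferred as the
exonic region outside the CDS; both are supported.  When a gene carries
several transcript isoforms, the longest-CDS isoform represents the gene by
default (``collapse="longest_cds"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "TranscriptSequences",
    "TranscriptCatalog",
    "Gff3Error",
    "load_catalog",
    "infer_utrs",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: GFF3 feature types treated as transcript containers.
_TRANSCRIPT_TYPES = frozenset({"mRNA", "transcript"})


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Gff3Error(ValueError):
    """Raised for structurally invalid GFF3 input."""


Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """Interval-level description of one transcript on the genome.

    Intervals are 1-based inclusive and stored sorted 5'→3' in transcript
    orientation: ascending genomic coordinates on the + strand, descending
    on the − strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[Interval]
    utr5_intervals: list[Interval] = field(default_factory=list)
    utr3_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.cds_intervals:
            raise ValueError(f"transcript {self.transcript_id}: no CDS intervals")
        for name in ("cds_intervals", "utr5_intervals", "utr3_intervals"):
            setattr(self, name, _orient(getattr(self, name), self.strand))

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)


def _orient(intervals: Iterable[Interval], strand: str) -> list[Interval]:
    """Sort intervals 5'→3' in transcript orientation, checking for overlap."""
    ivs = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if e1 < s1 or e2 < s2:
            raise ValueError(f"malformed interval in {ivs}")
        if s2 <= e1:
            raise ValueError(f"overlapping intervals {(s1, e1)} and {(s2, e2)}")
    return ivs[::-1] if strand == "-" else ivs


@dataclass
class TranscriptSequences:
    """Extracted sequences for one transcript; position 1 is the 5' end."""

    transcript_id: str
    gene_id: str
    cds: str
    utr5: str = ""
    utr3: str = ""

    @property
    def frame_ok(self) -> bool:
        """True when the CDS length is divisible by 3 (usable for codon counts)."""
        return len(self.cds) % 3 == 0


@dataclass
class TranscriptCatalog:
    """Mapping transcript_id → TranscriptSequences with provenance."""

    sequences: dict[str, TranscriptSequences]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, rec in self.sequences.items():
            if tid != rec.transcript_id:
                raise ValueError(f"catalog key {tid!r} != record id {rec.transcript_id!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[TranscriptSequences]:
        return iter(self.sequences.values())

    def __getitem__(self, transcript_id: str) -> TranscriptSequences:
        return self.sequences[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.sequences

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def gene_ids(self) -> list[str]:
        return [rec.gene_id for rec in self]

    def by_gene(self) -> dict[str, TranscriptSequences]:
        """gene_id → record; requires one transcript per gene (post-collapse)."""
        out: dict[str, TranscriptSequences] = {}
        for rec in self:
            if rec.gene_id in out:
                raise ValueError(
                    f"gene {rec.gene_id} has multiple transcripts; collapse the catalog first"
                )
            out[rec.gene_id] = rec
        return out

    def flagged_ids(self) -> list[str]:
        """Transcripts whose CDS length is not divisible by 3."""
        return [rec.transcript_id for rec in self if not rec.frame_ok]

    def write_region_fasta(self, region: str, path: str | Path) -> None:
        """Write one region ('cds', 'utr5' or 'utr3') as FASTA; empty regions skipped."""
        if region not in {"cds", "utr5", "utr3"}:
            raise ValueError(f"unknown region {region!r}")
        with open(path, "w") as fh:
            for rec in self:
                seq = getattr(rec, region)
                if seq:
                    fh.write(f">{rec.transcript_id}\n{seq}\n")

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tgene_id\tcds_len\tutr5_len\tutr3_len\tflag\n")
            for rec in self:
                flag = "" if rec.frame_ok else "cds_not_divisible_by_3"
                fh.write(
                    f"{rec.transcript_id}\t{rec.gene_id}\t{len(rec.cds)}"
                    f"\t{len(rec.utr5)}\t{len(rec.utr3)}\t{flag}\n"
                )


# ---------------------------------------------------------------------------
# GFF3 parsing


def _parse_attributes(col: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise Gff3Error(f"GFF3 line {lineno}: malformed attribute {item!r}")
        key, _, value = item.partition("=")
        attrs[key] = value
    return attrs


@dataclass
class _RawFeature:
    seqid: str
    ftype: str
    start: int
    end: int
    strand: str
    attrs: dict[str, str]
    lineno: int


def _read_gff3(path: str | Path) -> list[_RawFeature]:
    feats: list[_RawFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##FASTA"):
                break
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3Error(f"GFF3 line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_col = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise Gff3Error(f"GFF3 line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from exc
            if end < start:
                raise Gff3Error(f"GFF3 line {lineno}: end < start ({end} < {start})")
            feats.append(_RawFeature(seqid, ftype, start, end, strand, _parse_attributes(attr_col, lineno), lineno))
    return feats


def infer_utrs(model: TranscriptModel, exon_intervals: list[Interval]) -> TranscriptModel:
    """Fill UTR intervals from exon structure: exonic region outside the CDS.

    The exonic region 5' of the CDS (in transcript orientation) becomes the
    5'UTR, the region 3' of it the 3'UTR.  Raises ``ValueError`` when the CDS
    is not contained in the exons.
    """
    exons = sorted(exon_intervals)
    cds_lo = min(s for s, _ in model.cds_intervals)
    cds_hi = max(e for _, e in model.cds_intervals)
    for s, e in model.cds_intervals:
        if not any(es <= s and e <= ee for es, ee in exons):
            raise ValueError(
                f"transcript {model.transcript_id}: CDS interval ({s},{e}) not contained in exons"
            )
    left: list[Interval] = []
    right: list[Interval] = []
    for s, e in exons:
        if e < cds_lo:
            left.append((s, e))
        elif s < cds_lo:
            left.append((s, cds_lo - 1))
        if s > cds_hi:
            right.append((s, e))
        elif e > cds_hi:
            right.append((cds_hi + 1, e))
    if model.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    return replace(model, utr5_intervals=utr5, utr3_intervals=utr3)


def _splice(genome: Mapping[str, str], model: TranscriptModel, intervals: list[Interval]) -> str:
    chrom_seq = genome[model.chrom]
    parts = []
    for s, e in intervals:
        if e > len(chrom_seq):
            raise Gff3Error(
                f"transcript {model.transcript_id}: interval ({s},{e}) exceeds "
                f"sequence {model.chrom} of length {len(chrom_seq)}"
            )
        piece = chrom_seq[s - 1 : e]
        parts.append(reverse_complement(piece) if model.strand == "-" else piece)
    return "".join(parts)


def extract_sequences(genome: Mapping[str, str], model: TranscriptModel) -> TranscriptSequences:
    """Splice CDS and UTR sequences for one transcript model."""
    if model.chrom not in genome:
        raise Gff3Error(
            f"sequence {model.chrom!r} (needed by transcript {model.transcript_id}) missing from FASTA"
        )
    return TranscriptSequences(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        cds=_splice(genome, model, model.cds_intervals),
        utr5=_splice(genome, model, model.utr5_intervals),
        utr3=_splice(genome, model, model.utr3_intervals),
    )


def build_transcript_models(
    features: list[_RawFeature], id_attribute: str = "ID"
) -> list[TranscriptModel]:
    """Assemble TranscriptModels from raw GFF3 features.

    CDS/exon/UTR rows link to their transcript through ``Parent``; transcript
    rows link to their gene the same way.  Transcripts with no annotated UTRs
    but with exon rows get UTRs inferred from exon-minus-CDS.
    """
    tx_gene: dict[str, str] = {}
    per_tx: dict[str, dict[str, list[Interval]]] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # tid -> (chrom, strand)

    for feat in features:
        if feat.ftype in _TRANSCRIPT_TYPES:
            tid = feat.attrs.get(id_attribute)
            if tid is None:
                raise Gff3Error(
                    f"GFF3 line {feat.lineno}: transcript row lacks attribute {id_attribute!r}"
                )
            tx_gene[tid] = feat.attrs.get("Parent", tid)
        elif feat.ftype in {"CDS", "exon", "five_prime_UTR", "three_prime_UTR"}:
            parent = feat.attrs.get("Parent") or feat.attrs.get(id_attribute)
            if parent is None:
                raise Gff3Error(f"GFF3 line {feat.lineno}: {feat.ftype} row lacks Parent")
            for tid in parent.split(","):
                bucket = per_tx.setdefault(tid, {})
                bucket.setdefault(feat.ftype, []).append((feat.start, feat.end))
                known = tx_meta.setdefault(tid, (feat.seqid, feat.strand))
                if known != (feat.seqid, feat.strand):
                    raise Gff3Error(
                        f"GFF3 line {feat.lineno}: transcript {tid} mixes seqid/strand "
                        f"{known} and {(feat.seqid, feat.strand)}"
                    )

    models: list[TranscriptModel] = []
    for tid, bucket in per_tx.items():
        if "CDS" not in bucket:
            continue
        chrom, strand = tx_meta[tid]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=tx_gene.get(tid, tid),
            chrom=chrom,
            strand=strand,
            cds_intervals=bucket["CDS"],
            utr5_intervals=bucket.get("five_prime_UTR", []),
            utr3_intervals=bucket.get("three_prime_UTR", []),
        )
        if not model.utr5_intervals and not model.utr3_intervals and "exon" in bucket:
            model = infer_utrs(model, bucket["exon"])
        models.append(model)
    return models


def _collapse_longest_cds(models: list[TranscriptModel]) -> list[TranscriptModel]:
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        # deterministic: longer CDS wins, ties by lexicographically smaller id
        if cur is None or (m.cds_length, _neg_id(m)) > (cur.cds_length, _neg_id(cur)):
            best[m.gene_id] = m
    return list(best.values())


def _neg_id(m: TranscriptModel):
    return tuple(-ord(c) for c in m.transcript_id)


def load_catalog(
    fasta_path: str | Path,
    gff3_path: str | Path,
    id_attribute: str = "ID",
    collapse: str | None = "longest_cds",
) -> TranscriptCatalog:
    """Load genome FASTA + GFF3 and return extracted transcript sequences.

    Parameters
    ----------
    id_attribute
        Attribute naming transcript rows (``Parent`` links children); some
        annotation dialects use e.g. ``transcript_id``.
    collapse
        ``"longest_cds"`` keeps one isoform per gene (longest CDS, ties by
        transcript id); ``None`` keeps every transcript.
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    features = _read_gff3(gff3_path)
    models = build_transcript_models(features, id_attribute=id_attribute)
    if collapse == "longest_cds":
        models = _collapse_longest_cds(models)
    elif collapse is not None:
        raise ValueError(f"unknown collapse mode {collapse!r}")

    sequences: dict[str, TranscriptSequences] = {}
    for model in sorted(models, key=lambda m: m.transcript_id):
        sequences[model.transcript_id] = extract_sequences(genome, model)
    if not sequences:
        raise Gff3Error(f"no transcripts with CDS features found in {gff3_path}")

    n_flagged = sum(1 for r in sequences.values() if not r.frame_ok)
    if n_flagged:
        logger.warning("%d transcripts have CDS length not divisible by 3", n_flagged)
    return TranscriptCatalog(
        sequences=sequences,
        provenance={
            "fasta": str(fasta_path),
            "gff3": str(gff3_path),
            "n_transcripts": len(sequences),
            "n_flagged": n_flagged,
            "collapse": collapse,
        },
    )
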