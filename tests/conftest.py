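"""Shared fixtures: hand-built micro annotations and a small simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from codoncontrib.synthetic_data import SimulationSpec, simulate_study, write_study


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A scaled-down study: 150 genes, short CDSs, defaults otherwise."""
    return SimulationSpec(n_genes=150, cds_length_codons=(80.0, 10.0), seed=7)


@pytest.fixture(scope="session")
def small_study(small_spec):
    return simulate_study(small_spec)


@pytest.fixture(scope="session")
def small_study_dir(small_study, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    write_study(small_study, outdir)
    return outdir


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def write_micro_genome(tmp_path, genome: str = "CCATGAAGAAATGACC", strand: str = "+",
                       explicit_utrs: bool = True):
    """One single-exon gene: CDS 3..14, UTRs 1..2 and 15..16 on a 16 bp contig."""
    fasta = tmp_path / "micro.fa"
    fasta.write_text(f">chr1\n{genome}\n")
    rows = [
        "##gff-version 3",
        f"chr1\ttest\tgene\t1\t16\t.\t{strand}\t.\tID=geneA",
        f"chr1\ttest\tmRNA\t1\t16\t.\t{strand}\t.\tID=mrnaA;Parent=geneA",
        f"chr1\ttest\texon\t1\t16\t.\t{strand}\t.\tID=exonA;Parent=mrnaA",
        f"chr1\ttest\tCDS\t3\t14\t.\t{strand}\t.\tID=cdsA;Parent=mrnaA",
    ]
    if explicit_utrs:
        five = (1, 2) if strand == "+" else (15, 16)
        three = (15, 16) if strand == "+" else (1, 2)
        rows.insert(4, f"chr1\ttest\tfive_prime_UTR\t{five[0]}\t{five[1]}\t.\t{strand}\t.\tID=u5;Parent=mrnaA")
        rows.append(f"chr1\ttest\tthree_prime_UTR\t{three[0]}\t{three[1]}\t.\t{strand}\t.\tID=u3;Parent=mrnaA")
    gff = tmp_path / "micro.gff3"
    gff.write_text("\n".join(rows) + "\n")
    return fasta, gff
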