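"""Codon/amino-acid/base frequency computation and matrix assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from codoncontrib.sequence_features import (
    AMINO_ACIDS,
    CODONS,
    STOP_CODONS,
    FeatureMatrix,
    amino_acid_frequencies,
    build_feature_matrix,
    codon_frequencies,
    default_registry,
    region_composition,
)
from codoncontrib.synthetic_data import SimulationSpec, simulate_catalog


def brute_force_codon_freq(cds: str) -> dict[str, float]:
    """Independent oracle: slide a window in steps of 3 and count."""
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    counted = [c for c in codons if "N" not in c]
    return {c: counted.count(c) / len(counted) for c in CODONS}


def brute_force_aa_freq(cds: str) -> dict[str, float]:
    """Independent oracle: translate with biopython, then count letters."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3) if "N" not in cds[i : i + 3]]
    aa = "".join(str(Seq(c).translate()) for c in codons).replace("*", "")
    return {a: aa.count(a) / len(aa) for a in AMINO_ACIDS}


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    sense = [c for c in CODONS if c not in STOP_CODONS]
    body = "".join(rng.choice(sense, size=n_codons - 2))
    return "ATG" + body + "TAA"


class TestCodonFrequencies:
    def test_four_distinct_codons(self):
        freqs = codon_frequencies("ATGAAGAAATGA")
        expect = {"ATG": 0.25, "AAG": 0.25, "AAA": 0.25, "TGA": 0.25}
        for codon in CODONS:
            assert freqs[codon] == pytest.approx(expect.get(codon, 0.0))

    def test_homogeneous_sequence(self):
        assert codon_frequencies("AAGAAGAAG")["AAG"] == 1.0

    def test_codons_with_n_excluded_everywhere(self):
        freqs = codon_frequencies("ATGNNNAAG")
        assert freqs["ATG"] == 0.5 and freqs["AAG"] == 0.5
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_incomplete_frame_raises_unless_dropping_enabled(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            codon_frequencies("ATGAA")
        assert codon_frequencies("ATGAA", drop_incomplete=True)["ATG"] == 1.0

    def test_matches_brute_force_oracle_on_random_sequences(self, rng):
        for _ in range(10):
            cds = random_cds(rng, 300)
            freqs = codon_frequencies(cds)
            oracle = brute_force_codon_freq(cds)
            for codon in CODONS:
                assert freqs[codon] == pytest.approx(oracle[codon], abs=0)


class TestAminoAcidFrequencies:
    def test_stop_excluded_from_denominator(self):
        freqs = amino_acid_frequencies("ATGAAGAAATGA")
        assert freqs["M"] == pytest.approx(1 / 3)
        assert freqs["K"] == pytest.approx(2 / 3)

    def test_lysine_only(self):
        assert amino_acid_frequencies("AAAAAGAAAAAG")["K"] == 1.0

    def test_matches_translate_then_count_oracle(self, rng):
        for _ in range(10):
            cds = random_cds(rng, 120)
            freqs = amino_acid_frequencies(cds)
            oracle = brute_force_aa_freq(cds)
            for aa in AMINO_ACIDS:
                assert freqs[aa] == pytest.approx(oracle[aa], abs=1e-12)


class TestRegionComposition:
    def test_all_c(self):
        comp = region_composition("CC")
        assert comp.base_freq["C"] == 1.0 and comp.gc == 1.0 and comp.length == 2

    def test_uniform(self):
        comp = region_composition("ACGT")
        assert all(comp.base_freq[b] == 0.25 for b in "ACGT")
        assert comp.gc == 0.5

    def test_empty_sequence_gives_nan_sentinel(self):
        comp = region_composition("")
        assert math.isnan(comp.gc) and comp.length == 0

    def test_n_excluded_from_frequencies_but_not_length(self):
        comp = region_composition("ANNG")
        assert comp.base_freq["A"] == 0.5 and comp.base_freq["G"] == 0.5
        assert comp.length == 4

    def test_matches_counting_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        comp = region_composition(seq)
        for b in "ACGT":
            assert comp.base_freq[b] == pytest.approx(seq.count(b) / 500, abs=0)
        assert comp.gc == pytest.approx((seq.count("G") + seq.count("C")) / 500)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=60), st.integers(min_value=0, max_value=2**31 - 1))
def test_frequency_blocks_sum_to_one(n_codons, seed):
    """Codon and amino-acid frequencies are proper distributions for any CDS."""
    rng = np.random.default_rng(seed)
    cds = random_cds(rng, max(n_codons, 3))
    assert sum(codon_frequencies(cds).values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(amino_acid_frequencies(cds).values()) == pytest.approx(1.0, abs=1e-9)


def test_lysine_codon_identity(rng):
    """AAG + AAA codon mass equals K frequency × (coding codons / counted codons)."""
    for _ in range(5):
        cds = random_cds(rng, 200)
        cf = codon_frequencies(cds)
        af = amino_acid_frequencies(cds)
        counted = len(cds) // 3
        coding = counted - sum(
            1 for i in range(0, len(cds), 3) if cds[i : i + 3] in STOP_CODONS
        )
        assert cf["AAG"] + cf["AAA"] == pytest.approx(af["K"] * coding / counted, abs=1e-12)


class TestBuildFeatureMatrix:
    def test_registry_order_and_normalization(self, small_study):
        fc = {rec.gene_id: 1.5 for rec in small_study.catalog}
        fm = build_feature_matrix(small_study.catalog, fc)
        assert fm.feature_names == [d.name for d in default_registry()]
        codon_cols = [c for c in fm.feature_names if c.startswith("codon:")]
        aa_cols = [c for c in fm.feature_names if c.startswith("aa:")]
        assert np.allclose(fm.values[codon_cols].sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(fm.values[aa_cols].sum(axis=1), 1.0, atol=1e-9)
        for region in ("cds", "utr5", "utr3"):
            cols = [f"base:{b}:{region}" for b in "ACGT"]
            assert np.allclose(fm.values[cols].sum(axis=1), 1.0, atol=1e-9)

    def test_gene_without_utr_imputed_and_retained(self, tmp_path):
        spec = SimulationSpec(n_genes=40, cds_length_codons=(30.0, 3.0),
                              utr5_length=(2.0, 5.0), seed=5)
        sim = simulate_catalog(spec)
        fc = {rec.gene_id: 1.0 for rec in sim.catalog}
        fm = build_feature_matrix(sim.catalog, fc)
        no_utr5 = [rec.gene_id for rec in sim.catalog if len(rec.utr5) == 0]
        assert no_utr5, "spec should produce genes without a 5'UTR"
        assert not fm.values.isna().any().any()
        assert set(fm.report.imputed_regions.get("utr5", [])) == set(no_utr5)
        # imputed value is the mean over genes that have the region
        have = fm.values.drop(index=no_utr5)
        assert fm.values.loc[no_utr5[0], "gc:utr5"] == pytest.approx(have["gc:utr5"].mean())
        assert fm.values.loc[no_utr5[0], "len:utr5"] == 0

    def test_planted_aag_boost_visible_in_matrix(self):
        spec = SimulationSpec(n_genes=400, cds_length_codons=(200.0, 20.0),
                              aag_boost=(0.2, 0.05), seed=9)
        sim = simulate_catalog(spec)
        fc = {rec.gene_id: 1.0 for rec in sim.catalog}
        fm = build_feature_matrix(sim.catalog, fc)
        boosted = sorted(sim.boosted_genes)
        rest = [g for g in fm.gene_ids if g not in sim.boosted_genes]
        margin = fm.values.loc[boosted, "codon:AAG"].mean() - fm.values.loc[rest, "codon:AAG"].mean()
        assert margin == pytest.approx(0.05, abs=0.01)

    def test_out_of_frame_genes_never_reach_codon_features(self, small_study):
        cat = small_study.catalog
        # corrupt one transcript to be out of frame
        import copy

        cat2 = copy.deepcopy(cat)
        tid = cat2.transcript_ids[0]
        rec = cat2.sequences[tid]
        rec.cds = rec.cds + "A"
        fc = {r.gene_id: 1.0 for r in cat2}
        fm = build_feature_matrix(cat2, fc)
        assert rec.gene_id not in fm.gene_ids
        assert fm.report.dropped[rec.gene_id] == "cds_not_divisible_by_3"

    def test_no_overlap_is_hard_error(self, small_study):
        with pytest.raises(ValueError, match="no genes"):
            build_feature_matrix(small_study.catalog, {"absent_gene": 1.0})

    def test_row_order_independent_of_catalog_order(self, small_study):
        from codoncontrib.annotation_io import TranscriptCatalog

        cat = small_study.catalog
        reversed_cat = TranscriptCatalog(
            sequences=dict(reversed(list(cat.sequences.items()))), provenance={}
        )
        fc = {rec.gene_id: 2.0 for rec in cat}
        a = build_feature_matrix(cat, fc)
        b = build_feature_matrix(reversed_cat, fc)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_tsv_round_trip(self, small_study, tmp_path):
        fc = {rec.gene_id: 1.0 for rec in small_study.catalog}
        fm = build_feature_matrix(small_study.catalog, fc)
        fm.to_tsv(tmp_path / "f.tsv")
        fm.write_registry(tmp_path / "r.json")
        back = FeatureMatrix.from_tsv(tmp_path / "f.tsv", tmp_path / "r.json")
        pd.testing.assert_frame_equal(fm.values, back.values)
        assert back.category_map == fm.category_map
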