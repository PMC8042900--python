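"""Generator self-checks: reproducibility, planted composition, target R²."""

import numpy as np
import pandas as pd
import pytest

from codoncontrib.association import ContributionReport
from codoncontrib.sequence_features import build_feature_matrix, codon_frequencies
from codoncontrib.synthetic_data import (
    SimulationSpec,
    recovery_report,
    simulate_catalog,
    simulate_expression,
    simulate_study,
    write_study,
)


class TestSpecValidation:
    def test_exactly_one_noise_specification(self):
        with pytest.raises(ValueError, match="target_r2"):
            SimulationSpec(target_r2=0.6, noise_sd=0.5)
        with pytest.raises(ValueError, match="target_r2"):
            SimulationSpec(target_r2=None, noise_sd=None)
        with pytest.raises(ValueError, match="target_r2"):
            SimulationSpec(target_r2=1.2)

    def test_infeasible_boost_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationSpec(aag_boost=(0.1, 1.0))

    def test_missing_rate_bounded_by_one_gap_rule(self):
        with pytest.raises(ValueError, match="missing"):
            SimulationSpec(protein_missing_rate=0.3)  # 4 x 0.3 > 1


class TestCatalogGeneration:
    def test_zero_aag_weight_and_no_boost_yields_no_interior_aag(self):
        weights = {c: 1.0 for c in codon_frequencies("ATGTGA", drop_incomplete=True)}
        weights = {c: (0.0 if c == "AAG" else 1.0) for c in weights}
        spec = SimulationSpec(n_genes=30, cds_length_codons=(60.0, 5.0),
                              codon_weights=weights, aag_boost=(0.0, 0.0), seed=2)
        sim = simulate_catalog(spec)
        for rec in sim.catalog:
            interior = rec.cds[3:-3]
            codons = {interior[i:i + 3] for i in range(0, len(interior), 3)}
            assert "AAG" not in codons

    def test_uniform_weights_give_expected_aag_frequency(self):
        spec = SimulationSpec(n_genes=500, cds_length_codons=(300.0, 10.0),
                              aag_boost=(0.0, 0.0), seed=4)
        sim = simulate_catalog(spec)
        freqs = [codon_frequencies(rec.cds)["AAG"] for rec in sim.catalog]
        # interior codons uniform over 61 sense codons
        se = np.sqrt((1 / 61) * (60 / 61) / (300 * 500))
        assert np.mean(freqs) == pytest.approx(1 / 61, abs=5 * se + 1e-4)

    def test_cds_structure(self, small_study):
        stops = {"TAA", "TAG", "TGA"}
        for rec in small_study.catalog:
            assert rec.cds.startswith("ATG")
            assert rec.cds[-3:] in stops
            assert len(rec.cds) % 3 == 0


class TestReproducibility:
    def test_bitwise_identical_files_for_same_seed(self, tmp_path):
        spec = SimulationSpec(n_genes=40, cds_length_codons=(60.0, 8.0), seed=21)
        a, b = tmp_path / "a", tmp_path / "b"
        write_study(simulate_study(spec), a)
        write_study(simulate_study(spec), b)
        for name in ("genome.fa", "annot.gff3", "transcripts.tsv", "proteins.tsv",
                     "annotations.tsv", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_different_seed_changes_output(self, tmp_path):
        base = SimulationSpec(n_genes=10, cds_length_codons=(40.0, 4.0), seed=1)
        other = SimulationSpec(n_genes=10, cds_length_codons=(40.0, 4.0), seed=2)
        s1, s2 = simulate_study(base), simulate_study(other)
        assert s1.catalog[s1.catalog.transcript_ids[0]].cds != s2.catalog[
            s2.catalog.transcript_ids[0]].cds


class TestExpressionGeneration:
    def test_target_r2_self_check(self):
        spec = SimulationSpec(n_genes=3000, cds_length_codons=(150.0, 20.0),
                              target_r2=0.6, seed=8)
        study = simulate_study(spec)
        for trt in ("30C", "40C"):
            assert study.truth.realized_r2[trt] == pytest.approx(0.6, abs=0.05)

    def test_null_effects_give_null_r2(self):
        spec = SimulationSpec(n_genes=2000, cds_length_codons=(100.0, 10.0),
                              effect_spec=(), noise_sd=0.7, target_r2=None, seed=9)
        study = simulate_study(spec)
        assert study.truth.realized_r2["30C"] == 0.0
        # protein fold changes carry no signal from transcript fold changes
        t = study.truth.transcript_log2fc["30C"]
        p = study.truth.protein_log2fc["30C"]
        assert abs(np.corrcoef(t, p)[0, 1]) < 0.06

    def test_zero_missing_rate_makes_imputation_a_noop(self):
        from codoncontrib.expression import filter_and_impute_protein

        spec = SimulationSpec(n_genes=100, cds_length_codons=(60.0, 5.0),
                              protein_missing_rate=0.0, seed=3)
        study = simulate_study(spec)
        assert not study.proteins.values.isna().any().any()
        out, rep = filter_and_impute_protein(study.proteins, normalize=False)
        pd.testing.assert_frame_equal(out.values, study.proteins.values)
        assert rep.n_imputed == 0 and not rep.dropped_genes

    def test_missingness_at_most_one_per_gene_condition(self, small_study):
        proteins = small_study.proteins
        for cond in proteins.condition_names:
            block = proteins.values[proteins.samples_for(cond)]
            assert (block.isna().sum(axis=1) <= 1).all()
        # entry-level rate near the requested 10%
        rate = proteins.values.isna().to_numpy().mean()
        assert rate == pytest.approx(0.10, abs=0.04)

    def test_planted_transcript_fc_flows_into_tables(self, small_study):
        tx = small_study.transcripts
        t30 = tx.values[tx.samples_for("30C")].mean(axis=1)
        t20 = tx.values[tx.samples_for("20C")].mean(axis=1)
        est = np.log2(t30 / t20)
        truth = small_study.truth.transcript_log2fc["30C"]
        assert np.corrcoef(est, truth.loc[est.index])[0, 1] > 0.95


class TestRecoveryReport:
    def _contribution(self, feats: list[tuple[str, str, float]], explained: float):
        df = pd.DataFrame(feats, columns=["feature", "category", "contribution_pct"])
        cats = df.groupby("category", as_index=False)["contribution_pct"].sum()
        scale = explained / df["contribution_pct"].sum() if len(df) else 0.0
        df["contribution_pct"] *= scale
        cats["contribution_pct"] *= scale
        return ContributionReport(features=df, categories=cats,
                                  total_explained_pct=explained,
                                  unexplained_pct=100 - explained)

    def _correlations(self, rs: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame({"feature": list(rs), "r": list(rs.values())})

    def _truth(self, betas, realized=0.6):
        return type("T", (), {
            "betas": betas, "realized_r2": {"30C": realized},
        })()

    def test_all_checks_pass_on_consistent_inputs(self):
        truth = self._truth({"transcript_fc": 0.5, "codon:AAG": 0.4})
        contribution = self._contribution(
            [("transcript_fc", "transcript", 30.0), ("codon:AAG", "codon", 25.0),
             ("aa:K", "amino_acid", 2.0)], explained=57.0)
        corr = self._correlations({"transcript_fc": 0.5, "codon:AAG": 0.3})
        rep = recovery_report(truth, contribution, corr, "30C")
        assert rep.all_passed
        assert rep.checks["planted_features_rank_top"] is True

    def test_zero_effect_spec_marks_ranking_not_applicable(self):
        truth = self._truth({}, realized=0.0)
        contribution = self._contribution([], explained=0.0)
        rep = recovery_report(truth, contribution, self._correlations({}), "30C")
        assert rep.checks["planted_features_rank_top"] is None
        assert rep.checks["correlation_signs_match"] is True
        assert rep.checks["explained_variance_recovered"] is True
        assert rep.all_passed

    def test_corrupted_contribution_fails_ranking_check(self):
        """Negative control: shuffled attribution must be caught."""
        truth = self._truth({"transcript_fc": 0.5, "codon:AAG": 0.4})
        contribution = self._contribution(
            [("gc:utr5", "gc", 40.0), ("aa:K", "amino_acid", 17.0)], explained=57.0)
        corr = self._correlations({"transcript_fc": 0.5, "codon:AAG": 0.3})
        rep = recovery_report(truth, contribution, corr, "30C")
        assert rep.checks["planted_features_rank_top"] is False
        assert not rep.all_passed

    def test_sign_mismatch_detected(self):
        truth = self._truth({"transcript_fc": 0.5})
        contribution = self._contribution([("transcript_fc", "transcript", 57.0)], 57.0)
        rep = recovery_report(truth, contribution,
                              self._correlations({"transcript_fc": -0.4}), "30C")
        assert rep.checks["correlation_signs_match"] is False


def test_feature_effects_survive_full_matrix_assembly(small_study):
    """Planted protein log2 fc correlates with the features it was built from."""
    truth = small_study.truth
    fm = build_feature_matrix(
        small_study.catalog,
        {g: float(2 ** truth.transcript_log2fc.loc[g, "30C"])
         for g in truth.transcript_log2fc.index},
    )
    p = truth.protein_log2fc.loc[fm.gene_ids, "30C"]
    r_tx = np.corrcoef(fm.values["transcript_fc"], p)[0, 1]
    r_aag = np.corrcoef(fm.values["codon:AAG"], p)[0, 1]
    assert r_tx > 0.2 and r_aag > 0.1
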