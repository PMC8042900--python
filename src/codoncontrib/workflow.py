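"""In-memory orchestration: simulated study → fold changes → contribution fit.

Mirrors the file-based CLI pipeline for programmatic use (tests, notebooks):
impute the protein table, build the per-contrast fold-change table, assemble
the feature matrix, and fit the factor-contribution model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .association import FactorContributionModel, FactorContributionResults
from .expression import filter_and_impute_protein, fold_change_table
from .sequence_features import FeatureMatrix, build_feature_matrix
from .synthetic_data import RecoveryReport, SimulatedStudy, SimulationSpec, recovery_report, simulate_study

__all__ = ["ContrastAnalysis", "analyze_study", "recovery_trial"]


@dataclass
class ContrastAnalysis:
    """Everything computed for one treatment-vs-control contrast."""

    treatment: str
    fold_changes: pd.DataFrame
    features: FeatureMatrix
    results: FactorContributionResults


def analyze_study(
    study: SimulatedStudy,
    treatment: str,
    seed: int = 0,
    **fit_kwargs,
) -> ContrastAnalysis:
    """Run the full analysis of one contrast on a (simulated or real) study."""
    proteins, _ = filter_and_impute_protein(
        study.proteins, expected_replicates=study.spec.replicates
    )
    fc = fold_change_table(study.transcripts, proteins, study.spec.control, treatment)
    indexed = fc.set_index("gene_id")
    features = build_feature_matrix(study.catalog, indexed["transcript_fc"])
    model = FactorContributionModel(indexed.loc[features.gene_ids, "protein_fc"], features)
    results = model.fit(seed=seed, **fit_kwargs)
    return ContrastAnalysis(
        treatment=treatment, fold_changes=fc, features=features, results=results
    )


def recovery_trial(
    seed: int,
    spec: SimulationSpec | None = None,
    treatment: str = "30C",
    **fit_kwargs,
) -> tuple[ContrastAnalysis, RecoveryReport]:
    """One parameter-recovery run: simulate under the default (or given) spec
    re-seeded with ``seed``, analyze, and score against the ground truth."""
    import dataclasses

    spec = dataclasses.replace(spec or SimulationSpec(), seed=seed)
    study = simulate_study(spec)
    analysis = analyze_study(study, treatment, seed=seed, **fit_kwargs)
    report = recovery_report(
        study.truth, analysis.results.contribution, analysis.results.correlations, treatment
    )
    return analysis, report
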