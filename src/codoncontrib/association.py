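"""Correlation screen, MARS contribution decomposition, and verification fits.

This is the analytic core: given the genes × features matrix and the
per-gene protein fold change, it

1. screens every feature by Pearson correlation (two-tailed t-based p,
   starred at the 0.05 / 0.01 levels),
2. fits a MARS model to decompose the explained variance into per-feature
   and per-category percentage contributions (feature share of summed RSS
   importance × R² × 100; the remainder to 100% is unexplained), and
3. verifies the selected effects with ordinary least squares and the
   elastic net, reporting sign/selection agreement.

The entry point is :class:`FactorContributionModel`, whose ``fit`` returns
a :class:`FactorContributionResults` carrying all of the above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mars import MarsRegression, MarsResults
from .penalized import ElasticNetResult, fit_elastic_net
from .sequence_features import FeatureMatrix, category_of

__all__ = [
    "correlation_screen",
    "fit_ols",
    "contribution_report",
    "ContributionReport",
    "VerificationReport",
    "fit_verification",
    "FactorContributionModel",
    "FactorContributionResults",
]


def _stars(p: np.ndarray) -> np.ndarray:
    return np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))


def correlation_screen(
    features: FeatureMatrix | pd.DataFrame,
    response: pd.Series | np.ndarray,
    log2_response: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every feature with the response.

    Returns a frame with columns feature, category, r, p, star, constant —
    constant features get r = 0, p = 1 and the flag set.  ``log2_response``
    correlates against log2 of the response instead of the raw fold change.
    """
    frame = features.values if isinstance(features, FeatureMatrix) else features
    if isinstance(response, pd.Series):
        if not frame.index.equals(response.index):
            if set(frame.index) != set(response.index):
                raise ValueError("feature matrix and response cover different genes")
            response = response.reindex(frame.index)
        y = response.to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
        if len(y) != len(frame):
            raise ValueError("response length does not match feature matrix")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 genes for a correlation screen")
    if log2_response:
        y = np.log2(y)

    X = frame.to_numpy(dtype=float)
    xs = X.std(axis=0)
    ys = y.std()
    constant = (xs == 0) | (ys == 0)
    xs_safe = np.where(xs > 0, xs, 1.0)
    zx = (X - X.mean(axis=0)) / xs_safe
    zy = (y - y.mean()) / (ys if ys > 0 else 1.0)
    r = zx.T @ zy / n
    r = np.clip(np.where(constant, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(constant, 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
    if isinstance(features, FeatureMatrix):
        cats = [features.category_map[c] for c in frame.columns]
    else:
        cats = [category_of(c) for c in frame.columns]
    return pd.DataFrame(
        {
            "feature": frame.columns,
            "category": cats,
            "r": r,
            "p": p,
            "star": _stars(p),
            "constant": constant,
        }
    ).reset_index(drop=True)


def fit_ols(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """OLS with intercept; returns per-feature estimate, se, t, p.

    Rank-deficient designs raise, naming the collinear columns (identified
    by pivoted QR).
    """
    import statsmodels.api as sm
    from scipy.linalg import qr as scipy_qr

    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]

    design = np.column_stack([np.ones(n), X])
    _, R, piv = scipy_qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag.max() * max(n, p + 1) * np.finfo(float).eps).sum())
    if rank < p + 1:
        bad = sorted(piv[rank:])
        bad_names = ["(intercept)" if i == 0 else names[i - 1] for i in bad]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad_names}")

    res = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {
            "feature": ["(intercept)"] + names,
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )


@dataclass
class ContributionReport:
    """Per-feature / per-category percentage contributions to protein variation.

    Feature contributions are (RSS importance share) × R² × 100, so
    categories sum to the total explained percentage and explained +
    unexplained = 100.
    """

    features: pd.DataFrame  # feature, category, contribution_pct
    categories: pd.DataFrame  # category, contribution_pct
    total_explained_pct: float
    unexplained_pct: float

    def __post_init__(self) -> None:
        assert abs(self.total_explained_pct + self.unexplained_pct - 100.0) < 1e-6
        if len(self.categories):
            assert abs(self.categories["contribution_pct"].sum() - self.total_explained_pct) < 1e-6

    def top_features(self, k: int) -> list[str]:
        return self.features.nlargest(k, "contribution_pct")["feature"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# total_explained_pct\t{self.total_explained_pct:.6g}\n")
            fh.write(f"# unexplained_pct\t{self.unexplained_pct:.6g}\n")
            self.features.to_csv(fh, sep="\t", index=False)


def contribution_report(
    results: MarsResults,
    category_map: Mapping[str, str],
    importance_basis: str = "rss",
) -> ContributionReport:
    """Decompose the MARS R² into per-feature and per-category percentages."""
    if importance_basis not in {"rss", "gcv"}:
        raise ValueError("importance_basis must be 'rss' or 'gcv'")
    imp = results.importance()
    col = f"{importance_basis}_importance"
    used = imp[imp[col] > 0].copy()
    explained = results.rsquared * 100.0
    total_imp = used[col].sum()
    if total_imp > 0:
        used["contribution_pct"] = used[col] / total_imp * explained
    else:
        used["contribution_pct"] = 0.0
        explained = 0.0
    missing = [f for f in used["feature"] if f not in category_map]
    if missing:
        raise KeyError(f"selected features lack a category: {missing}")
    used["category"] = [category_map[f] for f in used["feature"]]
    feats = used[["feature", "category", "contribution_pct"]].sort_values(
        "contribution_pct", ascending=False, kind="stable"
    ).reset_index(drop=True)
    cats = (
        feats.groupby("category", as_index=False)["contribution_pct"]
        .sum()
        .sort_values("contribution_pct", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return ContributionReport(
        features=feats,
        categories=cats,
        total_explained_pct=explained,
        unexplained_pct=100.0 - explained,
    )


@dataclass
class VerificationReport:
    """OLS / elastic-net verification of the MARS selection.

    ``agreement`` covers the union of features selected by any of the three
    methods (MARS term, elastic-net nonzero coefficient, OLS p < 0.05) with
    each method's effect sign (0 = not selected).
    """

    ols: pd.DataFrame
    enet: ElasticNetResult
    agreement: pd.DataFrame

    @property
    def all_signs_agree(self) -> bool:
        return bool(self.agreement["signs_agree"].all())


def _sign_agree(signs: Sequence[int]) -> bool:
    nz = [s for s in signs if s != 0]
    return len(set(nz)) <= 1


def fit_verification(
    X: pd.DataFrame,
    y: np.ndarray,
    mars_results: MarsResults,
    enet_alpha: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    ols_p_max: float = 0.05,
) -> VerificationReport:
    """Verify the MARS selection with OLS and the elastic net.

    The elastic net runs on the full design (its penalty handles the exact
    collinearities of compositional feature blocks); OLS — which cannot —
    runs on the MARS-selected features.
    """
    names = list(X.columns)
    mars_sel = mars_results.selected_features
    ols_features = sorted(mars_sel) if mars_sel else names
    ols = fit_ols(X[ols_features], y, ols_features)
    enet = fit_elastic_net(X.to_numpy(dtype=float), y, alpha=enet_alpha, cv_folds=cv_folds, seed=seed)

    enet_sel = set(enet.nonzero_features(names))
    ols_body = ols[ols["feature"] != "(intercept)"].set_index("feature")
    ols_sel = set(ols_body.index[ols_body["p"] < ols_p_max])

    union = sorted(mars_sel | enet_sel | ols_sel)
    rows = []
    for f in union:
        j = names.index(f)
        s_mars = mars_results.feature_sign(f) if f in mars_sel else 0
        s_enet = int(np.sign(enet.coef[j])) if f in enet_sel else 0
        s_ols = int(np.sign(ols_body.loc[f, "estimate"])) if f in ols_sel else 0
        rows.append(
            {
                "feature": f,
                "mars_selected": f in mars_sel,
                "ols_selected": f in ols_sel,
                "enet_selected": f in enet_sel,
                "mars_sign": s_mars,
                "ols_sign": s_ols,
                "enet_sign": s_enet,
                "signs_agree": _sign_agree([s_mars, s_enet, s_ols]),
            }
        )
    agreement = pd.DataFrame(rows, columns=[
        "feature", "mars_selected", "ols_selected", "enet_selected",
        "mars_sign", "ols_sign", "enet_sign", "signs_agree",
    ])
    return VerificationReport(ols=ols, enet=enet, agreement=agreement)


class FactorContributionModel:
    """Protein fold change regressed on sequence/transcription features.

    Parameters
    ----------
    response
        Per-gene protein fold change aligned with the feature matrix rows.
    features
        :class:`FeatureMatrix` (or plain DataFrame with registry-style
        column names) of candidate drivers.
    response_transform
        ``"log2"`` (default) fits log2 fold change — fold-change noise is
        multiplicative, so the variance decomposition lives naturally on
        the log scale; ``"raw"`` fits the ratio as-is.  The correlation
        screen always reports raw-scale correlations by default.
    """

    def __init__(
        self,
        response: pd.Series | np.ndarray,
        features: FeatureMatrix | pd.DataFrame,
        response_transform: str = "log2",
    ) -> None:
        if isinstance(features, FeatureMatrix):
            self.frame = features.values
            self.category_map = features.category_map
        else:
            self.frame = features
            self.category_map = {c: category_of(c) for c in features.columns}
        if isinstance(response, pd.Series):
            if set(response.index) != set(self.frame.index):
                raise ValueError("response and feature matrix cover different genes")
            response = response.reindex(self.frame.index)
            self.response = response.to_numpy(dtype=float)
        else:
            self.response = np.asarray(response, dtype=float).ravel()
            if len(self.response) != len(self.frame):
                raise ValueError("response length does not match feature matrix")
        if (self.response <= 0).any():
            raise ValueError("fold changes must be strictly positive")
        if response_transform not in {"log2", "raw"}:
            raise ValueError("response_transform must be 'log2' or 'raw'")
        self.response_transform = response_transform

    @classmethod
    def from_feature_matrix(
        cls, features: FeatureMatrix, response: pd.Series, **kwargs
    ) -> "FactorContributionModel":
        return cls(response, features, **kwargs)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response_col: str = "protein_fc", **kwargs
    ) -> "FactorContributionModel":
        feats = data.drop(columns=[response_col])
        return cls(data[response_col], feats, **kwargs)

    def fit(
        self,
        max_terms: int = 21,
        degree: int = 1,
        penalty: float | None = None,
        max_knots: int = 64,
        verify: bool = True,
        enet_alpha: float = 0.5,
        cv_folds: int = 10,
        seed: int = 0,
        correlate_log2: bool = False,
    ) -> "FactorContributionResults":
        y = self.response if self.response_transform == "raw" else np.log2(self.response)
        # constant columns carry no information and break standardization
        usable = self.frame.loc[:, self.frame.std(axis=0) > 0]
        correlations = correlation_screen(self.frame, self.response, log2_response=correlate_log2)
        mars = MarsRegression(
            y,
            usable.to_numpy(dtype=float),
            feature_names=list(usable.columns),
            max_terms=max_terms,
            degree=degree,
            penalty=penalty,
            max_knots=max_knots,
        ).fit()
        contribution = contribution_report(mars, self.category_map)
        verification = (
            fit_verification(usable, y, mars, enet_alpha=enet_alpha, cv_folds=cv_folds, seed=seed)
            if verify
            else None
        )
        return FactorContributionResults(
            model=self,
            correlations=correlations,
            mars=mars,
            contribution=contribution,
            verification=verification,
        )


@dataclass
class FactorContributionResults:
    """Everything the contribution analysis produces for one contrast."""

    model: FactorContributionModel
    correlations: pd.DataFrame
    mars: MarsResults
    contribution: ContributionReport
    verification: VerificationReport | None = None

    @property
    def rsquared(self) -> float:
        return self.mars.rsquared

    def summary(self) -> str:
        c = self.contribution
        lines = [
            "Factor contribution analysis",
            "=" * 62,
            f"genes: {len(self.model.frame)}    features: {self.model.frame.shape[1]}"
            f"    response: protein fold change ({self.model.response_transform})",
            f"MARS R-squared: {self.rsquared:.4f}   GCV: {self.mars.gcv:.5g}"
            f"   terms: {len(self.mars.terms)}",
            "-" * 62,
            "Category contributions (% of protein variation):",
        ]
        for _, row in c.categories.iterrows():
            lines.append(f"  {row['category']:<14s} {row['contribution_pct']:6.1f}%")
        lines.append(f"  {'unexplained':<14s} {c.unexplained_pct:6.1f}%")
        lines.append("-" * 62)
        lines.append("Top features:")
        for _, row in c.features.head(8).iterrows():
            lines.append(
                f"  {row['feature']:<18s} {row['category']:<12s} {row['contribution_pct']:6.1f}%"
            )
        sig = self.correlations[self.correlations["p"] < 0.01]
        lines.append(f"Significant correlations at 0.01 (two-tailed): {len(sig)}")
        if self.verification is not None:
            agree = self.verification.agreement
            lines.append(
                f"Verification: {int(agree['signs_agree'].sum())}/{len(agree)} features with "
                "consistent signs across MARS/OLS/elastic net"
            )
        lines.append("=" * 62)
        return "\n".join(lines)

    def write_outputs(self, outdir: str | Path) -> list[Path]:
        """Write correlation, model, contribution and verification tables."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        p = outdir / "correlations.tsv"
        self.correlations.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "contribution.tsv"
        self.contribution.to_tsv(p)
        written.append(p)
        p = outdir / "mars_model.json"
        names = self.mars.model.feature_names
        with open(p, "w") as fh:
            json.dump(
                {
                    "r_squared": self.rsquared,
                    "gcv": self.mars.gcv,
                    "n_obs": self.mars.n_obs,
                    "terms": [
                        {
                            "label": t.label(names),
                            "coefficient": float(c),
                            "factors": [
                                {
                                    "feature": names[f.feature],
                                    "knot": f.knot,
                                    "direction": f.direction,
                                }
                                for f in t.factors
                            ],
                        }
                        for t, c in zip(self.mars.terms, self.mars.params)
                    ],
                },
                fh,
                indent=1,
            )
        written.append(p)
        if self.verification is not None:
            p = outdir / "verification.tsv"
            self.verification.agreement.to_csv(p, sep="\t", index=False)
            written.append(p)
            p = outdir / "ols.tsv"
            self.verification.ols.to_csv(p, sep="\t", index=False)
            written.append(p)
        return written
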