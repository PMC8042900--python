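"""Multivariate adaptive regression splines (MARS) with GCV backward pruning.

The model is a sum of hinge basis functions max(0, x - t) / max(0, t - x)
with knots t at observed data values, built in two passes:

* **forward** — greedy pair-wise hinge addition.  At each step every
  (parent term, feature, knot) candidate is scored by the exact decrease in
  the residual sum of squares obtained by adding the hinge pair jointly;
  the best pair is appended.  With ``degree`` > 1 candidate terms are
  products of an existing term and a new hinge.  The search is exact — for
  every candidate the RSS decrease equals the least-squares improvement —
  implemented with sorted suffix sums so a step costs O(n·terms) per
  feature rather than O(n·terms·knots).
* **backward** — terms are removed one at a time (always the one whose
  removal least increases RSS), and the model size minimizing the
  generalized cross-validation criterion

      GCV(k) = (RSS_k / n) / (1 - C(k)/n)^2,   C(k) = k + penalty·(k-1)/2

  is selected.  The penalty defaults to 2 for additive models and 3 when
  interactions are allowed.

Ties in the forward search are broken deterministically: lowest feature
index first, then smallest knot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["HingeFactor", "BasisTerm", "MarsRegression", "MarsResults", "PruneStep"]

_EPS = 1e-12


@dataclass(frozen=True)
class HingeFactor:
    """One multiplicative factor: a hinge (direction ±1) or a linear term (direction 0)."""

    feature: int
    knot: float | None
    direction: int  # +1: max(0, x-t); -1: max(0, t-x); 0: linear (knot None)

    def column(self, X: np.ndarray) -> np.ndarray:
        x = X[:, self.feature]
        if self.direction == 0:
            return x.copy()
        if self.direction == 1:
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)

    def label(self, names: Sequence[str]) -> str:
        name = names[self.feature]
        if self.direction == 0:
            return name
        if self.direction == 1:
            return f"h({name}-{self.knot:g})"
        return f"h({self.knot:g}-{name})"


@dataclass(frozen=True)
class BasisTerm:
    """Product of hinge/linear factors; the empty product is the intercept."""

    factors: tuple[HingeFactor, ...] = ()

    @property
    def is_intercept(self) -> bool:
        return not self.factors

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> frozenset[int]:
        return frozenset(f.feature for f in self.factors)

    def column(self, X: np.ndarray) -> np.ndarray:
        col = np.ones(X.shape[0])
        for f in self.factors:
            col = col * f.column(X)
        return col

    def label(self, names: Sequence[str]) -> str:
        if self.is_intercept:
            return "(intercept)"
        return " * ".join(f.label(names) for f in self.factors)


@dataclass
class PruneStep:
    """One model size visited by the backward pass."""

    size: int
    term_indices: tuple[int, ...]
    rss: float
    gcv: float | None  # None when the size is inadmissible


def _suffix_sums(a: np.ndarray) -> np.ndarray:
    """suffix[i] = sum(a[i:]) along axis 0, with a trailing zero row."""
    out = np.zeros((a.shape[0] + 1,) + a.shape[1:])
    np.cumsum(a[::-1], axis=0, out=out[:0:-1])
    return out


class MarsRegression:
    """MARS model specification; ``fit()`` returns a :class:`MarsResults`.

    Parameters
    ----------
    endog, exog
        Response vector (n,) and design matrix (n, p).
    max_terms
        Maximum number of basis terms including the intercept.
    degree
        Maximum number of hinge factors per term (1 = additive).
    penalty
        GCV cost per knot; default 2 when ``degree`` == 1, else 3.
    max_knots
        Maximum candidate knots per feature; when a feature has more
        distinct values, a quantile-indexed subset of the observed values
        is used (knots always remain observed data values).
    forward_tol
        Stop the forward pass when the best RSS improvement falls below
        ``forward_tol`` × total sum of squares.
    linear_only
        Restrict the basis to linear (unhinged) columns; with enough terms
        this reproduces ordinary least squares.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        feature_names: Sequence[str] | None = None,
        max_terms: int = 21,
        degree: int = 1,
        penalty: float | None = None,
        max_knots: int = 64,
        forward_tol: float = 1e-4,
        linear_only: bool = False,
    ) -> None:
        self.y = np.asarray(endog, dtype=float).ravel()
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("exog must be 2-D with one row per response value")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("missing values in design matrix or response")
        self.n, self.p = self.X.shape
        if self.n <= max_terms:
            raise ValueError(f"need n > max_terms ({self.n} <= {max_terms})")
        self.feature_names = (
            list(feature_names) if feature_names is not None else [f"x{j}" for j in range(self.p)]
        )
        if len(self.feature_names) != self.p:
            raise ValueError("feature_names length mismatch")
        self.max_terms = int(max_terms)
        self.degree = int(degree)
        self.penalty = float(penalty) if penalty is not None else (2.0 if self.degree == 1 else 3.0)
        self.max_knots = int(max_knots)
        self.forward_tol = float(forward_tol)
        self.linear_only = bool(linear_only)
        self._prepare_knots()

    # -- candidate knots -------------------------------------------------

    def _prepare_knots(self) -> None:
        self._order = []
        self._xsorted = []
        self._knots = []
        self._knot_pos = []
        for j in range(self.p):
            x = self.X[:, j]
            order = np.argsort(x, kind="stable")
            xs = x[order]
            distinct = np.unique(xs)
            # interior knots only: a pair at knot t already spans the linear
            # term (h+ - h- = x - t), and pairs at the extremes degenerate
            knots = distinct[1:-1] if distinct.size >= 3 else distinct[:-1]
            if knots.size > self.max_knots:
                idx = np.unique(np.round(np.linspace(0, knots.size - 1, self.max_knots)).astype(int))
                knots = knots[idx]
            self._order.append(order)
            self._xsorted.append(xs)
            self._knots.append(knots)
            # first index with xs > knot: hinge support starts here
            self._knot_pos.append(np.searchsorted(xs, knots, side="right"))

    # -- forward pass ----------------------------------------------------

    def _score_feature(
        self,
        j: int,
        w: np.ndarray,
        Q: np.ndarray,
        r: np.ndarray,
    ) -> tuple[float, float | None, float]:
        """Best joint RSS decrease for a hinge pair on feature j under parent weight w.

        Returns (improvement, knot, linear_only_improvement).  The pair at
        knot t spans {w·x, w·max(0, x-t)} given the parent column w is in
        the basis, so the decrease is the linear-term gain plus the extra
        hinge gain, maximized over knots with suffix sums.
        """
        x = self.X[:, j]
        g = w * x
        qg = Q.T @ g
        g_t = g - Q @ qg
        gn2 = float(g_t @ g_t)
        scale = float(g @ g) + _EPS
        if gn2 > _EPS * scale:
            d_lin = float(g_t @ r) ** 2 / gn2
        else:
            d_lin, gn2 = 0.0, 0.0

        knots = self._knots[j]
        if self.linear_only or knots.size == 0:
            return d_lin, None, d_lin

        order = self._order[j]
        xs = self._xsorted[j]
        pos = self._knot_pos[j]
        wo = w[order]
        # stacked vectors whose inner products with every hinge we need
        V = np.column_stack([Q, r] + ([g_t] if gn2 > 0.0 else []))
        Vw = V[order] * wo[:, None]
        s1 = _suffix_sums(Vw)[pos]            # K × m : Σ v_i w_i over support
        sx = _suffix_sums(Vw * xs[:, None])[pos]  # K × m : Σ v_i w_i x_i
        dots = sx - knots[:, None] * s1       # vᵀh for each knot/vector

        w2 = wo * wo
        c0 = _suffix_sums(w2[:, None])[pos][:, 0]
        c1 = _suffix_sums((w2 * xs)[:, None])[pos][:, 0]
        c2 = _suffix_sums((w2 * xs * xs)[:, None])[pos][:, 0]
        hh = c2 - 2 * knots * c1 + knots * knots * c0  # ‖h‖² per knot

        k = Q.shape[1]
        proj2 = (dots[:, :k] ** 2).sum(axis=1)
        hr = dots[:, k]
        if gn2 > 0.0:
            hg = dots[:, k + 1]
            proj2 = proj2 + hg * hg / gn2
            hr = hr - hg * float(g_t @ r) / gn2
        res2 = hh - proj2
        ok = res2 > _EPS * (hh + _EPS)
        gain = np.zeros_like(hh)
        gain[ok] = hr[ok] ** 2 / res2[ok]
        best = int(np.argmax(gain))  # first occurrence → smallest knot on ties
        return d_lin + float(gain[best]), float(knots[best]), d_lin

    def _forward(self) -> tuple[list[BasisTerm], np.ndarray]:
        terms: list[BasisTerm] = [BasisTerm()]
        B = np.ones((self.n, 1))
        tss = float(((self.y - self.y.mean()) ** 2).sum())
        tol_abs = self.forward_tol * tss
        step = 2 if not self.linear_only else 1
        self.forward_rss_: list[float] = []  # achieved RSS after each forward step

        while len(terms) + step <= self.max_terms:
            Q, _ = np.linalg.qr(B)
            r = self.y - Q @ (Q.T @ self.y)
            if float(r @ r) <= _EPS * max(tss, 1.0):
                break
            best_imp = 0.0
            best: tuple[int, int, float | None] | None = None  # (parent, feature, knot)
            for parent_idx, parent in enumerate(terms):
                if parent.degree >= self.degree:
                    continue
                w = B[:, parent_idx]
                for j in range(self.p):
                    if j in parent.variables:
                        continue
                    imp, knot, _ = self._score_feature(j, w, Q, r)
                    if imp > best_imp * (1.0 + 1e-10) + _EPS:
                        best_imp, best = imp, (parent_idx, j, knot)
            if best is None or best_imp < tol_abs:
                break
            parent_idx, j, knot = best
            parent = terms[parent_idx]
            if self.linear_only or knot is None:
                new = [BasisTerm(parent.factors + (HingeFactor(j, None, 0),))]
            else:
                new = [
                    BasisTerm(parent.factors + (HingeFactor(j, knot, 1),)),
                    BasisTerm(parent.factors + (HingeFactor(j, knot, -1),)),
                ]
            added = False
            for term in new:
                col = term.column(self.X)
                Q, _ = np.linalg.qr(B)
                resid = col - Q @ (Q.T @ col)
                if float(resid @ resid) > _EPS * (float(col @ col) + _EPS):
                    B = np.column_stack([B, col])
                    terms.append(term)
                    added = True
                else:
                    # routine once a feature's linear span is in the basis: the
                    # second hinge of a later pair on that feature is redundant
                    logger.debug(
                        "collinear basis term skipped: %s", term.label(self.feature_names)
                    )
            if not added:
                warnings.warn("selected candidate was entirely collinear; forward pass stopped",
                              stacklevel=2)
                break
            self.forward_rss_.append(self._rss(B)[0])
        return terms, B

    # -- backward pass ---------------------------------------------------

    def _rss(self, B: np.ndarray) -> tuple[float, np.ndarray]:
        coef, *_ = np.linalg.lstsq(B, self.y, rcond=None)
        resid = self.y - B @ coef
        return float(resid @ resid), coef

    def _gcv(self, rss: float, k: int) -> float | None:
        c = k + self.penalty * (k - 1) / 2.0
        denom = 1.0 - c / self.n
        if denom <= 0:
            return None
        return (rss / self.n) / denom**2

    def _backward(self, terms: list[BasisTerm], B: np.ndarray) -> list[PruneStep]:
        current = list(range(len(terms)))
        trace: list[PruneStep] = []
        while True:
            rss, _ = self._rss(B[:, current])
            gcv = self._gcv(rss, len(current))
            if gcv is None:
                warnings.warn(
                    f"model size {len(current)} inadmissible for GCV (effective "
                    f"parameters exceed n); size skipped",
                    stacklevel=2,
                )
            trace.append(PruneStep(len(current), tuple(current), rss, gcv))
            removable = [i for i in current if not terms[i].is_intercept]
            if not removable:
                break
            best_rss, best_drop = np.inf, None
            for drop in removable:
                subset = [i for i in current if i != drop]
                rss_d, _ = self._rss(B[:, subset])
                if rss_d < best_rss * (1.0 - 1e-12) or best_drop is None:
                    best_rss, best_drop = rss_d, drop
            current = [i for i in current if i != best_drop]
        return trace

    def fit(self) -> "MarsResults":
        terms, B = self._forward()
        trace = self._backward(terms, B)
        admissible = [s for s in trace if s.gcv is not None]
        if not admissible:
            raise ValueError("no admissible model size for GCV; reduce max_terms")
        best = min(admissible, key=lambda s: (s.gcv, s.size))
        coef_rss, coef = self._rss(B[:, list(best.term_indices)])
        selected_terms = [terms[i] for i in best.term_indices]
        return MarsResults(
            model=self,
            forward_terms=terms,
            terms=selected_terms,
            params=coef,
            rss=coef_rss,
            gcv=best.gcv,
            trace=trace,
            selected_size=best.size,
        )


@dataclass
class MarsResults:
    """Fitted MARS model: pruned terms, coefficients, GCV, fit statistics."""

    model: MarsRegression
    forward_terms: list[BasisTerm]
    terms: list[BasisTerm]
    params: np.ndarray
    rss: float
    gcv: float
    trace: list[PruneStep]
    selected_size: int
    _importance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_obs(self) -> int:
        return self.model.n

    @property
    def tss(self) -> float:
        y = self.model.y
        return float(((y - y.mean()) ** 2).sum())

    @property
    def rsquared(self) -> float:
        tss = self.tss
        return 1.0 - self.rss / tss if tss > 0 else 0.0

    @property
    def selected_features(self) -> set[str]:
        names = self.model.feature_names
        return {names[v] for t in self.terms for v in t.variables}

    def design_matrix(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.model.X if X is None else np.asarray(X, dtype=float)
        return np.column_stack([t.column(X) for t in self.terms])

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        return self.design_matrix(X) @ self.params

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def feature_sign(self, feature: int | str) -> int:
        """Sign of the marginal association captured for one feature (0 if unused)."""
        if isinstance(feature, str):
            feature = self.model.feature_names.index(feature)
        cols = [
            c * self.params[i]
            for i, t in enumerate(self.terms)
            if feature in t.variables
            for c in [t.column(self.model.X)]
        ]
        if not cols:
            return 0
        partial = np.sum(cols, axis=0)
        x = self.model.X[:, feature]
        if partial.std() == 0 or x.std() == 0:
            return 0
        return int(np.sign(np.corrcoef(partial, x)[0, 1]))

    # -- variable importance ---------------------------------------------

    def importance(self) -> pd.DataFrame:
        """Per-feature importance from the pruning trace.

        ``nsubsets`` counts the backward-pass subsets (up to the selected
        size) containing the feature; ``rss_importance`` / ``gcv_importance``
        sum the criterion decrease attributed to the term(s) re-introducing
        the feature along the trace; ``normalized_importance`` scales the
        RSS importance so the top feature is 100.
        """
        if self._importance is not None:
            return self._importance
        names = self.model.feature_names
        by_size = {s.size: s for s in self.trace}
        nsub = dict.fromkeys(names, 0)
        rss_imp = dict.fromkeys(names, 0.0)
        gcv_imp = dict.fromkeys(names, 0.0)
        for size in range(1, self.selected_size + 1):
            step = by_size.get(size)
            if step is None:
                continue
            vars_here = {names[v] for i in step.term_indices for v in self.forward_terms[i].variables}
            for v in vars_here:
                nsub[v] += 1
            prev = by_size.get(size - 1)
            if prev is None:
                continue
            added = set(step.term_indices) - set(prev.term_indices)
            added_vars = {names[v] for i in added for v in self.forward_terms[i].variables}
            d_rss = prev.rss - step.rss
            d_gcv = (prev.gcv - step.gcv) if (prev.gcv is not None and step.gcv is not None) else 0.0
            for v in added_vars:
                rss_imp[v] += d_rss
                gcv_imp[v] += d_gcv
        rss_arr = np.array([max(rss_imp[v], 0.0) for v in names])
        gcv_arr = np.array([max(gcv_imp[v], 0.0) for v in names])
        top = rss_arr.max()
        out = pd.DataFrame(
            {
                "feature": names,
                "nsubsets": [nsub[v] for v in names],
                "rss_importance": rss_arr,
                "gcv_importance": gcv_arr,
                "normalized_importance": 100.0 * rss_arr / top if top > 0 else rss_arr,
            }
        )
        self._importance = out
        return out

    def summary(self) -> str:
        names = self.model.feature_names
        lines = [
            "MARS regression results",
            "=" * 58,
            f"n_obs: {self.n_obs}    terms (of {len(self.forward_terms)} forward): {len(self.terms)}",
            f"R-squared: {self.rsquared:.4f}    GCV: {self.gcv:.6g}    penalty: {self.model.penalty:g}",
            "-" * 58,
            f"{'term':<40s} {'coef':>12s}",
        ]
        for term, c in zip(self.terms, self.params):
            lines.append(f"{term.label(names):<40s} {c:>12.5g}")
        lines.append("=" * 58)
        return "\n".join(lines)
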