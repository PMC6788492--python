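"""Smoltification-axis identification and biomarker panel selection.

Workflow (mirrors how the candidate assays were validated): fit a PCA over
all candidate-gene log2 expression from monthly freshwater samples,
identify the component that best separates earlier and later months (the
smoltification axis), rank every gene by the significance of its Pearson
correlation with that axis, and keep the top N significant genes as the
panel.  A dual-axis variant additionally requires significance against a
de-smoltification axis, reproducing the stricter two-axis panel used for
seawater-tolerance classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .pca import ExpressionPCA, _as_samples_by_genes

__all__ = [
    "SmoltAxis",
    "PanelDefinition",
    "find_axis",
    "find_smolt_axis",
    "rank_genes",
    "select_panel",
    "select_panel_dual_axis",
    "SmoltPanelSelector",
]


@dataclass
class SmoltAxis:
    """A chosen PC axis and its correlation with the month ordinal."""

    component_index: int  # 1-based
    r_month: float
    p_month: float


@dataclass
class PanelDefinition:
    """An ordered biomarker panel and the rule that selected it."""

    assay_ids: list[str]
    selection_rule: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.assay_ids)

    def to_frame(self, ranking: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {"rank": np.arange(1, len(self.assay_ids) + 1), "assay_id": self.assay_ids}
        )
        if ranking is not None:
            r = ranking.set_index("assay_id")
            out["direction"] = [
                "up" if r.loc[a, "r"] >= 0 else "down" for a in self.assay_ids
            ]
            out["r"] = [r.loc[a, "r"] for a in self.assay_ids]
            out["p"] = [r.loc[a, "p"] for a in self.assay_ids]
        return out


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its exact two-sided p via t = r sqrt((n-2)/(1-r^2))."""
    n = len(x)
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt((x * x).sum())
    sy = np.sqrt((y * y).sum())
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    r = float(np.clip((x * y).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def find_axis(scores: pd.DataFrame, target, k_max: int = 3) -> SmoltAxis:
    """Component (1..k_max) whose scores correlate most strongly with target."""
    target = np.asarray(target, dtype=float)
    if len(np.unique(target)) < 2:
        raise ValueError("target covariate has no variation")
    k = min(k_max, scores.shape[1])
    best = None
    for i in range(k):
        r, p = _pearson_with_p(scores.iloc[:, i].to_numpy(), target)
        if best is None or abs(r) > abs(best.r_month):
            best = SmoltAxis(i + 1, r, p)
    return best


def find_smolt_axis(
    model: ExpressionPCA, scores: pd.DataFrame, month_index, k_max: int = 3
) -> tuple[SmoltAxis, pd.DataFrame]:
    """Pick the month-separating axis and orient it so later months score higher.

    Returns the axis (with r >= 0 after orientation) and the re-oriented
    score matrix.
    """
    month = np.asarray(month_index, dtype=float)
    if len(np.unique(month)) < 2:
        raise ValueError("all samples share one month; cannot find a smolt axis")
    axis = find_axis(scores, month, k_max=k_max)
    if axis.r_month < 0:
        current = int(model.orientation_[axis.component_index - 1])
        model.set_orientation(axis.component_index, -current)
        axis = SmoltAxis(axis.component_index, -axis.r_month, axis.p_month)
    return axis, model.scores_


def rank_genes(expr, axis_scores) -> pd.DataFrame:
    """Rank genes by significance of Pearson correlation with axis scores.

    Returns a DataFrame with columns ``assay_id, r, p, rank,
    direction_observed, computable``; rank 1 is most significant (ascending
    p, ties by descending \\|r\\| then assay id).  Constant genes get
    ``computable=False`` and sort last.
    """
    df = _as_samples_by_genes(expr)
    y = np.asarray(axis_scores, dtype=float)
    if len(y) != len(df):
        raise ValueError("axis scores are not aligned to samples")
    if len(df) < 3:
        raise ValueError("need at least 3 samples for correlation ranking")
    rows = []
    for gene in df.columns:
        r, p = _pearson_with_p(df[gene].to_numpy(dtype=float), y)
        rows.append(
            {
                "assay_id": gene,
                "r": r,
                "p": p,
                "direction_observed": "up" if r > 0 else ("down" if r < 0 else ""),
                "computable": not np.isnan(p) if p == p else False,
            }
        )
    out = pd.DataFrame(rows)
    out["computable"] = out["p"].notna()
    order = out.sort_values(
        by=["computable", "p", "r", "assay_id"],
        ascending=[False, True, True, True],
        key=lambda col: -col.abs() if col.name == "r" else col,
    ).index
    out["rank"] = 0
    out.loc[order, "rank"] = np.arange(1, len(out) + 1)
    return out.sort_values("rank").reset_index(drop=True)


def select_panel(ranking: pd.DataFrame, n: int = 10, alpha: float = 0.05) -> PanelDefinition:
    """Top-n genes by rank with p < alpha (may return fewer than n)."""
    ok = ranking[(ranking["computable"]) & (ranking["p"] < alpha)].sort_values("rank")
    chosen = list(ok["assay_id"].head(n))
    if not chosen:
        warnings.warn(f"no genes significant at alpha={alpha}; panel is empty", stacklevel=2)
    return PanelDefinition(chosen, {"rule": "top_n", "n": n, "alpha": alpha})


def select_panel_dual_axis(
    ranking_a: pd.DataFrame,
    ranking_b: pd.DataFrame,
    n: int = 20,
    alpha: float = 1e-5,
) -> PanelDefinition:
    """Genes significant (p < alpha) on BOTH axes, ordered by min(p_a, p_b).

    The published two-axis panel required significance against both the
    smoltification and the de-smoltification axis; the intersection reading
    of "both" is implemented here.
    """
    a = ranking_a.set_index("assay_id")
    b = ranking_b.set_index("assay_id")
    common = [g for g in a.index if g in b.index]
    ok = [
        g
        for g in common
        if a.loc[g, "computable"]
        and b.loc[g, "computable"]
        and a.loc[g, "p"] < alpha
        and b.loc[g, "p"] < alpha
    ]
    ok.sort(key=lambda g: (min(a.loc[g, "p"], b.loc[g, "p"]), g))
    chosen = ok[:n]
    if not chosen:
        warnings.warn(
            f"no genes significant on both axes at alpha={alpha}; panel is empty",
            stacklevel=2,
        )
    return PanelDefinition(
        chosen, {"rule": "dual_axis", "n": n, "alpha": alpha}
    )


class SmoltPanelSelector(BaseEstimator, TransformerMixin):
    """End-to-end panel discovery as a transformer.

    ``fit(X, y)`` takes samples x genes log2 expression and the per-sample
    month ordinal ``y``; it fits the candidate-gene PCA, locates and orients
    the smoltification axis, ranks genes against it and selects the panel.
    With ``desmolt`` scores supplied (a per-sample covariate tracking the
    de-smolt reversal, e.g. a late-month indicator), a second axis is
    located and the dual-axis intersection rule is applied instead.
    ``transform`` restricts an expression matrix to the panel genes.

    Attributes: ``pca_``, ``axis_``, ``ranking_``, ``panel_``, ``scores_``
    (and ``desmolt_axis_``, ``desmolt_ranking_`` in dual-axis mode).
    """

    def __init__(
        self,
        n: int = 10,
        alpha: float = 0.05,
        scale: bool = True,
        k_max: int = 3,
    ):
        self.n = n
        self.alpha = alpha
        self.scale = scale
        self.k_max = k_max

    def fit(self, X, y, *, desmolt=None):
        df = _as_samples_by_genes(X)
        self.pca_ = ExpressionPCA(scale=self.scale).fit(df)
        self.axis_, scores = find_smolt_axis(
            self.pca_, self.pca_.scores_, y, k_max=self.k_max
        )
        self.scores_ = scores
        axis_scores = scores.iloc[:, self.axis_.component_index - 1]
        self.ranking_ = rank_genes(df, axis_scores)
        if desmolt is None:
            self.panel_ = select_panel(self.ranking_, n=self.n, alpha=self.alpha)
        else:
            d_axis = find_axis(scores, np.asarray(desmolt, float), k_max=self.k_max)
            if d_axis.component_index == self.axis_.component_index:
                # best de-smolt axis may coincide with the smolt axis on
                # degenerate data; fall back to the next-best component
                others = [
                    i + 1
                    for i in range(min(self.k_max, scores.shape[1]))
                    if i + 1 != self.axis_.component_index
                ]
                cand = [
                    find_axis(scores.iloc[:, [i - 1]], np.asarray(desmolt, float), k_max=1)
                    for i in others
                ]
                best = int(np.argmax([abs(c.r_month) for c in cand]))
                d_axis = SmoltAxis(others[best], cand[best].r_month, cand[best].p_month)
            self.desmolt_axis_ = d_axis
            self.desmolt_ranking_ = rank_genes(
                df, scores.iloc[:, d_axis.component_index - 1]
            )
            self.panel_ = select_panel_dual_axis(
                self.ranking_, self.desmolt_ranking_, n=self.n, alpha=self.alpha
            )
        return self

    def transform(self, X) -> pd.DataFrame:
        df = _as_samples_by_genes(X)
        missing = [g for g in self.panel_.assay_ids if g not in df.columns]
        if missing:
            raise ValueError(f"expression matrix lacks panel genes: {missing}")
        return df[self.panel_.assay_ids]
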