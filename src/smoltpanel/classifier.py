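"""Seawater-tolerance classification from panel-PCA scores.

Labelled fish (pre-smolt / smolt / de-smolt, assigned at the trial level
from acute seawater-transfer survival) are projected into the biomarker
panel PCA.  One threshold per axis is estimated by maximizing Youden's J
(sensitivity + specificity - 1) over ROC cutpoints:

* the smoltification axis threshold separates pre-smolts from smolts
  (de-smolts excluded from that fit);
* the de-smoltification axis threshold separates smolts from de-smolts
  (pre-smolts excluded).

New fish are classified by which region of the score plane they fall in;
fish in the smolt region are called seawater tolerant, everything else
intolerant.  Conventions: the smolt region is closed (a fish exactly on a
threshold is a smolt), and a fish on the wrong side of both thresholds is a
pre-smolt (a fish that never smolted cannot be a de-smolt).  The side of
each threshold that belongs to smolts is learned from the labels, never
assumed, because PCA axis signs are arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .data import STATUSES
from .pca import ExpressionPCA, _as_samples_by_genes
from .panel import PanelDefinition

__all__ = [
    "YoudenResult",
    "youden_threshold",
    "SeawaterToleranceClassifier",
    "fit_classifier",
    "classify",
    "monthly_summary",
]


@dataclass
class YoudenResult:
    """Optimal ROC cutpoint by maximum Youden's J."""

    threshold: float
    j: float
    orientation: str  # 'above': positives score above the threshold
    curve: pd.DataFrame = field(repr=False, default=None)


def youden_threshold(scores, labels, positive) -> YoudenResult:
    """Cutpoint maximizing J = sensitivity + specificity - 1.

    Candidate cutpoints are the midpoints between consecutive distinct
    sorted scores plus the two infinite bounds; both orientations are
    evaluated.  Ties are broken by smallest \\|threshold\\|, then the lower
    threshold, then orientation ``'above'``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    pos = y == positive
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present to fit a threshold")
    uniq = np.unique(s)
    cand = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    if len(uniq) == 1:
        warnings.warn("all scores identical; threshold is degenerate (J=0)", stacklevel=2)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    rows = []
    for t in cand:
        above = s > t
        sens_a = (above & pos).sum() / n_pos
        spec_a = (~above & ~pos).sum() / n_neg
        rows.append((t, "above", sens_a, spec_a, sens_a + spec_a - 1.0))
        sens_b = (~above & pos).sum() / n_pos
        spec_b = (above & ~pos).sum() / n_neg
        rows.append((t, "below", sens_b, spec_b, sens_b + spec_b - 1.0))
    curve = pd.DataFrame(
        rows, columns=["threshold", "orientation", "sensitivity", "specificity", "j"]
    )
    best_j = curve["j"].max()
    ties = curve[curve["j"] >= best_j - 1e-12].copy()
    ties["abs_t"] = ties["threshold"].abs()
    ties = ties.sort_values(
        by=["abs_t", "threshold", "orientation"], ascending=[True, True, True]
    )
    top = ties.iloc[0]
    return YoudenResult(float(top["threshold"]), float(top["j"]), str(top["orientation"]), curve)


class SeawaterToleranceClassifier(BaseEstimator, ClassifierMixin):
    """Dual-threshold smolt-status classifier over a panel PCA.

    Parameters
    ----------
    panel:
        Panel genes to use (:class:`PanelDefinition` or list of ids);
        ``None`` uses every gene in the training matrix.
    base_pca:
        A pre-fitted :class:`ExpressionPCA` (e.g. the monthly-survey panel
        PCA that labelled trial fish are projected into).  ``None`` fits a
        PCA on the training expression itself.
    smolt_axis, desmolt_axis:
        1-based component indices carrying the pre-smolt->smolt and the
        smolt->de-smolt contrast (defaults 1 and 2 for a panel-only PCA).
    """

    def __init__(
        self,
        panel=None,
        base_pca: ExpressionPCA | None = None,
        smolt_axis: int = 1,
        desmolt_axis: int = 2,
        scale: bool = True,
    ):
        self.panel = panel
        self.base_pca = base_pca
        self.smolt_axis = smolt_axis
        self.desmolt_axis = desmolt_axis
        self.scale = scale

    def _panel_genes(self, df: pd.DataFrame) -> list[str]:
        if self.panel is None:
            return list(df.columns)
        genes = self.panel.assay_ids if isinstance(self.panel, PanelDefinition) else list(self.panel)
        missing = [g for g in genes if g not in df.columns]
        if missing:
            raise ValueError(f"expression matrix lacks panel genes: {missing}")
        return genes

    def fit(self, X, y):
        df = _as_samples_by_genes(X)
        y = pd.Series(np.asarray(y, dtype=object), index=df.index)
        bad = ~y.isin(STATUSES)
        if bad.any():
            raise ValueError(f"unknown smolt status labels: {sorted(set(y[bad]))}")
        present = [s for s in STATUSES if (y == s).any()]
        if len(present) < 2:
            raise ValueError("training labels must cover at least 2 of the 3 statuses")
        genes = self._panel_genes(df)
        df = df[genes]
        self.pca_ = self.base_pca if self.base_pca is not None else ExpressionPCA(scale=self.scale).fit(df)
        scores = self.pca_.transform(df)
        s1 = scores.iloc[:, self.smolt_axis - 1]
        s2 = scores.iloc[:, self.desmolt_axis - 1]

        mask = y.isin(["pre_smolt", "smolt"])
        if y[mask].nunique() == 2:
            res = youden_threshold(s1[mask], y[mask], positive="smolt")
            self.t_smolt_, self.j_smolt_ = res.threshold, res.j
            self.orientation_smolt_ = res.orientation
        else:
            warnings.warn(
                "pre-smolt/smolt contrast missing a class; smolt-axis "
                "threshold set to an infinite bound (2-class model)",
                stacklevel=2,
            )
            # everything falls on the smolt side
            self.t_smolt_, self.j_smolt_, self.orientation_smolt_ = -np.inf, 0.0, "above"
        mask = y.isin(["smolt", "de_smolt"])
        if y[mask].nunique() == 2:
            res = youden_threshold(s2[mask], y[mask], positive="smolt")
            self.t_desmolt_, self.j_desmolt_ = res.threshold, res.j
            self.orientation_desmolt_ = res.orientation
        else:
            warnings.warn(
                "smolt/de-smolt contrast missing a class; de-smolt-axis "
                "threshold set to an infinite bound (2-class model)",
                stacklevel=2,
            )
            self.t_desmolt_, self.j_desmolt_, self.orientation_desmolt_ = -np.inf, 0.0, "above"
        self.classes_ = np.asarray(STATUSES, dtype=object)
        self.genes_ = genes
        return self

    def decision_scores(self, X) -> pd.DataFrame:
        """Scores of samples on the two classification axes."""
        df = _as_samples_by_genes(X)
        df = df[self._fitted_genes(df)]
        scores = self.pca_.transform(df)
        return pd.DataFrame(
            {
                "smolt_axis": scores.iloc[:, self.smolt_axis - 1],
                "desmolt_axis": scores.iloc[:, self.desmolt_axis - 1],
            },
            index=df.index,
        )

    def _fitted_genes(self, df: pd.DataFrame) -> list[str]:
        if not hasattr(self, "pca_"):
            raise RuntimeError("classifier is not fitted")
        missing = [g for g in self.genes_ if g not in df.columns]
        if missing:
            raise ValueError(f"expression matrix lacks panel genes: {missing}")
        return self.genes_

    def _smolt_side(self, s: np.ndarray, t: float, orientation: str) -> np.ndarray:
        # smolt region is closed: equality counts as smolt
        return s >= t if orientation == "above" else s <= t

    def predict(self, X) -> np.ndarray:
        sc = self.decision_scores(X)
        s1 = sc["smolt_axis"].to_numpy()
        s2 = sc["desmolt_axis"].to_numpy()
        smolt1 = self._smolt_side(s1, self.t_smolt_, self.orientation_smolt_)
        smolt2 = self._smolt_side(s2, self.t_desmolt_, self.orientation_desmolt_)
        out = np.where(~smolt1, "pre_smolt", np.where(~smolt2, "de_smolt", "smolt"))
        return out.astype(object)

    def classify(self, X) -> pd.DataFrame:
        """Per-fish axis scores, status and seawater-tolerance flag."""
        sc = self.decision_scores(X)
        status = self.predict(X)
        return pd.DataFrame(
            {
                "sample_id": sc.index,
                "smolt_axis_score": sc["smolt_axis"].to_numpy(),
                "desmolt_axis_score": sc["desmolt_axis"].to_numpy(),
                "status": status,
                "seawater_tolerant": status == "smolt",
            }
        ).set_index("sample_id", drop=False)

    def thresholds_frame(self) -> pd.DataFrame:
        """One-row serialization of the fitted threshold model."""
        return pd.DataFrame(
            [
                {
                    "smolt_axis": self.smolt_axis,
                    "desmolt_axis": self.desmolt_axis,
                    "t_smolt": self.t_smolt_,
                    "orientation_smolt": self.orientation_smolt_,
                    "j_smolt": self.j_smolt_,
                    "t_desmolt": self.t_desmolt_,
                    "orientation_desmolt": self.orientation_desmolt_,
                    "j_desmolt": self.j_desmolt_,
                }
            ]
        )


def fit_classifier(
    expr_train,
    status,
    panel=None,
    base_pca: ExpressionPCA | None = None,
    smolt_axis: int = 1,
    desmolt_axis: int = 2,
    scale: bool = True,
) -> SeawaterToleranceClassifier:
    """Fit the dual-threshold model on labelled trial fish."""
    clf = SeawaterToleranceClassifier(
        panel=panel,
        base_pca=base_pca,
        smolt_axis=smolt_axis,
        desmolt_axis=desmolt_axis,
        scale=scale,
    )
    return clf.fit(expr_train, status)


def classify(model: SeawaterToleranceClassifier, expr_new) -> pd.DataFrame:
    return model.classify(expr_new)


def monthly_summary(results: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Contingency counts of modelled status by set and month.

    Returns one row per (set_label, month_index) with columns
    ``pre_smolt, smolt, de_smolt``; rows sum to the number of classified
    fish in that stratum.
    """
    if len(results) == 0:
        return pd.DataFrame(columns=["set_label", "month_index", *STATUSES])
    joined = results.join(meta[["set_label", "month_index"]], how="left")
    tab = (
        joined.groupby(["set_label", "month_index"])["status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(STATUSES), fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    return tab
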