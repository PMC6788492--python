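"""Ct-to-expression normalization.

Pipeline: raw Ct values are (1) linearized with the per-assay amplification
efficiency, ``v = E ** (minCt - Ct)``; (2) the most stable reference gene or
gene pair is chosen from the candidate housekeeping assays by a model-based
variance decomposition (Andersen-style: intragroup variance plus shrunken
intergroup deviations, lower = more stable); (3) target expression is
normalized with the efficiency-corrected ddCt method against the chosen
reference and a group-specific calibrator sample, reported as
``log2(2**-ddCt)`` — algebraically the negated ddCt.

The stability decomposition, given log expression ``y_igj`` (gene *i*,
stratum *g*, sample *j*; *k* genes, strata sizes ``n_g``):

1. sample-center: ``z = y - mean_over_genes(y)`` per sample (removes the
   common sample effect);
2. per gene/stratum mean ``zbar_ig`` and within variance ``v_ig``;
3. bias-corrected intragroup variance (sample-centering mixes 1/k of every
   gene's noise into each z): ``sigma2_ig = (v_ig - V_g/(k^2-k)) * k/(k-2)``
   clipped at 0, with ``V_g = sum_i v_ig`` (for k = 2 the correction is
   singular and ``v_ig`` is used as-is);
4. intergroup deviation ``d_ig = zbar_ig - mean_g(zbar_ig)`` with sampling
   variance ``u_ig = sigma2_ig / n_g``;
5. moment estimate of the true deviation variance,
   ``gamma2 = max(0, sum(d^2)/((k-1)(G-1)) - mean(u))``, and shrunken
   deviations ``dtilde = d * gamma2 / (gamma2 + u)``;
6. single-gene stability ``rho_i = mean_g(|dtilde_ig| + sqrt(u_ig))``; a
   gene pair uses the averaged deviations ``(dtilde_i + dtilde_j)/2``
   (opposite-direction deviations cancel) and quarter-sum variance
   ``(u_i + u_j)/4``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CtMatrix

__all__ = [
    "linearize",
    "reference_stability",
    "normalize_ddct",
    "StabilityResult",
    "NormalizationModel",
    "DeltaDeltaCtNormalizer",
]


def _efficiencies(assays: pd.DataFrame, assay_ids, fixed: float | None) -> pd.Series:
    """Per-assay efficiency vector for the given assays (fixed overrides)."""
    if fixed is not None:
        if not 1.0 < fixed <= 2.2:
            raise ValueError(f"fixed efficiency must be in (1, 2.2], got {fixed}")
        return pd.Series(float(fixed), index=list(assay_ids))
    if "efficiency" not in assays.columns:
        raise ValueError(
            "assay table has no 'efficiency' column; supply per-assay "
            "efficiencies or use a fixed efficiency of 2.0"
        )
    eff = assays.set_index("assay_id")["efficiency"] if "assay_id" in assays.columns else assays["efficiency"]
    missing = [a for a in assay_ids if a not in eff.index or pd.isna(eff.get(a))]
    if missing:
        raise ValueError(f"no amplification efficiency for assays: {missing}")
    return eff.reindex(list(assay_ids)).astype(float)


def linearize(ct: CtMatrix, assays: pd.DataFrame, fixed_efficiency: float | None = None) -> CtMatrix:
    """Efficiency-linearize raw Ct values: ``v = E ** (minCt - Ct)``.

    ``minCt`` is the minimum observed (non-missing) Ct of each assay within
    the analysed batch, so outputs lie in (0, 1] with 1 at the most highly
    expressed well.  Missing wells stay missing; an assay with no observed
    well at all is an error.
    """
    if ct.value_kind != "ct":
        raise ValueError(f"expected raw Ct values, got value_kind={ct.value_kind!r}")
    eff = _efficiencies(assays, ct.assay_ids, fixed_efficiency)
    vals = ct.values
    all_missing = np.all(np.isnan(vals), axis=1)
    if all_missing.any():
        bad = [a for a, m in zip(ct.assay_ids, all_missing) if m]
        raise ValueError(f"assay(s) with no observed Ct value: {bad}")
    min_ct = np.nanmin(vals, axis=1, keepdims=True)
    lin = eff.to_numpy()[:, None] ** (min_ct - vals)
    return CtMatrix(pd.DataFrame(lin, index=ct.data.index, columns=ct.data.columns), "linear")


@dataclass
class StabilityResult:
    """Reference-gene stability values and the chosen reference.

    ``gene_stability`` maps each housekeeping assay to its stability value
    (dimensionless, >= 0, lower = more stable); ``pair_stability`` maps each
    unordered pair.  ``chosen_reference`` is the single gene or pair
    attaining the overall minimum (ties broken lexicographically).
    """

    gene_stability: pd.Series
    pair_stability: pd.Series
    chosen_reference: tuple[str, ...]
    strata: pd.Series
    details: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reference": g, "n_genes": 1, "stability": v}
            for g, v in self.gene_stability.items()
        ] + [
            {"reference": "+".join(p), "n_genes": 2, "stability": v}
            for p, v in self.pair_stability.items()
        ]
        out = pd.DataFrame(rows)
        out["chosen"] = out["reference"] == "+".join(self.chosen_reference)
        return out


def _stability_components(y: np.ndarray, strata_codes: np.ndarray):
    """Shrunken intergroup deviations and per-stratum sampling variances.

    ``y`` is genes x samples log expression (no NaN), ``strata_codes`` an
    integer stratum label per sample.  Returns (dtilde, u) each of shape
    (k genes, G strata).
    """
    k, _ = y.shape
    groups = np.unique(strata_codes)
    G = len(groups)
    z = y - y.mean(axis=0, keepdims=True)
    zbar = np.empty((k, G))
    u = np.empty((k, G))
    for gi, g in enumerate(groups):
        zg = z[:, strata_codes == g]
        n_g = zg.shape[1]
        zbar[:, gi] = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        if k > 2:
            sigma2 = np.maximum((v - v.sum() / (k * k - k)) * k / (k - 2), 0.0)
        else:
            sigma2 = v
        u[:, gi] = sigma2 / n_g
    d = zbar - zbar.mean(axis=1, keepdims=True)
    gamma2 = max(np.sum(d * d) / ((k - 1) * (G - 1)) - u.mean(), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dtilde = np.where(gamma2 + u > 0, d * gamma2 / (gamma2 + u), 0.0)
    return dtilde, u


def reference_stability(
    hk: CtMatrix,
    strata: pd.Series | np.ndarray,
    min_stratum_size: int = 2,
) -> StabilityResult:
    """Rank candidate reference genes (and pairs) by expression stability.

    Parameters
    ----------
    hk:
        Linearized values (``value_kind="linear"``) restricted to the
        candidate housekeeping assays; log2-transformed internally.
    strata:
        One grouping label per sample (typically set x month).  Strata with
        fewer than ``min_stratum_size`` samples are excluded with a warning;
        at least two usable strata are required.
    """
    if hk.value_kind != "linear":
        raise ValueError(f"expected linearized values, got value_kind={hk.value_kind!r}")
    if hk.shape[0] < 2:
        raise ValueError("need at least 2 candidate housekeeping genes")
    strata = pd.Series(np.asarray(strata), index=hk.sample_ids)
    counts = strata.value_counts()
    small = counts[counts < min_stratum_size]
    if len(small):
        warnings.warn(
            f"excluding strata with <{min_stratum_size} samples: {list(small.index)}",
            stacklevel=2,
        )
        keep = strata.isin(counts[counts >= min_stratum_size].index)
        hk = hk.subset_samples(list(strata.index[keep]))
        strata = strata[keep]
    if strata.nunique() < 2:
        raise ValueError("need at least 2 usable strata for stability estimation")
    vals = hk.values
    if np.isnan(vals).any():
        raise ValueError("missing values in housekeeping matrix; drop or subset first")
    if (vals <= 0).any():
        raise ValueError("linearized values must be positive")
    y = np.log2(vals)
    codes = pd.factorize(strata)[0]
    dtilde, u = _stability_components(y, codes)
    rho = (np.abs(dtilde) + np.sqrt(u)).mean(axis=1)
    genes = hk.assay_ids
    gene_stab = pd.Series(rho, index=genes, name="stability")
    # pair stability: averaged (possibly counteracting) group deviations
    # and quarter-sum sampling variance of the pair mean.  Deviations are
    # relative to the candidate set's per-sample mean, so with few
    # candidates a pair tends to beat every single gene (halved drift);
    # the single-gene ranking is the meaningful per-gene stability order.
    pair_idx, pair_vals = [], []
    for i, j in itertools.combinations(range(len(genes)), 2):
        dp = (dtilde[i] + dtilde[j]) / 2.0
        up = (u[i] + u[j]) / 4.0
        pair_idx.append((genes[i], genes[j]))
        pair_vals.append((np.abs(dp) + np.sqrt(up)).mean())
    pair_stab = pd.Series(pair_vals, index=pd.Index(pair_idx), name="stability")
    candidates = [((g,), v) for g, v in gene_stab.items()] + [
        (tuple(p), v) for p, v in pair_stab.items()
    ]
    chosen = min(candidates, key=lambda t: (t[1], t[0]))[0]
    return StabilityResult(gene_stab, pair_stab, chosen, strata)


@dataclass
class NormalizationModel:
    """Everything needed to apply ddCt normalization to new samples."""

    reference: tuple[str, ...]
    calibrators: dict[str, str]  # group -> calibrator sample id
    efficiencies: pd.Series  # per assay
    aggregation: str = "mean"  # mean (single ref) / geometric_mean (pair)

    def __post_init__(self) -> None:
        if len(self.reference) not in (1, 2):
            raise ValueError("reference must be a single gene or a pair")
        self.aggregation = "mean" if len(self.reference) == 1 else "geometric_mean"


def normalize_ddct(
    ct: CtMatrix,
    sample_groups: pd.Series,
    model: NormalizationModel,
) -> CtMatrix:
    """Efficiency-corrected ddCt normalization to log2 relative expression.

    For sample *s* in group *g* with calibrator *c(g)*::

        x_as = log2(E_a ** (Ct_a,c(g) - Ct_a,s)) - R_s

    ``R_s`` aggregates the reference gene(s): a single gene contributes its
    own log2 term; a pair contributes the arithmetic mean of the two log2
    terms (equivalently the log2 geometric mean of linearized ratios).
    Calibrator samples map to exactly 0 for every assay.  Algebraically the
    result is ``log2(2**-ddCt)`` = ``-ddCt``, with per-assay efficiency
    correction.

    Missing calibrator Ct for an assay turns that assay's whole column for
    the group into missing values (with a warning); a missing reference Ct
    for a sample voids that sample.
    """
    if ct.value_kind != "ct":
        raise ValueError(f"expected raw Ct values, got value_kind={ct.value_kind!r}")
    sample_groups = pd.Series(sample_groups)
    missing = [s for s in ct.sample_ids if s not in sample_groups.index]
    if missing:
        raise ValueError(f"no group label for samples: {missing}")
    for r in model.reference:
        if r not in ct.data.index:
            raise ValueError(f"reference assay {r!r} not in matrix")
    eff = model.efficiencies.reindex(ct.assay_ids)
    if eff.isna().any():
        raise ValueError(
            f"no efficiency for assays: {list(eff.index[eff.isna()])}"
        )
    log2e = np.log2(eff.to_numpy())[:, None]
    out = pd.DataFrame(
        np.nan, index=ct.data.index, columns=ct.data.columns, dtype=float
    )
    for group, cal in model.calibrators.items():
        cols = [s for s in ct.sample_ids if sample_groups[s] == group]
        if not cols:
            continue
        if cal not in ct.data.columns:
            raise ValueError(f"calibrator sample {cal!r} for group {group!r} not in matrix")
        cal_ct = ct.data[cal].to_numpy()[:, None]
        if np.isnan(cal_ct).any():
            bad = [a for a, m in zip(ct.assay_ids, np.isnan(cal_ct).ravel()) if m]
            warnings.warn(
                f"calibrator {cal!r} has missing Ct for assays {bad}; those "
                f"assays become missing for group {group!r}",
                stacklevel=2,
            )
        sub = ct.data[cols].to_numpy()
        terms = log2e * (cal_ct - sub)  # log2(E ** dCt), assays x samples
        ref_rows = [ct.assay_ids.index(r) for r in model.reference]
        r_s = terms[ref_rows, :].mean(axis=0, keepdims=True)
        out.loc[:, cols] = terms - r_s
    unassigned = sample_groups.reindex(ct.sample_ids)
    unknown = set(unassigned.unique()) - set(model.calibrators)
    if unknown:
        raise ValueError(f"no calibrator for group(s): {sorted(map(str, unknown))}")
    return CtMatrix(out, "log2rel")


class DeltaDeltaCtNormalizer(BaseEstimator, TransformerMixin):
    """Transformer from raw Ct matrices to calibrated log2 relative expression.

    ``fit`` selects the reference gene or pair by stability (unless one is
    forced), resolves the per-group calibrator samples, and stores per-assay
    efficiencies; ``transform`` applies efficiency-corrected ddCt.

    Parameters
    ----------
    reference:
        ``"auto"`` (stability selection over housekeeping assays) or an
        explicit assay id / pair of ids.
    strata_cols:
        Metadata columns crossed to form the stability strata
        (default ``("set_label", "month_index")``).
    fixed_efficiency:
        Force a single efficiency for every assay (2.0 gives the classic
        uncorrected ddCt); ``None`` uses the per-assay measured values.
    """

    def __init__(
        self,
        reference: str | tuple = "auto",
        strata_cols: tuple = ("set_label", "month_index"),
        fixed_efficiency: float | None = None,
    ):
        self.reference = reference
        self.strata_cols = strata_cols
        self.fixed_efficiency = fixed_efficiency

    def fit(self, X: CtMatrix, y=None, *, meta: pd.DataFrame, assays: pd.DataFrame):
        meta = meta.loc[list(X.sample_ids)]
        self.efficiencies_ = _efficiencies(assays, X.assay_ids, self.fixed_efficiency)
        hk_ids = [
            a
            for a in X.assay_ids
            if a in assays.index and bool(assays.loc[a, "is_housekeeping"])
        ]
        if self.reference == "auto":
            if len(hk_ids) < 2:
                raise ValueError(
                    "reference='auto' needs >=2 housekeeping assays in the matrix"
                )
            hk_lin = linearize(X.subset_assays(hk_ids), assays, self.fixed_efficiency)
            strata = meta[list(self.strata_cols)].astype(str).agg("|".join, axis=1)
            self.stability_ = reference_stability(hk_lin, strata)
            ref = self.stability_.chosen_reference
        else:
            ref = (self.reference,) if isinstance(self.reference, str) else tuple(self.reference)
            self.stability_ = None
        calibrators: dict[str, str] = {}
        for group, sub in meta.groupby("group", observed=True):
            cals = sub.index[sub["is_calibrator"]]
            if len(cals) != 1:
                raise ValueError(
                    f"group {group!r} must have exactly one calibrator sample, "
                    f"found {len(cals)}"
                )
            calibrators[group] = cals[0]
        self.model_ = NormalizationModel(ref, calibrators, self.efficiencies_)
        self.reference_ = ref
        self.calibrators_ = calibrators
        return self

    def transform(self, X: CtMatrix, *, meta: pd.DataFrame) -> CtMatrix:
        if not hasattr(self, "model_"):
            raise RuntimeError("normalizer is not fitted")
        groups = meta.loc[list(X.sample_ids), "group"]
        eff = self.efficiencies_
        extra = [a for a in X.assay_ids if a not in eff.index]
        if extra:
            raise ValueError(f"no efficiency recorded for assays: {extra}")
        return normalize_ddct(X, groups, self.model_)

    def fit_transform(self, X: CtMatrix, y=None, **kw) -> CtMatrix:  # type: ignore[override]
        meta = kw["meta"]
        return self.fit(X, meta=meta, assays=kw["assays"]).transform(X, meta=meta)
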