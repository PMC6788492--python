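"""Physiology and environment validation of the biomarker panel.

Three checks tie the gene-expression axes back to classical smoltification
indices:

* body condition factor, ``100 * mass / length^3`` (g, cm);
* Pearson correlations of the panel-PCA axes (PC1/PC2) with gill NKA
  activity (log10-transformed, as conventionally plotted), body size,
  condition and any appearance covariates;
* per-gene Student's t-tests (pooled variance) between freshwater and
  seawater fish sampled at the same time.

Significance is reported at an uncorrected alpha (0.05 by default, matching
how the panels were originally reported across 37 assays); a
Benjamini-Hochberg column can be added on request.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pca import _as_samples_by_genes
from .panel import _pearson_with_p

__all__ = ["condition_factor", "correlate_axes", "fw_sw_tests"]


def condition_factor(mass_g, length_cm):
    """Fulton's condition factor, ``100 * mass / length**3``.

    Vectorized; every mass and length must be strictly positive.
    """
    mass = np.asarray(mass_g, dtype=float)
    length = np.asarray(length_cm, dtype=float)
    if np.any(mass[~np.isnan(mass)] <= 0) or np.any(length[~np.isnan(length)] <= 0):
        raise ValueError("mass and length must be > 0")
    out = 100.0 * mass / length**3
    return float(out) if out.ndim == 0 else out


def correlate_axes(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    log10_nka: bool = True,
) -> pd.DataFrame:
    """Pearson correlations between PCA axes and physiology covariates.

    Uses pairwise-complete observations.  ``nka_activity`` is log10
    transformed before correlating (it is reported and plotted on a log
    scale).  Entries with fewer than 3 complete pairs or a zero-variance
    side are flagged not computable.

    Returns one row per (axis, covariate) with columns ``axis, covariate,
    n, r, p, significant, computable``.
    """
    covariates = covariates.loc[scores.index]
    rows = []
    for axis in scores.columns:
        a = scores[axis].to_numpy(dtype=float)
        for cov in covariates.columns:
            c = pd.to_numeric(covariates[cov], errors="coerce").to_numpy(dtype=float)
            if log10_nka and cov == "nka_activity":
                with np.errstate(invalid="ignore", divide="ignore"):
                    c = np.log10(c)
            ok = ~np.isnan(a) & ~np.isnan(c)
            n = int(ok.sum())
            if n < 3:
                rows.append((axis, cov, n, np.nan, np.nan, False, False))
                continue
            r, p = _pearson_with_p(a[ok], c[ok])
            computable = not np.isnan(r)
            rows.append(
                (axis, cov, n, r, p, bool(computable and p < alpha), computable)
            )
    return pd.DataFrame(
        rows, columns=["axis", "covariate", "n", "r", "p", "significant", "computable"]
    )


def fw_sw_tests(
    expr,
    environment,
    alpha: float = 0.05,
    welch: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-tests between freshwater and seawater fish.

    Student's pooled-variance t-test by default (``welch=True`` switches to
    the unequal-variance form).  Direction is ``sign(mean_SW - mean_FW)``.
    Genes constant in both groups are flagged not computable.

    Returns one row per gene with columns ``assay_id, mean_fw, mean_sw,
    t, p, direction, significant, computable`` (plus ``p_bh`` if
    ``bh_correct``).
    """
    df = _as_samples_by_genes(expr)
    env = pd.Series(np.asarray(environment, dtype=object), index=df.index)
    bad = ~env.isin(["FW", "SW"])
    if bad.any():
        raise ValueError(f"environment must be FW or SW; got {sorted(set(env[bad]))}")
    fw = df[env == "FW"]
    sw = df[env == "SW"]
    if len(fw) < 2 or len(sw) < 2:
        raise ValueError("need >=2 samples in each environment")
    rows = []
    for gene in df.columns:
        x = fw[gene].dropna().to_numpy(dtype=float)
        y = sw[gene].dropna().to_numpy(dtype=float)
        m_fw, m_sw = x.mean(), y.mean()
        if len(x) < 2 or len(y) < 2 or (x.var(ddof=1) == 0 and y.var(ddof=1) == 0):
            rows.append((gene, m_fw, m_sw, np.nan, np.nan, 0, False, False))
            continue
        t, p = stats.ttest_ind(y, x, equal_var=not welch)
        direction = int(np.sign(m_sw - m_fw))
        rows.append((gene, m_fw, m_sw, float(t), float(p), direction, bool(p < alpha), True))
    out = pd.DataFrame(
        rows,
        columns=["assay_id", "mean_fw", "mean_sw", "t", "p", "direction", "significant", "computable"],
    )
    if bh_correct:
        ok = out["computable"]
        p_bh = np.full(len(out), np.nan)
        if ok.any():
            p_bh[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_bh"] = p_bh
        out.loc[ok, "significant"] = out.loc[ok, "p_bh"] < alpha
    return out
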