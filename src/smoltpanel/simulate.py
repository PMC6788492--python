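"""Synthetic Ct-level datasets with known ground truth.

The generator emulates the structure of a monthly hatchery smoltification
survey so that every pipeline stage (linearization, reference-gene
selection, ddCt, panel discovery, threshold classification, validation
stats) can be exercised against a known answer:

* monthly cohorts of several groups (species/ecotype), each with its own
  per-gene expression offset and one designated calibrator sample;
* a monotone latent smolt state ``s(m)`` driving signal genes up or down,
  and a late de-smolt reversal ``d(m)`` loading on a distinct axis; signal
  genes partially revert under ``d`` (de-smolts drift back toward
  freshwater physiology), de-smolt-axis genes load on ``d`` only;
* three housekeeping genes of varying stability (one clean, two with
  extra noise and group-level offsets) and a block of null genes;
* gill NKA activity and body covariates correlated with the latent state.

Log2 expression is ``x = baseline + group offset +
beta_s * s(m) + beta_d * d(m) + noise`` and Ct values are synthesized by
inverting the linearization formula, ``Ct = Ct_ref - x * ln2 / ln(E)``, so
the normalization path is exactly exercised.  True statuses come from
latent thresholds: de-smolt if ``d > d*``, else smolt if ``s > s*``, else
pre-smolt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data import CtMatrix, validate_assay_table, validate_sample_meta

__all__ = [
    "GeneSpec",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "inject_seawater_arm",
    "trial_config",
]


@dataclass(frozen=True)
class GeneSpec:
    """One simulated assay.

    ``beta_s``/``beta_d`` are log2 effects per unit of the smolt latent s
    and the de-smolt latent d.  ``sigma`` is residual noise (log2),
    ``sigma_group`` the SD of per-group offsets (None = config default;
    set larger to make a housekeeping gene unstable).  ``efficiency``
    None means drawn once from the configured range.
    """

    assay_id: str
    role: str  # signal_up / signal_down / desmolt_axis / housekeeping_stable / housekeeping_unstable / null
    beta_s: float = 0.0
    beta_d: float = 0.0
    baseline_log2: float = 0.0
    sigma: float = 0.5
    sigma_group: float | None = None
    efficiency: float | None = None


def default_genes() -> tuple[GeneSpec, ...]:
    """Default gene set: 10 up, 10 down, 5 de-smolt, 3 housekeeping, 10 null.

    Signal effect sizes span 1.0-1.5 log2 units over the month range (the
    latent s runs 0..1); the candidate assays being emulated were picked
    from the extremes of microarray fold changes, so strong responses are
    the norm.  De-smolts revert toward their freshwater expression by a
    gene-specific fraction of the smolt effect (0.1-0.5): the reversal is
    partial — the bulk of the distinct de-smolt signature is carried by
    the dedicated de-smolt-axis genes, so de-smolts drop only part-way
    down the smolt axis while separating clearly on the de-smolt axis.
    Housekeeping stability varies through residual noise: one clean gene,
    two increasingly noisy ones.
    """
    genes: list[GeneSpec] = []
    betas = np.linspace(1.0, 1.5, 10)
    reversals = np.linspace(0.1, 0.5, 10)
    for i, b in enumerate(betas):
        genes.append(
            GeneSpec(f"up{i+1:02d}", "signal_up", beta_s=b, beta_d=-reversals[i] * b)
        )
    for i, b in enumerate(betas):
        genes.append(
            GeneSpec(
                f"dn{i+1:02d}", "signal_down", beta_s=-b, beta_d=reversals[-1 - i] * b
            )
        )
    for i in range(5):
        sign = 1.0 if i % 2 == 0 else -1.0
        genes.append(
            GeneSpec(f"ds{i+1:02d}", "desmolt_axis", beta_d=sign * (1.0 + 0.1 * i))
        )
    genes.append(
        GeneSpec("hk_stable", "housekeeping_stable", sigma=0.05, sigma_group=0.0)
    )
    genes.append(
        GeneSpec("hk_noisy1", "housekeeping_unstable", sigma=0.15, sigma_group=0.0)
    )
    genes.append(
        GeneSpec("hk_noisy2", "housekeeping_unstable", sigma=0.3, sigma_group=0.0)
    )
    for i in range(10):
        genes.append(GeneSpec(f"null{i+1:02d}", "null"))
    return tuple(genes)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and generative parameters (defaults = study conditions)."""

    groups: tuple = ("coho", "sockeye", "chinook_stream", "chinook_ocean")
    sets_per_group: int = 1
    months: tuple = (0, 1, 2, 3, 4)
    fish_per_set_month: int = 10
    genes: tuple = field(default_factory=default_genes)
    #: latent smolt state per month (monotone increasing)
    smolt_state: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    #: latent de-smolt reversal per month (zero until onset)
    desmolt_state: tuple = (0.0, 0.0, 0.0, 0.0, 1.0)
    #: groups that de-smolt (d applies there only); None = every group.
    #: The survey being emulated saw de-smolting only in the ocean-type
    #: fish held longest in freshwater.
    desmolt_groups: tuple | None = ("chinook_ocean",)
    s_threshold: float = 0.4
    d_threshold: float = 0.5
    sigma_group: float = 0.2
    #: NKA activity = c0 + c1 * s + noise, truncated positive
    nka_c0: float = 2.0
    nka_c1: float = 8.0
    nka_sigma: float = 1.5
    length0_cm: float = 6.0
    length_growth_cm: float = 0.8
    length_sigma: float = 0.4
    condition_base: float = 1.15
    condition_smolt_drop: float = 0.15
    condition_sigma: float = 0.05
    ct_ref: float = 25.0
    efficiency_range: tuple = (1.85, 2.05)
    seed: int = 1

    def validate(self) -> None:
        problems = []
        if len(self.months) != len(self.smolt_state) or len(self.months) != len(self.desmolt_state):
            problems.append("months, smolt_state and desmolt_state must have equal length")
        if any(b > a for a, b in zip(self.smolt_state[1:], self.smolt_state[:-1])):
            problems.append("smolt_state must be monotone non-decreasing")
        if self.fish_per_set_month < 1:
            problems.append("fish_per_set_month must be >= 1")
        if self.sets_per_group < 1:
            problems.append("sets_per_group must be >= 1")
        if not self.genes:
            problems.append("genes must be non-empty")
        ids = [g.assay_id for g in self.genes]
        if len(set(ids)) != len(ids):
            problems.append("gene assay_ids must be unique")
        lo, hi = self.efficiency_range
        if not (1.0 < lo <= hi <= 2.2):
            problems.append("efficiency_range must lie in (1, 2.2]")
        if self.desmolt_groups is not None and not set(self.desmolt_groups) <= set(self.groups):
            problems.append("desmolt_groups must be a subset of groups")
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Generative truth: per-fish latents/status, gene roles, offsets."""

    samples: pd.DataFrame  # sample_id, s, d, status
    genes: pd.DataFrame  # assay_id, role, beta_s, beta_d, sigma
    group_offsets: pd.DataFrame  # genes x groups
    log2_expression: pd.DataFrame  # realized x (genes x samples)


class SyntheticDataset(NamedTuple):
    ct: CtMatrix
    meta: pd.DataFrame
    assays: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig


def _status(s: float, d: float, cfg: SyntheticConfig) -> str:
    if d > cfg.d_threshold:
        return "de_smolt"
    if s > cfg.s_threshold:
        return "smolt"
    return "pre_smolt"


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a full synthetic survey; the seed fully determines output."""
    cfg = config or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.genes)
    gene_ids = [g.assay_id for g in genes]

    eff = np.array(
        [
            g.efficiency if g.efficiency is not None else rng.uniform(*cfg.efficiency_range)
            for g in genes
        ]
    )
    sigma_group = np.array(
        [cfg.sigma_group if g.sigma_group is None else g.sigma_group for g in genes]
    )
    offsets = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(genes), len(cfg.groups))) * sigma_group[:, None],
        index=gene_ids,
        columns=list(cfg.groups),
    )

    desmolt_groups = set(cfg.groups if cfg.desmolt_groups is None else cfg.desmolt_groups)
    sample_ids, meta_rows, truth_rows, x_cols = [], [], [], []
    month_s = dict(zip(cfg.months, cfg.smolt_state))
    month_d = dict(zip(cfg.months, cfg.desmolt_state))
    beta_s = np.array([g.beta_s for g in genes])
    beta_d = np.array([g.beta_d for g in genes])
    base = np.array([g.baseline_log2 for g in genes])
    sigma = np.array([g.sigma for g in genes])

    for group in cfg.groups:
        for k in range(cfg.sets_per_group):
            set_label = f"{group}_set{k+1}"
            for m in cfg.months:
                s = month_s[m]
                d = month_d[m] if group in desmolt_groups else 0.0
                for i in range(cfg.fish_per_set_month):
                    sid = f"{set_label}_m{m}_f{i+1:02d}"
                    x = (
                        base
                        + offsets[group].to_numpy()
                        + beta_s * s
                        + beta_d * d
                        + rng.normal(0.0, 1.0, size=len(genes)) * sigma
                    )
                    x_cols.append(x)
                    sample_ids.append(sid)
                    status = _status(s, d, cfg)
                    nka = max(cfg.nka_c0 + cfg.nka_c1 * s + rng.normal(0, cfg.nka_sigma), 0.1)
                    length = max(
                        cfg.length0_cm + cfg.length_growth_cm * m + rng.normal(0, cfg.length_sigma),
                        1.0,
                    )
                    cond = max(
                        cfg.condition_base
                        - cfg.condition_smolt_drop * s
                        + rng.normal(0, cfg.condition_sigma),
                        0.5,
                    )
                    mass = cond * length**3 / 100.0
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "group": group,
                            "set_label": set_label,
                            "month_index": m,
                            "environment": "FW",
                            "nka_activity": nka,
                            "length_cm": length,
                            "mass_g": mass,
                            "brightness": 0.2 + 0.6 * s + rng.normal(0, 0.15),
                            "caudal_darkness": 0.1 + 0.5 * s + rng.normal(0, 0.15),
                            "is_calibrator": False,
                        }
                    )
                    truth_rows.append({"sample_id": sid, "s": s, "d": d, "status": status})

    x_mat = pd.DataFrame(np.column_stack(x_cols), index=gene_ids, columns=sample_ids)
    ct_vals = cfg.ct_ref - x_mat.to_numpy() * np.log(2.0) / np.log(eff)[:, None]
    ct = CtMatrix(pd.DataFrame(ct_vals, index=gene_ids, columns=sample_ids), "ct")

    meta = pd.DataFrame(meta_rows)
    # one calibrator per group: the first fish of the first month
    for group in cfg.groups:
        idx = meta.index[meta["group"] == group][0]
        meta.loc[idx, "is_calibrator"] = True
    meta = validate_sample_meta(meta)

    assays = validate_assay_table(
        pd.DataFrame(
            {
                "assay_id": gene_ids,
                "gene_symbol": gene_ids,
                "predicted_direction": [
                    "up" if g.role == "signal_up" else "down" if g.role == "signal_down" else ""
                    for g in genes
                ],
                "functional_group": [g.role for g in genes],
                "efficiency": eff,
                "passed_efficiency": True,
                "is_housekeeping": [g.role.startswith("housekeeping") for g in genes],
            }
        )
    )
    truth = GroundTruth(
        samples=pd.DataFrame(truth_rows).set_index("sample_id", drop=False),
        genes=pd.DataFrame(
            {
                "assay_id": gene_ids,
                "role": [g.role for g in genes],
                "beta_s": beta_s,
                "beta_d": beta_d,
                "sigma": sigma,
            }
        ).set_index("assay_id", drop=False),
        group_offsets=offsets,
        log2_expression=x_mat,
    )
    return SyntheticDataset(ct, meta, assays, truth, cfg)


def inject_seawater_arm(
    dataset: SyntheticDataset,
    month: int,
    effect_map: dict[str, float] | None = None,
    groups: tuple | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Add a seawater cohort mirroring an existing freshwater month.

    Duplicates the design of the chosen month's cohort (same latent states
    and fish count, fresh residual noise), shifts gene means by
    ``effect_map`` (log2 units; missing genes shift 0) and labels the new
    fish ``environment="SW"``.  A zero/empty effect map gives a pure null
    contrast for type-I calibration of :func:`smoltpanel.validation.fw_sw_tests`.
    """
    cfg = dataset.config
    if month not in cfg.months:
        raise ValueError(f"month {month} not in config months {cfg.months}")
    effect_map = effect_map or {}
    unknown = [g for g in effect_map if g not in dataset.truth.genes.index]
    if unknown:
        raise ValueError(f"effect map names unknown genes: {unknown}")
    sel_groups = tuple(groups) if groups is not None else cfg.groups
    meta = dataset.meta
    cohort = meta[(meta["month_index"] == month) & meta["group"].isin(sel_groups)]
    if len(cohort) == 0:
        raise ValueError(f"no freshwater fish at month {month} for groups {sel_groups}")
    rng = np.random.default_rng(cfg.seed + 7919 * (month + 1) if seed is None else seed)

    genes = list(cfg.genes)
    gene_ids = [g.assay_id for g in genes]
    beta_s = np.array([g.beta_s for g in genes])
    beta_d = np.array([g.beta_d for g in genes])
    base = np.array([g.baseline_log2 for g in genes])
    sigma = np.array([g.sigma for g in genes])
    shift = np.array([effect_map.get(g, 0.0) for g in gene_ids])
    s = dict(zip(cfg.months, cfg.smolt_state))[month]
    d_month = dict(zip(cfg.months, cfg.desmolt_state))[month]
    eff = dataset.assays["efficiency"].reindex(gene_ids).to_numpy()

    new_cols, new_meta, new_truth = {}, [], []
    for sid, row in cohort.iterrows():
        d = (
            d_month
            if cfg.desmolt_groups is None or row["group"] in cfg.desmolt_groups
            else 0.0
        )
        x = (
            base
            + dataset.truth.group_offsets[row["group"]].to_numpy()
            + beta_s * s
            + beta_d * d
            + shift
            + rng.normal(0.0, 1.0, size=len(genes)) * sigma
        )
        new_id = f"{sid}_SW"
        new_cols[new_id] = cfg.ct_ref - x * np.log(2.0) / np.log(eff)
        nm = row.to_dict()
        nm.update(sample_id=new_id, environment="SW", is_calibrator=False)
        new_meta.append(nm)
        new_truth.append(
            {"sample_id": new_id, "s": s, "d": d, "status": _status(s, d, cfg)}
        )

    ct = CtMatrix(
        pd.concat([dataset.ct.data, pd.DataFrame(new_cols, index=gene_ids)], axis=1),
        "ct",
    )
    meta_out = validate_sample_meta(
        pd.concat([meta.reset_index(drop=True), pd.DataFrame(new_meta)], ignore_index=True)
    )
    truth = GroundTruth(
        samples=pd.concat(
            [dataset.truth.samples.reset_index(drop=True), pd.DataFrame(new_truth)],
            ignore_index=True,
        ).set_index("sample_id", drop=False),
        genes=dataset.truth.genes,
        group_offsets=dataset.truth.group_offsets,
        log2_expression=dataset.truth.log2_expression,
    )
    return SyntheticDataset(ct, meta_out, dataset.assays, truth, cfg)


def trial_config(seed: int = 1, fish_per_trial: int = 40) -> SyntheticConfig:
    """Config emulating labelled seawater-transfer trials for one group.

    A single ocean-type-like group sampled at four times spanning the
    smoltification window: two pre-smolt trials, one smolt trial, one
    de-smolt trial.  Latent states are staged so each trial has an
    unambiguous status, mirroring trial-level labels assigned from acute
    seawater-transfer survival in the companion experiment being emulated.
    """
    return SyntheticConfig(
        groups=("chinook_ocean",),
        desmolt_groups=("chinook_ocean",),
        months=(0, 1, 2, 3),
        smolt_state=(0.1, 0.3, 0.8, 0.9),
        desmolt_state=(0.0, 0.0, 0.0, 1.0),
        fish_per_set_month=fish_per_trial,
        seed=seed,
    )
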