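# Methods

This note documents the statistical models implemented in `smoltpanel`,
their assumptions, the tunable parameters, and the design decisions taken
where the workflow left choices open.

## Ct normalization

**Linearization.** For assay *a* with amplification efficiency
E<sub>a</sub> ∈ (1, 2.2] (per-cycle fold amplification; 2 is ideal), raw
cycle thresholds become relative quantities
`v_as = E_a^(minCt_a − Ct_as)`, where `minCt_a` is the minimum observed Ct
of the assay within the analysed batch. Outputs lie in (0, 1], with 1 at
the most highly expressed well. The batch-local `minCt` makes values
comparable only within one analysis — intentional, since every downstream
statistic is relative. Failed wells stay missing and are never imputed; an
assay missing in more than half its wells is dropped with a warning
(`CtMatrix.drop_sparse_assays`), a policy chosen to match the 50%
missingness filter common in the upstream discovery analyses.

**Reference-gene stability.** Candidate housekeeping assays are ranked by
a model-based variance decomposition in the spirit of the established
reference-gene stability estimator (intra- plus intergroup variation).
With log₂ expression y<sub>igj</sub> (gene *i* of *k*, stratum *g* of *G*,
sample *j* of n<sub>g</sub>; strata default to the set × month crossing):

1. z = y − per-sample mean over genes (removes the common sample effect);
2. per gene/stratum mean z̄<sub>ig</sub> and within-stratum variance
   v<sub>ig</sub>;
3. bias-corrected intragroup variance
   σ²<sub>ig</sub> = (v<sub>ig</sub> − V<sub>g</sub>/(k²−k))·k/(k−2),
   clipped at 0, with V<sub>g</sub> = Σ<sub>i</sub> v<sub>ig</sub>
   (sample-centering mixes 1/k of every gene's noise into each z; for
   k = 2 the correction is singular and v is used as-is);
4. intergroup deviation d<sub>ig</sub> = z̄<sub>ig</sub> − mean over strata,
   with sampling variance u<sub>ig</sub> = σ²<sub>ig</sub>/n<sub>g</sub>;
5. γ² = max(0, Σd²/((k−1)(G−1)) − mean(u)) estimates the variance of the
   true deviations; the shrunken deviation is d̃ = d·γ²/(γ²+u);
6. stability ρ<sub>i</sub> = mean over strata of (|d̃<sub>ig</sub>| +
   √u<sub>ig</sub>); a pair uses the averaged deviations (d̃_i+d̃_j)/2 —
   opposite deviations counteract — and the quarter-sum variance
   (u_i+u_j)/4.

Lower is more stable; the reference is the single gene or pair attaining
the overall minimum (ties broken lexicographically). One caveat is
documented rather than hidden: deviations are measured *relative to the
candidate set*, so with very few candidates (the common three-gene panel)
d sums to zero across genes and a pair mechanically halves whatever
deviation the excluded gene carries. Pairs therefore often edge out
singles; the single-gene ranking is the meaningful per-gene stability
order, and the tests assert recovery of the known most-stable gene on that
ranking. The exact shrinkage constants follow the equations above; an
independent pure-Python implementation of the same equations serves as the
numerical oracle (agreement ≤ 1e-10).

**ΔΔCt.** For sample *s* in group *g* with that group's calibrator c(g):

    x_as = log2(E_a^(Ct_a,c(g) − Ct_a,s)) − R_s

R<sub>s</sub> is the reference term: the single reference gene's own log₂
term, or for a pair the arithmetic mean of the two log₂ terms (equal to
the log₂ geometric mean of the linearized ratios). Calibrator samples map
to exactly 0. The published transform `log₂(2^−ΔΔCt)` is algebraically the
negated ΔΔCt; the package computes it with per-assay efficiencies
(Pfaffl-style) for consistency with the linearization step, and
`fixed_efficiency=2.0` restores the classic Livak behaviour. Whether the
original workflow used measured or ideal efficiencies in this step is not
stated; per-assay correction is the default here.

## Panel discovery

PCA is computed by SVD on centered, unit-variance-scaled log₂ expression
(scaling is a flag; the original report does not state it, and scaling
makes the axis insensitive to per-gene dynamic range). Determinism across
linear-algebra backends is enforced by making the largest-magnitude
loading of each component positive; a separate per-component orientation
sign is then set so that the smoltification axis correlates positively
with month (later months score higher). Explained-variance fractions are
reported over all min(n−1, p) components and sum to 1.

The smoltification axis is the component among the first k_max (default 3,
matching how the leading components were inspected in practice) with
maximal |Pearson r| against the month ordinal. Genes are ranked by the
exact-t p-value of their correlation with the axis scores; ties break by
larger |r|, then assay id; constant genes are flagged not-computable and
rank last. `select_panel` keeps the top-n genes with p < α (defaults
n = 10, α = 0.05, uncorrected — matching how the original panels were
reported across 37 assays; a Benjamini–Hochberg switch exists but is off
by default). `select_panel_dual_axis` implements the stricter two-axis
rule as the *intersection* of per-axis significance, ordered by min(p);
"significant on both axes" is ambiguous between intersection and combined
evidence, and intersection was chosen and recorded.

## Seawater-tolerance classifier

Candidate ROC cutpoints are the midpoints between consecutive distinct
scores plus ±∞; both orientations are evaluated and Youden's
J = sensitivity + specificity − 1 is maximized. Ties break by smallest
|threshold|, then the lower threshold, then orientation "above" — a
determinism rule, since the data leave the optimum non-unique. The
smolt-axis threshold is fit on pre-smolt vs smolt fish (de-smolts
excluded) and the de-smolt-axis threshold on smolt vs de-smolt fish
(pre-smolts excluded). If a status is absent the corresponding threshold
degenerates to an infinite bound with a warning (2-class model).

Classification geometry: a fish on the pre-smolt side of the smolt-axis
threshold is pre-smolt; otherwise, on the de-smolt side of the second
threshold, de-smolt; otherwise smolt. Two boundary conventions are
declared because the source material does not print them: the smolt region
is closed (a fish exactly on a threshold is a smolt), and a fish on the
wrong side of both thresholds is pre-smolt — a fish that never crossed the
smolt threshold cannot be in the post-smolt de-smolt state. Which side of
each axis is "smolt" is always learned from the training labels because
PCA signs are arbitrary.

## Validation statistics

Condition factor is 100·mass/length³ (g, cm). Axis–covariate correlations
use pairwise-complete observations and the exact-t Pearson p; NKA activity
is log₁₀-transformed first (it is conventionally reported and plotted on a
log scale). Freshwater/seawater contrasts use the pooled-variance
Student's t-test (the test named in the source workflow; Welch by flag),
two-sided, α = 0.05 uncorrected, with direction = sign(mean_SW − mean_FW).
Degenerate cases (zero variance, < 3 complete pairs) are flagged
not-computable rather than erroring.

## Synthetic-data generator

The generator emulates a four-group (Coho, Sockeye, stream- and ocean-type
Chinook analogues) monthly survey: 5 months × 10 fish per group by
default, one calibrator fish per group. Log₂ expression is

    x = baseline + δ_group + β_s·s(m) + β_d·d(m) + ε,   ε ~ N(0, σ²)

with s(m) a monotone latent smolt state (0, 0.25, 0.5, 0.75, 1 across
months) and d(m) a de-smolt reversal (0 until the final month, then 1)
that applies only to the designated de-smolting group (the ocean-type
analogue — in the survey being emulated only the fish held longest in
freshwater reverted; configurable, `None` = all groups). Ct values invert
the linearization formula, `Ct = Ct_ref − x·ln2/lnE` with Ct_ref = 25
cycles, so the normalization path is exercised exactly; amplification
efficiencies are drawn once from U(1.85, 2.05). True statuses come from
latent thresholds (de-smolt if d > 0.5, else smolt if s > 0.4, else
pre-smolt), giving the classifier an objective recovery target analogous
to trial-level labels.

Default gene panel (38 assays): 10 up- and 10 downregulated signal genes
with |β_s| spanning 1.0–1.5 log₂ units over the month range — the
catalogued candidates were selected from the extremes of microarray fold
changes, so strong responders are the realistic norm — with residual noise
σ = 0.5; 5 de-smolt-axis genes loading only on d (|β_d| 1.0–1.4); 3
housekeeping genes whose stability varies through noise (σ = 0.05, 0.15,
0.3; the clean gene is the generative best reference); and 10 null genes.
Group offsets are N(0, 0.2²) per gene × group. Signal genes revert under d
by a gene-specific fraction of their smolt effect, linearly spaced
0.1–0.5: the reversal is deliberately partial and heterogeneous. Two
modelling facts force this shape. First, if every gene's de-smolt loading
were proportional to its smolt loading the gene-space signal would be
rank-1 and no gene could correlate with an orthogonal de-smolt axis — the
dual-axis selection rule would be unsatisfiable in principle. Second,
under the pre-smolt-wins precedence rule, de-smolts must stay on the smolt
side of the smolt-axis threshold to be classifiable, so the bulk of the
distinct de-smolt signature is carried by the dedicated de-smolt-axis
genes rather than by reversal of the smolt panel. NKA activity is
2 + 8·s + N(0, 1.5²) µmol ADP (mg protein)⁻¹ h⁻¹ truncated positive;
length grows 0.8 cm/month from 6 cm; mass follows a condition factor that
declines with s (smolts grow leaner); brightness and caudal-darkness
appearance covariates track s with noise.

`inject_seawater_arm` duplicates a month's cohort design with fresh
residual noise (verbatim duplication would make the FW/SW t-tests
degenerate), applies per-gene log₂ mean shifts, and labels the new fish
SW — a zero shift gives the null contrast used for type-I calibration.

What the generator does *not* emulate: missing wells, chip/batch effects
beyond group offsets, non-Gaussian expression noise, unequal monthly
sample sizes, within-trial status heterogeneity, and any image-derived
covariate structure beyond simple latent coupling. Passing tests
demonstrate the pipeline's correctness and its power under these idealized
conditions, not field performance.

## Problem sizes and calibrations

The simulation calibrations run at the study-scale defaults: the null
FW/SW rejection rate is pooled over 1000 replicate single-group cohorts
(8 fish per arm, the monthly gene-expression subset size of the emulated
survey) and lands at the nominal 0.05 ± 0.02; stable-reference selection
is checked over 200 replicate surveys (observed ≈ 99%); top-10 panel
recovery (≥ 8 of 10 panel members are true signal genes) over 100
replicate surveys (observed ≈ 100%). The held-out classifier check trains
on half of four labelled 40-fish trial cohorts and tests on the other
half. The dual-axis panel at these settings reliably captures the
de-smolt-axis program (≥ 4 of 5 genes) plus the most strongly reverting
signal genes; because the de-smolt signature is deliberately concentrated
in the dedicated genes (see above), the dual-axis panel is not expected to
contain most of the 20 signal genes, and the tests assert the program
capture rather than a signal-gene count.

## Known limitations

- Reference-gene stability is relative to the candidate set; with three
  candidates the pair-vs-single comparison is structurally biased toward
  pairs (documented above).
- The axis search inspects only the first k_max components; a
  month-separating axis pushed below that by strong batch structure would
  be missed (k_max is a parameter).
- Thresholds are hard cutpoints; no probability or confidence accompanies
  a classification.
- The printed gene counts and thresholds of the original study depend on
  its supplementary measured data and companion-trial fish, which are not
  redistributable here; the corresponding acceptance check runs only when
  those files are supplied locally.
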