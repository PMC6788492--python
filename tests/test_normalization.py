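import warnings

import numpy as np
import pandas as pd
import pytest

import smoltpanel as sp
from smoltpanel.data import CtMatrix, validate_assay_table
from smoltpanel.normalization import (
    NormalizationModel,
    linearize,
    normalize_ddct,
    reference_stability,
)
from oracles import stability_oracle


def _assays(ids, eff):
    return validate_assay_table(pd.DataFrame({"assay_id": ids, "efficiency": eff}))


class TestLinearize:
    def test_known_values(self):
        ct = CtMatrix(
            pd.DataFrame([[20.0, 21.0]], index=["g"], columns=["s1", "s2"]), "ct"
        )
        lin = linearize(ct, _assays(["g"], [2.0]))
        assert lin.value_kind == "linear"
        assert lin.data.loc["g", "s1"] == 1.0  # zero exponent
        assert lin.data.loc["g", "s2"] == 0.5  # one cycle halves product

    def test_non_ideal_efficiency(self):
        # E=1.9, minCt=18, Ct=20.5 -> 1.9 ** (-2.5)
        ct = CtMatrix(
            pd.DataFrame([[18.0, 20.5]], index=["g"], columns=["s1", "s2"]), "ct"
        )
        lin = linearize(ct, _assays(["g"], [1.9]))
        assert lin.data.loc["g", "s2"] == pytest.approx(1.9**-2.5, rel=1e-12)
        assert lin.data.loc["g", "s2"] == pytest.approx(0.20096, abs=5e-6)

    def test_outputs_in_unit_interval_and_missing_preserved(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(15, 35, size=(4, 12))
        vals[1, 3] = np.nan
        ct = CtMatrix(
            pd.DataFrame(vals, index=list("abcd"), columns=[f"s{i}" for i in range(12)]),
            "ct",
        )
        lin = linearize(ct, _assays(list("abcd"), [1.9, 2.0, 2.1, 1.85]))
        arr = lin.values
        assert np.isnan(arr[1, 3])
        ok = arr[~np.isnan(arr)]
        assert np.all(ok > 0) and np.all(ok <= 1.0)

    def test_all_missing_assay_is_error(self):
        ct = CtMatrix(
            pd.DataFrame([[np.nan, np.nan], [20.0, 21.0]], index=["bad", "ok"],
                         columns=["s1", "s2"]),
            "ct",
        )
        with pytest.raises(ValueError, match="bad"):
            linearize(ct, _assays(["bad", "ok"], [2.0, 2.0]))


class TestReferenceStability:
    def _linear(self, y, samples=None):
        # y: log2 matrix -> linear values
        df = pd.DataFrame(
            2.0**np.asarray(y),
            index=[f"hk{i}" for i in range(len(y))],
            columns=samples or [f"s{j}" for j in range(len(y[0]))],
        )
        return CtMatrix(df, "linear")

    def test_constant_genes_have_zero_stability(self):
        hk = self._linear([[1.0] * 8, [2.0] * 8, [0.5] * 8])
        res = reference_stability(hk, ["a"] * 4 + ["b"] * 4)
        assert np.allclose(res.gene_stability, 0.0)
        assert res.chosen_reference  # deterministic argmin exists

    def test_stratum_offsets_penalized(self):
        # gene A: iid noise, no stratum offset; gene B: same noise + +/-0.5
        # stratum offsets; a third quiet gene anchors the relative frame
        rng = np.random.default_rng(42)
        n = 40
        strata = ["a"] * n + ["b"] * n
        noise_a = rng.normal(0, 0.1, 2 * n)
        noise_b = rng.normal(0, 0.1, 2 * n)
        offs = np.array([0.5] * n + [-0.5] * n)
        anchor = rng.normal(0, 0.05, 2 * n)
        hk = self._linear([noise_a, noise_b + offs, anchor])
        res = reference_stability(hk, strata)
        assert res.gene_stability["hk0"] < res.gene_stability["hk1"]

    @pytest.mark.parametrize("k,G,n,seed", [(3, 2, 4, 0), (4, 3, 6, 1), (5, 4, 10, 2)])
    def test_matches_equation_oracle(self, k, G, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 0.3, size=(k, G * n)) + rng.normal(
            0, 0.4, size=(k, G)
        ).repeat(n, axis=1)
        strata = [g for g in range(G) for _ in range(n)]
        hk = self._linear(y)
        res = reference_stability(hk, strata)
        rho, pairs = stability_oracle(y, strata)
        assert np.allclose(res.gene_stability.to_numpy(), rho, atol=1e-10)
        genes = list(res.gene_stability.index)
        for (i, j), v in pairs.items():
            assert res.pair_stability[(genes[i], genes[j])] == pytest.approx(v, abs=1e-10)
        # chosen reference attains the overall minimum
        all_vals = list(res.gene_stability) + list(res.pair_stability)
        chosen_val = (
            res.gene_stability[res.chosen_reference[0]]
            if len(res.chosen_reference) == 1
            else res.pair_stability[res.chosen_reference]
        )
        assert chosen_val == pytest.approx(min(all_vals), abs=1e-12)

    def test_small_strata_excluded_then_error(self):
        hk = self._linear(np.random.default_rng(0).normal(0, 0.1, (3, 5)))
        with pytest.warns(UserWarning, match="excluding"):
            reference_stability(hk, ["a", "a", "b", "b", "c"])
        with pytest.raises(ValueError, match="strata"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reference_stability(hk, ["a", "a", "a", "a", "c"])


class TestNormalizeDdct:
    def test_calibrator_maps_to_zero(self, small_ct):
        ct, meta, assays = small_ct
        model = NormalizationModel(
            ("ref",), {"coho": "a1", "sockeye": "b1"},
            pd.Series(2.0, index=["gene1", "gene2", "ref"]),
        )
        out = normalize_ddct(ct, meta["group"], model)
        assert out.value_kind == "log2rel"
        assert np.allclose(out.data[["a1", "b1"]], 0.0)

    def test_one_cycle_doubling(self):
        # target one cycle below calibrator, reference equal -> +1.0
        ct = CtMatrix(
            pd.DataFrame({"cal": [24.0, 25.0], "s": [23.0, 25.0]}, index=["t", "ref"]),
            "ct",
        )
        model = NormalizationModel(
            ("ref",), {"g": "cal"}, pd.Series(2.0, index=["t", "ref"])
        )
        out = normalize_ddct(ct, pd.Series("g", index=["cal", "s"]), model)
        assert out.data.loc["t", "s"] == pytest.approx(1.0, abs=1e-12)

    def test_pair_reference_hand_computed(self):
        # E_target=1.9, target 2 cycles below calibrator; pair reference with
        # dCt -1 and +1 at E=2 -> log2(1.9^2) - 0
        ct = CtMatrix(
            pd.DataFrame(
                {"cal": [25.0, 25.0, 25.0], "s": [23.0, 26.0, 24.0]},
                index=["t", "r1", "r2"],
            ),
            "ct",
        )
        model = NormalizationModel(
            ("r1", "r2"), {"g": "cal"},
            pd.Series([1.9, 2.0, 2.0], index=["t", "r1", "r2"]),
        )
        out = normalize_ddct(ct, pd.Series("g", index=["cal", "s"]), model)
        assert model.aggregation == "geometric_mean"
        assert out.data.loc["t", "s"] == pytest.approx(2 * np.log2(1.9), abs=1e-12)
        assert out.data.loc["t", "s"] == pytest.approx(1.852, abs=5e-4)

    def test_negated_ddct_identity(self):
        # with E=2 the result is exactly -ddCt for random inputs
        rng = np.random.default_rng(3)
        ct_vals = rng.uniform(18, 30, size=(5, 9))
        ids = [f"g{i}" for i in range(4)] + ["ref"]
        cols = [f"s{j}" for j in range(9)]
        ct = CtMatrix(pd.DataFrame(ct_vals, index=ids, columns=cols), "ct")
        model = NormalizationModel(
            ("ref",), {"g": "s0"}, pd.Series(2.0, index=ids)
        )
        out = normalize_ddct(ct, pd.Series("g", index=cols), model)
        dct = ct_vals[:4] - ct_vals[4]  # Ct_target - Ct_ref per sample
        ddct = dct - dct[:, [0]]  # vs calibrator s0
        assert np.allclose(out.data.iloc[:4].to_numpy(), -ddct, atol=1e-10)

    def test_pair_of_identical_genes_equals_single(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(20, 28, size=(3, 6))
        vals[2] = vals[1]  # r2 identical to r1
        ids = ["t", "r1", "r2"]
        cols = [f"s{j}" for j in range(6)]
        ct = CtMatrix(pd.DataFrame(vals, index=ids, columns=cols), "ct")
        eff = pd.Series([1.95, 2.0, 2.0], index=ids)
        groups = pd.Series("g", index=cols)
        single = normalize_ddct(ct, groups, NormalizationModel(("r1",), {"g": "s0"}, eff))
        pair = normalize_ddct(ct, groups, NormalizationModel(("r1", "r2"), {"g": "s0"}, eff))
        assert np.allclose(single.data.loc["t"], pair.data.loc["t"], atol=1e-12)

    def test_monotone_in_target_ct(self):
        # lower target Ct => strictly higher log2rel, reference fixed
        cts = np.linspace(30, 20, 11)
        ct = CtMatrix(
            pd.DataFrame(
                np.vstack([cts, np.full(11, 25.0)]),
                index=["t", "ref"],
                columns=[f"s{j}" for j in range(11)],
            ),
            "ct",
        )
        model = NormalizationModel(
            ("ref",), {"g": "s0"}, pd.Series([1.9, 2.0], index=["t", "ref"])
        )
        out = normalize_ddct(ct, pd.Series("g", index=ct.sample_ids), model)
        vals = out.data.loc["t"].to_numpy()
        assert np.all(np.diff(vals) > 0)

    def test_missing_calibrator_ct_voids_assay_with_warning(self):
        ct = CtMatrix(
            pd.DataFrame(
                {"cal": [np.nan, 25.0], "s": [23.0, 25.0]}, index=["t", "ref"]
            ),
            "ct",
        )
        model = NormalizationModel(
            ("ref",), {"g": "cal"}, pd.Series(2.0, index=["t", "ref"])
        )
        with pytest.warns(UserWarning, match="calibrator"):
            out = normalize_ddct(ct, pd.Series("g", index=["cal", "s"]), model)
        assert np.isnan(out.data.loc["t", "s"])
        assert out.data.loc["ref", "s"] == 0.0


class TestDeltaDeltaCtNormalizer:
    def test_auto_reference_and_transform(self, small_ct):
        ct, meta, assays = small_ct
        norm = sp.DeltaDeltaCtNormalizer(reference="ref")
        out = norm.fit(ct, meta=meta, assays=assays).transform(ct, meta=meta)
        assert norm.reference_ == ("ref",)
        assert norm.calibrators_ == {"coho": "a1", "sockeye": "b1"}
        # gene1 in a2: one cycle above calibrator (20 -> 21), ref flat -> -1
        assert out.data.loc["gene1", "a2"] == pytest.approx(-1.0)

    def test_auto_needs_housekeeping(self, small_ct):
        ct, meta, assays = small_ct
        assays = assays.copy()
        assays["is_housekeeping"] = False
        with pytest.raises(ValueError, match="housekeeping"):
            sp.DeltaDeltaCtNormalizer().fit(ct, meta=meta, assays=assays)

    def test_exactly_one_calibrator_per_group_enforced(self, small_ct):
        ct, meta, assays = small_ct
        meta = meta.copy()
        meta["is_calibrator"] = False
        with pytest.raises(ValueError, match="calibrator"):
            sp.DeltaDeltaCtNormalizer(reference="ref").fit(ct, meta=meta, assays=assays)

    def test_fixed_efficiency_validated(self, small_ct):
        ct, meta, assays = small_ct
        with pytest.raises(ValueError, match="efficiency"):
            sp.DeltaDeltaCtNormalizer(reference="ref", fixed_efficiency=2.5).fit(
                ct, meta=meta, assays=assays
            )

    def test_stability_selection_on_survey(self, survey, normalized):
        _, norm = normalized
        stab = norm.stability_.gene_stability
        assert set(stab.index) == {"hk_stable", "hk_noisy1", "hk_noisy2"}
        assert stab.idxmin() == "hk_stable"
        assert all(v >= 0 and np.isfinite(v) for v in stab)
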