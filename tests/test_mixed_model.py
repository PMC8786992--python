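"""Mixed model: closed-form balanced cases, invariances, and an external
REML cross-check against statsmodels MixedLM."""

import numpy as np
import pandas as pd
import pytest

from radrepro import (
    DEFAULT_DESIGN,
    GroupParams,
    MixedModelSpec,
    SyntheticConfig,
    batch_mixed_models,
    fit_feature_mixed_model,
    simulate,
    get_preset,
)
from radrepro.feature_table import FeatureTable
from conftest import make_table


def _plain_table(values_matrix, pids, feature="original_glcm_A", design=DEFAULT_DESIGN,
                 metadata=None):
    vals = {}
    for i, p in enumerate(pids):
        for j, s in enumerate(design.setting_labels):
            vals[(p, s, feature)] = float(values_matrix[i, j])
    return make_table(vals, design=design, metadata=metadata)


class TestClosedForms:
    def test_constant_per_subject_gives_zero_coefficients(self):
        m = np.tile(np.array([1.0, 4.0, 2.5, 7.0])[:, None], (1, 6))
        t = _plain_table(m, ["P1", "P2", "P3", "P4"])
        res = fit_feature_mixed_model(
            t, "original_glcm_A",
            MixedModelSpec(include_scanner=False, include_voltage=False, include_volume=False),
        )
        for c in res.setting_coefficients().values():
            assert c == pytest.approx(0.0, abs=1e-10)
        # variance ratio is profiled on a bounded log grid, so "zero" residual
        # variance resolves to ~var_subject / lambda_max
        assert res.var_residual == pytest.approx(0.0, abs=1e-5)

    def test_planted_shift_recovered_exactly_without_noise(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        m = np.tile(base[:, None], (1, 6))
        m[:, 5] += 2.0  # IR80 shift
        t = _plain_table(m, [f"P{i}" for i in range(8)])
        res = fit_feature_mixed_model(
            t, "original_glcm_A",
            MixedModelSpec(include_scanner=False, include_voltage=False, include_volume=False),
        )
        coefs = res.setting_coefficients()
        assert coefs["IR80"] == pytest.approx(2.0, abs=1e-9)
        for s in ("IR20", "IR40", "IR50", "IR60"):
            assert coefs[s] == pytest.approx(0.0, abs=1e-9)

    def test_balanced_coefficients_equal_paired_mean_differences(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(12, 6)) + rng.normal(size=12)[:, None]
        t = _plain_table(m, [f"P{i}" for i in range(12)])
        res = fit_feature_mixed_model(
            t, "original_glcm_A",
            MixedModelSpec(include_scanner=False, include_voltage=False, include_volume=False),
        )
        coefs = res.setting_coefficients()
        for j, s in enumerate(DEFAULT_DESIGN.setting_labels):
            if s == "FBP":
                continue
            assert coefs[s] == pytest.approx(float(np.mean(m[:, j] - m[:, 0])), abs=1e-10)

    def test_constant_offset_shifts_only_intercept(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(10, 6))
        t1 = _plain_table(m, [f"P{i}" for i in range(10)])
        t2 = _plain_table(m + 100.0, [f"P{i}" for i in range(10)])
        r1 = fit_feature_mixed_model(t1, "original_glcm_A")
        r2 = fit_feature_mixed_model(t2, "original_glcm_A")
        for s, c in r1.setting_coefficients().items():
            assert r2.setting_coefficients()[s] == pytest.approx(c, abs=1e-10)
        assert r2.params["Intercept"] - r1.params["Intercept"] == pytest.approx(100.0, abs=1e-8)


class TestAgainstStatsmodels:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_reml_fit_matches_mixedlm(self, seed):
        import statsmodels.formula.api as smf

        table, _ = simulate(
            SyntheticConfig(n_patients=40, n_features_per_group={1: 1, 2: 0, 3: 1, 4: 0}, seed=seed)
        )
        for name in table.feature_names:
            res = fit_feature_mixed_model(table, name)
            mat, pids = table.feature_matrix(name)
            meta = table.metadata.loc[pids]
            df = pd.DataFrame(
                {
                    "y": mat.ravel(),
                    "subject": np.repeat(pids, 6),
                    "setting": pd.Categorical(
                        np.tile(table.design.setting_labels, len(pids)),
                        categories=table.design.setting_labels,
                    ),
                    "scanner": np.repeat(meta["scanner"].to_numpy(), 6),
                    "voltage": np.repeat(meta["tube_voltage"].to_numpy(), 6),
                    "volume": np.repeat(meta["tumour_volume_cm3"].to_numpy(), 6),
                }
            )
            sm_fit = smf.mixedlm(
                "y ~ setting + scanner + voltage + volume", df, groups=df["subject"]
            ).fit(reml=True)
            np.testing.assert_allclose(res.params.to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-8)
            assert res.var_subject == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
            assert res.var_residual == pytest.approx(float(sm_fit.scale), rel=1e-3)


class TestStructure:
    def test_label_order_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(8, 6))
        pids = [f"P{i}" for i in range(8)]
        t1 = _plain_table(m, pids)
        # same data, design listed in reversed order (reference unchanged)
        design2 = DEFAULT_DESIGN.subset(tuple(reversed(DEFAULT_DESIGN.setting_labels)), "FBP")
        perm = [list(DEFAULT_DESIGN.setting_labels).index(s) for s in design2.setting_labels]
        t2 = _plain_table(m[:, perm], pids, design=design2)
        r1 = fit_feature_mixed_model(t1, "original_glcm_A")
        r2 = fit_feature_mixed_model(t2, "original_glcm_A")
        for s, c in r1.setting_coefficients().items():
            assert r2.setting_coefficients()[s] == pytest.approx(c, abs=1e-10)

    def test_variance_components_nonnegative_and_locally_optimal(self):
        table, _ = simulate(get_preset("group1", seed=9))
        name = table.feature_names[0]
        res = fit_feature_mixed_model(table, name)
        assert res.var_subject >= 0 and res.var_residual >= 0
        model = res.model
        lam_hat = res.var_subject / res.var_residual
        crit_hat = model._profile(lam_hat)[0]
        for factor in (0.5, 2.0):
            assert model._profile(lam_hat * factor)[0] >= crit_hat - 1e-6

    def test_rank_deficiency_names_terms(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(6, 6))
        pids = [f"P{i}" for i in range(6)]
        meta = pd.DataFrame(
            {
                "patient_id": pids,
                "scanner": ["scannerA", "scannerB"] * 3,
                "tube_voltage": ["100kVp", "120kVp"] * 3,  # aliased with scanner
                "tumour_volume_cm3": 20.0,
            }
        ).set_index("patient_id")
        t = _plain_table(m, pids, metadata=meta)
        with pytest.raises(ValueError, match="collinear"):
            fit_feature_mixed_model(t, "original_glcm_A")

    def test_volume_like_feature_drops_volume_covariate(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(6, 6))
        vals = {}
        for i, p in enumerate([f"P{i}" for i in range(6)]):
            for j, s in enumerate(DEFAULT_DESIGN.setting_labels):
                vals[(p, s, "original_shape_VoxelVolume")] = float(m[i, j])
        t = make_table(vals)
        res = fit_feature_mixed_model(t, "original_shape_VoxelVolume")
        assert "volume" not in res.params.index


class TestRecoveryAndBatch:
    def test_parameter_recovery_with_noise(self):
        # subject SD 1.0, residual SD 0.2, planted IR80 shift 0.5
        rng = np.random.default_rng(11)
        estimates, covered = [], []
        for _ in range(120):
            n = 100
            b = rng.normal(0, 1.0, size=n)
            m = b[:, None] + rng.normal(0, 0.2, size=(n, 6))
            m[:, 5] += 0.5
            t = _plain_table(m, [f"P{i}" for i in range(n)])
            res = fit_feature_mixed_model(
                t, "original_glcm_A",
                MixedModelSpec(include_scanner=False, include_voltage=False, include_volume=False),
            )
            est = res.setting_coefficients()["IR80"]
            ci = res.conf_int().loc["setting[IR80]"]
            estimates.append(est)
            covered.append(ci["lower"] <= 0.5 <= ci["upper"])
        assert abs(np.mean(estimates) - 0.5) < 0.02
        assert 0.90 <= np.mean(covered) <= 0.99

    def test_null_simulation_fdr_control(self):
        fractions = []
        for seed in range(10):
            table, _ = simulate(
                SyntheticConfig(
                    n_patients=30,
                    n_features_per_group={1: 0, 2: 30, 3: 0, 4: 0},
                    seed=seed,
                )
            )
            _, terms = batch_mixed_models(table)
            setting = terms[terms["term"].str.startswith("setting[")]
            any_sig = setting.groupby("feature")["p_fdr"].min() < 0.05
            fractions.append(any_sig.mean())
        assert np.mean(fractions) <= 0.08

    def test_trend_features_all_significant(self):
        table, _ = simulate(get_preset("group3", seed=13))
        _, terms = batch_mixed_models(table)
        setting = terms[terms["term"].str.startswith("setting[")]
        min_p = setting.groupby("feature")["p_fdr"].min()
        assert (min_p < 0.05).mean() >= 0.95

    def test_single_feature_batch_matches_direct_fit(self):
        table, _ = simulate(
            SyntheticConfig(n_patients=20, n_features_per_group={1: 1, 2: 0, 3: 0, 4: 0}, seed=1)
        )
        name = table.feature_names[0]
        fits, terms = batch_mixed_models(table, features=[name])
        direct = fit_feature_mixed_model(table, name)
        np.testing.assert_allclose(
            fits[0].params.to_numpy(), direct.params.to_numpy(), atol=1e-12
        )
        # singleton families (scanner/voltage/volume) are m=1 identities
        single = terms[~terms["term"].str.startswith(("setting[", "Intercept"))]
        np.testing.assert_allclose(
            single["p_fdr"].to_numpy(), single["p_raw"].to_numpy(), atol=1e-15
        )
        # the setting family is adjusted across its five contrasts
        from radrepro import fdr_adjust

        setting = terms[terms["term"].str.startswith("setting[")]
        np.testing.assert_allclose(
            setting["p_fdr"].to_numpy(),
            fdr_adjust(setting["p_raw"].to_numpy()),
            atol=1e-15,
        )
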