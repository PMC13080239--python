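"""Statistical layer: volcano, group tests, regressions, correlations,
clustering/PCA, and type-I error calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from myoflux.stats import (
    classify_fold_change,
    compare_groups,
    correlation_ledger,
    marker_regression,
    pathway_score,
    pca,
    score_capacity_regression,
    volcano,
    zscore,
    zscore_cluster,
)
from myoflux.synthetic import CohortConfig, generate_cohort, generate_null

from conftest import toy_matrix


class TestVolcanoClassification:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (0.4, 0.01, "down"),
            (2.5, 0.2, "unchanged"),
            (2.5, 0.01, "up"),
            (0.4, 0.2, "unchanged"),
            (0.5, 0.01, "unchanged"),  # thresholds are strict
            (2.0, 0.01, "unchanged"),
            (1.0, 0.001, "unchanged"),
        ],
    )
    def test_threshold_logic(self, fc, p, expected):
        assert classify_fold_change(fc, p) == expected

    @settings(deadline=None, max_examples=200)
    @given(
        fc=st.floats(min_value=0.01, max_value=100.0),
        p=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_partition_exhaustive_exclusive(self, fc, p):
        cls = classify_fold_change(fc, p)
        assert cls in ("up", "down", "unchanged")
        if cls == "down":
            assert fc < 0.5 and p < 0.05
        if cls == "up":
            assert fc > 2.0 and p < 0.05

    def test_identical_groups_nothing_regulated(self):
        m = toy_matrix(
            {
                "a1": {"P1": 10.0, "P2": 5.0},
                "a2": {"P1": 11.0, "P2": 5.5},
                "b1": {"P1": 10.0, "P2": 5.0},
                "b2": {"P1": 11.0, "P2": 5.5},
            },
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = volcano(m, "A", "B")
        assert res.fraction_up == 0.0 and res.fraction_down == 0.0

    def test_planted_strong_downregulation_detected(self):
        m = toy_matrix(
            {
                "a1": {"P1": 100.0, "P2": 50.0},
                "a2": {"P1": 101.0, "P2": 51.0},
                "a3": {"P1": 99.0, "P2": 49.0},
                "b1": {"P1": 40.0, "P2": 50.0},
                "b2": {"P1": 40.5, "P2": 51.0},
                "b3": {"P1": 39.5, "P2": 49.0},
            },
            {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
        )
        res = volcano(m, "A", "B")
        assert res.table.loc["P1", "class"] == "down"
        assert res.table.loc["P2", "class"] == "unchanged"

    def test_disjoint_subset_warns_empty(self):
        m = toy_matrix(
            {
                "a1": {"P1": 10.0},
                "a2": {"P1": 10.0},
                "b1": {"P1": 10.0},
                "b2": {"P1": 10.0},
            },
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = volcano(m, "A", "B", subset=["GHOST"])
        assert res.n_tested == 0

    def test_planted_fractions_recovered_strong_effect(self):
        """Regulated fractions planted among metabolic proteins (7.4% up,
        34.6% down at strong effect) are recovered within binomial 95%
        bounds."""
        cfg = CohortConfig(
            n_per_group={"control": 4, "diet": 5, "obese": 5},
            n_proteins=700,
            n_metabolic=300,
            fold_up=4.0,
            fold_down=0.25,
            seed=7,
        )
        cohort = generate_cohort(cfg)
        metabolic = cohort.truth.protein_sets["metabolic"]
        res = volcano(cohort.matrix, "control", "diet", subset=metabolic)
        n = len(metabolic)
        p_dn = round(0.346 * n) / n
        p_up = round(0.074 * n) / n
        half_dn = 1.96 * np.sqrt(p_dn * (1 - p_dn) / n)
        half_up = 1.96 * np.sqrt(p_up * (1 - p_up) / n)
        assert abs(res.fraction_down - p_dn) <= half_dn
        assert abs(res.fraction_up - p_up) <= half_up


class TestCompareGroups:
    def test_identical_groups_high_p(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups(a, a)
        assert res.p_value > 0.99

    def test_textbook_t_statistic(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [3.0, 4.0, 5.0, 6.0, 7.0]
        res = compare_groups(a, b)
        # pooled t = (3-5)/(sqrt(2.5)*sqrt(2/5)) = -2 exactly
        assert res.test_used == "t-test"
        assert res.statistic == pytest.approx(-2.0)
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(2.0, df=8), rel=1e-12
        )

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_rank_fallback_on_nonnormal_data(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(0, 2, 40)) ** 3  # heavy-tailed
        b = np.exp(rng.normal(0, 2, 40)) ** 3
        res = compare_groups(a, b)
        assert res.test_used == "rank-test"

    def test_null_rejection_rate_calibrated(self):
        """Type-I error of the gated test is ~5% at alpha 0.05."""
        rng = np.random.default_rng(12345)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0, 1, 5)
            if compare_groups(a, b).p_value < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) <= 0.02


class TestMarkerRegression:
    def _matrix(self, x, extra=None):
        data = {f"s{i}": {"P1": float(v)} for i, v in enumerate(x)}
        if extra:
            for prot, vals in extra.items():
                for i, v in enumerate(vals):
                    data[f"s{i}"][prot] = float(v)
        return toy_matrix(data, {})

    def test_exact_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        m = self._matrix(x)
        capacity = pd.Series(
            [2 * v + 1 for v in x], index=[f"s{i}" for i in range(5)]
        )
        res = marker_regression(capacity, m, ["P1"])
        assert res.table.loc["P1", "r2"] == pytest.approx(1.0)
        assert res.table.loc["P1", "slope"] == pytest.approx(2.0)
        assert res.n_significant == 1

    def test_independent_protein_zero_slope(self):
        # chosen so sum(dx*dy) = 0 exactly: slope is 0 by hand OLS
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 1.0, 3.0]
        m = self._matrix(x)
        capacity = pd.Series(y, index=[f"s{i}" for i in range(5)])
        res = marker_regression(capacity, m, ["P1"])
        assert res.table.loc["P1", "slope"] == pytest.approx(0.0, abs=1e-12)
        assert res.n_significant == 0

    def test_constant_abundance_skipped(self):
        m = self._matrix([2.0] * 5)
        capacity = pd.Series(range(5), index=[f"s{i}" for i in range(5)], dtype=float)
        res = marker_regression(capacity, m, ["P1"])
        assert res.skipped == ["P1"]
        assert res.n_total == 0

    def test_sensitivity_and_fpr_over_seeds(self, model, mapping):
        """Planted causal markers recovered at the generator's default
        effect size (OXPHOS fold 0.5, log2 noise sd 0.25, n = 5 per group):
        sensitivity >= 0.8 and false-positive rate <= 0.2 over 50 seeds.

        The per-sample ATP capacity is proxied by the realized OXPHOS Vmax
        scale from instantiation (the load ramp tracks it within ~1%,
        checked in the capacity suite), which keeps 50 cohorts fast."""
        from myoflux.instantiate import instantiate_cohort
        from myoflux.synthetic import CohortConfig, generate_cohort

        sens, fprs = [], []
        for seed in range(50):
            cfg = CohortConfig(
                n_per_group={"control": 5, "diet": 5},
                n_proteins=130,
                n_metabolic=60,
                metabolic_fractions={"diet": (0.0, 0.0)},
                other_fractions={"diet": (0.0, 0.0)},
                extra_plan={
                    "diet": [("pathway:oxphos", 0.5), ("pathway:tca", 0.5)]
                },
                seed=seed,
            )
            cohort = generate_cohort(cfg, model)
            instances = instantiate_cohort(model, mapping, cohort.matrix, "control")
            capacity = pd.Series(
                {i.sample_id: i.scale["oxphos"] for i in instances}
            )
            causal = cohort.truth.markers["atp"]
            null_prots = [
                p
                for p in cohort.truth.protein_sets["metabolic"]
                if p.startswith("MET")
            ][:20]
            res_c = marker_regression(capacity, cohort.matrix, causal)
            res_n = marker_regression(capacity, cohort.matrix, null_prots)
            sens.append(res_c.n_significant / res_c.n_total)
            fprs.append(res_n.n_significant / res_n.n_total)
        assert np.mean(sens) >= 0.8
        assert np.mean(fprs) <= 0.2


class TestPathwayScore:
    def _matrix(self):
        return toy_matrix(
            {
                "s1": {"P1": 2.0, "P2": 3.0, "P3": 5.0, "P4": 10.0},
                "s2": {"P1": 4.0, "P2": 6.0, "P3": 5.0, "P4": 10.0},
            },
            {},
        )

    def test_full_set_share_one(self):
        m = self._matrix()
        score = pathway_score(m, ["P1", "P2", "P3", "P4"])
        assert np.allclose(score, 1.0)

    def test_hand_computed_share(self):
        m = self._matrix()
        score = pathway_score(m, ["P1", "P2"])
        assert score["s1"] == pytest.approx(5.0 / 20.0)
        assert score["s2"] == pytest.approx(10.0 / 25.0)

    def test_doubling_members_increases_share(self):
        m = self._matrix()
        base = pathway_score(m, ["P1", "P2"])["s1"]
        m.intensity.loc[["P1", "P2"], "s1"] *= 2
        assert pathway_score(m, ["P1", "P2"])["s1"] > base

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            pathway_score(self._matrix(), ["GHOST"])


class TestScoreCapacityRegression:
    def test_affine_score_r2_one(self):
        idx = [f"s{i}" for i in range(6)]
        caps = pd.DataFrame({"max_atp": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, index=idx)
        score = pd.Series([0.1 + 0.02 * v for v in caps["max_atp"]], index=idx)
        res = score_capacity_regression(score, caps)
        assert res.loc["max_atp", "r2"] == pytest.approx(1.0)
        assert bool(res.loc["max_atp", "significant"])

    def test_null_p_uniform(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 2000
        idx = [f"s{i}" for i in range(10)]
        for _ in range(reps):
            caps = pd.DataFrame({"c": rng.normal(0, 1, 10)}, index=idx)
            score = pd.Series(rng.normal(0, 1, 10), index=idx)
            res = score_capacity_regression(score, caps)
            hits += bool(res.loc["c", "p_value"] < 0.05)
        assert abs(hits / reps - 0.05) <= 0.02

    def test_planted_negative_inflammation_coupling(self, tiny_cohort):
        """Obese-group inflammation is planted up while OXPHOS is mildly
        down: the inflammation share correlates negatively with the latent
        ATP (OXPHOS) scale across the cohort."""
        m = tiny_cohort.matrix
        infl = tiny_cohort.truth.protein_sets["inflammation"]
        score = pathway_score(m, infl)
        latent = tiny_cohort.truth.pathway_scales["oxphos"]
        caps = pd.DataFrame({"atp_latent": latent})
        res = score_capacity_regression(score, caps)
        assert res.loc["atp_latent", "slope"] < 0


class TestCorrelationLedger:
    def _features(self):
        return pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0],
                "y": [1.0, 3.0, 2.0, 4.0],
                "z": [2.0, 2.0, 2.0, 2.0],
            },
            index=["s1", "s2", "s3", "s4"],
        )

    def test_diagonal_and_symmetry(self):
        led = correlation_ledger(self._features())
        assert np.allclose(np.diag(led.r), 1.0)
        assert np.allclose(led.r, led.r.T)
        assert (led.mask == led.mask.T).all().all()

    def test_hand_computed_r(self):
        led = correlation_ledger(self._features())
        # x=[1,2,3,4], y=[1,3,2,4]: r = 0.8 by direct computation
        assert led.r.loc["x", "y"] == pytest.approx(0.8)

    def test_zero_variance_excluded(self):
        led = correlation_ledger(self._features())
        assert led.excluded == ["z"]
        assert "z" not in led.r.columns

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_ledger(self._features().iloc[:3])

    def test_null_significant_fraction_calibrated(self):
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 2000
        for _ in range(reps):
            f = pd.DataFrame(
                {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
            )
            led = correlation_ledger(f)
            hits += bool(led.mask.loc["a", "b"])
        assert abs(hits / reps - 0.05) <= 0.02


class TestClusterPca:
    def test_zscore_exact(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(5, 3, (4, 6)))
        z = zscore(df)
        assert np.all(np.abs(z.mean(axis=1)) < 1e-12)
        assert np.all(np.abs(z.std(axis=1, ddof=1) - 1) < 1e-12)

    def test_duplicated_samples_merge_first(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.normal(size=(8, 4)), columns=["a", "b", "c", "d"],
            index=[f"P{i}" for i in range(8)],
        )
        df["b"] = df["a"]  # duplicate sample
        cl = zscore_cluster(df)
        first = cl.col_linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_constant_feature_dropped(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 1.0], "b": [2.0, 1.0, 1.0], "c": [3.0, 2.0, 1.0]},
            index=["P1", "P2", "CONST"],
        ).T
        # make one row constant
        df.loc["CONST"] = 1.0
        cl = zscore_cluster(df.T.T)  # DataFrame path
        assert "CONST" in cl.dropped

    def test_three_group_separation_on_pc1(self, tiny_cohort):
        metabolic = tiny_cohort.truth.protein_sets["metabolic"]
        res = pca(tiny_cohort.matrix, subset=metabolic)
        labels = [tiny_cohort.matrix.group[s] for s in res.scores.index]
        sil = silhouette_score(
            res.scores[["PC1"]].to_numpy(), labels, metric="euclidean"
        )
        assert sil > 0

    def test_pca_sign_convention(self, tiny_cohort):
        metabolic = tiny_cohort.truth.protein_sets["metabolic"]
        res = pca(tiny_cohort.matrix, subset=metabolic)
        for comp in res.loadings.columns:
            j = res.loadings[comp].abs().idxmax()
            assert res.loadings.loc[j, comp] > 0
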