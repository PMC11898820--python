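"""Fixed-effect ANOVA engine: oracle equivalence, letters, Levene, reports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from henpop.association import (
    DesignError,
    DesignSpec,
    association_scan,
    breed_summary,
    compact_letter_display,
    filter_outliers,
    fit_oneway,
    levene_test,
    study_frame,
)
from henpop.synthetic_data import default_config, simulate_genotypes, simulate_phenotypes


def oracle_ols(y, groups, covariate=None):
    """Brute-force least squares: dummy coding, explicit normal-equation
    inversion. Returns (f, p, ls_means dict)."""
    levels = list(dict.fromkeys(groups))
    n, k = len(y), len(levels)
    X = np.ones((n, 1))
    for lv in levels[1:]:
        X = np.column_stack([X, (np.asarray(groups) == lv).astype(float)])
    if covariate is not None:
        X = np.column_stack([X, covariate])
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    sse_full = float(((y - X @ beta) ** 2).sum())
    Xr = np.ones((n, 1)) if covariate is None else np.column_stack([np.ones(n), covariate])
    br = np.linalg.inv(Xr.T @ Xr) @ Xr.T @ y
    sse_red = float(((y - Xr @ br) ** 2).sum())
    df_err = n - X.shape[1]
    f = ((sse_red - sse_full) / (k - 1)) / (sse_full / df_err)
    p = float(stats.f.sf(f, k - 1, df_err))
    xbar = 0.0 if covariate is None else float(np.mean(covariate)) * beta[-1]
    means = {}
    for i, lv in enumerate(levels):
        means[lv] = float(beta[0] + (beta[i] if i > 0 else 0.0) + xbar)
    return f, p, means


def random_design(rng, with_covariate):
    k = int(rng.integers(2, 5))
    sizes = rng.integers(3, 16, size=k)
    groups, ys, covs = [], [], []
    for i, sz in enumerate(sizes):
        groups += [f"g{i}"] * int(sz)
        ys += list(rng.normal(10 + 2 * i, 3, size=int(sz)))
        covs += list(rng.normal(50, 8, size=int(sz)))
    df = pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(len(ys))],
        "breed": "X",
        "g": groups,
        "y": ys,
        "age": covs,
    })
    spec = DesignSpec(response="y", factor="g", covariate="age" if with_covariate else None)
    return df, spec


class TestOracleEquivalence:
    @pytest.mark.parametrize("with_covariate", [False, True])
    def test_matches_brute_force_on_random_designs(self, with_covariate):
        rng = np.random.default_rng(20240917 if with_covariate else 20240916)
        for _ in range(30):
            df, spec = random_design(rng, with_covariate)
            fit = fit_oneway(df, spec)
            cov = df["age"].to_numpy() if with_covariate else None
            f, p, means = oracle_ols(df["y"].to_numpy(), list(df["g"]), cov)
            assert fit.f_stat == pytest.approx(f, rel=1e-10)
            assert fit.p_value == pytest.approx(p, rel=1e-10, abs=1e-300)
            for lv, m in means.items():
                assert fit.ls_means[lv] == pytest.approx(m, rel=1e-10)

    def test_matches_statsmodels_anova(self):
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(7)
        df, spec = random_design(rng, False)
        fit = fit_oneway(df, spec)
        model = smf.ols("y ~ C(g)", data=df).fit()
        table = sm.stats.anova_lm(model)
        assert fit.f_stat == pytest.approx(float(table["F"].iloc[0]), rel=1e-9)
        assert fit.p_value == pytest.approx(float(table["PR(>F)"].iloc[0]), rel=1e-9)

    def test_ls_means_equal_group_means_without_covariate(self):
        rng = np.random.default_rng(11)
        df, spec = random_design(rng, False)
        fit = fit_oneway(df, spec)
        for lv in fit.levels:
            assert fit.ls_means[lv] == pytest.approx(
                df.loc[df["g"] == lv, "y"].mean(), abs=1e-12
            )

    def test_balanced_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(3)
        y1, y2 = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(24)],
            "breed": "X",
            "g": ["a"] * 12 + ["b"] * 12,
            "y": np.concatenate([y1, y2]),
        })
        fit = fit_oneway(df, DesignSpec("y", "g"))
        t, _ = stats.ttest_ind(y1, y2)
        assert fit.f_stat == pytest.approx(t * t, rel=1e-12)

    def test_f_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(5)
        df, spec = random_design(rng, False)
        f0 = fit_oneway(df, spec).f_stat
        df2 = df.assign(y=3.7 * df["y"] + 100.0)
        assert fit_oneway(df2, spec).f_stat == pytest.approx(f0, rel=1e-9)


class TestDegenerateDesigns:
    def test_identical_groups_give_zero_f_and_shared_letter(self):
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(9)],
            "breed": "X",
            "g": ["a", "b", "c"] * 3,
            "y": [5.0, 5.0, 5.0] * 3,
        })
        fit = fit_oneway(df, DesignSpec("y", "g"))
        assert fit.f_stat == 0.0
        assert set(fit.letters.values()) == {"a"}

    def test_single_level_is_design_error(self):
        df = pd.DataFrame({"sample_id": ["a", "b"], "breed": "X", "g": ["u", "u"], "y": [1.0, 2.0]})
        with pytest.raises(DesignError):
            fit_oneway(df, DesignSpec("y", "g"))

    def test_zero_residual_df_is_design_error(self):
        df = pd.DataFrame({"sample_id": ["a", "b"], "breed": "X", "g": ["u", "v"], "y": [1.0, 2.0]})
        with pytest.raises(DesignError):
            fit_oneway(df, DesignSpec("y", "g"))

    def test_empty_level_dropped_with_warning(self):
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "breed": "X",
            "g": ["a"] * 4 + ["b"] * 4,
            "y": np.arange(8.0),
        })
        spec = DesignSpec("y", "g", level_order=["a", "b", "c"])
        with pytest.warns(UserWarning, match="dropping"):
            fit = fit_oneway(df, spec)
        assert fit.dropped_levels == ["c"]


class TestPairwiseAndLetters:
    def test_pairwise_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(13)
        df, spec = random_design(rng, False)
        fit = fit_oneway(df, spec)
        P = fit.pairwise.to_numpy()
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)

    def test_identical_groups_pairwise_p_one(self):
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "breed": "X",
            "g": ["a"] * 4 + ["b"] * 4,
            "y": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        fit = fit_oneway(df, DesignSpec("y", "g"))
        assert fit.pairwise.loc["a", "b"] == pytest.approx(1.0)

    def test_shifted_group_separates(self):
        rng = np.random.default_rng(21)
        n = 15
        base = rng.normal(0, 1, 2 * n)
        se = 1 / np.sqrt(n)
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(3 * n)],
            "breed": "X",
            "g": ["a"] * n + ["b"] * n + ["c"] * n,
            "y": np.concatenate([base, rng.normal(5 * se, 1, n)]),
        })
        fit = fit_oneway(df, DesignSpec("y", "g"))
        assert fit.pairwise.loc["c", "a"] < 0.05
        assert fit.pairwise.loc["c", "b"] < 0.05
        assert fit.pairwise.loc["a", "b"] >= 0.05
        assert set(fit.letters["c"]).isdisjoint(fit.letters["a"] + fit.letters["b"])

    def test_adjustments_are_ordered(self):
        rng = np.random.default_rng(2)
        df, spec = random_design(rng, False)
        p_none = fit_oneway(df, spec).pairwise
        spec_b = DesignSpec("y", "g", adjust="bonferroni")
        spec_t = DesignSpec("y", "g", adjust="tukey")
        p_bonf = fit_oneway(df, spec_b).pairwise
        p_tukey = fit_oneway(df, spec_t).pairwise
        off = ~np.eye(len(p_none), dtype=bool)
        assert (p_bonf.to_numpy()[off] >= p_none.to_numpy()[off] - 1e-12).all()
        assert (p_tukey.to_numpy()[off] >= p_none.to_numpy()[off] - 1e-12).all()


def letters_from_pmatrix(pairs, levels, means):
    P = pd.DataFrame(1.0, index=levels, columns=levels)
    for (a, b), p in pairs.items():
        P.loc[a, b] = P.loc[b, a] = p
    return compact_letter_display(P, means)


class TestCompactLetterDisplay:
    def test_all_nonsignificant_single_letter(self):
        letters = letters_from_pmatrix({}, ["x", "y", "z"], {"x": 3, "y": 2, "z": 1})
        assert letters == {"x": "a", "y": "a", "z": "a"}

    def test_all_significant_four_distinct_letters_by_mean(self):
        levels = ["PH", "C", "BB", "LC"]
        means = {"C": 188.05, "BB": 170.60, "PH": 151.89, "LC": 140.44}
        pairs = {(a, b): 0.001 for i, a in enumerate(levels) for b in levels[i + 1:]}
        letters = letters_from_pmatrix(pairs, levels, means)
        assert letters == {"C": "a", "BB": "b", "PH": "c", "LC": "d"}

    def test_chain_case_gets_bridging_letter(self):
        # A != C significant, A~B and B~C not: expect a / ab / b
        letters = letters_from_pmatrix(
            {("A", "C"): 0.01, ("A", "B"): 0.5, ("B", "C"): 0.5},
            ["A", "B", "C"], {"A": 3, "B": 2, "C": 1},
        )
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_partition_property_on_random_matrices(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            levels = [f"L{i}" for i in range(k)]
            means = {lv: float(rng.normal()) for lv in levels}
            P = pd.DataFrame(1.0, index=levels, columns=levels)
            for i in range(k):
                for j in range(i + 1, k):
                    p = float(rng.uniform())
                    P.iloc[i, j] = P.iloc[j, i] = p
            letters = compact_letter_display(P, means)
            for i in range(k):
                assert letters[levels[i]], "every level gets at least one letter"
                for j in range(i + 1, k):
                    share = set(letters[levels[i]]) & set(letters[levels[j]])
                    if P.iloc[i, j] >= 0.05:
                        assert share, (letters, P.round(3).to_dict())
                    else:
                        assert not share, (letters, P.round(3).to_dict())


class TestLevene:
    def test_mirrored_groups_statistic_zero(self):
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(10)],
            "breed": "X",
            "g": ["a"] * 5 + ["b"] * 5,
            "y": [1.0, 2, 3, 4, 5, 11.0, 12, 13, 14, 15],
        })
        stat, p = levene_test(df, DesignSpec("y", "g"))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_brown_forsythe(self):
        rng = np.random.default_rng(17)
        a, b, c = rng.normal(0, 1, 20), rng.normal(0, 3, 25), rng.normal(2, 1, 15)
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(60)],
            "breed": "X",
            "g": ["a"] * 20 + ["b"] * 25 + ["c"] * 15,
            "y": np.concatenate([a, b, c]),
        })
        stat, p = levene_test(df, DesignSpec("y", "g"))
        ref_stat, ref_p = stats.levene(a, b, c, center="median")
        assert stat == pytest.approx(ref_stat, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-10)

    def test_detects_inflated_scale(self):
        rng = np.random.default_rng(19)
        hits = 0
        for _ in range(50):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 5, 50)
            df = pd.DataFrame({
                "sample_id": [f"s{i}" for i in range(100)],
                "breed": "X",
                "g": ["a"] * 50 + ["b"] * 50,
                "y": np.concatenate([a, b]),
            })
            _, p = levene_test(df, DesignSpec("y", "g"))
            hits += p < 0.05
        assert hits >= 48  # power >= ~95% at scale x5


@pytest.fixture(scope="module")
def sim_study():
    cfg = default_config(seed=42)
    gt = simulate_genotypes(cfg)
    tt, _ = simulate_phenotypes(gt, cfg)
    return gt, tt


class TestScanAndSummary:
    def test_scan_has_56_cells(self, sim_study):
        gt, tt = sim_study
        scan = association_scan(gt, tt)
        assert len(scan) == 56
        assert list(dict.fromkeys(scan["locus"])) == [f"SNP{i}" for i in range(1, 8)]
        assert list(scan["trait"][:8]) == [t.name for t in tt.traits]

    def test_missing_trait_errors_by_name(self, sim_study):
        gt, tt = sim_study
        with pytest.raises(DesignError, match="NOPE"):
            association_scan(gt, tt, trait_names=["NOPE"])

    def test_breed_summary_recovers_structure(self, sim_study):
        gt, tt = sim_study
        summary = breed_summary(gt, tt)
        assert len(summary) == 8 * 4
        afep = summary[summary.trait == "AFEP"].set_index("breed")
        # generated breed ordering of AFEP means: C > BB > PH > LC
        assert afep.loc["C", "mean"] > afep.loc["BB", "mean"] > afep.loc["PH", "mean"]
        assert (summary["sd"].dropna() >= 0).all()

    def test_single_breed_summary_design_error(self, sim_study):
        gt, tt = sim_study
        from henpop.core_data import GenotypeTable
        ph = GenotypeTable(gt.loci, [s for s in gt.samples if s.breed == "PH"])
        with pytest.raises(DesignError):
            breed_summary(ph, tt)

    def test_breed_of_one_keeps_mean_drops_sd_and_letters(self, sim_study):
        gt, tt = sim_study
        from henpop.core_data import GenotypeTable
        keep = [s for s in gt.samples if s.breed != "LC"] + [
            s for s in gt.samples if s.breed == "LC"
        ][:1]
        sub = GenotypeTable(gt.loci, keep)
        summary = breed_summary(sub, tt)
        lc = summary[(summary.trait == "AFEP") & (summary.breed == "LC")].iloc[0]
        assert lc["n"] == 1
        assert np.isfinite(lc["mean"])
        assert np.isnan(lc["sd"])
        assert lc["letters"] == ""

    def test_outlier_filter_logs_and_blanks(self, sim_study):
        gt, tt = sim_study
        data = study_frame(gt, tt)
        data.loc[0, "AFEP"] = 10000.0
        filtered, removed = filter_outliers(data, ["AFEP"])
        assert any(r[1] == "AFEP" for r in removed)
        assert np.isnan(filtered.loc[0, "AFEP"])
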