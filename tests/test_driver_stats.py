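import numpy as np
import pandas as pd
import pytest

from socturn.driver_stats import (
    DEFAULT_EXCLUSIONS,
    ModelSpec,
    apply_exclusions,
    order_consistency,
    pearson_summary,
    sequential_anova,
    significance_code,
)


def make_data(n=54, seed=0, beta_ph=0.0, beta_x=0.0, collinear_r=None):
    rng = np.random.default_rng(seed)
    ph = rng.normal(5, 1, n)
    x = rng.normal(size=n)
    if collinear_r is not None:
        x = collinear_r * (ph - ph.mean()) / ph.std() + np.sqrt(
            1 - collinear_r**2
        ) * rng.normal(size=n)
    y = beta_ph * ph + beta_x * x + rng.normal(size=n)
    return pd.DataFrame({
        "site_id": np.arange(1, n + 1),
        "region": rng.choice(["Jura", "Midland", "Alps"], n),
        "mi_cat": rng.choice(["MI-", "MI+"], n),
        "ti_cat": rng.choice(["TT-", "TT+"], n),
        "pco1": rng.normal(size=n),
        "pco2": rng.normal(size=n),
        "ph": ph,
        "x": x,
        "orientation_deg": rng.uniform(0, 360, n),
        "y": y,
    })


class TestExclusions:
    def test_incubation_drops_three_sites(self):
        data = make_data(54)
        data["tau_i"] = 10.0
        assert len(apply_exclusions(data, "log_taui")) == 51

    def test_radiocarbon_drops_one_site(self):
        data = make_data(54)
        assert len(apply_exclusions(data, "log_tau14c")) == 53

    def test_doc_drops_saturated_only(self):
        data = make_data(54)
        data["saturated"] = False
        data.loc[data["site_id"].isin([6, 24]), "saturated"] = True
        assert len(apply_exclusions(data, "doc")) == 52

    def test_empty_exclusion_list_is_identity(self):
        data = make_data(20)
        assert len(apply_exclusions(data, "log_taui", exclusions=())) == 20


class TestSequentialAnova:
    def test_matches_statsmodels_type1(self):
        """Cross-check against statsmodels anova_lm(typ=1) on a formula-
        expressible model."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        data = make_data(40, seed=2, beta_ph=0.5)
        spec = ModelSpec(
            response="y",
            term_order=("BGR", "MI", "TI", "MI:TI", "pH"),
            exclusions=(),
        )
        mine = sequential_anova(data, spec)
        fit = smf.ols(
            "y ~ C(region) + C(mi_cat) + C(ti_cat) "
            "+ C(mi_cat):C(ti_cat) + ph",
            data=data,
        ).fit()
        theirs = anova_lm(fit, typ=1)
        for my_term, sm_term in (
            ("BGR", "C(region)"),
            ("MI", "C(mi_cat)"),
            ("TI", "C(ti_cat)"),
            ("MI:TI", "C(mi_cat):C(ti_cat)"),
            ("pH", "ph"),
        ):
            assert mine.loc[my_term, "sum_sq"] == pytest.approx(
                theirs.loc[sm_term, "sum_sq"], rel=1e-8
            )
            assert mine.loc[my_term, "p"] == pytest.approx(
                theirs.loc[sm_term, "PR(>F)"], rel=1e-8
            )

    def test_matches_nested_rss_bruteforce(self):
        """Each term's SS equals the RSS difference of successive nested
        least-squares fits (n = 20 fixture)."""
        data = make_data(20, seed=7, beta_ph=0.8, beta_x=0.4)
        spec = ModelSpec(response="y", term_order=("pH", "x"), exclusions=())
        table = sequential_anova(data, spec)
        # brute force: three nested fits
        ones = np.ones((20, 1))
        ph = data["ph"].to_numpy()[:, None]
        x = data["x"].to_numpy()[:, None]
        y = data["y"].to_numpy()

        def rss(m):
            beta, *_ = np.linalg.lstsq(m, y, rcond=None)
            r = y - m @ beta
            return float(r @ r)

        r0 = rss(ones)
        r1 = rss(np.hstack([ones, ph]))
        r2 = rss(np.hstack([ones, ph, x]))
        assert table.loc["pH", "sum_sq"] == pytest.approx(r0 - r1, rel=1e-8)
        assert table.loc["x", "sum_sq"] == pytest.approx(r1 - r2, rel=1e-8)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(r2, rel=1e-8)

    def test_decomposition_sums_to_total(self):
        data = make_data(45, seed=3, beta_ph=0.3)
        spec = ModelSpec(
            response="y",
            term_order=("BGR", "MI", "TI", "MI:TI", "pco1", "pco2"),
            exclusions=(),
        )
        table = sequential_anova(data, spec)
        y = data["y"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-10)

    def test_orthogonal_predictors_order_invariant(self):
        rng = np.random.default_rng(4)
        n = 64
        a = np.repeat([1.0, -1.0], n // 2)
        b = np.tile([1.0, -1.0], n // 2)  # exactly orthogonal to a
        data = pd.DataFrame({
            "site_id": np.arange(n), "a": a, "b": b,
            "y": 0.5 * a + 0.2 * b + rng.normal(size=n),
        })
        t1 = sequential_anova(
            data, ModelSpec("y", ("a", "b"), exclusions=())
        )
        t2 = sequential_anova(
            data, ModelSpec("y", ("b", "a"), exclusions=())
        )
        for term in ("a", "b"):
            assert t1.loc[term, "sum_sq"] == pytest.approx(
                t2.loc[term, "sum_sq"], rel=1e-10
            )

    def test_orientation_is_two_df_term(self):
        data = make_data(30, seed=9)
        table = sequential_anova(
            data, ModelSpec("y", ("orientation",), exclusions=())
        )
        assert table.loc["orientation", "df"] == 2

    def test_collinear_term_raises(self):
        data = make_data(25, seed=1)
        data["ph2"] = data["ph"] * 2.0
        with pytest.raises(np.linalg.LinAlgError, match="ph2"):
            sequential_anova(
                data, ModelSpec("y", ("pH", "ph2"), exclusions=())
            )

    def test_type_i_error_calibration(self):
        """Under a pure-noise response each term rejects at the nominal 5%
        rate (±2 points over 1000 simulations)."""
        rng = np.random.default_rng(123)
        n, n_sim = 20, 1000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        base = pd.DataFrame({"site_id": np.arange(n), "x1": x1, "x2": x2})
        hits = np.zeros(2)
        for _ in range(n_sim):
            data = base.assign(y=rng.normal(size=n))
            table = sequential_anova(
                data, ModelSpec("y", ("x1", "x2"), exclusions=())
            )
            hits += table.loc[["x1", "x2"], "p"].to_numpy() < 0.05
        for rate in hits / n_sim:
            assert rate == pytest.approx(0.05, abs=0.02)


class TestOrderConsistency:
    def test_single_ordering_rejected(self):
        data = make_data(30)
        with pytest.raises(ValueError, match="at least 2"):
            order_consistency(
                data, [ModelSpec("y", ("pH", "x"), exclusions=())]
            )

    def test_different_term_sets_rejected(self):
        data = make_data(30)
        with pytest.raises(ValueError, match="share"):
            order_consistency(data, [
                ModelSpec("y", ("pH", "x"), exclusions=()),
                ModelSpec("y", ("pH", "pco1"), exclusions=()),
            ])

    def test_orthogonal_design_no_crossed_out(self):
        n = 64
        rng = np.random.default_rng(6)
        a = np.repeat([1.0, -1.0], n // 2)
        b = np.tile([1.0, -1.0], n // 2)
        data = pd.DataFrame({
            "site_id": np.arange(n), "a": a, "b": b,
            "y": 0.8 * a + rng.normal(size=n),
        })
        rep = order_consistency(data, [
            ModelSpec("y", ("a", "b"), exclusions=()),
            ModelSpec("y", ("b", "a"), exclusions=()),
        ])
        assert not (rep.verdicts["verdict"] == "crossed_out").any()
        assert rep.verdicts.loc["a", "verdict"] == "significant"

    def test_interaction_name_order_insensitive(self):
        data = make_data(48, seed=10)
        rep = order_consistency(data, [
            ModelSpec("y", ("MI", "TI", "MI:TI"), exclusions=()),
            ModelSpec("y", ("TI", "MI", "TI:MI"), exclusions=()),
        ])
        assert "MI:TI" in rep.verdicts.index

    def test_collinear_pair_gets_crossed_out(self):
        """With r = 0.9 collinearity and a true effect on only one
        variable, order swapping exposes the other as order-dependent in
        most simulated datasets."""
        n_crossed = 0
        n_sim = 200
        for seed in range(n_sim):
            data = make_data(
                54, seed=seed, beta_ph=0.8, beta_x=0.0, collinear_r=0.9
            )
            rep = order_consistency(data, [
                ModelSpec("y", ("pH", "x"), exclusions=()),
                ModelSpec("y", ("x", "pH"), exclusions=()),
            ])
            if rep.verdicts.loc["x", "verdict"] == "crossed_out":
                n_crossed += 1
        assert n_crossed >= 0.80 * n_sim

    def test_screening_only_removes_positives(self):
        """The consistency verdict can never be significant where a single
        ordering is not: screened type-I error ≤ any single ordering's."""
        for seed in range(50):
            data = make_data(30, seed=seed)
            rep = order_consistency(data, [
                ModelSpec("y", ("pH", "x"), exclusions=()),
                ModelSpec("y", ("x", "pH"), exclusions=()),
            ])
            for term in ("pH", "x"):
                sig_each = [
                    float(t.loc[term, "p"]) < 0.05 for t in rep.tables
                ]
                if rep.verdicts.loc[term, "verdict"] == "significant":
                    assert all(sig_each)


class TestPearson:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        out = pearson_summary(df, [("a", "b")])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = np.cov(a, b, ddof=1)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        out = pearson_summary(pd.DataFrame({"a": a, "b": b}), [("a", "b")])
        assert out.loc[0, "r"] == pytest.approx(r_hand, rel=1e-12)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(8)
        small = 0
        for _ in range(40):
            df = pd.DataFrame({
                "a": rng.normal(size=1000), "b": rng.normal(size=1000)
            })
            r = pearson_summary(df, [("a", "b")]).loc[0, "r"]
            small += abs(r) < 0.1
        assert small >= 38  # ≥95% of runs

    def test_pairwise_complete_and_errors(self):
        df = pd.DataFrame({"a": [1.0, 2, np.nan, 4, 5],
                           "b": [2.0, 4, 5, np.nan, 7],
                           "c": [1.0, 1, 1, 1, 1]})
        out = pearson_summary(df, [("a", "b")])
        assert out.loc[0, "n"] == 3
        with pytest.raises(ValueError, match="variance"):
            pearson_summary(df, [("a", "c")])


def test_significance_codes():
    assert significance_code(0.0005) == "***"
    assert significance_code(0.005) == "**"
    assert significance_code(0.03) == "*"
    assert significance_code(0.07) == "."
    assert significance_code(0.5) == "n.s."
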