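import warnings

import numpy as np
import pandas as pd
import pytest

from socturn.site_design import (
    climate_categories,
    dryness_index,
    filter_population,
    gower_distance,
    pcoa_soil_landform,
    select_orthogonal,
)
from socturn.synthdata import GeneratorConfig, generate_population


def make_sites(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "site_id": [f"S{i:03d}" for i in range(n)],
        "region": rng.choice(["A", "B", "C"], n),
        "temp": rng.normal(7, 2.5, n),
        "dryness": rng.integers(0, 60, n),
        "ph": rng.uniform(3.5, 7.5, n),
        "clay": rng.uniform(5, 60, n),
        "slope": rng.uniform(0, 45, n),
        "orientation": rng.choice(list("NESW"), n),
    })


class TestFilterPopulation:
    def test_threshold_is_strict_larger_than(self):
        df = pd.DataFrame({"site_id": [1, 2, 3], "slope": [50.0, 50.01, 60.0],
                           "is_lwf": [False, False, False]})
        kept = filter_population(df)
        assert kept["site_id"].tolist() == [1]

    def test_monitoring_sites_exempt(self):
        df = pd.DataFrame({"site_id": [1, 2], "slope": [60.0, 60.0],
                           "is_lwf": [True, False]})
        assert filter_population(df)["site_id"].tolist() == [1]

    def test_missing_lwf_column_treated_as_false(self):
        df = pd.DataFrame({"site_id": [1, 2], "slope": [10.0, 70.0]})
        assert filter_population(df)["site_id"].tolist() == [1]


class TestDrynessIndex:
    def test_strict_inequality(self):
        p = np.full(12, 80.0)
        assert dryness_index(p, p) == 0

    def test_all_dry(self):
        pet = np.full(360, 80.0)
        assert dryness_index(pet - 1.0, pet) == 360

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 150, 360)
        pet = rng.uniform(0, 150, 360)
        brute = sum(1 for a, b in zip(p, pet) if a < b)
        assert dryness_index(p, pet) == brute

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dryness_index(np.ones(12), np.ones(13))


class TestClimateCategories:
    def test_four_quadrants_occupied(self):
        # one site in each temperature×moisture quadrant
        df = pd.DataFrame({"temp": [1, 2, 3, 4], "dryness": [1, 3, 2, 4]})
        cats = climate_categories(df)
        combos = set(zip(cats["ti_cat"], cats["mi_cat"]))
        assert len(combos) == 4

    def test_antirank_collapses_to_two_categories(self):
        # perfectly anticorrelated climate covariates can only occupy the
        # cold-dry and warm-moist cells: the design problem in a nutshell
        df = pd.DataFrame({"temp": [1, 2, 3, 4], "dryness": [4, 3, 2, 1]})
        cats = climate_categories(df)
        combos = set(zip(cats["ti_cat"], cats["mi_cat"]))
        assert combos == {("TT-", "MI-"), ("TT+", "MI+")}

    def test_balanced_counts_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 100
            df = pd.DataFrame({"temp": rng.normal(size=n),
                               "dryness": rng.normal(size=n)})
            cats = climate_categories(df)
            for col, val in (("ti_cat", "TT-"), ("mi_cat", "MI+")):
                assert abs((cats[col] == val).sum() - n / 2) <= 1

    def test_tie_at_median_goes_to_lower_bin(self):
        df = pd.DataFrame({"temp": [1.0, 2.0, 3.0], "dryness": [1, 2, 3]})
        cats = climate_categories(df)
        # the middle site sits exactly at both medians
        assert cats.loc[1, "ti_cat"] == "TT-"
        assert cats.loc[1, "mi_cat"] == "MI+"  # fewer dry months = moist side

    def test_invariant_to_monotone_rescaling(self):
        df = make_sites(50, seed=3)
        base = climate_categories(df)
        scaled = df.assign(temp=np.exp(df["temp"] / 3.0),
                           dryness=df["dryness"] ** 2)
        assert climate_categories(scaled).equals(base)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"temp": [1.0, 1.0], "dryness": [0, 5]})
        with pytest.raises(ValueError, match="constant"):
            climate_categories(df)


class TestPcoa:
    def test_identical_sites_identical_coordinates(self):
        df = make_sites(10, seed=4)
        df.loc[1, ["ph", "clay", "slope", "orientation"]] = df.loc[
            0, ["ph", "clay", "slope", "orientation"]
        ]
        pco1, pco2, _ = pcoa_soil_landform(df)
        assert pco1[0] == pytest.approx(pco1[1], abs=1e-8)
        assert pco2[0] == pytest.approx(pco2[1], abs=1e-8)

    def test_single_gradient_recovered_on_first_axis(self):
        df = pd.DataFrame({
            "ph": [4.0, 5.0, 6.0],
            "clay": [20.0, 20.0, 20.0],
            "slope": [10.0, 10.0, 10.0],
            "orientation": ["N", "N", "N"],
        })
        pco1, pco2, _ = pcoa_soil_landform(df)
        assert np.all(np.abs(pco2) < 1e-8)
        assert np.all(np.diff(np.sort(pco1)) > 0)
        order = np.argsort(pco1)
        assert list(order) in ([0, 1, 2], [2, 1, 0])

    def test_standardized_euclidean_equals_pca_scores(self):
        """Classical MDS on standardised Euclidean distances reproduces PCA
        scores up to sign (random 20×4 matrices)."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.normal(size=(20, 4))
            df = pd.DataFrame(x, columns=["ph", "clay", "slope", "extra"])
            df["orientation"] = "N"
            pco1, pco2, _ = pcoa_soil_landform(
                df, distance="euclidean_standardized",
                numeric=("ph", "clay", "slope", "extra"),
            )
            z = (x - x.mean(0)) / x.std(0, ddof=0)
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            scores = u * s
            for got, want in ((pco1, scores[:, 0]), (pco2, scores[:, 1])):
                agree = min(
                    np.max(np.abs(got - want)), np.max(np.abs(got + want))
                )
                assert agree < 1e-8

    def test_eigenvalue_trace_identity(self):
        """The full signed spectrum sums to the total dispersion (trace of
        the double-centred −½D² matrix); for a Euclidean distance the
        positive part alone accounts for all of it."""
        df = make_sites(25, seed=6)
        _, _, eig = pcoa_soil_landform(df)
        d = gower_distance(df)
        j = np.eye(25) - np.ones((25, 25)) / 25
        b = -0.5 * j @ (d**2) @ j
        assert eig.sum() == pytest.approx(np.trace(b), rel=1e-8)
        _, _, eig_e = pcoa_soil_landform(df, distance="euclidean_standardized")
        assert eig_e[eig_e > 0].sum() == pytest.approx(eig_e.sum(), abs=1e-8)

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            pcoa_soil_landform(make_sites(2))


@pytest.fixture(scope="module")
def population():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_population(GeneratorConfig(seed=5))


class TestSelectOrthogonal:

    def test_deterministic_given_input(self, population):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = select_orthogonal(population, n_target=54)
            b = select_orthogonal(population, n_target=54)
        assert a.selected_ids == b.selected_ids
        assert a.orthogonality_report == b.orthogonality_report

    def test_target_size_and_stratification(self, population):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_orthogonal(population, n_target=54)
        assert len(sel.selected_ids) == 54
        chosen = sel.selected
        # every selected site passed the filters and has both categories
        assert chosen["ti_cat"].isin(["TT-", "TT+"]).all()
        assert chosen["mi_cat"].isin(["MI-", "MI+"]).all()

    def test_beats_random_subsets(self, population):
        """The designed selection yields a lower max |correlation| among
        design terms than the bulk of random same-size subsets."""
        from socturn.site_design import _design_max_corr

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_orthogonal(population, n_target=54)
        designed = sel.orthogonality_report["max_abs_corr"]
        pop = sel.table
        rng = np.random.default_rng(0)
        wins = 0
        n_trials = 100
        for _ in range(n_trials):
            idx = rng.choice(len(pop), size=54, replace=False)
            rand = _design_max_corr(pop.iloc[idx])["max_abs_corr"]
            wins += designed <= rand
        assert wins >= 90  # stratification + plane-spread rarely loses

    def test_too_large_target_rejected(self, population):
        with pytest.raises(ValueError):
            select_orthogonal(population.head(10), n_target=20)

    def test_empty_cell_warns_and_reports_gap(self):
        df = make_sites(30, seed=8)
        # force a missing combination: region C only cold-dry
        df.loc[df["region"] == "C", "temp"] = df["temp"].min() - 5
        df.loc[df["region"] == "C", "dryness"] = int(df["dryness"].max() + 5)
        with pytest.warns(UserWarning, match="no candidate"):
            sel = select_orthogonal(df, n_target=12)
        assert len(sel.gaps) >= 1
        assert len(sel.selected_ids) == 12
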