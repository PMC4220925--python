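"""Spatial descriptors and the eight-component deviance partition."""

import numpy as np
import pandas as pd
import pytest

import invasibility as inv
from invasibility.partition import (DeviancePartition, build_spatial_terms,
                                    explained_fraction, partition_deviance)


class TestSpatialTerms:
    def test_single_site_all_zero(self):
        coords = pd.DataFrame({"x": [3.7], "y": [-2.0]})
        terms = build_spatial_terms(coords)
        assert terms.shape == (1, 9)
        assert (terms.to_numpy() == 0).all()

    def test_two_sites_on_x_axis(self):
        coords = pd.DataFrame({"x": [1.0, -1.0], "y": [0.0, 0.0]})
        terms = build_spatial_terms(coords)
        assert terms["spatial_x"].tolist() == [1.0, -1.0]
        assert terms["spatial_x2"].tolist() == [1.0, 1.0]
        assert terms["spatial_x3"].tolist() == [1.0, -1.0]
        y_cols = [c for c in terms.columns if "y" in c]
        assert (terms[y_cols].to_numpy() == 0).all()

    def test_exactly_nine_centred_terms(self, rng):
        coords = pd.DataFrame({"x": rng.uniform(0, 100, 50),
                               "y": rng.uniform(0, 100, 50)})
        terms = build_spatial_terms(coords)
        assert terms.shape[1] == 9
        assert abs(terms["spatial_x"].mean()) < 1e-12
        assert abs(terms["spatial_y"].mean()) < 1e-12

    def test_missing_coordinate_names_site(self):
        coords = pd.DataFrame({"x": [1.0, np.nan], "y": [0.0, 1.0]},
                              index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            build_spatial_terms(coords)


class TestExplainedFraction:
    def test_arithmetic(self):
        fit = inv.GlmFit(spec=inv.GlmSpec("poisson_log", "y"),
                         coefficients={}, null_deviance=120.0,
                         residual_deviance=30.0, aic=0.0, dispersion=1.0,
                         converged=True, nobs=10, df_resid=9)
        assert explained_fraction(fit) == pytest.approx(0.75)

    def test_zero_null_deviance_rejected(self):
        fit = inv.GlmFit(spec=inv.GlmSpec("poisson_log", "y"),
                         coefficients={}, null_deviance=0.0,
                         residual_deviance=0.0, aic=0.0, dispersion=1.0,
                         converged=True, nobs=10, df_resid=9)
        with pytest.raises(ValueError):
            explained_fraction(fit)


def _orthonormal_design(n=200, k=4, seed=13):
    """Mean-zero orthonormal columns spanning known response shares."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, k))
    raw = raw - raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    return q


@pytest.fixture(scope="module")
def gaussian_toy():
    """E/P/S each one orthogonal column with R² exactly 0.2/0.1/0.05."""
    q = _orthonormal_design()
    y = (np.sqrt(0.2) * q[:, 0] + np.sqrt(0.1) * q[:, 1]
         + np.sqrt(0.05) * q[:, 2] + np.sqrt(0.65) * q[:, 3])
    return pd.DataFrame({"y": y, "e": q[:, 0], "p": q[:, 1], "s": q[:, 2]})


class TestGaussianLimit:
    def test_orthogonal_known_shares_recovered(self, gaussian_toy):
        fractions = partition_deviance(
            "y", "gaussian_identity",
            {"E": ["e"], "P": ["p"], "S": ["s"]}, gaussian_toy,
            select=False)
        assert fractions.pure_env == pytest.approx(0.20, abs=1e-10)
        assert fractions.pure_pressure == pytest.approx(0.10, abs=1e-10)
        assert fractions.pure_spatial == pytest.approx(0.05, abs=1e-10)
        for shared in (fractions.env_pressure, fractions.env_spatial,
                       fractions.pressure_spatial, fractions.three_way):
            assert shared == pytest.approx(0.0, abs=1e-10)
        assert fractions.unexplained == pytest.approx(0.65, abs=1e-10)

    def test_matches_r2_inclusion_exclusion_oracle(self, rng):
        """Correlated Gaussian toy vs an independent lstsq R² oracle."""
        n = 200
        base = rng.normal(size=(n, 5))
        data = pd.DataFrame({
            "e1": base[:, 0], "e2": 0.6 * base[:, 0] + base[:, 1],
            "p1": 0.4 * base[:, 0] + base[:, 2], "s1": base[:, 3],
        })
        data["y"] = (0.5 * data["e1"] + 0.3 * data["p1"] + 0.2 * data["s1"]
                     + base[:, 4])

        def r2(cols):
            if not cols:
                return 0.0
            X = np.column_stack([np.ones(n), data[cols].to_numpy()])
            y = data["y"].to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            tss = float(((y - y.mean()) ** 2).sum())
            return 1 - rss / tss

        E, P, S = ["e1", "e2"], ["p1"], ["s1"]
        D = {"E": r2(E), "P": r2(P), "S": r2(S), "EP": r2(E + P),
             "ES": r2(E + S), "PS": r2(P + S), "EPS": r2(E + P + S)}
        g = (D["E"] + D["P"] + D["S"] - D["EP"] - D["ES"] - D["PS"]
             + D["EPS"])
        fractions = partition_deviance(
            "y", "gaussian_identity", {"E": E, "P": P, "S": S}, data,
            select=False)
        assert fractions.pure_env == pytest.approx(D["EPS"] - D["PS"],
                                                   abs=1e-8)
        assert fractions.pure_pressure == pytest.approx(D["EPS"] - D["ES"],
                                                        abs=1e-8)
        assert fractions.pure_spatial == pytest.approx(D["EPS"] - D["EP"],
                                                       abs=1e-8)
        assert fractions.three_way == pytest.approx(g, abs=1e-8)
        assert fractions.unexplained == pytest.approx(1 - D["EPS"], abs=1e-8)


class TestPartitionProperties:
    @pytest.fixture(scope="class")
    def sim_data(self):
        sites = inv.simulate_sites(seed=99)
        frame = inv.sites_to_frame(sites).set_index("site_id")
        species = [inv.SpeciesInfo("nns", "non_native")]
        table = inv.simulate_densities(
            sites, species,
            inv.EffectConfig(env_coefficients={"drainage_area": 0.6},
                             seed=100))
        frame["occ"] = (table.density["nns"] > 0).astype(int).to_numpy()
        spatial = build_spatial_terms(frame[["x", "y"]])
        return pd.concat([frame, spatial], axis=1), list(spatial.columns)

    def test_fractions_sum_to_one(self, sim_data):
        data, s_terms = sim_data
        fractions = partition_deviance(
            "occ", "binomial_logit",
            {"E": ["temperature", "drainage_area"],
             "P": ["pressure_land_use", "pressure_urban_area"],
             "S": s_terms}, data)
        assert fractions.total() == pytest.approx(1.0, abs=1e-10)

    def test_set_relabelling_permutes_fractions(self, sim_data):
        data, s_terms = sim_data
        sets = {"E": ["temperature", "drainage_area"],
                "P": ["pressure_land_use"], "S": s_terms[:3]}
        base = partition_deviance("occ", "binomial_logit", sets, data,
                                  select=False)
        swapped = partition_deviance(
            "occ", "binomial_logit",
            {"E": sets["P"], "P": sets["E"], "S": sets["S"]}, data,
            select=False)
        assert swapped.pure_env == pytest.approx(base.pure_pressure, abs=1e-10)
        assert swapped.pure_pressure == pytest.approx(base.pure_env, abs=1e-10)
        assert swapped.pure_spatial == pytest.approx(base.pure_spatial,
                                                     abs=1e-10)
        assert swapped.env_spatial == pytest.approx(base.pressure_spatial,
                                                    abs=1e-10)
        assert swapped.three_way == pytest.approx(base.three_way, abs=1e-10)
        assert swapped.unexplained == pytest.approx(base.unexplained,
                                                    abs=1e-10)

    def test_empty_spatial_set_reduces_to_two_set_partition(self, sim_data):
        data, _ = sim_data
        sets = {"E": ["temperature", "drainage_area"],
                "P": ["pressure_land_use", "BOD5"], "S": []}
        fractions = partition_deviance("occ", "binomial_logit", sets, data,
                                       select=False)
        assert fractions.pure_spatial == pytest.approx(0.0, abs=1e-12)
        assert fractions.env_spatial == pytest.approx(0.0, abs=1e-12)
        assert fractions.pressure_spatial == pytest.approx(0.0, abs=1e-12)
        assert fractions.three_way == pytest.approx(0.0, abs=1e-12)
        # two-set arithmetic computed directly
        fit = lambda terms: inv.fit_glm(
            inv.GlmSpec("binomial_logit", "occ", tuple(terms)), data)
        D_E = fit(sets["E"]).explained_fraction
        D_P = fit(sets["P"]).explained_fraction
        D_EP = fit(sets["E"] + sets["P"]).explained_fraction
        assert fractions.pure_env == pytest.approx(D_EP - D_P, abs=1e-10)
        assert fractions.pure_pressure == pytest.approx(D_EP - D_E, abs=1e-10)
        assert fractions.env_pressure == pytest.approx(D_E + D_P - D_EP,
                                                       abs=1e-10)

    def test_independent_response_mostly_unexplained(self):
        """With a response unrelated to anything, every pure and shared
        component stays near zero and the unexplained share near one."""
        rng = np.random.default_rng(31)
        totals = []
        for rep in range(5):
            sites = inv.simulate_sites(seed=500 + rep)
            frame = inv.sites_to_frame(sites).set_index("site_id")
            frame["occ"] = rng.binomial(1, 0.4, size=len(frame))
            model = DeviancePartition.from_coordinates(
                frame, "occ", "binomial_logit",
                ["temperature", "precipitation", "altitude", "drainage_area"],
                ["pressure_land_use", "pressure_urban_area",
                 "pressure_sediment_load"])
            fractions = model.fit().fractions
            s = fractions.to_series()
            totals.append(s)
            assert s["unexplained"] > 0.85
        mean = pd.concat(totals, axis=1).mean(axis=1)
        for comp in ("pure_env", "pure_pressure", "pure_spatial",
                     "env_pressure", "env_spatial", "pressure_spatial",
                     "three_way"):
            assert abs(mean[comp]) < 0.03

    def test_overlapping_sets_rejected(self, sim_data):
        data, _ = sim_data
        with pytest.raises(ValueError, match="disjoint"):
            DeviancePartition(data, "occ", "binomial_logit",
                              {"E": ["temperature"], "P": ["temperature"],
                               "S": []})

    def test_summary_and_report_frame(self, sim_data):
        data, s_terms = sim_data
        model = DeviancePartition(
            data, "occ", "binomial_logit",
            {"E": ["drainage_area"], "P": ["pressure_land_use"],
             "S": s_terms[:2]}, select=False)
        res = model.fit()
        text = res.summary()
        assert "pure environment" in text and "unexplained" in text
        row = res.to_frame()
        pct_cols = [c for c in row.columns if c.startswith("pct_")]
        assert row[pct_cols].to_numpy().sum() == pytest.approx(100.0,
                                                               abs=1e-8)
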