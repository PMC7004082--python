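import numpy as np
import pandas as pd
import pytest

from sitefidelity.fidelity import (PairDraw, boldness_fidelity_model, draw_pairs,
                                   exact_fidelity_expectation, fidelity_iteration,
                                   run_fidelity_randomization, similarity_outcomes,
                                   summarize_fidelity)
from sitefidelity.geo import enu_to_latlon
from sitefidelity.synthetic import SimConfig, simulate_sites

COLONY = (78.9, 12.1)


def sites_from_enu(entries):
    """entries: list of (bird, trip, east_m, north_m[, day])."""
    rows = []
    for k, entry in enumerate(entries):
        bird, trip, x, y = entry[:4]
        day = entry[4] if len(entry) > 4 else k
        lat, lon = enu_to_latlon(COLONY[0], COLONY[1], x, y)
        rows.append({"site_id": f"s{k}", "bird_id": bird,
                     "trip_id": f"{bird}_{trip}", "colony_id": "A",
                     "stage": "incubation", "lat_c": float(lat),
                     "lon_c": float(lon),
                     "t_mid": pd.Timestamp("2017-06-15") + pd.Timedelta(days=day)})
    return pd.DataFrame(rows)


class TestDrawPairs:
    def test_two_bird_colony_gives_one_between_pair(self, rng):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 12000),
                                ("b", 1, 5000, 5000)])
        pair = draw_pairs(sites, "s0", rng)
        assert list(pair.between_site_ids) == ["b"]

    def test_within_site_always_from_other_trip(self, rng):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 1, 0, 11000),
                                ("a", 2, 0, 12000), ("b", 1, 5000, 5000)])
        for _ in range(20):
            pair = draw_pairs(sites, "s0", rng)
            assert pair.within_site_id == "s2"

    def test_single_trip_focal_rejected(self, rng):
        sites = sites_from_enu([("a", 1, 0, 10000), ("b", 1, 5000, 5000),
                                ("b", 2, 5000, 6000)])
        with pytest.raises(ValueError, match="single trip"):
            draw_pairs(sites, "s0", rng)

    def test_lone_bird_colony_rejected(self, rng):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 12000)])
        with pytest.raises(ValueError, match="2 birds"):
            draw_pairs(sites, "s0", rng)

    def test_within_draw_uniform_over_candidates(self, rng):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 11000),
                                ("a", 3, 0, 12000), ("a", 4, 0, 13000),
                                ("b", 1, 5000, 5000)])
        n = 3000
        counts = pd.Series([draw_pairs(sites, "s0", rng).within_site_id
                            for _ in range(n)]).value_counts()
        p = 1 / 3
        se = np.sqrt(p * (1 - p) / n)
        for sid in ("s1", "s2", "s3"):
            assert counts[sid] / n == pytest.approx(p, abs=3 * se)


class TestSimilarityOutcomes:
    def test_identical_within_site_scores_all_ones(self):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 10000),
                                ("b", 1, 5000, 5000), ("c", 1, -9000, 0)])
        pair = PairDraw("s0", "s1", {"b": "s2", "c": "s3"})
        outcomes, _ = similarity_outcomes(pair, sites)
        assert outcomes.tolist() == [1, 1]

    def test_distant_within_site_scores_all_zeros(self):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 40000),
                                ("b", 1, 0, 11000), ("c", 1, 0, 9000)])
        pair = PairDraw("s0", "s1", {"b": "s2", "c": "s3"})
        outcomes, _ = similarity_outcomes(pair, sites)
        assert outcomes.tolist() == [0, 0]

    def test_meridian_toy_geometry_half(self):
        # within at 2 km; between sites at 1 km and 3 km from the focal site
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 12000),
                                ("b", 1, 0, 11000), ("c", 1, 0, 13000)])
        pair = PairDraw("s0", "s1", {"b": "s2", "c": "s3"})
        outcomes, _ = similarity_outcomes(pair, sites)
        assert outcomes.tolist() == [0, 1]
        assert outcomes.mean() == 0.5

    def test_time_difference_is_absolute_days(self):
        sites = sites_from_enu([("a", 1, 0, 10000, 10), ("a", 2, 0, 12000, 3),
                                ("b", 1, 0, 11000, 0)])
        pair = PairDraw("s0", "s1", {"b": "s2"})
        _, dt = similarity_outcomes(pair, sites)
        assert dt == pytest.approx(7.0)


class TestIterationEstimates:
    def test_raw_proportion_without_time_covariate(self, rng):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 10000),
                                ("b", 1, 5000, 5000), ("b", 2, 5500, 5000),
                                ("c", 1, -9000, 0), ("c", 2, -9500, 0)])
        est = fidelity_iteration(sites, rng, include_time=False)
        a = est.loc[est.bird_id == "a"].iloc[0]
        assert a["fidelity"] == 1.0  # its two sites coincide: nothing closer
        assert a["se"] == 0.0

    def test_separated_bird_clamped_and_flagged(self, rng):
        sites = sites_from_enu([("a", 1, 0, 10000), ("a", 2, 0, 10000),
                                ("b", 1, 5000, 5000), ("b", 2, 5500, 5000),
                                ("c", 1, -9000, 0), ("c", 2, -9500, 0)])
        est = fidelity_iteration(sites, rng, include_time=True)
        a = est.loc[est.bird_id == "a"].iloc[0]
        m = 4  # 2 focal sites x 2 other birds
        assert a["flagged"]
        assert a["fidelity"] == pytest.approx(1 - 1 / (2 * m))

    def test_montecarlo_matches_exhaustive_pairing_oracle(self):
        cfg = SimConfig(colony_coords=[("A", 78.9, 12.1)], n_birds_per_colony=4,
                        n_trips_per_bird=3, rng_seed=11)
        sites, _ = simulate_sites(cfg)
        exact = exact_fidelity_expectation(sites)
        est = run_fidelity_randomization(sites, n_iter=1000, seed=5,
                                        include_time=False)
        mc = est.groupby("bird_id")["fidelity"].mean()
        assert np.all((exact - mc).abs() < 0.02)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(colony_coords=[("A", 78.9, 12.1)], n_birds_per_colony=3,
                        n_trips_per_bird=3, rng_seed=2)
        sites, _ = simulate_sites(cfg)
        e1 = run_fidelity_randomization(sites, n_iter=10, seed=9)
        e2 = run_fidelity_randomization(sites, n_iter=10, seed=9)
        pd.testing.assert_frame_equal(e1, e2)

    def test_single_iteration_one_estimate_per_bird(self):
        cfg = SimConfig(colony_coords=[("A", 78.9, 12.1)], n_birds_per_colony=3,
                        n_trips_per_bird=2, rng_seed=2)
        sites, _ = simulate_sites(cfg)
        est = run_fidelity_randomization(sites, n_iter=1, seed=0)
        assert est.groupby("bird_id").size().eq(1).all()
        assert est["fidelity"].between(0, 1).all()

    def test_planted_fidelity_ordering_recovered(self):
        """Birds with fidelity 1 outrank birds with fidelity 0 in every run."""
        wins = 0
        for seed in range(20):
            cfg = SimConfig(colony_coords=[("A", 78.9, 12.1)],
                            n_birds_per_colony=8, n_trips_per_bird=4,
                            fidelity_levels=[1, 1, 1, 1, 0, 0, 0, 0],
                            rng_seed=seed)
            sites, birds = simulate_sites(cfg)
            est = run_fidelity_randomization(sites, n_iter=30, seed=seed,
                                            include_time=False)
            summ = summarize_fidelity(est).merge(
                birds[["bird_id", "fidelity_level"]], on="bird_id")
            hi = summ.loc[summ.fidelity_level == 1, "fidelity_mean"].mean()
            lo = summ.loc[summ.fidelity_level == 0, "fidelity_mean"].mean()
            wins += hi > lo
        assert wins == 20


class TestBoldnessFidelityModel:
    @staticmethod
    def _birds(n):
        return pd.DataFrame({"bird_id": [f"b{i}" for i in range(n)],
                             "boldness": np.linspace(-1, 1, n),
                             "sex": ["F", "M"] * (n // 2),
                             "colony_id": ["A"] * (n // 2) + ["B"] * (n // 2),
                             "date": np.arange(n) % 5 * 1.0})

    def test_exact_linear_relation_recovered(self):
        birds = self._birds(24)
        est = pd.DataFrame({"iteration": 0, "bird_id": birds.bird_id,
                            "fidelity": 0.5 + 0.2 * birds.boldness})
        res = boldness_fidelity_model(est, birds, test_interactions=False)
        co = res.coefficients.set_index("name")
        assert co.loc["boldness", "mean"] == pytest.approx(0.2, abs=1e-10)
        assert res.terms["boldness"]["p"] < 1e-10

    def test_aliased_covariates_raise(self):
        birds = self._birds(24)
        birds["sex"] = np.where(birds["colony_id"] == "A", "F", "M")  # aliased
        est = pd.DataFrame({"iteration": 0, "bird_id": birds.bird_id,
                            "fidelity": 0.5 + 0.0 * birds.boldness})
        with pytest.raises(ValueError, match="aliased"):
            boldness_fidelity_model(est, birds, test_interactions=False)

    def test_iteration_interval_brackets_mean(self, rng):
        birds = self._birds(20)
        frames = [pd.DataFrame({"iteration": i, "bird_id": birds.bird_id,
                                "fidelity": np.clip(0.5 + 0.1 * birds.boldness +
                                                    rng.normal(0, 0.05, 20), 0, 1)})
                  for i in range(50)]
        res = boldness_fidelity_model(pd.concat(frames), birds,
                                      test_interactions=False)
        co = res.coefficients.set_index("name")
        assert (co["ci_lo"] <= co["mean"]).all()
        assert (co["mean"] <= co["ci_hi"]).all()
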