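"""Generator contracts: determinism, balance, identities and noise scaling."""

import numpy as np
import pytest

import soilecol as se
from soilecol import synthetic as syn


class TestDesign:
    @pytest.mark.parametrize("n_reps,expected", [(5, 50), (1, 10), (3, 30)])
    def test_balanced_size(self, n_reps, expected):
        d = se.simulate_design(n_reps)
        assert len(d) == expected
        assert d.n_replicates == n_reps

    def test_unique_ids_and_cells(self):
        d = se.simulate_design(4)
        ids = [s.sample_id for s in d.samples]
        assert len(set(ids)) == len(ids)
        assert len(d.groups()) == 10

    def test_invalid_replicates(self):
        with pytest.raises(ValueError):
            se.simulate_design(0)

    def test_deterministic(self):
        assert se.simulate_design(5, seed=7) == se.simulate_design(5, seed=7)


class TestColonyCounts:
    def test_degenerate_proportions_put_all_in_one_class(self, design):
        eff = se.default_group_effects(seed=0)
        params = {
            g: syn.GroupParams(
                class_proportions=(1.0, 0.0, 0.0),
                occurrence_prob=p.occurrence_prob,
                mean_abundance=p.mean_abundance,
                c0=p.c0,
                k=p.k,
                chemistry_means=p.chemistry_means,
            )
            for g, p in eff.params.items()
        }
        eff2 = syn.GroupEffects(params=params, band_positions=eff.band_positions)
        counts = se.simulate_colony_counts(design, eff2, seed=1)
        for arr in counts.values():
            assert arr[1] == arr[2] == 0 and arr[0] > 0

    def test_empirical_proportions_match_thirds(self):
        # 1e5 multinomial draws: each class within 3 binomial SE of 1/3
        n = 100_000
        se3 = 3 * np.sqrt((1 / 3) * (2 / 3) / n)
        d = se.simulate_design(1, seed=0)
        params = se.default_group_effects(seed=0)
        uniform = {
            g: syn.GroupParams(
                class_proportions=(1 / 3, 1 / 3, 1 / 3),
                occurrence_prob=p.occurrence_prob,
                mean_abundance=p.mean_abundance,
                c0=p.c0,
                k=p.k,
                chemistry_means=p.chemistry_means,
            )
            for g, p in params.params.items()
        }
        eff = syn.GroupEffects(params=uniform, band_positions=params.band_positions)
        counts = se.simulate_colony_counts(
            d, eff, total_mean=n, dispersion=0.0, seed=3
        )
        arr = next(iter(counts.values()))
        props = arr / arr.sum()
        assert np.all(np.abs(props - 1 / 3) < se3)

    def test_deterministic(self, design, effects):
        a = se.simulate_colony_counts(design, effects, seed=9)
        b = se.simulate_colony_counts(design, effects, seed=9)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_invalid_total(self, design, effects):
        with pytest.raises(ValueError):
            se.simulate_colony_counts(design, effects, total_mean=0)


class TestLaneTrace:
    def test_single_band_argmax_at_position(self):
        tr = se.simulate_lane_trace([(0.3, 100.0)], noise_sd=0.0, n_points=501)
        assert abs(np.argmax(tr) / 500 - 0.3) <= 1 / 500

    def test_zero_bands_zero_everything(self):
        tr = se.simulate_lane_trace([], noise_sd=0.0, n_points=100)
        assert np.all(tr == 0)

    def test_max_matches_tallest_band(self):
        tr = se.simulate_lane_trace(
            [(0.2, 80.0), (0.7, 120.0)], noise_sd=0.0, n_points=2000
        )
        assert abs(tr.max() - 120.0) / 120.0 < 0.01

    def test_position_validation(self):
        with pytest.raises(ValueError):
            se.simulate_lane_trace([(1.5, 10.0)])

    def test_nonnegative_with_noise(self):
        tr = se.simulate_lane_trace([(0.5, 5.0)], noise_sd=10.0, seed=2)
        assert tr.min() >= 0


class TestBandCommunity:
    def test_full_occupancy_gives_pool_richness(self, design):
        eff = se.default_group_effects(pool_size=20, seed=0)
        params = {
            g: syn.GroupParams(
                class_proportions=p.class_proportions,
                occurrence_prob=np.ones(20),
                mean_abundance=p.mean_abundance,
                c0=p.c0,
                k=p.k,
                chemistry_means=p.chemistry_means,
            )
            for g, p in eff.params.items()
        }
        eff2 = syn.GroupEffects(params=params, band_positions=eff.band_positions)
        ab = se.simulate_band_community(design, eff2, seed=1)
        assert all(np.count_nonzero(v) == 20 for v in ab.values())

    def test_disjoint_pools_zero_between_group_dice(self):
        d = se.simulate_design(2, seed=0)
        eff = se.default_group_effects(pool_size=10, seed=0)
        params = {}
        for g, p in eff.params.items():
            occ = np.zeros(10)
            occ[:5] = 1.0
            if g[1] == "autumn":
                occ = occ[::-1].copy()
            params[g] = syn.GroupParams(
                class_proportions=p.class_proportions,
                occurrence_prob=occ,
                mean_abundance=p.mean_abundance,
                c0=p.c0,
                k=p.k,
                chemistry_means=p.chemistry_means,
            )
        eff2 = syn.GroupEffects(params=params, band_positions=eff.band_positions)
        ab = se.simulate_band_community(d, eff2, seed=1)
        spring = [ab[s.sample_id] for s in d.samples if s.season == "spring"]
        autumn = [ab[s.sample_id] for s in d.samples if s.season == "autumn"]
        for a in spring:
            for b in autumn:
                assert se.dice_similarity(a, b) == 0.0

    def test_no_group_effect_dice_within_equals_between(self):
        # permutation-style oracle: with identical group parameters the mean
        # within-group Dice equals the between-group mean up to MC error
        d = se.simulate_design(10, seed=0)
        eff = se.default_group_effects(
            pool_size=30, season_effect=0.0, land_use_effect=0.0, seed=0
        )
        ab = se.simulate_band_community(d, eff, seed=5)
        samples = list(d.samples)
        within, between = [], []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = samples[i], samples[j]
                val = se.dice_similarity(ab[a.sample_id], ab[b.sample_id])
                key = (
                    within
                    if (a.land_use, a.season) == (b.land_use, b.season)
                    else between
                )
                key.append(val)
        assert abs(np.mean(within) - np.mean(between)) < 0.03

    def test_deterministic(self, design, effects):
        a = se.simulate_band_community(design, effects, seed=4)
        b = se.simulate_band_community(design, effects, seed=4)
        assert all(np.array_equal(a[k], b[k]) for k in a)


class TestRespiration:
    def test_noiseless_matches_model(self):
        series = se.simulate_respiration(800.0, 0.05, noise_sd=0.0)
        t, cm = series[:, 0], series[:, 1]
        assert np.allclose(cm, 800.0 * (1 - np.exp(-0.05 * t)))

    def test_value_at_day_28(self):
        series = se.simulate_respiration(800.0, 0.05, days=[28], noise_sd=0.0)
        assert series[0, 1] == pytest.approx(602.7224288467148, rel=1e-12)

    def test_zero_at_time_zero_and_asymptote(self):
        series = se.simulate_respiration(800.0, 0.05, days=[1e-12, 1000.0])
        assert series[0, 1] == pytest.approx(0.0, abs=1e-6)
        assert series[1, 1] == pytest.approx(800.0, rel=1e-9)

    def test_monotonize_and_nonnegativity(self):
        series = se.simulate_respiration(
            100.0, 0.05, noise_sd=50.0, monotonize=True, seed=8
        )
        assert np.all(np.diff(series[:, 1]) >= 0)
        assert series[:, 1].min() >= 0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            se.simulate_respiration(-1.0, 0.05)
        with pytest.raises(ValueError):
            se.simulate_respiration(800.0, 0.05, days=[3, 2, 1])


class TestSoilChemistry:
    def test_zero_noise_equals_means(self, design, effects):
        chem = se.simulate_soil_chemistry(design, effects, noise_cv=0.0, seed=1)
        for s in design.samples:
            means = effects[(s.land_use, s.season)].chemistry_means
            rec = chem[s.sample_id]
            assert rec["C_org"] == pytest.approx(means[0])
            assert rec["C_ext"] == pytest.approx(means[1])
            assert rec["C_HAFA"] == pytest.approx(means[2])

    def test_fractionation_identities_always_hold(self, design, effects):
        chem = se.simulate_soil_chemistry(design, effects, noise_cv=0.3, seed=2)
        for rec in chem.values():
            assert 0 <= rec["C_HAFA"] <= rec["C_ext"] <= rec["C_org"]
            assert rec["C_NH"] == pytest.approx(rec["C_ext"] - rec["C_HAFA"], abs=1e-12)

    def test_empirical_cv_matches_target(self, effects):
        # Monte-Carlo oracle: lognormal CV of C_org near the requested 0.1
        d = se.simulate_design(100, seed=0)  # 1000 samples
        chem = se.simulate_soil_chemistry(d, effects, noise_cv=0.1, seed=3)
        vals = np.array(
            [chem[s.sample_id]["C_org"] for s in d.samples if s.land_use == "CO"]
        )
        cv = vals.std() / vals.mean()
        assert abs(cv - 0.1) < 0.02  # within 20% of the target CV

    def test_invalid_cv(self, design, effects):
        with pytest.raises(ValueError):
            se.simulate_soil_chemistry(design, effects, noise_cv=0.7)
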