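"""Spatial analysis: mirror-shuffle null, K-S test, densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovisound import (
    GradientSimConfig,
    KSResult,
    PermutationNullConfig,
    gradient_test,
    ks_two_sample,
    mirror_shuffle_null,
    simulate_gradient,
    spatial_density,
)
from ovisound.spatial import _ks_d, first_night_subset


def brute_force_ks_d(a, b):
    """Oracle: evaluate |ECDF difference| on a fine sweep of evaluation points."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pts = np.concatenate([a, b])
    pts = np.unique(np.concatenate([pts, pts - 1e-9]))
    fa = np.array([(a <= t).mean() for t in pts])
    fb = np.array([(b <= t).mean() for t in pts])
    return np.max(np.abs(fa - fb))


class TestMirrorShuffle:
    def test_sign_flip_and_fixed_point(self):
        eggs = pd.DataFrame(
            {"night_index": [1, 1], "female_id": ["f", "f"],
             "cluster_id": ["c1", "c2"], "position_cm": [-30.0, 0.0], "n_eggs": [1, 1]}
        )
        null = mirror_shuffle_null(eggs, PermutationNullConfig(n_shuffles=500, seed=1))
        vals = null.reshape(500, 2)
        assert set(np.unique(vals[:, 0])) <= {-30.0, 30.0}
        assert np.all(vals[:, 1] == 0.0)  # x=0 is a fixed point

    def test_magnitudes_preserved_every_replicate(self, eggs_frame):
        cfg = PermutationNullConfig(n_shuffles=50, seed=2, unit="cluster")
        null = mirror_shuffle_null(eggs_frame, cfg).reshape(50, -1)
        expected = np.abs(eggs_frame["position_cm"].to_numpy())
        for rep in null:
            assert np.allclose(np.abs(rep), expected)

    def test_single_egg_sign_fraction_binomial(self):
        eggs = pd.DataFrame(
            {"night_index": [1], "female_id": ["f"], "cluster_id": ["c"],
             "position_cm": [-30.0], "n_eggs": [1]}
        )
        null = mirror_shuffle_null(eggs, PermutationNullConfig(n_shuffles=10_000, seed=3))
        frac_neg = np.mean(null < 0)
        se = 0.5 / np.sqrt(10_000)
        assert abs(frac_neg - 0.5) < 3 * se

    def test_egg_unit_expands_by_cluster_size(self, eggs_frame):
        cfg = PermutationNullConfig(n_shuffles=4, seed=4, unit="egg")
        null = mirror_shuffle_null(eggs_frame, cfg)
        assert null.size == 4 * eggs_frame["n_eggs"].sum()

    def test_out_of_bounds_position_errors_naming_record(self, eggs_frame):
        bad = eggs_frame.copy()
        bad.loc[2, "position_cm"] = 80.0
        with pytest.raises(ValueError, match="c3"):
            mirror_shuffle_null(bad, PermutationNullConfig())


class TestKsTwoSample:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([0, 0, 0], [1, 1, 1], 1.0),
            ([1, 2], [1.5, 2.5], 0.5),
        ],
    )
    def test_known_distances(self, a, b, d):
        assert ks_two_sample(a, b).d == pytest.approx(d, abs=1e-12)

    def test_internal_statistic_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = np.round(rng.normal(size=rng.integers(2, 40)), 1)  # rounding forces ties
            b = np.round(rng.normal(size=rng.integers(2, 40)), 1)
            assert _ks_d(np.sort(a), np.sort(b)) == pytest.approx(
                ks_two_sample(a, b).d, abs=1e-12
            )

    @given(
        a=st.lists(st.sampled_from([0.0, 1.0, 2.0, 3.0, 4.0]), min_size=1, max_size=6),
        b=st.lists(st.sampled_from([0.0, 1.0, 2.0, 3.0, 4.0]), min_size=1, max_size=6),
    )
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_brute_force_oracle(self, a, b):
        assert ks_two_sample(a, b).d == pytest.approx(brute_force_ks_d(a, b), abs=1e-9)

    @given(
        a=st.lists(st.integers(-100, 100), min_size=2, max_size=15, unique=True),
        b=st.lists(st.integers(-100, 100), min_size=2, max_size=15, unique=True),
    )
    @settings(max_examples=100, deadline=None)
    def test_d_invariant_under_common_monotone_transform(self, a, b):
        # half-cm grid so the transform stays injective in float arithmetic
        a, b = np.array(a) / 2.0, np.array(b) / 2.0
        d0 = ks_two_sample(a, b).d
        f = lambda x: np.exp(0.05 * x) + 0.1 * x  # strictly increasing
        assert ks_two_sample(f(a), f(b)).d == pytest.approx(d0, abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestGradientTest:
    def test_mirror_invariant_data_gives_zero_d(self):
        eggs = pd.DataFrame(
            {"night_index": 1, "female_id": "f1",
             "cluster_id": [f"c{i}" for i in range(4)],
             "position_cm": [0.0, 0.0, 0.0, 0.0], "n_eggs": [2, 1, 1, 3]}
        )
        res = gradient_test(eggs, PermutationNullConfig(n_shuffles=50, seed=6))
        assert res.d == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_first_night_restriction_subsets_per_female(self, eggs_frame):
        sub = first_night_subset(eggs_frame)
        # f1 first laid night 1, f2 night 1: clusters c1, c2 only
        assert sorted(sub["cluster_id"]) == ["c1", "c2"]
        res = gradient_test(
            eggs_frame, PermutationNullConfig(n_shuffles=30, seed=7), first_night_only=True
        )
        assert res.n_obs == eggs_frame.loc[[0, 1], "n_eggs"].sum()

    def test_bimodal_speaker_data_strongly_rejected(self):
        eggs = simulate_gradient(GradientSimConfig(n_females=30, seed=8))
        res = gradient_test(eggs, PermutationNullConfig(n_shuffles=199, seed=9))
        assert res.p <= 0.01
        assert res.d > 0.2

    def test_cluster_unit_changes_sample_sizes(self, eggs_frame):
        cfg = PermutationNullConfig(n_shuffles=20, seed=10)
        egg_res = gradient_test(eggs_frame, cfg, weight_by_eggs=True)
        clu_res = gradient_test(eggs_frame, cfg, weight_by_eggs=False)
        assert egg_res.n_obs == eggs_frame["n_eggs"].sum()
        assert clu_res.n_obs == len(eggs_frame)

    def test_asymptotic_method_reports_same_d(self, eggs_frame):
        cfg = PermutationNullConfig(n_shuffles=50, seed=11)
        a = gradient_test(eggs_frame, cfg, p_method="permutation")
        b = gradient_test(eggs_frame, cfg, p_method="asymptotic")
        assert a.d == pytest.approx(b.d, abs=1e-12)
        assert b.p_method == "asymptotic"


class TestSpatialDensity:
    def test_tight_cluster_at_speaker_puts_mode_at_speaker(self):
        eggs = pd.DataFrame(
            {"night_index": 1, "female_id": "f1",
             "cluster_id": ["c1", "c2", "c3"],
             "position_cm": [-75.0, -74.5, -74.0], "n_eggs": [5, 5, 5]}
        )
        dens = spatial_density(eggs, bandwidth=3.0)
        mode = dens.loc[dens["density"].idxmax(), "position_cm"]
        assert mode <= -70

    def test_mixture_modes_within_one_bandwidth(self):
        eggs = simulate_gradient(
            GradientSimConfig(
                n_females=60, n_nights=2, clusters_per_night_rate=10,
                sigma_speaker=6.0, sigma_feeder=6.0, seed=12,
            )
        )
        bw = 4.0
        dens = spatial_density(eggs, unit="cluster", bandwidth=bw)
        d = dens["density"].to_numpy()
        x = dens["position_cm"].to_numpy()
        local_max = [
            x[i] for i in range(1, len(d) - 1)
            if d[i] >= d[i - 1] and d[i] >= d[i + 1] and d[i] > 0.3 * d.max()
        ]
        assert any(abs(m + 75) <= bw + 1 for m in local_max)
        assert any(abs(m) <= bw + 1 for m in local_max)
        assert not any(m > 30 for m in local_max)

    def test_density_integrates_to_one_over_arena(self, eggs_frame):
        for unit in ("egg", "cluster"):
            dens = spatial_density(eggs_frame, unit=unit)
            area = np.trapezoid(dens["density"], dens["position_cm"])
            assert area == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_positions_error(self):
        eggs = pd.DataFrame(
            {"night_index": 1, "female_id": "f", "cluster_id": ["a", "b"],
             "position_cm": [0.0, 0.0], "n_eggs": [1, 1]}
        )
        with pytest.raises(ValueError, match="distinct"):
            spatial_density(eggs)
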