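import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndm import (
    AtrophyMap,
    SyntheticSpec,
    bilateral_seed_vector,
    build_laplacian,
    correlation_trace,
    default_times,
    fwe_correct,
    propagate,
    repeated_seed_scan,
    synth_atrophy,
    synth_connectome,
)
from ndm.seed_scan import SeedScanResult

from conftest import make_regions


def make_map(c, t_values):
    t_values = np.asarray(t_values, dtype=float)
    return AtrophyMap(
        labels=c.regions.labels,
        t_values=t_values,
        p_values=np.full(c.n, 0.5),
    )


class TestBilateralSeedVector:
    def test_pair_has_two_ones(self, study82):
        _, c, _, _ = study82
        pair = c.regions.homologue_pairs()[0]
        f0 = bilateral_seed_vector(c.regions, pair)
        assert f0.sum() == 2.0
        assert set(np.flatnonzero(f0)) == set(pair)

    def test_by_label_includes_homologue(self, study82):
        _, c, _, _ = study82
        f0 = bilateral_seed_vector(c.regions, "lh_parstriangularis")
        assert f0.sum() == 2.0

    def test_midline_single_nonzero(self):
        regions = make_regions(["lh_a", "rh_a", "brainstem"])
        f0 = bilateral_seed_vector(regions, "brainstem")
        assert f0.sum() == 1.0

    def test_unknown_region_errors(self, study82):
        _, c, _, _ = study82
        with pytest.raises(KeyError):
            bilateral_seed_vector(c.regions, "nonexistent")
        with pytest.raises(ValueError):
            bilateral_seed_vector(c.regions, (0, 999))

    def test_41_distinct_initial_conditions(self, study82):
        _, c, _, _ = study82
        vecs = {tuple(bilateral_seed_vector(c.regions, g)) for g in c.regions.seed_groups()}
        assert len(vecs) == 41


class TestCorrelationTrace:
    def test_planted_profile_perfect_correlation(self, study82):
        spec, c, _, truth = study82
        dec = build_laplacian(c)
        pair = c.regions.homologue_pairs()[truth["seed_pair_index"]]
        f0 = bilateral_seed_vector(c.regions, pair)
        traj = propagate(dec, f0, default_times())
        clean = propagate(dec, f0, np.array([spec.t_star])).values[0]
        amap = make_map(c, clean)
        r = correlation_trace(traj, amap, exclude=pair)
        assert r[int(spec.t_star)] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_profile(self, study82):
        spec, c, _, truth = study82
        dec = build_laplacian(c)
        pair = c.regions.homologue_pairs()[truth["seed_pair_index"]]
        f0 = bilateral_seed_vector(c.regions, pair)
        traj = propagate(dec, f0, default_times())
        clean = propagate(dec, f0, np.array([spec.t_star])).values[0]
        r = correlation_trace(traj, make_map(c, -clean), exclude=pair)
        assert r[int(spec.t_star)] == pytest.approx(-1.0, abs=1e-12)

    def test_t0_is_missing_not_zero(self, study82):
        _, c, amap, _ = study82
        dec = build_laplacian(c)
        pair = c.regions.homologue_pairs()[0]
        traj = propagate(dec, bilateral_seed_vector(c.regions, pair), default_times())
        r = correlation_trace(traj, amap, exclude=pair)
        assert np.isnan(r[0])
        assert not np.any(np.isnan(r[1:]))


class TestRepeatedSeedScan:
    def test_default_dimensions(self, study82):
        _, c, amap, _ = study82
        res = repeated_seed_scan(c, amap)
        assert res.corr_matrix.shape == (41, 51)
        assert res.n_regions_used == 80
        assert res.n_seeds == 41

    def test_noise_free_recovers_planted_seed_exactly(self):
        spec = SyntheticSpec(rng_seed=5, seed_pair=20, t_star=15.0, noise_sigma=0.0)
        c = synth_connectome(spec)
        amap, truth = synth_atrophy(spec, c)
        res = repeated_seed_scan(c, amap)
        assert res.top_seed() == truth["seed_label"]
        k = truth["seed_pair_index"]
        assert res.max_r[k] == pytest.approx(1.0, abs=1e-10)
        assert res.t_star[k] == truth["t_star"]

    def test_max_r_is_rowwise_maximum(self, study82):
        _, c, amap, _ = study82
        res = repeated_seed_scan(c, amap)
        np.testing.assert_allclose(res.max_r, np.nanmax(res.corr_matrix, axis=1))
        assert np.all(np.abs(res.corr_matrix[~np.isnan(res.corr_matrix)]) <= 1.0)

    def test_degenerate_atrophy_errors(self, study82):
        _, c, _, _ = study82
        with pytest.raises(ValueError, match="degenerate"):
            repeated_seed_scan(c, make_map(c, np.ones(c.n)))

    def test_misaligned_regions_error(self, study82):
        _, c, amap, _ = study82
        bad = AtrophyMap(
            labels=np.array([f"x{i}" for i in range(82)]),
            t_values=amap.t_values,
            p_values=amap.p_values,
        )
        with pytest.raises(ValueError, match="misaligned"):
            repeated_seed_scan(c, bad)

    def test_atrophy_scale_invariance(self, study82):
        _, c, amap, _ = study82
        res1 = repeated_seed_scan(c, amap)
        scaled = AtrophyMap(amap.labels, amap.t_values * 37.2, amap.p_values)
        res2 = repeated_seed_scan(c, scaled)
        np.testing.assert_allclose(res1.corr_matrix, res2.corr_matrix, atol=1e-12)

    def test_max_r_monotone_in_time_grid(self, study82):
        _, c, amap, _ = study82
        short = repeated_seed_scan(c, amap, times=default_times(30))
        long = repeated_seed_scan(c, amap, times=default_times(50))
        assert np.all(long.max_r >= short.max_r - 1e-14)

    def test_seed_magnitude_irrelevant(self, study82):
        # Pearson correlation is invariant to the seed amplitude
        _, c, amap, _ = study82
        dec = build_laplacian(c)
        pair = c.regions.homologue_pairs()[3]
        f0 = bilateral_seed_vector(c.regions, pair)
        r1 = correlation_trace(propagate(dec, f0, default_times()), amap, pair)
        r2 = correlation_trace(propagate(dec, 5.0 * f0, default_times()), amap, pair)
        np.testing.assert_allclose(r1[1:], r2[1:], atol=1e-12)

    def test_output_tables(self, study82, tmp_path):
        _, c, amap, _ = study82
        res = repeated_seed_scan(c, amap)
        res.to_tsv(tmp_path / "seeds.tsv")
        res.surface_to_tsv(tmp_path / "surface.tsv")
        frame = res.to_frame()
        assert list(frame.columns) == ["seed_label", "max_r", "t_star", "p", "p_fwe"]
        assert frame["max_r"].is_monotonic_decreasing

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=10, deadline=None)
    def test_scale_invariance_property(self, scale):
        spec = SyntheticSpec(rng_seed=9, seed_pair=1, t_star=8.0)
        c = synth_connectome(spec)
        amap, _ = synth_atrophy(spec, c)
        base = repeated_seed_scan(c, amap)
        scaled = repeated_seed_scan(
            c, AtrophyMap(amap.labels, amap.t_values * scale, amap.p_values)
        )
        np.testing.assert_allclose(base.corr_matrix, scaled.corr_matrix, atol=1e-10)


def _result_with_p(p_values):
    s = len(p_values)
    return SeedScanResult(
        seed_labels=[f"seed{i}" for i in range(s)],
        seed_groups=[(2 * i, 2 * i + 1) for i in range(s)],
        times=default_times(),
        corr_matrix=np.zeros((s, 51)),
        max_r=np.zeros(s),
        t_star=np.zeros(s),
        p_values=np.asarray(p_values, dtype=float),
        p_fwe=np.asarray(p_values, dtype=float),
        n_regions_used=80,
    )


class TestFweCorrect:
    def test_bonferroni_41(self):
        res = fwe_correct(_result_with_p([0.001] + [0.5] * 40))
        assert res.p_fwe[0] == pytest.approx(0.041)

    def test_clamped_at_one(self):
        res = fwe_correct(_result_with_p([0.5, 0.6]))
        assert np.all(res.p_fwe == 1.0)

    def test_single_seed_identity(self):
        res = fwe_correct(_result_with_p([0.123]))
        assert res.p_fwe[0] == pytest.approx(0.123)

    def test_corrected_at_least_uncorrected(self, study82):
        _, c, amap, _ = study82
        res = repeated_seed_scan(c, amap)
        assert np.all(res.p_fwe >= res.p_values)
        assert np.all((res.p_fwe > 0) & (res.p_fwe <= 1))

    def test_holm_no_larger_than_bonferroni(self):
        base = _result_with_p([0.001, 0.01, 0.02, 0.5])
        holm = fwe_correct(base, method="holm")
        bonf = fwe_correct(base, method="bonferroni")
        assert np.all(holm.p_fwe <= bonf.p_fwe + 1e-15)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            fwe_correct(_result_with_p([0.5]), method="fdr")
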