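import numpy as np
import pandas as pd
import pytest

from ramanphen.chemometrics import fit_dapc, fit_pca
from ramanphen.distance_stats import (
    DistanceTable,
    anova_distances,
    compute_reference,
    correlate_band,
    distance_table,
    regress_distance_vs_covariate,
    tcd,
    tpd,
    tsd,
)
from ramanphen.spectra_io import Spectrum, SpectrumSet


def _spec(intens, sid="s"):
    x = np.asarray(intens, float)
    return Spectrum(np.arange(400.0, 400.0 + x.size), x, sample_id=sid)


def _naive_l1(a, b):
    total = 0.0
    for x, y in zip(a, b):
        total += np.sqrt((x - y) ** 2)
    return total


class TestDistances:
    def test_identical_inputs_give_zero(self):
        s = _spec([1.0, 2.0, 3.0, 4.0, 5.0])
        assert tsd(s, s) == 0.0
        assert tpd(np.arange(5.0), np.arange(5.0)) == 0.0
        assert tcd(np.arange(5.0), np.arange(5.0)) == 0.0

    def test_unit_coordinate_examples(self):
        assert tsd(_spec([1.0, 0.0]), _spec([0.0, 1.0])) == 2.0
        assert tpd(np.ones(5) + 1.0, np.ones(5)) == 5.0
        assert tcd(np.array([3.0]), np.array([1.0])) == 2.0  # single canonical

    def test_matches_naive_elementwise_loop(self, rng):
        """Oracle: a literal per-element loop over sqrt((x-y)^2)."""
        for _ in range(100):
            n = rng.integers(5, 60)
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert tsd(_spec(a), _spec(b)) == pytest.approx(_naive_l1(a, b), abs=1e-12)
            assert tpd(a[:5], b[:5]) == pytest.approx(_naive_l1(a[:5], b[:5]), abs=1e-12)
            m = min(5, n)
            assert tcd(a, b) == pytest.approx(_naive_l1(a[:m], b[:m]), abs=1e-12)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(100):
            n = rng.integers(5, 30)
            a, b, c = rng.normal(size=(3, n))
            dab = tsd(_spec(a), _spec(b))
            dba = tsd(_spec(b), _spec(a))
            dac = tsd(_spec(a), _spec(c))
            dcb = tsd(_spec(c), _spec(b))
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-9
        assert tsd(_spec(a), _spec(a)) == 0.0

    def test_l1_bound_on_unit_vectors(self, rng):
        """On vector-normalized spectra TSD <= 2 sqrt(grid length)."""
        for _ in range(20):
            n = int(rng.integers(10, 200))
            a, b = rng.normal(size=(2, n))
            a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
            assert tsd(_spec(a), _spec(b)) <= 2.0 * np.sqrt(n) + 1e-9

    def test_l2_option(self):
        assert tsd(_spec([1.0, 0.0]), _spec([0.0, 1.0]), kind="l2") == pytest.approx(np.sqrt(2))

    def test_grid_mismatch_rejected(self):
        a = Spectrum([400.0, 401.0], [1.0, 2.0])
        b = Spectrum([500.0, 501.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="grid"):
            tsd(a, b)

    def test_tpd_needs_five_components(self):
        with pytest.raises(ValueError, match="at least 5"):
            tpd(np.ones(4), np.ones(4))

    def test_tpd_tsd_zero_sets_coincide_on_low_rank_data(self, rng):
        """Lossless PCA (rank <= 5): TPD = 0 exactly when TSD = 0."""
        shapes = rng.normal(size=(3, 40))
        coeffs = rng.normal(size=(8, 3))
        X = coeffs @ shapes
        X[5] = X[2]  # duplicate spectrum -> zero distance pair
        sset = SpectrumSet(
            [Spectrum(np.arange(400.0, 440.0), r, sample_id=f"s{i}") for i, r in enumerate(X)]
        )
        pca = fit_pca(sset)
        for i in (2, 3):
            d_s = tsd(sset.spectra[i], sset.spectra[5])
            d_p = tpd(pca.transform(X[i]), pca.transform(X[5]))
            assert (d_s < 1e-9) == (d_p < 1e-9)


class TestReferenceAndTable:
    def test_reference_of_single_control(self, toy_set):
        ref = compute_reference(toy_set.subset([0]), "a")
        np.testing.assert_array_equal(ref.intensities, toy_set.spectra[0].intensities)

    def test_reference_pointwise_mean(self):
        sset = SpectrumSet(
            [_spec([0.0, 2.0], "s1"), _spec([2.0, 0.0], "s2")],
            pd.DataFrame({"sample_id": ["s1", "s2"], "condition": ["c", "c"]}),
        )
        ref = compute_reference(sset, "c")
        np.testing.assert_array_equal(ref.intensities, [1.0, 1.0])

    def test_missing_group_rejected(self, toy_set):
        with pytest.raises(ValueError, match="no spectra"):
            compute_reference(toy_set, "nope")

    def test_distance_table_shape_and_reference_zero(self, toy_set):
        pca = fit_pca(toy_set)
        dapc = fit_dapc(pca, [str(v) for v in toy_set.factor_values("condition")], 4)
        dt = distance_table(toy_set, "a", pca=pca, dapc=dapc)
        assert set(dt.table["metric"]) == {"TSD", "TPD", "TCD"}
        assert len(dt.table) == 3 * len(toy_set)
        assert (dt.table["value"] >= 0).all()
        assert "mean of processed spectra" in dt.reference_definition


class TestAnova:
    @staticmethod
    def _table(values, groups):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "metric": "TSD",
                "value": values,
                "reference_id": "ref",
            }
        )
        meta = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(values))], "group": groups}
        )
        return DistanceTable(df, "synthetic"), meta

    def test_null_rejection_rate_controlled(self, rng):
        """Two groups from one distribution: alpha=0.01 rejections are rare
        over seeded repeats."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            values = rng.normal(1.0, 0.2, size=60).clip(min=0)
            dt, meta = self._table(values, ["g1"] * 30 + ["g2"] * 30)
            rep = anova_distances(dt, meta, ["group"])
            rejections += rep.anova["group"] < 0.01
        assert rejections / n_rep <= 0.05

    def test_strong_separation_detected(self, rng):
        a = rng.normal(1.0, 0.05, size=30)
        b = rng.normal(1.5, 0.05, size=30)  # 10 pooled SDs apart
        dt, meta = self._table(np.concatenate([a, b]).clip(min=0), ["g1"] * 30 + ["g2"] * 30)
        rep = anova_distances(dt, meta, ["group"])
        assert rep.anova["group"] < 0.001

    def test_only_displaced_group_significant_in_pairs(self, rng):
        a = rng.normal(1.0, 0.05, size=20)
        b = rng.normal(1.0, 0.05, size=20)
        c = rng.normal(1.6, 0.05, size=20)
        dt, meta = self._table(
            np.concatenate([a, b, c]).clip(min=0), ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        )
        rep = anova_distances(dt, meta, ["group"])
        pairs = rep.pairwise.set_index(["group_a", "group_b"])["significant"]
        assert not pairs.loc[("a", "b")]
        assert pairs.loc[("a", "c")] and pairs.loc[("b", "c")]
        assert len(rep.pairwise) == 3  # all unordered pairs

    def test_single_level_factor_rejected(self, rng):
        dt, meta = self._table(rng.random(10), ["g"] * 10)
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            anova_distances(dt, meta, ["group"])


class TestRegression:
    @staticmethod
    def _table(values, covariate):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "metric": "TSD",
                "value": values,
                "reference_id": "ref",
            }
        )
        meta = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(values))], "nitrate_percent": covariate}
        )
        return DistanceTable(df, "synthetic"), meta

    def test_exactly_linear_distances(self):
        x = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        dt, meta = self._table(2.0 - 0.015 * x, x)
        slope, intercept, r = regress_distance_vs_covariate(dt, meta, "nitrate_percent")
        assert slope == pytest.approx(-0.015)
        assert intercept == pytest.approx(2.0)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_gives_small_r(self, rng):
        x = np.tile([0.0, 20.0, 40.0, 60.0, 80.0], 10)
        dt, meta = self._table(rng.random(50), x)
        _, _, r = regress_distance_vs_covariate(dt, meta, "nitrate_percent")
        assert abs(r) < 0.3

    def test_constant_covariate_rejected(self, rng):
        dt, meta = self._table(rng.random(10), np.full(10, 50.0))
        with pytest.raises(ValueError, match="distinct"):
            regress_distance_vs_covariate(dt, meta, "nitrate_percent")


class TestCorrelateBand:
    @staticmethod
    def _set_with_band(rng, amps, band=1150.0):
        grid = np.arange(400.0, 1801.0, 1.0)
        profile = np.exp(-0.5 * ((grid - band) / 6.0) ** 2)
        spectra = [
            Spectrum(grid, a * profile + 0.001 * rng.normal(size=grid.size), sample_id=f"s{i}")
            for i, a in enumerate(amps)
        ]
        return SpectrumSet(spectra)

    def test_proportional_measurements_correlate(self, rng):
        amps = np.linspace(0.5, 2.5, 12)
        sset = self._set_with_band(rng, amps)
        meas = {f"s{i}": a for i, a in enumerate(amps)}
        assert correlate_band(sset, 1150.0, meas) > 0.95

    def test_anti_proportional_measurements(self, rng):
        amps = np.linspace(0.5, 2.5, 12)
        sset = self._set_with_band(rng, amps)
        meas = {f"s{i}": 3.0 - a for i, a in enumerate(amps)}
        assert correlate_band(sset, 1150.0, meas) < -0.95

    def test_shuffled_measurements_fall_below_null_quantile(self, rng):
        """Permutation null: after shuffling, |R| rarely exceeds the
        n-dependent 95% null quantile 1.96/sqrt(n)."""
        n = 12
        amps = np.linspace(0.5, 2.5, n)
        sset = self._set_with_band(rng, amps)
        crit = 1.96 / np.sqrt(n - 3)  # Fisher-z approximation
        below = 0
        for _ in range(100):
            shuffled = rng.permutation(amps)
            meas = {f"s{i}": v for i, v in enumerate(shuffled)}
            r = correlate_band(sset, 1150.0, meas)
            below += np.abs(np.arctanh(r)) < crit
        assert below >= 90

    def test_band_outside_grid_rejected(self, rng):
        sset = self._set_with_band(rng, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="outside"):
            correlate_band(sset, 2500.0, {"s0": 1, "s1": 2, "s2": 3})

    def test_half_window_averaging(self, rng):
        amps = np.linspace(0.5, 2.5, 10)
        sset = self._set_with_band(rng, amps)
        meas = {f"s{i}": a for i, a in enumerate(amps)}
        assert correlate_band(sset, 1150.0, meas, half_window=5.0) > 0.95
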