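import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emonet as em
from emonet.connectivity import DEFAULT_BANDS
from emonet.errors import IntegrityError, SchemaError, ShapeError
from emonet.source_model import RegionEpochs


def _region_epochs(rng, n_ep=2, n_r=4, n_t=250, rate=250.0):
    lab = [em.EpochLabel(0, "self", "neutral", 0)] * n_ep
    return RegionEpochs(rng.standard_normal((n_ep, n_r, n_t)), rate, lab)


class TestBandDecompose:
    def test_band_edges_are_canonical(self):
        assert DEFAULT_BANDS == {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
                                 "alpha": (8.0, 13.0), "beta": (13.0, 30.0),
                                 "gamma": (30.0, 45.0)}

    def test_tone_lands_in_its_band(self):
        """A 10 Hz tone concentrates in alpha (FFT band-power oracle)."""
        t = np.arange(1000) / 250.0
        lab = [em.EpochLabel(0, "self", "neutral", 0)]
        re = RegionEpochs(np.sin(2 * np.pi * 10 * t)[None, None, :], 250.0, lab)
        out = em.band_decompose(re)
        power = {b: float((o.data ** 2).sum()) for b, o in out.items()}
        total = sum(power.values())
        assert power["alpha"] / total >= 0.90
        for b in ("delta", "theta", "beta", "gamma"):
            assert power[b] / total < 0.02

    def test_zero_signal_gives_zero_bands(self):
        lab = [em.EpochLabel(0, "self", "neutral", 0)]
        re = RegionEpochs(np.zeros((1, 3, 250)), 250.0, lab)
        out = em.band_decompose(re)
        assert len(out) == 5
        for o in out.values():
            assert np.allclose(o.data, 0.0)
            assert o.data.shape == re.data.shape

    def test_band_above_nyquist_rejected(self, rng):
        re = _region_epochs(rng, rate=50.0)
        with pytest.raises(em.errors.InvalidBandError):
            em.band_decompose(re)


class TestFcMatrix:
    def test_duplicate_region_r_one(self, rng):
        x = rng.standard_normal(250)
        m = em.fc_matrix(np.stack([x, x, rng.standard_normal(250)]))
        assert m[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_region_r_minus_one(self, rng):
        x = rng.standard_normal(250)
        m = em.fc_matrix(np.stack([x, -x]))
        assert m[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        ep = rng.standard_normal((68, 250))
        m = em.fc_matrix(ep)
        # independent oracle: explicit covariance / std-product per pair
        for i, j in [(0, 1), (5, 40), (66, 67), (13, 13)]:
            xi, xj = ep[i] - ep[i].mean(), ep[j] - ep[j].mean()
            oracle = (xi * xj).sum() / np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
            assert m[i, j] == pytest.approx(oracle, abs=1e-12)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_zero_variance_region_zeroed_not_nan(self, rng, caplog):
        ep = rng.standard_normal((3, 100))
        ep[1] = 4.2
        with caplog.at_level("WARNING"):
            m = em.fc_matrix(ep)
        assert np.all(np.isfinite(m))
        assert np.all(m[1, [0, 2]] == 0) and np.all(m[[0, 2], 1] == 0)
        assert m[1, 1] == 1.0
        assert "zero-variance" in caplog.text

    def test_too_few_samples_rejected(self):
        with pytest.raises(ShapeError):
            em.fc_matrix(np.ones((3, 2)))

    @given(scale=st.floats(0.1, 10), offset=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(99)
        ep = rng.standard_normal((4, 100))
        m0 = em.fc_matrix(ep)
        m1 = em.fc_matrix(ep * scale + offset)
        assert np.allclose(m0, m1, atol=1e-10)
        assert np.max(np.abs(m1)) <= 1.0 + 1e-12


class TestVectorize:
    def _sym(self, rng, n):
        a = rng.standard_normal((n, n))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        return m

    def test_full_atlas_vector_length(self, rng):
        fc = {b: self._sym(rng, 68) for b in em.BAND_ORDER}
        vec, names = em.vectorize_fc(fc)
        assert vec.size == 11390
        assert len(names) == 11390
        per_band = 68 * 67 // 2
        assert per_band == 2278
        assert all(n.startswith("delta:") for n in names[:per_band])
        assert all(n.startswith("gamma:") for n in names[-per_band:])

    def test_smallest_nondegenerate_case(self, rng):
        m = self._sym(rng, 3)
        vec, names = em.vectorize_fc({"gamma": m}, bands=("gamma",))
        assert vec.size == 3
        assert np.allclose(vec, [m[0, 1], m[0, 2], m[1, 2]])
        assert names == ["gamma:0|1", "gamma:0|2", "gamma:1|2"]

    @pytest.mark.parametrize("n_regions", [2, 3, 10, 68])
    def test_feature_count_law(self, rng, n_regions):
        fc = {b: self._sym(rng, n_regions) for b in em.BAND_ORDER}
        vec, _ = em.vectorize_fc(fc)
        assert vec.size == 5 * n_regions * (n_regions - 1) // 2

    def test_round_trip(self, rng):
        fc = {b: self._sym(rng, 7) for b in em.BAND_ORDER}
        vec, _ = em.vectorize_fc(fc)
        back = em.devectorize_fc(vec, 7)
        for b in em.BAND_ORDER:
            assert np.allclose(back[b], fc[b], atol=1e-14)

    def test_asymmetric_rejected(self, rng):
        m = self._sym(rng, 4)
        m[0, 1] += 1e-6
        with pytest.raises(IntegrityError):
            em.vectorize_fc({b: m for b in em.BAND_ORDER})

    def test_missing_band_rejected(self, rng):
        fc = {b: self._sym(rng, 4) for b in ("delta", "theta")}
        with pytest.raises(SchemaError):
            em.vectorize_fc(fc)


class TestFeatureTable:
    def test_build_from_band_epochs(self, rng):
        re = _region_epochs(rng, n_ep=3, n_r=5)
        bands = em.band_decompose(re)
        ft = em.build_feature_table(bands)
        assert ft.X.shape == (3, 5 * 10)
        assert np.all(np.abs(ft.X) <= 1.0)
        assert ft.band_columns("beta").size == 10

    def test_csv_round_trip(self, tmp_path, rng):
        re = _region_epochs(rng, n_ep=2, n_r=3)
        ft = em.build_feature_table(em.band_decompose(re))
        p = tmp_path / "features.csv"
        ft.to_csv(p)
        back = em.FeatureTable.from_csv(p)
        assert np.allclose(back.X, ft.X, atol=1e-12)
        assert back.feature_names == ft.feature_names
        assert list(back.y) == list(ft.y)

    def test_planted_pair_visible_in_gamma_features(self, planted_features):
        """The (1,5) gamma coupling planted in (positive, vr) separates that
        condition from every other, matching a source-level oracle."""
        ft = planted_features
        idx = ft.band_columns("gamma")
        # locate the column for pair (1, 5) explicitly
        iu, ju = np.triu_indices(12, k=1)
        k = int(np.flatnonzero((iu == 1) & (ju == 5))[0])
        col = idx[k]
        vr = (ft.groups["scenario"] == "vr").to_numpy()
        pos = ft.y == "positive"
        planted_mean = ft.X[vr & pos, col].mean()
        other_mean = np.abs(ft.X[~(vr & pos), col]).mean()
        assert planted_mean > other_mean + 0.2
        assert planted_mean > 0.4
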