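import numpy as np
import pytest

import emonet as em
from emonet.errors import InvalidSpecError
from emonet.synthetic import RatingSpec, simulate_song_sources


class TestMakeLeadField:
    def test_study_faithful_dimensions(self):
        lf = em.make_lead_field(59, 68, 68, seed=1)
        assert lf.gain.shape == (59, 68)
        assert lf.n_regions == 68
        assert len(lf.region_names) == 68
        assert np.bincount(lf.region_of_source, minlength=68).min() == 1
        assert sum(n.endswith("-lh") for n in lf.region_names) == 34
        assert lf.metadata["conductivities_S_per_m"] == {
            "scalp": 1.0, "skull": 0.0125, "brain": 1.0}

    def test_identity_fixture(self):
        lf = em.make_lead_field(4, 4, 4, identity=True)
        assert np.array_equal(lf.gain, np.eye(4))
        assert np.array_equal(lf.region_of_source, [0, 1, 2, 3])

    def test_deterministic_under_seed(self):
        a = em.make_lead_field(16, 20, 10, seed=9)
        b = em.make_lead_field(16, 20, 10, seed=9)
        assert np.array_equal(a.gain, b.gain)
        c = em.make_lead_field(16, 20, 10, seed=10)
        assert not np.array_equal(a.gain, c.gain)

    def test_full_column_rank_when_overdetermined(self):
        lf = em.make_lead_field(30, 20, 10, seed=0)
        assert np.linalg.matrix_rank(lf.gain) == 20

    def test_more_regions_than_sources_rejected(self):
        with pytest.raises(InvalidSpecError):
            em.make_lead_field(10, 5, 8)

    def test_hdf5_round_trip(self, tmp_path):
        lf = em.make_lead_field(8, 10, 5, seed=3)
        p = tmp_path / "lf.h5"
        em.save_lead_field(lf, p)
        back = em.load_lead_field(p)
        assert np.array_equal(back.gain, lf.gain)
        assert np.array_equal(back.region_of_source, lf.region_of_source)
        assert back.region_names == lf.region_names
        assert back.metadata["conductivities_S_per_m"]["skull"] == 0.0125


class TestSimulateSession:
    def test_label_bookkeeping(self, small_lead_field):
        spec = em.SimSpec(n_subjects=2, songs_per_class=2, duration_s=2.0,
                          rate=250.0, seed=1)
        songs, gt = em.simulate_session(small_lead_field, spec)
        assert len(songs) == 2 * 2 * 3 * 2
        per = {}
        for s in songs:
            per.setdefault((s.label.subject, s.label.scenario), []).append(
                s.label.song)
        for key, nums in per.items():
            assert sorted(nums) == list(range(6))  # classes x songs_per_class
        assert len(gt["song_labels"]) == 2 * 2 * 6

    def test_deterministic_under_seed(self, small_lead_field):
        spec = em.SimSpec(n_subjects=1, songs_per_class=1, duration_s=2.0,
                          rate=250.0, seed=3)
        a, _ = em.simulate_session(small_lead_field, spec)
        b, _ = em.simulate_session(small_lead_field, spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.recording.data, sb.recording.data)

    def test_null_model_mean_correlation_near_zero(self, small_lead_field):
        """No planted coupling: source-level band FC averages to ~0."""
        spec = em.SimSpec(n_subjects=1, scenarios=("self",),
                          classes=("neutral",), songs_per_class=1,
                          duration_s=40.0, rate=250.0, seed=8)
        rng = np.random.default_rng(0)
        src = simulate_song_sources(small_lead_field, spec, "neutral",
                                    "self", rng)
        n_ep, n_t = 40, 250
        rs = []
        for e in range(n_ep):
            m = em.fc_matrix(src[:, e * n_t:(e + 1) * n_t])
            iu, ju = np.triu_indices(12, k=1)
            rs.append(m[iu, ju])
        rs = np.concatenate(rs)
        assert abs(rs.mean()) < 3 / np.sqrt(rs.size * n_t / 10)

    def test_planted_coupling_recovered_by_source_oracle(self, small_lead_field):
        """gamma rho=0.9 in (positive, vr): the band-limited source
        correlation of the planted pair far exceeds the null class."""
        pair = em.PlantedPair(1, 5, "gamma", 0.9)
        spec = em.SimSpec(n_subjects=1, songs_per_class=1, duration_s=20.0,
                          rate=250.0,
                          planted_pairs={("positive", "vr"): [pair]}, seed=2)
        from emonet.preprocess import design_bandpass_fir, _filter_zero_phase
        kernel = design_bandpass_fir(30.0, 45.0, 250.0, max_taps=2000)

        def gamma_r(cls, scen, seed_stream):
            src = simulate_song_sources(small_lead_field, spec, cls, scen,
                                        np.random.default_rng(seed_stream))
            g = _filter_zero_phase(src, kernel)
            return np.corrcoef(g[1], g[5])[0, 1]

        r_planted = gamma_r("positive", "vr", 1)
        r_null = gamma_r("negative", "vr", 1)
        assert r_planted > 0.8
        assert abs(r_null) < 0.3
        assert r_planted > r_null + 0.5

    @pytest.mark.parametrize("rho_pair", [(0.0, 0.3), (0.3, 0.6), (0.6, 0.9)])
    def test_planted_effect_monotone_in_rho(self, small_lead_field, rho_pair):
        from emonet.preprocess import design_bandpass_fir, _filter_zero_phase
        kernel = design_bandpass_fir(30.0, 45.0, 250.0, max_taps=2000)
        rs = []
        for rho in rho_pair:
            spec = em.SimSpec(
                n_subjects=1, songs_per_class=1, duration_s=20.0, rate=250.0,
                planted_pairs={("positive", "vr"):
                               [em.PlantedPair(1, 5, "gamma", rho)]}, seed=6)
            src = simulate_song_sources(small_lead_field, spec, "positive",
                                        "vr", np.random.default_rng(13))
            g = _filter_zero_phase(src, kernel)
            rs.append(abs(np.corrcoef(g[1], g[5])[0, 1]))
        assert rs[1] > rs[0]

    def test_invalid_band_rejected(self, small_lead_field):
        with pytest.raises(InvalidSpecError):
            em.SimSpec(planted_pairs={("positive", "vr"):
                                      [em.PlantedPair(0, 1, "mu", 0.5)]})

    def test_sensor_snr_honoured(self, small_lead_field):
        spec = em.SimSpec(n_subjects=1, scenarios=("self",),
                          classes=("neutral",), songs_per_class=1,
                          duration_s=20.0, rate=250.0, noise_snr=3.0, seed=5)
        songs, _ = em.simulate_session(small_lead_field, spec)
        rec = songs[0].recording
        rng = np.random.default_rng(np.random.SeedSequence([5, 7]).spawn(1)[0])
        clean = small_lead_field.gain @ simulate_song_sources(
            small_lead_field, spec, "neutral", "self", rng)[
                small_lead_field.region_of_source]
        noise = rec.data - clean
        snr = np.sqrt((clean ** 2).mean() / (noise ** 2).mean())
        assert snr == pytest.approx(3.0, rel=0.05)


class TestSimulateRatings:
    def test_configured_means_recovered(self):
        """Reported means 4.69 (self) vs 3.00 (vr) reproduced within 3 SE."""
        spec = RatingSpec({("SAM", "pleasure", "negative", "self"): 4.69,
                           ("SAM", "pleasure", "negative", "vr"): 3.00},
                          1.5, 16, seed=0)
        means_self, means_vr = [], []
        for s in range(30):
            spec.seed = s
            tab = em.simulate_ratings(spec)
            means_self.append(tab[tab.scenario == "self"].score.mean())
            means_vr.append(tab[tab.scenario == "vr"].score.mean())
        se = 1.5 / np.sqrt(16 * 30)
        assert abs(np.mean(means_self) - 4.69) < 3 * se + 0.1  # rounding bias
        assert abs(np.mean(means_vr) - 3.00) < 3 * se + 0.1

    def test_degenerate_sd_gives_rounded_mean(self):
        spec = RatingSpec({("SAM", "pleasure", "negative", "self"): 4.69,
                           ("SAM", "pleasure", "negative", "vr"): 3.00},
                          0.0, 8, seed=0)
        tab = em.simulate_ratings(spec)
        assert set(tab[tab.scenario == "self"].score) == {5.0}
        assert set(tab[tab.scenario == "vr"].score) == {3.0}

    def test_scores_within_bounds(self):
        tab = em.simulate_ratings(em.default_rating_spec(seed=1))
        for scale, (lo, hi) in em.SCALE_BOUNDS.items():
            sub = tab[tab.scale == scale].score
            assert sub.between(lo, hi).all()
            assert np.allclose(sub, np.round(sub))

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(InvalidSpecError):
            RatingSpec({("SAM", "pleasure", "negative", "self"): 12.0}, 1.0, 8)

    def test_deterministic(self):
        a = em.simulate_ratings(em.default_rating_spec(seed=5))
        b = em.simulate_ratings(em.default_rating_spec(seed=5))
        assert a.equals(b)


class TestEdfExport:
    def test_round_trip_through_independent_reader(self, tmp_path, rng):
        rec = em.Recording(rng.standard_normal((4, 750)) * 40, 250.0,
                           ["C3", "C4", "O1", "O2"])
        path = tmp_path / "rec.edf"
        em.write_edf(path, rec)
        back = em.read_recording(path)
        assert back.data.shape == rec.data.shape
        assert back.rate == 250.0
        assert back.channel_names == ["C3", "C4", "O1", "O2"]
        # 16-bit quantization bounds the round-trip error
        q = 2 * np.abs(rec.data).max() / 65535
        assert np.max(np.abs(back.data - rec.data)) <= 2 * q

    def test_non_integer_rate_rejected(self, rng):
        rec = em.Recording(rng.standard_normal((2, 100)), 250.5)
        with pytest.raises(InvalidSpecError):
            em.write_edf("unused.edf", rec)
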