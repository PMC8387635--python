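import numpy as np
import pytest

import emonet as em


@pytest.fixture()
def rng():
    # fresh generator per test: draws never depend on execution order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lead_field():
    """12 regions, one source per region, 24 sensors."""
    return em.make_lead_field(24, 12, 12, seed=7)


@pytest.fixture(scope="session")
def planted_session(small_lead_field):
    """Tiny simulated session with one strong gamma coupling in (positive, vr)."""
    spec = em.SimSpec(
        n_subjects=1, songs_per_class=1, duration_s=34.0, rate=250.0,
        planted_pairs={("positive", "vr"): [em.PlantedPair(1, 5, "gamma", 0.9)]},
        noise_snr=3.0, seed=11)
    songs, gt = em.simulate_session(small_lead_field, spec)
    return spec, songs, gt


@pytest.fixture(scope="session")
def planted_features(small_lead_field, planted_session):
    """Feature table for the tiny planted session (30 epochs/song)."""
    _, songs, _ = planted_session
    inv = em.sloreta_operator(small_lead_field)
    sets = []
    for song in songs:
        es = em.preprocess_recording(song.recording, song.label,
                                     target_hz=250.0, tail_s=30.0)
        src = em.apply_inverse(es, inv)
        re = em.parcellate(src, small_lead_field.region_of_source, es.rate,
                           es.labels, small_lead_field.region_names,
                           small_lead_field.n_regions)
        sets.append(em.build_feature_table(em.band_decompose(re)))
    X = np.concatenate([t.X for t in sets])
    y = np.concatenate([t.y for t in sets])
    import pandas as pd
    groups = pd.concat([t.groups for t in sets], ignore_index=True)
    return em.FeatureTable(X, sets[0].feature_names, y, groups)


@pytest.fixture(scope="session")
def blob_features():
    """Three well-separated Gaussian classes in 10 features (6 sigma apart),
    each class a mixture of two nearby sub-blobs (the two 'songs')."""
    rng = np.random.default_rng(777)
    n_per = 40
    X = rng.standard_normal((3 * n_per, 10))
    y = np.repeat(["negative", "neutral", "positive"], n_per)
    means = np.zeros((3, 10))
    means[0, 0], means[1, 1], means[2, 2] = 6.0, 6.0, 6.0
    for k in range(3):
        X[k * n_per:(k + 1) * n_per] += means[k]
        # two sub-blobs per class, offset +-0.5 along an uninformative axis
        X[k * n_per:k * n_per + n_per // 2, 9] += 0.5
        X[k * n_per + n_per // 2:(k + 1) * n_per, 9] -= 0.5
    return X, y
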